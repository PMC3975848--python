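"""File I/O: session containers, events sidecars and standard EEG readers.

Synthetic sessions round-trip through a compressed ``.npz`` container plus a
plain-text events CSV. Real recordings in EDF or BrainVision format are read
through MNE when it is installed (``pip install vmil[eeg-io]``); EDF export
additionally needs an MNE export backend (``edfio``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, TrialEvents
from .simulate import SyntheticSession

__all__ = [
    "save_session",
    "load_session",
    "save_cohort",
    "load_cohort",
    "write_events_csv",
    "read_events_csv",
    "write_feature_table",
    "read_feature_table",
    "write_ttt_series",
    "read_ttt_series",
    "save_source_model",
    "load_source_model",
    "save_forest",
    "load_forest",
    "read_raw",
    "export_edf",
]

_EVENT_COLUMNS = [
    "trial",
    "baseline_onset",
    "planning_onset",
    "go_onset",
    "reached_sample",
    "timeout",
    "start_x",
    "start_y",
    "start_z",
    "target_x",
    "target_y",
    "target_z",
]


def write_events_csv(events: TrialEvents, path: str | Path) -> None:
    """Events sidecar: one row per trial, 0-based sample indices."""
    df = pd.DataFrame(
        {
            "trial": np.arange(events.n_trials),
            "baseline_onset": events.baseline_onset,
            "planning_onset": events.planning_onset,
            "go_onset": events.go_onset,
            "reached_sample": events.reached_sample,
            "timeout": events.timeout.astype(int),
            "start_x": events.start_pos[:, 0],
            "start_y": events.start_pos[:, 1],
            "start_z": events.start_pos[:, 2],
            "target_x": events.target_pos[:, 0],
            "target_y": events.target_pos[:, 1],
            "target_z": events.target_pos[:, 2],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# fs={events.fs} go_limit={events.go_limit}\n")
        df.to_csv(fh, index=False)


def read_events_csv(path: str | Path) -> TrialEvents:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events CSV missing columns: {sorted(missing)}")
    return TrialEvents(
        baseline_onset=df["baseline_onset"].to_numpy(),
        planning_onset=df["planning_onset"].to_numpy(),
        go_onset=df["go_onset"].to_numpy(),
        reached_sample=df["reached_sample"].to_numpy(),
        timeout=df["timeout"].to_numpy().astype(bool),
        start_pos=df[["start_x", "start_y", "start_z"]].to_numpy(),
        target_pos=df[["target_x", "target_y", "target_z"]].to_numpy(),
        fs=float(meta["fs"]),
        go_limit=float(meta["go_limit"]),
    )


def save_session(session: SyntheticSession, path: str | Path) -> None:
    """Write one synthetic session to a compressed array container."""
    ev = session.events
    np.savez_compressed(
        path,
        subject=session.subject,
        data=session.eeg.data,
        fs=session.eeg.fs,
        channel_labels=np.array(session.eeg.channel_labels),
        reference=session.eeg.reference,
        baseline_onset=ev.baseline_onset,
        planning_onset=ev.planning_onset,
        go_onset=ev.go_onset,
        reached_sample=ev.reached_sample,
        timeout=ev.timeout,
        start_pos=ev.start_pos,
        target_pos=ev.target_pos,
        go_limit=ev.go_limit,
        ttt_true=session.ttt_true,
        latent_curve=session.latent_curve,
        true_mixing=session.true_mixing,
        artifact_index=-1 if session.artifact_index is None else session.artifact_index,
    )


def load_session(path: str | Path) -> SyntheticSession:
    with np.load(path, allow_pickle=False) as z:
        fs = float(z["fs"])
        eeg = EEGRecording(
            data=z["data"],
            fs=fs,
            channel_labels=[str(c) for c in z["channel_labels"]],
            reference=str(z["reference"]),
        )
        events = TrialEvents(
            baseline_onset=z["baseline_onset"],
            planning_onset=z["planning_onset"],
            go_onset=z["go_onset"],
            reached_sample=z["reached_sample"],
            timeout=z["timeout"],
            start_pos=z["start_pos"],
            target_pos=z["target_pos"],
            fs=fs,
            go_limit=float(z["go_limit"]),
        )
        art = int(z["artifact_index"])
        return SyntheticSession(
            subject=int(z["subject"]),
            eeg=eeg,
            events=events,
            ttt_true=z["ttt_true"],
            latent_curve=z["latent_curve"],
            true_mixing=z["true_mixing"],
            artifact_index=None if art < 0 else art,
        )


def write_feature_table(
    table: pd.DataFrame, path: str | Path, c: float | None = None,
    fs: float | None = None,
) -> None:
    """Feature table to CSV with a metadata header line (subject, phase,
    trial-domain cut-off, sampling rate)."""
    meta = {
        "subject": table.attrs.get("subject", ""),
        "phase": table.attrs.get("phase", ""),
        "c": "" if c is None else c,
        "fs": "" if fs is None else fs,
    }
    with open(path, "w") as fh:
        fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        table.to_csv(fh)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split())
        table = pd.read_csv(fh, index_col=0)
    for key in ("subject", "phase", "c", "fs"):
        if meta.get(key):
            table.attrs[key] = (
                meta[key] if key == "phase" else _maybe_number(meta[key])
            )
    return table


def _maybe_number(s: str):
    try:
        f = float(s)
        return int(f) if f.is_integer() else f
    except ValueError:
        return s


def write_ttt_series(ttt, path: str | Path) -> None:
    """TTTSeries to CSV: raw and (if present) trial-domain filtered values."""
    data = {"trial": np.arange(len(ttt)), "ttt": ttt.raw,
            "timeout": ttt.timeout.astype(int)}
    if ttt.filtered is not None:
        data["ttt_filtered"] = ttt.filtered
    with open(path, "w") as fh:
        fh.write(f"# subject={'' if ttt.subject is None else ttt.subject} "
                 f"c={'' if ttt.c is None else ttt.c}\n")
        pd.DataFrame(data).to_csv(fh, index=False)


def read_ttt_series(path: str | Path):
    from .features import TTTSeries

    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh)
    return TTTSeries(
        raw=df["ttt"].to_numpy(),
        timeout=df["timeout"].to_numpy().astype(bool),
        c=float(meta["c"]) if meta.get("c") else None,
        filtered=df["ttt_filtered"].to_numpy() if "ttt_filtered" in df else None,
        subject=int(meta["subject"]) if meta.get("subject") else None,
    )


def save_source_model(model, prefix: str | Path) -> None:
    """Source model to ``<prefix>.npz`` (matrices) plus ``<prefix>.csv``
    (per-component kept flag and rejection reason)."""
    prefix = Path(prefix)
    np.savez_compressed(
        prefix.with_suffix(".npz"),
        unmixing=model.unmixing,
        mixing=model.mixing,
        topographies=model.topographies,
        lags=np.asarray(model.lags),
        kept_components=model.kept_components,
    )
    rows = []
    kept = set(int(k) for k in model.kept_components)
    for i in range(model.n_components):
        rows.append(
            {
                "component": i,
                "kept": int(i in kept),
                "rejection_reason": model.rejection_reasons.get(i, ""),
            }
        )
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".csv"), index=False)


def load_source_model(prefix: str | Path):
    from .sobi import SourceModel

    prefix = Path(prefix)
    with np.load(prefix.with_suffix(".npz")) as z:
        model = SourceModel(
            unmixing=z["unmixing"],
            mixing=z["mixing"],
            topographies=z["topographies"],
            lags=tuple(int(t) for t in z["lags"]),
            kept_components=z["kept_components"],
        )
    csv_path = prefix.with_suffix(".csv")
    if csv_path.exists():
        df = pd.read_csv(csv_path).fillna({"rejection_reason": ""})
        model.rejection_reasons = {
            int(r.component): str(r.rejection_reason)
            for r in df.itertuples()
            if r.rejection_reason
        }
    return model


_FOREST_FORMAT_VERSION = 1


def save_forest(forest, path: str | Path) -> None:
    """Persist a fitted forest (joblib, with a format version)."""
    import joblib

    joblib.dump(
        {
            "format_version": _FOREST_FORMAT_VERSION,
            "spec": forest.spec,
            "bag": forest._bag,
            "columns": forest.columns_,
            "oob_indices": forest.oob_indices_,
        },
        path,
    )


def load_forest(path: str | Path):
    import joblib

    from .model import TrialForest

    payload = joblib.load(path)
    if payload.get("format_version") != _FOREST_FORMAT_VERSION:
        raise ValueError(
            f"unsupported forest file version {payload.get('format_version')}"
        )
    forest = TrialForest(payload["spec"])
    forest._bag = payload["bag"]
    forest.columns_ = payload["columns"]
    forest.oob_indices_ = payload["oob_indices"]
    return forest


def _require_mne():
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "reading/writing standard EEG formats requires MNE: "
            "pip install vmil[eeg-io]"
        ) from exc
    return mne


def read_raw(path: str | Path) -> EEGRecording:
    """Read an EDF file or a BrainVision header (.vhdr) into an EEGRecording.

    Data are returned in microvolts (MNE loads volts internally).
    """
    mne = _require_mne()
    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG format: {path.suffix!r}")
    return EEGRecording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        reference="unknown",
    )


def export_edf(rec: EEGRecording, path: str | Path) -> None:
    """Export a recording to EDF through MNE (requires the edfio backend)."""
    mne = _require_mne()
    info = mne.create_info(
        ch_names=list(rec.channel_labels), sfreq=rec.fs, ch_types="eeg"
    )
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    raw.export(str(path), fmt="edf", overwrite=True)


def save_cohort(
    cohort: list[SyntheticSession], out_dir: str | Path
) -> list[Path]:
    """Write each session as .npz + events CSV under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sess in cohort:
        base = out_dir / f"subject{sess.subject:02d}"
        save_session(sess, base.with_suffix(".npz"))
        write_events_csv(sess.events, base.with_name(base.name + "_events.csv"))
        paths.append(base.with_suffix(".npz"))
    return paths


def load_cohort(in_dir: str | Path) -> list[SyntheticSession]:
    paths = sorted(Path(in_dir).glob("subject*.npz"))
    if not paths:
        raise FileNotFoundError(f"no subject*.npz files in {in_dir}")
    return [load_session(p) for p in paths]
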