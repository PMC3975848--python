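"""Cross-subject decoding of motor performance from bandpower features.

The modelling surface follows the Model/Results convention: build a
:class:`TTTDecoder` from per-subject feature tables and TTT series, call
``fit()`` to run leave-one-subject-out (LOSO) cross-validation, and work
with the returned :class:`DecodingResults` — per-subject predictions and
R2_mod, a ``summary()`` table, the group permutation test, and the
forest-interpretation procedures (variable importance, feature influence).

LOSO is used instead of within-subject cross-validation because trial series
are strongly autocorrelated (learning curves): trials of one subject are not
i.i.d., but subjects are exchangeable. The learner is a bagged ensemble of
regression trees with random feature subsets at each split (a random
forest), trained on trial-domain low-passed features to predict the
trial-domain low-passed, per-subject standardized TTT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingRegressor
from sklearn.tree import DecisionTreeRegressor

from .evaluate import PermutationOutcome, group_permutation_test, r2_mod, r_squared
from .features import DEFAULT_CUTOFF, TTTSeries, trial_domain_lowpass, zscore

__all__ = ["ForestSpec", "TrialForest", "TTTDecoder", "DecodingResults"]


@dataclass(frozen=True)
class ForestSpec:
    """Random-forest hyperparameters.

    ``max_features`` defaults to ceil(p / 3), the regression-forest
    convention; ``min_leaf`` of 5 keeps leaves from memorizing single trials.
    """

    n_trees: int = 500
    max_features: int | None = None
    min_leaf: int = 5
    bootstrap: bool = True
    seed: int = 0

    def resolve_max_features(self, n_features: int) -> int:
        m = (
            self.max_features
            if self.max_features is not None
            else math.ceil(n_features / 3)
        )
        if not 1 <= m <= n_features:
            raise ValueError(
                f"max_features={m} outside [1, {n_features}]"
            )
        return m


class TrialForest:
    """Bagged regression trees with retained out-of-bag row indices.

    A thin, deterministic wrapper around scikit-learn's bagging ensemble of
    CART trees with per-split random feature subsets; the out-of-bag indices
    per tree are kept for Breiman-style permutation importance.
    """

    def __init__(self, spec: ForestSpec | None = None):
        self.spec = spec or ForestSpec()
        self._bag: BaggingRegressor | None = None
        self.columns_: list[str] | None = None
        self.oob_indices_: list[np.ndarray] | None = None

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "TrialForest":
        if len(X) == 0:
            raise ValueError("empty training set")
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("row count != target count")
        if X.isna().any().any() or np.isnan(y).any():
            raise ValueError("NaN in training data")
        m = self.spec.resolve_max_features(X.shape[1])
        tree = DecisionTreeRegressor(
            max_features=m, min_samples_leaf=self.spec.min_leaf
        )
        self._bag = BaggingRegressor(
            estimator=tree,
            n_estimators=self.spec.n_trees,
            bootstrap=self.spec.bootstrap,
            random_state=self.spec.seed % (2**31),
            n_jobs=1,
        )
        self._bag.fit(X.to_numpy(dtype=float), y)
        self.columns_ = list(X.columns)
        n = len(X)
        all_rows = np.arange(n)
        self.oob_indices_ = [
            np.setdiff1d(all_rows, np.unique(samp))
            for samp in self._bag.estimators_samples_
        ]
        return self

    @property
    def trees_(self) -> list[DecisionTreeRegressor]:
        self._check_fitted()
        return list(self._bag.estimators_)  # type: ignore[union-attr]

    def _check_fitted(self) -> None:
        if self._bag is None:
            raise ValueError("forest is not fitted")

    def _check_columns(self, X: pd.DataFrame) -> None:
        if list(X.columns) != self.columns_:
            missing = set(self.columns_) - set(X.columns)  # type: ignore[arg-type]
            extra = set(X.columns) - set(self.columns_)  # type: ignore[arg-type]
            raise ValueError(
                "feature columns do not match training columns "
                f"(missing: {sorted(missing)}, unexpected: {sorted(extra)}, "
                "or column order differs)"
            )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Mean over tree outputs for each row."""
        self._check_fitted()
        self._check_columns(X)
        return self._bag.predict(X.to_numpy(dtype=float))  # type: ignore[union-attr]


class TTTDecoder:
    """Cross-subject TTT decoding model.

    Parameters
    ----------
    feature_tables : list of DataFrame
        Per-subject trials x (IC, band) log-bandpower tables with identical
        columns (see ``features.build_feature_table``).
    ttt : list of TTTSeries or ndarray
        Per-subject normalized TTT (raw, s/m).
    spec : ForestSpec
        Forest hyperparameters (seed included).
    c : float
        Trial-domain cut-off (rad/trial) used for feature filtering, the
        training target and the R2_mod denominator.
    filter_features, filter_targets : bool
        Apply the trial-domain low-pass to features / use the low-passed,
        per-subject standardized TTT as the regression target. Disabling
        ``filter_targets`` trains on the raw standardized TTT.
    """

    def __init__(
        self,
        feature_tables: list[pd.DataFrame],
        ttt: list[TTTSeries | np.ndarray],
        spec: ForestSpec | None = None,
        c: float = DEFAULT_CUTOFF,
        subjects: list[int] | None = None,
        filter_features: bool = True,
        filter_targets: bool = True,
    ):
        if len(feature_tables) != len(ttt):
            raise ValueError("feature table count != TTT series count")
        if len(feature_tables) < 2:
            raise ValueError("leave-one-subject-out needs at least 2 subjects")
        cols = list(feature_tables[0].columns)
        for t in feature_tables[1:]:
            if list(t.columns) != cols:
                raise ValueError("feature columns differ across subjects")
        self.feature_tables = feature_tables
        self.ttt_raw = [
            t.raw if isinstance(t, TTTSeries) else np.asarray(t, dtype=float)
            for t in ttt
        ]
        self.spec = spec or ForestSpec()
        self.c = c
        self.subjects = (
            list(subjects) if subjects is not None else list(range(len(ttt)))
        )
        self.filter_features = filter_features
        self.filter_targets = filter_targets

    # -- derived per-subject arrays ------------------------------------
    def _features(self, s: int) -> pd.DataFrame:
        X = self.feature_tables[s]
        if not self.filter_features:
            return X
        filt = trial_domain_lowpass(X.to_numpy(dtype=float), self.c, axis=0)
        return pd.DataFrame(filt, columns=X.columns, index=X.index)

    def _target(self, s: int) -> np.ndarray:
        z = zscore(self.ttt_raw[s])
        return trial_domain_lowpass(z, self.c) if self.filter_targets else z

    def _eval_x(self, s: int) -> np.ndarray:
        """Observed series the predictions are scored against: the held-out
        subject's standardized raw TTT (its slow part is what R2_mod credits)."""
        return zscore(self.ttt_raw[s])

    def _fold_seed(self, fold: int) -> int:
        return int(
            np.random.SeedSequence(
                entropy=self.spec.seed, spawn_key=(fold,)
            ).generate_state(1)[0]
            % (2**31)
        )

    def fit(self) -> "DecodingResults":
        """Run leave-one-subject-out cross-validation.

        For each subject, a forest is trained on the pooled trials of all
        other subjects and predicts the held-out subject's trials in order;
        no held-out row ever enters its own training set.
        """
        n_sub = len(self.feature_tables)
        feats = [self._features(s) for s in range(n_sub)]
        targets = [self._target(s) for s in range(n_sub)]
        predictions: list[np.ndarray] = []
        models: list[TrialForest] = []
        for s in range(n_sub):
            train_X = pd.concat(
                [feats[j] for j in range(n_sub) if j != s], ignore_index=True
            )
            train_y = np.concatenate([targets[j] for j in range(n_sub) if j != s])
            forest = TrialForest(replace(self.spec, seed=self._fold_seed(s)))
            forest.fit(train_X, train_y)
            predictions.append(forest.predict(feats[s]))
            models.append(forest)
        return DecodingResults(
            model=self,
            fold_models=models,
            predicted=predictions,
            train_features=feats,
            train_targets=targets,
        )


@dataclass
class DecodingResults:
    """LOSO cross-validation results.

    ``fold_models[s]`` is the forest trained with subject ``s`` held out;
    ``predicted[s]`` its predictions on that subject's trials.
    """

    model: TTTDecoder
    fold_models: list[TrialForest]
    predicted: list[np.ndarray]
    train_features: list[pd.DataFrame] = field(repr=False, default_factory=list)
    train_targets: list[np.ndarray] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        self.actual = [self.model._eval_x(s) for s in range(self.n_subjects)]
        for a, p in zip(self.actual, self.predicted):
            if len(a) != len(p):
                raise ValueError("actual and predicted lengths differ")

    @property
    def n_subjects(self) -> int:
        return len(self.model.feature_tables)

    @property
    def c(self) -> float:
        return self.model.c

    # -- prediction quality --------------------------------------------
    def r2_table(self) -> pd.DataFrame:
        """Per-subject R2, R2 denominator and R2_mod."""
        rows = []
        for s in range(self.n_subjects):
            x, y = self.actual[s], self.predicted[s]
            denom = r_squared(x, trial_domain_lowpass(x, self.c))
            rows.append(
                {
                    "subject": self.model.subjects[s],
                    "r2": r_squared(x, y),
                    "r2_lowpass": denom,
                    "r2_mod": r2_mod(x, y, self.c, denominator=denom),
                }
            )
        return pd.DataFrame(rows).set_index("subject")

    @property
    def r2_mod_values(self) -> np.ndarray:
        return self.r2_table()["r2_mod"].to_numpy()

    def group_mean(self) -> float:
        return float(self.r2_mod_values.mean())

    def group_median(self) -> float:
        return float(np.median(self.r2_mod_values))

    def permutation_test(
        self,
        n_perm: int = 10_000,
        seed: int = 0,
        aggregate: str = "mean",
        recompute_denominator: bool = False,
    ) -> PermutationOutcome:
        """Group-level significance of the aggregated R2_mod."""
        pairs = list(zip(self.actual, self.predicted))
        return group_permutation_test(
            pairs,
            c=self.c,
            n_perm=n_perm,
            seed=seed,
            aggregate=aggregate,
            recompute_denominator=recompute_denominator,
        )

    # -- interpretation -------------------------------------------------
    def variable_importance(
        self, n_repeats: int = 10, seed: int = 0
    ) -> list[pd.DataFrame]:
        """Breiman out-of-bag permutation importance per fold model."""
        from .interpret import variable_importance

        out = []
        for s in range(self.n_subjects):
            train_X = pd.concat(
                [
                    self.train_features[j]
                    for j in range(self.n_subjects)
                    if j != s
                ],
                ignore_index=True,
            )
            train_y = np.concatenate(
                [self.train_targets[j] for j in range(self.n_subjects) if j != s]
            )
            table = variable_importance(
                self.fold_models[s], train_X, train_y, n_repeats=n_repeats, seed=seed
            )
            table["fold"] = self.model.subjects[s]
            out.append(table)
        return out

    def importance_summary(
        self, n_repeats: int = 10, seed: int = 0, top_k: int = 3
    ) -> pd.DataFrame:
        from .interpret import aggregate_importance

        return aggregate_importance(
            self.variable_importance(n_repeats=n_repeats, seed=seed), top_k=top_k
        )

    def feature_influence(self, variable: str, fold: int = 0, grid_size: int = 50):
        """Value-substitution influence curve of one variable for one fold."""
        from .interpret import feature_influence

        train_X = pd.concat(
            [self.train_features[j] for j in range(self.n_subjects) if j != fold],
            ignore_index=True,
        )
        return feature_influence(
            self.fold_models[fold], train_X, variable, grid_size=grid_size
        )

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        """Human-readable results table."""
        table = self.r2_table()
        lines = [
            "Cross-subject TTT decoding (leave-one-subject-out)",
            "=" * 52,
            f"subjects: {self.n_subjects}   "
            f"trials/subject: {len(self.actual[0])}   "
            f"features: {self.model.feature_tables[0].shape[1]}",
            f"forest: {self.model.spec.n_trees} trees, "
            f"min leaf {self.model.spec.min_leaf}, "
            f"cut-off c = {self.c} rad/trial",
            "-" * 52,
            table.round(3).to_string(),
            "-" * 52,
            f"group mean R2_mod:   {self.group_mean():+.3f}",
            f"group median R2_mod: {self.group_median():+.3f}",
        ]
        return "\n".join(lines)

    def plot_prediction(self, subject: int = 0, ax=None):
        """Low-passed observed series vs prediction for one subject."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        x = self.actual[subject]
        ax.plot(trial_domain_lowpass(x, self.c), "k-", label="observed (low-pass)")
        ax.plot(self.predicted[subject], "k--", label="predicted")
        ax.set_xlabel("trial")
        ax.set_ylabel("standardized TTT")
        ax.set_title(
            f"subject {self.model.subjects[subject]}: "
            f"R2_mod = {self.r2_mod_values[subject]:.2f}"
        )
        ax.legend(frameon=False)
        return ax
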