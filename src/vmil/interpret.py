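"""Forest interpretation: permutation importance and value-substitution
influence curves.

Variable importance follows Breiman's out-of-bag formulation: for each tree,
the mean squared error on its out-of-bag rows is compared with the error
after permuting one variable's values among those rows; the averaged error
increase is the variable's importance. Uninformative variables score near
zero, and duplicated informative variables share (and therefore dilute)
their importance.

Feature influence traces a variable's marginal effect on the ensemble
output: substitute a fixed value v-hat for the variable in every training
row, predict, and average — swept over a grid spanning the variable's
training range (values outside that range act like the nearest endpoint, a
property of axis-aligned tree partitions). This is a partial-dependence
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import TrialForest

__all__ = [
    "variable_importance",
    "InfluenceCurve",
    "feature_influence",
    "aggregate_importance",
]


def variable_importance(
    forest: TrialForest,
    X: pd.DataFrame,
    y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Breiman out-of-bag permutation importance for every feature column.

    Returns a DataFrame indexed by variable with the mean out-of-bag error
    increase (target-variance units) and its dense rank (1 = most important).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    forest._check_fitted()
    forest._check_columns(X)
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n_features = Xv.shape[1]
    increase = np.zeros(n_features)
    n_trees_used = 0
    for tree, oob in zip(forest.trees_, forest.oob_indices_):
        if len(oob) == 0:
            continue
        n_trees_used += 1
        Xo = Xv[oob]
        yo = y[oob]
        base = float(((tree.predict(Xo) - yo) ** 2).mean())
        k = len(oob)
        for j in range(n_features):
            # batch the repeats into one predict call per (tree, variable)
            stacked = np.tile(Xo, (n_repeats, 1))
            col = np.tile(Xo[:, j], n_repeats).reshape(n_repeats, k)
            rng.permuted(col, axis=1, out=col)
            stacked[:, j] = col.ravel()
            err = ((tree.predict(stacked) - np.tile(yo, n_repeats)) ** 2).reshape(
                n_repeats, k
            ).mean(axis=1)
            increase[j] += float(err.mean()) - base
    if n_trees_used == 0:
        raise ValueError("no tree has out-of-bag rows; cannot compute importance")
    increase /= n_trees_used
    out = pd.DataFrame(
        {"importance": increase},
        index=pd.Index(forest.columns_, name="variable"),
    )
    out["rank"] = (
        out["importance"].rank(ascending=False, method="min").astype(int)
    )
    return out


@dataclass
class InfluenceCurve:
    """Average model output as one variable is swept over its training range."""

    variable: str
    grid: np.ndarray  # substituted values, training min..max
    mean_prediction: np.ndarray  # target units

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.mean_prediction):
            raise ValueError("grid and curve lengths differ")

    def slope_sign(self) -> int:
        """Sign of the overall trend (endpoint difference)."""
        return int(np.sign(self.mean_prediction[-1] - self.mean_prediction[0]))

    def spearman(self) -> float:
        """Rank correlation of the curve with the grid (monotonicity score)."""
        from scipy.stats import spearmanr

        return float(spearmanr(self.grid, self.mean_prediction).statistic)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        ax.plot(self.grid, self.mean_prediction, "k-")
        ax.set_xlabel(f"{self.variable} (log bandpower)")
        ax.set_ylabel("mean predicted TTT (standardized)")
        return ax


def feature_influence(
    forest: TrialForest,
    training_features: pd.DataFrame,
    variable: str,
    grid_size: int = 50,
) -> InfluenceCurve:
    """Value-substitution influence of ``variable`` on the ensemble output."""
    forest._check_fitted()
    if variable not in training_features.columns:
        raise ValueError(f"unknown variable {variable!r}")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    lo = float(training_features[variable].min())
    hi = float(training_features[variable].max())
    grid = np.linspace(lo, hi, grid_size)
    X = training_features.copy()
    curve = np.empty(grid_size)
    for i, v in enumerate(grid):
        X[variable] = v
        curve[i] = float(forest.predict(X).mean())
    return InfluenceCurve(variable=variable, grid=grid, mean_prediction=curve)


def aggregate_importance(
    fold_tables: list[pd.DataFrame], top_k: int = 3
) -> pd.DataFrame:
    """Cross-fold summary of per-fold importance tables.

    Returns per-variable mean and sd of importance, the per-fold ranks, and a
    consistency score: the fraction of folds where the variable ranks in the
    top ``top_k``.
    """
    if not fold_tables:
        raise ValueError("need at least one fold table")
    imp = pd.concat(
        [t["importance"].rename(i) for i, t in enumerate(fold_tables)], axis=1
    )
    ranks = pd.concat(
        [t["rank"].rename(i) for i, t in enumerate(fold_tables)], axis=1
    )
    out = pd.DataFrame(
        {
            "mean_importance": imp.mean(axis=1),
            "sd_importance": imp.std(axis=1, ddof=0),
            "consistency": (ranks <= top_k).mean(axis=1),
        }
    )
    out["mean_rank"] = ranks.mean(axis=1)
    for i in ranks.columns:
        out[f"rank_fold{i}"] = ranks[i]
    return out.sort_values("mean_importance", ascending=False)
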