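"""SVM recursive feature elimination with frequency voting.

With an RBF kernel there is no per-feature primal weight, so feature
importance uses the standard kernel generalisation of weight-based RFE
(Guyon et al.): with the dual solution held fixed, feature f's score is
the change in the margin objective (1/2) a' K a when f is removed from
the kernel computation.  One feature (the lowest-scoring) is eliminated
per iteration and the SVM is refit on the survivors.

The voting scheme runs RFE inside every outer LOOCV fold for several
stopping sizes N (default 4, 5, 6), pools the survivor sets, ranks
features by selection frequency, and returns the top four as the final
selection.  Ties are broken by better (lower) mean elimination rank and
then by lower column index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classification import (
    CvRun,
    SvmConfig,
    _fold_weights,
    _inner_loo_grid_search,
    fit_svm_precomputed,
    nested_loocv,
    standardize_train_test,
)

__all__ = ["RfeRanking", "CandidatePool", "rfe_rank", "select_by_frequency_voting", "evaluate_selected"]


@dataclass
class RfeRanking:
    """Outcome of one elimination run.

    ``elimination_order`` lists 0-based column indices, first-eliminated
    first; ``survivors`` are the columns still standing, in original
    column order.
    """

    elimination_order: list
    survivors: list
    n_features: int

    def survivor_set(self, n: int) -> list:
        """The n features retained when stopping the elimination at n."""
        if n < len(self.survivors) or n > self.n_features:
            raise ValueError(
                f"survivor_set({n}) needs {len(self.survivors)} <= n <= {self.n_features}"
            )
        eliminated = set(self.elimination_order[: self.n_features - n])
        return [f for f in range(self.n_features) if f not in eliminated]

    @property
    def importance_rank(self) -> np.ndarray:
        """Rank 1 = most important (eliminated last or never)."""
        rank = np.empty(self.n_features, dtype=float)
        for step, f in enumerate(self.elimination_order):
            rank[f] = self.n_features - step
        for j, f in enumerate(sorted(self.survivors)):
            rank[f] = len(self.survivors) - j  # arbitrary but deterministic
        return rank


def _per_feature_sq_diffs(X: np.ndarray) -> np.ndarray:
    """(p, n, n) array of per-feature pairwise squared differences."""
    diff = X.T[:, :, None] - X.T[:, None, :]
    return diff * diff


def rfe_rank(X, y, config: SvmConfig = None, n_stop: int = 1, c: float = None, gamma: float = None) -> RfeRanking:
    """Rank features by recursive elimination under the kernel-RFE criterion.

    ``X`` is a training-fold feature matrix (standardised internally).
    If ``c``/``gamma`` are not given they are chosen once, by inner-LOOCV
    grid search on all features, and held fixed during elimination.
    Deterministic given the data and configuration.
    """
    config = config or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if not 1 <= n_stop <= p:
        raise ValueError(f"n_stop must be in 1..{p}")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    Xs = standardize_train_test(X)
    weights = _fold_weights(y, config.class_weight)
    if c is None or gamma is None:
        (c, gamma), _ = _inner_loo_grid_search(Xs, y, config, weights)

    d2f = _per_feature_sq_diffs(Xs)
    surviving = list(range(p))
    order = []
    while len(surviving) > n_stop:
        d2 = d2f[surviving].sum(axis=0)
        K = np.exp(-gamma * d2)
        (a, sv, _), _ = fit_svm_precomputed(K, y, c, weights)
        Ksv = K[np.ix_(sv, sv)]
        base = a @ Ksv @ a
        d2_sv = d2f[np.ix_(surviving, sv, sv)]
        K_minus = Ksv[None, :, :] * np.exp(gamma * d2_sv)
        crit = 0.5 * np.abs(base - np.einsum("i,fij,j->f", a, K_minus, a))
        worst = int(np.argmin(crit))  # ties: lowest position, deterministic
        order.append(surviving.pop(worst))
    return RfeRanking(elimination_order=order, survivors=surviving, n_features=p)


@dataclass
class CandidatePool:
    """Pooled RFE selections over outer folds and stopping sizes."""

    counts: np.ndarray  # per-feature selection frequency
    final_selection: list  # top-4 features, 0-based column indices
    mean_rank: np.ndarray  # mean elimination rank per feature (1 = best)
    n_values: tuple
    n_folds: int

    def __post_init__(self):
        if len(self.final_selection) != 4:
            raise ValueError("final selection must have exactly 4 features")


def select_by_frequency_voting(X, y, config: SvmConfig = None, n_values=(4, 5, 6)) -> CandidatePool:
    """Frequency-voting biomarker selection over nested LOOCV loops.

    For each outer fold (training on n-1 subjects) and each stopping
    size N, the N RFE survivors enter a candidate pool; features are
    ranked by pooled selection frequency and the top four returned.
    """
    config = config or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if n < 5:
        raise ValueError("frequency voting needs >= 5 subjects")
    n_values = tuple(sorted(int(v) for v in n_values))
    if not n_values:
        raise ValueError("n_values must be non-empty")
    if n_values[0] < 1 or n_values[-1] > p:
        raise ValueError("n_values out of range")

    counts = np.zeros(p)
    rank_sum = np.zeros(p)
    for i in range(n):
        tr = np.arange(n) != i
        ranking = rfe_rank(X[tr], y[tr], config=config, n_stop=1)
        for nv in n_values:
            counts[ranking.survivor_set(nv)] += 1
        rank_sum += ranking.importance_rank
    mean_rank = rank_sum / n
    # order: frequency desc, mean elimination rank asc (better), index asc
    order = sorted(range(p), key=lambda f: (-counts[f], mean_rank[f], f))
    return CandidatePool(
        counts=counts,
        final_selection=order[:4],
        mean_rank=mean_rank,
        n_values=n_values,
        n_folds=n,
    )


def evaluate_selected(X, y, config: SvmConfig = None, selection=None) -> CvRun:
    """Nested LOOCV restricted to a selected feature subset."""
    if selection is None or len(selection) == 0:
        raise ValueError("selection must be a non-empty index list")
    return nested_loocv(X, y, config=config, feature_subset=list(selection))
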