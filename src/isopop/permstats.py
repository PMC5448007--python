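"""Resampling machinery shared by the IBD, ROH and Ne modules.

Group contrasts in this package are never judged with asymptotic null
distributions: the observed statistic (a Wilcoxon rank sum, or any callable)
is compared against its distribution under random relabelling of
*individuals*.  Pairwise quantities (per-pair IBD totals) are handled by
re-deriving the within-group pair sets from each permuted label vector, so
the exchangeable unit is always the individual — permuting pairs directly
would break exchangeability.

Bootstrap confidence intervals use the percentile method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PermutationResult",
    "wilcoxon_rank_sum",
    "label_permutation_test",
    "bootstrap_ci",
]


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None = None


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank sum of ``x`` in the pooled sample, with midranks for ties.

    This is the raw two-sample rank-sum statistic; no asymptotic p-value is
    attached — significance always comes from :func:`label_permutation_test`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum())


def _pair_values_by_group(matrix: np.ndarray, labels: np.ndarray,
                          group: str) -> np.ndarray:
    idx = np.flatnonzero(labels == group)
    if idx.size < 2:
        raise ValueError(f"group {group!r} has fewer than 2 individuals")
    sub = matrix[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return sub[iu]


def label_permutation_test(
    values,
    labels: Sequence[str],
    statistic: Callable[[np.ndarray, np.ndarray], float] = wilcoxon_rank_sum,
    n_perm: int = 10_000,
    pairwise: bool = False,
    seed: int | None = None,
) -> PermutationResult:
    """Two-group permutation test with individual-level relabelling.

    Parameters
    ----------
    values
        If ``pairwise`` is False: one value per individual (array-like,
        aligned with ``labels``).  If True: a symmetric n x n matrix of
        per-pair values; each (permuted) labelling contributes the values of
        within-group pairs of each group to the statistic.
    labels
        Exactly two distinct labels must be present.
    statistic
        Callable ``statistic(group_a_values, group_b_values)``.
    n_perm
        Number of label permutations.
    seed
        Seed for the permutation stream.

    Returns
    -------
    PermutationResult
        Two-sided p-value with the +1 correction:
        ``p = (1 + #{|s_perm - mean(null)| >= |s_obs - mean(null)|}) / (n_perm + 1)``.
    """
    labels = np.asarray(labels, dtype=object)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    ga, gb = groups
    rng = np.random.default_rng(seed)

    if pairwise:
        matrix = np.asarray(values, dtype=float)
        if matrix.shape != (labels.size, labels.size):
            raise ValueError("pairwise values must be an n x n matrix")

        def stat_for(lab):
            return statistic(
                _pair_values_by_group(matrix, lab, ga),
                _pair_values_by_group(matrix, lab, gb),
            )

    else:
        vals = np.asarray(values, dtype=float)
        if vals.shape != labels.shape:
            raise ValueError("values must align with labels")

        def stat_for(lab):
            return statistic(vals[lab == ga], vals[lab == gb])

    observed = float(stat_for(labels))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stat_for(rng.permutation(labels))
    center = null.mean()
    dev = abs(observed - center)
    p = (1.0 + np.sum(np.abs(null - center) >= dev - 1e-12)) / (n_perm + 1.0)
    return PermutationResult(observed, null, float(p), n_perm, seed)


def bootstrap_ci(
    units,
    estimator: Callable[[np.ndarray], float],
    B: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
    max_failures: float = 0.01,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ``estimator`` over resampled ``units``.

    ``units`` may be a 1-D array of values or a sequence of arbitrary
    resampling units (e.g. per-pair segment lists); the estimator receives a
    resampled array/list of the same length.  Replicates in which the
    estimator raises are redrawn, up to ``max_failures * B`` times.
    """
    units = np.asarray(units, dtype=object) if not isinstance(
        units, np.ndarray) else units
    n = len(units)
    if n < 2:
        raise ValueError("need at least 2 resampling units")
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    failures = 0
    max_fail = max(1, int(max_failures * B))
    i = 0
    while i < B:
        idx = rng.integers(0, n, size=n)
        try:
            reps[i] = estimator(units[idx])
        except (ValueError, ZeroDivisionError, FloatingPointError):
            failures += 1
            if failures > max_fail:
                raise ValueError(
                    f"estimator failed in more than {max_failures:.0%} of "
                    "bootstrap replicates"
                )
            continue
        i += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
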