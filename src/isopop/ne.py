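"""Effective population size from IBD sharing.

When a pair of individuals finds a common ancestor g generations back,
recombination has whittled the shared material into segments whose lengths
shrink with g; and the chance of finding a recent common ancestor is
inversely proportional to the effective population size Ne.  The constant-
size closed form used here inverts that relationship: with f the mean
fraction of the genome a random pair shares in segments of at least u cM,

    Ne = 50 * (1 - f + sqrt(1 - f)) / (u * f)

which behaves as Ne ≈ 100 / (u * f) for small f.  A small isolate has large
f and tiny Ne; an outbred population shares almost nothing above u = 7 cM
and its estimate runs into the tens or hundreds of thousands.

Inference: percentile-bootstrap confidence intervals (resampling detected
segments, or pairs as the statistically conservative unit) and permutation
tests on the between-group difference in f.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .permstats import PermutationResult, bootstrap_ci, label_permutation_test
from .segments import IBDSegment

__all__ = ["NeEstimate", "sharing_fraction", "pair_sharing_totals",
           "ne_point", "ne_bootstrap", "ne_permutation_diff", "estimate_ne"]


@dataclass
class NeEstimate:
    f: float
    u_cm: float
    ne: float
    ci: tuple[float, float] | None
    genome_cm: float
    n_pairs: int
    p_value: float | None = None

    def __str__(self) -> str:
        ci = f" (95% CI {self.ci[0]:.1f}-{self.ci[1]:.1f})" if self.ci else ""
        return (f"Ne = {self.ne:.1f}{ci} from f = {self.f:.5f} at "
                f"u = {self.u_cm:g} cM over {self.n_pairs} pairs")


def pair_sharing_totals(segments: list[IBDSegment], pairs,
                        u_cm: float) -> np.ndarray:
    """Total cM shared in segments >= u, per listed pair (zeros included)."""
    pairs = [tuple(sorted(map(str, p))) for p in pairs]
    if not pairs:
        raise ValueError("empty pair set")
    idx = {p: k for k, p in enumerate(pairs)}
    tot = np.zeros(len(pairs))
    for seg in segments:
        if seg.length_cm >= u_cm:
            k = idx.get(tuple(sorted((seg.sample_a, seg.sample_b))))
            if k is not None:
                tot[k] += seg.length_cm
    return tot


def sharing_fraction(segments: list[IBDSegment], pairs, u_cm: float,
                     genome_cm: float) -> float:
    """Mean over pairs of (total cM in that pair's segments >= u)/genome_cm.

    ``pairs`` must enumerate every within-group pair — pairs sharing
    nothing count as zero, they are not dropped.
    """
    if genome_cm <= 0:
        raise ValueError("genome_cm must be > 0")
    return float(pair_sharing_totals(segments, pairs, u_cm).mean() / genome_cm)


def ne_point(f: float, u_cm: float) -> float:
    """Closed-form constant-size Ne from the sharing fraction f at
    threshold u; decreasing in both f and u; f=1 maps to 0."""
    if u_cm <= 0:
        raise ValueError("u_cm must be > 0")
    if f == 0:
        raise ValueError("no sharing above threshold; Ne unbounded")
    if not (0.0 < f <= 1.0):
        raise ValueError("f must be in (0, 1]")
    return 50.0 * (1.0 - f + np.sqrt(1.0 - f)) / (u_cm * f)


def ne_bootstrap(
    segments: list[IBDSegment],
    pairs,
    u_cm: float,
    genome_cm: float,
    B: int = 10_000,
    unit: str = "segment",
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile 95% CI for Ne by resampling detected segments (default)
    or whole pairs (the dependence unit; wider, more conservative CIs).

    Raises if more than 1% of replicates produce f = 0 (advice: lower u).
    """
    pairs = [tuple(sorted(map(str, p))) for p in pairs]
    n_pairs = len(pairs)
    if n_pairs == 0:
        raise ValueError("empty pair set")
    pair_set = set(pairs)
    keep = [s for s in segments if s.length_cm >= u_cm
            and tuple(sorted((s.sample_a, s.sample_b))) in pair_set]
    if unit == "segment":
        if not keep:
            raise ValueError("no segments above threshold to resample")
        lengths = np.array([s.length_cm for s in keep])

        def estimator(resampled):
            f = resampled.sum() / (n_pairs * genome_cm)
            return ne_point(f, u_cm)

        units = lengths
    elif unit == "pair":
        totals = pair_sharing_totals(keep, pairs, u_cm)

        def estimator(resampled):
            f = resampled.mean() / genome_cm
            return ne_point(f, u_cm)

        units = totals
    else:
        raise ValueError("unit must be 'segment' or 'pair'")
    try:
        return bootstrap_ci(units, estimator, B=B, seed=seed,
                            max_failures=0.01)
    except ValueError as e:
        raise ValueError(
            f"bootstrap failed ({e}); consider a lower u threshold") from e


def ne_permutation_diff(
    segments: list[IBDSegment],
    sample_ids,
    populations,
    u_cm: float,
    genome_cm: float,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test for equal sharing fractions (equivalently Ne)
    across two groups.

    Individual labels are permuted; within-group pair sets are re-derived
    for every permutation; the statistic is the difference in group mean
    per-pair sharing (group order: lexicographic).
    """
    sample_ids = np.asarray(sample_ids, dtype=object)
    populations = np.asarray(populations, dtype=object)
    n = sample_ids.size
    idx = {str(s): k for k, s in enumerate(sample_ids)}
    matrix = np.zeros((n, n))
    for seg in segments:
        if seg.length_cm >= u_cm:
            a = idx.get(seg.sample_a)
            b = idx.get(seg.sample_b)
            if a is not None and b is not None:
                matrix[a, b] += seg.length_cm
                matrix[b, a] += seg.length_cm
    matrix /= genome_cm

    def diff_mean(xa, xb):
        return float(np.mean(xa) - np.mean(xb))

    return label_permutation_test(matrix, populations, statistic=diff_mean,
                                  n_perm=n_perm, pairwise=True, seed=seed)


def estimate_ne(
    segments: list[IBDSegment],
    sample_ids,
    u_cm: float = 7.0,
    genome_cm: float | None = None,
    B: int = 10_000,
    unit: str = "segment",
    seed: int | None = None,
) -> NeEstimate:
    """Point estimate plus bootstrap CI for one group of samples.

    ``genome_cm`` defaults to nothing here — pass the total autosomal map
    length of the panel the segments came from.  If no pair shares
    anything above u, the estimate is reported as infinite (f = 0).
    """
    if genome_cm is None or genome_cm <= 0:
        raise ValueError("genome_cm (total map length) is required")
    ids = [str(s) for s in sample_ids]
    pairs = list(combinations(ids, 2))
    f = sharing_fraction(segments, pairs, u_cm, genome_cm)
    if f == 0:
        return NeEstimate(0.0, u_cm, float("inf"), None, genome_cm,
                          len(pairs))
    ne = ne_point(f, u_cm)
    ci = ne_bootstrap(segments, pairs, u_cm, genome_cm, B=B, unit=unit,
                      seed=seed)
    return NeEstimate(f, u_cm, ne, ci, genome_cm, len(pairs))
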