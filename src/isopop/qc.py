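"""Quality control: marker/sample filters, LD pruning, method-of-moments
relatedness (PI-hat) and greedy relatedness exclusion.

The QC recipe mirrors standard isolate-study practice: drop low-call-rate
and rare markers, prune to an approximately independent marker set
(r² < 0.2) for stratification analyses, estimate pairwise PI-hat from IBS
counts, and remove samples until no pair exceeds the relatedness ceiling
(PI-hat > 0.1, i.e. closer than third-degree relatives) — close relatives
would otherwise masquerade as population-level IBD sharing.
"""

from __future__ import annotations

import logging

import numpy as np

from .panel import MISSING_DOSAGE, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "filter_markers",
    "filter_samples",
    "ld_prune",
    "pi_hat",
    "pi_hat_matrix",
    "relatedness_exclusion",
]


def _allele_freq(dos: np.ndarray) -> np.ndarray:
    """Per-marker frequency of the counted allele, missing-aware."""
    ok = dos != MISSING_DOSAGE
    n = ok.sum(axis=0)
    s = np.where(ok, dos, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, s / (2.0 * n), np.nan)


def filter_markers(g: GenotypeMatrix, max_missing_rate: float = 0.05,
                   min_maf: float = 0.01) -> GenotypeMatrix:
    """Keep markers with call rate >= 1 - max_missing_rate and MAF >= min_maf.

    Idempotent; marker order preserved.  An empty result is allowed (logged).
    """
    if not (0 <= max_missing_rate <= 1 and 0 <= min_maf <= 0.5):
        raise ValueError("rates out of range")
    miss = (g.dosages == MISSING_DOSAGE).mean(axis=0)
    p = _allele_freq(g.dosages)
    maf = np.minimum(p, 1.0 - p)
    keep = (miss <= max_missing_rate) & ~np.isnan(maf) & (maf >= min_maf)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_markers: removed %d of %d markers",
                    dropped, g.n_markers)
    if not keep.any():
        logger.warning("filter_markers: no markers retained")
    return g.subset_markers(np.flatnonzero(keep))


def filter_samples(g: GenotypeMatrix,
                   max_missing_rate: float = 0.05) -> GenotypeMatrix:
    """Keep samples with genotype call rate >= 1 - max_missing_rate."""
    miss = (g.dosages == MISSING_DOSAGE).mean(axis=1)
    keep = miss <= max_missing_rate
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_samples: removed %d of %d samples",
                    dropped, g.n_samples)
    return g.subset_samples(np.flatnonzero(keep))


def ld_prune(g: GenotypeMatrix, r2_threshold: float = 0.2,
             window_markers: int = 50, step_markers: int = 5) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns retained marker indices.

    Within each sliding window (within chromosome), marker pairs with
    r² >= threshold are resolved by dropping the right-hand marker.  After
    pruning, no retained pair within any window violates the threshold.
    Deterministic.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    if window_markers < 2:
        raise ValueError("window must cover at least 2 markers")
    d = g.dosages.astype(float)
    d[d < 0] = np.nan
    removed = np.zeros(g.n_markers, dtype=bool)
    for lo, hi in g.markers.chrom_slices().values():
        start = lo
        while start < hi:
            stop = min(start + window_markers, hi)
            idx = [j for j in range(start, stop) if not removed[j]]
            for ai in range(len(idx)):
                i = idx[ai]
                if removed[i]:
                    continue
                for j in idx[ai + 1:]:
                    if removed[j]:
                        continue
                    if _r2_nan(d[:, i], d[:, j]) >= r2_threshold:
                        removed[j] = True
            if stop == hi:
                break
            start += step_markers
    return np.flatnonzero(~removed)


def _r2_nan(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0 or vy == 0:
        return 0.0
    c = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(c * c / (vx * vy))


# ---------------------------------------------------------------------------
# PI-hat


def pi_hat(g: GenotypeMatrix, sample_a: str, sample_b: str,
           min_markers: int = 1000,
           freqs: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Method-of-moments IBD-sharing estimate for one pair.

    From the observed IBS-0/1/2 marker counts and their expectations under
    pooled sample allele frequencies, solves for the probabilities
    (P0, P1, P2) of sharing 0/1/2 alleles identical by descent; components
    are truncated into [0, 1] and renormalised.  PI-hat = P1/2 + P2.

    Requires at least ``min_markers`` jointly non-missing markers (the
    moment estimates are unstable below that).
    """
    ia = g.sample_index(sample_a)
    ib = g.sample_index(sample_b)
    if freqs is None:
        freqs = _allele_freq(g.dosages)
    return _pi_hat_idx(g.dosages, ia, ib, freqs, min_markers)


def _pi_hat_idx(dos: np.ndarray, ia: int, ib: int, p: np.ndarray,
                min_markers: int) -> tuple[float, np.ndarray]:
    a = dos[ia]
    b = dos[ib]
    ok = (a != MISSING_DOSAGE) & (b != MISSING_DOSAGE) & ~np.isnan(p) \
        & (p > 0) & (p < 1)
    if ok.sum() < min_markers:
        raise ValueError(
            f"only {int(ok.sum())} jointly non-missing markers "
            f"(need >= {min_markers}) — PI-hat estimate unstable")
    aa, bb, pp = a[ok].astype(int), b[ok].astype(int), p[ok]
    qq = 1.0 - pp
    ibs = np.where(aa == bb, 2, np.where(np.abs(aa - bb) == 2, 0, 1))
    n = ibs.size
    n0 = float(np.sum(ibs == 0))
    n1 = float(np.sum(ibs == 1))
    n2 = float(np.sum(ibs == 2))
    # expectations per marker given IBD state (plug-in frequencies)
    e0_ibd0 = np.sum(2 * pp**2 * qq**2)
    e1_ibd0 = np.sum(4 * pp**3 * qq + 4 * pp * qq**3)
    e2_ibd0 = np.sum(pp**4 + qq**4 + 4 * pp**2 * qq**2)
    e1_ibd1 = np.sum(2 * pp * qq)
    e2_ibd1 = np.sum(pp**2 + qq**2)
    z0 = n0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    z1 = (n1 - z0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    z2 = (n2 - z0 * e2_ibd0 - z1 * e2_ibd1) / n
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    s = z.sum()
    z = z / s if s > 0 else np.array([1.0, 0.0, 0.0])
    return float(z[1] / 2.0 + z[2]), z


def pi_hat_matrix(g: GenotypeMatrix, min_markers: int = 1000) -> np.ndarray:
    """Symmetric matrix of pairwise PI-hat (diagonal = 1)."""
    p = _allele_freq(g.dosages)
    n = g.n_samples
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _pi_hat_idx(
                g.dosages, i, j, p, min_markers)[0]
    return out


def relatedness_exclusion(g: GenotypeMatrix, threshold: float = 0.1,
                          min_markers: int = 1000,
                          pi: np.ndarray | None = None) -> np.ndarray:
    """Greedy removal of related samples; returns retained sample indices.

    While any pair exceeds the PI-hat threshold, drop the sample involved
    in the most offending pairs (ties broken by larger mean PI-hat, then by
    lexicographically larger sample id).  Guarantees no retained pair
    exceeds the threshold.
    """
    if pi is None:
        pi = pi_hat_matrix(g, min_markers=min_markers)
    pi = np.array(pi, dtype=float)
    np.fill_diagonal(pi, 0.0)
    active = np.ones(g.n_samples, dtype=bool)
    while True:
        off = (pi > threshold) & active[:, None] & active[None, :]
        counts = off.sum(axis=1)
        if counts.max() == 0:
            break
        cand = np.flatnonzero(counts == counts.max())
        if cand.size > 1:
            means = np.array([
                pi[c, active].mean() if active.sum() > 1 else 0.0
                for c in cand])
            cand = cand[means == means.max()]
        if cand.size > 1:
            ids = [str(g.sample_ids[c]) for c in cand]
            cand = cand[[np.argmax(ids)]]
        worst = int(cand[0])
        active[worst] = False
        logger.info("relatedness_exclusion: removed %s",
                    g.sample_ids[worst])
    return np.flatnonzero(active)
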