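"""Population stratification and differentiation.

Three classical tools, applied to pruned genotype data:

* identity-by-state (IBS) similarity between samples, and classical
  multidimensional scaling (principal-coordinate analysis) of the
  corresponding distance matrix — the stratification picture in which a
  genetic isolate separates from its source population;
* pairwise Weir & Cockerham (1984) F_ST between populations, ratio of
  variance-component sums across loci, with label-permutation p-values and
  a bootstrap-over-loci confidence interval;
* Spearman rank correlation with a permutation p-value, used downstream to
  relate per-individual homozygosity to MDS coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .panel import MISSING_DOSAGE, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["ibs_matrix", "MDSResult", "mds", "FstResult", "pairwise_fst",
           "spearman"]


def ibs_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Sample-by-sample IBS similarity in [0, 1].

    For each pair: mean over jointly non-missing markers of
    (number of shared alleles) / 2, where a marker contributes 1 for
    identical genotypes, 1/2 for genotypes sharing one allele, 0 for
    opposite homozygotes.  Diagonal is 1.  A pair with zero overlapping
    markers raises.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = g.dosages.astype(np.int16)
    ok = d != MISSING_DOSAGE
    n = g.n_samples
    sim = np.eye(n)
    for i in range(n):
        both = ok[i] & ok[i + 1:]
        cnt = both.sum(axis=1)
        if np.any(cnt == 0):
            j = i + 1 + int(np.argmax(cnt == 0))
            raise ValueError(
                f"samples {g.sample_ids[i]} and {g.sample_ids[j]} share no "
                "genotyped markers")
        diff = np.abs(d[i] - d[i + 1:]) * both
        # shared alleles at a marker = 2 - |dosage difference| (exact for
        # biallelic dosages: 0/0→2, 1/1→2, 2/1→1, 2/0→0, ...)
        sim_row = (2.0 * cnt - diff.sum(axis=1)) / (2.0 * cnt)
        sim[i, i + 1:] = sim_row
        sim[i + 1:, i] = sim_row
    return sim


@dataclass
class MDSResult:
    coordinates: np.ndarray      # samples x k, ordered by eigenvalue
    eigenvalues: np.ndarray      # the k retained (positive) eigenvalues
    sample_ids: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"C{i + 1}": self.coordinates[:, i]
                for i in range(self.coordinates.shape[1])}
        return pd.DataFrame({"sample": self.sample_ids, **cols})


def mds(ibs: np.ndarray, k: int = 4,
        sample_ids: np.ndarray | None = None) -> MDSResult:
    """Classical scaling (principal coordinates) of D = 1 - IBS.

    Double-centres -D²/2, eigendecomposes, and returns eigenvector columns
    scaled by the square root of their eigenvalues.  Negative eigenvalues
    are truncated; if fewer than ``k`` positive eigenvalues exist the
    returned dimension is reduced (logged).  Sign convention: the largest-
    magnitude loading of each axis is positive.
    """
    ibs = np.asarray(ibs, dtype=float)
    n = ibs.shape[0]
    if ibs.shape != (n, n) or not np.allclose(ibs, ibs.T):
        raise ValueError("IBS matrix must be square and symmetric")
    if not np.allclose(np.diag(ibs), 1.0):
        raise ValueError("IBS matrix must have unit diagonal")
    if k > n - 1:
        raise ValueError("k must be <= n_samples - 1")
    dist = 1.0 - ibs
    b = dist**2
    b = -0.5 * (b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean())
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-9 * abs(vals[0])) if vals[0] > 0 else \
        np.zeros_like(vals, dtype=bool)
    n_pos = int(pos.sum())
    if n_pos < k:
        logger.info("mds: only %d positive eigenvalues, reducing k from %d",
                    n_pos, k)
        k_eff = n_pos
    else:
        k_eff = k
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    for j in range(k_eff):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    if sample_ids is None:
        sample_ids = np.array([f"s{i}" for i in range(n)], dtype=object)
    return MDSResult(coords, vals[:k_eff], np.asarray(sample_ids, dtype=object))


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


def _wc_components(dos: np.ndarray, groups: list[np.ndarray]):
    """Per-locus Weir-Cockerham variance components a, b, c (vectorised).

    ``groups``: list of sample-index arrays, one per population.  Loci
    monomorphic across all populations (or with a population entirely
    missing) get NaN components and are excluded from sums.
    """
    r = len(groups)
    n_i = np.stack([np.sum(dos[g] != MISSING_DOSAGE, axis=0)
                    for g in groups]).astype(float)          # r x m
    cnt = np.stack([np.where(dos[g] != MISSING_DOSAGE, dos[g], 0).sum(axis=0)
                    for g in groups]).astype(float)
    het = np.stack([np.sum(dos[g] == 1, axis=0) for g in groups]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = cnt / (2.0 * n_i)
        h_i = het / n_i
        nbar = n_i.mean(axis=0)
        nsum = n_i.sum(axis=0)
        nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1.0)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar)**2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
            / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    poly = (pbar > 0) & (pbar < 1) & np.all(n_i >= 1, axis=0) & (nbar > 1)
    a = np.where(poly, a, np.nan)
    b = np.where(poly, b, np.nan)
    c = np.where(poly, c, np.nan)
    return a, b, c


def _theta(dos: np.ndarray, groups: list[np.ndarray]) -> float:
    a, b, c = _wc_components(dos, groups)
    ok = ~np.isnan(a)
    if not ok.any():
        raise ValueError("all loci monomorphic across the populations")
    denom = np.nansum(a + b + c)
    if denom == 0:
        return 0.0
    return float(np.nansum(a) / denom)


@dataclass
class FstResult:
    populations: list[str]
    fst: pd.DataFrame            # pop x pop point estimates
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    p_value: pd.DataFrame

    def pair(self, a: str, b: str) -> dict:
        return {
            "fst": float(self.fst.loc[a, b]),
            "ci": (float(self.ci_low.loc[a, b]), float(self.ci_high.loc[a, b])),
            "p": float(self.p_value.loc[a, b]),
        }


def pairwise_fst(g: GenotypeMatrix, n_perm: int = 100,
                 ci_boot_loci: int = 100, seed: int | None = None) -> FstResult:
    """Pairwise Weir-Cockerham F_ST between all population pairs.

    The point estimate is the ratio of sums Σa / Σ(a+b+c) across loci
    (stable for low-information loci).  The p-value is the proportion of
    sample-label permutations with F_ST >= observed, with the +1/(n+1)
    correction; the 95% CI is a percentile bootstrap over loci.
    """
    pops = sorted(set(g.populations))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    for p in pops:
        if np.sum(g.populations == p) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    nan = np.full((len(pops), len(pops)), np.nan)
    fst = pd.DataFrame(nan.copy(), index=pops, columns=pops)
    lo = fst.copy()
    hi = fst.copy()
    pv = fst.copy()
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            ia = np.flatnonzero(g.populations == pops[i])
            ib = np.flatnonzero(g.populations == pops[j])
            sub = np.concatenate([ia, ib])
            dos = g.dosages[sub]
            na = ia.size
            groups = [np.arange(na), np.arange(na, sub.size)]
            theta = _theta(dos, groups)

            # permutation p: reassign population labels at random
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(sub.size)
                count += _theta(dos, [perm[:na], perm[na:]]) >= theta - 1e-15
            p_val = (1.0 + count) / (n_perm + 1.0)

            # bootstrap over loci
            a, b, c = _wc_components(dos, groups)
            ok = np.flatnonzero(~np.isnan(a))
            reps = np.empty(ci_boot_loci)
            tot = (a + b + c)
            for k in range(ci_boot_loci):
                pick = ok[rng.integers(0, ok.size, ok.size)]
                d = tot[pick].sum()
                reps[k] = a[pick].sum() / d if d != 0 else 0.0
            ci = np.quantile(reps, [0.025, 0.975])

            fst.loc[pops[i], pops[j]] = fst.loc[pops[j], pops[i]] = theta
            lo.loc[pops[i], pops[j]] = lo.loc[pops[j], pops[i]] = ci[0]
            hi.loc[pops[i], pops[j]] = hi.loc[pops[j], pops[i]] = ci[1]
            pv.loc[pops[i], pops[j]] = pv.loc[pops[j], pops[i]] = p_val
    return FstResult(pops, fst, lo, hi, pv)


def spearman(x, y, n_perm: int = 10_000,
             seed: int | None = None) -> tuple[float, float]:
    """Spearman rank correlation with a permutation p-value.

    Average ranks for ties; two-sided p by permuting ``y`` (suited to the
    small panels this package analyses).  Constant input raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rx = rankdata(x)
    ry = rankdata(y)

    def rho_of(ryy):
        return float(np.corrcoef(rx, ryy)[0, 1])

    rho = rho_of(ry)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += abs(rho_of(rng.permutation(ry))) >= abs(rho) - 1e-15
    return rho, (1.0 + count) / (n_perm + 1.0)
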