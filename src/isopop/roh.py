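"""Runs-of-homozygosity scanning on unphased genotypes.

The scan reproduces the standard window-based ROH criteria: a 50-SNP
window sliding across a chromosome is "homozygous" if it holds at most one
heterozygote and at most five missing calls; a SNP is ROH-eligible when at
least 5% of the windows overlapping it are homozygous; maximal runs of
eligible SNPs are split at inter-marker gaps over 1 Mb and reported if
they span >= 1000 kb, contain >= 100 SNPs and average <= 50 kb per SNP.
Long ROH indicate autozygosity — both haplotypes inherited from a recent
common ancestor — and are strongly enriched in bottlenecked isolates.

`roh_scan_bruteforce` is a deliberately literal re-statement of the same
criteria (plain loops, no vectorisation) kept as an independent oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import MISSING_DOSAGE, GenotypeMatrix
from .permstats import PermutationResult, label_permutation_test
from .segments import ROHSegment

__all__ = ["roh_scan", "roh_scan_bruteforce", "roh_bins",
           "roh_totals", "roh_totals_and_test", "ROH_BIN_EDGES_MB"]

# length bins (Mb): [min, 1.5), [1.5, 2.5), [2.5, 5), [5, 10), [10, inf)
ROH_BIN_EDGES_MB = (1.5, 2.5, 5.0, 10.0)


def _eligible_snps(dos: np.ndarray, window_snps: int, window_max_het: int,
                   window_max_missing: int, hit_threshold: float) -> np.ndarray:
    """Boolean ROH-eligibility per SNP for one sample on one chromosome.

    Vectorised sliding-window evaluation via cumulative sums.
    """
    n = dos.size
    if n < window_snps:
        return np.zeros(n, dtype=bool)
    het = (dos == 1).astype(np.int32)
    mis = (dos == MISSING_DOSAGE).astype(np.int32)
    ch = np.concatenate([[0], np.cumsum(het)])
    cm_ = np.concatenate([[0], np.cumsum(mis)])
    n_win = n - window_snps + 1
    w_het = ch[window_snps:] - ch[:n_win]
    w_mis = cm_[window_snps:] - cm_[:n_win]
    hom_win = (w_het <= window_max_het) & (w_mis <= window_max_missing)
    # windows overlapping SNP i are those starting in
    # [max(0, i-window+1), min(i, n_win-1)]
    hw = np.concatenate([[0], np.cumsum(hom_win.astype(np.int64))])
    i = np.arange(n)
    w_lo = np.maximum(0, i - window_snps + 1)
    w_hi = np.minimum(i, n_win - 1)
    n_overlap = (w_hi - w_lo + 1).astype(float)
    n_hom = (hw[w_hi + 1] - hw[w_lo]).astype(float)
    return n_hom / n_overlap >= hit_threshold


def _runs_to_segments(elig: np.ndarray, bp: np.ndarray, sample: str,
                      chrom: str, offset: int, min_kb: float, min_snps: int,
                      max_kb_per_snp: float, max_gap_kb: float
                      ) -> list[ROHSegment]:
    segs = []
    n = elig.size
    i = 0
    while i < n:
        if not elig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and elig[j + 1]:
            j += 1
        # split the eligible run at large inter-marker gaps first
        pieces = []
        a = i
        for k in range(i, j):
            if bp[k + 1] - bp[k] > max_gap_kb * 1000:
                pieces.append((a, k))
                a = k + 1
        pieces.append((a, j))
        for a, b in pieces:
            n_snps = b - a + 1
            span_kb = (bp[b] - bp[a] + 1) / 1000.0
            if (span_kb >= min_kb and n_snps >= min_snps
                    and span_kb / n_snps <= max_kb_per_snp):
                segs.append(ROHSegment(
                    sample=sample, chrom=chrom,
                    start_bp=int(bp[a]), end_bp=int(bp[b]),
                    start_idx=offset + a, end_idx=offset + b,
                    n_markers=n_snps))
        i = j + 1
    return segs


def roh_scan(
    g: GenotypeMatrix,
    min_kb: float = 1000.0,
    min_snps: int = 100,
    max_kb_per_snp: float = 50.0,
    max_gap_kb: float = 1000.0,
    window_snps: int = 50,
    window_max_het: int = 1,
    window_max_missing: int = 5,
    hit_threshold: float = 0.05,
) -> list[ROHSegment]:
    """Scan every sample for runs of homozygosity.

    Chromosomes with fewer than ``window_snps`` markers are skipped.
    Deterministic; output sorted by sample, chromosome, position.
    """
    segs: list[ROHSegment] = []
    slices = g.markers.chrom_slices()
    for s in range(g.n_samples):
        sid = str(g.sample_ids[s])
        for chrom, (lo, hi) in slices.items():
            dos = g.dosages[s, lo:hi]
            if dos.size < window_snps:
                continue
            elig = _eligible_snps(dos, window_snps, window_max_het,
                                  window_max_missing, hit_threshold)
            segs.extend(_runs_to_segments(
                elig, g.markers.bp[lo:hi], sid, str(chrom), lo,
                min_kb, min_snps, max_kb_per_snp, max_gap_kb))
    return segs


def roh_scan_bruteforce(g: GenotypeMatrix, **kw) -> list[ROHSegment]:
    """Literal (loop-based) restatement of the ROH criteria; test oracle.

    Enumerates every window and every candidate run with plain Python
    loops, applying each criterion exactly as stated.
    """
    p = dict(min_kb=1000.0, min_snps=100, max_kb_per_snp=50.0,
             max_gap_kb=1000.0, window_snps=50, window_max_het=1,
             window_max_missing=5, hit_threshold=0.05)
    p.update(kw)
    segs: list[ROHSegment] = []
    for s in range(g.n_samples):
        sid = str(g.sample_ids[s])
        for chrom, (lo, hi) in g.markers.chrom_slices().items():
            dos = list(g.dosages[s, lo:hi])
            bp = list(g.markers.bp[lo:hi])
            n = len(dos)
            W = p["window_snps"]
            if n < W:
                continue
            hom_windows = []
            for w in range(n - W + 1):
                chunk = dos[w:w + W]
                n_het = sum(1 for x in chunk if x == 1)
                n_mis = sum(1 for x in chunk if x == MISSING_DOSAGE)
                hom_windows.append(n_het <= p["window_max_het"]
                                   and n_mis <= p["window_max_missing"])
            elig = []
            for i in range(n):
                total = hom = 0
                for w in range(max(0, i - W + 1), min(i, n - W) + 1):
                    total += 1
                    hom += hom_windows[w]
                elig.append(hom / total >= p["hit_threshold"])
            i = 0
            while i < n:
                if not elig[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < n and elig[j + 1]:
                    j += 1
                a = i
                bounds = []
                for k in range(i, j):
                    if bp[k + 1] - bp[k] > p["max_gap_kb"] * 1000:
                        bounds.append((a, k))
                        a = k + 1
                bounds.append((a, j))
                for a2, b2 in bounds:
                    n_snps = b2 - a2 + 1
                    span_kb = (bp[b2] - bp[a2] + 1) / 1000.0
                    if span_kb >= p["min_kb"] and n_snps >= p["min_snps"] \
                            and span_kb / n_snps <= p["max_kb_per_snp"]:
                        segs.append(ROHSegment(
                            sample=sid, chrom=str(chrom),
                            start_bp=int(bp[a2]), end_bp=int(bp[b2]),
                            start_idx=lo + a2, end_idx=lo + b2,
                            n_markers=n_snps))
                i = j + 1
    return segs


def roh_bins(segments: list[ROHSegment], sample_ids, populations=None,
             min_mb: float = 1.0) -> pd.DataFrame:
    """Proportion of individuals with >= 1 ROH per length bin.

    Bins (Mb): [min_mb, 1.5), [1.5, 2.5), [2.5, 5), [5, 10), [10, inf).
    Individuals without any ROH stay in the denominator.
    """
    sample_ids = np.asarray(sample_ids, dtype=object)
    if populations is None:
        populations = np.full(sample_ids.size, "all", dtype=object)
    populations = np.asarray(populations, dtype=object)
    edges = [min_mb, *ROH_BIN_EDGES_MB, np.inf]
    names = [f"[{edges[i]:g},{edges[i + 1]:g})" if np.isfinite(edges[i + 1])
             else f">={edges[i]:g}" for i in range(len(edges) - 1)]
    hit = {sid: np.zeros(len(names), dtype=bool) for sid in sample_ids}
    for seg in segments:
        mb = seg.length_mb
        if mb < min_mb or seg.sample not in hit:
            continue
        b = int(np.searchsorted(edges, mb, "right")) - 1
        b = min(b, len(names) - 1)
        hit[seg.sample][b] = True
    rows = []
    for pop in dict.fromkeys(populations):
        members = sample_ids[populations == pop]
        mat = np.stack([hit[s] for s in members])
        rows.append({"population": pop, "n": len(members),
                     **{nm: mat[:, i].mean() for i, nm in enumerate(names)}})
    return pd.DataFrame(rows)


def roh_totals(segments: list[ROHSegment], sample_ids) -> pd.DataFrame:
    """Per-individual ROH count, mean segment size (Mb) and total length."""
    sample_ids = np.asarray(sample_ids, dtype=object)
    idx = {sid: k for k, sid in enumerate(sample_ids)}
    n = np.zeros(len(sample_ids), dtype=int)
    tot = np.zeros(len(sample_ids))
    for seg in segments:
        k = idx.get(seg.sample)
        if k is None:
            continue
        n[k] += 1
        tot[k] += seg.length_mb
    mean = np.where(n > 0, tot / np.maximum(n, 1), 0.0)
    return pd.DataFrame({"sample": sample_ids, "n_segments": n,
                         "mean_mb": mean, "total_mb": tot})


def roh_totals_and_test(
    segments: list[ROHSegment],
    sample_ids,
    populations,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, PermutationResult]]:
    """Group comparison of per-individual ROH statistics.

    Returns the per-individual table plus, for each of segment count, mean
    segment size and total length, a Wilcoxon rank-sum permutation test
    between the two populations (labels permuted at the individual level).
    """
    populations = np.asarray(populations, dtype=object)
    if len(set(populations)) != 2:
        raise ValueError("exactly two populations required")
    for pop in set(populations):
        if (populations == pop).sum() < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 samples")
    table = roh_totals(segments, sample_ids)
    tests = {}
    for col in ("n_segments", "mean_mb", "total_mb"):
        tests[col] = label_permutation_test(
            table[col].to_numpy(float), populations,
            n_perm=n_perm, seed=seed)
    return table, tests
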