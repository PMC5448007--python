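"""Hash-seeded IBD segment detection on phased haplotypes.

The detector follows the GERMLINE design: each chromosome is cut into
fixed (non-sliding) 64-marker words; exact word matches between haplotypes,
found by hashing, seed candidate segments; runs of consecutive matching
words are extended marker-by-marker at both ends, tolerating at most
``max_mismatch`` mismatching markers per 64-marker window.  The four
haplotype-combination match sets of a sample pair are merged into
genotype-level segments (union of overlapping or near-adjacent intervals),
so a phase switch does not fragment a long IBD segment.  Segments shorter
than ``min_cm`` are discarded.

Exact 64-marker word equality between non-IBD haplotypes is essentially
impossible at typical heterozygosity, so the hash seeds are precise; the
per-window mismatch budget is what admits sparse genotyping error inside
true segments.

Regions of low SNP density cannot support confident detection; the sparse-
region mask (any 50-consecutive-marker span wider than 1 Mb) and the 20%
overlap filter remove segments that live mostly in such regions.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING_ALLELE, MarkerMap, PhasedPanel
from .segments import IBDSegment

logger = logging.getLogger(__name__)

__all__ = [
    "germline_scan",
    "sparse_region_mask",
    "filter_segments_by_mask",
    "pair_summaries",
    "PairSharingSummary",
    "segments_to_dataframe",
]

WORD = 64


def _pack_words(haps: np.ndarray, n_words: int) -> np.ndarray:
    """Pack each consecutive 64-marker tile of each haplotype into a uint64.

    Missing alleles are packed as 0 — a missing site can therefore break a
    hash seed, but extension (which treats missing as matching) recovers
    the span.
    """
    bits = (haps[:, : n_words * WORD] == 1).astype(np.uint64)
    bits = bits.reshape(haps.shape[0], n_words, WORD)
    weights = (np.uint64(1) << np.arange(WORD, dtype=np.uint64))
    return bits @ weights


def _extend(ha: np.ndarray, hb: np.ndarray, lo: int, hi: int,
            max_mismatch: int, stop_lo: int, stop_hi: int) -> tuple[int, int, int]:
    """Greedy marker-by-marker extension of an exact-match run [lo, hi].

    Extension continues while every trailing 64-marker window keeps at most
    ``max_mismatch`` mismatches; missing alleles always match.  Returns the
    extended inclusive bounds and the mismatch count inside them.
    """
    miss = (ha == MISSING_ALLELE) | (hb == MISSING_ALLELE)
    neq = (ha != hb) & ~miss

    def grow(idx_iter, current_mm):
        out = []
        mm_positions = list(current_mm)
        for i in idx_iter:
            if neq[i]:
                # mismatches already accepted inside the 64-marker window
                # around the candidate position
                recent = sum(1 for p in mm_positions if abs(p - i) < WORD)
                if recent + 1 > max_mismatch:
                    break
                mm_positions.append(i)
            out.append(i)
        return out, mm_positions

    mm_inside = [int(i) for i in np.flatnonzero(neq[lo:hi + 1]) + lo]
    right, mm_positions = grow(range(hi + 1, stop_hi), mm_inside)
    new_hi = right[-1] if right else hi
    left, mm_positions = grow(range(lo - 1, stop_lo - 1, -1), mm_positions)
    new_lo = left[-1] if left else lo
    # trim mismatching end markers: a segment should end on a match
    while new_lo < lo and neq[new_lo]:
        new_lo += 1
    while new_hi > hi and neq[new_hi]:
        new_hi -= 1
    n_mm = int(neq[new_lo:new_hi + 1].sum())
    return new_lo, new_hi, n_mm


def _merge_intervals(ivals: list[tuple[int, int]],
                     max_gap: int) -> list[tuple[int, int]]:
    """Union of inclusive marker-index intervals, bridging gaps < max_gap."""
    if not ivals:
        return []
    ivals = sorted(ivals)
    out = [list(ivals[0])]
    for a, b in ivals[1:]:
        if a <= out[-1][1] + max_gap:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def germline_scan(
    panel: PhasedPanel,
    word_markers: int = WORD,
    max_mismatch_per_window: int = 1,
    min_cm: float = 3.0,
    max_missing_frac: float = 0.05,
) -> list[IBDSegment]:
    """Detect IBD segments between all sample pairs of a phased panel.

    Returns genotype-level segments (per sample pair, per chromosome),
    non-overlapping within a pair, each at least ``min_cm`` long on the
    genetic map, sorted canonically.  Chromosomes with fewer than one full
    word of markers are skipped (logged).  Deterministic; invariant to
    sample and haplotype ordering.
    """
    if word_markers != WORD:
        raise ValueError("the packed-hash implementation uses 64-marker words")
    m = panel.markers
    haps = panel.haplotypes
    n_haps = haps.shape[0]
    segments: list[IBDSegment] = []

    for chrom, (clo, chi) in m.chrom_slices().items():
        n_mark = chi - clo
        n_words = n_mark // WORD
        if n_words == 0:
            logger.info("germline_scan: chromosome %s has %d markers "
                        "(< %d), skipped", chrom, n_mark, WORD)
            continue
        sub = haps[:, clo:chi]
        words = _pack_words(sub, n_words)

        # hash seeding: group haplotypes by word value at each position
        pair_words: dict[tuple[int, int], list[int]] = defaultdict(list)
        for w in range(n_words):
            col = words[:, w]
            order = np.argsort(col, kind="stable")
            sorted_vals = col[order]
            starts = np.flatnonzero(
                np.concatenate([[True], sorted_vals[1:] != sorted_vals[:-1]]))
            ends = np.concatenate([starts[1:], [n_haps]])
            for s, e in zip(starts, ends):
                if e - s < 2:
                    continue
                group = np.sort(order[s:e])
                for x in range(len(group)):
                    for y in range(x + 1, len(group)):
                        pair_words[(int(group[x]), int(group[y]))].append(w)

        # word runs -> extended haplotype-level intervals
        hap_ivals: dict[tuple[int, int], list[tuple[int, int]]] = \
            defaultdict(list)
        for (i, j), wlist in pair_words.items():
            runs: list[tuple[int, int]] = []
            start = prev = wlist[0]
            for w in wlist[1:]:
                if w == prev + 1:
                    prev = w
                else:
                    runs.append((start, prev))
                    start = prev = w
            runs.append((start, prev))
            ha, hb = sub[i], sub[j]
            for ws, we in runs:
                lo = ws * WORD
                hi = we * WORD + WORD - 1
                lo2, hi2, _ = _extend(
                    ha, hb, lo, hi, max_mismatch_per_window, 0, n_mark)
                hap_ivals[(i // 2, j // 2)].append((lo2, hi2))

        # genotype-level merge per sample pair
        for (sa, sb), ivals in sorted(hap_ivals.items()):
            if sa == sb:
                continue
            for lo, hi in _merge_intervals(ivals, max_gap=WORD):
                gi, gj = clo + lo, clo + hi
                length_cm = float(m.cm[gj] - m.cm[gi])
                if length_cm < min_cm:
                    continue
                name_a = str(panel.sample_ids[sa])
                name_b = str(panel.sample_ids[sb])
                if name_b < name_a:
                    sa, sb = sb, sa
                    name_a, name_b = name_b, name_a
                da = panel.haplotypes[2 * sa:2 * sa + 2, gi:gj + 1]
                db = panel.haplotypes[2 * sb:2 * sb + 2, gi:gj + 1]
                n_miss = int(((da == MISSING_ALLELE).any(axis=0) |
                              (db == MISSING_ALLELE).any(axis=0)).sum())
                if n_miss > max_missing_frac * (hi - lo + 1):
                    continue
                mm = _best_phase_mismatches(da, db)
                segments.append(IBDSegment(
                    sample_a=name_a,
                    sample_b=name_b,
                    chrom=str(chrom),
                    start_cm=float(m.cm[gi]), end_cm=float(m.cm[gj]),
                    start_bp=int(m.bp[gi]), end_bp=int(m.bp[gj]),
                    start_idx=gi, end_idx=gj,
                    n_markers=hi - lo + 1, n_mismatch=mm,
                ))
    segments.sort(key=lambda s: (s.sample_a, s.sample_b, s.chrom, s.start_cm))
    return segments


def _best_phase_mismatches(da: np.ndarray, db: np.ndarray) -> int:
    """Mismatches under the marker-wise best haplotype phase assignment.

    A genotype-level segment can switch between haplotype pairings along
    its length (that is the point of the merge), so the mismatch count is
    taken per marker as the minimum over the four pairings — i.e. markers
    where no haplotype of A matches any haplotype of B.
    """
    mm = None
    for x in range(2):
        for y in range(2):
            ha, hb = da[x], db[y]
            miss = (ha == MISSING_ALLELE) | (hb == MISSING_ALLELE)
            neq = (ha != hb) & ~miss
            mm = neq if mm is None else (mm & neq)
    return int(mm.sum())


# ---------------------------------------------------------------------------
# sparse-region exclusion


def sparse_region_mask(m: MarkerMap, span_markers: int = 50,
                       max_mb: float = 1.0) -> list[tuple[str, int, int]]:
    """Intervals where any ``span_markers``-consecutive-marker window is
    wider than ``max_mb`` — i.e. fewer than 50 SNPs per Mb locally.

    Returns merged (chrom, start_bp, end_bp) intervals.  A gap between two
    consecutive markers larger than ``max_mb`` is itself sparse.
    """
    out: list[tuple[str, int, int]] = []
    max_bp = int(max_mb * 1e6)
    for chrom, (lo, hi) in m.chrom_slices().items():
        bp = m.bp[lo:hi]
        n = len(bp)
        ivals = []
        k = min(span_markers, n)
        if k >= 2:
            spans = bp[k - 1:] - bp[: n - k + 1]
            for s in np.flatnonzero(spans > max_bp):
                ivals.append((int(bp[s]), int(bp[s + k - 1])))
        # a single inter-marker gap > max_bp is sparse even on short maps
        gaps = np.flatnonzero(np.diff(bp) > max_bp)
        for gidx in gaps:
            ivals.append((int(bp[gidx]), int(bp[gidx + 1])))
        merged: list[list[int]] = []
        for a, b in sorted(ivals):
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        out.extend((str(chrom), a, b) for a, b in merged)
    return out


def filter_segments_by_mask(
    segments: list[IBDSegment],
    mask: list[tuple[str, int, int]],
    max_overlap: float = 0.2,
) -> list[IBDSegment]:
    """Drop segments whose bp overlap with the sparse mask exceeds
    ``max_overlap`` of their own bp length."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, a, b in mask:
        by_chrom[chrom].append((a, b))
    kept = []
    for seg in segments:
        if seg.start_bp is None:
            kept.append(seg)
            continue
        length = seg.end_bp - seg.start_bp + 1
        ov = 0
        for a, b in by_chrom.get(seg.chrom, ()):
            ov += max(0, min(seg.end_bp, b) - max(seg.start_bp, a) + 1)
        if ov <= max_overlap * length:
            kept.append(seg)
    return kept


# ---------------------------------------------------------------------------
# pair summaries


@dataclass
class PairSharingSummary:
    """Per-pair IBD totals and their group summary statistics."""

    scope: str                      # e.g. "within ISO" / "between"
    n_samples: int
    n_pairs: int
    n_segments: int
    per_pair: pd.DataFrame          # sample_a, sample_b, n_segments,
    #                                 total_mb, mean_mb
    stats: pd.DataFrame             # mean/median/sd of the three columns

    def __str__(self) -> str:
        s = self.stats
        return (
            f"{self.scope}: {self.n_samples} samples, {self.n_pairs} pairs, "
            f"{self.n_segments} segments; "
            f"segments/pair {s.loc['mean', 'n_segments']:.2f}/"
            f"{s.loc['median', 'n_segments']:.0f}/"
            f"{s.loc['sd', 'n_segments']:.2f}, "
            f"Mb/pair {s.loc['mean', 'total_mb']:.2f}/"
            f"{s.loc['median', 'total_mb']:.2f}/"
            f"{s.loc['sd', 'total_mb']:.2f} (mean/median/SD)"
        )


def pair_summaries(
    segments: list[IBDSegment],
    sample_ids,
    labels,
    scope: str = "within",
    group: str | None = None,
) -> PairSharingSummary:
    """Aggregate detected segments into per-pair and group statistics.

    ``scope='within'`` enumerates all pairs inside ``group`` (or inside
    each label if group is None — then labels must have one unique value);
    ``scope='between'`` enumerates cross-label pairs.  Pairs with no
    detected segment contribute zero count and zero total, as in the
    population comparisons this reproduces.
    """
    sample_ids = np.asarray(sample_ids, dtype=object)
    labels = np.asarray(labels, dtype=object)
    if scope == "within":
        if group is None:
            uniq = sorted(set(labels))
            if len(uniq) != 1:
                raise ValueError("scope='within' needs an explicit group "
                                 "when several labels are present")
            group = uniq[0]
        members = sample_ids[labels == group]
        pairs = [(str(a), str(b)) for k, a in enumerate(members)
                 for b in members[k + 1:]]
        scope_name = f"within {group}"
    elif scope == "between":
        uniq = sorted(set(labels))
        if len(uniq) != 2:
            raise ValueError("scope='between' needs exactly two labels")
        ga = sample_ids[labels == uniq[0]]
        gb = sample_ids[labels == uniq[1]]
        pairs = [(str(a), str(b)) for a in ga for b in gb]
        scope_name = f"between {uniq[0]} and {uniq[1]}"
    else:
        raise ValueError("scope must be 'within' or 'between'")

    key = {tuple(sorted(p)): k for k, p in enumerate(pairs)}
    n_seg = np.zeros(len(pairs), dtype=int)
    tot_mb = np.zeros(len(pairs))
    used = 0
    for seg in segments:
        k = key.get(tuple(sorted((seg.sample_a, seg.sample_b))))
        if k is None:
            continue
        n_seg[k] += 1
        tot_mb[k] += seg.length_mb
        used += 1
    with np.errstate(invalid="ignore"):
        mean_mb = np.where(n_seg > 0, tot_mb / np.maximum(n_seg, 1), 0.0)
    per_pair = pd.DataFrame({
        "sample_a": [p[0] for p in pairs],
        "sample_b": [p[1] for p in pairs],
        "n_segments": n_seg,
        "total_mb": tot_mb,
        "mean_mb": mean_mb,
    })
    stats = pd.DataFrame(
        {
            col: {
                "mean": per_pair[col].mean(),
                "median": per_pair[col].median(),
                "sd": per_pair[col].std(ddof=1) if len(pairs) > 1 else 0.0,
            }
            for col in ("n_segments", "total_mb", "mean_mb")
        }
    )
    n_samples = len(set(s for p in pairs for s in p))
    return PairSharingSummary(scope_name, n_samples, len(pairs), used,
                              per_pair, stats)


def segments_to_dataframe(segments: list[IBDSegment]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "sample_a": s.sample_a, "sample_b": s.sample_b, "chrom": s.chrom,
            "start_bp": s.start_bp, "end_bp": s.end_bp,
            "start_cm": s.start_cm, "end_cm": s.end_cm,
            "length_cm": s.length_cm, "length_mb": s.length_mb,
            "n_markers": s.n_markers, "n_mismatch": s.n_mismatch,
        }
        for s in segments
    ])
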