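"""Forward ("gene-dropping") simulation of a bottlenecked isolate with full
ground truth, plus a renewal-process simulator of pairwise IBD sharing.

The gene-dropping simulator emulates the demographic narrative the analysis
targets: a small founder group (the historical record puts the isolate's
bottleneck at 151 inhabitants) expanding rapidly, versus a large outbred
control of effectively constant size.  Every haplotype in the final
generation is a crossover mosaic of labelled founder haplotypes, so true IBD
between any two samples and true autozygosity within a sample are exactly
derivable — the substrate against which the hash-based IBD detector and the
ROH scanner are validated.

Model
-----
* Diploid, monoecious Wright-Fisher with random mating; the two parents of
  a child are distinct (no selfing).
* Recombination is a Poisson process on the cM scale (no interference):
  crossover count per transmitted genome ~ Poisson(total length in Morgans),
  positions uniform; chromosomes assort independently.
* No mutation.  Optional per-allele genotyping error and per-genotype
  missingness can be injected when a panel is drawn, so that QC filters can
  be exercised; both default to zero.

The renewal simulator (:func:`simulate_pair_sharing`) generates per-pair
genome sharing fractions for a *constant*-size population directly, without
genotypes, and is the detection-free oracle for the IBD-based effective
population-size estimator.  Its per-segment law is chosen so that the
marginal time to the most recent common ancestor (TMRCA) at a uniformly
random point is Exponential(rate 1/(2N)) — the coalescent-limit law the
closed-form Ne estimator inverts — and the segment covering that point is
Erlang(2, g/100 cM⁻¹).  This requires the per-segment TMRCA to be drawn
length-biased, g ~ Gamma(shape 2, scale 2N), with segment length
Exponential(mean 100/g cM); drawing g from its unbiased marginal instead
would over-represent short-TMRCA (long) segments along the chromosome and
the simulator would not match the estimator it is meant to check.  Under
this law the expected sharing fraction is exactly f = a(a+2r)/(a+r)^2
with a = 1/(2N) and r = u/100, whose inversion is the closed form
implemented in :mod:`isopop.ne`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING_ALLELE, MarkerMap, PhasedPanel
from .segments import IBDSegment

__all__ = [
    "Epoch",
    "DemographyConfig",
    "isolate_config",
    "control_config",
    "FounderSegmentLabeling",
    "make_marker_map",
    "simulate_gene_dropping",
    "sample_panel",
    "true_ibd_segments",
    "true_autozygous_segments",
    "simulate_pair_sharing",
]


# ---------------------------------------------------------------------------
# demography


@dataclass
class Epoch:
    """One demographic epoch.

    Population size over the epoch interpolates geometrically from
    ``start_size`` to ``end_size`` (constant if ``end_size`` is None).
    """

    duration: int
    start_size: int
    end_size: int | None = None

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("epoch duration must be >= 1 generation")
        if self.end_size is None:
            self.end_size = self.start_size
        if self.start_size < 2 or self.end_size < 2:
            raise ValueError("population sizes must be >= 2")

    def sizes(self) -> np.ndarray:
        t = np.arange(1, self.duration + 1) / self.duration
        s = self.start_size * (self.end_size / self.start_size) ** t
        return np.maximum(2, np.rint(s).astype(int))


@dataclass
class DemographyConfig:
    """Founder count plus an ordered list of epochs (generation 0 is the
    founder generation; epoch sizes give generations 1..T)."""

    founder_count: int
    epochs: list[Epoch]
    error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.founder_count < 2:
            raise ValueError("founder_count must be >= 2")
        if not self.epochs:
            raise ValueError("at least one epoch required")
        if not (0.0 <= self.error_rate < 1.0 and 0.0 <= self.missing_rate < 1.0):
            raise ValueError("rates must be in [0, 1)")

    def generation_sizes(self) -> np.ndarray:
        return np.concatenate([e.sizes() for e in self.epochs])


def isolate_config(seed: int | None = None) -> DemographyConfig:
    """Scaled bottleneck-and-expansion scenario: 151 founders growing
    exponentially to 2,000 over 12 generations.

    The founder count matches the isolate's recorded 17th-century bottleneck
    (151 inhabitants); the expansion is scaled down from the real census of
    19,500 to keep forward simulation at desk scale while preserving the
    qualitative contrast (high IBD, ROH and LD; small Ne).
    """
    return DemographyConfig(151, [Epoch(12, 151, 2000)], seed=seed)


def control_config(seed: int | None = None) -> DemographyConfig:
    """Outbred control: constant size 10,000 for 12 generations (a scaled
    stand-in for a national population with Ne of order 10^5)."""
    return DemographyConfig(10_000, [Epoch(12, 10_000)], seed=seed)


# ---------------------------------------------------------------------------
# marker maps


def make_marker_map(
    chrom_cm,
    n_markers: int,
    spacing: str = "random",
    bp_per_cm: float = 1e6,
    seed: int | None = None,
) -> MarkerMap:
    """Build a synthetic autosomal marker map.

    Parameters
    ----------
    chrom_cm : sequence of float
        Chromosome lengths in cM.
    n_markers : int
        Total marker count, allocated to chromosomes proportionally.
    spacing : {"random", "regular"}
        Random (uniform positions) emulates an irregular array; regular
        spacing is convenient for fixtures.
    bp_per_cm : float
        Physical scale; default 1 Mb per cM.
    """
    chrom_cm = np.asarray(chrom_cm, dtype=float)
    rng = np.random.default_rng(seed)
    counts = np.maximum(
        2, np.rint(n_markers * chrom_cm / chrom_cm.sum()).astype(int))
    chroms, ids, bps, cms = [], [], [], []
    for ci, (L, m) in enumerate(zip(chrom_cm, counts), start=1):
        if spacing == "regular":
            pos = np.linspace(0.0, L, m, endpoint=False) + L / (2 * m)
        elif spacing == "random":
            pos = np.sort(rng.uniform(0.0, L, m))
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        chroms.append(np.full(m, str(ci), dtype=object))
        ids.append(np.array([f"snp{ci}_{j}" for j in range(m)], dtype=object))
        bps.append(np.maximum(1, np.rint(pos * bp_per_cm).astype(np.int64)))
        cms.append(pos)
    return MarkerMap(
        np.concatenate(chroms), np.concatenate(ids),
        np.concatenate(bps), np.concatenate(cms),
    )


# ---------------------------------------------------------------------------
# founder-segment labeling

Hap = tuple[np.ndarray, np.ndarray]  # (segment end positions, founder ids)


@dataclass
class FounderSegmentLabeling:
    """Ground-truth founder-origin mosaic for every sampled haplotype.

    Haplotypes are stored on a single concatenated cM axis; ``offsets`` maps
    chromosome c to [offsets[c], offsets[c+1]).  Each haplotype is a pair of
    arrays ``(ends, fids)``: segment i covers (ends[i-1], ends[i]] and
    descends verbatim from founder haplotype ``fids[i]``.
    """

    sample_ids: np.ndarray
    chrom_names: list[str]
    chrom_cm: np.ndarray
    haps: list[tuple[Hap, Hap]]
    n_founder_haps: int

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.chrom_cm = np.asarray(self.chrom_cm, dtype=float)
        self.offsets = np.concatenate([[0.0], np.cumsum(self.chrom_cm)])
        self.validate()

    @property
    def total_cm(self) -> float:
        return float(self.offsets[-1])

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero(self.sample_ids == sample_id)
        if len(idx) == 0:
            raise KeyError(f"unknown sample {sample_id!r}")
        return int(idx[0])

    def validate(self) -> None:
        """Check that every haplotype tiles the genome exactly."""
        total = self.total_cm
        for si, (h0, h1) in enumerate(self.haps):
            for ends, fids in (h0, h1):
                if len(ends) != len(fids) or len(ends) == 0:
                    raise ValueError("malformed haplotype segment arrays")
                if np.any(np.diff(ends) <= 0):
                    raise ValueError("segment ends not strictly increasing")
                if abs(ends[-1] - total) > 1e-9:
                    raise ValueError(
                        f"haplotype of sample {self.sample_ids[si]} does not "
                        "tile the genome")
                if fids.min() < 0 or fids.max() >= self.n_founder_haps:
                    raise ValueError("founder id out of range")

    def intervals_table(self) -> pd.DataFrame:
        """Long-format table: sample, hap, chrom, start_cM, end_cM, founder."""
        rows = []
        for sid, (h0, h1) in zip(self.sample_ids, self.haps):
            for hap_no, (ends, fids) in enumerate((h0, h1)):
                for c, (a, b, fid) in self._split_by_chrom(ends, fids):
                    rows.append((f"{sid}_h{hap_no}", c, a, b, int(fid)))
        return pd.DataFrame(
            rows, columns=["haplotype_id", "chrom", "start_cM", "end_cM",
                           "founder_id"])

    def _split_by_chrom(self, ends, fids):
        for ci, name in enumerate(self.chrom_names):
            lo, hi = self.offsets[ci], self.offsets[ci + 1]
            ja = np.searchsorted(ends, lo, "right")
            jb = np.searchsorted(ends, hi, "left")
            prev = lo
            for j in range(ja, jb + 1):
                end = min(ends[j], hi)
                if end > prev:
                    yield name, (prev - lo, end - lo, fids[j])
                prev = end


def _shared_intervals(x: Hap, y: Hap) -> list[tuple[float, float]]:
    """Maximal intervals (global cM axis) where two haplotypes carry the
    same founder id."""
    ex, fx = x
    ey, fy = y
    allb = np.union1d(ex, ey)
    ix = np.searchsorted(ex, allb, "left")
    iy = np.searchsorted(ey, allb, "left")
    eq = fx[ix] == fy[iy]
    out = []
    start = 0.0
    prev_end = 0.0
    open_ = False
    for k in range(len(allb)):
        if eq[k] and not open_:
            start = prev_end
            open_ = True
        elif not eq[k] and open_:
            out.append((start, prev_end))
            open_ = False
        prev_end = allb[k]
    if open_:
        out.append((start, prev_end))
    return out


def _union_intervals(ivals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    out = [list(ivals[0])]
    for a, b in ivals[1:]:
        if a <= out[-1][1] + 1e-12:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def _intervals_to_segments(
    labeling: FounderSegmentLabeling,
    ivals: list[tuple[float, float]],
    min_cm: float,
    sample_a: str,
    sample_b: str,
) -> list[IBDSegment]:
    """Split global-axis intervals at chromosome boundaries, filter by
    length and convert to per-chromosome coordinates."""
    segs = []
    for a, b in ivals:
        ca = np.searchsorted(labeling.offsets, a, "right") - 1
        cb = np.searchsorted(labeling.offsets, b, "left") - 1
        for ci in range(ca, cb + 1):
            lo = max(a, labeling.offsets[ci])
            hi = min(b, labeling.offsets[ci + 1])
            if hi - lo >= min_cm:
                segs.append(IBDSegment(
                    sample_a, sample_b, labeling.chrom_names[ci],
                    start_cm=lo - labeling.offsets[ci],
                    end_cm=hi - labeling.offsets[ci]))
    return segs


def true_ibd_segments(
    labeling: FounderSegmentLabeling,
    sample_a: str,
    sample_b: str,
    min_cm: float = 3.0,
) -> list[IBDSegment]:
    """Ground-truth IBD between two samples: maximal intervals where *any*
    haplotype of A and *any* haplotype of B descend from the same founder
    haplotype, length >= ``min_cm`` (per chromosome)."""
    ia = labeling.sample_index(sample_a)
    ib = labeling.sample_index(sample_b)
    ivals: list[tuple[float, float]] = []
    for ha in labeling.haps[ia]:
        for hb in labeling.haps[ib]:
            ivals.extend(_shared_intervals(ha, hb))
    return _intervals_to_segments(
        labeling, _union_intervals(ivals), min_cm, sample_a, sample_b)


def true_autozygous_segments(
    labeling: FounderSegmentLabeling,
    sample: str,
    min_cm: float = 1.0,
) -> list[IBDSegment]:
    """Ground-truth autozygosity: intervals where a sample's two haplotypes
    descend from the same founder haplotype."""
    i = labeling.sample_index(sample)
    h0, h1 = labeling.haps[i]
    ivals = _union_intervals(_shared_intervals(h0, h1))
    return _intervals_to_segments(labeling, ivals, min_cm, sample, sample)


# ---------------------------------------------------------------------------
# gene dropping


def _transmit(parent: tuple[Hap, Hap], total_cm: float,
              cuts: np.ndarray, h: int) -> Hap:
    """One meiosis: recombine the parent's two haplotypes.

    ``cuts`` are the sorted switch positions on the concatenated cM axis
    (Poisson crossovers plus the chromosome boundaries where independent
    assortment flipped the source); ``h`` is the starting haplotype."""
    (e0, f0), (e1, f1) = parent
    bounds = np.empty(len(cuts) + 2)
    bounds[0] = 0.0
    if len(cuts):
        bounds[1:-1] = cuts
    bounds[-1] = total_cm
    # segment indices covering each interval start/end, per source haplotype
    ja0 = np.searchsorted(e0, bounds[:-1], "right")
    jb0 = np.searchsorted(e0, bounds[1:], "left")
    ja1 = np.searchsorted(e1, bounds[:-1], "right")
    jb1 = np.searchsorted(e1, bounds[1:], "left")
    pieces_e: list[np.ndarray] = []
    pieces_f: list[np.ndarray] = []
    for k in range(len(bounds) - 1):
        cut = bounds[k + 1]
        if cut <= bounds[k]:
            continue
        if (h + k) % 2 == 0:
            e, f, ja, jb = e0, f0, ja0[k], jb0[k]
        else:
            e, f, ja, jb = e1, f1, ja1[k], jb1[k]
        seg_e = e[ja:jb + 1].copy()
        seg_e[-1] = cut
        pieces_e.append(seg_e)
        pieces_f.append(f[ja:jb + 1])
    if not pieces_e:  # degenerate zero-length genome: copy one haplotype
        e, f = ((e0, f0) if h == 0 else (e1, f1))
        return e.copy(), f.copy()
    ends = np.concatenate(pieces_e)
    fids = np.concatenate(pieces_f)
    # merge adjacent segments from the same founder haplotype
    if len(fids) > 1:
        keep = np.empty(len(fids), dtype=bool)
        keep[-1] = True
        np.not_equal(fids[1:], fids[:-1], out=keep[:-1])
        if not keep.all():
            ends = ends[keep]
            fids = fids[keep]
    return ends, fids


def _run_wright_fisher(
    config: DemographyConfig,
    chrom_cm: np.ndarray,
    rng: np.random.Generator,
    n_sample: int | None = None,
) -> list[tuple[Hap, Hap]]:
    """Simulate the demography and return ``n_sample`` final-generation
    individuals (default: all).

    The pedigree (parent choices) is drawn first for every individual of
    every generation; haplotype transmissions are then materialised only
    along lineages ancestral to the sampled individuals, which prunes most
    of the work in large constant-size scenarios.
    """
    total = float(chrom_cm.sum())
    boundaries = np.cumsum(chrom_cm)[:-1]
    n_bound = boundaries.size
    morgans = total / 100.0
    sizes = config.generation_sizes()

    # pedigree: two distinct parents per individual per generation
    peds = []
    n_prev = config.founder_count
    for size in sizes:
        p1 = rng.integers(n_prev, size=size)
        p2 = (p1 + 1 + rng.integers(n_prev - 1, size=size)) % n_prev
        peds.append((p1, p2))
        n_prev = size
    if n_sample is None:
        n_sample = int(sizes[-1])
    if n_sample > sizes[-1]:
        raise ValueError("n_sample exceeds final generation size")
    chosen = rng.choice(int(sizes[-1]), size=n_sample, replace=False)

    # mark the individuals each generation actually needed
    needed: list[np.ndarray] = [np.empty(0)] * (len(sizes) + 1)
    needed[-1] = np.unique(chosen)
    for t in range(len(sizes) - 1, -1, -1):
        p1, p2 = peds[t]
        kids = needed[t + 1]
        needed[t] = np.unique(np.concatenate([p1[kids], p2[kids]]))

    # founder haplotypes: one whole-genome segment each, labelled 0..2F-1
    ends0 = np.array([total])
    prev: dict[int, tuple[Hap, Hap]] = {
        int(i): (
            (ends0.copy(), np.array([2 * i], dtype=np.int32)),
            (ends0.copy(), np.array([2 * i + 1], dtype=np.int32)),
        )
        for i in needed[0]
    }
    for t in range(len(sizes)):
        p1, p2 = peds[t]
        kids = needed[t + 1]
        n_tx = 2 * kids.size
        # pre-draw all meiosis randomness for this generation
        n_x = rng.poisson(morgans, size=n_tx)
        all_cuts = rng.uniform(0.0, total, int(n_x.sum()))
        offs = np.concatenate([[0], np.cumsum(n_x)])
        bflip = (rng.random((n_tx, n_bound)) < 0.5) if n_bound else None
        starts = rng.integers(0, 2, size=n_tx)
        cur: dict[int, tuple[Hap, Hap]] = {}
        for k, child in enumerate(kids):
            hap_pair = []
            for m, parent_idx in enumerate((p1[child], p2[child])):
                j = 2 * k + m
                cuts = all_cuts[offs[j]:offs[j + 1]]
                if n_bound:
                    flips = boundaries[bflip[j]]
                    if flips.size:
                        cuts = np.concatenate([cuts, flips])
                hap_pair.append(_transmit(
                    prev[int(parent_idx)], total, np.sort(cuts),
                    int(starts[j])))
            cur[int(child)] = (hap_pair[0], hap_pair[1])
        prev = cur
    return [prev[int(i)] for i in chosen]


def simulate_gene_dropping(
    config: DemographyConfig,
    marker_map: MarkerMap,
    founder_freqs: np.ndarray | None = None,
    n_sample: int | None = None,
    population_label: str = "pop0",
    seed: int | None = None,
) -> tuple[PhasedPanel, FounderSegmentLabeling]:
    """Run the demographic scenario and return a marker panel with truth.

    Parameters
    ----------
    config
        Demography; generation 0 holds ``founder_count`` unrelated founders
        whose haplotypes are the labelled ancestral material.
    marker_map
        Marker panel to materialise; chromosome lengths are the per-
        chromosome cM spans of this map.
    founder_freqs
        Per-marker allele-1 frequency in (0, 1) from which founder alleles
        are drawn independently.  Default: Uniform(0.05, 0.95) draws, which
        keeps markers polymorphic.
    n_sample
        Number of final-generation individuals to return (default: all).
    seed
        Overrides ``config.seed``.

    Returns
    -------
    (PhasedPanel, FounderSegmentLabeling)
        Panel of phased genotypes for the sampled individuals and the exact
        founder-origin mosaic of their haplotypes.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    slices = marker_map.chrom_slices()
    chrom_names = marker_map.chromosomes()
    # chromosome length = position of the last marker measured from the
    # chromosome's first marker (markers live on [0, L])
    chrom_cm = np.array(
        [marker_map.cm[hi - 1] - marker_map.cm[lo] for lo, hi in
         (slices[c] for c in chrom_names)])
    if founder_freqs is None:
        founder_freqs = rng.uniform(0.05, 0.95, len(marker_map))
    founder_freqs = np.asarray(founder_freqs, dtype=float)
    if founder_freqs.shape != (len(marker_map),):
        raise ValueError("founder_freqs must have one frequency per marker")
    if np.any((founder_freqs <= 0) | (founder_freqs >= 1)):
        raise ValueError("founder allele frequencies must be in (0, 1)")

    sampled = _run_wright_fisher(config, chrom_cm, rng, n_sample=n_sample)
    n_sample = len(sampled)
    sample_ids = np.array(
        [f"{population_label}_{i:04d}" for i in range(n_sample)], dtype=object)

    labeling = FounderSegmentLabeling(
        sample_ids, chrom_names, chrom_cm, sampled,
        2 * config.founder_count)

    # marker positions on the concatenated axis
    offsets = labeling.offsets
    gpos = np.empty(len(marker_map))
    for ci, c in enumerate(chrom_names):
        lo, hi = slices[c]
        gpos[lo:hi] = offsets[ci] + (marker_map.cm[lo:hi] - marker_map.cm[lo])

    # founder alleles are drawn lazily, one independent substream per
    # founder haplotype, and only for founders that survive in the sample
    # (identical in distribution to materialising all founders up front,
    # but a large constant-size scenario touches only a fraction of them)
    used = np.unique(np.concatenate(
        [f for pair in labeling.haps for (_, f) in pair]))
    allele_base = int(rng.integers(2**31 - 1))
    m_total = len(marker_map)
    founder_alleles = np.empty((used.size, m_total), dtype=np.uint8)
    for r, fid in enumerate(used):
        sub = np.random.default_rng((allele_base, int(fid)))
        founder_alleles[r] = sub.random(m_total) < founder_freqs

    col = np.arange(m_total)
    haps = np.empty((2 * n_sample, m_total), dtype=np.uint8)
    for si, (h0, h1) in enumerate(labeling.haps):
        for k, (ends, fids) in enumerate((h0, h1)):
            idx = np.searchsorted(ends, gpos, "left")
            idx = np.minimum(idx, len(ends) - 1)
            rows = np.searchsorted(used, fids[idx])
            haps[2 * si + k] = founder_alleles[rows, col]

    if config.error_rate > 0:
        flip = rng.random(haps.shape) < config.error_rate
        haps[flip] ^= 1
    if config.missing_rate > 0:
        miss = rng.random((n_sample, len(marker_map))) < config.missing_rate
        haps[0::2][miss] = MISSING_ALLELE
        haps[1::2][miss] = MISSING_ALLELE

    panel = PhasedPanel(
        haps, sample_ids, marker_map,
        np.full(n_sample, population_label, dtype=object))
    return panel, labeling


def sample_panel(panel: PhasedPanel, labeling: FounderSegmentLabeling,
                 index: np.ndarray) -> tuple[PhasedPanel, FounderSegmentLabeling]:
    """Restrict a simulated panel and its labeling to a subset of samples."""
    index = np.asarray(index)
    hap_idx = np.stack([2 * index, 2 * index + 1], axis=1).ravel()
    sub = PhasedPanel(panel.haplotypes[hap_idx], panel.sample_ids[index],
                      panel.markers, panel.populations[index])
    lab = FounderSegmentLabeling(
        labeling.sample_ids[index], labeling.chrom_names, labeling.chrom_cm,
        [labeling.haps[i] for i in index], labeling.n_founder_haps)
    return sub, lab


# ---------------------------------------------------------------------------
# renewal simulator of pair sharing (constant N)


def simulate_pair_sharing(
    N: int,
    u_cm: float,
    genome_cm,
    n_pairs: int,
    seed: int | None = None,
    _block_elems: int = 20_000_000,
) -> np.ndarray:
    """Per-pair genome fractions shared in IBD segments >= ``u_cm``.

    Walks each chromosome as a renewal process: each segment carries a pair
    TMRCA ``g`` (length-biased, g ~ Gamma(2, 2N); see module docstring)
    and a length
    ~ Exponential(mean 100/g cM), truncated at the chromosome end.  The
    returned fraction for a pair is (total length of segments of length
    >= u) / (total genome length).

    Parameters
    ----------
    N : int
        Constant effective population size (diploid), >= 2.
    u_cm : float
        Minimum segment length in cM, > 0.
    genome_cm : float or sequence of float
        A single chromosome length, or per-chromosome lengths.
    n_pairs : int
        Number of independent pairs to simulate.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if u_cm <= 0:
        raise ValueError("u_cm must be > 0")
    chrom_cm = np.atleast_1d(np.asarray(genome_cm, dtype=float))
    if np.any(chrom_cm <= 0):
        raise ValueError("chromosome lengths must be > 0")
    rng = np.random.default_rng(seed)
    p = 1.0 / (2.0 * N)
    mean_len = 100.0 * p
    total = chrom_cm.sum()
    shared = np.zeros(n_pairs)

    for L in chrom_cm:
        # stationary initialisation: the chromosome start falls inside a
        # segment of the stationary process — TMRCA from the point
        # marginal Exp(mean 2N), remaining (forward-recurrence) length
        # Exp(100/g).  Starting with an ordinary fresh draw instead would
        # under-represent long segments near the chromosome start and
        # bias the sharing fraction low.
        g0 = rng.exponential(2.0 * N, n_pairs)
        first = rng.exponential(100.0 / g0)
        credit = np.minimum(first, L)
        shared += np.where(credit >= u_cm, credit, 0.0)
        pos = first
        active = np.flatnonzero(first < L)
        while active.size:
            need = int((L - pos[active].min()) / mean_len * 1.2) + 16
            k = max(16, min(need, max(1, _block_elems // active.size)))
            na = active.size
            g = rng.gamma(2.0, 2.0 * N, (na, k))
            ln = rng.exponential(1.0, (na, k)) * (100.0 / g)
            cum = pos[active, None] + np.cumsum(ln, axis=1)
            start = cum - ln
            inside = cum <= L
            shared[active] += np.sum(ln * (inside & (ln >= u_cm)), axis=1)
            done = cum[:, -1] >= L
            if done.any():
                rows = np.flatnonzero(done)
                first_out = np.argmax(cum[rows] > L, axis=1)
                trunc = L - start[rows, first_out]
                ok = trunc >= u_cm
                shared[active[rows[ok]]] += trunc[ok]
            pos[active] = cum[:, -1]
            active = active[~done]
    return shared / total
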