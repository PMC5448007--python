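"""Core data containers: marker map, unphased genotypes, phased haplotypes.

All downstream analyses (QC, stratification, LD, IBD, ROH, Ne) consume these
three containers.  The marker map is the coordinate backbone: every segment
length in cM or Mb is derived from it.

Conventions
-----------
* bp positions are 1-based and intervals are closed.
* Dosages are minor-allele counts in {0, 1, 2}; ``-1`` marks missing.
* Phased alleles are in {0, 1}; ``255`` marks missing.
* Autosomes only; chromosomes are arbitrary string labels kept in file order.
* When a map lacks cM positions, 1 cM := 1 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_DOSAGE = -1
MISSING_ALLELE = 255

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "PhasedPanel",
    "MISSING_DOSAGE",
    "MISSING_ALLELE",
]


@dataclass
class MarkerMap:
    """Ordered biallelic marker map.

    Parameters
    ----------
    chrom : array of str
        Chromosome label per marker; markers of one chromosome must be
        contiguous and sorted by position.
    ids : array of str
        Marker identifiers.
    bp : array of int
        1-based physical positions, non-decreasing within chromosome.
    cm : array of float, optional
        Genetic positions.  If omitted, derived from bp at 1 cM per Mb.
    a1, a2 : arrays of str, optional
        Allele pair per marker (a1 = the allele counted by the dosage).
    """

    chrom: np.ndarray
    ids: np.ndarray
    bp: np.ndarray
    cm: np.ndarray | None = None
    a1: np.ndarray | None = None
    a2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        if self.cm is None:
            self.cm = self.bp / 1e6
        self.cm = np.asarray(self.cm, dtype=float)
        n = len(self.chrom)
        if not (len(self.ids) == len(self.bp) == len(self.cm) == n):
            raise ValueError("marker map columns have unequal lengths")
        if self.a1 is None:
            self.a1 = np.full(n, "A", dtype=object)
        if self.a2 is None:
            self.a2 = np.full(n, "B", dtype=object)
        self.a1 = np.asarray(self.a1, dtype=object)
        self.a2 = np.asarray(self.a2, dtype=object)
        # chromosome blocks must be contiguous, positions sorted within
        seen: dict[str, int] = {}
        prev = None
        for i, c in enumerate(self.chrom):
            if c != prev:
                if c in seen:
                    raise ValueError(f"chromosome {c!r} appears in two blocks")
                seen[c] = i
                prev = c
        for c, (lo, hi) in self.chrom_slices().items():
            if np.any(np.diff(self.bp[lo:hi]) < 0):
                raise ValueError(f"bp positions decrease within chromosome {c}")
            if np.any(np.diff(self.cm[lo:hi]) < 0):
                raise ValueError(f"cM positions decrease within chromosome {c}")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def n_markers(self) -> int:
        return len(self.chrom)

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slices(self) -> dict[str, tuple[int, int]]:
        """Map chromosome -> (start, stop) marker-index slice."""
        out: dict[str, tuple[int, int]] = {}
        start = 0
        chroms = self.chrom
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = (start, i)
                start = i
        return out

    def chrom_span_cm(self) -> dict[str, float]:
        """cM span (last minus first marker) per chromosome."""
        return {
            c: float(self.cm[hi - 1] - self.cm[lo])
            for c, (lo, hi) in self.chrom_slices().items()
        }

    def total_cm(self) -> float:
        """Total autosomal map length: sum of per-chromosome cM spans."""
        return float(sum(self.chrom_span_cm().values()))

    def subset(self, index: np.ndarray) -> "MarkerMap":
        index = np.asarray(index)
        return MarkerMap(
            self.chrom[index], self.ids[index], self.bp[index],
            self.cm[index], self.a1[index], self.a2[index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "id": self.ids,
                "bp": self.bp,
                "cm": self.cm,
                "a1": self.a1,
                "a2": self.a2,
            }
        )

    def interp_cm(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        """Linearly interpolate cM at arbitrary bp positions on a chromosome."""
        lo, hi = self.chrom_slices()[chrom]
        return np.interp(np.asarray(bp, dtype=float),
                         self.bp[lo:hi].astype(float), self.cm[lo:hi])


def _check_labels(sample_ids, populations, n):
    sample_ids = np.asarray(sample_ids, dtype=object)
    if len(sample_ids) != n:
        raise ValueError("sample id count mismatch")
    if len(set(sample_ids)) != n:
        raise ValueError("duplicate sample ids")
    if populations is None:
        populations = np.full(n, "pop0", dtype=object)
    populations = np.asarray(populations, dtype=object)
    if len(populations) != n:
        raise ValueError("population label count mismatch")
    return sample_ids, populations


@dataclass
class GenotypeMatrix:
    """Unphased dosages, samples x markers, values in {0,1,2,-1(missing)}."""

    dosages: np.ndarray
    sample_ids: np.ndarray
    markers: MarkerMap
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x markers)")
        if self.dosages.shape[1] != len(self.markers):
            raise ValueError("marker count mismatch between dosages and map")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING_DOSAGE))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")
        self.sample_ids, self.populations = _check_labels(
            self.sample_ids, self.populations, self.dosages.shape[0]
        )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING_DOSAGE

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero(self.sample_ids == sample_id)
        if len(idx) == 0:
            raise KeyError(f"unknown sample {sample_id!r}")
        return int(idx[0])

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index], self.sample_ids,
            self.markers.subset(index), self.populations,
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index], self.sample_ids[index],
            self.markers, self.populations[index],
        )


@dataclass
class PhasedPanel:
    """Phased biallelic haplotypes.

    ``haplotypes`` has shape (2 * n_samples, n_markers); rows 2i and 2i+1
    are the two haplotypes of sample i.  This container carries *known*
    phase (from a simulator or an external phasing run); nothing in the
    package phases genotypes statistically.
    """

    haplotypes: np.ndarray
    sample_ids: np.ndarray
    markers: MarkerMap
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype count must be 2 x sample count")
        if self.haplotypes.shape[1] != len(self.markers):
            raise ValueError("marker count mismatch between haplotypes and map")
        bad = ~np.isin(self.haplotypes, (0, 1, MISSING_ALLELE))
        if bad.any():
            raise ValueError("alleles must be 0, 1 or 255 (missing)")
        self.sample_ids, self.populations = _check_labels(
            self.sample_ids, self.populations, self.haplotypes.shape[0] // 2
        )

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero(self.sample_ids == sample_id)
        if len(idx) == 0:
            raise KeyError(f"unknown sample {sample_id!r}")
        return int(idx[0])

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse phase to dosages (missing if either allele missing)."""
        h = self.haplotypes.astype(np.int16)
        a = h[0::2]
        b = h[1::2]
        dos = (a + b).astype(np.int16)
        dos[(a == MISSING_ALLELE) | (b == MISSING_ALLELE)] = MISSING_DOSAGE
        return GenotypeMatrix(
            dos.astype(np.int8), self.sample_ids, self.markers, self.populations
        )
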