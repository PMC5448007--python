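"""Segment records shared by the IBD detector, ROH scanner and simulator."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["IBDSegment", "ROHSegment"]


@dataclass
class IBDSegment:
    """A shared (identical-by-descent) interval between two samples.

    Lengths are carried in both genetic (cM) and physical (Mb) units; the
    marker-index and bp fields are filled by the detector and left ``None``
    for ground-truth segments that exist independently of any marker panel.
    """

    sample_a: str
    sample_b: str
    chrom: str
    start_cm: float
    end_cm: float
    start_bp: int | None = None
    end_bp: int | None = None
    start_idx: int | None = None
    end_idx: int | None = None
    n_markers: int | None = None
    n_mismatch: int | None = None

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def length_mb(self) -> float:
        if self.start_bp is None or self.end_bp is None:
            # genetic map only: fall back on the 1 cM := 1 Mb convention
            return self.length_cm
        return (self.end_bp - self.start_bp + 1) / 1e6


@dataclass
class ROHSegment:
    """A run of homozygosity in one individual."""

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    start_idx: int
    end_idx: int
    n_markers: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1e3

    @property
    def length_mb(self) -> float:
        return self.length_kb / 1e3
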