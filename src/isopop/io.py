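"""Readers and writers for the text genotype formats the pipeline consumes.

Supported formats
-----------------
* PED/MAP (whitespace-separated PLINK text): unphased genotypes.
* VCF 4.x (via pysam): unphased dosages or phased haplotypes (``GT`` with
  ``|`` separators); non-biallelic records are skipped with a logged count.
* HAPS-style phased text (one marker per line: chrom, id, bp, allele0,
  allele1, then two 0/1 columns per sample) with a companion ``.sample``
  file carrying sample ids and population labels.
* Founder-labeling TSV (haplotype_id, chrom, start_cM, end_cM, founder_id).

Round-trip identity (write then read) holds for all retained records.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .panel import (MISSING_ALLELE, MISSING_DOSAGE, GenotypeMatrix,
                    MarkerMap, PhasedPanel)
from .simdata import FounderSegmentLabeling

logger = logging.getLogger(__name__)

__all__ = [
    "read_ped_map", "write_ped_map",
    "read_vcf", "write_vcf",
    "read_haps", "write_haps",
    "write_labeling", "read_labeling",
]


class FormatError(ValueError):
    """Malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# PED / MAP


def write_ped_map(g: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    m = g.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for i in range(len(m)):
            fh.write(f"{m.chrom[i]}\t{m.ids[i]}\t{m.cm[i]:.6f}\t{m.bp[i]}\n")
    code = {
        2: lambda i: (m.a1[i], m.a1[i]),
        1: lambda i: (m.a1[i], m.a2[i]),
        0: lambda i: (m.a2[i], m.a2[i]),
        MISSING_DOSAGE: lambda i: ("0", "0"),
    }
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for s in range(g.n_samples):
            row = [str(g.populations[s]), str(g.sample_ids[s]),
                   "0", "0", "0", "-9"]
            dos = g.dosages[s]
            for i in range(len(m)):
                a, b = code[int(dos[i])](i)
                row.append(str(a))
                row.append(str(b))
            fh.write(" ".join(row) + "\n")


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    chroms, ids, cms, bps = [], [], [], []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 columns")
            chroms.append(parts[0])
            ids.append(parts[1])
            try:
                cms.append(float(parts[2]))
                bps.append(int(parts[3]))
            except ValueError as e:
                raise FormatError(f"{map_path}:{ln}: {e}") from None
    n_mark = len(ids)

    sample_ids, pops, rows = [], [], []
    allele_sets: list[dict[str, int]] = [dict() for _ in range(n_mark)]
    raw: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_mark:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_mark} columns, "
                    f"got {len(parts)}")
            pops.append(parts[0])
            sample_ids.append(parts[1])
            pairs = list(zip(parts[6::2], parts[7::2]))
            raw.append(pairs)
            for i, (a, b) in enumerate(pairs):
                for al in (a, b):
                    if al != "0":
                        allele_sets[i].setdefault(al, len(allele_sets[i]))

    a1 = np.empty(n_mark, dtype=object)
    a2 = np.empty(n_mark, dtype=object)
    for i, seen in enumerate(allele_sets):
        alleles = sorted(seen)
        if len(alleles) > 2:
            raise FormatError(
                f"{ped_path}: marker {ids[i]} has more than two alleles")
        a1[i] = alleles[0] if alleles else "A"
        a2[i] = alleles[1] if len(alleles) > 1 else "B"

    dos = np.full((len(raw), n_mark), MISSING_DOSAGE, dtype=np.int8)
    for s, pairs in enumerate(raw):
        for i, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                continue
            dos[s, i] = int(a == a1[i]) + int(b == a1[i])
    markers = MarkerMap(np.array(chroms, dtype=object),
                        np.array(ids, dtype=object),
                        np.array(bps), np.array(cms), a1, a2)
    return GenotypeMatrix(dos, np.array(sample_ids, dtype=object), markers,
                          np.array(pops, dtype=object))


# ---------------------------------------------------------------------------
# VCF (pysam)


def _vcf_header(markers: MarkerMap, sample_ids, populations) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    spans = {}
    for c, (lo, hi) in markers.chrom_slices().items():
        spans[c] = int(markers.bp[hi - 1]) + 1
    for c, length in spans.items():
        header.add_line(f"##contig=<ID={c},length={length}>")
    # population labels travel in the companion .sample file, not the VCF
    for sid in sample_ids:
        header.add_sample(str(sid))
    return header


def write_vcf(data: GenotypeMatrix | PhasedPanel, path: str | Path) -> None:
    """Write a plain-text VCF; phased panels get ``|``-separated GT."""
    phased = isinstance(data, PhasedPanel)
    m = data.markers
    header = _vcf_header(m, data.sample_ids, data.populations)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(len(m)):
            rec = out.new_record(
                contig=str(m.chrom[i]), start=int(m.bp[i]) - 1,
                stop=int(m.bp[i]),
                alleles=(str(m.a2[i]), str(m.a1[i])),  # REF=a2, ALT=a1
                id=str(m.ids[i]),
            )
            if phased:
                h = data.haplotypes
                for s in range(data.n_samples):
                    x, y = int(h[2 * s, i]), int(h[2 * s + 1, i])
                    gt = (None if x == MISSING_ALLELE else x,
                          None if y == MISSING_ALLELE else y)
                    rec.samples[s]["GT"] = gt
                    rec.samples[s].phased = True
            else:
                for s in range(data.n_samples):
                    d = int(data.dosages[s, i])
                    if d == MISSING_DOSAGE:
                        rec.samples[s]["GT"] = (None, None)
                    else:
                        rec.samples[s]["GT"] = (1, 1) if d == 2 else (
                            (0, 1) if d == 1 else (0, 0))
            out.write(rec)


def read_vcf(path: str | Path, phased: bool = False,
             populations=None) -> GenotypeMatrix | PhasedPanel:
    """Read a biallelic VCF into a genotype matrix or phased panel.

    With ``phased=True`` every genotype must be phased (``|``); an unphased
    heterozygote raises.  Multi-allelic and non-SNP records are skipped
    (count logged).
    """
    chroms, ids, bps, a1s, a2s = [], [], [], [], []
    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = np.array(list(vf.header.samples), dtype=object)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            chroms.append(rec.contig)
            ids.append(rec.id or f"{rec.contig}:{rec.pos}")
            bps.append(rec.pos)
            a2s.append(rec.ref)
            a1s.append(rec.alts[0])
            col = []
            for s in sample_ids:
                call = rec.samples[str(s)]
                gt = call["GT"]
                if phased and not call.phased and gt[0] is not None \
                        and len(set(gt)) > 1:
                    raise FormatError(
                        f"{path}: unphased genotype for sample {s} at "
                        f"{rec.contig}:{rec.pos} in phased mode")
                col.append(gt)
            rows.append(col)
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic records", skipped)
    markers = MarkerMap(
        np.array(chroms, dtype=object), np.array(ids, dtype=object),
        np.array(bps), None, np.array(a1s, dtype=object),
        np.array(a2s, dtype=object))
    n_s, n_m = len(sample_ids), len(markers)
    if phased:
        haps = np.full((2 * n_s, n_m), MISSING_ALLELE, dtype=np.uint8)
        for i, col in enumerate(rows):
            for s, gt in enumerate(col):
                if gt[0] is not None:
                    haps[2 * s, i] = gt[0]
                if len(gt) > 1 and gt[1] is not None:
                    haps[2 * s + 1, i] = gt[1]
        return PhasedPanel(haps, sample_ids, markers, populations)
    dos = np.full((n_s, n_m), MISSING_DOSAGE, dtype=np.int8)
    for i, col in enumerate(rows):
        for s, gt in enumerate(col):
            if gt[0] is not None and (len(gt) < 2 or gt[1] is not None):
                dos[s, i] = sum(gt)
    return GenotypeMatrix(dos, sample_ids, markers, populations)


# ---------------------------------------------------------------------------
# HAPS-style phased text


def write_haps(panel: PhasedPanel, prefix: str | Path) -> None:
    prefix = Path(prefix)
    m = panel.markers
    with open(prefix.with_suffix(".haps"), "w") as fh:
        for i in range(len(m)):
            cols = [str(m.chrom[i]), str(m.ids[i]), str(m.bp[i]),
                    str(m.a2[i]), str(m.a1[i])]
            for v in panel.haplotypes[:, i]:
                cols.append("?" if v == MISSING_ALLELE else str(int(v)))
            fh.write(" ".join(cols) + "\n")
    with open(prefix.with_suffix(".sample"), "w") as fh:
        fh.write("ID_1 ID_2 missing population\n0 0 0 D\n")
        for sid, pop in zip(panel.sample_ids, panel.populations):
            fh.write(f"{sid} {sid} 0 {pop}\n")


def read_haps(prefix: str | Path, cm: np.ndarray | None = None) -> PhasedPanel:
    prefix = Path(prefix)
    haps_path = prefix.with_suffix(".haps")
    sample_path = prefix.with_suffix(".sample")
    sample_ids, pops = [], []
    with open(sample_path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    for ln, parts in enumerate(lines[2:], 3):
        if len(parts) < 4:
            raise FormatError(f"{sample_path}:{ln}: expected 4 columns")
        sample_ids.append(parts[0])
        pops.append(parts[3])
    n_s = len(sample_ids)

    chroms, ids, bps, a1s, a2s, hap_cols = [], [], [], [], [], []
    with open(haps_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5 + 2 * n_s:
                raise FormatError(
                    f"{haps_path}:{ln}: expected {5 + 2 * n_s} columns, "
                    f"got {len(parts)}")
            chroms.append(parts[0])
            ids.append(parts[1])
            try:
                bps.append(int(parts[2]))
            except ValueError:
                raise FormatError(f"{haps_path}:{ln}: bad bp position") from None
            a2s.append(parts[3])
            a1s.append(parts[4])
            try:
                hap_cols.append([
                    MISSING_ALLELE if v == "?" else int(v)
                    for v in parts[5:]])
            except ValueError:
                raise FormatError(f"{haps_path}:{ln}: bad allele code") from None
    markers = MarkerMap(
        np.array(chroms, dtype=object), np.array(ids, dtype=object),
        np.array(bps), cm, np.array(a1s, dtype=object),
        np.array(a2s, dtype=object))
    haps = np.array(hap_cols, dtype=np.uint8).T
    return PhasedPanel(haps, np.array(sample_ids, dtype=object), markers,
                       np.array(pops, dtype=object))


# ---------------------------------------------------------------------------
# founder labeling TSV


def write_labeling(labeling: FounderSegmentLabeling, path: str | Path) -> None:
    labeling.intervals_table().to_csv(path, sep="\t", index=False)


def read_labeling(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
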