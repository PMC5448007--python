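"""End-to-end pipeline: QC → stratification → F_ST → LD decay → IBD → ROH
→ Ne, with a config file, deterministic seeding and TSV outputs.

The pipeline runs either on user-supplied files (PED/MAP or VCF genotypes,
HAPS/VCF phased haplotypes, population labels) or on the bundled synthetic
scenario (bottlenecked isolate vs outbred control) generated on the fly.
Every output file carries a header comment with the tool version and a
hash of the effective configuration, so a run can be matched to its
settings later.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .panel import GenotypeMatrix, PhasedPanel
from . import io as iomod
from . import qc as qcmod
from . import simdata
from .ibd import (filter_segments_by_mask, germline_scan, pair_summaries,
                  segments_to_dataframe, sparse_region_mask)
from .lddecay import decay_profile
from .ne import estimate_ne, ne_permutation_diff
from .permstats import wilcoxon_rank_sum, label_permutation_test
from .roh import roh_bins, roh_scan, roh_totals_and_test
from .structure import ibs_matrix, mds, pairwise_fst

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures",
           "combine_panels"]

_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "isopop_out",
    "synthetic": {
        "enabled": True,
        "chrom_cm": [80.0] * 6,
        "n_markers": 24_000,
        "n_isolate": 40,
        "n_control": 40,
        "control_size": 10_000,
    },
    "inputs": {
        "haps_prefix": None,
        "vcf": None,
        "ped_prefix": None,
    },
    "qc": {
        "geno": 0.05,
        "mind": 0.05,
        "maf": 0.01,
        "pi_hat_max": 0.1,
        "pi_hat_min_markers": 1000,
        "prune_r2": 0.2,
        "prune_window": 50,
        "prune_step": 5,
    },
    "mds": {"k": 4},
    "fst": {"permutations": 100, "ci_boot_loci": 100},
    "ld": {"subsample": 25, "max_kb": 500.0, "bin_kb": 5.0,
           "chroms": None},
    "ibd": {"min_cm": 3.0, "word": 64, "max_mismatch": 1,
            "exclude_sparse": False, "permutations": 1000},
    "roh": {"min_kb": 1000.0, "min_snps": 100, "density": 50.0,
            "gap": 1000.0, "permutations": 1000},
    "ne": {"u_cm": 7.0, "bootstrap": 1000, "permutations": 1000,
           "unit": "segment"},
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for k, v in override.items():
        if k not in defaults:
            raise ValueError(f"unknown config key {path + k!r}")
        if isinstance(defaults[k], dict) and isinstance(v, dict):
            out[k] = _merge(defaults[k], v, path + k + ".")
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected."""

    settings: dict = field(default_factory=lambda: dict(_DEFAULTS))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(_merge(_DEFAULTS, d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(d)

    def __getitem__(self, key):
        return self.settings[key]

    def hash(self) -> str:
        blob = json.dumps(self.settings, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def combine_panels(a: PhasedPanel, b: PhasedPanel) -> PhasedPanel:
    """Concatenate two phased panels that share a marker map."""
    if len(a.markers) != len(b.markers) or np.any(a.markers.bp != b.markers.bp):
        raise ValueError("panels must share a marker map")
    return PhasedPanel(
        np.vstack([a.haplotypes, b.haplotypes]),
        np.concatenate([a.sample_ids, b.sample_ids]),
        a.markers,
        np.concatenate([a.populations, b.populations]),
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# isopop {__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _simulate_scenario(cfg: PipelineConfig, seed: int):
    s = cfg["synthetic"]
    rng = np.random.default_rng(seed)
    map_seed, iso_seed, ctl_seed = rng.integers(2**31 - 1, size=3)
    mmap = simdata.make_marker_map(
        s["chrom_cm"], s["n_markers"], spacing="random", seed=int(map_seed))
    freqs = np.random.default_rng(int(map_seed) + 1).uniform(
        0.05, 0.95, len(mmap))
    iso_panel, iso_lab = simdata.simulate_gene_dropping(
        simdata.isolate_config(), mmap, founder_freqs=freqs,
        n_sample=s["n_isolate"], population_label="ISO", seed=int(iso_seed))
    ctl_cfg = simdata.DemographyConfig(
        s["control_size"], [simdata.Epoch(12, s["control_size"])])
    ctl_panel, ctl_lab = simdata.simulate_gene_dropping(
        ctl_cfg, mmap, founder_freqs=freqs,
        n_sample=s["n_control"], population_label="CTL", seed=int(ctl_seed))
    return combine_panels(iso_panel, ctl_panel), (iso_lab, ctl_lab)


def _load_inputs(cfg: PipelineConfig) -> PhasedPanel:
    inp = cfg["inputs"]
    if inp["haps_prefix"]:
        return iomod.read_haps(inp["haps_prefix"])
    if inp["vcf"]:
        return iomod.read_vcf(inp["vcf"], phased=True)
    raise ValueError("no phased input configured and synthetic mode disabled")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None
                 ) -> dict:
    """Run every stage and write the report bundle; returns a result dict.

    Deterministic for a fixed config (all stage seeds derive from
    ``cfg['seed']``).  A stage failure raises with the stage named;
    outputs written before the failure are retained.
    """
    t0 = time.time()
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.hash()
    seed = int(cfg["seed"])
    sub = np.random.default_rng(seed).integers(2**31 - 1, size=8)
    report: dict = {"config_hash": h, "version": __version__, "seed": seed}
    stage = "setup"
    try:
        # ----------------------------------------------------------- input
        stage = "input"
        if cfg["synthetic"]["enabled"]:
            panel, _labs = _simulate_scenario(cfg, int(sub[0]))
        else:
            panel = _load_inputs(cfg)
        geno = panel.to_genotypes()
        logger.info("input: %d samples x %d markers (%.1fs)",
                    geno.n_samples, geno.n_markers, time.time() - t0)

        # -------------------------------------------------------------- qc
        stage = "qc"
        q = cfg["qc"]
        geno_f = qcmod.filter_samples(
            qcmod.filter_markers(geno, q["geno"], q["maf"]), q["mind"])
        kept_m = np.flatnonzero(np.isin(geno.markers.ids, geno_f.markers.ids))
        kept_s = np.flatnonzero(np.isin(geno.sample_ids, geno_f.sample_ids))
        if q["pi_hat_max"] is not None:
            pi = qcmod.pi_hat_matrix(geno_f, q["pi_hat_min_markers"])
            keep = qcmod.relatedness_exclusion(
                geno_f, q["pi_hat_max"], pi=pi)
            geno_f = geno_f.subset_samples(keep)
            kept_s = kept_s[keep]
        panel_f = PhasedPanel(
            panel.haplotypes[np.stack([2 * kept_s, 2 * kept_s + 1], 1)
                             .ravel()][:, kept_m],
            panel.sample_ids[kept_s], geno_f.markers,
            panel.populations[kept_s])
        report["qc"] = {
            "markers_kept": int(geno_f.n_markers),
            "samples_kept": int(geno_f.n_samples),
            "samples_by_pop": {
                p: int((geno_f.populations == p).sum())
                for p in sorted(set(geno_f.populations))},
        }
        _write_tsv(pd.DataFrame([report["qc"]["samples_by_pop"]]),
                   out / "qc_report.tsv", h)

        pops = sorted(set(geno_f.populations))
        two_pops = len(pops) == 2

        # ---------------------------------------------------- mds (pruned)
        stage = "mds"
        pruned = geno_f.subset_markers(qcmod.ld_prune(
            geno_f, q["prune_r2"], q["prune_window"], q["prune_step"]))
        mres = mds(ibs_matrix(pruned), cfg["mds"]["k"],
                   sample_ids=geno_f.sample_ids)
        mdf = mres.to_dataframe()
        mdf["population"] = geno_f.populations
        _write_tsv(mdf, out / "mds.tsv", h)
        report["mds"] = {"eigenvalues": mres.eigenvalues.tolist(),
                         "pruned_markers": int(pruned.n_markers)}

        # ------------------------------------------------------------- fst
        stage = "fst"
        f = cfg["fst"]
        fres = pairwise_fst(geno_f, n_perm=f["permutations"],
                            ci_boot_loci=f["ci_boot_loci"], seed=int(sub[1]))
        _write_tsv(fres.fst.reset_index(names="population"),
                   out / "fst.tsv", h)
        report["fst"] = {
            f"{a}~{b}": fres.pair(a, b)
            for a, b in combinations(fres.populations, 2)}

        # -------------------------------------------------------------- ld
        stage = "ld"
        ld = cfg["ld"]
        chroms = ld["chroms"] or geno_f.markers.chromosomes()
        ld_frames = []
        report["ld"] = {}
        for k, pop in enumerate(pops):
            prof = decay_profile(
                geno_f, population=pop, chroms=chroms, max_kb=ld["max_kb"],
                bin_kb=ld["bin_kb"], subsample_n=ld["subsample"],
                seed=int(sub[2]) + k)
            ld_frames.append(prof.to_dataframe())
            report["ld"][pop] = {
                "mean_r2_overall": float(np.nansum(
                    prof.mean_r2 * prof.n_pairs) / prof.n_pairs.sum())}
        _write_tsv(pd.concat(ld_frames), out / "ld_decay.tsv", h)

        # ------------------------------------------------------------- ibd
        stage = "ibd"
        ib = cfg["ibd"]
        segments = germline_scan(
            panel_f, word_markers=ib["word"],
            max_mismatch_per_window=ib["max_mismatch"], min_cm=ib["min_cm"])
        if ib["exclude_sparse"]:
            mask = sparse_region_mask(panel_f.markers)
            segments = filter_segments_by_mask(segments, mask)
        _write_tsv(segments_to_dataframe(segments),
                   out / "ibd_segments.tsv", h)
        report["ibd"] = {}
        for pop in pops:
            summ = pair_summaries(segments, geno_f.sample_ids,
                                  geno_f.populations, "within", pop)
            report["ibd"][f"within_{pop}"] = {
                "n_pairs": summ.n_pairs, "n_segments": summ.n_segments,
                "mean_total_mb": float(summ.stats.loc["mean", "total_mb"]),
                "median_total_mb": float(
                    summ.stats.loc["median", "total_mb"]),
            }
        if two_pops:
            summ = pair_summaries(segments, geno_f.sample_ids,
                                  geno_f.populations, "between")
            report["ibd"]["between"] = {
                "n_pairs": summ.n_pairs, "n_segments": summ.n_segments,
                "mean_total_mb": float(summ.stats.loc["mean", "total_mb"])}
            # permutation test on per-pair totals (individual relabelling)
            n = geno_f.n_samples
            idx = {s: i for i, s in enumerate(geno_f.sample_ids)}
            mat = np.zeros((n, n))
            for s in segments:
                a, b = idx.get(s.sample_a), idx.get(s.sample_b)
                if a is not None and b is not None:
                    mat[a, b] += s.length_mb
                    mat[b, a] += s.length_mb
            tres = label_permutation_test(
                mat, geno_f.populations, statistic=wilcoxon_rank_sum,
                n_perm=ib["permutations"], pairwise=True, seed=int(sub[3]))
            report["ibd"]["p_total_mb"] = tres.p_value

        # ------------------------------------------------------------- roh
        stage = "roh"
        r = cfg["roh"]
        roh_segs = roh_scan(
            geno_f, min_kb=r["min_kb"], min_snps=r["min_snps"],
            max_kb_per_snp=r["density"], max_gap_kb=r["gap"])
        _write_tsv(pd.DataFrame([
            {"sample": s.sample, "chrom": s.chrom, "start_bp": s.start_bp,
             "end_bp": s.end_bp, "n_markers": s.n_markers,
             "length_kb": s.length_kb} for s in roh_segs]),
            out / "roh_segments.tsv", h)
        bins = roh_bins(roh_segs, geno_f.sample_ids, geno_f.populations,
                        min_mb=r["min_kb"] / 1000.0)
        _write_tsv(bins, out / "roh_bins.tsv", h)
        report["roh"] = {"bins": bins.to_dict("records")}
        if two_pops:
            totals, tests = roh_totals_and_test(
                roh_segs, geno_f.sample_ids, geno_f.populations,
                n_perm=r["permutations"], seed=int(sub[4]))
            _write_tsv(totals, out / "roh_totals.tsv", h)
            report["roh"]["mean_total_mb"] = {
                p: float(totals.total_mb[geno_f.populations == p].mean())
                for p in pops}
            report["roh"]["p_total_mb"] = tests["total_mb"].p_value

        # -------------------------------------------------------------- ne
        stage = "ne"
        ne_cfg = cfg["ne"]
        genome_cm = geno_f.markers.total_cm()
        report["ne"] = {"u_cm": ne_cfg["u_cm"], "genome_cm": genome_cm}
        for pop in pops:
            ids = geno_f.sample_ids[geno_f.populations == pop]
            est = estimate_ne(
                segments, ids, u_cm=ne_cfg["u_cm"], genome_cm=genome_cm,
                B=ne_cfg["bootstrap"], unit=ne_cfg["unit"],
                seed=int(sub[5]))
            report["ne"][pop] = {
                "f": est.f, "ne": est.ne,
                "ci": list(est.ci) if est.ci else None}
        if two_pops:
            pres = ne_permutation_diff(
                segments, geno_f.sample_ids, geno_f.populations,
                ne_cfg["u_cm"], genome_cm,
                n_perm=ne_cfg["permutations"], seed=int(sub[6]))
            report["ne"]["p_diff_f"] = pres.p_value
        with open(out / "ne_report.json", "w") as fh:
            json.dump(report["ne"], fh, indent=2)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    report["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small, seed-reproducible synthetic dataset bundle.

    Produces PED/MAP, phased VCF, HAPS text and the founder-labeling TSV
    for a scaled isolate+control pair; regenerable bit-identically from
    the same seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    map_seed, iso_seed, ctl_seed = (int(x) for x in
                                    rng.integers(2**31 - 1, size=3))
    mmap = simdata.make_marker_map([50.0, 50.0], 4000, seed=map_seed)
    freqs = np.random.default_rng(map_seed + 1).uniform(0.05, 0.95,
                                                        len(mmap))
    iso, iso_lab = simdata.simulate_gene_dropping(
        simdata.isolate_config(), mmap, founder_freqs=freqs, n_sample=20,
        population_label="ISO", seed=iso_seed)
    ctl, ctl_lab = simdata.simulate_gene_dropping(
        simdata.DemographyConfig(2000, [simdata.Epoch(12, 2000)]), mmap,
        founder_freqs=freqs, n_sample=20, population_label="CTL",
        seed=ctl_seed)
    panel = combine_panels(iso, ctl)
    paths = {}
    iomod.write_ped_map(panel.to_genotypes(), out / "panel")
    paths["ped"] = out / "panel.ped"
    iomod.write_vcf(panel, out / "panel.vcf")
    paths["vcf"] = out / "panel.vcf"
    iomod.write_haps(panel, out / "panel")
    paths["haps"] = out / "panel.haps"
    iomod.write_labeling(iso_lab, out / "isolate_labeling.tsv")
    paths["labeling"] = out / "isolate_labeling.tsv"
    return paths
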