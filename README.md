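# isopop

Genetic-isolate characterization: identity-by-descent (IBD) sharing,
runs of homozygosity (ROH), linkage-disequilibrium (LD) decay, pairwise
F_ST and IBD-based effective population size (Ne), with a forward
simulator that provides exact ground truth for every detector.

## The problem

A population founded by few individuals and expanded rapidly — an
island community reduced to ~150 inhabitants by a 17th-century epidemic
and now numbering tens of thousands, say — concentrates its ancestry in
a handful of founder genomes. The genomic fingerprints are distinctive:
random pairs of members share long chromosomal segments identical by
descent, individuals carry long autozygous (homozygous) tracts, LD
decays slowly with distance, and the recent effective population size
inferred from segment sharing is orders of magnitude below that of an
outbred reference. `isopop` implements the full analysis chain used to
establish such a pattern from genome-wide SNP data, for researchers
evaluating candidate isolates or building power arguments for mapping
studies in them.

## The statistics at the core

* **IBD detection** (GERMLINE-style): phased haplotypes are cut into
  64-marker words; exact word matches, found by hashing, seed segments
  that are extended allowing ≤ 1 mismatch per 64-marker window; the four
  haplotype pairings of a sample pair are merged into genotype-level
  segments and filtered at ≥ 3 cM.
* **ROH scanning**: sliding 50-SNP windows (≤ 1 het, ≤ 5 missing) mark
  eligible SNPs; maximal runs ≥ 1000 kb with ≥ 100 SNPs at ≤ 50 kb/SNP
  are reported, split at gaps > 1 Mb.
* **Weir–Cockerham F_ST**: per-locus variance components a, b, c
  combined as Σa/Σ(a+b+c), permutation p-values, bootstrap-over-loci
  CIs.
* **LD decay**: mean dosage r² in 5-kb distance bins to 500 kb on
  25-subject subsamples.
* **Effective population size**: with `f` the mean fraction of genome a
  pair shares in segments ≥ `u` cM,

      Ne = 50 (1 − f + √(1 − f)) / (u f),

  with percentile-bootstrap CIs and permutation tests on group
  differences (default u = 7 cM, targeting sharing from roughly the
  last 20 generations).
* **Gene-dropping simulation**: Wright–Fisher forward simulation with
  Poisson recombination and founder-segment tracking, yielding panels
  (PED/MAP, VCF, HAPS) plus the exact founder-origin mosaic from which
  true IBD and true autozygosity are derived.

See `docs/methods.md` for model assumptions, parameter defaults and
known limitations (including the calibration of the Ne closed form).

## Worked example

Simulate an isolate (151 founders growing to 2,000 over 12 generations)
and an outbred control (constant 10,000) on a shared 400-cM map, detect
IBD, and estimate Ne — `examples/03_ibd_and_ne.py`:

```python
import numpy as np
import isopop as ip
from isopop.pipeline import combine_panels

mmap = ip.make_marker_map([80.0] * 5, 18_000, spacing="random", seed=4)
freqs = np.random.default_rng(5).uniform(0.05, 0.95, len(mmap))
iso, _ = ip.simulate_gene_dropping(ip.isolate_config(), mmap,
                                   founder_freqs=freqs, n_sample=30,
                                   population_label="ISO", seed=4)
ctl, _ = ip.simulate_gene_dropping(ip.control_config(), mmap,
                                   founder_freqs=freqs, n_sample=30,
                                   population_label="CTL", seed=5)
panel = combine_panels(iso, ctl)
segments = ip.germline_scan(panel, min_cm=3.0)
for pop in ("ISO", "CTL"):
    print(ip.pair_summaries(segments, panel.sample_ids,
                            panel.populations, "within", pop))
    est = ip.estimate_ne(segments,
                         panel.sample_ids[panel.populations == pop],
                         u_cm=7.0, genome_cm=mmap.total_cm(), B=1000,
                         seed=0)
    print(" ", est)
```

prints

```
within ISO: 30 samples, 435 pairs, 1108 segments; segments/pair 2.55/2/1.48, Mb/pair 24.06/20.48/18.98 (mean/median/SD)
  Ne = 300.2 (95% CI 285.7-315.2) from f = 0.04594 at u = 7 cM over 435 pairs
within CTL: 30 samples, 435 pairs, 46 segments; segments/pair 0.11/0/0.46, Mb/pair 1.51/0.00/15.23 (mean/median/SD)
  Ne = 4554.7 (95% CI 3318.7-7008.9) from f = 0.00313 at u = 7 cM over 435 pairs
```

The isolate's pairs share ~16× more genome IBD than the control's, and
its estimated recent Ne lands near the harmonic mean of its simulated
population sizes, an order of magnitude below the control's — the
pattern that defines a genetic isolate. The other example scripts cover
simulation with ground truth (`01`), QC/MDS/F_ST (`02`), ROH (`04`) and
LD decay (`05`).

A thin CLI mirrors the library (`isopop simulate | qc | mds | fst | ld
| ibd | roh | ne | test | run | fixtures`); `isopop run` executes the
whole pipeline from a YAML config and writes a TSV/JSON report bundle.

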