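# Methods

`isopop` quantifies the genomic signatures of a population isolate —
elevated identity-by-descent (IBD) sharing, long runs of homozygosity
(ROH), slow decay of linkage disequilibrium (LD), allele-frequency
differentiation (F_ST) and a small IBD-derived effective population size
(Ne) — and ships a forward simulator that produces panels with exact
ground truth so every detector can be validated end to end.

## The demographic model behind the synthetic data

The gene-dropping simulator (`isopop.simdata`) is a diploid, monoecious
Wright–Fisher model: each generation, every child draws two distinct
parents uniformly at random (random mating, selfing excluded) and
receives one recombinant haplotype from each. Recombination is a Poisson
process on the genetic (cM) scale with no interference — crossover count
per transmitted genome ~ Poisson(map length in Morgans), positions
uniform, chromosomes assorting independently. There is no mutation:
every allele in the sample descends verbatim from one of the labelled
founder haplotypes, so the founder-origin mosaic of each sampled
haplotype (`FounderSegmentLabeling`) is exact. True IBD between two
samples is the union, over the four haplotype combinations, of intervals
with equal founder-haplotype id; true autozygosity is the same
computation within one individual.

The default scenarios encode the study conditions the package targets:

* **Isolate** — 151 founders (the recorded size of the historical
  bottleneck) growing exponentially to 2,000 over 12 generations. The
  expansion endpoint is scaled down from the real census (~19,500) to
  keep forward simulation at desk scale; the qualitative contrasts (high
  IBD/ROH/LD, small Ne) are insensitive to the endpoint because they are
  driven by the founder count and the number of generations.
* **Control** — constant size 10,000 for 12 generations, a scaled
  stand-in for an outbred national population (real-data Ne estimates
  are of order 10^5; at desk scale what matters is that coalescence
  within the simulated window is rare, which holds from ~10^4 upward).

Founder allele frequencies default to Uniform(0.05, 0.95) draws, keeping
markers polymorphic for the F_ST and LD analyses. Optional per-allele
genotyping error and per-genotype missingness (both default 0) exist so
the QC filters can be exercised. Marker maps are synthetic: marker
positions uniform (or regular) on each chromosome, physical scale 1 cM =
1 Mb.

What the generator does **not** emulate: mutation, genotyping-array
ascertainment bias, allele-frequency spectra of real SNP arrays,
recombination hotspots/interference, sex chromosomes, and overlapping
generations. Consequently, passing tests demonstrate correctness of the
detectors and estimators under the stated model, not robustness to
array artefacts; on real data the QC stage (call-rate, MAF, relatedness
filters) carries that weight.

## IBD detection

`germline_scan` follows the hash-seeding design of GERMLINE: each
chromosome is cut into fixed, non-overlapping 64-marker words; exact
word equality between haplotypes (found by grouping packed 64-bit
words) seeds candidate matches; runs of consecutive matching words are
extended marker by marker, allowing at most 1 mismatching marker per
64-marker window (both parameters exposed). The four haplotype-pair
match sets of a sample pair are merged into genotype-level segments —
union of overlapping intervals, bridging gaps shorter than one word —
so a phase switch does not fragment a long segment. Segments shorter
than 3 cM (configurable) are dropped. Missing alleles count as matches
during extension, bounded by a 5% per-segment missingness cap; a
missing site inside a word spoils that word's hash, which only costs
sensitivity when an entire 64-marker stretch is affected.

A segment's `n_mismatch` is counted marker-wise under the best phase
assignment (markers where no haplotype of A matches any haplotype of
B), which is the quantity the per-window budget bounds. Exact word
matches between non-IBD haplotypes are vanishingly rare at typical
heterozygosity, so false seeds are negligible; the measured false-IBD
rate on unrelated panels is far below 1% of the genome.

Low SNP density regions cannot support confident detection:
`sparse_region_mask` flags any 50-consecutive-marker span wider than
1 Mb, and `filter_segments_by_mask` removes segments overlapping the
mask by more than 20% of their length.

## ROH scanning

`roh_scan` implements the standard window-based criteria: a 50-SNP
window is homozygous if it contains at most 1 heterozygote and at most
5 missing calls; a SNP is eligible when at least 5% of windows
overlapping it are homozygous; maximal eligible runs are split at
inter-marker gaps above 1 Mb and reported if they span at least 1000 kb
with at least 100 SNPs at no worse than 50 kb/SNP. All thresholds are
arguments. The length-bin summary reports, per population, the
proportion of individuals with at least one ROH in
[min, 1.5), [1.5, 2.5), [2.5, 5), [5, 10), [10, ∞) Mb; because the scan
enforces a 1000-kb minimum, the first bin starts at the scan minimum
rather than below it. A deliberately literal loop-based restatement of
the same criteria (`roh_scan_bruteforce`) is kept in the package as the
test oracle; the vectorised scan must produce identical call sets on
randomized fixtures.

## Stratification, F_ST, LD

* IBS similarity: mean shared-allele fraction over jointly non-missing
  markers; classical MDS (principal coordinates) of D = 1 − IBS with
  eigenvalue-ordered axes, negative eigenvalues truncated, and the
  largest-magnitude loading of each axis made positive.
* F_ST: two-level Weir & Cockerham (1984) variance components, combined
  as the ratio of sums Σa/Σ(a+b+c) across loci (stable for
  low-information loci). p-values come from sample-label permutations
  (default 100, so the smallest attainable p is 1/101 ≈ 0.0099) and the
  95% CI from a percentile bootstrap over loci — permutation cannot
  yield a CI for a point estimate, so the CI construction is this
  package's choice and is not numerically comparable to tables produced
  by other CI conventions.
* LD decay: squared Pearson correlation of dosages over
  pairwise-complete samples, all intra-chromosomal pairs within 500 kb,
  averaged in half-open 5-kb bins (first bin 1–5 kb; closer pairs fold
  into it), on fixed-size random subsamples of 25 individuals per
  population to control for sample size.

## Relatedness QC

PI-hat is the method-of-moments IBD estimate from observed IBS-0/1/2
counts and their expectations under pooled plug-in allele frequencies
(no small-sample correction terms; the estimate needs at least 1,000
jointly called markers by default). Exclusion is greedy: while any pair
exceeds PI-hat 0.1, remove the sample with the most offending pairs
(ties: larger mean PI-hat, then lexicographically larger id). The rule
guarantees no retained pair exceeds the threshold; the original outcome
it emulates reported only the removal count, so the algorithm is this
package's explicit choice.

## Effective population size

With f the mean fraction of the genome a pair shares in IBD segments of
at least u cM, the constant-size closed form is

    Ne = 50 · (1 − f + √(1 − f)) / (u · f),

decreasing in f and u, with the small-f limit Ne ≈ 100/(u·f). The
default threshold u = 7 cM targets sharing from roughly the last ~20
generations (~500 years at 25 years/generation — reporting metadata,
not computation). f averages over **all** within-group pairs; pairs with
no qualifying segment contribute zero. The genome length defaults to
the panel's total autosomal map length.

Inference: percentile-bootstrap CIs, resampling either detected
segments (default, mirroring "bootstrap the detector output"; yields
tight CIs because it ignores pair-level dependence) or whole pairs (the
exchangeable unit; wider and recommended for honest uncertainty); and a
permutation test on the between-group difference in f that relabels
individuals and re-derives pair sets, never permuting pairs directly.

### The renewal oracle and estimator calibration

`simulate_pair_sharing` is a detection-free oracle for the closed form:
it walks each chromosome as a marked renewal process whose law is
exactly the model the estimator inverts. At a uniformly random point
the pair TMRCA is Exponential(mean 2N) (the coalescent limit) and the
segment covering the point is Erlang(2, g/100 cM⁻¹); this forces the
per-segment law to be TMRCA ~ Gamma(2, 2N) (length-biased) with length
~ Exponential(mean 100/g cM), and each chromosome to start inside a
stationary segment (point-marginal TMRCA with its exponential forward
recurrence) rather than with a fresh draw. Under this law the expected
sharing fraction is f = a(a+2r)/(a+r)² with a = 1/(2N), r = u/100,
whose inversion is precisely the closed form; a 40,000-pair measurement
agrees with the exact value within 0.2% ± 0.4%. Segments are truncated
at chromosome ends and qualify by their truncated length, which is what
a detector would observe.

The closed form is **calibrated for this pair-level model, not for
genotype-level detector output**. Physically, a haplotype pair with
TMRCA g is broken at rate 2g per Morgan, giving hap-pair sharing
f_hap ≈ 50/(N·u) for small f, and the genotype-level union over the
four haplotype combinations gives f_geno ≈ 4·f_hap ≈ 200/(N·u) —
while the closed form inverts f = 100/(N·u). Applying the published
procedure (genotype-level detected sharing into the closed form)
therefore recovers roughly **half** the true size of a simulated
Wright–Fisher population; an independent coalescent check
(msprime/tskit true IBD at constant N=500) reproduces the same
factor. The package implements the procedure as practised (detector
output straight into the closed form) and reports this calibration
property rather than silently rescaling; comparisons
*between* populations (the isolate's Ne orders of magnitude below the
control's) are unaffected.

## Permutation and bootstrap machinery

The two-sided permutation p-value is
(1 + #{|s_perm − mean(null)| ≥ |s_obs − mean(null)|})/(n_perm + 1) —
never zero, bounded below by 1/(n_perm+1); the statistic defaults to
the Wilcoxon rank sum with midranks. For pairwise quantities the
permutation unit is always the individual. Bootstrap CIs are
percentile, (2.5, 97.5) quantiles of B replicates; failing replicates
are redrawn up to a 1% cap.

## Problem sizes used by the test suite

Chosen once, from operation-count estimates, to keep the default suite
fast while leaving Monte-Carlo noise well inside the asserted margins:

* Renewal-recovery check: N ∈ {200, 750, 3000}, u = 7 cM, single
  3000-cM genome, 10 seeds; 1,653 pairs for N ≤ 750 and 400 pairs for
  N = 3000 (segment count per pair grows linearly in N).
* Full-pipeline recovery: constant N = 500, 45 generations, 10 × 100 cM
  genome, 20,000 regularly spaced markers, 60-sample panels, 8 seeds.
* Bootstrap coverage: the N = 750 scenario with 1,653 pairs, B = 1,000,
  50 replicate experiments.
* End-to-end contrast: 6 seeds of 40 + 40 samples on a 6 × 80 cM genome
  with 24,000 randomly placed markers; permutation tests at 999
  replicates (smallest attainable p = 0.001).
* ROH oracle equivalence: 500 randomized fixtures of 60–300 SNPs with
  randomized scan parameters.

## Known limitations

* The Ne closed form's genotype-level calibration gap described above:
  absolute Ne values from detector output are biased low by a factor
  near 2 under the constant-size model. Absolute estimates in the
  literature produced by the same procedure carry the same property.
* Segment-level bootstrap CIs understate uncertainty (they mirror the
  common practice of bootstrapping detector output directly);
  pair-level CIs are offered and used in the calibration tests.
* The LD pruner is greedy left-to-right within sliding windows; it
  guarantees no retained pair above the r² threshold inside any window
  but is not a globally maximal independent set.
* MDS on very large panels is dense O(n³) eigendecomposition; panels
  here are hundreds of samples, where this is immaterial.
* PI-hat uses plug-in frequencies without finite-sample corrections;
  for panels of fewer than ~20 samples the component estimates are
  noticeably noisy (the relatedness threshold 0.1 is far above that
  noise at the default marker counts).
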