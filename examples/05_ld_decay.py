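"""LD decay by distance: the isolate decays slower than the control.

Mean r² between genotype dosages is averaged in 5-kb distance bins on
fixed-size subsamples of 25, exactly as population panels are compared;
elevated long-range LD is a hallmark of a bottlenecked, expanding
population.
"""

import numpy as np

import isopop as ip
from isopop.pipeline import combine_panels

mmap = ip.make_marker_map([80.0] * 4, 16_000, spacing="random", seed=8)
freqs = np.random.default_rng(9).uniform(0.05, 0.95, len(mmap))
iso, _ = ip.simulate_gene_dropping(
    ip.isolate_config(), mmap, founder_freqs=freqs, n_sample=30,
    population_label="ISO", seed=8)
ctl, _ = ip.simulate_gene_dropping(
    ip.control_config(), mmap, founder_freqs=freqs, n_sample=30,
    population_label="CTL", seed=9)
geno = combine_panels(iso, ctl).to_genotypes()

profiles = {}
for k, pop in enumerate(("ISO", "CTL")):
    profiles[pop] = ip.decay_profile(
        geno, population=pop, chroms=mmap.chromosomes(),
        subsample_n=25, seed=10 + k)

print("distance bin    r2(ISO)  r2(CTL)")
for i in (0, 9, 19, 49, 99):
    p_iso, p_ctl = profiles["ISO"], profiles["CTL"]
    print(f"<= {p_iso.bin_hi_kb[i]:5.0f} kb     "
          f"{p_iso.mean_r2[i]:.4f}   {p_ctl.mean_r2[i]:.4f}")
print("(isolate r2 stays elevated at long range; the control sits near "
      "the 1/n sampling floor)")
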