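"""Simulate a cfDNA sample and look at its allele counts.

Builds one maternal-trisomy sample (1,000 targeted SNPs, mean depth 1,000
reads, fetal fraction 10%) and prints the depth signature that makes
trisomy visible: studied-chromosome loci run ~(1 + FF/2)x deeper than the
euploid reference chromosome.
"""

import numpy as np

from nipthmm import MATERNAL_TRISOMY, SimulationConfig, simulate_sample

cfg = SimulationConfig(
    n_loci=1000,
    read_depth=1000,
    fetal_fraction=0.10,
    condition=MATERNAL_TRISOMY,
    seed=7,
)
sample = simulate_sample(cfg)

studied, reference = sample.studied, sample.reference
print(f"condition: {sample.condition}, true FF: {sample.ff_true:.2f}")
print(f"mean total depth  studied:   {studied.total.mean():7.1f}")
print(f"mean total depth  reference: {reference.total.mean():7.1f}")
print(f"depth ratio: {studied.total.mean() / reference.total.mean():.4f} "
      f"(expected 1 + FF/2 = {1 + cfg.fetal_fraction / 2:.3f})")

# a few loci with their ground-truth genotypes
print("\nfirst 5 loci (count_a, count_b, mother, fetus):")
for i in range(5):
    obs = studied.locus(i)
    print(f"  locus {i}: ({obs.count_a:4d}, {obs.count_b:4d})  "
          f"{obs.maternal_genotype}  {obs.fetal_genotype}")

het = np.mean((studied.f_b > 0) & (studied.f_b < studied.f_total))
print(f"\nfetal heterozygosity on the studied chromosome: {het:.3f}")
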