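"""Decode per-locus fetal state with the RC and AR hidden Markov models.

Trains emissions from 100 samples per condition at (RD 2000, FF 10%), then
Viterbi-decodes one maternal-trisomy test sample.  The RC model sees the
depth shift (EUP mean RD vs TRI mean RD*(1+FF/2)); the 7-state AR model
sees the allelic-ratio patterns of informative SNPs.
"""

import numpy as np

from nipthmm import (
    CONDITIONS,
    MATERNAL_TRISOMY,
    SimulationConfig,
    expected_allelic_ratio,
    fit_emissions,
    simulate_cohort,
    simulate_sample,
    viterbi_decode,
)
from nipthmm.hmm import SEVEN_STATES, rc_observations, seven_state_observations

RD, FF = 2000, 0.10

training = [
    simulate_cohort(
        SimulationConfig(read_depth=RD, fetal_fraction=FF, condition=c),
        100,
        np.random.default_rng([1, i]),
    )
    for i, c in enumerate(CONDITIONS)
]
rc = fit_emissions(training, "RC")
ar = fit_emissions(training, "AR")

print("RC emissions (state: mean, sd):")
for s, mu, var in zip(rc.space.states, rc.means[:, 0], rc.variances[:, 0]):
    print(f"  {s}: {mu:7.1f}  {np.sqrt(var):6.1f}")

print("\nAR emissions vs noise-free expected ratios at FF 10%:")
for s, mu in zip(SEVEN_STATES, ar.means[:, 0]):
    print(f"  {s}: fitted {mu:6.2f}   expected {expected_allelic_ratio(s, FF):6.2f}")

sample = simulate_sample(
    SimulationConfig(read_depth=RD, fetal_fraction=FF, condition=MATERNAL_TRISOMY),
    np.random.default_rng(42),
)
path_rc = viterbi_decode(rc_observations(sample.studied), rc)
obs_ar, _ = seven_state_observations(sample.studied, ar.ratio_cap)
path_ar = viterbi_decode(obs_ar[0], ar)

print(f"\nRC decoded TRI fraction: {np.mean(path_rc == 1):.3f} "
      "(trisomy sample; higher is better)")
frac = {s: float(np.mean(path_ar == i)) for i, s in enumerate(SEVEN_STATES)}
print("AR decoded state fractions:",
      {k: round(v, 3) for k, v in frac.items() if v > 0})
print("AR trisomy-group mass:", round(frac["T1"] + frac["T2"] + frac["T3"], 3))
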