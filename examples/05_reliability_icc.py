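"""Intra-observer reliability from replicate measurement sessions.

A second measurement session is emulated by re-annotating every landmark
with small Gaussian placement error (here 0.3 mm SD, a plausible
annotation jitter).  The intraclass correlation of the derived variables
across the two sessions quantifies measurement reliability; values above
0.9 are conventionally read as excellent."""

from tmjmetrics import (
    SimulationConfig,
    add_rater_noise,
    reliability_icc,
    simulate_cohort,
)

cohort = simulate_cohort(SimulationConfig(seed=2))
session2 = add_rater_noise(cohort, noise_sd=0.3, seed=1002)

results = reliability_icc([cohort, session2])
for variable, res in results.items():
    print(f"{variable:10s} ICC(2,1) = {res.icc:.3f} "
          f"({res.n_subjects} joint-positions x {res.n_raters} sessions)")
print()
print("Angles span a wide between-joint range, so modest landmark noise")
print("still yields near-perfect ICC; coordinate ICCs are lower because")
print("their between-joint variance is only a few millimetres.")
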