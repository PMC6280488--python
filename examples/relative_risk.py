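"""Compare two treatment arms by relative risk of severe haemorrhage.

The binomial RR uses event counts with the Katz log-scale interval; the
lognormal RR is the ratio of fitted tail probabilities with a
matched-row bootstrap CI (each arm resampled and refitted, replicates
paired by row). Bootstrap size 1000 mirrors common practice; reduce it
for a quick look.
"""

from dataclasses import replace

from bloodloss import generate, rr_binomial, rr_lognormal_bootstrap, trial_scenario

cfg = trial_scenario("active_management", seed=3)
cfg = replace(cfg, arms=tuple(replace(a, n=3000) for a in cfg.arms))
samples, truth = generate(cfg)
print(f"arms: {samples[0].arm_label} vs {samples[1].arm_label}, "
      f"n = {samples[0].n}/arm; true severe-event RR = {truth.rr1000:.3f}\n")

b = rr_binomial(samples[0], samples[1], 1000.0)
l = rr_lognormal_bootstrap(samples[0], samples[1], 1000.0, n_boot=400, seed=4)

for res in (b, l):
    print(f"{res.approach:<9} RR = {res.rr:.3f}  "
          f"95% CI ({res.ci95[0]:.3f}, {res.ci95[1]:.3f})  width {res.width:.3f}")
print(f"\nlognormal CI width is {100 * l.width / b.width:.0f}% of the binomial's;")
print("both intervals should cover the generating RR.")
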