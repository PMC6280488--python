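"""Fit two- and three-parameter lognormal models to blood-loss volumes.

Simulates one arm of a large prevention trial (volumes in grams, with
the digit heaping and limit-of-detection noise real measurements show),
fits both models, and compares them by AIC/BIC. The threshold model's
extra parameter t shifts the support and usually pays for itself.
"""

from bloodloss import compare_fits, fit_mle_2p, fit_mle_3p, generate, trial_scenario

cfg = trial_scenario("active_management", seed=1)
samples, truth = generate(cfg)
arm = samples[0]
print(f"arm {arm.arm_label!r}: n = {arm.n} volumes in {arm.unit}")
print(f"generating parameters: {truth.params[arm.arm_label]}\n")

fit2 = fit_mle_2p(arm)
fit3 = fit_mle_3p(arm)

for fit in (fit2, fit3):
    print(f"{fit.model}  loglik = {fit.loglik:.1f}  AIC = {fit.aic:.1f}")
    for row in fit.display_table():
        print(f"  {row['parameter']:<9} {row['estimate']:>8}  "
              f"SE {row['se']:<7}  95% CI ({row['ci95_lower']}, {row['ci95_upper']})")
print()
best = compare_fits([fit2, fit3])[0]
print(f"preferred model by AIC: {best['model']} "
      f"(delta AIC of runner-up: {compare_fits([fit2, fit3])[1]['delta_aic']:.1f})")
print("The fitted location/scale should sit close to the generating values;")
print("the threshold estimate is noisier but its CI should cover the truth.")
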