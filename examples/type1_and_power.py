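"""Type-I-error and power study cells for the latent-factor simulator.

Runs a reduced-replicate null study (beta = 0) to check calibration, then a
small power sweep over effect sizes under model 2. At full scale (10,000
replicates, B = 1,000) the null study reproduces the published type-I-error
table; this desk-scale version shows the same calibration within its
binomial confidence interval in under a minute.
"""

import multppe as mp

null_spec = mp.SimulationModelSpec.from_correlations(model_id=1, K=10, n=500)
results = mp.type1_study(null_spec, replicates=300, B=500,
                         levels=(0.01, 0.05), seed=9)
print("type I error (model 1, n=500, K=10, 300 replicates, B=500):")
for res in results:
    lo, hi = res.ci95
    print(f"  alpha = {res.level}: rate = {res.rate:.4f} "
          f"(exact 95% CI {lo:.4f}-{hi:.4f})")
print("  -> each CI should cover its nominal level.\n")

print("power sweep (model 2, n=1000, K=20, 100 replicates, alpha=0.05):")
for beta in (0.05, 0.1, 0.25):
    spec = mp.SimulationModelSpec.from_correlations(model_id=2, K=20,
                                                    beta=beta, n=1000)
    res = mp.power_study(spec, replicates=100, B=500, level=0.05, seed=9)
    print(f"  beta = {beta}: power = {res.rate:.2f}")
print("  -> power rises with the effect size and saturates near 1.")
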