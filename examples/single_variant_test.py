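"""Test one genetic variant against ten correlated phenotypes.

Simulates a variant that truly affects the second factor block of the
phenotypes, runs the MultP-PE permutation test, and prints the LOOCV
prediction-error profile and the p-value. A low prediction error at some
penalty — relative to genotype shuffles — is the evidence of association.
"""

import numpy as np

import multppe as mp

spec = mp.SimulationModelSpec.from_correlations(model_id=2, K=10, beta=0.15,
                                                n=1000)
rng = np.random.default_rng(1)
phenotypes, genotype = mp.simulate_dataset(spec, rng)

result = mp.multp_pe_test(phenotypes, genotype, B=1000, rng=rng)

print("log lambda   T_lambda (observed)   per-lambda p")
for logl, T, p in zip(mp.DEFAULT_LOG_LAMBDAS, result.T_matrix[0],
                      result.p_lambda_matrix[0]):
    print(f"{logl:10.1f}   {T:19.2f}   {p:12.3f}")
print(f"\nmin-p statistic: {result.minp[0]:.3f}")
print(f"overall p-value: {result.p_value_str}  (B = {result.B} permutations)")
print("\nThe observed prediction errors sit below the permutation "
      "distribution at every penalty, so the variant is associated with "
      "the phenotype set.")
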