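"""Power of the additive quantitative-trait test at a rare variant.

Analytic power uses the 1-df noncentral chi-square with
ncp = n * 2 * maf * (1-maf) * beta^2 / sigma_resid^2; the Monte-Carlo check
simulates genotype/trait pairs and pushes them through the same Wald test
the GWAS engine applies.
"""

from pressorgwas.meta import (
    PowerSpec,
    power_expected_finite,
    power_monte_carlo,
    power_quantitative,
)

spec = PowerSpec(n=1534, maf=0.017, beta=13.0, sigma=19.7, alpha=1e-4)
print(f"design: n={spec.n}, MAF={spec.maf}, beta={spec.beta} mcg/min/allele, "
      f"trait SD={spec.sigma}, alpha={spec.alpha}")
print(f"noncentrality parameter: {spec.ncp:.2f}")
print(f"analytic power (fixed ncp):        {power_quantitative(spec):.4f}")
print(f"expected finite-sample power:      {power_expected_finite(spec, seed=0):.4f}")
mc, se = power_monte_carlo(spec, n_replicates=2000, seed=0)
print(f"Monte-Carlo power (2000 reps):     {mc:.4f} +/- {se:.4f}")
# At ~52 expected carriers the realized genotype variance fluctuates between
# samples; the expected finite-sample power therefore sits slightly below
# the fixed-ncp value (a Jensen gap), and the Monte-Carlo estimate centers
# on the former.

print("\npower as the sample grows (same variant):")
for n in (500, 1000, 1534, 2500, 5000):
    p = power_quantitative(PowerSpec(n=n, maf=0.017, beta=13.0, sigma=19.7, alpha=1e-4))
    print(f"  n={n:>5}: {p:.3f}")
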