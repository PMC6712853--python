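"""Reconstruct published meta-analysis results from phase-level summaries.

Given each lead SNP's per-phase effect (beta with a 95% CI), recover the
standard errors from the CI half-widths and combine the phases by
inverse-variance fixed-effect meta-analysis. This is the standard way to
check a reported meta-analysis against its per-study inputs.
"""

from pressorgwas.meta import fixed_effect_meta, se_from_ci

# per-phase effect estimates for three lead SNPs associated with
# phenylephrine infusion rate: (beta, CI low, CI high) for phases I and II
phase_effects = {
    "rs2069661 (F2RL2)": ((13.71, 7.81, 19.6), (14.32, 3.28, 25.4)),
    "rs77080086 (PDE4B)": ((12.17, 7.43, 16.91), (6.43, -3.32, 16.2)),
    "rs11572377 (EDN2)": ((12.26, 6.32, 18.2), (15.14, 5.08, 25.19)),
}

print(f"{'lead SNP':<20} {'beta_meta':>9} {'95% CI':>16} {'P_meta':>10}")
for name, phases in phase_effects.items():
    studies = [(b, se_from_ci(lo, hi)) for b, lo, hi in phases]
    m = fixed_effect_meta(studies, name)
    ci = f"({m.ci95[0]:.2f}, {m.ci95[1]:.2f})"
    print(f"{name:<20} {m.beta_meta:9.2f} {ci:>16} {m.p:10.2e}")

# beta_meta is in mcg/min of phenylephrine per copy of the effect allele;
# each phase's weight is the inverse of its squared standard error, so the
# tighter phase-I estimates dominate the combined effect.
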