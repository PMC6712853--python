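"""Genotype QC: VCF round trip, variant/sample filters, relatedness, PCs.

Writes one phase of a synthetic cohort as VCF 4.2 (GT + DS), reads it back,
then applies the standard screens: info score > 0.7, sample call rate 95%,
variant call rate 99%, MAF 1%, HWE P >= 1e-7, and IBD-based removal of
first/second-degree relatives (pi_hat >= 0.1875).
"""

import tempfile
from pathlib import Path

import numpy as np

from pressorgwas.genoqc import (
    compute_pcs,
    estimate_relatedness,
    prune_related,
    read_vcf,
    sample_filter,
    variant_filter,
    write_vcf,
)
from pressorgwas.simulate import SimulationConfig, generate_cohort

cohort = generate_cohort(
    SimulationConfig(n_patients=300, n_variants=3000, genotyped_fraction=0.5, seed=9)
)
gm = cohort.genotypes["I"]

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "phaseI.vcf"
    write_vcf(gm, path)
    back, n_multi = read_vcf(path)
    drift = np.nanmax(np.abs(back.dosages - gm.dosages))
    print(f"VCF round trip: {back.n_samples} samples x {back.n_variants} variants, "
          f"max dosage drift {drift:.2g}")

gm, sample_report = sample_filter(gm)
gm, variant_report = variant_filter(gm)
print(f"sample filter removed {sample_report.counts}")
print(f"variant filter removed {variant_report.counts} (order: info -> call rate -> MAF -> HWE)")

pairs = estimate_relatedness(gm)
print(f"relatedness: {len(pairs)} pairs, max pi_hat = {pairs['pi_hat'].max():.3f}")
gm, rel_report = prune_related(gm)
print(f"pruned {rel_report.counts['related']} of a related pair (threshold 0.1875)")

coords, eigvals = compute_pcs(gm, n_pcs=6)
print(f"top-6 PC eigenvalues: {np.round(eigvals, 2)}")
# with a single simulated ancestry the eigenvalue spectrum is flat; planted
# subpopulations would lift PC1 well above the bulk.
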