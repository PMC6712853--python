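"""End-to-end analysis pipeline.

Orchestrates: simulate (or load) episodes and genotypes -> episode QC ->
phenotype features -> k-means response clustering and semantic labeling ->
patient aggregation (concordance rule) -> per-phase genotype QC with PCs ->
covariate screening -> per-phase linear GWAS -> fixed-effect meta-analysis
-> LD clumping -> subgroup logistic validation of top hits -> analytic
power, with a stage-by-stage attrition table and a deterministic manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pressorgwas import assoc, clustering, cohortstats, episodes as epi, genoqc, meta as metamod
from pressorgwas.simulate import CLASS_NAMES, SimulationConfig, generate_cohort

logger = logging.getLogger("pressorgwas")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "validate_top_hits"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; every threshold is a named key."""

    outdir: str = "pressorgwas_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    episode_tsv: str | None = None  # read instead of simulating when set
    vcf_phase1: str | None = None
    vcf_phase2: str | None = None
    icd_tsv: str | None = None
    # episode QC
    min_duration: float = 10.0
    min_sbp_readings: int = 3
    sbp_bounds: tuple[float, float] = (20.0, 200.0)
    # clustering
    k: int = 3
    k_sweep: tuple[int, ...] = (2, 3)
    n_init: int = 10
    # genotype QC
    min_info: float = 0.7
    sample_call_rate: float = 0.95
    variant_call_rate: float = 0.99
    min_maf: float = 0.01
    min_hwe_p: float = 1e-7
    relatedness_threshold: float = 0.1875
    n_pcs: int = 6
    # association
    screen_alpha: float = 0.05
    suggestive_p: float = 1e-5
    tophit_p: float = 1e-6
    n_top_hits: int = 3
    clump_r2: float = 0.1
    clump_window: int = 500_000
    # power
    power_alpha: float = 1e-4
    power_maf: float = 0.017
    power_beta: float = 13.0

    def validate(self) -> None:
        self.simulation.validate()
        if self.episode_tsv is not None and not Path(self.episode_tsv).exists():
            raise ValueError(f"episode_tsv does not exist: {self.episode_tsv}")
        for name in ("vcf_phase1", "vcf_phase2", "icd_tsv"):
            v = getattr(self, name)
            if v is not None and not Path(v).exists():
                raise ValueError(f"{name} does not exist: {v}")
        if not (0 < self.min_maf < 0.5 and 0 < self.min_hwe_p < 1):
            raise ValueError("min_maf/min_hwe_p out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(simulation=sim, **raw)
        for name in ("sbp_bounds", "k_sweep"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to
    ``outdir/manifest.json``). Re-running with the same config and seed is
    bit-identical."""
    try:
        config.validate()
    except ValueError as exc:
        raise PipelineError("config", str(exc)) from exc
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    attrition: list[dict] = []
    manifest: dict = {"seed": config.seed, "stages": {}, "attrition": attrition}

    # ---- stage: input ----------------------------------------------------
    stage = "input"
    try:
        if config.episode_tsv is None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = generate_cohort(sim)
            eps = cohort.episodes
            icd = cohort.icd_events
            genotypes = cohort.genotypes
            truth_path = outdir / "truth.json"
            cohort.truth.to_json(truth_path)
        else:
            eps = epi.read_episodes(config.episode_tsv)
            icd = (
                pd.read_csv(config.icd_tsv, sep="\t", dtype=str)
                if config.icd_tsv
                else pd.DataFrame(columns=["patient_id", "code", "date"])
            )
            genotypes = {}
            for phase, path in (("I", config.vcf_phase1), ("II", config.vcf_phase2)):
                if path:
                    gm, n_multi = genoqc.read_vcf(path, phase=phase)
                    if n_multi:
                        logger.info("phase %s: skipped %d multiallelic records", phase, n_multi)
                    genotypes[phase] = gm
        epi.write_episodes(eps, outdir / "episodes.tsv")
        attrition.append({"stage": stage, "n_in": len(eps), "n_out": len(eps)})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: episode QC ----------------------------------------------
    stage = "episode_qc"
    try:
        rules = epi.QCRules(
            min_duration=config.min_duration,
            min_sbp_readings=config.min_sbp_readings,
            sbp_bounds=config.sbp_bounds,
        )
        kept, exclusions = epi.qc_filter(eps, rules)
        epi.write_exclusion_log(exclusions, outdir / "exclusions.tsv")
        n_excluded = len({e.episode_id for e in exclusions})
        if len(kept) + n_excluded != len(eps):
            raise PipelineError(stage, "attrition mismatch in episode QC")
        attrition.append({"stage": stage, "n_in": len(eps), "n_out": len(kept)})
        feats = epi.features_table(kept, rules)
        _write_tsv(feats, outdir / "features.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: clustering ----------------------------------------------
    stage = "clustering"
    try:
        X = feats[list(clustering.FEATURES)].to_numpy(dtype=float)
        sweep = clustering.evaluate_k(X, config.k_sweep, seed=config.seed)
        _write_tsv(sweep, outdir / "k_sweep.tsv")
        model = clustering.kmeans_fit(
            X, config.k, seed=config.seed, n_init=config.n_init
        )
        clustering.label_clusters(model)
        model.to_json(outdir / "cluster_model.json")
        labeled = clustering.assign_labels(model, feats)
        _write_tsv(
            labeled[["patient_id", "episode_id", "cluster", "label"]],
            outdir / "episode_labels.tsv",
        )
        attrition.append({"stage": stage, "n_in": len(feats), "n_out": len(labeled)})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: patient aggregation --------------------------------------
    stage = "aggregate"
    try:
        patients, dropped = epi.aggregate_patients(labeled)
        _write_tsv(patients, outdir / "patients.tsv")
        _write_tsv(dropped, outdir / "discordant_patients.tsv")
        attrition.append(
            {
                "stage": stage,
                "n_in": int(labeled["patient_id"].nunique()),
                "n_out": len(patients),
            }
        )
        sizes = patients["label"].value_counts().to_dict()
        manifest["stages"]["cluster_sizes"] = {c: int(sizes.get(c, 0)) for c in CLASS_NAMES}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: genotype QC ----------------------------------------------
    stage = "genotype_qc"
    qc_matrices: dict[str, genoqc.GenotypeMatrix] = {}
    pcs: dict[str, pd.DataFrame] = {}
    try:
        for phase, gm in genotypes.items():
            gm2, srep = genoqc.sample_filter(gm, config.sample_call_rate)
            gm3, vrep = genoqc.variant_filter(
                gm2,
                min_info=config.min_info,
                min_call_rate=config.variant_call_rate,
                min_maf=config.min_maf,
                min_hwe_p=config.min_hwe_p,
            )
            gm4, rrep = genoqc.prune_related(gm3, config.relatedness_threshold)
            coords, eig = genoqc.compute_pcs(gm4, config.n_pcs)
            _write_tsv(coords, outdir / f"pcs_phase{phase}.tsv")
            qc_matrices[phase] = gm4
            pcs[phase] = coords
            manifest["stages"][f"qc_phase{phase}"] = {
                "samples_in": gm.n_samples,
                "samples_removed_call_rate": srep.counts.get("call_rate", 0),
                "samples_removed_related": rrep.counts.get("related", 0),
                "variants_in": gm.n_variants,
                "variants_removed": vrep.counts,
                "samples_out": gm4.n_samples,
                "variants_out": gm4.n_variants,
            }
            attrition.append(
                {"stage": f"{stage}_phase{phase}", "n_in": gm.n_samples, "n_out": gm4.n_samples}
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: covariate screen -----------------------------------------
    stage = "covariate_screen"
    try:
        ptab = patients.set_index("patient_id")
        comorb = cohortstats.reportable_conditions(icd) if len(icd) else {}
        comorb_classes = ("250", "401", "272", "278", "414", "428", "427")
        cand = pd.DataFrame(index=ptab.index)
        cand["age"] = ptab["age"]
        cand["sex"] = assoc.encode_sex(ptab["sex"])
        cand["weight"] = ptab["weight"]
        cand["mean_sbp"] = ptab["mean_sbp"]
        cand["sd_sbp"] = ptab["sd_sbp"]
        cand["anesthesia_type"] = ptab["anesthesia_type"]
        for cls in comorb_classes:
            cand[f"icd_{cls}"] = [
                1.0 if cls in comorb.get(pid, set()) else 0.0 for pid in ptab.index
            ]
        selected, screen_table = assoc.screen_covariates(
            ptab["avg_rate"].to_numpy(), cand, alpha=config.screen_alpha
        )
        _write_tsv(screen_table, outdir / "covariate_screen.tsv")
        manifest["stages"]["covariates_selected"] = selected
        # BP features feed the cluster definition; GWAS adjusts for the
        # demographic covariates plus PCs.
        gwas_covs = [c for c in selected if c not in ("mean_sbp", "sd_sbp")]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: GWAS per phase --------------------------------------------
    stage = "gwas"
    phase_tables: dict[str, pd.DataFrame] = {}
    phase_pheno: dict[str, pd.DataFrame] = {}
    try:
        for phase, gm in qc_matrices.items():
            in_pheno = gm.samples["id"].isin(ptab.index)
            gm = gm.subset(sample_idx=np.flatnonzero(in_pheno))
            rows = ptab.loc[gm.samples["id"]]
            cov = pd.DataFrame(index=rows.index)
            for c in gwas_covs:
                if c == "sex":
                    cov["sex"] = assoc.encode_sex(rows["sex"])
                elif c == "anesthesia_type":
                    cov = pd.concat(
                        [cov, pd.get_dummies(rows["anesthesia_type"], prefix="anesth", drop_first=True, dtype=float)],
                        axis=1,
                    )
                elif c.startswith("icd_"):
                    cls = c.removeprefix("icd_")
                    cov[c] = [1.0 if cls in comorb.get(pid, set()) else 0.0 for pid in rows.index]
                else:
                    cov[c] = rows[c].astype(float)
            pc = pcs[phase].set_index("id").loc[gm.samples["id"]]
            cov = pd.concat([cov.reset_index(drop=True), pc.reset_index(drop=True)], axis=1)
            results = assoc.gwas_linear(gm, rows["avg_rate"].to_numpy(), cov)
            table = assoc.results_table(results, gm)
            _write_tsv(table, outdir / f"gwas_phase{phase}.tsv")
            phase_tables[phase] = table
            phase_pheno[phase] = rows
            qc_matrices[phase] = gm
            attrition.append(
                {"stage": f"{stage}_phase{phase}", "n_in": int(in_pheno.sum()), "n_out": gm.n_samples}
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: meta + diagnostics + clumping ------------------------------
    stage = "meta"
    try:
        if len(phase_tables) >= 2:
            meta_table = metamod.meta_analyze(phase_tables)
        elif phase_tables:
            only = next(iter(phase_tables.values()))
            meta_table = only.rename(columns={"beta": "beta_meta", "se": "se_meta"})
            meta_table = meta_table[meta_table["status"] == "ok"].copy()
            meta_table["direction"] = "+"
            meta_table["k_studies"] = 1
        else:
            meta_table = pd.DataFrame()
        if len(meta_table):
            _write_tsv(meta_table, outdir / "meta.tsv")
            lam = metamod.genomic_lambda(meta_table["p"])
            manifest["stages"]["genomic_lambda"] = lam
            qq = metamod.qq_table(meta_table["p"])
            _write_tsv(qq, outdir / "qq.tsv")
            man = metamod.manhattan_table(
                meta_table.rename(columns={"p_meta": "p"})
            )
            _write_tsv(man, outdir / "manhattan.tsv")
            pooled = _pool_matrices(list(qc_matrices.values()))
            clump = metamod.ld_clump(
                meta_table,
                pooled,
                p_index=config.suggestive_p,
                r2_threshold=config.clump_r2,
                window=config.clump_window,
            )
            _write_tsv(clump, outdir / "clump.tsv")
            manifest["stages"]["n_suggestive_loci"] = int(len(clump))
        attrition.append(
            {
                "stage": stage,
                "n_in": sum(len(t) for t in phase_tables.values()),
                "n_out": int(len(meta_table)),
            }
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: subgroup validation ----------------------------------------
    stage = "validate"
    try:
        if len(meta_table) and len(qc_matrices) >= 1:
            validation = validate_top_hits(
                meta_table,
                qc_matrices,
                phase_pheno,
                pcs,
                k=config.n_top_hits,
            )
            _write_tsv(validation, outdir / "validation.tsv")
            manifest["stages"]["n_validated_snps"] = int(validation["id"].nunique()) if len(validation) else 0
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: power -------------------------------------------------------
    stage = "power"
    try:
        n_total = sum(p.n_samples for p in qc_matrices.values())
        sigma = float(patients["avg_rate"].std(ddof=1))
        spec = metamod.PowerSpec(
            n=max(n_total, 1),
            maf=config.power_maf,
            beta=config.power_beta,
            sigma=sigma if np.isfinite(sigma) and sigma > 0 else 19.7,
            alpha=config.power_alpha,
        )
        power = metamod.power_quantitative(spec)
        manifest["stages"]["power"] = {
            "n": spec.n,
            "maf": spec.maf,
            "beta": spec.beta,
            "sigma": spec.sigma,
            "alpha": spec.alpha,
            "ncp": spec.ncp,
            "power": power,
        }
        with open(outdir / "power.json", "w", encoding="utf-8") as fh:
            json.dump(manifest["stages"]["power"], fh, indent=1)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- manifest -----------------------------------------------------------
    hashes = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv")) if p.is_file()
    }
    manifest["hashes"] = hashes
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _pool_matrices(matrices: list[genoqc.GenotypeMatrix]) -> genoqc.GenotypeMatrix:
    """Stack per-phase matrices on their shared variant panel (for r^2)."""
    if len(matrices) == 1:
        return matrices[0]
    base = matrices[0]
    common = base.variants["id"]
    for m in matrices[1:]:
        common = common[common.isin(m.variants["id"])]
    common = list(common)
    parts, samples = [], []
    for m in matrices:
        idx = m.variants.set_index("id").index.get_indexer(common)
        parts.append(m.dosages[:, idx])
        samples.append(m.samples)
    variants = base.variants.set_index("id").loc[common].reset_index()
    variants = variants[["chrom", "pos", "id", "ref", "alt", "info_score"]]
    return genoqc.GenotypeMatrix(
        dosages=np.vstack(parts),
        variants=variants,
        samples=pd.concat(samples, ignore_index=True),
    )


def validate_top_hits(
    meta_table: pd.DataFrame,
    matrices: dict[str, genoqc.GenotypeMatrix],
    phenotypes: dict[str, pd.DataFrame],
    pcs: dict[str, pd.DataFrame],
    k: int = 3,
) -> pd.DataFrame:
    """Subgroup case-control validation of the top-k meta-analysis SNPs.

    For each top SNP (by meta P) and each phase, fits logistic models of
    resistant-vs-sensitive and resistant-vs-pooled (intermediate+sensitive)
    status on the dosage with age, sex, weight, and the phase PCs as
    covariates. BP summaries are excluded: they define the clusters.
    """
    top = meta_table.nsmallest(k, "p")["id"].tolist()
    rows = []
    for phase, gm in matrices.items():
        pheno = phenotypes[phase]
        pc = pcs[phase].set_index("id").loc[gm.samples["id"]].reset_index(drop=True)
        for comparison in ("resistant_vs_sensitive", "resistant_vs_pooled"):
            if comparison == "resistant_vs_sensitive":
                mask = pheno["label"].isin(["resistant", "sensitive"]).to_numpy()
            else:
                mask = np.ones(len(pheno), dtype=bool)
            status = (pheno["label"] == "resistant").astype(float).to_numpy()[mask]
            if len(np.unique(status)) < 2:
                continue
            sub = gm.subset(sample_idx=np.flatnonzero(mask))
            cov = pd.DataFrame(
                {
                    "age": pheno["age"].to_numpy()[mask],
                    "sex": assoc.encode_sex(pheno["sex"].to_numpy()[mask]),
                    "weight": pheno["weight"].to_numpy()[mask],
                }
            )
            cov = pd.concat([cov, pc.loc[mask].reset_index(drop=True)], axis=1)
            hits = [t for t in top if t in set(sub.variants["id"])]
            for res in assoc.logistic_assoc(sub, status, cov, variant_ids=hits):
                rows.append(
                    {
                        "id": res.variant_id,
                        "phase": phase,
                        "comparison": comparison,
                        "n_case": res.n_case,
                        "n_control": res.n_control,
                        "odds_ratio": res.odds_ratio,
                        "ci_low": res.ci95[0],
                        "ci_high": res.ci95[1],
                        "p": res.p,
                        "status": res.status,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "phase",
            "comparison",
            "n_case",
            "n_control",
            "odds_ratio",
            "ci_low",
            "ci_high",
            "p",
            "status",
        ],
    )
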