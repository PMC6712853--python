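"""Synthetic anesthesia cohort with known ground truth.

Emulates the data-generating structure of an EHR-derived phenylephrine
response study: a three-class latent response structure (resistant /
intermediate / sensitive) with class-conditional distributions of average
infusion rate, mean SBP, and SBP variability; covariate effects of age, sex,
and body weight on the infusion rate; sparse causal variants with per-allele
effects on the rate (or on the latent class); LD-blocked genotypes for two
phase subcohorts; population-structure axes; and planted QC violations whose
exact reason codes the episode-processing module must later reproduce.

Class-conditional feature defaults (means +/- SDs):

=============  =========  ============  =========
feature        resistant  intermediate  sensitive
=============  =========  ============  =========
share          0.13       0.56          0.31
rate mcg/min   76.2+-22.4 32.1+-11.8    32.4+-12.3
mean SBP mmHg  108.0+-11.0 105.4+-8.7   123.9+-10.9
SD SBP mmHg    15.0+-6.4  10.0+-3.7     19.9+-7.3
=============  =========  ============  =========

The mixture these defaults imply has marginal rate mean ~37 and SD ~20
mcg/min, the regime relevant for the power analysis. Covariate effect
defaults (0.08 per year of age, -4.05 for female sex, 0.14 per kg) match the
magnitudes a full-covariate regression recovers on such cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from pressorgwas.episodes import Bolus, Episode, SbpReading, Segment, REASON_CODES
from pressorgwas.genoqc import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "Cohort",
    "generate_cohort",
    "simulate_patient_table",
    "simulate_genotypes",
    "inject_artifacts",
    "CLASS_NAMES",
]

CLASS_NAMES = ("resistant", "intermediate", "sensitive")

#: ICD-9 3-digit comorbidity classes simulated, with baseline prevalence and
#: a multiplicative enrichment in the resistant group (heart failure, kidney
#: disease, fluid/electrolyte disorders etc. are more prevalent there).
ICD_CLASSES = {
    "250": (0.030, 2.0),  # diabetes mellitus
    "401": (0.050, 1.3),  # essential hypertension
    "272": (0.040, 1.2),  # lipid metabolism disorders
    "278": (0.020, 1.8),  # overweight / obesity
    "414": (0.025, 1.4),  # ischemic heart disease
    "428": (0.015, 2.5),  # heart failure
    "427": (0.020, 1.5),  # cardiac dysrhythmias
    "585": (0.010, 2.2),  # chronic kidney disease
    "276": (0.015, 2.0),  # fluid / electrolyte / acid-base disorders
    "530": (0.030, 1.0),  # esophageal disorders (non-differential filler)
    "715": (0.035, 1.0),  # osteoarthrosis (filler)
    "V45": (0.010, 1.2),  # post-procedural states
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_patients: int = 4000
    phase_split: float = 0.5  # fraction of genotyped patients in phase I
    genotyped_fraction: float = 0.4  # share of patients with genetic data
    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_causal: int = 2  # variants with a direct per-allele rate effect
    causal_beta: float = 13.0  # mcg/min per effect allele
    causal_maf: float = 0.017  # allele frequency pinned for causal variants
    n_class_causal: int = 0  # variants acting on the latent class instead
    class_causal_logodds: float = 0.0  # log-odds toward 'resistant' per allele
    class_probs: tuple[float, float, float] = (0.13, 0.56, 0.31)
    class_rate_means: tuple[float, float, float] = (76.2, 32.1, 32.4)
    class_rate_sds: tuple[float, float, float] = (22.4, 11.8, 12.3)
    class_sbp_means: tuple[float, float, float] = (108.0, 105.4, 123.9)
    class_sbp_sds: tuple[float, float, float] = (11.0, 8.7, 10.9)
    class_sbpsd_means: tuple[float, float, float] = (15.0, 10.0, 19.9)
    class_sbpsd_sds: tuple[float, float, float] = (6.4, 3.7, 7.3)
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.08, "sex": -4.05, "weight": 0.14}
    )
    residual_sd: float = 0.0  # extra rate noise on top of the class draw
    n_subpops: int = 1
    subpop_divergence: float = 0.02
    ld_block_size: int = 20
    ld_rho: float = 0.8
    artifact_rates: dict = field(default_factory=dict)
    multi_episode_rate: float = 0.04  # patients with a second episode
    discordant_class_prob: float = 0.5  # second episode re-draws its class
    seed: int = 0

    def validate(self) -> None:
        def _bad(name, msg):
            raise ValueError(f"SimulationConfig.{name}: {msg}")

        if self.n_patients < 1:
            _bad("n_patients", "must be >= 1")
        if not 0 < self.phase_split < 1:
            _bad("phase_split", "must lie in (0, 1)")
        if not 0 < self.genotyped_fraction <= 1:
            _bad("genotyped_fraction", "must lie in (0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            _bad("maf_range", "must satisfy 0 < lo <= hi < 1")
        if abs(sum(self.class_probs) - 1.0) > 1e-12:
            _bad("class_probs", "must sum to 1 within 1e-12")
        if any(p < 0 for p in self.class_probs):
            _bad("class_probs", "must be nonnegative")
        for name in ("class_rate_sds", "class_sbp_sds", "class_sbpsd_sds"):
            if any(not np.isfinite(s) or s <= 0 for s in getattr(self, name)):
                _bad(name, "all SDs must be finite and > 0")
        for name in (
            "class_rate_means",
            "class_sbp_means",
            "class_sbpsd_means",
            "causal_beta",
            "residual_sd",
        ):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)):
                _bad(name, "must be finite")
        if self.residual_sd < 0:
            _bad("residual_sd", "must be >= 0")
        if self.n_causal + self.n_class_causal > self.n_variants:
            _bad("n_causal", "more causal variants than variants")
        if not 0 <= self.ld_rho < 1:
            _bad("ld_rho", "must lie in [0, 1)")
        if self.ld_block_size < 1:
            _bad("ld_block_size", "must be >= 1")
        if self.n_subpops < 1:
            _bad("n_subpops", "must be >= 1")
        for code, rate in self.artifact_rates.items():
            if code not in REASON_CODES + ("sbp_outlier",):
                _bad("artifact_rates", f"unknown violation code {code!r}")
            if not 0 <= rate <= 1:
                _bad("artifact_rates", f"rate for {code!r} outside [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth of one simulated cohort, for parameter-recovery oracles."""

    class_labels: dict  # patient_id -> class name
    episode_classes: dict  # episode_id -> class name
    causal_betas: dict  # variant_id -> true per-allele rate effect
    class_causal_logodds: dict  # variant_id -> log-odds toward resistant
    subpop: dict  # patient_id -> subpopulation index
    allele_freqs: dict  # variant_id -> drawn ancestral frequency
    episode_violations: dict  # episode_id -> [reason codes]
    value_violations: dict  # episode_id -> count of planted bad SBP values
    phase: dict  # sample_id -> "I" | "II"

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class Cohort:
    episodes: list[Episode]
    patients: pd.DataFrame  # patient_id, class, age, sex, weight, ...
    icd_events: pd.DataFrame  # patient_id, code, date
    genotypes: dict  # phase -> GenotypeMatrix
    truth: TruthRecord


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator, n_samples: int
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, np.ndarray]:
    """Draw LD-blocked genotypes for ``n_samples`` individuals.

    Within each block of ``ld_block_size`` adjacent variants, haplotype
    alleles come from a latent AR(1) Gaussian copula with correlation
    ``ld_rho``; blocks are independent. Per-variant ancestral frequencies are
    uniform on ``maf_range`` and perturbed per subpopulation on the
    sqrt(p(1-p)) scale by ``subpop_divergence``.

    Returns (dosages, variant table, ancestral frequencies, subpop index).
    """
    m = config.n_variants
    p_anc = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    causal_idx = _causal_indices(config)
    p_anc[causal_idx] = config.causal_maf

    n_pop = config.n_subpops
    subpop = rng.integers(0, n_pop, size=n_samples)
    p_pop = np.clip(
        p_anc[None, :]
        + config.subpop_divergence
        * rng.standard_normal((n_pop, m))
        * np.sqrt(p_anc * (1 - p_anc))[None, :],
        1e-4,
        1 - 1e-4,
    )

    rho = config.ld_rho
    bs = config.ld_block_size
    dosages = np.empty((n_samples, m), dtype=np.float64)
    for start in range(0, m, bs):
        stop = min(start + bs, m)
        width = stop - start
        # two haplotypes per person, latent AR(1) within the block
        z = np.empty((2 * n_samples, width))
        z[:, 0] = rng.standard_normal(2 * n_samples)
        scale = np.sqrt(1 - rho**2)
        for j in range(1, width):
            z[:, j] = rho * z[:, j - 1] + scale * rng.standard_normal(2 * n_samples)
        u = norm.cdf(z)
        pp = p_pop[:, start:stop][np.repeat(subpop, 2)]
        alleles = (u < pp).astype(np.float64)
        dosages[:, start:stop] = alleles[0::2] + alleles[1::2]

    chrom_of = np.minimum(np.arange(m) * 22 // max(m, 1), 21) + 1
    pos_within = np.zeros(m, dtype=int)
    for c in range(1, 23):
        mask = chrom_of == c
        pos_within[mask] = 10_000 + 5_000 * np.arange(mask.sum())
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=m)]
    alt = np.array(
        [bases[(list(bases).index(r) + rng.integers(1, 4)) % 4] for r in ref]
    )
    variants = pd.DataFrame(
        {
            "chrom": [str(c) for c in chrom_of],
            "pos": pos_within,
            "id": [f"snp{i:06d}" for i in range(m)],
            "ref": ref,
            "alt": alt,
            "info_score": rng.uniform(0.85, 1.0, size=m),
        }
    )
    return dosages, variants, p_anc, subpop


def _causal_indices(config: SimulationConfig) -> np.ndarray:
    """Deterministic causal-variant placement: one per widely spaced block."""
    total = config.n_causal + config.n_class_causal
    if total == 0:
        return np.array([], dtype=int)
    n_blocks = max(config.n_variants // config.ld_block_size, 1)
    step = max(n_blocks // max(total, 1), 1)
    blocks = [(i * step) % n_blocks for i in range(total)]
    # center of each chosen block
    return np.array(
        [min(b * config.ld_block_size + config.ld_block_size // 2, config.n_variants - 1) for b in blocks],
        dtype=int,
    )


# ---------------------------------------------------------------------------
# Patients
# ---------------------------------------------------------------------------

_CLASS_SEX_F = (0.45, 0.506, 0.601)  # P(female | class)
_CLASS_AGE = ((62.4, 13.9), (59.5, 14.7), (67.4, 12.5))
_CLASS_WEIGHT = ((94.7, 27.6), (88.6, 23.0), (85.4, 22.1))
_CLASS_ANESTH = (
    (0.793, 0.039, 0.168),
    (0.809, 0.044, 0.147),
    (0.843, 0.034, 0.123),
)
_ANESTH_TYPES = ("general", "spinal", "other")


def simulate_patient_table(
    config: SimulationConfig,
    rng: np.random.Generator,
    dosages: np.ndarray | None = None,
    causal_betas: np.ndarray | None = None,
    class_shift: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw patient-level latent classes, covariates, and target phenotypes.

    The target average infusion rate for patient i of class c is

        rate_i = class_rate_mean[c] + N(0, class_rate_sd[c])
                 + b_age (age_i - 62) + b_sex female_i + b_wt (weight_i - 88)
                 + sum_v beta_v dosage_iv + N(0, residual_sd),

    truncated below at 0.5 mcg/min. Covariates are centered at the cohort
    reference values so the class means keep their interpretation.
    """
    n = config.n_patients
    logits = np.log(np.asarray(config.class_probs, dtype=float) + 1e-300)
    logits = np.tile(logits, (n, 1))
    if class_shift is not None:
        logits[:, 0] = logits[:, 0] + class_shift
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cls = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)

    age = np.empty(n)
    weight = np.empty(n)
    female = np.empty(n)
    anesth = np.empty(n, dtype=object)
    for c in range(3):
        mask = cls == c
        k = int(mask.sum())
        age[mask] = np.clip(
            rng.normal(_CLASS_AGE[c][0], _CLASS_AGE[c][1], k), 18, 95
        )
        weight[mask] = np.clip(
            rng.normal(_CLASS_WEIGHT[c][0], _CLASS_WEIGHT[c][1], k), 35, 250
        )
        female[mask] = (rng.random(k) < _CLASS_SEX_F[c]).astype(float)
        anesth[mask] = rng.choice(_ANESTH_TYPES, size=k, p=_CLASS_ANESTH[c])

    eff = config.covariate_effects
    rate = (
        np.asarray(config.class_rate_means)[cls]
        + rng.standard_normal(n) * np.asarray(config.class_rate_sds)[cls]
        + eff.get("age", 0.0) * (age - 62.0)
        + eff.get("sex", 0.0) * female
        + eff.get("weight", 0.0) * (weight - 88.0)
    )
    if config.residual_sd > 0:
        rate = rate + rng.standard_normal(n) * config.residual_sd
    if dosages is not None and causal_betas is not None:
        rate = rate + dosages @ causal_betas
    rate = np.maximum(rate, 0.5)

    sbp_mean = (
        np.asarray(config.class_sbp_means)[cls]
        + rng.standard_normal(n) * np.asarray(config.class_sbp_sds)[cls]
    )
    sbp_sd = np.maximum(
        np.asarray(config.class_sbpsd_means)[cls]
        + rng.standard_normal(n) * np.asarray(config.class_sbpsd_sds)[cls],
        0.8,
    )
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "class": [CLASS_NAMES[c] for c in cls],
            "class_idx": cls,
            "age": age,
            "sex": np.where(female == 1.0, "F", "M"),
            "weight": weight,
            "anesthesia_type": anesth,
            "target_rate": rate,
            "target_sbp_mean": sbp_mean,
            "target_sbp_sd": sbp_sd,
        }
    )


# ---------------------------------------------------------------------------
# Episodes
# ---------------------------------------------------------------------------


def _make_episode(
    rng: np.random.Generator,
    patient: pd.Series,
    episode_id: str,
    target_rate: float,
    target_sbp_mean: float,
    target_sbp_sd: float,
) -> Episode:
    duration = float(rng.uniform(30, 180))
    n_seg = int(rng.integers(1, 4))
    cuts = np.sort(rng.uniform(0.15, 0.85, size=n_seg - 1)) * duration
    bounds = np.concatenate([[0.0], cuts, [duration]])
    widths = np.diff(bounds)
    jitter = rng.uniform(0.7, 1.3, size=n_seg)
    # rescale so the duration-weighted mean equals the target exactly
    jitter *= duration / float(widths @ jitter)
    segments = [
        Segment(float(bounds[k]), float(bounds[k + 1]), float(target_rate * jitter[k]))
        for k in range(n_seg)
    ]

    times = [0.0]
    while times[-1] < duration:
        times.append(times[-1] + float(rng.uniform(2, 5)))
    times = np.array(times[:-1]) if times[-1] > duration else np.array(times)
    phi = 0.5
    innov_sd = target_sbp_sd * np.sqrt(1 - phi**2)
    vals = np.empty(len(times))
    x = rng.standard_normal() * target_sbp_sd
    for i in range(len(times)):
        vals[i] = target_sbp_mean + x
        x = phi * x + innov_sd * rng.standard_normal()
    modality = "invasive" if rng.random() < 0.3 else "noninvasive"
    readings = [
        SbpReading(float(t), float(v), modality) for t, v in zip(times, vals)
    ]
    return Episode(
        patient_id=patient["patient_id"],
        episode_id=episode_id,
        age=float(patient["age"]),
        sex=patient["sex"],
        weight=float(patient["weight"]),
        anesthesia_type=patient["anesthesia_type"],
        infusion_segments=segments,
        sbp_readings=readings,
        bolus_events=[],
    )


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------


def inject_artifacts(
    episodes: list[Episode],
    config: SimulationConfig,
    seed: int,
) -> tuple[list[Episode], dict, dict]:
    """Plant QC violations at the configured rates.

    Each violation is planted on a disjoint set of clean episodes and the
    exact reason code episode-processing must emit is recorded. Returns
    (episodes, episode_violations, value_violations); with all rates zero the
    episode list is returned unchanged.
    """
    config.validate()
    if not config.artifact_rates or all(
        r == 0 for r in config.artifact_rates.values()
    ):
        return episodes, {}, {}
    rng = np.random.default_rng(seed)
    episodes = list(episodes)
    n = len(episodes)
    order = rng.permutation(n)
    cursor = 0
    episode_violations: dict[str, list[str]] = {}
    value_violations: dict[str, int] = {}

    def take(k: int) -> list[int]:
        nonlocal cursor
        picked = order[cursor : cursor + k].tolist()
        cursor += len(picked)
        return picked

    for code, rate in sorted(config.artifact_rates.items()):
        k = int(round(rate * n))
        for idx in take(k):
            ep = episodes[idx]
            episodes[idx] = _plant(rng, ep, code)
            if code == "sbp_outlier":
                value_violations[ep.episode_id] = (
                    value_violations.get(ep.episode_id, 0) + 1
                )
            else:
                episode_violations.setdefault(ep.episode_id, []).append(code)
    return episodes, episode_violations, value_violations


def _plant(rng: np.random.Generator, ep: Episode, code: str) -> Episode:
    segs, readings, boluses = (
        list(ep.infusion_segments),
        list(ep.sbp_readings),
        list(ep.bolus_events),
    )
    weight = ep.weight
    if code == "short_infusion":
        # compress the timeline into 9 minutes, keeping >= 3 readings inside
        t1 = ep.infusion_window[1]
        f = 9.0 / t1
        segs = [Segment(s.t_start * f, s.t_end * f, s.rate, s.unit) for s in segs]
        readings = [SbpReading(r.t * f, r.value, r.modality) for r in readings]
        boluses = [Bolus(b.drug, b.t * f) for b in boluses]
    elif code == "few_sbp":
        readings = readings[:2]
    elif code == "bolus_during_infusion":
        t0, t1 = ep.infusion_window
        drug = "ephedrine" if rng.random() < 0.5 else "phenylephrine"
        boluses = boluses + [Bolus(drug, float((t0 + t1) / 2))]
    elif code == "mixed_modality":
        i = len(readings) // 2
        r = readings[i]
        other = "invasive" if r.modality == "noninvasive" else "noninvasive"
        readings[i] = SbpReading(r.t, r.value, other)
    elif code == "bad_unit":
        segs = [Segment(s.t_start, s.t_end, s.rate, "mcg/kg/min") for s in segs]
    elif code == "missing_weight":
        weight = None
    elif code == "sbp_outlier":
        i = int(rng.integers(0, len(readings)))
        r = readings[i]
        bad = 250.0 if rng.random() < 0.5 else 15.0
        readings[i] = SbpReading(r.t, bad, r.modality)
    elif code == "no_infusion":
        segs = []
    else:
        raise ValueError(f"unknown violation code {code!r}")
    return Episode(
        patient_id=ep.patient_id,
        episode_id=ep.episode_id,
        age=ep.age,
        sex=ep.sex,
        weight=weight,
        anesthesia_type=ep.anesthesia_type,
        infusion_segments=segs,
        sbp_readings=readings,
        bolus_events=boluses,
    )


# ---------------------------------------------------------------------------
# ICD events
# ---------------------------------------------------------------------------


def _simulate_icd(
    rng: np.random.Generator, patients: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    dates = pd.date_range("2012-07-01", "2016-11-30", freq="D")
    cls_idx = patients["class_idx"].to_numpy()
    for code, (base_prev, resist_mult) in ICD_CLASSES.items():
        prev = np.where(cls_idx == 0, base_prev * resist_mult, base_prev)
        has = rng.random(len(patients)) < prev
        # sub-threshold mentions: coded on fewer than 3 distinct dates
        noise = rng.random(len(patients)) < 0.01
        for pid in patients["patient_id"][has]:
            n_dates = int(rng.integers(3, 7))
            for d in rng.choice(len(dates), size=n_dates, replace=False):
                suffix = f".{rng.integers(0, 100):02d}" if rng.random() < 0.8 else ""
                rows.append(
                    {
                        "patient_id": pid,
                        "code": f"{code}{suffix}",
                        "date": dates[d].date().isoformat(),
                    }
                )
        for pid in patients["patient_id"][noise & ~has]:
            n_dates = int(rng.integers(1, 3))
            for d in rng.choice(len(dates), size=n_dates, replace=False):
                rows.append(
                    {
                        "patient_id": pid,
                        "code": f"{code}.{rng.integers(0, 100):02d}",
                        "date": dates[d].date().isoformat(),
                    }
                )
    return pd.DataFrame(rows, columns=["patient_id", "code", "date"])


# ---------------------------------------------------------------------------
# Top-level generator
# ---------------------------------------------------------------------------


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full synthetic cohort with ground truth.

    Draws genotypes, latent classes, covariates and per-patient target
    phenotypes; renders one (sometimes two) anesthesia episodes per patient
    whose recomputed features recover the generating class structure; plants
    the configured QC violations; and splits genotyped patients into phase
    I/II matrices sharing one variant panel. Identical config (including
    seed) reproduces the cohort bit-identically.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    dosages, variants, p_anc, subpop = simulate_genotypes(config, rng, n)
    causal_idx = _causal_indices(config)
    betas = np.zeros(config.n_variants)
    causal_betas: dict[str, float] = {}
    class_causal: dict[str, float] = {}
    direct = causal_idx[: config.n_causal]
    through_class = causal_idx[config.n_causal :]
    betas[direct] = config.causal_beta
    for i in direct:
        causal_betas[variants["id"][i]] = config.causal_beta
    class_shift = None
    if len(through_class):
        class_shift = dosages[:, through_class].sum(axis=1) * config.class_causal_logodds
        for i in through_class:
            class_causal[variants["id"][i]] = config.class_causal_logodds

    patients = simulate_patient_table(config, rng, dosages, betas, class_shift)

    episodes: list[Episode] = []
    episode_classes: dict[str, str] = {}
    extra = rng.random(n) < config.multi_episode_rate
    redraw = rng.random(n) < config.discordant_class_prob
    for i, row in patients.iterrows():
        eid = f"E{i:06d}a"
        episodes.append(
            _make_episode(
                rng,
                row,
                eid,
                row["target_rate"],
                row["target_sbp_mean"],
                row["target_sbp_sd"],
            )
        )
        episode_classes[eid] = row["class"]
        if extra[i]:
            if redraw[i]:
                c = int(rng.choice(3, p=config.class_probs))
                tr = max(
                    config.class_rate_means[c]
                    + rng.standard_normal() * config.class_rate_sds[c],
                    0.5,
                )
                tm = (
                    config.class_sbp_means[c]
                    + rng.standard_normal() * config.class_sbp_sds[c]
                )
                ts = max(
                    config.class_sbpsd_means[c]
                    + rng.standard_normal() * config.class_sbpsd_sds[c],
                    0.8,
                )
                ep_class = CLASS_NAMES[c]
            else:
                tr, tm, ts = (
                    row["target_rate"],
                    row["target_sbp_mean"],
                    row["target_sbp_sd"],
                )
                ep_class = row["class"]
            eid2 = f"E{i:06d}b"
            episodes.append(_make_episode(rng, row, eid2, tr, tm, ts))
            episode_classes[eid2] = ep_class

    episodes, ep_viol, val_viol = inject_artifacts(
        episodes, config, seed=int(rng.integers(0, 2**31 - 1))
    )

    icd = _simulate_icd(rng, patients)

    n_geno = int(round(config.genotyped_fraction * n))
    geno_ids = rng.choice(n, size=n_geno, replace=False)
    geno_ids.sort()
    in_phase1 = rng.random(n_geno) < config.phase_split
    phase_of = {}
    genotypes = {}
    for phase, mask in (("I", in_phase1), ("II", ~in_phase1)):
        idx = geno_ids[mask]
        sample_df = pd.DataFrame(
            {"id": patients["patient_id"].to_numpy()[idx], "phase": phase}
        )
        genotypes[phase] = GenotypeMatrix(
            dosages=dosages[idx].copy(),
            variants=variants.copy(),
            samples=sample_df,
        )
        for sid in sample_df["id"]:
            phase_of[sid] = phase

    truth = TruthRecord(
        class_labels=dict(zip(patients["patient_id"], patients["class"])),
        episode_classes=episode_classes,
        causal_betas=causal_betas,
        class_causal_logodds=class_causal,
        subpop=dict(zip(patients["patient_id"], subpop.tolist())),
        allele_freqs=dict(zip(variants["id"], p_anc.tolist())),
        episode_violations=ep_viol,
        value_violations=val_viol,
        phase=phase_of,
    )
    return Cohort(
        episodes=episodes,
        patients=patients,
        icd_events=icd,
        genotypes=genotypes,
        truth=truth,
    )
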