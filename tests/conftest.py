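import numpy as np
import pandas as pd
import pytest

from pressorgwas.episodes import Bolus, Episode, SbpReading, Segment
from pressorgwas.genoqc import GenotypeMatrix
from pressorgwas.simulate import SimulationConfig, generate_cohort


def make_matrix(dosages, chrom=None, pos=None, info=None, sample_ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix around a raw dosage array with default metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "id": [f"v{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "info_score": info if info is not None else np.ones(m),
        }
    )
    samples = pd.DataFrame({"id": sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]})
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def make_episode(
    episode_id="E1",
    patient_id="P1",
    segments=((0.0, 30.0, 50.0),),
    sbp=((5.0, 110.0), (15.0, 115.0), (25.0, 105.0)),
    modality="noninvasive",
    boluses=(),
    weight=80.0,
    **kw,
) -> Episode:
    return Episode(
        patient_id=patient_id,
        episode_id=episode_id,
        age=kw.get("age", 60.0),
        sex=kw.get("sex", "F"),
        weight=weight,
        anesthesia_type=kw.get("anesthesia_type", "general"),
        infusion_segments=[Segment(a, b, r) for a, b, r in segments],
        sbp_readings=[SbpReading(t, v, modality) for t, v in sbp],
        bolus_events=[Bolus(d, t) for d, t in boluses],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared across tests (600 patients, 800 variants)."""
    cfg = SimulationConfig(
        n_patients=600,
        n_variants=800,
        n_causal=1,
        genotyped_fraction=0.8,
        seed=11,
    )
    return cfg, generate_cohort(cfg)
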