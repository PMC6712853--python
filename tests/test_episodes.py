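"""Episode parsing, QC exclusion rules, and phenotype feature derivation."""

import math

import numpy as np
import pytest

from conftest import make_episode
from pressorgwas import episodes as epi
from pressorgwas.episodes import (
    Episode,
    QCRules,
    SbpReading,
    Segment,
    aggregate_patients,
    compute_features,
    features_table,
    qc_filter,
    read_episodes,
    write_episodes,
)


class TestParsing:
    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("\t".join(epi.COLUMNS) + "\n")
        assert read_episodes(p) == []

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("patient_id\tepisode_id\n")
        with pytest.raises(ValueError, match="missing mandatory column"):
            read_episodes(p)

    def test_round_trip_is_value_identical(self, tmp_path, small_cohort):
        _, cohort = small_cohort
        eps = cohort.episodes[:50]
        path = tmp_path / "cohort.tsv"
        write_episodes(eps, path)
        back = read_episodes(path)
        assert len(back) == len(eps)
        by_id = {e.episode_id: e for e in back}
        for orig in eps:
            got = by_id[orig.episode_id]
            assert got.patient_id == orig.patient_id
            assert got.sex == orig.sex
            assert (got.weight is None) == (orig.weight is None)
            if orig.weight is not None:
                assert got.weight == pytest.approx(orig.weight, rel=1e-9)
            assert len(got.infusion_segments) == len(orig.infusion_segments)
            for a, b in zip(got.infusion_segments, orig.infusion_segments):
                assert a.t_start == pytest.approx(b.t_start, rel=1e-9)
                assert a.t_end == pytest.approx(b.t_end, rel=1e-9)
                assert a.rate == pytest.approx(b.rate, rel=1e-9)
                assert a.unit == b.unit
            assert len(got.sbp_readings) == len(orig.sbp_readings)
            for a, b in zip(got.sbp_readings, orig.sbp_readings):
                assert a.value == pytest.approx(b.value, rel=1e-9)
                assert a.modality == b.modality

    def test_nonstandard_unit_is_preserved_for_screening(self, tmp_path):
        ep = make_episode(segments=())
        ep.infusion_segments = [Segment(0, 30, 1.2, unit="mcg/kg/min")]
        path = tmp_path / "u.tsv"
        write_episodes([ep], path)
        (got,) = read_episodes(path)
        assert got.infusion_segments[0].unit == "mcg/kg/min"

    def test_malformed_rows_collected_not_dropped(self, tmp_path):
        path = tmp_path / "bad.tsv"
        header = "\t".join(epi.COLUMNS)
        good = "P1\tE1\tdemo\t.\t.\t.\t.\t.\t.\t60\tF\t80\tgeneral"
        seg = "P1\tE1\tsegment\t0\t30\t50\tmcg/min\t.\t.\t.\t.\t.\t."
        bad = "P1\tE1\tsbp\tnot_a_number\t.\t110\t.\tnoninvasive\t.\t.\t.\t.\t."
        path.write_text("\n".join([header, good, seg, bad]) + "\n")
        eps, issues = read_episodes(path, errors="collect")
        assert len(eps) == 1 and len(issues) == 1
        with pytest.raises(epi.EpisodeParseError):
            read_episodes(path)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError, match="t_start"):
            make_episode(segments=((10.0, 5.0, 40.0),))
        with pytest.raises(ValueError, match="overlap"):
            make_episode(segments=((0.0, 20.0, 40.0), (10.0, 30.0, 50.0)))


class TestQCRules:
    def test_short_infusion_excluded(self):
        ep = make_episode(
            segments=((0.0, 9.0, 50.0),),
            sbp=((2.0, 110.0), (4.0, 112.0), (8.0, 108.0)),
        )
        kept, log = qc_filter([ep])
        assert kept == []
        assert [e.reason_code for e in log] == ["short_infusion"]

    def test_outlier_reading_dropped_value_level(self):
        sbp = ((2.0, 250.0), (5.0, 110.0), (10.0, 112.0), (15.0, 108.0))
        ep = make_episode(sbp=sbp)
        kept, log = qc_filter([ep])
        assert len(kept) == 1 and log == []
        f = compute_features(ep)
        assert f.n_sbp == 3
        assert f.mean_sbp == pytest.approx(110.0)

    def test_outlier_cost_can_trigger_few_sbp(self):
        ep = make_episode(sbp=((2.0, 250.0), (5.0, 110.0), (10.0, 112.0)))
        kept, log = qc_filter([ep])
        assert kept == []
        assert [e.reason_code for e in log] == ["few_sbp"]

    def test_boundary_values_are_artifacts(self):
        # open interval: exactly 20 / 200 mmHg are dropped
        ep = make_episode(sbp=((2.0, 20.0), (5.0, 200.0), (10.0, 110.0), (12.0, 111.0), (14.0, 112.0)))
        f = compute_features(ep)
        assert f.n_sbp == 3

    def test_bolus_during_infusion(self):
        ep = make_episode(boluses=(("ephedrine", 15.0),))
        kept, log = qc_filter([ep])
        assert kept == [] and log[0].reason_code == "bolus_during_infusion"
        # bolus outside the infusion window is harmless
        ep2 = make_episode(boluses=(("ephedrine", 45.0),))
        kept2, log2 = qc_filter([ep2])
        assert len(kept2) == 1 and log2 == []

    def test_non_confounding_bolus_ignored(self):
        ep = make_episode(boluses=(("propofol", 15.0),))
        kept, _ = qc_filter([ep])
        assert len(kept) == 1

    def test_mixed_modality(self):
        ep = make_episode()
        ep.sbp_readings = [
            SbpReading(5.0, 110.0, "invasive"),
            SbpReading(10.0, 112.0, "noninvasive"),
            SbpReading(15.0, 108.0, "invasive"),
        ]
        kept, log = qc_filter([ep])
        assert kept == [] and log[0].reason_code == "mixed_modality"

    def test_bad_unit_and_missing_weight(self):
        ep = make_episode()
        ep.infusion_segments = [Segment(0, 30, 1.1, unit="mcg/kg/min")]
        kept, log = qc_filter([ep])
        assert "bad_unit" in {e.reason_code for e in log}
        ep2 = make_episode(weight=None)
        kept2, log2 = qc_filter([ep2])
        assert [e.reason_code for e in log2] == ["missing_weight"]

    def test_empty_input(self):
        kept, log = qc_filter([])
        assert kept == [] and log == []

    def test_partition_property(self, small_cohort):
        _, cohort = small_cohort
        kept, log = qc_filter(cohort.episodes)
        excluded_ids = {e.episode_id for e in log}
        assert len(kept) + len(excluded_ids) == len(cohort.episodes)
        assert not excluded_ids & {e.episode_id for e in kept}

    def test_duration_threshold_monotonicity(self, small_cohort):
        _, cohort = small_cohort
        eps = cohort.episodes[:200]
        sizes = []
        for thr in (5.0, 10.0, 40.0, 120.0):
            kept, _ = qc_filter(eps, QCRules(min_duration=thr))
            sizes.append(len(kept))
        assert sizes == sorted(sizes, reverse=True)


class TestFeatures:
    def test_duration_weighted_average(self):
        ep = make_episode(
            segments=((0.0, 10.0, 40.0), (10.0, 30.0, 80.0)),
            sbp=((5.0, 100.0), (15.0, 110.0), (25.0, 120.0)),
        )
        f = compute_features(ep)
        assert f.avg_rate == pytest.approx((40 * 10 + 80 * 20) / 30)
        assert f.avg_rate == pytest.approx(66.667, abs=5e-4)

    def test_arithmetic_mean_alternative(self):
        ep = make_episode(segments=((0.0, 10.0, 40.0), (10.0, 30.0, 80.0)))
        f = compute_features(ep, rate_method="arithmetic")
        assert f.avg_rate == pytest.approx(60.0)

    def test_mean_and_sample_sd(self):
        ep = make_episode(sbp=((5.0, 100.0), (15.0, 110.0), (25.0, 120.0)))
        f = compute_features(ep)
        assert f.mean_sbp == pytest.approx(110.0)
        assert f.sd_sbp == pytest.approx(10.0)  # sample SD, n-1

    def test_constant_series_zero_sd(self):
        ep = make_episode(sbp=((5.0, 110.0), (15.0, 110.0), (25.0, 110.0)))
        assert compute_features(ep).sd_sbp == 0.0

    def test_readings_outside_window_ignored(self):
        sbp = ((-5.0, 300.0), (5.0, 100.0), (15.0, 110.0), (25.0, 120.0), (35.0, 55.0))
        ep = make_episode(sbp=sbp)
        f = compute_features(ep)
        assert f.n_sbp == 3 and f.mean_sbp == pytest.approx(110.0)

    def test_order_invariance(self):
        sbp = [(25.0, 120.0), (5.0, 100.0), (15.0, 110.0)]
        segs = [(10.0, 30.0, 80.0), (0.0, 10.0, 40.0)]
        a = compute_features(make_episode(segments=tuple(segs), sbp=tuple(sbp)))
        b = compute_features(
            make_episode(segments=tuple(sorted(segs)), sbp=tuple(sorted(sbp)))
        )
        assert a == b

    def test_no_valid_readings_signals_qc_order_bug(self):
        ep = make_episode(sbp=((5.0, 250.0), (15.0, 250.0), (25.0, 250.0)))
        with pytest.raises(ValueError, match="QC-order"):
            compute_features(ep)


class TestAggregation:
    @staticmethod
    def _table(rows):
        import pandas as pd

        base = {
            "mean_sbp": 110.0,
            "sd_sbp": 10.0,
            "age": 60.0,
            "weight": 80.0,
            "sex": "F",
            "anesthesia_type": "general",
        }
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_discordant_patient_dropped(self):
        t = self._table(
            [
                {"patient_id": "P1", "episode_id": "a", "avg_rate": 70.0, "label": "resistant"},
                {"patient_id": "P1", "episode_id": "b", "avg_rate": 30.0, "label": "sensitive"},
            ]
        )
        patients, dropped = aggregate_patients(t)
        assert len(patients) == 0
        assert list(dropped["patient_id"]) == ["P1"]

    def test_concordant_patient_averaged(self):
        t = self._table(
            [
                {"patient_id": "P1", "episode_id": "a", "avg_rate": 30.0, "label": "sensitive"},
                {"patient_id": "P1", "episode_id": "b", "avg_rate": 34.0, "label": "sensitive"},
            ]
        )
        patients, dropped = aggregate_patients(t)
        assert len(dropped) == 0
        assert patients.loc[0, "avg_rate"] == pytest.approx(32.0)

    def test_single_episode_passthrough(self):
        t = self._table(
            [{"patient_id": "P1", "episode_id": "a", "avg_rate": 41.5, "label": "intermediate"}]
        )
        patients, _ = aggregate_patients(t)
        assert patients.loc[0, "avg_rate"] == 41.5
        assert patients.loc[0, "n_episodes"] == 1

    def test_missing_label_raises(self):
        t = self._table(
            [{"patient_id": "P1", "episode_id": "a", "avg_rate": 41.5, "label": np.nan}]
        )
        with pytest.raises(ValueError, match="without a cluster label"):
            aggregate_patients(t)
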