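"""VCF round trips, variant/sample filters, HWE, relatedness, PCA."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from pressorgwas.genoqc import (
    GenotypeMatrix,
    compute_pcs,
    estimate_relatedness,
    hard_call,
    hwe_test,
    prune_related,
    read_vcf,
    sample_filter,
    variant_filter,
    write_vcf,
)


class TestVcfIO:
    def test_gt_and_ds_parsing(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="d">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\tva\tA\tG\t.\tPASS\t.\tGT:DS\t0/1:1.37\t0/0:0.02\n"
            "1\t200\tvb\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        )
        gm, n_multi = read_vcf(path)
        assert n_multi == 0
        # DS preferred where present
        assert gm.dosages[0, 0] == pytest.approx(1.37)
        assert gm.dosages[1, 0] == pytest.approx(0.02)
        # GT fallback maps 0/1 -> 1, 1/1 -> 2
        assert gm.dosages[0, 1] == 1.0
        assert gm.dosages[1, 1] == 2.0

    def test_multiallelic_skipped_with_count(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\tva\tA\tG,T\t.\tPASS\t.\tGT\t1/2\n"
            "1\t200\tvb\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
        )
        gm, n_multi = read_vcf(path)
        assert n_multi == 1
        assert gm.n_variants == 1 and gm.variants.loc[0, "id"] == "vb"

    def test_write_read_round_trip(self, tmp_path, small_cohort):
        _, cohort = small_cohort
        gm = cohort.genotypes["I"].subset(
            sample_idx=np.arange(10), variant_idx=np.arange(40)
        )
        path = tmp_path / "rt.vcf"
        write_vcf(gm, path)
        back, n_multi = read_vcf(path)
        assert n_multi == 0
        np.testing.assert_allclose(back.dosages, gm.dosages, atol=1e-6)
        assert list(back.variants["id"]) == list(gm.variants["id"])
        np.testing.assert_allclose(
            back.variants["info_score"], gm.variants["info_score"], atol=1e-6
        )

    def test_missing_dosage_round_trip(self, tmp_path):
        dos = np.array([[0.0, np.nan], [1.5, 2.0]])
        gm = make_matrix(dos)
        path = tmp_path / "miss.vcf"
        write_vcf(gm, path)
        back, _ = read_vcf(path)
        assert np.isnan(back.dosages[0, 1])
        assert back.dosages[1, 0] == pytest.approx(1.5)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="lie in"):
            make_matrix(np.array([[3.0]]))
        with pytest.raises(ValueError, match="duplicate"):
            make_matrix(np.zeros((2, 2)), sample_ids=["a", "a"])


class TestHWE:
    def test_exact_equilibrium(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_hand_computed_deviation(self):
        # counts (30, 30, 40): p = 0.45, expected (20.25, 49.5, 30.25)
        from scipy.stats import chi2

        p = hwe_test(30, 30, 40)
        expected = np.array([20.25, 49.5, 30.25])
        observed = np.array([30, 30, 40])
        stat = ((observed - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(15.52, abs=0.01)
        assert p == pytest.approx(chi2.sf(stat, 1), rel=1e-12)

    def test_monomorphic_convention(self):
        assert hwe_test(50, 0, 0) == 1.0
        assert hwe_test(0, 0, 50) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 3)

    def test_null_simulated_hwe_rarely_fails_screen(self):
        rng = np.random.default_rng(5)
        n, m = 500, 2000
        p = rng.uniform(0.05, 0.5, m)
        dos = rng.binomial(2, p, size=(n, m)).astype(float)
        gm = make_matrix(dos)
        _, report = variant_filter(gm, min_info=0.0, min_call_rate=0.0, min_maf=0.0)
        assert len(report.removed["hwe"]) == 0


class TestFilters:
    def test_all_pass_fixture(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.3, size=(200, 20)).astype(float)
        gm = make_matrix(dos)
        out, report = variant_filter(gm)
        assert report.counts == {"info": 0, "call_rate": 0, "maf": 0, "hwe": 0}
        assert out.n_variants == 20

    def test_one_planted_failure_per_filter(self):
        rng = np.random.default_rng(1)
        n = 400
        dos = rng.binomial(2, 0.3, size=(n, 6)).astype(float)
        info = np.ones(6)
        info[1] = 0.5  # fails info
        dos[: int(0.02 * n) + 1, 2] = np.nan  # fails call rate 0.99
        dos[:, 3] = rng.binomial(2, 0.004, size=n)  # fails MAF
        half = n // 2
        dos[:half, 4] = 0.0  # gross HWE violation: no heterozygotes
        dos[half:, 4] = 2.0
        gm = make_matrix(dos, info=info)
        out, report = variant_filter(gm)
        assert report.counts == {"info": 1, "call_rate": 1, "maf": 1, "hwe": 1}
        assert report.removed["info"] == ["v1"]
        assert report.removed["call_rate"] == ["v2"]
        assert report.removed["maf"] == ["v3"]
        assert report.removed["hwe"] == ["v4"]
        assert out.n_variants == 2

    def test_maf_half_percent_removed(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, [0.005, 0.3], size=(2000, 2)).astype(float)
        gm = make_matrix(dos)
        _, report = variant_filter(gm)
        assert report.removed["maf"] == ["v0"]

    def test_sample_filter_threshold(self):
        dos = np.tile(np.array([0.0, 1.0, 2.0, 1.0, 0.0] * 4), (3, 1))
        dos[0, :2] = np.nan  # 10% missing -> removed at 95%
        gm = make_matrix(dos)
        out, report = sample_filter(gm)
        assert report.removed["call_rate"] == ["s0"]
        assert out.n_samples == 2

    def test_filters_idempotent(self, small_cohort):
        _, cohort = small_cohort
        gm = cohort.genotypes["I"]
        once, _ = variant_filter(gm)
        twice, report2 = variant_filter(once)
        assert twice.n_variants == once.n_variants
        assert report2.n_removed == 0
        s_once, _ = sample_filter(gm)
        _, s_rep2 = sample_filter(s_once)
        assert s_rep2.n_removed == 0


class TestRelatedness:
    @staticmethod
    def _population(rng, n, m=3000):
        p = rng.uniform(0.05, 0.5, m)
        return p, rng.binomial(2, p, size=(n, m)).astype(float)

    def test_duplicate_sample_detected_and_pruned(self):
        rng = np.random.default_rng(3)
        p, dos = self._population(rng, 12)
        dos[1] = dos[0]  # duplicate
        gm = make_matrix(dos)
        pairs = estimate_relatedness(gm)
        dup = pairs[(pairs.id1 == "s0") & (pairs.id2 == "s1")]["pi_hat"].iloc[0]
        assert dup == pytest.approx(1.0, abs=0.05)
        pruned, report = prune_related(gm)
        assert len(report.removed["related"]) == 1
        assert pruned.n_samples == 11

    def test_parent_child_pi_half(self):
        rng = np.random.default_rng(4)
        m = 5000
        p = rng.uniform(0.05, 0.5, m)
        hap = lambda: (rng.random(m) < p).astype(float)  # noqa: E731
        shared = hap()
        parent = shared + hap()
        child = shared + hap()
        _, others = self._population(rng, 10, m)
        gm = make_matrix(np.vstack([parent, child, others[:, :m]]))
        pairs = estimate_relatedness(gm)
        pc = pairs[(pairs.id1 == "s0") & (pairs.id2 == "s1")]["pi_hat"].iloc[0]
        assert pc == pytest.approx(0.5, abs=0.05)

    def test_unrelated_max_pi_small(self):
        rng = np.random.default_rng(6)
        p, dos = self._population(rng, 15, 5000)
        pairs = estimate_relatedness(make_matrix(dos))
        assert pairs["pi_hat"].max() < 0.1

    def test_pruned_output_has_no_flagged_pair(self):
        rng = np.random.default_rng(7)
        p, dos = self._population(rng, 14, 4000)
        dos[1] = dos[0]
        dos[3] = dos[2]
        gm = make_matrix(dos)
        pruned, _ = prune_related(gm)
        pairs = estimate_relatedness(pruned)
        assert (pairs["pi_hat"] < 0.1875).all()

    def test_few_variants_warns(self):
        rng = np.random.default_rng(8)
        dos = rng.binomial(2, 0.3, size=(4, 30)).astype(float)
        with pytest.warns(UserWarning, match="noisy"):
            estimate_relatedness(make_matrix(dos))


class TestPCA:
    def test_orthonormal_and_sorted(self):
        rng = np.random.default_rng(9)
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, 200), size=(60, 200)).astype(float)
        coords, eig = compute_pcs(make_matrix(dos), n_pcs=6)
        U = coords[[f"PC{i+1}" for i in range(6)]].to_numpy()
        np.testing.assert_allclose(U.T @ U, np.eye(6), atol=1e-8)
        assert (np.diff(eig) <= 1e-9).all()

    def test_separates_planted_subpopulations(self):
        from pressorgwas.simulate import SimulationConfig, simulate_genotypes

        cfg = SimulationConfig(
            n_patients=200, n_variants=800, n_subpops=2, subpop_divergence=0.15
        )
        rng = np.random.default_rng(10)
        dos, variants, _, subpop = simulate_genotypes(cfg, rng, 200)
        gm = make_matrix(dos)
        coords, _ = compute_pcs(gm, n_pcs=2)
        pc1 = coords["PC1"].to_numpy()
        a, b = pc1[subpop == 0], pc1[subpop == 1]
        within_sd = max(a.std(), b.std())
        assert abs(a.mean() - b.mean()) > 3 * within_sd

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.1, 0.5, 200)
        dos = rng.binomial(2, p, size=(50, 200)).astype(float)
        gm = make_matrix(dos)
        coords, eig = compute_pcs(gm, n_pcs=5)
        # independent oracle: eigendecomposition of the sample covariance of
        # the standardized matrix
        phat = dos.mean(axis=0) / 2
        keep = (phat > 0) & (phat < 1)
        x = (dos[:, keep] - 2 * phat[keep]) / np.sqrt(2 * phat[keep] * (1 - phat[keep]))
        cov = x @ x.T / (x.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        np.testing.assert_allclose(eig, w[:5], rtol=1e-8)
        for j in range(5):
            dot = abs(float(v[:, j] @ coords[f"PC{j+1}"].to_numpy()))
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_n_pcs_beyond_rank_rejected(self):
        dos = np.random.default_rng(12).binomial(2, 0.3, size=(4, 10)).astype(float)
        with pytest.raises(ValueError, match="rank"):
            compute_pcs(make_matrix(dos), n_pcs=6)


def test_hard_call_thresholds():
    dos = np.array([0.0, 0.49, 0.5, 1.49, 1.5, 2.0, np.nan])
    out = hard_call(dos)
    np.testing.assert_array_equal(out[:6], [0, 0, 1, 1, 2, 2])
    assert np.isnan(out[6])
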