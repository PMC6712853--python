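"""Fixed-effect meta-analysis, inflation, clumping, and power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_matrix
from pressorgwas.meta import (
    PowerSpec,
    fixed_effect_meta,
    genomic_lambda,
    ld_clump,
    manhattan_table,
    meta_analyze,
    power_monte_carlo,
    power_quantitative,
    qq_table,
    se_from_ci,
)

#: Published phase-level effects (beta, 95% CI low, high) per phase for the
#: three lead SNPs of the reference study, used as numeric inputs.
PHASE_EFFECTS = {
    "rs2069661": ((13.71, 7.81, 19.6), (14.32, 3.28, 25.4)),
    "rs77080086": ((12.17, 7.43, 16.91), (6.43, -3.32, 16.2)),
    "rs11572377": ((12.26, 6.32, 18.2), (15.14, 5.08, 25.19)),
}


class TestSeFromCi:
    def test_hand_computed_values(self):
        assert se_from_ci(7.81, 19.6) == pytest.approx(3.008, abs=5e-4)
        assert se_from_ci(-3.32, 16.2) == pytest.approx(4.980, abs=5e-4)

    def test_unit_half_width(self):
        assert se_from_ci(-1.959964, 1.959964) == pytest.approx(1.0, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="upper"):
            se_from_ci(2.0, 1.0)
        with pytest.raises(ValueError, match="level"):
            se_from_ci(0.0, 1.0, level=1.5)


class TestFixedEffectMeta:
    def test_reconstructs_published_meta_betas(self):
        expected = {"rs2069661": 13.85, "rs77080086": 11.07, "rs11572377": 13.00}
        for vid, phases in PHASE_EFFECTS.items():
            studies = [(b, se_from_ci(lo, hi)) for b, lo, hi in phases]
            m = fixed_effect_meta(studies, vid)
            assert m.beta_meta == pytest.approx(expected[vid], abs=0.01)

    def test_identical_studies_halve_variance(self):
        m = fixed_effect_meta([(2.0, 0.5), (2.0, 0.5)])
        assert m.beta_meta == pytest.approx(2.0)
        assert m.se_meta == pytest.approx(0.5 / np.sqrt(2))

    def test_matches_precision_weighted_mean_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            studies = [(rng.normal(), rng.uniform(0.1, 2.0)) for _ in range(3)]
            m = fixed_effect_meta(studies)
            w = np.array([1 / s[1] ** 2 for s in studies])
            b = np.array([s[0] for s in studies])
            assert m.beta_meta == pytest.approx(float((w * b).sum() / w.sum()), abs=1e-12)
            assert m.se_meta == pytest.approx(float(1 / np.sqrt(w.sum())), abs=1e-12)

    def test_invariants(self):
        studies = [(1.0, 0.5), (3.0, 0.2), (2.0, 1.0)]
        m = fixed_effect_meta(studies)
        assert min(s[0] for s in studies) <= m.beta_meta <= max(s[0] for s in studies)
        assert m.se_meta <= min(s[1] for s in studies)
        assert m.ci95 == pytest.approx(
            (m.beta_meta - 1.959964 * m.se_meta, m.beta_meta + 1.959964 * m.se_meta)
        )
        # order invariance
        m2 = fixed_effect_meta(studies[::-1])
        assert m2.beta_meta == pytest.approx(m.beta_meta, abs=1e-12)

    def test_single_study_passthrough(self):
        m = fixed_effect_meta([(1.5, 0.3)])
        assert m.beta_meta == pytest.approx(1.5, abs=1e-12)
        assert m.se_meta == pytest.approx(0.3, abs=1e-12)
        assert m.q_p == 1.0

    def test_direction_string(self):
        m = fixed_effect_meta([(1.0, 0.5), (-0.2, 0.5)])
        assert m.direction == "+-"

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="SE"):
            fixed_effect_meta([(1.0, 0.0)])

    def test_meta_analyze_tables(self):
        t1 = pd.DataFrame(
            {"id": ["a", "b"], "chrom": ["1", "1"], "pos": [100, 200],
             "effect_allele": ["G", "G"], "beta": [1.0, 2.0], "se": [0.5, 0.5],
             "p": [0.05, 0.01], "status": ["ok", "ok"]}
        )
        t2 = t1.copy()
        t2["beta"] = [1.4, np.nan]
        t2.loc[1, "status"] = "monomorphic"
        out = meta_analyze({"I": t1, "II": t2})
        assert list(out["id"]) == ["a"]  # only variants ok in every phase
        assert out.loc[0, "k_studies"] == 2


class TestGenomicLambda:
    def test_definitional_value(self):
        assert genomic_lambda([0.5] * 10) == pytest.approx(1.0, rel=1e-6)

    def test_null_uniform_near_one(self):
        rng = np.random.default_rng(1)
        lam = genomic_lambda(rng.uniform(size=100_000))
        assert 0.98 < lam < 1.02

    def test_inflated_chi2_detected(self):
        rng = np.random.default_rng(2)
        chi2 = 1.4 * rng.chisquare(1, size=50_000)
        p = stats.chi2.sf(chi2, 1)
        assert genomic_lambda(p) == pytest.approx(1.4, rel=0.03)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            genomic_lambda([0.0, 0.5])


class TestClumping:
    @staticmethod
    def _results(ids, chrom, pos, p):
        return pd.DataFrame({"id": ids, "chrom": chrom, "pos": pos, "p": p})

    def test_independent_variants_all_lead(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.3, size=(200, 4)).astype(float)
        gm = make_matrix(dos, pos=[1000, 2000, 3000, 4000])
        res = self._results(
            [f"v{i}" for i in range(4)], ["1"] * 4, [1000, 2000, 3000, 4000],
            [1e-8, 1e-7, 1e-6, 0.5],
        )
        out = ld_clump(res, gm)
        assert list(out["lead"]) == ["v0", "v1", "v2"]
        assert (out["n_members"] == 0).all()

    def test_correlated_pair_absorbed(self):
        rng = np.random.default_rng(4)
        g1 = rng.binomial(2, 0.4, 500).astype(float)
        noise = rng.binomial(1, 0.05, 500)
        g2 = np.clip(g1 + noise - rng.binomial(1, 0.05, 500), 0, 2)  # r2 ~ 0.8
        g3 = rng.binomial(2, 0.4, 500).astype(float)
        gm = make_matrix(np.column_stack([g1, g2, g3]), pos=[1000, 2000, 3000])
        res = self._results(["v0", "v1", "v2"], ["1"] * 3, [1000, 2000, 3000],
                            [1e-9, 1e-8, 1e-7])
        out = ld_clump(res, gm)
        assert list(out["lead"]) == ["v0", "v2"]
        assert out.loc[0, "members"] == "v1"

    def test_matches_greedy_brute_force(self):
        rng = np.random.default_rng(5)
        n, m = 300, 12
        base = rng.binomial(2, 0.3, size=(n, m // 2)).astype(float)
        # pair each variant with a noisy copy
        dos = np.empty((n, m))
        dos[:, 0::2] = base
        flip = rng.binomial(1, 0.08, size=base.shape)
        dos[:, 1::2] = np.clip(base + flip - rng.binomial(1, 0.08, size=base.shape), 0, 2)
        pos = np.arange(1, m + 1) * 10_000
        gm = make_matrix(dos, pos=pos)
        p = rng.uniform(1e-10, 1e-6, m)
        res = self._results([f"v{i}" for i in range(m)], ["1"] * m, pos, p)
        out = ld_clump(res, gm, p_index=1e-5, r2_threshold=0.1, window=500_000)

        # brute-force greedy oracle
        r2 = np.corrcoef(dos.T) ** 2
        remaining = set(range(m))
        expected = []
        for j in np.argsort(p):
            if j not in remaining:
                continue
            expected.append(f"v{j}")
            remaining.discard(j)
            for k in list(remaining):
                if abs(pos[k] - pos[j]) <= 500_000 and r2[j, k] >= 0.1:
                    remaining.discard(k)
        assert list(out["lead"]) == expected

    def test_window_limits_absorption(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, 0.4, 500).astype(float)
        gm = make_matrix(np.column_stack([g, g]), pos=[1000, 800_000])
        res = self._results(["v0", "v1"], ["1", "1"], [1000, 800_000], [1e-9, 1e-8])
        out = ld_clump(res, gm)
        assert list(out["lead"]) == ["v0", "v1"]  # identical but out of window

    def test_missing_variant_raises(self):
        gm = make_matrix(np.zeros((10, 1)) + 1.0)
        res = self._results(["zzz"], ["1"], [500], [1e-9])
        with pytest.raises(KeyError, match="absent"):
            ld_clump(res, gm)

    def test_one_lead_per_causal_block(self, small_cohort):
        from pressorgwas.assoc import gwas_linear, results_table

        cfg, cohort = small_cohort
        gm = cohort.genotypes["I"]
        pheno = cohort.patients.set_index("patient_id").loc[gm.samples["id"]]
        res = results_table(
            gwas_linear(gm, pheno["target_rate"].to_numpy()), gm
        )
        out = ld_clump(res, gm, p_index=1e-5)
        causal = set(cohort.truth.causal_betas)
        # each causal block yields exactly one lead; the lead sits in the
        # causal variant's block or is the causal variant itself
        assert len(out) >= len(causal) - 1  # weak signal can miss at small n


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        spec = PowerSpec(n=1000, maf=0.2, beta=0.0, sigma=10.0, alpha=0.05)
        assert power_quantitative(spec) == pytest.approx(0.05, rel=1e-6)

    def test_reference_design_exceeds_80_percent(self):
        spec = PowerSpec(n=1534, maf=0.017, beta=13.0, sigma=19.7, alpha=1e-4)
        assert power_quantitative(spec) > 0.80

    def test_monotonicity(self):
        base = dict(n=800, maf=0.1, beta=5.0, sigma=19.7, alpha=1e-4)
        p0 = power_quantitative(PowerSpec(**base))
        assert power_quantitative(PowerSpec(**{**base, "n": 1600})) > p0
        assert power_quantitative(PowerSpec(**{**base, "beta": 8.0})) > p0
        assert power_quantitative(PowerSpec(**{**base, "maf": 0.3})) > p0
        assert power_quantitative(PowerSpec(**{**base, "sigma": 30.0})) < p0

    def test_monte_carlo_agrees_with_analytic(self):
        spec = PowerSpec(n=400, maf=0.1, beta=5.0, sigma=19.7, alpha=1e-3)
        analytic = power_quantitative(spec)
        mc, se = power_monte_carlo(spec, n_replicates=1500, seed=7)
        assert abs(mc - analytic) <= 2 * se + 1e-9

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(n=100, maf=0.0, beta=1.0, sigma=1.0, alpha=0.05)
        with pytest.raises(ValueError):
            PowerSpec(n=100, maf=0.2, beta=1.0, sigma=1.0, alpha=1.5)


class TestPlottingTables:
    def test_qq_single_point(self):
        out = qq_table([0.5])
        assert out.loc[0, "expected"] == pytest.approx(-np.log10(0.5))
        assert out.loc[0, "observed"] == pytest.approx(0.3010, abs=5e-4)

    def test_qq_monotone_and_null_hugs_diagonal(self):
        rng = np.random.default_rng(8)
        out = qq_table(rng.uniform(size=10_000))
        assert (np.diff(out["observed"]) <= 1e-12).all() or (
            np.diff(out["observed"]) >= -1e-12
        ).all()
        body = out.iloc[:-10]  # all but the extreme tail
        assert (body["observed"] - body["expected"]).abs().max() < 0.5

    def test_manhattan_cumulative_coordinate(self):
        res = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "chrom": ["1", "2", "1"],
                "pos": [100, 50, 200],
                "p": [0.1, 0.01, 0.5],
            }
        )
        out = manhattan_table(res)
        assert list(out["id"]) == ["a", "c", "b"]
        assert out["genome_pos"].is_monotonic_increasing
        assert out.loc[out["id"] == "b", "neg_log10_p"].iloc[0] == pytest.approx(2.0)
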