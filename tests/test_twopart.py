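"""Two-part model: features, per-part regressions, meta, permutation, FDR."""

import numpy as np
import pytest
from scipy import stats

from micropheno import syndata, tables, twopart
from micropheno.tables import AbundanceTable, PhenotypeFrame
from micropheno.twopart import (
    bh_adjust,
    binary_assoc,
    make_features,
    meta_combine,
    quant_assoc,
    two_part_scan,
)


def _abund(fracs):
    f = np.asarray(fracs, float)
    return AbundanceTable(
        [f"s{i}" for i in range(f.shape[0])],
        [f"t{j}" for j in range(f.shape[1])],
        f,
    )


class TestFeatures:
    def test_presence_and_centering(self):
        ab = _abund(np.array([[0.1, 0.9], [0.2, 0.8], [0.0, 1.0]]))
        ft = make_features(ab, "t0")
        np.testing.assert_array_equal(ft.b, [1, 1, 0])
        assert ft.q[2] == 0.0
        assert abs(ft.q[ft.b > 0].mean()) < 1e-12

    def test_all_present_taxon(self):
        ab = _abund(np.array([[0.5, 0.5], [0.4, 0.6], [0.7, 0.3]]))
        ft = make_features(ab, "t0")
        assert ft.b.all() and ft.n_present == 3

    def test_log_standardization_population_sd(self):
        # log(0.01), log(0.04), log(0.16) are arithmetically spaced, so the
        # standardized values are symmetric: +-sqrt(3/2) = +-1.2247
        ab = _abund(
            np.array(
                [[0.01, 0.99], [0.04, 0.96], [0.16, 0.84], [0.0, 1.0]]
            )
        )
        ft = make_features(ab, "t0")
        np.testing.assert_allclose(
            ft.q, [-np.sqrt(1.5), 0.0, np.sqrt(1.5), 0.0], atol=1e-12
        )

    def test_absent_everywhere_degenerate(self):
        ab = _abund(np.array([[0.0, 1.0], [0.0, 1.0]]))
        ft = make_features(ab, "t0")
        assert ft.degenerate and ft.log_sd == 0.0


class TestBinaryAssoc:
    def test_constant_presence_undefined(self):
        ab = _abund(np.array([[0.5, 0.5], [0.4, 0.6], [0.7, 0.3]]))
        ft = make_features(ab, "t0")
        b1, p = binary_assoc(ft, np.array([1.0, 2.0, 3.0]))
        assert np.isnan(b1) and np.isnan(p)

    def test_matches_regression_oracle(self):
        rng = np.random.default_rng(0)
        b = np.array([0, 0, 0, 1, 1, 1], float)
        y = np.array([-1, -1, -1, 1, 1, 1], float) + 1e-6 * rng.standard_normal(6)
        ft = twopart.TwoPartFeatures("t", b, np.zeros(6), 3, 0.0, 0.0)
        beta1, p = binary_assoc(ft, y)
        lr = stats.linregress(b, y)
        assert abs(beta1 - 2.0) < 1e-5
        np.testing.assert_allclose(beta1, lr.slope, atol=1e-10)
        np.testing.assert_allclose(p, lr.pvalue, atol=1e-10)

    def test_null_pvalues_uniform(self):
        # 5000 null replicates at n=100 via the vectorized kernel
        rng = np.random.default_rng(1)
        n = 100
        b = (rng.random(n) < 0.5).astype(float)
        Y = rng.standard_normal((n, 5000))
        s = twopart._scan_stats(b[:, None], np.zeros((n, 1)), Y)
        p = s["p_binary"][0]
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestQuantAssoc:
    def test_constant_q_undefined(self):
        ft = twopart.TwoPartFeatures(
            "t", np.ones(6), np.zeros(6), 6, 0.0, 0.0
        )
        b2, p = quant_assoc(ft, np.arange(6.0))
        assert np.isnan(b2)

    def test_noiseless_limit(self):
        q = np.array([-1.2, -0.4, 0.1, 0.5, 1.0, 0.0])
        b = np.array([1, 1, 1, 1, 1, 0], float)
        y = 3.0 * q
        ft = twopart.TwoPartFeatures("t", b, q, 5, 0.0, 1.0)
        beta2, p = quant_assoc(ft, y)
        assert abs(beta2 - 3.0) < 1e-10
        assert p < 1e-12

    def test_matches_regression_oracle(self):
        rng = np.random.default_rng(2)
        q = rng.standard_normal(6)
        q -= q.mean()
        y = 0.7 * q + rng.standard_normal(6)
        ft = twopart.TwoPartFeatures("t", np.ones(6), q, 6, 0.0, 1.0)
        beta2, p = quant_assoc(ft, y)
        lr = stats.linregress(q, y)
        np.testing.assert_allclose(beta2, lr.slope, atol=1e-10)
        np.testing.assert_allclose(p, lr.pvalue, atol=1e-10)

    def test_too_few_present_undefined(self):
        ft = twopart.TwoPartFeatures(
            "t", np.array([1, 1, 1, 0, 0, 0], float),
            np.array([-1, 0, 1, 0, 0, 0], float), 3, 0.0, 1.0,
        )
        assert np.isnan(quant_assoc(ft, np.arange(6.0))[0])


class TestMetaCombine:
    def test_zero_z_gives_p_one(self):
        assert meta_combine(0.0, 0.0, 100, 50) == pytest.approx(1.0)

    def test_equal_z_equal_n_closed_form(self):
        # Z = 1.96 * sqrt(2) = 2.772, two-sided p ~= 0.00557
        p = meta_combine(1.96, 1.96, 80, 80)
        assert p == pytest.approx(2 * stats.norm.sf(1.96 * np.sqrt(2)), rel=1e-12)
        assert p == pytest.approx(0.00557, abs=5e-5)

    def test_vanishing_weight_recovers_other_component(self):
        z = 1.3
        p = meta_combine(z, 0.4, 1e6, 1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(z), rel=1e-6)

    def test_undefined_when_component_missing(self):
        assert np.isnan(meta_combine(np.nan, 1.0, 10, 10))


class TestBHAdjust:
    def test_closed_form_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_nan_excluded_from_family(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_adjust([0.01, 0.04]))


class TestTwoPartScan:
    def test_negative_B_rejected(self, cohort300):
        _, abund, pheno, _ = cohort300
        with pytest.raises(ValueError):
            two_part_scan(abund, pheno, B=-1)

    def test_requires_residuals(self, cohort300):
        counts, abund, pheno, _ = cohort300
        raw = PhenotypeFrame(pheno.sample_ids, pheno.phenotype, pheno.sex, pheno.cage)
        with pytest.raises(ValueError, match="residualize"):
            two_part_scan(abund, raw, B=10)

    def test_deterministic_under_seed(self, cohort300):
        _, abund, pheno, _ = cohort300
        a = two_part_scan(abund, pheno, B=50, seed=3)
        b = two_part_scan(abund, pheno, B=50, seed=3)
        np.testing.assert_array_equal(a["p_perm"], b["p_perm"])

    def test_affine_phenotype_invariance(self, cohort300):
        _, abund, pheno, _ = cohort300
        res = two_part_scan(abund, pheno, B=100, seed=5)
        shifted = PhenotypeFrame(
            pheno.sample_ids, pheno.phenotype, pheno.sex, pheno.cage,
            residual=3.5 * pheno.residual - 2.0,
        )
        res2 = two_part_scan(abund, shifted, B=100, seed=5)
        np.testing.assert_allclose(res["p_perm"], res2["p_perm"])
        np.testing.assert_allclose(res["p_final"], res2["p_final"], rtol=1e-8)

    def test_strong_taxon_hits_permutation_floor_and_smallest_q(self):
        cfg = syndata.SimulationConfig(
            n_samples=300, n_taxa=50, library_size_mean=10_000,
            n_causal_taxa=1, beta1_effects=np.array([2.5]),
            beta2_effects=np.array([2.5]), noise_sd=1.0,
            sex_effect=0.2, cage_effect_sd=0.1, seed=12,
        )
        t = syndata.gen_count_table(cfg)
        pheno, truth = syndata.gen_phenotype(t, cfg)
        pheno = tables.residualize(pheno)
        res = two_part_scan(tables.to_relative(t), pheno, B=1000, seed=13)
        row = res[res.taxon_id == truth.causal_taxa[0]].iloc[0]
        assert row.p_perm == pytest.approx(1 / 1001)
        assert row.q_value == res.q_value.min()
        assert row.q_value < 0.05

    def test_planted_effects_recovered(self, cohort300):
        _, abund, pheno, truth = cohort300
        res = two_part_scan(abund, pheno, B=1000, seed=1)
        sig = set(res[res.q_value < 0.05].taxon_id)
        assert len(sig & set(truth.causal_taxa)) == len(truth.causal_taxa)

    def test_degenerate_taxon_flagged_and_excluded_from_fdr(self):
        frac = np.array([[0.0, 0.5, 0.5], [0.0, 0.4, 0.6], [0.0, 0.3, 0.7],
                         [0.0, 0.6, 0.4], [0.0, 0.2, 0.8], [0.0, 0.7, 0.3]])
        ab = AbundanceTable([f"s{i}" for i in range(6)], ["dead", "a", "b"], frac)
        ph = PhenotypeFrame(
            ab.sample_ids, np.arange(6.0), np.array(["M"] * 6),
            np.array(["c"] * 6), residual=np.arange(6.0) - 2.5,
        )
        res = two_part_scan(ab, ph, B=20, seed=0)
        dead = res[res.taxon_id == "dead"].iloc[0]
        assert dead.degenerate and np.isnan(dead.q_value)
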