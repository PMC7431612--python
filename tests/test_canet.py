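"""SparCC estimation, permutation significance, CAG clustering, PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micropheno import canet, syndata, tables
from micropheno.canet import (
    build_network,
    cag_phenotype_corr,
    define_cags,
    permanova,
    qvalues_upper_triangle,
    sparcc,
    sparcc_pvalues,
)
from micropheno.tables import AbundanceTable, PhenotypeFrame


def _sim_counts(seed=0, n=500, m=50, pairs=(), prevalence=(1.0, 1.0)):
    cfg = syndata.SimulationConfig(
        n_samples=n, n_taxa=m, library_size_mean=40_000,
        prevalence_range=prevalence, basis_correlation_pairs=list(pairs),
        noise_sd=1.0, seed=seed,
    )
    return syndata.gen_count_table(cfg)


class TestSparcc:
    def test_structure(self):
        t = _sim_counts(seed=1, n=50, m=10)
        rho = sparcc(t, seed=2)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(rho, rho.T)
        assert (np.abs(rho) <= 1.0).all()

    def test_too_few_taxa_rejected(self):
        t = _sim_counts(seed=1, n=50, m=10)
        with pytest.raises(ValueError):
            sparcc(t.counts[:, :2])
        with pytest.raises(ValueError):
            sparcc(t.counts[:3, :])

    def test_deterministic_under_seed(self):
        t = _sim_counts(seed=3, n=100, m=12)
        np.testing.assert_array_equal(sparcc(t, seed=5), sparcc(t, seed=5))

    def test_independent_taxa_near_zero(self):
        t = _sim_counts(seed=2)
        rho = sparcc(t, seed=3)
        iu = np.triu_indices(t.n_taxa, 1)
        assert np.abs(rho[iu]).mean() < 0.1

    def test_planted_pair_recovered_and_largest(self):
        t = _sim_counts(seed=0, pairs=[(3, 17, 0.8)])
        rho = sparcc(t, seed=1)
        assert abs(rho[3, 17] - 0.8) < 0.15
        off = np.abs(rho - np.eye(t.n_taxa))
        assert np.unravel_index(np.argmax(off), off.shape) in [(3, 17), (17, 3)]

    def test_scaling_invariance_plain_closure(self):
        t = _sim_counts(seed=4, n=100, m=20)
        X = t.counts + 1  # strictly positive
        scale = np.random.default_rng(0).integers(2, 7, size=100)[:, None]
        a = sparcc(X, pseudocount="none", seed=6)
        b = sparcc(X * scale, pseudocount="none", seed=6)
        np.testing.assert_array_equal(a, b)

    def test_zero_counts_rejected_for_plain_closure(self):
        t = _sim_counts(seed=5, n=50, m=10, prevalence=(0.5, 0.9))
        with pytest.raises(ValueError, match="positive"):
            sparcc(t, pseudocount="none")


class TestSparccPvalues:
    def test_floor_and_planted_pair(self):
        t = _sim_counts(seed=9, n=500, m=30, pairs=[(2, 9, 0.9)])
        p, rho = sparcc_pvalues(t, n_perm=100, seed=10)
        assert p[2, 9] == pytest.approx(1 / 101)
        assert np.nanmin(p) >= 1 / 101

    def test_independent_taxa_calibrated(self):
        t = _sim_counts(seed=7, n=200, m=30, pairs=[])
        p, _ = sparcc_pvalues(t, n_perm=100, seed=8)
        iu = np.triu_indices(30, 1)
        frac = (p[iu] < 0.05).mean()
        assert abs(frac - 0.05) < 0.02


class TestBuildNetwork:
    def test_threshold_logic(self):
        rho = np.array([[1.0, 0.5], [0.5, 1.0]])
        q_ns = np.array([[np.nan, 0.20], [0.20, np.nan]])
        q_sig = np.array([[np.nan, 0.01], [0.01, np.nan]])
        assert len(build_network(rho, q_ns, ["a", "b"])) == 0
        edges = build_network(rho, q_sig, ["a", "b"])
        assert len(edges) == 1 and edges.iloc[0]["sign"] == "+"

    def test_raising_r_threshold_only_removes_edges(self):
        rng = np.random.default_rng(11)
        m = 12
        rho = np.clip((lambda A: (A + A.T) / 2)(rng.uniform(-1, 1, (m, m))), -1, 1)
        np.fill_diagonal(rho, 1.0)
        q = qvalues_upper_triangle(rng.random((m, m)) * 0.1)
        e35 = build_network(rho, q, [f"t{i}" for i in range(m)], 0.35)
        e45 = build_network(rho, q, [f"t{i}" for i in range(m)], 0.45)
        pairs35 = {tuple(r) for r in e35[["source", "target"]].to_numpy()}
        pairs45 = {tuple(r) for r in e45[["source", "target"]].to_numpy()}
        assert pairs45 <= pairs35


def _block_design(seed=0):
    b1, b2 = list(range(10)), list(range(10, 20))
    pairs = []
    for b in (b1, b2):
        pairs += [(b[i], b[j], 0.7) for i in range(10) for j in range(i + 1, 10)]
    pairs += [(i, j, -0.3) for i in b1 for j in b2]
    t = _sim_counts(seed=seed, n=300, m=30, pairs=pairs)
    return t, b1, b2


class TestDefineCags:
    def test_two_blocks_recovered_at_permutation_floor(self):
        t, b1, b2 = _block_design()
        rho = sparcc(t, seed=1)
        sub = rho[np.ix_(b1 + b2, b1 + b2)]
        labels, F, p, ok = define_cags(sub, k=2, n_perm=999, seed=2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]
        assert p == pytest.approx(1 / 1000)
        assert ok

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            define_cags(np.eye(4), k=4)

    def test_deterministic_given_distance(self):
        t, b1, b2 = _block_design(seed=3)
        rho = sparcc(t, seed=4)
        l1, *_ = define_cags(rho, k=2, n_perm=99, seed=5)
        l2, *_ = define_cags(rho, k=2, n_perm=99, seed=5)
        np.testing.assert_array_equal(l1, l2)


class TestPermanova:
    def _brute_force_p(self, d, labels):
        """Exact p over all distinct label permutations (with +1 both sides
        the estimate differs; enumerate to get the exceedance fraction)."""
        d = np.asarray(d, float)
        f_obs, _ = permanova(d, labels, n_perm=1, seed=0)
        n = len(labels)
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            lab = np.asarray(labels)[list(perm)]
            f, _ = permanova(d, lab, n_perm=1, seed=0)
            total += 1
            hits += f >= f_obs - 1e-12
        return hits / total

    def test_pseudo_f_matches_enumeration_oracle(self):
        d = np.array(
            [
                [0.0, 0.2, 0.9, 0.8],
                [0.2, 0.0, 0.85, 0.95],
                [0.9, 0.85, 0.0, 0.3],
                [0.8, 0.95, 0.3, 0.0],
            ]
        )
        labels = np.array([0, 0, 1, 1])
        exact = self._brute_force_p(d, labels)
        # the clean 2+2 split: only permutations preserving the partition
        # reach the observed F, i.e. 2 * 2! * 2! / 4! = 1/3
        assert exact == pytest.approx(1 / 3)
        _, p = permanova(d, labels, n_perm=999, seed=1)
        assert abs(p - exact) < 0.05

    def test_matches_skbio_oracle(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(13)
        pts = rng.standard_normal((12, 3))
        pts[6:] += 1.5
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = np.array([0] * 6 + [1] * 6)
        f_mine, _ = permanova(d, labels, n_perm=9, seed=0)
        dm = skbio_stats.DistanceMatrix(d, [str(i) for i in range(12)])
        ref = skbio_stats.permanova(dm, [str(g) for g in labels], permutations=99)
        assert f_mine == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(14)
        ps = []
        for rep in range(100):
            pts = rng.standard_normal((10, 2))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = rng.permutation([0] * 5 + [1] * 5)
            _, p = permanova(d, labels, n_perm=99, seed=rep)
            ps.append(p)
        assert abs(np.mean(ps) - 0.5) < 0.1


class TestCagPhenotypeCorr:
    def _setup(self, y):
        frac = np.column_stack([np.linspace(0.2, 0.6, 8), np.linspace(0.8, 0.4, 8)])
        ab = AbundanceTable([f"s{i}" for i in range(8)], ["a", "b"], frac)
        ph = PhenotypeFrame(
            ab.sample_ids, y, np.array(["M"] * 8), np.array(["c"] * 8), residual=y
        )
        return ab, ph

    def test_monotone_gives_unit_rho(self):
        y = np.arange(8.0)
        ab, ph = self._setup(y)
        df = cag_phenotype_corr(np.array([1, 2]), ab, ph)
        assert df[df.cag == 1].rho.iloc[0] == pytest.approx(1.0)
        assert df[df.cag == 2].rho.iloc[0] == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self):
        y = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0])
        ab, ph = self._setup(y)
        df = cag_phenotype_corr(np.array([1, 2]), ab, ph)
        s = ab.fractions[:, 0]
        rx = stats.rankdata(s)
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert df[df.cag == 1].rho.iloc[0] == pytest.approx(oracle, rel=1e-12)
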