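"""Community statistics: rarefaction, diversity, distances, ordination."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from rumenferm.community import (OTUTable, bh_adjust, bray_curtis, cca,
                                 diversity, normalize_to_min, permanova,
                                 upgma)
from rumenferm.exceptions import UndefinedResultError, ValidationError


def table_from(counts, meta=None):
    df = pd.DataFrame(counts)
    df.index = [f"S{i}" for i in range(df.shape[0])]
    df.columns = [f"OTU{j}" for j in range(df.shape[1])]
    return OTUTable(df, meta)


class TestRarefaction:
    def test_already_at_minimum_depths(self):
        t = table_from([[3, 2], [4, 1]])
        out = normalize_to_min(t, seed=0)
        assert (out.depths == 5).all()

    def test_identity_at_full_depth(self):
        t = table_from([[3, 2], [3, 2]])
        out = normalize_to_min(t, seed=0)
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_hypergeometric_expectation(self):
        """Rarefying (8, 2) to depth 5 matches the hypergeometric mean
        (4, 1) over many seeds within its standard error."""
        t = table_from([[8, 2], [4, 1]])
        draws = np.array([normalize_to_min(t, seed=s).counts.iloc[0].tolist()
                          for s in range(1000)])
        # var of first count: n K/N (1-K/N) (N-n)/(N-1)
        var = 5 * 0.8 * 0.2 * (10 - 5) / (10 - 1)
        se = math.sqrt(var / 1000)
        assert draws[:, 0].mean() == pytest.approx(4.0, abs=4 * se)
        assert (draws.sum(axis=1) == 5).all()

    def test_seed_reproducible(self):
        t = table_from([[50, 30, 20], [10, 5, 5]])
        a = normalize_to_min(t, seed=7).counts
        b = normalize_to_min(t, seed=7).counts
        pd.testing.assert_frame_equal(a, b)

    def test_never_creates_counts(self):
        t = table_from([[50, 0, 20], [10, 5, 5]])
        out = normalize_to_min(t, seed=3)
        assert (out.counts.to_numpy() <= t.counts.to_numpy()).all()

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            normalize_to_min(table_from([[0, 0], [1, 1]]), seed=0)


class TestDiversity:
    def test_uniform_maximum_entropy(self):
        t = table_from([[10] * 8])
        d = diversity(t).values.iloc[0]
        assert d["shannon"] == pytest.approx(math.log(8))
        assert d["evenness"] == pytest.approx(1.0)
        assert d["richness"] == 8

    def test_single_otu(self):
        d = diversity(table_from([[50, 0, 0]])).values.iloc[0]
        assert d["shannon"] == 0.0
        assert d["simpson"] == 0.0
        assert d["evenness"] == 0.0

    def test_hand_computed_indices(self):
        d = diversity(table_from([[5, 3, 2]])).values.iloc[0]
        assert d["shannon"] == pytest.approx(1.0297, abs=1e-4)
        assert d["simpson"] == pytest.approx(0.62)

    def test_chao1_equals_richness_without_singletons(self):
        d = diversity(table_from([[5, 3, 2]])).values.iloc[0]
        assert d["chao1"] == d["richness"] == 3

    def test_chao1_and_goods_with_singletons(self):
        # S=5, F1=2, F2=1: chao1 = 5 + 2*1/(2*(1+1)); goods = 1 - 2/12
        d = diversity(table_from([[5, 3, 2, 1, 1]])).values.iloc[0]
        assert d["chao1"] == pytest.approx(5.5)
        assert d["goods_coverage"] == pytest.approx(1 - 2 / 12)
        assert d["richness"] <= d["chao1"]

    @given(arrays(np.int64, 6, elements=st.integers(0, 50))
           .filter(lambda a: a.sum() > 0))
    def test_label_permutation_invariance(self, counts):
        d1 = diversity(table_from([counts])).values.iloc[0]
        d2 = diversity(table_from([counts[::-1]])).values.iloc[0]
        for k in ("shannon", "simpson", "richness", "chao1"):
            assert d1[k] == pytest.approx(d2[k])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(table_from([[5, 3, 2], [5, 3, 2]]))
        assert d.data[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_one(self):
        d = bray_curtis(table_from([[5, 0], [0, 7]]))
        assert d.data[0, 1] == pytest.approx(1.0)

    def test_hand_computed_untransformed(self):
        d = bray_curtis(table_from([[1, 1, 0], [0, 1, 1]]), transform="none")
        assert d.data[0, 1] == pytest.approx(0.5)

    def test_all_zero_pair_undefined(self):
        with pytest.raises((UndefinedResultError, ValidationError)):
            bray_curtis(table_from([[0, 0], [1, 1]]))

    @given(arrays(np.int64, (4, 5), elements=st.integers(0, 30))
           .filter(lambda a: (a.sum(axis=1) > 0).all()))
    def test_metric_properties(self, counts):
        d = bray_curtis(table_from(counts)).data
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()


def _upgma_oracle(dist: np.ndarray, ids):
    """Brute-force average linkage: cophenetic matrix of merge heights."""
    clusters = {i: frozenset([i]) for i in range(len(ids))}
    coph = np.zeros_like(dist)
    active = list(clusters)
    nxt = len(ids)
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            pairs = [(i, j) for i in clusters[a] for j in clusters[b]]
            h = np.mean([dist[i, j] for i, j in pairs])
            if best is None or h < best[0] - 1e-12:
                best = (h, a, b)
        h, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        clusters[nxt] = clusters[a] | clusters[b]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return coph


class TestUPGMA:
    def test_two_samples_join_at_distance(self):
        d = DistanceMatrix([[0, 0.4], [0.4, 0]], ids=["A", "B"])
        tree = TreeNode.read([upgma(d)])
        assert tree.tip_tip_distances().data[0, 1] == pytest.approx(0.4)

    def test_three_sample_topology(self):
        d = DistanceMatrix([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]],
                           ids=["A", "B", "C"])
        tree = TreeNode.read([upgma(d)])
        lca = tree.lca([tree.find("A"), tree.find("B")])
        assert {t.name for t in lca.tips()} == {"A", "B"}

    def test_four_sample_merge_heights_match_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.random((4, 4))
        sym = (x + x.T) / 2
        np.fill_diagonal(sym, 0.0)
        ids = ["A", "B", "C", "D"]
        d = DistanceMatrix(sym, ids=ids)
        tree = TreeNode.read([upgma(d)])
        tip_dist = tree.tip_tip_distances(endpoints=ids)
        coph = _upgma_oracle(sym, ids)
        for i, j in itertools.combinations(range(4), 2):
            assert tip_dist[ids[i], ids[j]] == pytest.approx(coph[i, j])


def _oneway_f_oracle(d: np.ndarray, labels) -> float:
    """Classical one-way pseudo-F from group sums of squared distances."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = np.unique(labels)
    ss_total = (d ** 2).sum() / (2 * n)
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub ** 2).sum() / (2 * idx.size)
    ss_between = ss_total - ss_within
    a = groups.size
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    @pytest.fixture
    def toy(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(1.5, 1, (3, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"S{i}" for i in range(6)]
        meta = pd.DataFrame({"grp": ["a"] * 3 + ["b"] * 3}, index=ids)
        return DistanceMatrix(d, ids=ids), meta

    def test_pseudo_f_matches_classical_formula(self, toy):
        dm, meta = toy
        res = permanova(dm, meta, ["grp"], n_perm=9, seed=0)
        f_oracle = _oneway_f_oracle(dm.data, meta["grp"].to_numpy())
        assert res.table.loc["grp", "pseudo_f"] == pytest.approx(f_oracle)

    def test_pseudo_f_matches_skbio(self, toy):
        dm, meta = toy
        res = permanova(dm, meta, ["grp"], n_perm=9, seed=0)
        sk = skbio_permanova(dm, meta["grp"].to_numpy(), permutations=9)
        assert res.table.loc["grp", "pseudo_f"] == pytest.approx(
            sk["test statistic"])

    def test_exhaustive_p_equals_enumeration_oracle(self, toy):
        """Exhaustive permutation p equals brute-force enumeration of all
        6! relabellings with the classical one-way statistic."""
        dm, meta = toy
        res = permanova(dm, meta, ["grp"], exhaustive=True)
        labels = meta["grp"].to_numpy()
        f_obs = _oneway_f_oracle(dm.data, labels)
        count = sum(
            _oneway_f_oracle(dm.data, labels[list(p)]) >= f_obs - 1e-12
            for p in itertools.permutations(range(6)))
        assert res.table.loc["grp", "p_value"] == pytest.approx(
            count / math.factorial(6))

    def test_separated_clusters_hit_p_floor(self):
        pts = np.vstack([np.zeros((4, 2)), np.full((4, 2), 50.0)])
        pts += np.random.default_rng(0).normal(0, 0.1, pts.shape)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"S{i}" for i in range(8)]
        meta = pd.DataFrame({"grp": ["a"] * 4 + ["b"] * 4}, index=ids)
        res = permanova(DistanceMatrix(d, ids=ids), meta, ["grp"],
                        n_perm=199, seed=1)
        # only permutations preserving the split reach F_obs
        assert res.table.loc["grp", "p_value"] <= 0.05

    def test_single_level_term_rejected(self, toy):
        dm, meta = toy
        meta = meta.assign(const="x")
        with pytest.raises(ValidationError):
            permanova(dm, meta, ["const"], n_perm=9)

    def test_two_factor_marginal_terms(self, small_otu_table):
        dm = bray_curtis(small_otu_table)
        res = permanova(dm, small_otu_table.metadata,
                        ["forage", "vitamin_e"], n_perm=99, seed=0)
        assert set(res.table.index) == {"forage", "vitamin_e"}
        # strong engineered forage split, vitamin E is pure noise
        assert res.table.loc["forage", "pseudo_f"] \
            > res.table.loc["vitamin_e", "pseudo_f"]
        assert res.table.loc["forage", "p_value"] <= 0.05
        assert (res.table["p_value"] >= 1 / 100).all()

    def test_power_increases_with_effect_size(self):
        """Rejection rate rises along a 3-point fold-change grid."""
        from rumenferm.simulate import OTUConfig, simulate_otu_table
        rates = []
        for fold in (1.0, 2.0, 8.0):
            cfg = OTUConfig(n_samples=16, n_otus=100, effect_otus=10,
                            fold_change=fold, depth_range=(2000, 4000))
            rejections = 0
            for rep in range(60):
                t = simulate_otu_table(cfg, seed=1000 + rep)
                res = permanova(bray_curtis(t), t.metadata, ["forage"],
                                n_perm=99, seed=rep)
                rejections += res.table.loc["forage", "p_value"] <= 0.05
            rates.append(rejections / 60)
        assert rates[0] < 0.25          # near-nominal at null
        assert rates[2] > 0.9           # near-certain at the top
        assert rates[0] <= rates[1] <= rates[2]


class TestCCA:
    def _structured(self, seed=0, n=12, k=8):
        rng = np.random.default_rng(seed)
        grad = np.linspace(-1, 1, n)
        optima = np.linspace(-1, 1, k)
        lam = 50 * np.exp(-((grad[:, None] - optima[None]) ** 2) / 0.5)
        counts = rng.poisson(lam)
        counts[counts.sum(axis=1) == 0, 0] = 1
        t = table_from(counts)
        env = pd.DataFrame({"grad": grad}, index=t.sample_ids)
        return t, env

    def test_total_inertia_is_chi_square_inertia(self):
        """Total inertia equals the scaled chi-square statistic of the
        table — the inertia of unconstrained correspondence analysis."""
        t, env = self._structured()
        res = cca(t, env, n_perm=0)
        y = t.counts.to_numpy(float)
        p = y / y.sum()
        r, c = p.sum(axis=1), p.sum(axis=0)
        expected = np.outer(r, c)
        chi2_inertia = ((p - expected) ** 2 / expected).sum()
        assert res.total_inertia == pytest.approx(chi2_inertia)
        assert res.constrained_inertia <= res.total_inertia + 1e-12

    def test_eigenvalues_match_skbio(self):
        from skbio.stats.ordination import cca as skbio_cca
        t, env = self._structured(seed=3)
        res = cca(t, env, n_perm=0)
        sk = skbio_cca(t.counts.astype(float), env.astype(float))
        sk_constrained = [v for name, v in sk.eigvals.items()
                          if name.startswith("CCA")]
        assert res.eigenvalues[0] == pytest.approx(sk_constrained[0],
                                                   rel=1e-6)

    def test_eigenvalues_non_increasing(self):
        t, env = self._structured(seed=1)
        env["noise"] = np.random.default_rng(9).normal(size=len(env))
        res = cca(t, env, n_perm=0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert (res.eigenvalues >= -1e-12).all()

    def test_gradient_variable_significant(self):
        t, env = self._structured()
        res = cca(t, env, n_perm=99, seed=0)
        assert res.pvalues["grad"] == pytest.approx(1 / 100)

    def test_orthogonal_env_not_significant(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(20, (12, 8))
        t = table_from(counts)
        env = pd.DataFrame({"junk": rng.normal(size=12)}, index=t.sample_ids)
        res = cca(t, env, n_perm=199, seed=5)
        assert res.constrained_inertia < 0.25 * res.total_inertia
        assert res.pvalues["junk"] > 0.05

    def test_binary_separator_splits_axis_one(self):
        counts = np.vstack([
            np.tile([40, 30, 20, 1, 1, 1], (5, 1)),
            np.tile([1, 1, 1, 20, 30, 40], (5, 1)),
        ])
        t = table_from(counts)
        env = pd.DataFrame({"grp": [0] * 5 + [1] * 5}, index=t.sample_ids)
        res = cca(t, env, n_perm=0)
        axis1 = res.site_scores["CCA1"].to_numpy()
        assert max(axis1[:5]) < min(axis1[5:]) or \
            min(axis1[:5]) > max(axis1[5:])

    def test_constant_variable_rejected(self):
        t, env = self._structured()
        env["flat"] = 1.0
        with pytest.raises(ValidationError):
            cca(t, env, n_perm=0)

    def test_rank_deficient_flagged(self):
        t, env = self._structured()
        env["twice"] = 2 * env["grad"]
        res = cca(t, env, n_perm=0)
        assert res.rank_deficient


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=20))
    def test_adjusted_dominate_raw_in_order(self, ps):
        adj = bh_adjust(ps)
        assert (adj <= 1 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()
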