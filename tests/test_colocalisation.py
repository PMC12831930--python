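"""mcd, set screening, the binomial meta-test, overrepresentation, Moran's I."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import genespace as gs
from tests.conftest import embedding_from_coords


def brute_force_mcd(coords, member_idx):
    """Independent mcd: full all-pairs distance matrix, python loops."""
    members = set(int(i) for i in member_idx)
    dists = []
    for i in range(len(coords)):
        if i in members:
            continue
        dists.append(min(np.hypot(*(coords[i] - coords[j])) for j in members))
    return float(np.median(dists))


def brute_force_morans(values, coords, k):
    """Independent Moran's I from first principles on a kNN weight graph."""
    n = len(values)
    d = np.array([[np.hypot(*(coords[i] - coords[j])) for j in range(n)]
                  for i in range(n)])
    np.fill_diagonal(d, np.inf)
    adj = np.zeros((n, n))
    for i in range(n):
        for j in np.argsort(d[i], kind="stable")[:k]:
            adj[i, j] = 1
    sym = ((adj + adj.T) > 0).astype(float)
    w = sym / sym.sum(axis=1, keepdims=True)
    xc = values - values.mean()
    num = sum(w[i, j] * xc[i] * xc[j] for i in range(n) for j in range(n))
    return (n / w.sum()) * num / (xc @ xc)


class TestMcd:
    def test_hand_geometry(self):
        emb = embedding_from_coords([[0, 0], [3, 4], [0, 1]], k=1)
        assert gs.median_complement_distance(emb, {"g0"}) == pytest.approx(3.0)

    def test_coincident_points_give_zero(self):
        emb = embedding_from_coords([[1, 1], [1, 1]], k=1)
        assert gs.median_complement_distance(emb, {"g0"}) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        coords = rng.normal(size=(n, 2))
        emb = embedding_from_coords(coords, k=2)
        m = int(rng.integers(1, n - 1))
        member_idx = rng.choice(n, size=m, replace=False)
        gene_set = {emb.gene_ids[i] for i in member_idx}
        assert gs.median_complement_distance(emb, gene_set) == pytest.approx(
            brute_force_mcd(coords, member_idx), abs=1e-10
        )

    def test_empty_intersection_rejected(self, uniform_embedding):
        with pytest.raises(ValueError):
            gs.median_complement_distance(uniform_embedding, {"nope"})

    def test_full_cover_rejected(self, uniform_embedding):
        with pytest.raises(ValueError):
            gs.median_complement_distance(
                uniform_embedding, set(uniform_embedding.gene_ids)
            )


class TestMcdPermutationTest:
    def test_boundary_set_all_but_one(self):
        emb = embedding_from_coords(
            np.random.default_rng(0).normal(size=(10, 2)), k=2
        )
        res = gs.mcd_permutation_test(emb, set(emb.gene_ids[:-1]), n_perm=99,
                                      seed=0)
        assert 0 < res.p_value <= 1

    def test_planted_tight_cluster_is_significant(self):
        rng = np.random.default_rng(1)
        field = rng.normal(0, 5, size=(1000, 2))
        blob = rng.normal(0, 0.1, size=(50, 2)) + [12, 12]
        emb = embedding_from_coords(np.vstack([field, blob]))
        blob_set = set(emb.gene_ids[1000:])
        res = gs.mcd_permutation_test(emb, blob_set, n_perm=999, seed=1)
        assert res.p_value <= 0.01

    def test_member_variant_calibrated_under_random_sets(self, uniform_embedding):
        genes = np.asarray(uniform_embedding.gene_ids, dtype=object)
        rng = np.random.default_rng(0)
        p_values = []
        for rep in range(200):
            chosen = set(rng.choice(genes, size=20, replace=False))
            res = gs.mcd_permutation_test(uniform_embedding, chosen,
                                          n_perm=199, seed=rep, variant="member")
            p_values.append(res.p_value)
        assert res.tail == "less"
        frac = np.mean(np.asarray(p_values) <= 0.05)
        assert 0.02 <= frac <= 0.10

    def test_calibrated_under_random_sets(self, uniform_embedding):
        genes = np.asarray(uniform_embedding.gene_ids, dtype=object)
        rng = np.random.default_rng(0)
        p_values = []
        for rep in range(200):
            chosen = set(rng.choice(genes, size=20, replace=False))
            res = gs.mcd_permutation_test(uniform_embedding, chosen,
                                          n_perm=199, seed=rep)
            p_values.append(res.p_value)
        frac = np.mean(np.asarray(p_values) <= 0.05)
        assert 0.02 <= frac <= 0.10


class TestScreenGeneSets:
    def test_small_sets_skipped_with_reason(self, uniform_embedding):
        coll = {"big": set(uniform_embedding.gene_ids[:30]),
                "small": set(uniform_embedding.gene_ids[:3])}
        table = gs.screen_gene_sets(uniform_embedding, coll, n_perm=49, seed=0)
        assert len(table) == 2
        assert table.set_index("set").loc["small", "skip_reason"] != ""
        assert np.isfinite(table.set_index("set").loc["big", "p_value"])

    def test_same_seed_reproduces_table(self, uniform_embedding):
        coll = {"a": set(uniform_embedding.gene_ids[:20]),
                "b": set(uniform_embedding.gene_ids[50:80])}
        t1 = gs.screen_gene_sets(uniform_embedding, coll, n_perm=49, seed=5)
        t2 = gs.screen_gene_sets(uniform_embedding, coll, n_perm=49, seed=5)
        assert t1.equals(t2)

    def test_planted_blob_has_smallest_p(self):
        rng = np.random.default_rng(1)
        field = rng.normal(0, 5, size=(400, 2))
        blob = rng.normal(0, 0.1, size=(40, 2)) + [12, 12]
        emb = embedding_from_coords(np.vstack([field, blob]))
        coll = {"blob": set(emb.gene_ids[400:])}
        for i in range(4):
            coll[f"rand{i}"] = set(
                np.asarray(emb.gene_ids, dtype=object)[
                    rng.choice(len(emb.gene_ids), 40, replace=False)]
            )
        table = gs.screen_gene_sets(emb, coll, n_perm=199, seed=0)
        assert table.set_index("set")["p_value"].idxmin() == "blob"


class TestBinomialMetaTest:
    def test_hallmark_screen_example(self):
        assert gs.binomial_meta_test(32, 50, 0.05) <= 2.2e-16

    def test_zero_significant_is_certain(self):
        assert gs.binomial_meta_test(0, 50, 0.05) == 1.0

    def test_enumerable_case(self):
        # X ~ Bin(3, 1/2): P(X >= 2) = 4/8
        assert gs.binomial_meta_test(2, 3, 0.5) == pytest.approx(0.5)

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            gs.binomial_meta_test(1, 2, 1.5)


class TestOverrepresentation:
    def test_full_overlap_of_everything_is_certain(self):
        genes = {"a", "b", "c"}
        assert gs.overrepresentation_test(genes, genes, genes) == pytest.approx(1.0)

    def test_enumerable_hypergeometric_case(self):
        universe = [f"g{i}" for i in range(10)]
        gene_set = set(universe[:5])
        cluster = set(universe[:2])  # overlap 2 of 2
        assert gs.overrepresentation_test(cluster, gene_set, universe) == (
            pytest.approx(10 / 45)
        )

    def test_zero_overlap_with_positive_expectation_is_large(self):
        universe = [f"g{i}" for i in range(20)]
        assert gs.overrepresentation_test(
            set(universe[:5]), set(universe[10:]), universe
        ) >= 0.5

    def test_table_includes_bh_correction(self, planted):
        _, _, truth, space = planted
        coll = gs.truth_gene_sets(truth)
        table = gs.overrepresentation_table(space.clustering, coll)
        assert {"p_value", "q_value"} <= set(table.columns)
        assert np.all(table["q_value"] + 1e-15 >= table["p_value"])
        # each planted programme is overrepresented in some cluster
        sig = table[table["q_value"] <= 0.01]
        assert set(coll) <= set(sig["set"])


class TestMoransI:
    def test_gradient_on_a_line_is_strongly_positive(self):
        coords = np.column_stack([np.arange(100.0), np.zeros(100)])
        emb = embedding_from_coords(coords, k=2)
        values = coords[:, 0]
        observed = gs.morans_i(emb, values)
        assert observed > 0.5
        assert observed == pytest.approx(
            brute_force_morans(values, coords, k=2), abs=1e-10
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        coords = rng.normal(size=(n, 2))
        values = rng.normal(size=n)
        emb = embedding_from_coords(coords, k=4)
        assert gs.morans_i(emb, values) == pytest.approx(
            brute_force_morans(values, coords, k=4), abs=1e-10
        )

    def test_null_mean_is_minus_one_over_n_minus_one(self, uniform_embedding):
        rng = np.random.default_rng(0)
        n = uniform_embedding.n_genes
        values = rng.normal(size=n)
        draws = [gs.morans_i(uniform_embedding, rng.permutation(values))
                 for _ in range(1000)]
        expected = -1 / (n - 1)
        assert np.mean(draws) == pytest.approx(expected, abs=3 * np.std(draws) / np.sqrt(1000))

    def test_two_nodes_perfect_anticorrelation(self):
        emb = embedding_from_coords([[0, 0], [1, 0]], k=1)
        assert gs.morans_i(emb, np.array([-1.0, 1.0])) == pytest.approx(-1.0)

    def test_affine_invariance(self, uniform_embedding):
        rng = np.random.default_rng(4)
        values = rng.normal(size=uniform_embedding.n_genes)
        base = gs.morans_i(uniform_embedding, values)
        assert gs.morans_i(uniform_embedding, 3.7 * values - 11.0) == (
            pytest.approx(base, abs=1e-10)
        )

    def test_constant_values_rejected(self, uniform_embedding):
        with pytest.raises(gs.UndefinedStatisticError):
            gs.morans_i(uniform_embedding, np.ones(uniform_embedding.n_genes))


class TestMoransPermutationTest:
    def test_p_floor_at_999_permutations(self):
        coords = np.column_stack([np.arange(60.0), np.zeros(60)])
        emb = embedding_from_coords(coords, k=2)
        res = gs.morans_i_permutation_test(emb, coords[:, 0], n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_calibrated_under_iid_values(self, uniform_embedding):
        rng = np.random.default_rng(0)
        p_values = []
        for rep in range(200):
            values = rng.normal(size=uniform_embedding.n_genes)
            res = gs.morans_i_permutation_test(uniform_embedding, values,
                                               n_perm=199, seed=rep)
            p_values.append(res.p_value)
        frac = np.mean(np.asarray(p_values) <= 0.05)
        assert 0.02 <= frac <= 0.10


class TestPermutationPConvention:
    def test_p_never_zero_and_floor_attained(self):
        null = np.arange(999, dtype=float)
        assert gs.perm_p_value(10_000.0, null, "greater") == 1 / 1000
        assert gs.perm_p_value(-10_000.0, null, "less") == 1 / 1000
        assert gs.perm_p_value(-10_000.0, null, "greater") == 1.0
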