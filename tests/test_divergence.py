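import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency

import songculture as sc
from songculture.divergence import (
    MRPPResult,
    group_median_matrix,
    mrpp,
    nj_dendrogram,
    spatial_median,
    tree_to_newick,
    type_frequency_test,
)


class TestMRPP:
    def test_effect_size_identity(self):
        # a reported element-level summary: delta 0.2841, m_delta 0.2887
        res = MRPPResult(delta=0.2841, m_delta=0.2887,
                         A=1 - 0.2841 / 0.2887, p=0.001, n_perm=10000)
        assert round(res.A, 4) == 0.0159

    def test_inconsistent_effect_size_rejected(self):
        with pytest.raises(ValueError):
            MRPPResult(delta=0.3, m_delta=0.3, A=0.5, p=0.5, n_perm=10)

    def test_random_groups_null(self, rng):
        X = rng.normal(size=(40, 3))
        dm = squareform(pdist(X))
        groups = rng.permutation(["a"] * 20 + ["b"] * 20)
        res = mrpp(dm, groups, n_perm=500, seed=1, unit_of_permutation="unit")
        assert abs(res.A) < 0.05
        assert res.p > 0.01

    def test_separated_clusters_extreme(self, rng):
        X = np.vstack([rng.normal(size=(15, 2)), rng.normal(size=(15, 2)) + 50])
        dm = squareform(pdist(X))
        groups = ["a"] * 15 + ["b"] * 15
        res = mrpp(dm, groups, n_perm=500, seed=1, unit_of_permutation="unit")
        assert res.delta < res.m_delta
        assert res.p == pytest.approx(1 / 501)
        assert res.A == pytest.approx(1 - res.delta / res.m_delta)

    def test_individual_level_permutation(self, small_two_class):
        _, _, _, D, _, _ = small_two_class
        half = sorted(set(D.individuals))[: len(set(D.individuals)) // 2]
        groups = ["g1" if ind in half else "g2" for ind in D.individuals]
        res = mrpp(D, groups, n_perm=300, seed=2)
        assert 0 <= res.p <= 1
        assert res.n_perm == 300

    def test_small_group_excluded(self, rng, caplog):
        dm = squareform(pdist(rng.normal(size=(11, 2))))
        groups = ["a"] * 5 + ["b"] * 5 + ["tiny"]
        with caplog.at_level("WARNING"):
            mrpp(dm, groups, n_perm=100, seed=1, unit_of_permutation="unit")
        assert "tiny" in caplog.text

    def test_coarser_grouping_weaker_effect(self, rng):
        """Pooling diverged groups into unions dilutes the effect size."""
        centers = {"p1": (0, 0), "p2": (4, 0), "p3": (0, 4), "p4": (4, 4)}
        pts, pops = [], []
        for name, c in centers.items():
            pts.append(rng.normal(c, 1.0, size=(15, 2)))
            pops += [name] * 15
        dm = squareform(pdist(np.vstack(pts)))
        # continents pool populations pairwise; population-level signal only
        continents = ["c1" if p in ("p1", "p2") else "c2" for p in pops]
        a_pop = mrpp(dm, pops, n_perm=400, seed=3, unit_of_permutation="unit").A
        a_cont = mrpp(dm, continents, n_perm=400, seed=3, unit_of_permutation="unit").A
        assert a_cont < a_pop


class TestTypeFrequency:
    def test_perfect_association(self):
        types = ["x"] * 10 + ["y"] * 10
        groups = ["a"] * 10 + ["b"] * 10
        res = type_frequency_test(types, groups, n_perm=300, seed=1)
        assert res.cramers_v == pytest.approx(1.0)
        assert res.p_perm < 0.01

    def test_proportional_table_no_association(self):
        types = (["x"] * 6 + ["y"] * 3) * 2
        groups = ["a"] * 9 + ["b"] * 9
        res = type_frequency_test(types, groups, n_perm=300, seed=1)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.cramers_v == pytest.approx(0.0, abs=1e-9)
        assert res.p_perm > 0.9

    def test_toy_table_matches_direct_computation(self, rng):
        types = rng.choice(["t1", "t2", "t3"], 120)
        groups = rng.choice(["g1", "g2", "g3", "g4"], 120)
        res = type_frequency_test(types, groups, n_perm=100, seed=1)
        expected = chi2_contingency(res.table.to_numpy(), correction=False)
        assert res.chi2 == pytest.approx(expected.statistic)
        assert res.df == (res.table.shape[0] - 1) * (res.table.shape[1] - 1)
        n = res.table.to_numpy().sum()
        assert res.cramers_v == pytest.approx(
            np.sqrt(res.chi2 / (n * (min(res.table.shape) - 1)))
        )

    def test_planted_usage_shift_detected(self):
        # a 2.25x multiplier lifts flat-note usage from ~0.10 to ~0.19 (ten
        # percentage points); 120 individuals/population gives the test
        # >99% power at alpha = 0.01 by noncentral-chi-square calculation
        spec = sc.GeneratorSpec(
            n_populations=2, individuals_per_pop=120,
            pop_frequency_shifts={"pop1": {"flat": 2.25}}, seed=21,
        )
        _, truth = sc.generate_dataset(spec)
        res = type_frequency_test(
            truth.units["true_type"], truth.units["population"],
            n_perm=1000, seed=5, individuals=truth.units["individual"],
        )
        assert res.p_perm < 0.01


class TestSpatialMedian:
    def test_single_point(self):
        np.testing.assert_allclose(spatial_median(np.array([[2.0, 3.0]])), [2.0, 3.0])

    def test_square_corners_center(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]])
        np.testing.assert_allclose(spatial_median(pts), [0.5, 0.5], atol=1e-7)

    def test_three_points_matches_grid_search(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0]])
        xs = np.linspace(-1, 5, 301)
        ys = np.linspace(-1, 4, 251)
        grid = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
        cost = np.linalg.norm(grid[:, None, :] - pts[None, :, :], axis=2).sum(axis=1)
        best = grid[np.argmin(cost)]
        np.testing.assert_allclose(spatial_median(pts), best, atol=0.03)

    def test_median_on_data_point(self):
        # heavily weighted point: the median coincides with it
        pts = np.array([[0, 0], [0, 0], [0, 0], [5, 0.0]])
        np.testing.assert_allclose(spatial_median(pts), [0, 0], atol=1e-7)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        M = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_dendrogram(M, ["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_additive_tree_distances_recovered(self, rng):
        # random 5-taxon additive distances via a random tree construction
        names = list("ABCDE")
        tree_dm = random_additive_distances(rng, names)
        tree = nj_dendrogram(tree_dm, names)
        recovered = tree.tip_tip_distances(names)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                assert recovered[a, b] == pytest.approx(tree_dm[i, j], abs=1e-9)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_dendrogram(np.zeros((2, 2)), ["A", "B"])

    def test_newick_serialization(self):
        M = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        nwk = tree_to_newick(nj_dendrogram(M, ["A", "B", "C"]))
        assert nwk.endswith(";")
        assert all(name in nwk for name in "ABC")


def random_additive_distances(rng, names):
    """Leaf-to-leaf distances of a random binary tree with positive lengths."""
    # caterpillar topology with random branch lengths is additive by construction
    n = len(names)
    pendant = rng.uniform(0.5, 3.0, n)
    internal = rng.uniform(0.5, 2.0, n - 2)
    # leaf i attaches at spine node min(i, n-2); spine distances cumulative
    spine_pos = np.concatenate([[0], np.cumsum(internal)])
    attach = np.minimum(np.arange(n), n - 2)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pendant[i] + pendant[j] + abs(spine_pos[attach[i]] - spine_pos[attach[j]])
            M[i, j] = M[j, i] = d
    return M


class TestGroupMedians:
    def test_median_matrix_shape_and_symmetry(self, rng):
        coords = rng.normal(size=(30, 3))
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        M, names = group_median_matrix(coords, groups)
        assert names == ["a", "b", "c"]
        np.testing.assert_allclose(M, M.T)
        assert np.all(np.diag(M) == 0)
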