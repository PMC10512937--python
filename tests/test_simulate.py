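"""Layouts, deme-size apportionment, coalescent and mutation process."""

import numpy as np
import pytest

from spatialdiv.diversity import pairwise_substitution_rate
from spatialdiv.geodesy import GeoPoint
from spatialdiv.simulate import (
    DemeLayout,
    Genealogy,
    SubstitutionModel,
    assign_sizes,
    build_grid_layout,
    build_island_layout,
    build_single_deme,
    largest_remainder_round,
    mutate_sequences,
    simulate_genealogy,
)


class TestGridLayouts:
    def test_linear_neighbour_counts(self):
        lay = build_grid_layout("A", 0.01, n_demes=100)
        degree = (lay.migration > 0).sum(axis=1)
        assert degree[0] == 1 and degree[99] == 1
        assert degree[50] == 2

    def test_ring_every_deme_two_neighbours(self):
        lay = build_grid_layout("B", 0.01, n_demes=100)
        assert ((lay.migration > 0).sum(axis=1) == 2).all()

    def test_plane_corner_and_interior(self):
        lay = build_grid_layout("C", 0.01, n_demes=100)
        degree = (lay.migration > 0).sum(axis=1)
        assert degree.min() == 2  # corners
        assert degree.max() == 4  # interior
        assert (degree == 4).sum() == 64

    def test_cylinder_wraps_longitudinally(self):
        lay = build_grid_layout("D", 0.01, n_demes=100)
        assert lay.grid_shape == (50, 2)
        # every deme: 2 ring neighbours + 1 across the rows
        assert ((lay.migration > 0).sum(axis=1) == 3).all()

    def test_uniform_adjacent_rate(self):
        lay = build_grid_layout("A", 0.25, n_demes=10)
        rates = lay.migration[lay.migration > 0]
        assert (rates == 0.25).all()

    def test_ring_adjacent_spacing_equalised(self):
        lay = build_grid_layout("B", 0.01, n_demes=50, spacing_m=10_000)
        D = lay.distances()
        adjacent = [D[i, (i + 1) % 50] for i in range(50)]
        assert np.ptp(adjacent) < 1.0  # rotational symmetry
        assert abs(np.mean(adjacent) - 10_000) < 300


class TestIslandLayout:
    def test_mean_rate_calibration(self):
        lay = build_island_layout(20, 0.05, seed=3)
        off = ~np.eye(20, dtype=bool)
        assert lay.migration[off].mean() == pytest.approx(0.05, abs=1e-12)

    def test_inverse_distance_proportionality(self):
        lay = build_island_layout(15, 0.01, seed=4)
        D = np.maximum(lay.distances(), 1_000.0)
        off = ~np.eye(15, dtype=bool)
        ratio = lay.migration[off] * D[off]
        assert np.allclose(ratio, ratio[0])

    def test_two_demes_single_pair(self):
        lay = build_island_layout(2, 0.07, seed=5)
        assert lay.migration[0, 1] == pytest.approx(0.07)
        assert lay.migration[1, 0] == pytest.approx(0.07)

    def test_symmetry(self):
        lay = build_island_layout(12, 0.02, seed=6)
        assert np.allclose(lay.migration, lay.migration.T)


class TestAssignSizes:
    def test_even_exact(self):
        lay = build_grid_layout("A", 0.01, n_demes=100)
        sizes = assign_sizes(lay, "even", 10_000)
        assert (sizes == 100).all()

    def test_largest_remainder_hand_example(self):
        # floors {3, 3, 2} leave 2 units; residuals {0.6, 0.6, 0.8} hand
        # them to deme 2 first, then the tie-broken first 0.6
        assert largest_remainder_round(np.array([3.6, 3.6, 2.8]), 10).tolist() == [4, 3, 3]

    def test_largest_remainder_preserves_total(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            w = rng.uniform(0.01, 5.0, rng.integers(2, 40))
            total = int(rng.integers(len(w), 5000))
            sizes = largest_remainder_round(w, total)
            assert sizes.sum() == total
            assert (sizes >= 0).all()

    def test_latitude_normal_sums_exactly(self):
        lay = build_island_layout(25, 0.01, seed=7)
        sizes = assign_sizes(lay, "latitude_normal", 10_000)
        assert sizes.sum() == 10_000
        assert (sizes >= 1).all()

    def test_latitude_normal_favours_equator(self):
        lay = build_island_layout(50, 0.01, seed=8)
        sizes = assign_sizes(lay, "latitude_normal", 10_000)
        lats = np.abs([p.lat for p in lay.demes])
        near = sizes[lats < 30].mean()
        far = sizes[lats > 60].mean()
        assert near > far

    def test_truncated_normal_centre_heavy(self):
        lay = build_grid_layout("A", 0.01, n_demes=25)
        sizes = assign_sizes(lay, "truncated_normal", 1_000)
        assert sizes.sum() == 1_000
        assert sizes[12] > sizes[0]
        assert sizes[12] > sizes[24]

    def test_zero_promotion(self):
        lay = build_island_layout(10, 0.01, seed=9)
        # extreme weights: dnorm at high latitude underflows to ~0 shares
        sizes = assign_sizes(lay, "latitude_normal", 10, latitude_coefficient=2.0)
        assert sizes.sum() == 10
        assert (sizes >= 1).all()


class TestCoalescent:
    def test_mean_tmrca_two_lineages(self):
        # E[T2] = Ne generations for a haploid deme of size Ne
        lay = build_single_deme(400)
        rng = np.random.default_rng(0)
        t = [simulate_genealogy(lay, rng, sample_sizes=[2]).tmrca for _ in range(2000)]
        se = np.std(t) / np.sqrt(len(t))
        assert abs(np.mean(t) - 400) < 3 * se

    def test_mean_tree_length(self):
        # E[L] = 2 Ne sum_{i<n} 1/i
        lay = build_single_deme(300)
        rng = np.random.default_rng(1)
        tl = [
            simulate_genealogy(lay, rng, sample_sizes=[8]).total_branch_length
            for _ in range(2000)
        ]
        expected = 2 * 300 * sum(1 / i for i in range(1, 8))
        se = np.std(tl) / np.sqrt(len(tl))
        assert abs(np.mean(tl) - expected) < 3 * se

    def test_two_deme_split_times_match_theory(self):
        # E[T | same deme] = 2N ; E[T | different] = 2N + 1/(2m)
        mig = np.array([[0.0, 0.02], [0.02, 0.0]])
        lay = DemeLayout(
            demes=(GeoPoint("a", 0, 0), GeoPoint("b", 0, 1)),
            sizes=np.array([60, 60]),
            migration=mig,
            model="stepping_stone",
        )
        rng = np.random.default_rng(2)
        same = [simulate_genealogy(lay, rng, sample_sizes=[2, 0]).tmrca for _ in range(1500)]
        diff = [simulate_genealogy(lay, rng, sample_sizes=[1, 1]).tmrca for _ in range(1500)]
        for obs, theory in ((same, 120.0), (diff, 120.0 + 25.0)):
            se = np.std(obs) / np.sqrt(len(obs))
            assert abs(np.mean(obs) - theory) < 3.5 * se

    def test_zero_migration_across_demes_raises(self):
        lay = DemeLayout(
            demes=(GeoPoint("a", 0, 0), GeoPoint("b", 0, 1)),
            sizes=np.array([10, 10]),
            migration=np.zeros((2, 2)),
            model="stepping_stone",
        )
        with pytest.raises(RuntimeError, match="no MRCA"):
            simulate_genealogy(lay, 0, sample_sizes=[1, 1])

    def test_ultrametric_and_ordered(self):
        lay = build_grid_layout("C", 0.1, n_demes=9, deme_size=20)
        g = simulate_genealogy(lay, 5)
        assert (g.time[: g.n_leaves] == 0).all()
        internal = g.time[g.n_leaves :]
        assert (internal > 0).all()
        assert (np.diff(internal) >= 0).all()  # numbered in coalescence order
        # parent times exceed child times
        keep = g.parent >= 0
        assert (g.time[g.parent[keep]] > g.time[keep]).all()

    def test_deterministic_given_seed(self):
        lay = build_grid_layout("A", 0.05, n_demes=5, deme_size=10)
        g1 = simulate_genealogy(lay, 42)
        g2 = simulate_genealogy(lay, 42)
        assert np.array_equal(g1.parent, g2.parent)
        assert np.array_equal(g1.time, g2.time)

    def test_newick_roundtrip_through_dendropy(self):
        import dendropy

        lay = build_single_deme(50)
        g = simulate_genealogy(lay, 3, sample_sizes=[6])
        tree = dendropy.Tree.get(data=g.to_newick(), schema="newick")
        assert len(tree.leaf_nodes()) == 6
        depths = [leaf.distance_from_root() for leaf in tree.leaf_nodes()]
        assert max(depths) - min(depths) < 1e-6 * max(depths)  # ultrametric


class TestMutation:
    def test_zero_rate_identical_leaves(self):
        lay = build_single_deme(100)
        g = simulate_genealogy(lay, 1, sample_sizes=[5])
        aln = mutate_sequences(g, SubstitutionModel(mu=0.0), 100, 2)
        assert len(set(aln.seqs)) == 1

    def test_zero_branch_copies_parent(self):
        g = Genealogy(
            parent=np.array([2, 2, -1]),
            time=np.array([0.0, 0.0, 0.0]),
            n_leaves=2,
            leaf_deme=np.array([0, 0]),
        )
        aln = mutate_sequences(g, SubstitutionModel(mu=1e-3), 200, 3)
        assert aln.seqs[0] == aln.seqs[1]

    def test_divergence_matches_jukes_cantor(self):
        # two leaves split t generations ago: E[p] = 3/4 (1 - e^{-8/3 mu t})
        mu, t = 1e-5, 20_000
        g = Genealogy(
            parent=np.array([2, 2, -1]),
            time=np.array([0.0, 0.0, float(t)]),
            n_leaves=2,
            leaf_deme=np.array([0, 0]),
        )
        rng = np.random.default_rng(4)
        p = [
            pairwise_substitution_rate(*mutate_sequences(g, SubstitutionModel(mu=mu), 500, rng).seqs)
            for _ in range(500)
        ]
        expected = 0.75 * (1 - np.exp(-8.0 / 3.0 * mu * t))
        se = np.std(p) / np.sqrt(len(p))
        assert abs(np.mean(p) - expected) < 3 * se

    def test_rate_matrix_properties(self):
        m = SubstitutionModel(
            exchangeabilities=(1.0, 2.5, 0.8, 1.1, 3.0, 1.0),
            base_freqs=(0.3, 0.2, 0.2, 0.3),
            mu=1e-6,
        )
        Q = m.rate_matrix()
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-18)
        pi = np.array(m.base_freqs)
        assert -float(pi @ np.diagonal(Q)) == pytest.approx(1e-6)
        # detailed balance (reversibility)
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T)
        P = m.transition_matrix(1e5)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert (P >= 0).all()

    def test_stationary_base_composition(self):
        m = SubstitutionModel(base_freqs=(0.4, 0.3, 0.2, 0.1), mu=1e-4)
        P = m.transition_matrix(10**9)
        # rows converge to the stationary distribution
        assert np.allclose(P, np.tile([0.4, 0.3, 0.2, 0.1], (4, 1)), atol=1e-6)
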