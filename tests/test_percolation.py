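"""Torus geometry, long-edge sampling, and threshold activation dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroperc import (
    ActivationState,
    LongEdgeModel,
    TorusLattice,
    UpdateRule,
    activation_step,
    build_graph,
    distance_shell_sizes,
    expected_long_degree,
    long_edge_probability,
    run_dynamics,
    solve_c_for_lambda,
    torus_l1_distance,
)


class TestTorusDistance:
    @pytest.mark.parametrize(
        "x, y, n, expected",
        [
            ((0, 0), (0, 0), 8, 0),
            ((0, 0), (7, 7), 8, 2),  # wraparound 1 + 1
            ((0, 0), (3, 4), 8, 7),  # min(3,5) + min(4,4)
            ((2, 2), (2, 3), 5, 1),
        ],
    )
    def test_examples(self, x, y, n, expected):
        assert torus_l1_distance(x, y, n) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            torus_l1_distance((0, 0), (8, 0), 8)

    @given(
        st.integers(3, 12),
        st.tuples(st.integers(0, 11), st.integers(0, 11)),
        st.tuples(st.integers(0, 11), st.integers(0, 11)),
        st.tuples(st.integers(0, 11), st.integers(0, 11)),
    )
    @settings(max_examples=200, deadline=None)
    def test_metric_axioms(self, n, x, y, z):
        x, y, z = [(a % n, b % n) for a, b in (x, y, z)]
        dxy = torus_l1_distance(x, y, n)
        assert dxy == torus_l1_distance(y, x, n)
        assert dxy <= n  # componentwise wrap caps each axis at n // 2
        assert (dxy == 0) == (x == y)
        assert dxy <= torus_l1_distance(x, z, n) + torus_l1_distance(z, y, n)


class TestLongEdgeModel:
    @pytest.mark.parametrize(
        "d, n, c, alpha, expected",
        [
            (10, 100, 1.0, 1.0, 0.001),
            (1, 10, 200.0, 1.0, 1.0),  # clamp at 1
            (4, 16, 2.0, 2.0, 2.0 / 256.0),
        ],
    )
    def test_probability_examples(self, d, n, c, alpha, expected):
        assert long_edge_probability(d, n, LongEdgeModel(c=c, alpha=alpha)) == pytest.approx(expected)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            long_edge_probability(0, 10, LongEdgeModel())

    def test_shell_sizes_match_enumeration(self):
        for n in (4, 5, 8):
            shells = distance_shell_sizes(n)
            brute = np.zeros(2 * (n // 2) + 1, dtype=int)
            for i in range(n):
                for j in range(n):
                    if (i, j) != (0, 0):
                        brute[torus_l1_distance((0, 0), (i, j), n)] += 1
            assert np.array_equal(shells, brute[: len(shells)])

    def test_expected_degree_zero_c(self):
        assert expected_long_degree(16, LongEdgeModel(c=0.0)) == 0.0

    def test_expected_degree_brute_force_n4(self):
        # exhaustive oracle: sum p_dist over every eligible pair from (0,0)
        model = LongEdgeModel(c=1.0, alpha=1.0)
        brute = 0.0
        for i in range(4):
            for j in range(4):
                d = torus_l1_distance((0, 0), (i, j), 4)
                if d >= 2:
                    brute += long_edge_probability(d, 4, model)
        assert expected_long_degree(4, model) == pytest.approx(brute)

    def test_large_n_alpha1_limit(self):
        # continuum limit of (1/N) sum_d S(d)/d on the L1 torus:
        # (4/N) * int_0^{N/2} int_0^{N/2} dx dy / (x + y) = 4 ln 2
        lam = expected_long_degree(128, LongEdgeModel(c=1.0, alpha=1.0))
        assert lam == pytest.approx(4.0 * np.log(2.0), rel=0.05)

    def test_solve_c_roundtrip(self):
        for lam in (0.5, 1.0, 2.0):
            c = solve_c_for_lambda(64, lam)
            assert expected_long_degree(64, LongEdgeModel(c=c)) == pytest.approx(lam, rel=1e-6)


class TestBuildGraph:
    def test_no_long_edges_when_c_zero(self, local_graph_4):
        assert len(local_graph_4.long_edges) == 0
        assert local_graph_4.adjacency.nnz == 2 * local_graph_4.n_short_edges
        assert np.all(local_graph_4.degrees() == 4)

    def test_deterministic_under_seed(self):
        model = LongEdgeModel(c=2.0)
        g1 = build_graph(12, model, seed=42)
        g2 = build_graph(12, model, seed=42)
        assert g1.long_edges == g2.long_edges
        assert (g1.adjacency != g2.adjacency).nnz == 0
        g3 = build_graph(12, model, seed=43)
        assert g1.long_edges != g3.long_edges

    def test_long_edges_respect_min_distance(self):
        g = build_graph(10, LongEdgeModel(c=20.0), seed=3)
        assert len(g.long_edges) > 0
        for (x1, y1), (x2, y2) in g.long_edge_coords():
            assert torus_l1_distance((x1, y1), (x2, y2), 10) >= 2

    def test_no_self_loops_or_duplicates(self):
        g = build_graph(8, LongEdgeModel(c=50.0), seed=1)
        assert all(a != b for a, b in g.long_edges)
        assert g.adjacency.max() == 1  # no parallel edges
        assert g.adjacency.diagonal().sum() == 0

    def test_mean_long_degree_matches_enumeration(self):
        # Monte-Carlo over 50 seeds vs. the exact shell-sum expectation
        n, model = 32, LongEdgeModel(c=1.0, alpha=1.0)
        lam = expected_long_degree(n, model)
        counts = [len(build_graph(n, model, seed=s).long_edges) for s in range(50)]
        mean_deg = 2.0 * np.mean(counts) / n**2
        se = 2.0 * np.std(counts, ddof=1) / np.sqrt(50) / n**2
        assert abs(mean_deg - lam) < 3.0 * max(se, 1e-12)


class TestActivationStep:
    def test_rule_validation(self):
        with pytest.raises(ValueError):
            UpdateRule(k=0)
        with pytest.raises(ValueError):
            UpdateRule(k=2, eps=0.9)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_uniform_states_absorbing(self, local_graph_4, k):
        n = local_graph_4.n
        rule = UpdateRule(k=k)
        off = ActivationState(np.zeros((n, n), dtype=np.uint8))
        assert activation_step(off, local_graph_4, rule).n_active == 0
        on = ActivationState(np.ones((n, n), dtype=np.uint8))
        assert activation_step(on, local_graph_4, rule).rho == 1.0

    def test_single_seed_k1_spreads_to_neighbors(self, local_graph_4):
        chi = np.zeros((4, 4), dtype=np.uint8)
        chi[1, 1] = 1
        out = activation_step(ActivationState(chi), local_graph_4, UpdateRule(k=1))
        expected = np.zeros((4, 4), dtype=np.uint8)
        for i, j in ((0, 1), (2, 1), (1, 0), (1, 2)):
            expected[i, j] = 1
        assert np.array_equal(out.chi, expected)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_matches_brute_force_enumeration(self, tiny_states, local_graph_4, k):
        """Oracle equivalence on 200 random 4x4 states, bit for bit."""
        rule = UpdateRule(k=k)
        for chi, expected in zip(tiny_states["states"], tiny_states["next"][k]):
            out = activation_step(ActivationState(chi), local_graph_4, rule)
            assert np.array_equal(out.chi, expected)

    def test_monotone_in_state(self, rng):
        """Adding active vertices never removes active vertices downstream."""
        g = build_graph(8, LongEdgeModel(c=2.0), seed=7)
        rule = UpdateRule(k=3)
        for _ in range(50):
            a = (rng.random((8, 8)) < 0.4).astype(np.uint8)
            b = np.maximum(a, (rng.random((8, 8)) < 0.2).astype(np.uint8))
            out_a = activation_step(ActivationState(a), g, rule).chi
            out_b = activation_step(ActivationState(b), g, rule).chi
            assert np.all(out_b >= out_a)

    def test_noise_requires_rng(self, local_graph_4):
        state = ActivationState(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            activation_step(state, local_graph_4, UpdateRule(k=1, eps=0.1))


class TestRunDynamics:
    def test_empty_start_is_all_inactive_at_step_zero(self, local_graph_4):
        traj = run_dynamics(0.0, local_graph_4, UpdateRule(k=2))
        assert traj.outcome == "all_inactive"
        assert traj.steps_taken == 0

    def test_full_start_is_all_active_for_small_k(self, local_graph_4):
        traj = run_dynamics(1.0, local_graph_4, UpdateRule(k=4))
        assert traj.outcome == "all_active"
        assert traj.steps_taken == 0

    def test_nonuniform_fixed_point_reported_as_cycle(self, local_graph_4):
        # a full column is invariant under k=2 on the pure torus
        chi = np.zeros((4, 4), dtype=np.uint8)
        chi[:, 0] = 1
        traj = run_dynamics(0.5, local_graph_4, UpdateRule(k=2), initial_state=chi)
        assert traj.outcome == "cycle"
        assert traj.final_rho == pytest.approx(0.25)

    def test_supercritical_runs_fill_the_lattice(self):
        model = LongEdgeModel(c=1.0)
        rule = UpdateRule(k=3)
        wins = 0
        for seed in range(20):
            g = build_graph(32, model, seed=seed)
            traj = run_dynamics(0.95, g, rule, max_steps=200, seed=seed + 1000)
            wins += traj.outcome == "all_active"
        assert wins >= 18  # >= 90% of runs

    def test_deterministic_under_seed(self):
        g = build_graph(12, LongEdgeModel(c=1.0), seed=2)
        rule = UpdateRule(k=2)
        t1 = run_dynamics(0.3, g, rule, seed=5)
        t2 = run_dynamics(0.3, g, rule, seed=5)
        assert np.array_equal(t1.rho, t2.rho)
        assert t1.outcome == t2.outcome

    def test_invalid_arguments(self, local_graph_4):
        with pytest.raises(ValueError):
            run_dynamics(1.5, local_graph_4, UpdateRule(k=1))
        with pytest.raises(ValueError):
            run_dynamics(0.5, local_graph_4, UpdateRule(k=1), max_steps=0)

    def test_rho_times_size_is_integer(self, local_graph_4):
        traj = run_dynamics(0.4, local_graph_4, UpdateRule(k=2), seed=3)
        counts = traj.rho * 16
        assert np.allclose(counts, np.round(counts))
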