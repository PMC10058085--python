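"""Reduced-order network solver: edge laws, Newton solve, FFR readout."""

import numpy as np
import pytest

from ctpffr.bc import MLMIN_TO_M3S, MMHG_TO_PA
from ctpffr.solver import (SolverSettings, build_vessel_graph, ffr_at,
                           poiseuille_resistance, pressure_at,
                           segment_coefficients, solve_network, solve_tree)
from ctpffr.tree import CoronaryTree, Node, Segment, Stenosis

MAP, PV = 96.0, 5.0


class TestSegmentCoefficients:
    def test_poiseuille_hand_value(self):
        # 8*mu*L/(pi r^4) for L=10 mm, r=2 mm, mu=0.0035 Pa.s
        assert poiseuille_resistance(10.0, 2.0, 0.0035) == \
            pytest.approx(5.570423e6, rel=1e-6)

    def test_clinical_units_conversion(self):
        a, b = segment_coefficients(10.0, 2.0)
        assert a == pytest.approx(5.570423e6 * MLMIN_TO_M3S / MMHG_TO_PA, rel=1e-6)
        assert b == 0.0

    def test_no_stenosis_degeneracy(self):
        a0, b0 = segment_coefficients(10.0, 2.0, stenosis_severity=0.0)
        a1, b1 = segment_coefficients(10.0, 2.0, stenosis_severity=None)
        assert a0 == pytest.approx(a1)
        assert b0 == b1 == 0.0

    def test_monotone_in_severity(self):
        sev = np.linspace(10.0, 90.0, 17)
        coeffs = [segment_coefficients(10.0, 2.0, s) for s in sev]
        a = np.array([c[0] for c in coeffs])
        b = np.array([c[1] for c in coeffs])
        assert np.all(np.diff(a) > 0)
        assert np.all(np.diff(b) > 0)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            poiseuille_resistance(0.0, 2.0)
        with pytest.raises(ValueError):
            poiseuille_resistance(10.0, -1.0)


class TestSolveNetwork:
    def test_single_edge_closed_form(self, single_edge_tree, hemo):
        """Series resistance: P_out = Pv + R*(MAP - Pv)/(a + R)."""
        R = 10.0
        graph = build_vessel_graph(single_edge_tree, hemo, {1: R}, step=100.0)
        sol = solve_network(graph, MAP)
        a = graph.edge_a.sum()
        expected = PV + R * (MAP - PV) / (a + R)
        assert sol.pressures[graph.tree_node_index[1]] == \
            pytest.approx(expected, rel=1e-10)

    def test_zero_loss_limit(self, hemo):
        """All a = b = 0: every nodal pressure equals MAP."""
        nodes = {0: Node(0, [0, 0, 0], 2.0), 1: Node(1, [10, 0, 0], 2.0),
                 2: Node(2, [20, 0, 0], 1.5)}
        segs = [Segment(0, 0, 1, 10, 2, 2), Segment(1, 1, 2, 10, 1.5, 1.5)]
        tree = CoronaryTree(nodes, segs, [], {2: "LAD"}, 0)
        graph = build_vessel_graph(tree, hemo, {2: 10.0}, step=100.0)
        graph.edge_a[:] = 0.0
        graph.edge_b[:] = 0.0
        sol = solve_network(graph, MAP)
        np.testing.assert_allclose(sol.pressures, MAP, rtol=1e-8)

    def test_symmetric_bifurcation_splits_evenly(self, symmetric_bifurcation,
                                                 hemo):
        graph = build_vessel_graph(symmetric_bifurcation, hemo,
                                   {2: 8.0, 3: 8.0}, step=1.0)
        sol = solve_network(graph, MAP)
        q2 = sol.edge_flows[graph.edge_dst == graph.tree_node_index[2]].sum()
        q3 = sol.edge_flows[graph.edge_dst == graph.tree_node_index[3]].sum()
        assert q2 == pytest.approx(q3, rel=1e-13)

    def test_linear_oracle_small_trees(self, hemo):
        """Exact linear-network solution (dense elimination) on a 4-edge tree."""
        r_c = 1.8
        nodes = {0: Node(0, [0, 0, 0], 2.2), 1: Node(1, [12, 0, 0], 2.2),
                 2: Node(2, [25, 6, 0], r_c), 3: Node(3, [25, -6, 0], r_c),
                 4: Node(4, [40, 9, 0], 1.4)}
        segs = [Segment(0, 0, 1, 12, 2.2, 2.2),
                Segment(1, 1, 2, 14, r_c, r_c),
                Segment(2, 1, 3, 14, r_c, 1.5),
                Segment(3, 2, 4, 16, 1.4, 1.4)]
        tree = CoronaryTree(nodes, segs, [], {3: "LCX", 4: "LAD"}, 0)
        res = {3: 12.0, 4: 9.0}
        graph = build_vessel_graph(tree, hemo, res, step=1000.0)  # one edge/segment
        sol = solve_network(graph, MAP)

        # independent oracle: assemble nodal conductance system and eliminate
        n = graph.n_nodes
        G = np.zeros((n, n))
        rhs = np.zeros(n)
        for u, v, a in zip(graph.edge_src, graph.edge_dst, graph.edge_a):
            g = 1.0 / a
            G[u, u] += g
            G[v, v] += g
            G[u, v] -= g
            G[v, u] -= g
        for o, R in zip(graph.outlet_nodes, graph.outlet_r):
            G[o, o] += 1.0 / R
            rhs[o] += PV / R
        free = [i for i in range(n) if i != graph.inlet]
        rhs_f = rhs[free] - G[np.ix_(free, [graph.inlet])].ravel() * MAP
        p_free = np.linalg.solve(G[np.ix_(free, free)], rhs_f)
        exact = np.full(n, MAP)
        exact[free] = p_free
        np.testing.assert_allclose(sol.pressures, exact, rtol=1e-10)

    def test_mass_conservation_and_pressure_bounds(self, stenosed_tube, hemo):
        graph, sol = solve_tree(stenosed_tube, hemo, {1: 8.0},
                                SolverSettings(step=1.0))
        assert sol.final_residual <= 1e-9 * sol.inlet_flow
        assert np.all(sol.pressures >= PV - 1e-9)
        assert np.all(sol.pressures <= MAP + 1e-9)
        assert sol.converged

    def test_refinement_stability(self, stenosed_tube, hemo):
        """Halving the discretisation step changes the FFR readout < 1e-3."""
        ffrs = []
        for step in (2.0, 1.0, 0.5):
            graph, sol = solve_tree(stenosed_tube, hemo, {1: 8.0},
                                    SolverSettings(step=step))
            ffrs.append(ffr_at(sol, graph, 0, offset=10.0)[0])
        assert abs(ffrs[1] - ffrs[0]) < 1e-3
        assert abs(ffrs[2] - ffrs[1]) < 1e-3

    def test_nonconvergence_carries_history(self, stenosed_tube, hemo):
        from ctpffr.solver import SolverError
        with pytest.raises(SolverError) as exc:
            solve_tree(stenosed_tube, hemo, {1: 8.0},
                       SolverSettings(step=1.0, max_iter=2))
        assert len(exc.value.residual_history) == 2


class TestFFRReadout:
    def test_lossless_tree_reads_one(self, single_edge_tree, hemo):
        nodes = dict(single_edge_tree.nodes)
        stens = [Stenosis(0, 0, 5.0, 2.0, 1e-6)]
        tree = CoronaryTree(nodes, single_edge_tree.segments, stens,
                            {1: "LAD"}, 0)
        graph, sol = solve_tree(tree, hemo, {1: 1e9}, SolverSettings(step=1.0))
        f, truncated = ffr_at(sol, graph, 0, offset=2.0)
        assert f == pytest.approx(1.0, abs=1e-6)

    def test_pressure_monotone_downstream(self, stenosed_tube, hemo):
        """On a lossy tube the readout decreases with the distal offset."""
        graph, sol = solve_tree(stenosed_tube, hemo, {1: 8.0},
                                SolverSettings(step=1.0))
        f0 = ffr_at(sol, graph, 0, offset=0.0)[0]
        f20 = ffr_at(sol, graph, 0, offset=19.0)[0]
        assert f20 <= f0

    def test_truncation_flag_when_tree_ends(self, stenosed_tube, hemo):
        graph, sol = solve_tree(stenosed_tube, hemo, {1: 8.0},
                                SolverSettings(step=1.0))
        f, truncated = ffr_at(sol, graph, 0, offset=500.0)
        assert truncated
        assert f == pytest.approx(
            sol.pressures[graph.tree_node_index[1]] / MAP, rel=1e-12)

    def test_unknown_stenosis_rejected(self, stenosed_tube, hemo):
        graph, sol = solve_tree(stenosed_tube, hemo, {1: 8.0},
                                SolverSettings(step=2.0))
        with pytest.raises(KeyError):
            ffr_at(sol, graph, 99)

    def test_interpolated_pressure_between_nodes(self, single_edge_tree, hemo):
        graph, sol = solve_tree(single_edge_tree, hemo, {1: 10.0},
                                SolverSettings(step=1.0))
        p_mid = pressure_at(sol, graph, 0, 5.0)
        assert sol.pressures.min() <= p_mid <= sol.pressures.max()
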