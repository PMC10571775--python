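"""KVA spring-network mechanics of the hexagonal patch."""

import networkx as nx
import numpy as np
import pytest

from hippomech.tissue_mechanics import (MechParams, apply_swelling,
                                        build_hex_patch, edge_forces,
                                        graph_laplacians, grow_rest_lengths,
                                        integrate, relax)


class TestBuildHexPatch:
    def test_flower_combinatorics(self, patch):
        # 7-hexagon flower: 24 corner nodes, 30 belt edges (Euler's formula)
        assert len(patch.belt_edges) == 30
        corner_nodes = {int(n) for e in patch.belt_edges for n in e}
        assert len(corner_nodes) == 24
        assert len(patch.trans_edges) == 42   # 7 cells x 6 spokes
        assert len(patch.boundary_nodes) == 18

    def test_interior_nodes_have_belt_degree_three(self, patch):
        deg = np.zeros(patch.n_nodes, dtype=int)
        for i, j in patch.belt_edges:
            deg[i] += 1
            deg[j] += 1
        interior = [n for n in range(24) if n not in patch.boundary_nodes]
        assert all(deg[n] == 3 for n in interior)

    def test_prestress_free_start(self, patch):
        net = patch.copy()
        net.fa_belt[:] = 0.0
        F = edge_forces(net)
        assert np.abs(F).max() < 1e-9

    def test_bad_edge_length(self):
        with pytest.raises(ValueError):
            build_hex_patch(0.0)


class TestGraphLaplacians:
    def test_row_sums_zero_and_symmetric(self, patch):
        LN, LT = graph_laplacians(patch)
        for L in (LN, LT):
            assert np.abs(L.sum(axis=1)).max() < 1e-12
            assert np.allclose(L, L.T)

    def test_constant_vector_in_kernel(self, patch):
        LN, _ = graph_laplacians(patch)
        assert np.abs(LN @ np.ones(patch.n_nodes)).max() < 1e-12

    def test_zero_eigenvalues_count_connected_components(self, patch):
        """Spectral count of components matches a graph-library oracle."""
        LN, LT = graph_laplacians(patch)
        for L, edges in ((LN, patch.belt_edges), (LT, patch.trans_edges)):
            g = nx.Graph()
            g.add_nodes_from(range(patch.n_nodes))
            g.add_edges_from(map(tuple, edges))
            expect = nx.number_connected_components(g)
            eig = np.linalg.eigvalsh(L)
            assert int(np.sum(np.abs(eig) < 1e-9)) == expect


class TestEdgeForces:
    def test_internal_forces_sum_to_zero(self, patch, rng):
        net = patch.copy()
        net.x += rng.normal(0, 0.2, net.x.shape)
        net.v = rng.normal(0, 0.1, net.v.shape)
        F = edge_forces(net)          # no imposed force
        assert np.abs(F.sum(axis=0)).max() < 1e-9

    def test_hookes_law_on_single_stretched_edge(self, patch):
        net = patch.copy()
        net.fa_belt[:] = 0.0
        i, j = net.belt_edges[0]
        u = (net.x[j] - net.x[i]) / np.linalg.norm(net.x[j] - net.x[i])
        delta = 0.3
        net.x[j] += delta * u
        F = edge_forces(net)
        k = net.k_belt[0]
        # moving j stretches edge 0 and disturbs j's other edges; check i,
        # whose only perturbed edge is the stretched one
        assert np.linalg.norm(F[i]) == pytest.approx(k * delta, rel=1e-9)

    def test_contraction_pulls_boundary_inward(self, patch):
        net = patch.copy()   # springs at rest, FA > 0 on belt edges
        F = edge_forces(net)
        c = net.centroid
        radial = [F[b] @ (net.x[b] - c) for b in net.boundary_nodes]
        # hull nodes on straight segments feel cancelling pulls (~0); no
        # boundary node is pulled outward and the net effect is inward
        assert max(radial) < 1e-9
        assert sum(radial) < -1.0

    def test_zero_length_edge_rejected(self, patch):
        net = patch.copy()
        i, j = net.belt_edges[0]
        net.x[j] = net.x[i]
        with pytest.raises(ValueError):
            edge_forces(net)


class TestIntegrate:
    def test_equilibrium_is_invariant(self, patch):
        net = patch.copy()
        net.fa_belt[:] = 0.0
        _, out = integrate(net, 0.0, horizon=5.0, mode="overdamped")
        assert np.abs(out.x - net.x).max() < 1e-8

    def test_passive_energy_dissipates(self, patch, rng):
        """Kelvin-Voigt network without active or imposed forces loses
        elastic + kinetic energy monotonically."""
        net = patch.copy()
        net.fa_belt[:] = 0.0
        net.x += rng.normal(0, 0.1, net.x.shape)

        def energy(x, v):
            E = 0.5 * (net.mass[:, None] * v ** 2).sum()
            for edges, k, l in ((net.belt_edges, net.k_belt, net.l_belt),
                                (net.trans_edges, net.k_trans, net.l_trans)):
                L = np.linalg.norm(x[edges[:, 1]] - x[edges[:, 0]], axis=1)
                E += float((0.5 * k * (L - l) ** 2).sum())
            return E

        sol, _ = integrate(net, 0.0, horizon=3.0, mode="inertial")
        ts = np.linspace(sol.t[0], sol.t[-1], 40)
        n = net.n_nodes
        Es = [energy(sol.sol(t)[:2 * n].reshape(n, 2),
                     sol.sol(t)[2 * n:].reshape(n, 2)) for t in ts]
        assert np.all(np.diff(Es) < 1e-6)

    def test_stationary_state_mode_independent(self, patch):
        net = patch.copy()
        net.fa_belt[:] = 0.0
        _, over = integrate(net, 120.0, horizon=60.0, mode="overdamped")
        _, iner = integrate(net, 120.0, horizon=60.0, mode="inertial")
        assert np.abs(over.x - iner.x).max() < 1e-2

    def test_stretch_dominates_compression_response(self, patch):
        """+800 pN/node stretching changes the area far more than -100
        pN/node compression (passive network)."""
        net = patch.copy()
        net.fa_belt[:] = 0.0
        a0 = net.total_area()
        up = relax(net, 800.0)
        down = relax(net, -100.0)
        d_up = abs(up.total_area() - a0) / a0
        d_down = abs(down.total_area() - a0) / a0
        assert d_up > 3 * d_down

    def test_unknown_mode_rejected(self, patch):
        with pytest.raises(ValueError):
            integrate(patch, 0.0, mode="magic")


class TestRelax:
    def test_returns_to_rest_after_transient_load(self, patch):
        """Kelvin-Voigt solid: release of a transient load restores the
        original configuration to within 1%."""
        net = patch.copy()
        net.fa_belt[:] = 0.0
        loaded = relax(net, 250.0)
        assert np.abs(loaded.x - net.x).max() > 0.1   # load did something
        released = relax(loaded, 0.0)
        scale = np.abs(net.x).max()
        assert np.abs(released.x - net.x).max() < 0.01 * scale

    def test_contractile_network_shrinks(self, patch):
        rel = relax(patch, 0.0)   # module defaults carry FA=100 on the belt
        assert rel.total_area() < patch.total_area()


class TestSwellingAndGrowth:
    def test_identity_swelling(self, patch):
        out = apply_swelling(patch, 0, 1.0)
        assert np.allclose(out.l_belt, patch.l_belt)
        assert np.allclose(out.l_trans, patch.l_trans)

    def test_unknown_cell_rejected(self, patch):
        with pytest.raises(KeyError):
            apply_swelling(patch, 99, 2.0)

    def test_swelling_makes_neighbors_irregular(self, patch):
        swollen = relax(apply_swelling(patch, 0, 2.0), 0.0)
        for c in range(1, 7):
            assert swollen.side_length_cv(c) > 1e-3

    def test_uniform_growth_closed_form(self, patch):
        r, T = 0.01, 12.0
        out = grow_rest_lengths(patch, r, r, T)
        assert np.allclose(out.l_belt, patch.l_belt * np.exp(r * T))
        assert np.allclose(out.l_trans, patch.l_trans * np.exp(r * T))
        same = grow_rest_lengths(patch, 0.0, 0.0, T)
        assert np.allclose(same.l_belt, patch.l_belt)

    def test_central_growth_compresses_neighbors(self, patch):
        """Growing only the central cell's rest lengths and relaxing leaves
        neighbor belt edges shorter than their rest lengths on average."""
        net = patch.copy()
        net.fa_belt[:] = 0.0
        belt_rates = np.zeros(len(net.belt_edges))
        belt_rates[net.cell_belt_edges[0]] = 0.05
        trans_rates = np.zeros(len(net.trans_edges))
        trans_rates[net.cell_trans_edges[0]] = 0.05
        grown = grow_rest_lengths(net, belt_rates, trans_rates, 10.0)
        rel = relax(grown, 0.0)
        neighbor_edges = sorted({e for c in range(1, 7)
                                 for e in rel.cell_belt_edges[c]}
                                - set(rel.cell_belt_edges[0]))
        L = np.linalg.norm(rel.x[rel.belt_edges[neighbor_edges, 1]]
                           - rel.x[rel.belt_edges[neighbor_edges, 0]], axis=1)
        assert (L - rel.l_belt[neighbor_edges]).mean() < 0


class TestExports:
    def test_state_frame_covers_nodes_and_edges(self, patch):
        from hippomech.tissue_mechanics import network_state_frame
        df = network_state_frame(patch)
        assert (df.kind == "node").sum() == patch.n_nodes
        assert (df.kind == "belt_edge").sum() == len(patch.belt_edges)
        assert (df.kind == "transverse_edge").sum() == len(patch.trans_edges)

    def test_cell_polygons_are_json_serializable_hexagons(self, patch):
        import json
        from hippomech.tissue_mechanics import cell_polygons
        polys = json.loads(json.dumps(cell_polygons(patch)))
        assert len(polys) == 7
        assert all(len(v) == 6 for v in polys.values())
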