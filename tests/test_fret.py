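"""Förster rates, network assembly, path search, red-pair detection."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pigment_eet import (
    EETNetwork,
    FretParams,
    GroupingError,
    TransitionDipole,
    build_network,
    detect_red_pairs,
    extract_pigments,
    fastest_paths,
    intersubunit_matrix,
    make_chlorin,
    make_toy_complex,
    pair_rate,
)


def _dipole(anchor, direction):
    return TransitionDipole(np.asarray(anchor, float),
                            np.asarray(direction, float))


class TestPairRate:
    def test_unit_case(self):
        d = _dipole((0, 0, 0), (1, 0, 0))
        a = _dipole((0, 0, 1), (1, 0, 0))
        edge = pair_rate(d, a, FretParams(coupling=1.0, n=1.0))
        assert edge.kappa2 == pytest.approx(1.0)
        assert edge.k_fret == pytest.approx(1.0)
        assert edge.tau_transfer == pytest.approx(1.0)

    def test_r_minus_6_law(self):
        params = FretParams(coupling=1.0, n=1.0, r_max=1e9)
        d = _dipole((0, 0, 0), (1, 0, 0))
        near = pair_rate(d, _dipole((0, 0, 5), (1, 0, 0)), params)
        far = pair_rate(d, _dipole((0, 0, 10), (1, 0, 0)), params)
        assert near.k_fret / far.k_fret == pytest.approx(64.0, rel=1e-9)

    def test_n_minus_4_law(self):
        d = _dipole((0, 0, 0), (1, 0, 0))
        a = _dipole((0, 0, 5), (1, 0, 0))
        k1 = pair_rate(d, a, FretParams(n=1.0)).k_fret
        k2 = pair_rate(d, a, FretParams(n=np.sqrt(2.0))).k_fret
        assert k1 / k2 == pytest.approx(4.0, rel=1e-9)

    def test_scaling_invariant_k_times_r6(self):
        params = FretParams(coupling=2.5, n=1.4, r_max=1e9)
        d = _dipole((0, 0, 0), (1, 0, 0))
        products = [
            pair_rate(d, _dipole((0, 0, R), (1, 0, 0)), params).k_fret * R**6
            for R in (3.0, 7.0, 19.0, 29.0)]
        assert np.allclose(products, products[0], rtol=1e-9)

    def test_rate_symmetry_with_symmetric_coupling(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            d = _dipole(rng.uniform(-5, 5, 3), rng.normal(size=3))
            a = _dipole(rng.uniform(6, 15, 3), rng.normal(size=3))
            params = FretParams(coupling=1.7, n=1.3)
            assert pair_rate(d, a, params).k_fret == \
                pair_rate(a, d, params).k_fret

    def test_per_class_coupling(self):
        d = _dipole((0, 0, 0), (1, 0, 0))
        a = _dipole((0, 0, 5), (1, 0, 0))
        params = FretParams(coupling={("CHL_B", "CHL_A"): 2.0,
                                      ("CHL_A", "CHL_A"): 1.0})
        kba = pair_rate(d, a, params, classes=("CHL_B", "CHL_A")).k_fret
        kaa = pair_rate(d, a, params, classes=("CHL_A", "CHL_A")).k_fret
        assert kba == pytest.approx(2.0 * kaa)


class TestBuildNetwork:
    def test_three_collinear_chlorins(self):
        pigments = [
            make_chlorin((10.0 * i, 0, 0), (0, 0, 1), (0, 1, 0),
                         chain_id="A", residue_number=601 + i)
            for i in range(3)]
        net = build_network(pigments, FretParams(r_max=1e9))
        assert net.graph.number_of_edges() == 6
        k_near = net.graph["A:601"]["A:602"]["k_fret"]
        k_far = net.graph["A:601"]["A:603"]["k_fret"]
        assert k_near / k_far == pytest.approx(64.0, rel=1e-9)

    def test_r_max_below_all_separations_gives_empty_network(self):
        pigments = [
            make_chlorin((30.0 * i, 0, 0), (0, 0, 1), (0, 1, 0),
                         chain_id="A", residue_number=601 + i)
            for i in range(3)]
        net = build_network(pigments, FretParams(r_max=5.0))
        assert net.graph.number_of_edges() == 0

    def test_matches_oracle_edge_table(self, toy_complex):
        model, truth, params = toy_complex
        net = build_network(extract_pigments(model), params)
        got = net.to_dataframe().sort_values(
            ["donor", "acceptor"]).reset_index(drop=True)
        want = truth.edges.sort_values(
            ["donor", "acceptor"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want, rtol=1e-12, atol=1e-15)

    def test_degenerate_chlorins_excluded_from_nodes(self, toy_complex):
        model, _, params = toy_complex
        pigments = extract_pigments(model)
        pigments[0].degenerate = True
        net = build_network(pigments, params)
        assert pigments[0].node_id not in net.graph


class TestIntersubunitMatrix:
    def _two_node_net(self, k=0.5):
        net = EETNetwork()
        net.graph.add_node("A:601", chain="A")
        net.graph.add_node("B:601", chain="B")
        net.graph.add_edge("A:601", "B:601", R=5.0, kappa2=1.0,
                           k_fret=k, tau=1 / k)
        net.graph.add_edge("B:601", "A:601", R=5.0, kappa2=1.0,
                           k_fret=k, tau=1 / k)
        return net

    def test_single_edge_pair(self):
        mat = intersubunit_matrix(self._two_node_net(0.5),
                                  {"A:601": "sub1", "B:601": "sub2"})
        assert mat.loc["sub1", "sub2"] == pytest.approx(0.5)
        assert mat.loc["sub2", "sub1"] == pytest.approx(0.5)
        assert mat.loc["sub1", "sub1"] == 0.0

    def test_ungrouped_node_raises(self):
        with pytest.raises(GroupingError):
            intersubunit_matrix(self._two_node_net(), {"A:601": "sub1"})

    def test_permutation_conjugates_matrix(self, toy_complex):
        model, _, params = toy_complex
        net = build_network(extract_pigments(model), params)
        grouping = {n: d["chain"] for n, d in net.graph.nodes(data=True)}
        mat = intersubunit_matrix(net, grouping)
        renamed = {n: {"A": "zz", "B": "aa"}[g] for n, g in grouping.items()}
        mat2 = intersubunit_matrix(net, renamed)
        assert mat.loc["A", "B"] == pytest.approx(mat2.loc["zz", "aa"])
        assert mat.loc["B", "A"] == pytest.approx(mat2.loc["aa", "zz"])

    def test_aggregate_conservation(self, toy_complex):
        model, _, params = toy_complex
        net = build_network(extract_pigments(model), params)
        grouping = {n: d["chain"] for n, d in net.graph.nodes(data=True)}
        mat = intersubunit_matrix(net, grouping)
        df = net.to_dataframe()
        inter = df[df.donor.str[0] != df.acceptor.str[0]].k_per_ps.sum()
        assert mat.to_numpy().sum() == pytest.approx(inter, rel=1e-12)


def _manual_net(edges):
    """EETNetwork from (u, v, tau) triples; node chain = first character."""
    net = EETNetwork()
    for u, v, tau in edges:
        for n in (u, v):
            if n not in net.graph:
                net.graph.add_node(n, chain=n[0])
        net.graph.add_edge(u, v, R=1.0, kappa2=1.0, k_fret=1.0 / tau, tau=tau)
    return net


class TestFastestPaths:
    def test_linear_chain(self):
        net = _manual_net([("A:1", "B:1", 1.0), ("B:1", "C:1", 1.0)])
        [(path, cost)] = fastest_paths(net, "A", "C", 1)
        assert path == ["A:1", "B:1", "C:1"]
        assert cost == pytest.approx(2.0)

    def test_two_hop_beats_direct_slow_edge(self):
        net = _manual_net([("A:1", "C:1", 10.0), ("A:1", "B:1", 2.0),
                           ("B:1", "C:1", 2.0)])
        paths = fastest_paths(net, "A", "C", 2)
        assert paths[0][0] == ["A:1", "B:1", "C:1"]
        assert paths[0][1] == pytest.approx(4.0)
        assert paths[1][1] == pytest.approx(10.0)

    def test_no_route_returns_empty(self):
        net = _manual_net([("A:1", "B:1", 1.0), ("C:1", "B:1", 1.0)])
        assert fastest_paths(net, "A", "C", 3) == []

    def test_empty_subunit_raises(self):
        net = _manual_net([("A:1", "B:1", 1.0)])
        with pytest.raises(GroupingError):
            fastest_paths(net, "A", "X", 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        """Oracle: enumerate every simple path on random 8-node graphs."""
        rng = np.random.default_rng(seed)
        nodes = [f"{c}:{i}" for c in "AB" for i in range(4)]
        edges = []
        for u, v in itertools.permutations(nodes, 2):
            if rng.uniform() < 0.35:
                edges.append((u, v, float(rng.uniform(0.5, 20.0))))
        net = _manual_net(edges) if edges else None
        if net is None or not any(n.startswith("A") for n in net.graph) \
                or not any(n.startswith("B") for n in net.graph):
            pytest.skip("degenerate random draw")
        k = 4
        got = fastest_paths(net, "A", "B", k)

        G = nx.DiGraph()
        for u, v, tau in edges:
            G.add_edge(u, v, tau=tau)
        sources = [n for n in G if n.startswith("A")]
        sinks = [n for n in G if n.startswith("B")]
        all_paths = []
        for s in sources:
            for t in sinks:
                if s == t or not G.has_node(s) or not G.has_node(t):
                    continue
                for p in nx.all_simple_paths(G, s, t):
                    cost = sum(G[u][v]["tau"] for u, v in zip(p[:-1], p[1:]))
                    all_paths.append((cost, len(p) - 1, p))
        want = sorted(all_paths)[:k]
        assert len(got) == len(want)
        for (gp, gc), (wc, _, wp) in zip(got, want):
            assert gc == pytest.approx(wc, rel=1e-12)
            assert gp == wp


class TestDetectRedPairs:
    def test_coplanar_pair_detected(self):
        a = make_chlorin((0, 0, 0), (0, 0, 1), (1, 0, 0),
                         chain_id="A", residue_number=603)
        b = make_chlorin((8, 0, 0), (0, 0, 1), (1, 0, 0),
                         chain_id="A", residue_number=609)
        pairs = detect_red_pairs([a, b], d_max=10.0, angle_max=30.0)
        assert len(pairs) == 1
        assert pairs.iloc[0]["mg_mg_A"] == pytest.approx(8.0)

    def test_tilted_pair_rejected(self):
        a = make_chlorin((0, 0, 0), (0, 0, 1), (1, 0, 0),
                         chain_id="A", residue_number=603)
        b = make_chlorin((8, 0, 0),
                         (0, np.sin(np.radians(80)), np.cos(np.radians(80))),
                         (1, 0, 0), chain_id="A", residue_number=609)
        assert len(detect_red_pairs([a, b], d_max=10.0, angle_max=30.0)) == 0

    def test_chl_b_pairs_ignored(self):
        a = make_chlorin((0, 0, 0), (0, 0, 1), (1, 0, 0), kind="CHL_B",
                         chain_id="A", residue_number=606)
        b = make_chlorin((8, 0, 0), (0, 0, 1), (1, 0, 0), kind="CHL_B",
                         chain_id="A", residue_number=607)
        assert len(detect_red_pairs([a, b])) == 0

    def test_planted_pairs_among_background(self):
        """Three planted coplanar close dimers among well-separated chlorins."""
        rng = np.random.default_rng(9)
        model, _ = make_toy_complex(n_chains=4, chlorins_per_chain=10,
                                    box=120.0, min_sep=12.0, seed=9)
        pigments = extract_pigments(model)
        planted = []
        for k in range(3):
            base = np.array([200.0 + 40.0 * k, 0.0, 0.0])
            normal = rng.normal(size=3)
            a = make_chlorin(base, normal, rng.normal(size=3),
                             chain_id="P", residue_number=603 + 10 * k)
            b = make_chlorin(base + 8.0 * _perp(normal), normal,
                             rng.normal(size=3),
                             chain_id="P", residue_number=609 + 10 * k)
            planted += [a, b]
        pairs = detect_red_pairs(pigments + planted,
                                 d_max=10.0, angle_max=35.0)
        found = {tuple(sorted((r.a, r.b))) for r in pairs.itertuples()}
        want = {tuple(sorted((a.node_id, b.node_id)))
                for a, b in zip(planted[::2], planted[1::2])}
        assert found == want


def _perp(v):
    v = np.asarray(v, float) / np.linalg.norm(v)
    w = np.cross(v, [1.0, 0.0, 0.0])
    if np.linalg.norm(w) < 1e-6:
        w = np.cross(v, [0.0, 1.0, 0.0])
    return w / np.linalg.norm(w)
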