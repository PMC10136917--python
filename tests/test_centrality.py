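"""Expected influence, bridge centrality, bridge selection and flow layering."""

import numpy as np
import pandas as pd
import pytest

from tinnet.centrality import (
    bridge_expected_influence,
    centrality_profile,
    expected_influence,
    flow_network,
    select_bridges,
    z_standardize,
)

from .conftest import toy_network


class TestExpectedInfluence:
    def test_empty_network_has_zero_influence(self):
        net = toy_network(["A", "B", "C"], {})
        assert (expected_influence(net) == 0).all()

    def test_toy_signed_sums(self):
        net = toy_network(["A", "B", "C"], {("A", "B"): 0.5, ("A", "C"): -0.2})
        ei = expected_influence(net)
        assert ei["A"] == pytest.approx(0.3)
        assert ei["B"] == pytest.approx(0.5)
        assert ei["C"] == pytest.approx(-0.2)

    def test_positive_node_influence_equals_strength(self):
        net = toy_network(["A", "B", "C"], {("A", "B"): 0.4, ("A", "C"): 0.1})
        ei = expected_influence(net)
        assert ei["A"] == pytest.approx(np.abs(net.W[0]).sum())

    def test_handshake_identity(self, default_cohort):
        net = default_cohort.truth.as_network()
        iu = np.triu_indices(net.p, 1)
        assert expected_influence(net).sum() == pytest.approx(
            2 * net.W[iu].sum(), abs=1e-10
        )


class TestBridgeExpectedInfluence:
    comm = {"A": "left", "B": "left", "C": "right", "D": "right"}

    def test_separated_communities_have_zero_bridge(self):
        net = toy_network(
            ["A", "B", "C", "D"], {("A", "B"): 0.3, ("C", "D"): 0.2}, self.comm
        )
        assert (bridge_expected_influence(net) == 0).all()

    def test_single_cross_edge_scores_both_endpoints(self):
        net = toy_network(
            ["A", "B", "C", "D"],
            {("A", "B"): 0.3, ("B", "C"): 0.4, ("C", "D"): 0.1},
            self.comm,
        )
        bei = bridge_expected_influence(net)
        assert bei["B"] == pytest.approx(0.4)
        assert bei["C"] == pytest.approx(0.4)
        assert bei["A"] == 0 and bei["D"] == 0

    def test_ei_minus_bei_is_within_community_degree(self, default_cohort):
        net = default_cohort.truth.as_network()
        ei = expected_influence(net)
        bei = bridge_expected_influence(net)
        comm = np.array([net.communities[l] for l in net.labels])
        within = (net.W * (comm[:, None] == comm[None, :])).sum(axis=1)
        assert np.allclose(ei - bei, within, atol=1e-12)

    def test_bridge_handshake_identity(self, default_cohort):
        net = default_cohort.truth.as_network()
        comm = np.array([net.communities[l] for l in net.labels])
        cross = comm[:, None] != comm[None, :]
        cross_sum = (net.W * cross)[np.triu_indices(net.p, 1)][
            cross[np.triu_indices(net.p, 1)]
        ].sum()
        assert bridge_expected_influence(net).sum() == pytest.approx(
            2 * cross_sum, abs=1e-10
        )

    def test_missing_community_label_raises(self):
        net = toy_network(["A", "B", "C", "D"], {("A", "C"): 0.2})
        net.communities = {}
        with pytest.raises(ValueError):
            bridge_expected_influence(net)


class TestSelectBridges:
    def test_sixteen_distinct_scores_match_brute_force_percentile(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(
            rng.permutation(np.linspace(-0.2, 0.6, 16)),
            index=[f"n{i}" for i in range(16)],
        )
        # oracle: type-7 percentile by explicit interpolation over order stats
        srt = np.sort(vals.to_numpy())
        h = 0.80 * (16 - 1)
        lo = int(np.floor(h))
        thr = srt[lo] + (h - lo) * (srt[lo + 1] - srt[lo]) if lo + 1 < 16 else srt[lo]
        expected = {n for n, v in vals.items() if v >= thr}
        assert set(select_bridges(vals)) == expected
        # h = 12 exactly, so the threshold is the 4th-largest value itself
        assert len(expected) == 4

    def test_all_equal_scores_select_everyone(self):
        vals = pd.Series(0.3, index=list("abcdef"))
        assert set(select_bridges(vals)) == set("abcdef")

    def test_selection_monotone_in_single_score(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(rng.normal(size=10), index=[f"n{i}" for i in range(10)])
        selected = set(select_bridges(vals))
        for node in selected:
            bumped = vals.copy()
            bumped[node] += 1.0
            assert node in select_bridges(bumped)


class TestZStandardize:
    def test_mean_zero_unit_sd(self):
        z = z_standardize(pd.Series([3.0, 1.0, 4.0, 1.0, 5.0]))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self):
        x = pd.Series([0.1, 0.5, -0.2, 0.9])
        assert np.allclose(z_standardize(x), z_standardize(3 * x + 7), atol=1e-12)

    def test_fixed_vector_matches_hand_computation(self):
        x = pd.Series([1.0, 2.0, 3.0, 6.0])
        sd = np.sqrt(((1 - 3) ** 2 + (2 - 3) ** 2 + 0 + (6 - 3) ** 2) / 3)
        assert np.allclose(z_standardize(x), (x - 3.0) / sd, atol=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            z_standardize(pd.Series([1.0, 1.0, 1.0]))


class TestCentralityProfile:
    def test_profile_flags_match_raw_bei_rule(self, default_cohort):
        net = default_cohort.truth.as_network()
        profile = centrality_profile(net)
        bei = bridge_expected_influence(net)
        assert set(profile.bridges) == set(select_bridges(bei))
        assert profile.table["EI_z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert profile.table["BEI_z"].std(ddof=1) == pytest.approx(1.0)


class TestFlowNetwork:
    def test_star_topology_is_all_direct(self):
        net = toy_network(
            ["F", "A", "B", "C"],
            {("F", "A"): 0.2, ("F", "B"): -0.4, ("F", "C"): 0.1},
        )
        flow = flow_network(net, "F")
        assert [n for n, _ in flow.direct] == ["B", "A", "C"]  # by |weight|
        assert flow.n_indirect == 0 and not flow.unreachable

    def test_chain_layers_by_hops(self):
        net = toy_network(["A", "B", "C"], {("A", "B"): 0.3, ("B", "C"): 0.3})
        flow = flow_network(net, "A")
        assert [n for n, _ in flow.direct] == ["B"]
        assert flow.indirect_layers == {2: ["C"]}

    def test_toy_six_node_counts_match_bfs_oracle(self):
        labels = ["F", "A", "B", "C", "D", "E"]
        edges = {
            ("F", "A"): 0.3, ("F", "B"): 0.2, ("F", "C"): -0.1,
            ("A", "D"): 0.4, ("B", "E"): 0.0,  # zero weight: E stays isolated
        }
        net = toy_network(labels, {k: v for k, v in edges.items() if v != 0})
        # oracle: hand BFS over the nonzero adjacency
        adj = {l: set() for l in labels}
        for (a, b), w in edges.items():
            if w != 0:
                adj[a].add(b)
                adj[b].add(a)
        dist = {"F": 0}
        frontier = ["F"]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        flow = flow_network(net, "F")
        assert flow.n_direct == sum(1 for l in labels if dist.get(l) == 1)
        assert flow.n_indirect == sum(1 for l in labels if dist.get(l, 0) >= 2)
        assert flow.unreachable == [l for l in labels if l not in dist]
        for layer, nodes in flow.indirect_layers.items():
            assert all(dist[n] == layer for n in nodes)

    def test_unknown_focal_raises_lookup_error(self, default_cohort):
        with pytest.raises(KeyError):
            flow_network(default_cohort.truth.as_network(), "nope")
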