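"""Node centrality for symptom networks.

Expected influence (EI) is the signed one-step sum of a node's edge weights;
bridge expected influence (BEI) restricts the sum to edges crossing into the
other community.  Bridge symptoms are flagged by the conventional blind 80th
percentile cut-off on the raw BEI distribution.  The flow decomposition lays
out every symptom by its hop distance from one focal symptom (here typically
suicidal ideation), separating direct neighbours from indirect relays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import EDGE_EPS, SymptomNetwork

__all__ = [
    "CentralityProfile",
    "FlowDecomposition",
    "expected_influence",
    "bridge_expected_influence",
    "select_bridges",
    "z_standardize",
    "centrality_profile",
    "flow_network",
]


def expected_influence(net: SymptomNetwork) -> pd.Series:
    """One-step expected influence: EI_i = sum_j W_ij (signed)."""
    return pd.Series(net.W.sum(axis=1), index=net.labels, name="EI")


def bridge_expected_influence(net: SymptomNetwork) -> pd.Series:
    """Signed sum of each node's edges into the other community."""
    if not net.communities:
        raise ValueError("network has no community labels")
    missing = [l for l in net.labels if l not in net.communities]
    if missing:
        raise ValueError(f"nodes without community label: {missing}")
    comm = np.array([net.communities[l] for l in net.labels])
    if len(set(comm)) < 2:
        raise ValueError("bridge influence needs at least 2 communities")
    cross = comm[:, None] != comm[None, :]
    return pd.Series((net.W * cross).sum(axis=1), index=net.labels, name="BEI")


def select_bridges(bei: pd.Series, percentile: float = 80.0) -> list[str]:
    """Nodes at or above the given percentile of the raw BEI distribution.

    The percentile uses linear interpolation between order statistics
    (numpy's default, R type-7); ties at the threshold are all included.
    """
    if len(bei) < 2:
        raise ValueError("bridge selection needs at least 2 nodes")
    threshold = np.percentile(bei.to_numpy(), percentile)
    return [node for node, v in bei.items() if v >= threshold]


def z_standardize(values: pd.Series) -> pd.Series:
    """(x - mean) / sample SD; raises on zero spread."""
    sd = values.std(ddof=1)
    if not sd > 0:
        raise ValueError("cannot z-standardise a constant vector")
    return (values - values.mean()) / sd


@dataclass
class CentralityProfile:
    """Raw and z-scored EI/BEI per node, with the bridge flags."""

    table: pd.DataFrame  # index: node; columns: community, EI, EI_z, BEI, BEI_z, is_bridge
    percentile: float = 80.0

    @property
    def bridges(self) -> list[str]:
        return list(self.table.index[self.table["is_bridge"]])


def centrality_profile(
    net: SymptomNetwork, percentile: float = 80.0
) -> CentralityProfile:
    """EI, BEI (raw + z) and percentile-rule bridge flags for every node.

    Selection operates on raw BEI; z-scores are for display.
    """
    ei = expected_influence(net)
    bei = bridge_expected_influence(net)
    bridges = set(select_bridges(bei, percentile))
    table = pd.DataFrame(
        {
            "community": [net.communities[l] for l in net.labels],
            "EI": ei,
            "EI_z": z_standardize(ei),
            "BEI": bei,
            "BEI_z": z_standardize(bei),
            "is_bridge": [l in bridges for l in net.labels],
        }
    )
    return CentralityProfile(table=table, percentile=percentile)


@dataclass
class FlowDecomposition:
    """One focal symptom's connections layered by hop distance.

    ``direct`` holds (neighbour, weight) sorted by |weight| descending;
    ``indirect_layers`` maps hop distance (>= 2) to the nodes at that
    distance; ``unreachable`` lists nodes with no path to the focal node.
    """

    focal: str
    direct: list[tuple[str, float]]
    indirect_layers: dict[int, list[str]] = field(default_factory=dict)
    unreachable: list[str] = field(default_factory=list)

    @property
    def n_direct(self) -> int:
        return len(self.direct)

    @property
    def n_indirect(self) -> int:
        return sum(len(v) for v in self.indirect_layers.values())

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "direct": [
                {"node": n, "weight": w} for n, w in self.direct
            ],
            "indirect_layers": {
                str(k): v for k, v in sorted(self.indirect_layers.items())
            },
            "unreachable": self.unreachable,
        }


def flow_network(net: SymptomNetwork, focal: str) -> FlowDecomposition:
    """BFS layering of all symptoms around one focal symptom.

    Direct nodes share a nonzero edge with the focal node and are ranked by
    absolute weight; remaining nodes are layered by unweighted shortest-path
    hop count through nonzero edges, with unreachable nodes reported apart.
    """
    if focal not in net.labels:
        raise KeyError(f"focal node {focal!r} not in network")
    G = net.to_graph()
    f = net.labels.index(focal)
    direct = sorted(
        (
            (net.labels[j], float(net.W[f, j]))
            for j in range(net.p)
            if j != f and abs(net.W[f, j]) > EDGE_EPS
        ),
        key=lambda t: (-abs(t[1]), t[0]),
    )
    dist = nx.single_source_shortest_path_length(G, focal)
    indirect: dict[int, list[str]] = {}
    for node in net.labels:
        d = dist.get(node)
        if d is not None and d >= 2:
            indirect.setdefault(d, []).append(node)
    unreachable = [n for n in net.labels if n not in dist]
    return FlowDecomposition(
        focal=focal, direct=direct, indirect_layers=indirect,
        unreachable=unreachable,
    )
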