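"""Co-occurrence networks over the 47 analysis items, stratified by post
length.

Blogs, online cafés and message boards allow long posts; Twitter posts are
capped at 140 characters, so the two strata are built separately
(``longform`` vs ``twitter``). Nodes are analysis items with a frequency
(posts mentioning the item) and a degree (distinct co-mentioned items);
an undirected edge's weight counts the posts mentioning both endpoints —
post-level count-once semantics carried through from coding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .coding import TransactionSet
from .frequency import round_half_up
from .lexicon import CHANNELS

__all__ = [
    "STRATA",
    "CooccurrenceNetwork",
    "build_network",
    "top_nodes",
    "top_edges",
]

STRATA: dict[str, tuple[str, ...]] = {
    "longform": ("blog", "cafe", "board"),
    "twitter": ("twitter",),
}


@dataclass
class CooccurrenceNetwork:
    stratum: str
    n_posts: int
    universe: int  # size of the item catalog the network was built over
    nodes: dict[str, tuple[int, int]]  # item -> (frequency, degree)
    edges: dict[tuple[str, str], int]  # sorted item pair -> post count

    def frequency(self, item: str) -> int:
        return self.nodes[item][0]

    def degree(self, item: str) -> int:
        return self.nodes[item][1]

    def weight(self, a: str, b: str) -> int:
        return self.edges.get(tuple(sorted((a, b))), 0)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(stratum=self.stratum, n_posts=self.n_posts)
        for item, (freq, deg) in self.nodes.items():
            g.add_node(item, frequency=freq, degree=deg)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"item_a": a, "item_b": b, "weight": w}
            for (a, b), w in sorted(
                self.edges.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["item_a", "item_b", "weight"])


def build_network(
    transactions: TransactionSet, stratum: str
) -> CooccurrenceNetwork:
    """Count pairwise co-mentions within one length stratum.

    Every unordered pair of items present in a post adds 1 to that edge;
    items never mentioned in the stratum are omitted from the node set.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected {sorted(STRATA)}")
    seen = set(transactions.channels.unique())
    unknown = seen - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels in transactions: {sorted(unknown)}")
    mask = transactions.channels.isin(STRATA[stratum]).to_numpy()
    X = transactions.matrix[mask].astype(np.int64)
    co = X.T @ X  # co[i, j] = posts mentioning both i and j; diagonal = frequency
    items = transactions.items
    freqs = np.diag(co)
    nodes: dict[str, tuple[int, int]] = {}
    edges: dict[tuple[str, str], int] = {}
    for i, a in enumerate(items):
        if freqs[i] == 0:
            continue
        degree = int(np.count_nonzero(co[i]) - (1 if freqs[i] else 0))
        nodes[a] = (int(freqs[i]), degree)
        for j in range(i + 1, len(items)):
            if co[i, j]:
                key = tuple(sorted((a, items[j])))
                edges[key] = int(co[i, j])
    return CooccurrenceNetwork(
        stratum=stratum,
        n_posts=int(mask.sum()),
        universe=len(items),
        nodes=nodes,
        edges=edges,
    )


def top_nodes(network: CooccurrenceNetwork, fraction: float) -> pd.DataFrame:
    """Top ``ceil(fraction × universe)`` nodes by frequency.

    Ties break by degree, then identifier. Percentages use the stratum's
    post count as denominator, so multi-label shares can exceed 50%.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    k = math.ceil(fraction * network.universe)
    ranked = sorted(
        network.nodes.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0])
    )[:k]
    rows = [
        {
            "item": item,
            "frequency": freq,
            "percent": round_half_up(100.0 * freq / network.n_posts)
            if network.n_posts
            else 0.0,
            "degree": deg,
        }
        for item, (freq, deg) in ranked
    ]
    return pd.DataFrame(rows, columns=["item", "frequency", "percent", "degree"])


def top_edges(network: CooccurrenceNetwork, k: int) -> pd.DataFrame:
    """The ``k`` heaviest edges (all edges when k exceeds the edge count)."""
    frame = network.edge_frame()
    return frame.head(k).reset_index(drop=True)
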