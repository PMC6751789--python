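"""Linking components across omics layers by weight correlation.

Components found independently in mRNA and miRNA data often describe the
same underlying signal (an immune infiltrate, a stromal programme, a batch
artifact).  Because each component carries a weight row over samples, two
components — within or across layers — are linked whenever the squared
Pearson correlation of their weight rows over the shared samples exceeds a
threshold (r² > 0.25 by default, i.e. |r| > 0.5).  Connected groups of
linked components form clusters that can be read as one multi-omics
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .ica import ConsensusICAResults

__all__ = ["ComponentGraph", "link_components", "cluster_components"]


@dataclass
class ComponentGraph:
    """Undirected graph of components linked by weight correlation.

    Nodes are ``layer:component`` strings; each edge carries the signed
    Pearson r and r² of the two weight rows.  ``shared_samples`` records
    which samples the correlations were computed on.
    """

    graph: nx.Graph
    threshold: float
    shared_samples: list[str] = field(default_factory=list)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [(a, b, d["r"], d["r2"]) for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "r2"])

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def link_components(results_a: ConsensusICAResults,
                    results_b: ConsensusICAResults | None = None,
                    r2_threshold: float = 0.25,
                    layers: tuple[str, str] = ("mRNA", "miRNA")
                    ) -> ComponentGraph:
    """Build the component graph from two decompositions (or one, within-layer).

    With two decompositions, every cross-layer pair of weight rows is
    correlated over the shared samples; with a single decomposition (or
    ``results_b is results_a``) all within-layer pairs are used, excluding
    self-pairs.  An edge is added when r² strictly exceeds the threshold.
    """
    within = results_b is None or results_b is results_a
    if within:
        results_b = results_a
        layers = (layers[0], layers[0])
    shared = [s for s in results_a.sample_ids
              if s in set(results_b.sample_ids)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples between decompositions")

    Wa = results_a.weights[shared].to_numpy(dtype=float)
    Wb = results_b.weights[shared].to_numpy(dtype=float)
    ids_a = [f"{layers[0]}:{c}" for c in results_a.component_ids]
    ids_b = [f"{layers[1]}:{c}" for c in results_b.component_ids]

    G = nx.Graph()
    for node, layer in [*[(i, layers[0]) for i in ids_a],
                        *[(i, layers[1]) for i in ids_b]]:
        G.add_node(node, layer=layer)

    def _corr(u: np.ndarray, v: np.ndarray) -> float:
        return float(np.corrcoef(u, v)[0, 1])

    for i, na in enumerate(ids_a):
        for j, nb in enumerate(ids_b):
            if within and j <= i:
                continue
            r = _corr(Wa[i], Wb[j])
            if r * r > r2_threshold:
                G.add_edge(na, nb, r=r, r2=r * r)
    return ComponentGraph(graph=G, threshold=r2_threshold,
                          shared_samples=shared)


def cluster_components(G: ComponentGraph) -> list[dict]:
    """Connected components of the link graph.

    Returns one dict per cluster with sorted ``members`` and the cluster's
    internal ``edges`` table; singletons are included (no edges).  Output
    order is by decreasing size, ties by first member id, so it does not
    depend on node insertion order.
    """
    clusters = []
    for comp in nx.connected_components(G.graph):
        members = sorted(comp)
        sub = G.graph.subgraph(comp)
        edges = pd.DataFrame(
            [(a, b, d["r"], d["r2"]) for a, b, d in sub.edges(data=True)],
            columns=["node_a", "node_b", "r", "r2"])
        clusters.append({"members": members, "edges": edges})
    clusters.sort(key=lambda c: (-len(c["members"]), c["members"][0]))
    return clusters
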