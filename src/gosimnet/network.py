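"""Gene functional-association networks.

A node is a gene; an edge connects two genes whose similarity score is
strictly greater than the chosen edge similarity threshold. The module
covers network construction, the score distribution used to pick a
threshold, subnetwork selection around genes of interest, and
deterministic export in formats a graph viewer can load.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import UsageError
from .gene_measures import GeneSimilarityMatrix

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("edge-tsv", "graphml", "cytoscape-json")


@dataclass
class AssociationNetwork:
    """Thresholded weighted gene graph with provenance.

    Undirected, no self-loops; every edge's ``score`` attribute is strictly
    greater than ``threshold``. Isolated genes stay in the node set so the
    fraction of connected genes is visible.
    """

    graph: nx.Graph
    threshold: float
    measure: str

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(a, b), max(a, b), d["score"])
            for a, b, d in self.graph.edges(data=True)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationNetwork):
            return NotImplemented
        rounded = lambda net: [(a, b, round(s, 6)) for a, b, s in net.edges]
        return (
            self.nodes == other.nodes
            and rounded(self) == rounded(other)
            and round(self.threshold, 6) == round(other.threshold, 6)
            and self.measure == other.measure
        )


def build_network(matrix: GeneSimilarityMatrix, threshold: float) -> AssociationNetwork:
    """Keep edges with score strictly greater than the threshold; ties at
    the threshold are excluded. A threshold above the maximum score yields
    a valid edgeless network (warned, not an error)."""
    g = nx.Graph()
    g.add_nodes_from(sorted(matrix.genes))
    off_diag = matrix.pairs()
    for a, b in off_diag:
        s = matrix.scores[(a, b)]
        if s > threshold:
            g.add_edge(a, b, score=float(s))
    if off_diag and g.number_of_edges() == 0:
        logger.warning(
            "threshold %g exceeds the maximum %s score %g; network has no edges",
            threshold, matrix.measure, max(matrix.scores[p] for p in off_diag),
        )
    return AssociationNetwork(graph=g, threshold=float(threshold), measure=matrix.measure)


def score_histogram(matrix: GeneSimilarityMatrix, bins: int = 10) -> pd.DataFrame:
    """Distribution of all off-diagonal pair scores; the counts always sum
    to C(n, 2). Used to choose an edge similarity threshold."""
    if bins < 1:
        raise UsageError(f"bins must be >= 1, got {bins}")
    scores = np.array([matrix.scores[p] for p in matrix.pairs()], dtype=float)
    counts, edges = np.histogram(scores, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def select_subnetwork(
    network: AssociationNetwork,
    genes: list[str],
    include_neighbors: bool = False,
) -> AssociationNetwork:
    """Induced subgraph on a gene subgroup, optionally widened by the
    selected genes' direct neighbors. Unknown genes are reported and
    ignored; an empty selection gives an empty network."""
    known = [g for g in genes if g in network.graph]
    unknown = sorted(set(genes) - set(known))
    if unknown:
        logger.warning("subnetwork selection: %d unknown gene(s) ignored: %s",
                       len(unknown), ", ".join(unknown))
    nodes = set(known)
    if include_neighbors:
        for g in known:
            nodes.update(network.graph.neighbors(g))
    sub = network.graph.subgraph(nodes).copy()
    return AssociationNetwork(
        graph=sub, threshold=network.threshold, measure=network.measure
    )


# -- export / import -------------------------------------------------------


def _sorted_copy(network: AssociationNetwork) -> nx.Graph:
    """Rebuild with sorted node/edge insertion so writers emit stable bytes."""
    g = nx.Graph()
    g.graph["threshold"] = network.threshold
    g.graph["measure"] = network.measure
    for n in network.nodes:
        g.add_node(n, **network.graph.nodes[n])
    for a, b, s in network.edges:
        g.add_edge(a, b, score=round(float(s), 6))
    return g


def export_network(network: AssociationNetwork, fmt: str, path: str | Path) -> None:
    """Write the network as edge-tsv, graphml or cytoscape-json.

    Output is bit-stable for identical input (sorted nodes and edges,
    scores rounded to 6 decimals) and round-trips through
    :func:`read_network`.
    """
    path = Path(path)
    if fmt == "edge-tsv":
        lines = [
            f"#measure={network.measure}",
            f"#threshold={network.threshold!r}",
            "#nodes=" + ",".join(network.nodes),
            "gene1\tgene2\tscore",
        ]
        lines += [f"{a}\t{b}\t{s:.6f}" for a, b, s in network.edges]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "graphml":
        nx.write_graphml(_sorted_copy(network), path)
    elif fmt == "cytoscape-json":
        g = _sorted_copy(network)
        payload = nx.cytoscape_data(g)
        payload["data"] = {"threshold": network.threshold, "measure": network.measure}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise UsageError(f"unknown export format {fmt!r}; expected one of {EXPORT_FORMATS}")


def read_network(path: str | Path, fmt: str) -> AssociationNetwork:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if fmt == "edge-tsv":
        measure, threshold, nodes = "", 0.0, []
        g = nx.Graph()
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if line.startswith("#measure="):
                    measure = line.split("=", 1)[1]
                elif line.startswith("#threshold="):
                    threshold = float(line.split("=", 1)[1])
                elif line.startswith("#nodes="):
                    nodes = [n for n in line.split("=", 1)[1].split(",") if n]
                elif line.startswith("#") or line.startswith("gene1\t") or not line:
                    continue
                else:
                    a, b, s = line.split("\t")
                    g.add_edge(a, b, score=float(s))
        g.add_nodes_from(nodes)
        return AssociationNetwork(graph=g, threshold=threshold, measure=measure)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        g2 = nx.Graph()
        g2.add_nodes_from(g.nodes)
        for a, b, d in g.edges(data=True):
            g2.add_edge(a, b, score=float(d["score"]))
        return AssociationNetwork(
            graph=g2,
            threshold=float(g.graph.get("threshold", 0.0)),
            measure=str(g.graph.get("measure", "")),
        )
    if fmt == "cytoscape-json":
        payload = json.loads(path.read_text())
        g = nx.cytoscape_graph(payload)
        g2 = nx.Graph()
        g2.add_nodes_from(str(n) for n in g.nodes)
        for a, b, d in g.edges(data=True):
            g2.add_edge(str(a), str(b), score=float(d["score"]))
        meta = payload.get("data", {})
        return AssociationNetwork(
            graph=g2,
            threshold=float(meta.get("threshold", 0.0)),
            measure=str(meta.get("measure", "")),
        )
    raise UsageError(f"unknown import format {fmt!r}; expected one of {EXPORT_FORMATS}")
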