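"""Phenotypic disease networks (PDNs) from binary comorbidity flags.

A PDN is an undirected weighted graph: nodes are diseases observed in the
patient subset (zero-prevalence diseases are omitted), and an edge joins two
diseases with weight equal to their co-occurrence prevalence — the fraction
of subset patients carrying both.  Edges with weight strictly below the
threshold (default 2%) are discarded; a weight exactly at the threshold is
retained.  Node degree and the unweighted average clustering coefficient are
the headline summary metrics: a complete graph over d diseases has
d(d-1)/2 edges, average degree d-1, and clustering coefficient exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import NetworkError


@dataclass
class DiseaseNetwork:
    """Wraps the networkx graph plus the subset size it was built from."""

    graph: nx.Graph
    n_patients: int

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"disease_a": a, "disease_b": b, "weight": d["weight"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["disease_a", "disease_b", "weight"])


def build_pdn(flags: pd.DataFrame, edge_threshold: float = 0.02) -> DiseaseNetwork:
    """Build the PDN of a patient subset from its binary comorbidity table."""
    if len(flags) == 0:
        raise NetworkError("empty patient subset")
    X = flags.to_numpy(dtype=float)
    if not np.isin(X, (0.0, 1.0)).all():
        raise NetworkError("comorbidity flags must be exactly 0/1")
    n = len(flags)
    prevalence = X.mean(axis=0)

    G = nx.Graph()
    names = list(flags.columns)
    for j, name in enumerate(names):
        if prevalence[j] > 0:
            G.add_node(name, prevalence=float(prevalence[j]))

    cooc = (X.T @ X) / n  # pairwise co-occurrence prevalence
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            w = cooc[i, j]
            # strictly-below-threshold edges are discarded; boundary kept
            if w >= edge_threshold and w > 0 \
                    and names[i] in G and names[j] in G:
                G.add_edge(names[i], names[j], weight=float(w))
    for node in G.nodes:
        G.nodes[node]["degree"] = G.degree(node)
    return DiseaseNetwork(graph=G, n_patients=n)


def average_degree(network: DiseaseNetwork) -> float:
    """2 |E| / |V|; the mean number of co-occurring diseases per disease."""
    G = network.graph
    if G.number_of_nodes() == 0:
        raise NetworkError("network has zero nodes")
    return 2.0 * G.number_of_edges() / G.number_of_nodes()


def average_clustering(network: DiseaseNetwork) -> float:
    """Mean unweighted local clustering coefficient over all nodes.

    Nodes with fewer than two neighbours contribute 0; weights influence only
    export/visualisation, not the coefficient.
    """
    G = network.graph
    if G.number_of_nodes() == 0:
        raise NetworkError("network has zero nodes")
    return float(nx.average_clustering(G, count_zeros=True))


def export_network(network: DiseaseNetwork, path) -> dict:
    """Write GraphML plus a weighted edge-list CSV (and a node table CSV).

    ``path`` is a stem; files ``<stem>.graphml``, ``<stem>_edges.csv`` and
    ``<stem>_nodes.csv`` are produced.  Round-trips losslessly through
    :func:`read_network`.
    """
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    graphml = stem.with_suffix(".graphml")
    G = network.graph.copy()
    G.graph["n_patients"] = network.n_patients
    nx.write_graphml(G, graphml)
    edges_csv = stem.parent / f"{stem.name}_edges.csv"
    network.edges.to_csv(edges_csv, index=False)
    nodes_csv = stem.parent / f"{stem.name}_nodes.csv"
    pd.DataFrame(
        [{"disease": v, **network.graph.nodes[v]} for v in network.graph.nodes],
        columns=["disease", "prevalence", "degree"],
    ).to_csv(nodes_csv, index=False)
    return {"graphml": graphml, "edges": edges_csv, "nodes": nodes_csv}


def read_network(path) -> DiseaseNetwork:
    """Read a PDN back from its GraphML export."""
    G = nx.read_graphml(Path(path).with_suffix(".graphml"))
    n_patients = int(G.graph.get("n_patients", 0))
    H = nx.Graph()
    for v, data in G.nodes(data=True):
        H.add_node(v, prevalence=float(data.get("prevalence", 0.0)),
                   degree=int(data.get("degree", 0)))
    for a, b, data in G.edges(data=True):
        H.add_edge(a, b, weight=float(data["weight"]))
    return DiseaseNetwork(graph=H, n_patients=n_patients)


def per_cluster_networks(flags: pd.DataFrame, labels,
                         edge_threshold: float = 0.02) -> dict:
    """PDN per cluster (denominator = that cluster's size) plus whole cohort."""
    labels = np.asarray(labels)
    out = {"all": build_pdn(flags, edge_threshold)}
    for c in np.unique(labels):
        out[int(c)] = build_pdn(flags[labels == c], edge_threshold)
    return out
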