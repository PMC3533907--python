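"""Shared test fixtures: hand-built contact graphs and score fields."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from spatcons.conservation import ResidueScores
from spatcons.structure_graph import ContactGraph, ResidueNode


def graph_from_coords(
    coords, edges=None, labels=None, chain="A"
) -> ContactGraph:
    """Build a ContactGraph directly from coordinates and an edge list.

    When ``edges`` is None, nodes are connected by Euclidean proximity is NOT
    assumed — an explicit edge list keeps tests exact.  All nodes default to
    surface.
    """
    coords = np.asarray(coords, dtype=float)
    nodes = [
        ResidueNode(
            chain_id=chain,
            residue_number=k + 1,
            icode=" ",
            amino_acid="ALA",
            coord=(float(c[0]), float(c[1]), float(c[2])),
            representative_atom="CB",
        )
        for k, c in enumerate(coords)
    ]
    g = nx.Graph()
    for n in nodes:
        g.add_node(n.node_id, residue=n)
    ids = [n.node_id for n in nodes]
    if edges is not None:
        for a, b in edges:
            g.add_edge(ids[a], ids[b])
    if labels is None:
        label_map = {nid: "surface" for nid in ids}
    else:
        label_map = {ids[k]: lab for k, lab in enumerate(labels)}
    return ContactGraph(nodes=nodes, graph=g, labels=label_map)


def scores_for(graph: ContactGraph, values) -> ResidueScores:
    ids = graph.surface_ids
    return ResidueScores(values=dict(zip(ids, [float(v) for v in values])))


def random_geometric_graph(
    n: int, radius: float, box: float, seed: int
) -> ContactGraph:
    """Random points in a cube, edges within ``radius`` — a null-model
    spatial graph where every node is surface."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, box, size=(n, 3))
    edges = []
    for i in range(n):
        d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
        for off in np.nonzero(d <= radius)[0]:
            edges.append((i, i + 1 + int(off)))
    return graph_from_coords(coords, edges)


@pytest.fixture(scope="session")
def line_graph():
    """5 collinear surface nodes 1 A apart, chained edges."""
    coords = [(float(k), 0.0, 0.0) for k in range(5)]
    return graph_from_coords(coords, edges=[(k, k + 1) for k in range(4)])
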