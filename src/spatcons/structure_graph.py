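"""Residue contact graphs from protein structures.

A single protein chain is represented as an undirected graph whose nodes are
residues (one representative atom each: C-beta, or C-alpha for glycine) and
whose edges connect residues with adjacent Voronoi cells.  A synthetic solvent
shell — a deterministic cubic grid of pseudo-water points surrounding the
molecule — is tessellated together with the residue atoms so that residues
whose Voronoi cells touch a solvent point can be labelled *surface*; residues
touching a supplied second molecule are *interface*; everything else is
*inner*.

Voronoi adjacency is computed as the edge set of the Delaunay tetrahedralization
of the combined point set (equivalent in general position; a tiny fixed-seed
jitter enforces general position).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "ResidueNode",
    "SolventShell",
    "ContactGraph",
    "NeighborhoodSpec",
    "load_structure",
    "build_solvent_shell",
    "voronoi_contact_graph",
    "neighborhood",
    "neighborhoods",
]

#: jitter amplitude (Angstrom) used to break exact degeneracies before Delaunay
JITTER = 1e-6


@dataclass(frozen=True)
class ResidueNode:
    """One residue with its representative-atom coordinate.

    ``representative_atom`` is ``CB`` except for glycine or when a missing
    C-beta forced a C-alpha fallback (``cb_fallback`` records the latter).
    """

    chain_id: str
    residue_number: int
    icode: str
    amino_acid: str
    coord: tuple[float, float, float]
    representative_atom: str
    cb_fallback: bool = False

    @property
    def node_id(self) -> str:
        return f"{self.chain_id}:{self.residue_number}{self.icode.strip()}"

    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass
class SolventShell:
    """Deterministic pseudo-solvent point cloud around a structure."""

    points: np.ndarray  # (m, 3)
    spacing: float
    clash_distance: float
    margin: float


@dataclass
class ContactGraph:
    """Residue contact graph with surface/inner/interface labels."""

    nodes: list[ResidueNode]
    graph: nx.Graph  # node keys are node_id strings
    labels: dict[str, str]  # node_id -> {"surface", "inner", "interface"}

    def node_by_id(self, node_id: str) -> ResidueNode:
        return self.graph.nodes[node_id]["residue"]

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    @property
    def surface_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes if self.labels[n.node_id] == "surface"]

    def coords(self) -> dict[str, np.ndarray]:
        return {n.node_id: n.xyz() for n in self.nodes}

    def sequence(self) -> str:
        """One-letter residue sequence in node (file) order."""
        return "".join(THREE_TO_ONE.get(n.amino_acid, "X") for n in self.nodes)

    # -- serialization -----------------------------------------------------

    def node_table(self) -> list[tuple]:
        return [
            (
                n.node_id,
                n.chain_id,
                n.residue_number,
                n.icode,
                n.amino_acid,
                n.coord[0],
                n.coord[1],
                n.coord[2],
                self.labels[n.node_id],
            )
            for n in self.nodes
        ]

    def write_tsv(self, node_path, edge_path) -> None:
        with open(node_path, "w") as fh:
            fh.write("node_id\tchain\tresnum\ticode\taa\tx\ty\tz\tlabel\n")
            for row in self.node_table():
                fh.write("\t".join(str(v) for v in row) + "\n")
        with open(edge_path, "w") as fh:
            fh.write("node_id_a\tnode_id_b\n")
            for a, b in sorted(self.graph.edges()):
                fh.write(f"{a}\t{b}\n")


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Neighbourhood definition: within D Angstrom and at most
    ``max_separation`` steps on the surface contact graph."""

    D: float
    max_separation: int = 3
    surface_only: bool = True

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.max_separation < 1:
            raise ValueError("max_separation must be >= 1")


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def _first_listed(atom):
    """Resolve a possibly-disordered atom to its first-listed altloc."""
    if atom.is_disordered():
        children = sorted(atom.disordered_get_list(), key=lambda a: a.serial_number)
        return children[0]
    return atom


def load_structure(pdb_text: str, chain_id: str) -> list[ResidueNode]:
    """Parse ATOM records of one chain into representative-atom nodes.

    HETATM records (waters, ligands) are ignored.  Glycine uses CA; any other
    residue uses CB, falling back to CA (recorded) when CB is absent; residues
    with neither atom are dropped with a warning.  Only the first MODEL is
    read.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("s", io.StringIO(pdb_text))
    models = list(structure.get_models())
    if not models:
        raise ValueError("empty chain: no models in PDB text")
    model = models[0]
    chain = None
    for ch in model:
        if ch.id == chain_id:
            chain = ch
            break
    if chain is None:
        raise ValueError(f"chain not found: {chain_id!r}")

    nodes: list[ResidueNode] = []
    for res in chain:
        hetfield, resseq, icode = res.id
        if hetfield != " ":  # HETATM (waters, ligands)
            continue
        resname = res.get_resname()
        fallback = False
        if resname == "GLY":
            atom = res["CA"] if "CA" in res else None
            rep = "CA"
        else:
            if "CB" in res:
                atom = res["CB"]
                rep = "CB"
            elif "CA" in res:
                atom = res["CA"]
                rep = "CA"
                fallback = True
            else:
                atom = None
                rep = ""
        if atom is None:
            warnings.warn(
                f"residue {chain_id}:{resseq}{icode.strip()} ({resname}) has no "
                "usable representative atom; dropped"
            )
            continue
        coord = _first_listed(atom).get_coord()
        if not np.all(np.isfinite(coord)):
            warnings.warn(f"non-finite coordinates for {chain_id}:{resseq}; dropped")
            continue
        nodes.append(
            ResidueNode(
                chain_id=chain_id,
                residue_number=resseq,
                icode=icode,
                amino_acid=resname,
                coord=(float(coord[0]), float(coord[1]), float(coord[2])),
                representative_atom=rep,
                cb_fallback=fallback,
            )
        )
    if not nodes:
        raise ValueError(f"empty chain: no usable residues in chain {chain_id!r}")
    return nodes


def build_solvent_shell(
    nodes: list[ResidueNode],
    spacing: float = 3.0,
    clash_distance: float = 2.5,
    margin: float = 8.0,
) -> SolventShell:
    """Cubic grid of pseudo-solvent points covering the structure.

    The grid fills the node bounding box expanded by ``margin`` on each side;
    points closer than ``clash_distance`` to any residue coordinate are
    removed.  Deterministic.
    """
    if not nodes:
        raise ValueError("empty structure")
    if spacing <= 0 or clash_distance <= 0 or margin <= 0:
        raise ValueError("spacing, clash_distance and margin must be positive")
    coords = np.array([n.coord for n in nodes], dtype=float)
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    axes = [np.arange(lo[k], hi[k] + spacing * 0.5, spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d, _ = cKDTree(coords).query(grid)
    points = grid[d >= clash_distance]
    return SolventShell(
        points=points, spacing=spacing, clash_distance=clash_distance, margin=margin
    )


def voronoi_contact_graph(
    nodes: list[ResidueNode],
    shell: SolventShell,
    other_chain_points: np.ndarray | None = None,
) -> ContactGraph:
    """Contact graph from the Delaunay tessellation of residues + solvent.

    Two residues are in contact iff their Voronoi cells share a facet, i.e.
    iff they are joined by a Delaunay edge of the combined point set.  A
    residue adjacent to a solvent point is *surface*; adjacent to an
    other-chain point (and not solvent), *interface*; otherwise *inner*.
    """
    n_res = len(nodes)
    pts = [np.array([n.coord for n in nodes], dtype=float)]
    if shell.points.size:
        pts.append(shell.points)
    n_shell = len(shell.points)
    if other_chain_points is not None and len(other_chain_points):
        pts.append(np.asarray(other_chain_points, dtype=float))
        n_other = len(other_chain_points)
    else:
        n_other = 0
    allpts = np.vstack(pts)
    if len(allpts) < 5:
        raise ValueError("tessellation failed: need >= 5 points")

    rng = np.random.default_rng(0)  # fixed seed: deterministic jitter
    jittered = allpts + rng.uniform(-JITTER, JITTER, size=allpts.shape)
    try:
        tri = Delaunay(jittered)
    except Exception as exc:  # qhull degeneracy
        raise ValueError(f"tessellation failed: {exc}") from exc

    # Delaunay edge set over point indices
    adj: dict[int, set[int]] = {i: set() for i in range(len(allpts))}
    for simplex in tri.simplices:
        for a in range(4):
            for b in range(a + 1, 4):
                i, j = int(simplex[a]), int(simplex[b])
                adj[i].add(j)
                adj[j].add(i)

    shell_range = range(n_res, n_res + n_shell)
    other_range = range(n_res + n_shell, n_res + n_shell + n_other)

    g = nx.Graph()
    labels: dict[str, str] = {}
    for i, node in enumerate(nodes):
        g.add_node(node.node_id, residue=node)
        touches_shell = any(k in adj[i] for k in shell_range) if n_shell else False
        touches_other = any(k in adj[i] for k in other_range) if n_other else False
        if touches_shell:
            labels[node.node_id] = "surface"
        elif touches_other:
            labels[node.node_id] = "interface"
        else:
            labels[node.node_id] = "inner"
    for i in range(n_res):
        for j in adj[i]:
            if j < n_res and j > i:
                g.add_edge(nodes[i].node_id, nodes[j].node_id)
    return ContactGraph(nodes=nodes, graph=g, labels=labels)


def neighborhood(graph: ContactGraph, i: str, spec: NeighborhoodSpec) -> set[str]:
    """Neighbours of surface residue ``i``: surface residues within ``spec.D``
    Angstrom (representative atoms) AND within ``spec.max_separation`` steps on
    the surface-induced contact graph."""
    if spec.surface_only and graph.labels.get(i) != "surface":
        raise ValueError(f"non-surface focal residue: {i}")
    if spec.surface_only:
        universe = set(graph.surface_ids)
    else:
        universe = set(graph.node_ids)
    sub = graph.graph.subgraph(universe)
    lengths = nx.single_source_shortest_path_length(sub, i, cutoff=spec.max_separation)
    ci = graph.node_by_id(i).xyz()
    out = set()
    for j in lengths:
        if j == i:
            continue
        if np.linalg.norm(graph.node_by_id(j).xyz() - ci) <= spec.D:
            out.add(j)
    return out


def neighborhoods(graph: ContactGraph, spec: NeighborhoodSpec) -> dict[str, set[str]]:
    """All surface neighbourhoods at once (BFS per node on the surface
    subgraph); equivalent to calling :func:`neighborhood` per residue."""
    surface = graph.surface_ids if spec.surface_only else graph.node_ids
    sub = graph.graph.subgraph(surface)
    coords = {j: graph.node_by_id(j).xyz() for j in surface}
    out: dict[str, set[str]] = {}
    for i in surface:
        lengths = nx.single_source_shortest_path_length(
            sub, i, cutoff=spec.max_separation
        )
        ci = coords[i]
        out[i] = {
            j
            for j in lengths
            if j != i and np.linalg.norm(coords[j] - ci) <= spec.D
        }
    return out
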