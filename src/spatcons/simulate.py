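"""Synthetic structures and simulated homolog families.

These fixtures realize, at desk scale, the scenario motivating DSPAC-based
sequence selection: a query protein with a conserved surface patch, an
in-group of homologs that share the patch, and an out-group of more divergent
homologs whose conserved patch sits elsewhere on the surface.  As homologs of
decreasing identity are admitted, the contrast between the conserved patch
and the diverging background grows — until the out-group enters and erodes
the patch, so the DSPAC-versus-threshold curve is convex with an interior
maximum.

Geometries
----------
sphere
    n nodes on a Fibonacci sphere.  The radius is set so that a functional
    region of the standard 9 A radius subtends roughly 15-20% of the surface
    — the regime of real enzyme chains, where a catalytic region of ~20
    residues sits on a surface of 100-150 — which also keeps the surface
    graph connected at the smallest neighbour threshold (5 A) swept by the
    selection grid.  All nodes classify as surface.
onion
    A dense outer shell around a small inner shell; inner-shell nodes are
    shielded from solvent and classify as inner.  A topology fixture only
    (node spacing is tighter than physical).
slab
    A two-layer cubic lattice patchwork, all surface.

Families are indel-free: every simulated sequence has the structure's length,
so the identity alignment is exact and realized percent identity equals the
fraction of positions matching the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conservation import Alignment, SubstitutionTable, AMINO_ACIDS
from .structure_graph import ONE_TO_THREE, ResidueNode

__all__ = [
    "ToyStructure",
    "SimulatedFamily",
    "make_toy_structure",
    "simulate_family",
    "write_bundle",
    "default_scenario",
]

#: mean inter-node spacing on the sphere surface (Angstrom); at n = 150 this
#: puts the sphere radius near 10.7 A, so a 9 A functional-region radius
#: covers ~18% of the surface, as on real enzyme chains
SPHERE_SPACING = 3.1

DEFAULT_TARGETS: tuple[float, ...] = tuple(range(85, 5, -5))


@dataclass
class ToyStructure:
    geometry: str
    nodes: list[ResidueNode]
    patch: list[str]  # node ids of the planted conserved cap
    antipodal_patch: list[str]  # relocated patch used by the out-group
    sequence: str  # one-letter, node order
    seed: int
    pdb_text: str

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def patch_positions(self) -> list[int]:
        ids = {nid: k for k, nid in enumerate(self.node_ids)}
        return [ids[nid] for nid in self.patch]

    def antipodal_positions(self) -> list[int]:
        ids = {nid: k for k, nid in enumerate(self.node_ids)}
        return [ids[nid] for nid in self.antipodal_patch]

    def pseudo_catalytic(self, k: int = 3) -> list[str]:
        """The k patch residues closest to the patch centroid, used as the
        pseudo-catalytic truth of the planted functional region."""
        coords = {n.node_id: n.xyz() for n in self.nodes}
        centroid = np.mean([coords[nid] for nid in self.patch], axis=0)
        ranked = sorted(self.patch, key=lambda nid: float(np.linalg.norm(coords[nid] - centroid)))
        return ranked[:k]


@dataclass
class SimulatedFamily:
    query_id: str
    root: str
    members: list[tuple[str, str]]  # (id, sequence), in-group then out-group
    realized: dict[str, float]  # id -> percent identity to root
    targets: dict[str, float]  # id -> target percent identity
    ingroup_ids: list[str]
    outgroup_ids: list[str]
    seed: int

    def to_alignment(self) -> Alignment:
        rows = [(self.query_id, self.root)] + list(self.members)
        return Alignment(sequences=rows, query_id=self.query_id)


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * (np.pi * (3.0 - np.sqrt(5.0)))
    r = np.sqrt(1.0 - z * z)
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _pdb_line(serial: int, name: str, resname: str, chain: str, resseq: int,
              xyz: np.ndarray) -> str:
    element = name[0]
    return (
        f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def _serialize(coords: np.ndarray, sequence: str, chain: str = "A") -> str:
    lines = []
    for k, (xyz, aa1) in enumerate(zip(coords, sequence)):
        resname = ONE_TO_THREE[aa1]
        atom = "CA" if aa1 == "G" else "CB"
        lines.append(_pdb_line(k + 1, atom, resname, chain, k + 1, xyz))
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_toy_structure(
    geometry: str, n: int, patch_size: int, seed: int
) -> ToyStructure:
    """Deterministic toy structure with a planted contiguous surface cap."""
    if n < 20:
        raise ValueError("n must be >= 20")
    if patch_size >= n / 4:
        raise ValueError("patch_size must be < n/4")
    rng = np.random.default_rng(seed)
    if geometry == "sphere":
        radius = SPHERE_SPACING * np.sqrt(n / (4 * np.pi))
        coords = _fibonacci_sphere(n, radius)
    elif geometry == "onion":
        n_inner = max(6, round(n / 6))
        n_outer = n - n_inner
        r_out = 2.6 * np.sqrt(n_outer / (4 * np.pi))
        coords = np.vstack(
            [_fibonacci_sphere(n_outer, r_out), _fibonacci_sphere(n_inner, 2.3)]
        )
    elif geometry == "slab":
        nx = int(np.ceil(np.sqrt(n / 2)))
        pts = []
        for layer in range(2):
            for a in range(nx):
                for b in range(nx):
                    pts.append((4.0 * a, 4.0 * b, 4.0 * layer))
        coords = np.array(pts[:n], dtype=float)
    else:
        raise ValueError(f"unknown geometry: {geometry!r}")

    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    nodes = [
        ResidueNode(
            chain_id="A",
            residue_number=k + 1,
            icode=" ",
            amino_acid=ONE_TO_THREE[sequence[k]],
            coord=(round(float(c[0]), 3), round(float(c[1]), 3), round(float(c[2]), 3)),
            representative_atom="CA" if sequence[k] == "G" else "CB",
        )
        for k, c in enumerate(coords)
    ]
    # Fibonacci ordering descends in z, so the first patch_size sphere nodes
    # form a contiguous polar cap; for other geometries sort explicitly.
    order_top = np.argsort(-coords[:, 2], kind="stable")
    patch = [nodes[i].node_id for i in order_top[:patch_size]]
    antipodal = [nodes[i].node_id for i in order_top[::-1][:patch_size]]
    return ToyStructure(
        geometry=geometry,
        nodes=nodes,
        patch=patch,
        antipodal_patch=antipodal,
        sequence=sequence,
        seed=seed,
        pdb_text=_serialize(coords, sequence),
    )


def _mutation_proposal(table: SubstitutionTable) -> np.ndarray:
    """(20, 20) row-stochastic matrix: P(b | a) proportional to 2^m(a,b) over
    b != a, so substitutions favour biochemically similar residues."""
    p = np.power(2.0, table.matrix)
    np.fill_diagonal(p, 0.0)
    return p / p.sum(axis=1, keepdims=True)


def _identity(seq: np.ndarray, root: np.ndarray) -> float:
    return 100.0 * float(np.mean(seq == root))


def _mutate_to_target(
    seq: np.ndarray,
    root: np.ndarray,
    frozen: set[int],
    target: float,
    rng: np.random.Generator,
    proposal: np.ndarray,
) -> np.ndarray:
    """Mutate random non-frozen positions (each at most once) until the
    realized identity drops to the target."""
    n = len(root)
    floor = 100.0 * len(frozen) / n
    if target < floor:
        raise ValueError(
            f"identity target unreachable: {target} < conserved floor {floor:.1f}"
        )
    candidates = [k for k in range(n) if k not in frozen and seq[k] == root[k]]
    rng.shuffle(candidates)
    out = seq.copy()
    for k in candidates:
        if _identity(out, root) <= target:
            break
        a = int(out[k])
        out[k] = rng.choice(20, p=proposal[a])
    return out


def simulate_family(
    structure: ToyStructure,
    identity_targets: tuple[float, ...] = DEFAULT_TARGETS,
    outgroup_split: float = 40.0,
    n_outgroup: int = 5,
    seed: int = 0,
    n_ingroup: int = 15,
) -> SimulatedFamily:
    """Simulate an in-group/out-group homolog family of the structure.

    In-group sequences mutate only non-patch positions, with substitutions
    drawn from a BLOSUM62-conditional proposal, until their target identity
    is reached.  Their target identities span the threshold grid from just
    above its top down to just above ``outgroup_split``, with quadratic
    spacing concentrated toward the divergent end — the shape of a real
    homolog search, where distant homologs vastly outnumber close ones.
    That concentration also drives the background conservation to its floor
    by the time the threshold reaches the split, so the only marginal effect
    of admitting the out-group is the erosion of the planted patch.
    Out-group sequences additionally randomize the original patch —
    uniformly over the other residue types, since functional divergence
    replaces functional residues with chemically different ones — and
    conserve the relocated (antipodal) patch instead; their targets sit
    below ``outgroup_split``.
    """
    targets = sorted(identity_targets)
    if targets[0] < 10 or targets[-1] > 95:
        raise ValueError("identity targets must lie within [10, 95]")
    if not (targets[0] <= outgroup_split <= targets[-1]):
        raise ValueError("outgroup_split must lie within the target range")
    rng = np.random.default_rng(seed)
    table = SubstitutionTable.blosum62()
    proposal = _mutation_proposal(table)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    root = np.array([aa_index[a] for a in structure.sequence], dtype=int)
    patch = set(structure.patch_positions())
    relocated = set(structure.antipodal_positions())

    hi = min(95.0, targets[-1] + 2.0)
    lo = outgroup_split + 2.0
    frac = (np.arange(n_ingroup) / (n_ingroup - 1)) ** 2  # dense near lo
    in_targets = (lo + (hi - lo) * frac)[::-1]
    out_targets = np.linspace(outgroup_split - 3.0, targets[0] + 2.0, n_outgroup)

    members: list[tuple[str, str]] = []
    realized: dict[str, float] = {}
    target_of: dict[str, float] = {}
    ingroup_ids, outgroup_ids = [], []
    for k, tgt in enumerate(in_targets):
        sid = f"in{k:02d}"
        seq = _mutate_to_target(root, root, patch, float(tgt), rng, proposal)
        members.append((sid, "".join(AMINO_ACIDS[c] for c in seq)))
        realized[sid] = _identity(seq, root)
        target_of[sid] = float(tgt)
        ingroup_ids.append(sid)
    for k, tgt in enumerate(out_targets):
        sid = f"out{k:02d}"
        seq = root.copy()
        for pos in sorted(patch - relocated):  # old patch: chemically divergent
            a = int(seq[pos])
            seq[pos] = (a + 1 + int(rng.integers(19))) % 20
        seq = _mutate_to_target(seq, root, relocated, float(tgt), rng, proposal)
        members.append((sid, "".join(AMINO_ACIDS[c] for c in seq)))
        realized[sid] = _identity(seq, root)
        target_of[sid] = float(tgt)
        outgroup_ids.append(sid)
    return SimulatedFamily(
        query_id="query",
        root=structure.sequence,
        members=members,
        realized=realized,
        targets=target_of,
        ingroup_ids=ingroup_ids,
        outgroup_ids=outgroup_ids,
        seed=seed,
    )


def write_bundle(out_dir, structure: ToyStructure, family: SimulatedFamily) -> dict:
    """Write the fixture bundle (PDB, FASTA, aligned FASTA, catalytic TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pdb": out / "structure.pdb",
        "query": out / "query.fasta",
        "hits": out / "hits.fasta",
        "msa": out / "aligned.fasta",
        "catalytic": out / "catalytic.tsv",
    }
    paths["pdb"].write_text(structure.pdb_text)
    paths["query"].write_text(f">{family.query_id}\n{family.root}\n")
    with open(paths["hits"], "w") as fh:
        for sid, s in family.members:
            fh.write(f">{sid}\n{s}\n")
    family.to_alignment().to_fasta(paths["msa"])
    with open(paths["catalytic"], "w") as fh:
        fh.write("chain\tresnum\ticode\n")
        for nid in structure.pseudo_catalytic():
            chain, resnum = nid.split(":")
            fh.write(f"{chain}\t{resnum}\t\n")
    return {k: str(v) for k, v in paths.items()}


def default_scenario(seed: int) -> tuple[ToyStructure, SimulatedFamily]:
    """The standard test scenario: a 150-node sphere with a 10-node planted
    cap, 15 in-group and 5 out-group homologs, out-group split at 40%."""
    structure = make_toy_structure("sphere", n=150, patch_size=10, seed=seed)
    family = simulate_family(structure, seed=seed + 1)
    return structure, family
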