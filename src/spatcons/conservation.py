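"""Alignment conservation scores and their mapping onto a structure.

The per-column conservation score is the Henikoff-weighted average, over all
unordered sequence pairs, of min-max-normalized BLOSUM62 similarities:

    Cons(i) = sum_{j<k} W_j W_k Mut(s_j(i), s_k(i)) / sum_{j<k} W_j W_k

    Mut(a, b) = (m(a,b) - min(m)) / (max(m) - min(m))   both residues standard
              = 0                                        gap or nonstandard

with m the BLOSUM62 score and max(m)/min(m) taken over the full standard
20x20 table.  W are position-based (Henikoff-Henikoff) sequence weights,
normalized to sum to one.  Cons lies in [0, 1]; an all-gap column scores 0.
A fully conserved column scores Mut(a, a), which reaches 1 only for
tryptophan; the score is used as defined, without rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .structure_graph import ContactGraph

__all__ = [
    "AMINO_ACIDS",
    "Alignment",
    "WeightVector",
    "SubstitutionTable",
    "ConservationProfile",
    "ResidueScores",
    "henikoff_weights",
    "mut",
    "conservation_profile",
    "map_profile_to_structure",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CODE = 20  # internal code for gap / nonstandard letters


@dataclass
class Alignment:
    """A gapped multiple sequence alignment with a designated query row."""

    sequences: list[tuple[str, str]]  # (id, gapped residue string)
    query_id: str

    def __post_init__(self):
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.query_id not in {sid for sid, _ in self.sequences}:
            raise ValueError(f"query_id {self.query_id!r} not among rows")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0][1]) if self.sequences else 0

    def row(self, seq_id: str) -> str:
        for sid, s in self.sequences:
            if sid == seq_id:
                return s
        raise KeyError(seq_id)

    def encoded(self) -> np.ndarray:
        """Integer matrix (n_seq, n_col); gaps/nonstandard -> GAP_CODE."""
        mat = np.full((self.n_sequences, self.n_columns), GAP_CODE, dtype=np.int8)
        for r, (_, s) in enumerate(self.sequences):
            for c, ch in enumerate(s):
                mat[r, c] = _AA_INDEX.get(ch.upper(), GAP_CODE)
        return mat

    @classmethod
    def from_fasta(cls, path, query_id: str | None = None) -> "Alignment":
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(sequences=records, query_id=query_id or records[0][0])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, s in self.sequences:
                fh.write(f">{sid}\n{s}\n")


@dataclass
class WeightVector:
    ids: list[str]
    weights: np.ndarray  # sums to 1

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class SubstitutionTable:
    """A symmetric residue substitution matrix with its min-max range."""

    matrix: np.ndarray  # (20, 20) integer scores over AMINO_ACIDS order
    max_m: int
    min_m: int

    @classmethod
    def blosum62(cls) -> "SubstitutionTable":
        raw = substitution_matrices.load("BLOSUM62")
        mat = np.zeros((20, 20))
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                mat[_AA_INDEX[a], _AA_INDEX[b]] = raw[a, b]
        return cls(matrix=mat, max_m=int(mat.max()), min_m=int(mat.min()))

    def mut_matrix(self) -> np.ndarray:
        """(21, 21) normalized similarity; the extra row/col is the gap (0)."""
        m = np.zeros((21, 21))
        m[:20, :20] = (self.matrix - self.min_m) / (self.max_m - self.min_m)
        return m


@dataclass
class ConservationProfile:
    cons: np.ndarray  # per-column value in [0, 1]
    weights: WeightVector

    @property
    def site_count(self) -> int:
        return len(self.cons)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("column_index_1based\tcons\n")
            for i, c in enumerate(self.cons, start=1):
                fh.write(f"{i}\t{c:.6g}\n")


@dataclass
class ResidueScores:
    """Conservation values on the surface residues of one chain."""

    values: dict[str, float]  # node_id -> cons
    unmapped: list[str] = field(default_factory=list)
    site_of: dict[str, int] = field(default_factory=dict)  # node_id -> column

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\tcons\n")
            for nid, v in self.values.items():
                fh.write(f"{nid}\t{v:.6g}\n")


def henikoff_weights(aln: Alignment) -> WeightVector:
    """Position-based sequence weights.

    At each column a sequence contributes 1/(r*s), with r the number of
    distinct residue types present and s the multiplicity of the sequence's
    own type; gap cells contribute nothing and gaps do not count as a type.
    Per-sequence totals are normalized to sum to one.
    """
    if aln.n_sequences < 2:
        raise ValueError("need >=2 sequences")
    enc = aln.encoded()
    n_seq, n_col = enc.shape
    raw = np.zeros(n_seq)
    for c in range(n_col):
        col = enc[:, c]
        mask = col != GAP_CODE
        if not mask.any():
            continue
        types, counts = np.unique(col[mask], return_counts=True)
        r = len(types)
        mult = dict(zip(types.tolist(), counts.tolist()))
        for j in np.nonzero(mask)[0]:
            raw[j] += 1.0 / (r * mult[int(col[j])])
    total = raw.sum()
    if total == 0:
        raise ValueError("alignment contains no residues")
    return WeightVector(ids=[sid for sid, _ in aln.sequences], weights=raw / total)


def mut(a: str, b: str, table: SubstitutionTable | None = None) -> float:
    """Normalized substitution similarity in [0, 1]; 0 for gaps/nonstandard."""
    table = table or SubstitutionTable.blosum62()
    ia = _AA_INDEX.get(a.upper(), GAP_CODE)
    ib = _AA_INDEX.get(b.upper(), GAP_CODE)
    if ia == GAP_CODE or ib == GAP_CODE:
        return 0.0
    return float((table.matrix[ia, ib] - table.min_m) / (table.max_m - table.min_m))


def conservation_profile(
    aln: Alignment,
    weights: WeightVector | None = None,
    table: SubstitutionTable | None = None,
) -> ConservationProfile:
    """Per-column conservation scores (see module docstring)."""
    if aln.n_sequences < 2:
        raise ValueError("need >=2 sequences")
    weights = weights or henikoff_weights(aln)
    table = table or SubstitutionTable.blosum62()
    w = weights.weights
    enc = aln.encoded()
    mutm = table.mut_matrix()
    outer = np.outer(w, w)
    iu = np.triu_indices(len(w), k=1)
    denom = outer[iu].sum()
    cons = np.empty(aln.n_columns)
    for c in range(aln.n_columns):
        col = enc[:, c].astype(int)
        sim = mutm[np.ix_(col, col)]
        cons[c] = (outer[iu] * sim[iu]).sum() / denom
    return ConservationProfile(cons=cons, weights=weights)


def _align_query_to_structure(query: str, struct_seq: str) -> dict[int, int]:
    """Map ungapped-query positions -> structure residue indices.

    Exact match (including as substring for truncated constructs) is used when
    possible; otherwise a global pairwise alignment.
    """
    if query == struct_seq:
        return {k: k for k in range(len(query))}
    idx = struct_seq.find(query)
    if idx >= 0:
        return {k: idx + k for k in range(len(query))}
    idx = query.find(struct_seq)
    if idx >= 0:
        return {idx + k: k for k in range(len(struct_seq))}
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(query, struct_seq)[0]
    mapping: dict[int, int] = {}
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        for off in range(qe - qs):
            mapping[qs + off] = ts + off
    return mapping


def map_profile_to_structure(
    profile: ConservationProfile,
    aln: Alignment,
    graph: ContactGraph,
    identity_floor: float = 0.95,
) -> ResidueScores:
    """Assign per-column conservation scores to surface residues.

    The ungapped query row is anchored to the structure's residue sequence;
    each mapped surface residue receives the Cons of its query column.
    Residues without a matching column are listed as unmapped and excluded
    from spatial statistics.
    """
    qrow = aln.row(aln.query_id)
    # ungapped query position -> alignment column
    q_positions = [c for c, ch in enumerate(qrow) if ch != "-"]
    query = "".join(qrow[c] for c in q_positions)
    struct_seq = graph.sequence()
    mapping = _align_query_to_structure(query, struct_seq)
    if mapping:
        matches = sum(
            1 for q, t in mapping.items() if query[q] == struct_seq[t]
        )
        identity = matches / len(mapping)
    else:
        identity = 0.0
    if identity < identity_floor:
        raise ValueError(
            f"query does not match structure (identity {identity:.2f} < "
            f"{identity_floor:.2f})"
        )
    res_index_to_col = {t: q_positions[q] for q, t in mapping.items()}
    values: dict[str, float] = {}
    site_of: dict[str, int] = {}
    unmapped: list[str] = []
    for k, node in enumerate(graph.nodes):
        nid = node.node_id
        if graph.labels[nid] != "surface":
            continue
        col = res_index_to_col.get(k)
        if col is None:
            unmapped.append(nid)
            continue
        values[nid] = float(profile.cons[col])
        site_of[nid] = col
    return ResidueScores(values=values, unmapped=unmapped, site_of=site_of)
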