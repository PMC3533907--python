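"""Homolog-set selection by DSPAC maximization.

Candidate homolog sets are nested by percent identity to the query: for each
threshold X (85% down to 10% in steps of 5) the candidate holds the query plus
every hit with identity >= X, and is eligible only when it contains at least
``min_sequences`` sequences (default 10).  Each eligible candidate is
(re)aligned, its conservation profile mapped onto the structure, and DSPAC
evaluated on every neighbour threshold D (5.0-9.0 A in steps of 0.5).  The
(X, D) cell with the maximum DSPAC is adopted; ties break toward larger X,
then smaller D.

Hit lists come from an external sequence search (the recommended retrieval is
a BLAST run with a permissive e-value of 1e+3); hits shorter than 80% or
longer than 150% of the query length are removed before thresholding.
Alignment is delegated to an injected aligner callable (default: the external
``mafft`` command); sets of equal-length, indel-free sequences can use
:class:`IdentityAligner`.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .conservation import (
    Alignment,
    SubstitutionTable,
    conservation_profile,
    henikoff_weights,
    map_profile_to_structure,
)
from .spatial_stats import DspacResult, dspac
from .structure_graph import ContactGraph, NeighborhoodSpec

__all__ = [
    "DEFAULT_X_GRID",
    "DEFAULT_D_GRID",
    "HomologSet",
    "CandidateSet",
    "SelectionResult",
    "IdentityAligner",
    "MafftAligner",
    "filter_hits",
    "percent_identity",
    "compute_identities",
    "build_candidate_sets",
    "select_max_dspac",
]

DEFAULT_X_GRID: tuple[float, ...] = tuple(range(85, 5, -5))  # 85, 80, ..., 10
DEFAULT_D_GRID: tuple[float, ...] = tuple(np.arange(5.0, 9.01, 0.5))

AlignerFn = Callable[[list[tuple[str, str]], str], Alignment]


@dataclass
class HomologSet:
    """Query sequence plus hit sequences with identities to the query."""

    query_id: str
    query_seq: str
    hits: list[tuple[str, str]]  # (id, ungapped sequence)
    identities: dict[str, float] = field(default_factory=dict)  # id -> %


@dataclass
class CandidateSet:
    X: float  # percent identity threshold
    member_ids: list[str]  # includes the query
    eligible: bool


@dataclass
class SelectionResult:
    grid: pd.DataFrame  # columns X, D, dspac, slope, n_points, p_value, eligible
    adopted_X: float | None
    adopted_D: float | None
    adopted_members: list[str]
    adopted_alignment: Alignment | None
    candidates: list[CandidateSet]

    def summary(self) -> dict:
        adopted = self.grid[
            (self.grid.X == self.adopted_X) & (self.grid.D == self.adopted_D)
        ]
        return {
            "adopted_X": self.adopted_X,
            "adopted_D": self.adopted_D,
            "adopted_dspac": (
                float(adopted.dspac.iloc[0]) if len(adopted) else None
            ),
            "adopted_p_value": (
                float(adopted.p_value.iloc[0]) if len(adopted) else None
            ),
            "n_members": len(self.adopted_members),
            "members": list(self.adopted_members),
            "n_candidates": len(self.candidates),
            "n_eligible": sum(c.eligible for c in self.candidates),
        }


class IdentityAligner:
    """Aligner for indel-free families: equal-length sequences are already
    aligned, so the identity alignment is exact."""

    def __call__(self, seqs: list[tuple[str, str]], query_id: str) -> Alignment:
        lengths = {len(s) for _, s in seqs}
        if len(lengths) > 1:
            raise ValueError("IdentityAligner requires equal-length sequences")
        return Alignment(sequences=list(seqs), query_id=query_id)


class MafftAligner:
    """External-aligner hook: writes FASTA, runs a command emitting aligned
    FASTA on stdout (default ``mafft --auto``)."""

    def __init__(self, command: Sequence[str] = ("mafft", "--auto", "--quiet")):
        self.command = list(command)

    def __call__(self, seqs: list[tuple[str, str]], query_id: str) -> Alignment:
        with tempfile.NamedTemporaryFile(
            "w", suffix=".fasta", delete=False
        ) as fh:
            for sid, s in seqs:
                fh.write(f">{sid}\n{s}\n")
            path = fh.name
        try:
            out = subprocess.run(
                self.command + [path], capture_output=True, text=True, check=True
            ).stdout
        except (subprocess.CalledProcessError, FileNotFoundError) as exc:
            raise RuntimeError(f"external aligner failed: {exc}") from exc
        finally:
            Path(path).unlink(missing_ok=True)
        records: list[tuple[str, str]] = []
        sid, chunks = None, []
        for line in out.splitlines():
            if line.startswith(">"):
                if sid is not None:
                    records.append((sid, "".join(chunks).upper()))
                sid, chunks = line[1:].split()[0], []
            else:
                chunks.append(line.strip())
        if sid is not None:
            records.append((sid, "".join(chunks).upper()))
        return Alignment(sequences=records, query_id=query_id)


def filter_hits(query: str, hits: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Length filter: keep hits within [80%, 150%] of the query length
    (boundaries inclusive); input order preserved."""
    if not query:
        raise ValueError("empty query sequence")
    lo = 0.8 * len(query)
    hi = 1.5 * len(query)
    return [(sid, s) for sid, s in hits if lo <= len(s) <= hi]


def percent_identity(aln: Alignment, seq_id: str) -> float:
    """Identity (%) between a row and the query on their pairwise projection:
    matching columns over columns where at least one of the pair is non-gap."""
    a = aln.row(aln.query_id)
    b = aln.row(seq_id)
    matches = comparable = 0
    for ca, cb in zip(a, b):
        if ca == "-" and cb == "-":
            continue
        comparable += 1
        if ca == cb and ca != "-":
            matches += 1
    if comparable == 0:
        raise ValueError(f"no overlap between {seq_id!r} and the query")
    return 100.0 * matches / comparable


def compute_identities(homologs: HomologSet, master_aln: Alignment) -> None:
    """Fill ``homologs.identities`` from the master alignment in place."""
    for sid, _ in homologs.hits:
        homologs.identities[sid] = percent_identity(master_aln, sid)


def build_candidate_sets(
    homologs: HomologSet,
    X_grid: Sequence[float] = DEFAULT_X_GRID,
    min_sequences: int = 10,
) -> list[CandidateSet]:
    """One nested candidate per identity threshold; the query is always a
    member; eligible iff the member count (query included) >= min_sequences."""
    if any(sid not in homologs.identities for sid, _ in homologs.hits):
        raise ValueError("identities not computed; call compute_identities first")
    out = []
    for X in X_grid:
        members = [homologs.query_id] + [
            sid for sid, _ in homologs.hits if homologs.identities[sid] >= X
        ]
        out.append(
            CandidateSet(X=X, member_ids=members, eligible=len(members) >= min_sequences)
        )
    return out


def select_max_dspac(
    homologs: HomologSet,
    candidates: list[CandidateSet],
    graph: ContactGraph,
    aligner: AlignerFn,
    D_grid: Sequence[float] = DEFAULT_D_GRID,
    max_separation: int = 3,
    table: SubstitutionTable | None = None,
    identity_floor: float = 0.95,
) -> SelectionResult:
    """Evaluate DSPAC over the (X, D) grid and adopt its maximum.

    Each eligible candidate is realigned via ``aligner``; degenerate cells
    (NaN DSPAC) are never adopted.  Ties break toward larger X then smaller D.
    """
    if not any(c.eligible for c in candidates):
        raise ValueError("no candidate with >= min_sequences")
    table = table or SubstitutionTable.blosum62()
    seq_of = dict(homologs.hits)
    seq_of[homologs.query_id] = homologs.query_seq

    rows = []
    alignments: dict[float, Alignment] = {}
    for cand in candidates:
        if not cand.eligible:
            for D in D_grid:
                rows.append((cand.X, float(D), np.nan, np.nan, 0, np.nan, False))
            continue
        seqs = [(sid, seq_of[sid]) for sid in cand.member_ids]
        try:
            aln = aligner(seqs, homologs.query_id)
        except Exception as exc:
            raise RuntimeError(
                f"aligner failed for candidate X={cand.X}: {exc}"
            ) from exc
        alignments[cand.X] = aln
        weights = henikoff_weights(aln)
        profile = conservation_profile(aln, weights, table)
        scores = map_profile_to_structure(
            profile, aln, graph, identity_floor=identity_floor
        )
        for D in D_grid:
            spec = NeighborhoodSpec(D=float(D), max_separation=max_separation)
            res = dspac(scores, graph, spec, D=float(D), X=cand.X)
            rows.append(
                (cand.X, float(D), res.dspac, res.slope, res.n_points,
                 res.p_value, True)
            )
    grid = pd.DataFrame(
        rows, columns=["X", "D", "dspac", "slope", "n_points", "p_value", "eligible"]
    )

    best = None  # (dspac, X, D)
    for cand in sorted(candidates, key=lambda c: -c.X):
        if not cand.eligible:
            continue
        sub = grid[(grid.X == cand.X) & grid.eligible]
        for _, row in sub.sort_values("D").iterrows():
            v = row.dspac
            if np.isnan(v):
                continue
            if best is None or v > best[0]:
                best = (v, cand.X, row.D)
    if best is None:
        raise ValueError("all eligible cells are degenerate")
    _, aX, aD = best
    members = next(c.member_ids for c in candidates if c.X == aX)
    return SelectionResult(
        grid=grid,
        adopted_X=aX,
        adopted_D=aD,
        adopted_members=list(members),
        adopted_alignment=alignments.get(aX),
        candidates=candidates,
    )
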