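"""Predicted functional regions and their evaluation.

A residue flagged significant by the LMIC Monte Carlo test seeds a predicted
functional region consisting of itself and its spatial neighbourhood.  The
reference ("real") functional region is the catalytic residues plus every
residue whose representative atom lies within a fixed radius (default 9 A)
of their geometric center.

Predictions are scored with a confusion matrix over an evaluation universe
(by default the scored surface residues, since only those can ever be
predicted):

    Sensitivity = TP / (TP + FN)      Specificity = TP / (TP + FP)
    Selectivity = TN / (TN + FP)      F = 2*Sens*Spec / (Sens + Spec)

Specificity here is precision (the fraction of predicted residues that are
real); selectivity is the true-negative rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .spatial_stats import McTestResult
from .structure_graph import ContactGraph, NeighborhoodSpec, neighborhoods

__all__ = [
    "FunctionalRegion",
    "PredictionResult",
    "Metrics",
    "predict_regions",
    "functional_region",
    "metrics",
    "read_catalytic_tsv",
]


@dataclass
class FunctionalRegion:
    catalytic: set[str]
    region: set[str]
    center: np.ndarray
    radius: float = 9.0


@dataclass
class PredictionResult:
    significant: set[str]
    predicted: set[str]
    provenance: dict[str, str]  # node_id -> "seed" | "neighbor"

    def write_tsv(self, path, actual: FunctionalRegion | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\tpredicted\tprovenance\tin_actual\n")
            for nid in sorted(self.predicted):
                in_actual = (
                    "" if actual is None else str(int(nid in actual.region))
                )
                fh.write(f"{nid}\t1\t{self.provenance[nid]}\t{in_actual}\n")


@dataclass
class Metrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    selectivity: float
    f_score: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)
            fh.write("\n")


def predict_regions(
    mc: McTestResult, graph: ContactGraph, spec: NeighborhoodSpec
) -> PredictionResult:
    """Union of each significant residue with its neighbourhood."""
    nb = neighborhoods(graph, spec)
    significant = mc.significant_ids
    predicted: set[str] = set()
    provenance: dict[str, str] = {}
    for i in significant:
        predicted.add(i)
        provenance[i] = "seed"
        for j in nb[i]:
            predicted.add(j)
            provenance.setdefault(j, "neighbor")
    return PredictionResult(
        significant=significant, predicted=predicted, provenance=provenance
    )


def functional_region(
    catalytic: set[str] | list[str], graph: ContactGraph, radius: float = 9.0
) -> FunctionalRegion:
    """Catalytic residues plus residues within ``radius`` of their geometric
    center (representative-atom coordinates)."""
    catalytic = set(catalytic)
    if not catalytic:
        raise ValueError("no catalytic residues")
    known = set(graph.node_ids)
    missing = catalytic - known
    if missing:
        raise ValueError(f"catalytic residue not in structure: {sorted(missing)}")
    coords = graph.coords()
    center = np.mean([coords[c] for c in sorted(catalytic)], axis=0)
    region = set(catalytic)
    for nid, xyz in coords.items():
        if np.linalg.norm(xyz - center) <= radius:
            region.add(nid)
    return FunctionalRegion(
        catalytic=catalytic, region=region, center=center, radius=radius
    )


def metrics(
    predicted: set[str], actual: FunctionalRegion, universe: set[str]
) -> Metrics:
    """Confusion-matrix scores of a prediction over an evaluation universe.

    The reference region is intersected with the universe before counting.
    0/0 ratios are reported as 0, except selectivity (1 when there are no
    negatives to misclassify).
    """
    if not predicted <= universe:
        raise ValueError("prediction outside universe")
    pos = actual.region & universe
    tp = len(predicted & pos)
    fp = len(predicted - pos)
    fn = len(pos - predicted)
    tn = len(universe) - tp - fp - fn
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tp / (tp + fp) if (tp + fp) else 0.0
    sel = tn / (tn + fp) if (tn + fp) else 1.0
    f = 2 * sens * spec / (sens + spec) if (sens + spec) else 0.0
    return Metrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, selectivity=sel, f_score=f,
    )


def read_catalytic_tsv(path, chain_id: str | None = None) -> set[str]:
    """Catalytic residue ids from a TSV with columns chain, resnum[, icode]."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("chain\t"):
                continue
            parts = line.split("\t")
            chain, resnum = parts[0], parts[1]
            icode = parts[2].strip() if len(parts) > 2 else ""
            if chain_id is not None and chain != chain_id:
                continue
            out.add(f"{chain}:{resnum}{icode}")
    return out
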