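"""Spatial autocorrelation statistics on the surface conservation field.

Three related quantities are computed over the scored surface residues of a
contact graph, all using the same binary neighbourhood (within D Angstrom and
at most three steps on the surface graph):

* the **Moran scatterplot** — each residue's z-scored conservation x_i against
  the centered mean conservation of its neighbours A_i = sum_{j in N(i)}
  (y_j - ybar) / n_i;
* **DSPAC** — the degree of spatial autocorrelation, reported as the Pearson
  correlation of the scatterplot (with a z-scored x-axis the regression slope
  and the correlation coincide up to the scale of the A-axis; the raw OLS
  slope is also available), with a two-sided no-correlation t-test;
* **LMIC** — a Local Moran's I of conservation,
  LMIC_i = (y_i - ybar) * sum_{j in N(i)} (y_j - ybar) / sigma^2,
  tested per residue by a conditional Monte Carlo permutation: residue i's
  value is held fixed while the remaining values are permuted over the other
  surface positions; i is significant when its observed LMIC exceeds the
  lowest of the top alpha-fraction of permuted values (strictly) and its
  conservation exceeds the surface mean.

sigma is the population (1/N) standard deviation, the spatial-statistics
convention for Local Moran's I.  No multiple-testing correction is applied
across residues; per-residue significance is marginal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .conservation import ResidueScores
from .structure_graph import ContactGraph, NeighborhoodSpec, neighborhoods

__all__ = [
    "MoranScatter",
    "DspacResult",
    "LmicResult",
    "McTestResult",
    "moran_scatter",
    "neighbor_average",
    "dspac",
    "dspac_no_correlation_test",
    "lmic",
    "lmic_mc_test",
]


@dataclass
class MoranScatter:
    ids: list[str]
    x: np.ndarray  # z-scored conservation
    a: np.ndarray  # centered neighbour average

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\tx\tneighbor_avg\n")
            for nid, xi, ai in zip(self.ids, self.x, self.a):
                fh.write(f"{nid}\t{xi:.6g}\t{ai:.6g}\n")


@dataclass
class DspacResult:
    dspac: float  # Pearson correlation of the Moran scatter; NaN if degenerate
    slope: float  # raw OLS slope of a ~ x
    n_points: int
    p_value: float
    D: float | None = None
    X: float | None = None

    @property
    def degenerate(self) -> bool:
        return not math.isfinite(self.dspac)


@dataclass
class LmicResult:
    values: dict[str, float]  # node_id -> LMIC
    mean: float  # surface conservation mean
    sigma: float  # population standard deviation


@dataclass
class McTestResult:
    lmic: LmicResult
    thresholds: dict[str, float]  # node_id -> permutation threshold
    significant: dict[str, bool]
    p_values: dict[str, float]  # (1 + #{perm >= obs}) / (n_perm + 1)
    perm_counts: dict[str, int]  # permuted datasets generated per residue
    n_perm: int
    alpha_fraction: float
    seed: int

    @property
    def significant_ids(self) -> set[str]:
        return {nid for nid, s in self.significant.items() if s}

    def write_tsv(self, path, scores: ResidueScores) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\tcons\tlmic\tperm_threshold\tp_value\tsignificant\n")
            for nid in self.lmic.values:
                fh.write(
                    f"{nid}\t{scores.values[nid]:.6g}\t{self.lmic.values[nid]:.6g}\t"
                    f"{self.thresholds[nid]:.6g}\t{self.p_values[nid]:.6g}\t"
                    f"{int(self.significant[nid])}\n"
                )


def _scored_arrays(scores: ResidueScores, graph: ContactGraph, spec: NeighborhoodSpec):
    """Ordered ids, values, and neighbourhoods restricted to scored residues."""
    order = [nid for nid in graph.surface_ids if nid in scores.values]
    y = np.array([scores.values[nid] for nid in order])
    nb_all = neighborhoods(graph, spec)
    scored = set(order)
    nb = {nid: nb_all[nid] & scored for nid in order}
    return order, y, nb


def neighbor_average(
    scores: ResidueScores, graph: ContactGraph, spec: NeighborhoodSpec, i: str
) -> float:
    """Centered mean conservation over the neighbours of residue ``i``.

    NaN when the neighbourhood is empty (the residue is then excluded from
    the scatterplot rather than raising).
    """
    order, y, nb = _scored_arrays(scores, graph, spec)
    if i not in nb:
        raise ValueError(f"residue {i} is not a scored surface residue")
    ybar = y.mean()
    idx = {nid: k for k, nid in enumerate(order)}
    members = nb[i]
    if not members:
        return float("nan")
    return float(sum(y[idx[j]] - ybar for j in members) / len(members))


def moran_scatter(
    scores: ResidueScores, graph: ContactGraph, spec: NeighborhoodSpec
) -> MoranScatter:
    """Scatterplot points for residues with at least one scored neighbour."""
    order, y, nb = _scored_arrays(scores, graph, spec)
    if len(order) == 0:
        raise ValueError("no scored surface residues")
    ybar = y.mean()
    sigma = y.std()  # population
    idx = {nid: k for k, nid in enumerate(order)}
    ids, xs, avs = [], [], []
    for nid in order:
        members = nb[nid]
        if not members:
            continue
        a = sum(y[idx[j]] - ybar for j in members) / len(members)
        ids.append(nid)
        xs.append(y[idx[nid]])
        avs.append(a)
    xs = np.array(xs)
    avs = np.array(avs)
    if sigma > 0:
        xs = (xs - ybar) / sigma
    else:
        xs = xs - ybar
    return MoranScatter(ids=ids, x=xs, a=avs)


def dspac(
    scores: ResidueScores,
    graph: ContactGraph,
    spec: NeighborhoodSpec,
    D: float | None = None,
    X: float | None = None,
) -> DspacResult:
    """Degree of spatial autocorrelation of the conservation field.

    Pearson correlation (and raw OLS slope) of the Moran scatterplot, with
    the two-sided no-correlation t-test p-value.  Degenerate scatters (fewer
    than 3 points or zero variance on either axis) yield NaN."""
    sc = moran_scatter(scores, graph, spec)
    n = len(sc.ids)
    if n < 3 or sc.x.std() == 0 or sc.a.std() == 0:
        return DspacResult(
            dspac=float("nan"), slope=float("nan"), n_points=n,
            p_value=float("nan"), D=D if D is not None else spec.D, X=X,
        )
    r = float(np.corrcoef(sc.x, sc.a)[0, 1])
    slope = float(np.cov(sc.a, sc.x, ddof=0)[0, 1] / np.var(sc.x))
    result = DspacResult(
        dspac=r, slope=slope, n_points=n, p_value=1.0,
        D=D if D is not None else spec.D, X=X,
    )
    result.p_value = dspac_no_correlation_test(result)
    return result


def dspac_no_correlation_test(result: DspacResult) -> float:
    """Two-sided p-value of t = r sqrt((n-2)/(1-r^2)) on n-2 df."""
    n = result.n_points
    if n < 3:
        raise ValueError("need >= 3 scatter points")
    r = result.dspac
    if not math.isfinite(r):
        return float("nan")
    if abs(r) >= 1.0:
        return float(np.nextafter(0.0, 1.0))
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def lmic(
    scores: ResidueScores, graph: ContactGraph, spec: NeighborhoodSpec
) -> LmicResult:
    """Local Moran's I of conservation for every scored surface residue."""
    order, y, nb = _scored_arrays(scores, graph, spec)
    if len(order) == 0:
        raise ValueError("no scored surface residues")
    ybar = float(y.mean())
    sigma = float(y.std())
    if sigma == 0:
        raise ValueError("constant conservation, LMIC undefined")
    idx = {nid: k for k, nid in enumerate(order)}
    values = {}
    for nid in order:
        local = sum(y[idx[j]] - ybar for j in nb[nid])
        values[nid] = float((y[idx[nid]] - ybar) * local / sigma**2)
    return LmicResult(values=values, mean=ybar, sigma=sigma)


def lmic_mc_test(
    scores: ResidueScores,
    graph: ContactGraph,
    spec: NeighborhoodSpec,
    n_perm: int = 10000,
    alpha_fraction: float = 0.05,
    seed: int = 0,
) -> McTestResult:
    """Conditional-permutation significance test of LMIC.

    For each scored surface residue i the coordinates and conservation of i
    are held fixed and the remaining conservation values are permuted over
    the other surface positions, ``n_perm`` times.  This attribute
    permutation is equivalent to randomly exchanging the coordinates of the
    other residues.  The threshold is the ceil(alpha*n_perm)-th largest
    permuted LMIC_i (the lowest of the top alpha fraction); i is flagged
    significant iff observed LMIC_i strictly exceeds it and Cons_i exceeds
    the surface mean.  Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("too few replicates: n_perm must be >= 100")
    order, y, nb = _scored_arrays(scores, graph, spec)
    if len(order) and y.std() == 0:
        # constant conservation: LMIC is undefined, but no residue can be
        # significant either (Cons_i > mean fails everywhere)
        nanv = float("nan")
        return McTestResult(
            lmic=LmicResult(values={nid: 0.0 for nid in order},
                            mean=float(y.mean()), sigma=0.0),
            thresholds={nid: nanv for nid in order},
            significant={nid: False for nid in order},
            p_values={nid: 1.0 for nid in order},
            perm_counts={nid: 0 for nid in order},
            n_perm=n_perm, alpha_fraction=alpha_fraction, seed=seed,
        )
    base = lmic(scores, graph, spec)
    ybar, sigma = base.mean, base.sigma
    idx = {nid: k for k, nid in enumerate(order)}
    centered = y - ybar
    k_top = math.ceil(alpha_fraction * n_perm)
    rng = np.random.default_rng(seed)

    thresholds, significant, p_values, perm_counts = {}, {}, {}, {}
    for nid in order:
        i = idx[nid]
        n_i = len(nb[nid])
        obs = base.values[nid]
        others = np.delete(centered, i)
        # each row is one permuted dataset; the first n_i entries land on N(i)
        block = np.broadcast_to(others, (n_perm, others.size)).copy()
        rng.permuted(block, axis=1, out=block)
        local_sums = block[:, :n_i].sum(axis=1) if n_i else np.zeros(n_perm)
        ref = centered[i] * local_sums / sigma**2
        thr = float(np.partition(ref, -k_top)[-k_top])
        thresholds[nid] = thr
        perm_counts[nid] = len(ref)
        p_values[nid] = float((1 + np.count_nonzero(ref >= obs)) / (n_perm + 1))
        significant[nid] = bool(obs > thr and y[i] > ybar)
    return McTestResult(
        lmic=base,
        thresholds=thresholds,
        significant=significant,
        p_values=p_values,
        perm_counts=perm_counts,
        n_perm=n_perm,
        alpha_fraction=alpha_fraction,
        seed=seed,
    )
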