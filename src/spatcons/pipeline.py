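"""End-to-end orchestration of selection, cluster detection and evaluation.

These functions tie the modules together the way the command line does:
structure -> contact graph -> candidate sweep -> adopted homolog set ->
LMIC Monte Carlo test -> predicted region -> metrics.  They are also the
substrate for the synthetic end-to-end experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import selection as sel
from .config import RunConfig
from .conservation import (
    Alignment,
    SubstitutionTable,
    conservation_profile,
    henikoff_weights,
    map_profile_to_structure,
)
from .predict_eval import (
    FunctionalRegion,
    Metrics,
    PredictionResult,
    functional_region,
    metrics,
    predict_regions,
)
from .simulate import SimulatedFamily, ToyStructure, default_scenario
from .spatial_stats import McTestResult, lmic_mc_test
from .structure_graph import (
    ContactGraph,
    NeighborhoodSpec,
    build_solvent_shell,
    load_structure,
    voronoi_contact_graph,
)

__all__ = [
    "build_graph",
    "run_select",
    "run_predict",
    "ScenarioOutcome",
    "run_synthetic_scenario",
]


def build_graph(pdb_text: str, chain_id: str, config: RunConfig) -> ContactGraph:
    nodes = load_structure(pdb_text, chain_id)
    shell = build_solvent_shell(
        nodes,
        spacing=config.shell_spacing,
        clash_distance=config.shell_clash,
        margin=config.shell_margin,
    )
    return voronoi_contact_graph(nodes, shell)


def run_select(
    graph: ContactGraph,
    query_id: str,
    query_seq: str,
    hits: list[tuple[str, str]],
    config: RunConfig,
    aligner: sel.AlignerFn | None = None,
    master_alignment: Alignment | None = None,
) -> sel.SelectionResult:
    """Length-filter hits, compute identities on the master alignment, build
    nested candidates, and adopt the max-DSPAC (X, D) cell."""
    aligner = aligner or sel.MafftAligner(config.aligner_command)
    kept = sel.filter_hits(query_seq, hits)
    homologs = sel.HomologSet(query_id=query_id, query_seq=query_seq, hits=kept)
    if master_alignment is None:
        master_alignment = aligner(
            [(query_id, query_seq)] + kept, query_id
        )
    sel.compute_identities(homologs, master_alignment)
    candidates = sel.build_candidate_sets(
        homologs, X_grid=config.X_grid, min_sequences=config.min_sequences
    )
    return sel.select_max_dspac(
        homologs,
        candidates,
        graph,
        aligner,
        D_grid=config.D_grid,
        max_separation=config.max_separation,
        identity_floor=config.identity_floor,
    )


def run_predict(
    graph: ContactGraph,
    alignment: Alignment,
    D: float,
    config: RunConfig,
    catalytic: set[str] | None = None,
):
    """LMIC Monte Carlo test and region prediction from one alignment.

    Returns (mc, prediction, metrics-or-None, scores)."""
    table = SubstitutionTable.blosum62()
    weights = henikoff_weights(alignment)
    profile = conservation_profile(alignment, weights, table)
    scores = map_profile_to_structure(
        profile, alignment, graph, identity_floor=config.identity_floor
    )
    spec = NeighborhoodSpec(D=D, max_separation=config.max_separation)
    mc = lmic_mc_test(
        scores,
        graph,
        spec,
        n_perm=config.n_perm,
        alpha_fraction=config.alpha_fraction,
        seed=config.seed,
    )
    prediction = predict_regions(mc, graph, spec)
    scored_universe = set(scores.values)
    result_metrics = None
    if catalytic is not None:
        actual = functional_region(catalytic, graph, radius=config.region_radius)
        universe = (
            scored_universe if config.universe == "surface" else set(graph.node_ids)
        )
        result_metrics = metrics(prediction.predicted & universe, actual, universe)
    return mc, prediction, result_metrics, scores


@dataclass
class ScenarioOutcome:
    adopted_X: float
    adopted_D: float
    adopted_dspac: float
    dspac_by_X: dict[float, float]  # max over D per threshold
    f_score: float
    metrics: Metrics
    prediction: PredictionResult
    selection: sel.SelectionResult


def run_synthetic_scenario(
    seed: int, config: RunConfig | None = None, n_perm: int | None = None
) -> ScenarioOutcome:
    """Run the full method on the default simulated family.

    The generator plants a 10-residue conserved cap on a 150-node sphere; the
    out-group (identities below 40%) conserves the antipodal cap instead.
    Returns the adopted thresholds, the DSPAC-vs-X curve, and the F-score of
    the predicted region against the planted-patch functional region.
    """
    config = config or RunConfig()
    if n_perm is not None:
        config.n_perm = n_perm
    config.seed = seed
    structure, family = default_scenario(seed)
    graph = build_graph(structure.pdb_text, "A", config)
    aligner = sel.IdentityAligner()
    master = family.to_alignment()
    selection = run_select(
        graph,
        family.query_id,
        family.root,
        family.members,
        config,
        aligner=aligner,
        master_alignment=master,
    )
    mc, prediction, result_metrics, _scores = run_predict(
        graph,
        selection.adopted_alignment,
        selection.adopted_D,
        config,
        catalytic=set(structure.pseudo_catalytic()),
    )
    eligible = selection.grid[selection.grid.eligible]
    by_x = {
        float(x): float(sub.dspac.max())
        for x, sub in eligible.groupby("X")
        if sub.dspac.notna().any()
    }
    return ScenarioOutcome(
        adopted_X=selection.adopted_X,
        adopted_D=selection.adopted_D,
        adopted_dspac=float(selection.summary()["adopted_dspac"]),
        dspac_by_X=by_x,
        f_score=result_metrics.f_score,
        metrics=result_metrics,
        prediction=prediction,
        selection=selection,
    )
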