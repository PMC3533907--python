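# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Structure representation

A chain is reduced to one representative atom per residue: C<sub>β</sub>,
or C<sub>α</sub> for glycine and for residues whose C<sub>β</sub> is missing
from the coordinates (the fallback is recorded on the node). HETATM records
are discarded; only the first MODEL is read; for alternate locations the
first-listed conformer is kept; residue identity is (chain, number,
insertion code) in original PDB numbering.

Voronoi adjacency is computed as the edge set of the Delaunay
tetrahedralization of the representative atoms together with a synthetic
solvent shell — a cubic grid (default spacing 3.0 Å) filling the bounding
box expanded by 8.0 Å, minus points within 2.5 Å of any atom. Facet-sharing
Voronoi cells and Delaunay edges coincide for points in general position; a
fixed-seed uniform jitter of 10⁻⁶ Å enforces general position without
affecting any distance at the precision that matters. A residue adjacent to
a solvent point is *surface*; adjacent to a supplied second molecule (and
not solvent), *interface*; otherwise *inner*. The deterministic grid shell
replaces stochastic water scattering: classification only needs *some*
solvent-like point adjacent to every exposed cell, and a grid with spacing
comfortably above the clash distance provides that reproducibly.

The shell parameters are configurable; the defaults were chosen so that the
grid is dense enough to reach every exposed pocket of a typically packed
chain (spacing just above the clash distance) while staying a few thousand
points for a 150-residue structure.

## Neighbourhoods

Two surface residues are neighbours when their representative atoms lie
within *D* Å **and** their separation degree — shortest-path length on the
subgraph induced by surface residues — is at most 3. The path-length bound
removes pairs that are close through the protein body but distant along the
surface. Both criteria are symmetric, so neighbourhood membership is
symmetric. Neighbourhood statistics use the neighbour count as the
normalizer; with binary weights this equals the sum-of-weights
normalization.

## Conservation

Per column, conservation is the weighted mean over unordered sequence pairs
of min–max normalized BLOSUM62 similarity. The normalization range is taken
over the full standard 20×20 table including the diagonal: max m = 11
(Trp–Trp), min m = −4. Consequences worth knowing: a pair involving a gap
or a nonstandard letter (B, Z, X, U, O, *) contributes 0; an all-gap column
scores 0; a perfectly conserved column scores Mut(a,a), which is 1.0 only
for tryptophan (e.g. 8/15 ≈ 0.53 for alanine). The score is used exactly as
defined, without per-column rescaling — the spatial statistics standardize
it anyway, and rescaling would change the meaning of "conserved" across
columns.

Sequence weights are position-based (Henikoff–Henikoff): at each column a
sequence contributes 1/(r·s) with r the number of distinct residue types
and s the multiplicity of its own type; gap cells contribute nothing and
gaps are not a residue type; totals are normalized to sum to one. The
conservation formula is scale-invariant in the weights, so the
normalization is free and makes weight vectors comparable across candidate
sets.

Mapping onto the structure anchors the ungapped query row to the chain's
residue sequence: exact (sub)string match when possible, otherwise a global
pairwise alignment; below 95% identity between query and structure the
mapping is refused. Only surface residues carry scores; structure residues
without a matching column are reported unmapped and excluded from all
spatial statistics.

## Spatial statistics

The Moran scatterplot pairs each scored surface residue's z-scored
conservation (population standard deviation) with the centered mean
conservation of its neighbours; residues with empty neighbourhoods are
excluded. DSPAC is reported as the Pearson correlation of that scatter.
With a z-scored x-axis, the regression slope and the correlation agree up
to the scale of the neighbour-average axis; the correlation is the headline
number because it is scale-free and bounded in [−1, 1], and the raw OLS
slope is computed alongside for anyone who wants it. The no-correlation
test is the standard two-sided t-test, t = r·√((n−2)/(1−r²)) on n−2
degrees of freedom. Scatters with fewer than 3 points or zero variance on
either axis are degenerate: DSPAC is reported as NaN and such cells can
never be adopted.

LMIC_i = (Cons_i − C̄)·Σ_{j∈N(i)}(Cons_j − C̄)/σ², with mean and population
standard deviation taken over all scored surface residues — the
spatial-statistics convention for Local Moran's I. Significance is assessed
by conditional permutation: residue *i*'s value stays fixed while the other
values are permuted over the other positions, which is mathematically
identical to randomly exchanging the other residues' coordinates but
cheaper. The observed value is *not* pooled into the reference set; the
threshold is the ⌈α·n_perm⌉-th largest permuted value (the lowest of the
top α fraction) and significance requires strictly exceeding it, plus
above-mean conservation. With n_perm = 10,000 and α = 0.05 the expected
flag rate among above-mean residues under exchangeability is
500/10001 ≈ 0.04995. All residues are tested and the above-mean filter is
applied at the decision step; testing only above-mean residues would yield
the same flag set. **No multiple-testing correction is applied across
residues** — per-residue significance is marginal, and the prediction
consumer should treat the flag set as a region hypothesis, not as
residue-level inference.

Determinism: one seeded generator drives all permutations in a fixed
residue order, so results are bit-identical for a fixed seed.

## Homolog-set selection

Hits are length-filtered to [80%, 150%] of the query length (inclusive).
Percent identity to the query is computed on the pairwise projection of the
master alignment with the union-non-gap denominator: matches over columns
where at least one of the pair has a residue. Candidate sets are nested by
construction — members at threshold X are a subset of members at X−5 — and
a candidate is eligible when it holds at least 10 sequences including the
query (exactly 10 qualifies). Each eligible candidate is realigned through
an injected aligner (external `mafft` by default; an identity aligner for
indel-free families; the test suite never shells out), scored, mapped, and
evaluated at every D. The maximum-DSPAC cell is adopted; exact ties break
toward larger X (fewer, closer sequences) and then smaller D (tighter
neighbourhoods). D is optimized jointly with X; a fixed-D workflow is
available by passing a single-element D grid.

## Prediction and evaluation

The predicted functional region is the union, over significant residues, of
each residue with its neighbourhood at the adopted D. The reference region
is the catalytic residues plus every residue whose representative atom lies
within 9 Å of their geometric center. The evaluation universe defaults to
the scored surface residues — the only residues the method can ever flag —
and the reference region is intersected with it before counting; a
configuration switch widens the universe to all residues. Zero-denominator
conventions: sensitivity, specificity and F report 0; selectivity reports
1 when there are no negatives to misclassify.

## Synthetic fixtures

The generator emulates the scenario that motivates DSPAC-based selection.
A toy structure places n residues (uniformly random amino acids) on a
Fibonacci sphere; the planted patch is a polar cap. The sphere radius is
set so a 9 Å functional region subtends roughly 18% of the surface,
matching the regime of real enzyme chains (a ~20-residue functional region
on a 100–150-residue surface); this also keeps the surface graph connected
at the smallest neighbour threshold of the sweep. An "onion" geometry (a
small shell inside a dense one) exercises inner-residue classification, and
a lattice slab provides a flat control.

Families are indel-free, so the identity alignment is exact and realized
identity equals the fraction of positions matching the root. In-group
sequences mutate only non-patch positions, with substitutions drawn
proportionally to 2^BLOSUM62, until the target identity is reached; each
position is touched at most once, so realized identity lands within one
mutation step of its target. In-group targets span the threshold grid with
quadratic spacing concentrated just above the out-group split — the shape
of a real homolog search, where distant homologs vastly outnumber close
ones. That concentration drives the background conservation to its floor by
the time the threshold reaches the split, so the only marginal effect of
admitting the out-group is erosion of the planted patch — which is what
makes the DSPAC-versus-X curve convex with an interior maximum at the
split. Out-group sequences replace the original patch with uniformly random
different residues (functional divergence substitutes chemically unlike
residues) and conserve the antipodal cap instead, placed at the opposite
pole so the two regimes are spatially unambiguous. The pseudo-catalytic
truth is the three patch residues nearest the patch centroid.

What the fixtures do **not** emulate: indels and alignment error, buried
functional residues, taxonomic weight structure beyond redundancy,
non-spherical surface topology, and retrieval noise in the hit list.
Passing tests therefore demonstrate that the statistics and the selection
mechanism behave as designed under the planted model — not that the method
attains any particular accuracy on real chains.

## Problem sizes and experiment design

The standard experiments use a 150-node sphere with a 10-node patch, 15
in-group and 5 out-group homologs; selection sweeps the full 16×9 grid;
significance runs use 10,000 permutations for single runs and 1,000 inside
the 20-seed replication loops, where only the flag decisions (stable well
before 10,000 replicates) enter the aggregate. Null calibration uses a
200-node random geometric graph, 20 replicates at 1,000 permutations.
Oracle comparisons (brute-force double loops and direct formula
evaluations) run on instances of at most 12 nodes or 6 sequences at
tolerance 10⁻¹².

## Known limitations

* The solvent-shell grid approximates tessellated water; very deep, narrow
  pockets reachable by a single water but not by a 3.0 Å grid point could
  be classified inner.
* DSPAC compares candidate sets of different sizes through scatters with
  different point counts; no small-sample correction is applied, matching
  the original design.
* The conditional permutation assumes exchangeability of conservation
  values across surface positions under the null; real conservation fields
  have spatial structure even off functional sites (e.g. folding cores
  touching the surface), so real-data flag rates are not calibrated at α.
* Identity thresholds are computed from the master alignment; a different
  aligner can shift identities near candidate boundaries.
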