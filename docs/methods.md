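# Methods

This note records the modelling assumptions, default parameters and
numerical choices behind each module, what the synthetic generators do and
do not emulate, and the design decisions taken where the methodology left
room.

## Flux polytope and LP conventions

All analyses operate on the steady-state flux polytope
`P = {v : Sv = 0, lb ≤ v ≤ ub}` of a genome-scale metabolic model.
Exchange reactions touch exactly one metabolite; negative exchange flux is
uptake, positive is secretion; flux units are mmol·gDW⁻¹·h⁻¹ (interpreted
as mmol/day at unit biomass in the community module). Bounds default to
[−1000, 1000] for reversible and [0, 1000] for irreversible reactions when
a file does not state them.

LPs are solved through COBRApy on GLPK. Feasibility comparisons use an
absolute tolerance of 1e-6 and optimality 1e-9 relative; every test
tolerance derives from these. Parsimonious FBA fixes the objective at a
fraction (default 1.0) of its optimum and minimizes Σ|v| by splitting each
flux into non-negative forward/backward parts — exact for LPs, no integer
variables. FVA solves two LPs per reaction; directions the solver reports
unbounded are clipped to ±1000 so downstream arithmetic stays finite (the
generating models are bounded anyway). Degenerate optimal faces mean flux
*vectors* are not unique; tests therefore compare objective values and
uniquely determined fluxes only. The test suite cross-checks all three
primitives against an independent scipy/HiGHS implementation built
directly from the stoichiometry.

## Relative expression integration (RMetD)

The integration step answers: *given only the direction and significance
of expression changes between a condition and a reference, how do the
achievable fluxes differ?* Its stages, in order:

1. Diet uptake limits are applied to both model copies (uptake lower bound
   = −amount).
2. Each objective product is maximized *independently* and its secretion
   lower bound set to `product_floor_fraction` (default 0.20) of that
   maximum in both copies. The floors guarantee the comparison happens on
   a physiologically working model rather than a vacuous zero-flux one.
   Computing the maxima independently (no other product's floor active)
   is a choice; with floors typically at 20 % it is rarely binding either
   way.
3. Gene calls (Q below `q_threshold`, default 0.05) are projected onto
   reactions through the GPR rules: a reaction is up/down only if *all*
   its significant genes agree; disagreeing genes neutralize the reaction
   (direction `unchanged`, reason `mixed-directions`). Genes absent from
   the model are counted in a coverage report, never errors.
4. FVA is run for the mapped reactions in the reference copy with the
   floors active but *without* fixing the primary objective at its
   optimum — fixing it would collapse the very ranges the scaling acts on.
5. The FVA interval becomes a hard bound in the reference copy. In the
   condition copy the interval is scaled multiplicatively: both endpoints
   × (1 + α) for up, × (1 − α) for down (α = `alpha`, default 0.20).
   Multiplying both signed endpoints expands an interval away from zero
   for up-regulation (e.g. [−5, 10] → [−6, 12]) and shrinks it toward zero
   for down-regulation, preserving reversibility and the ordering of the
   bounds. Scaled bounds are optionally clamped back into the original
   model bounds (`cap_at_model_bounds`, default on).
6. Both copies are solved by parsimonious FBA maximizing the primary
   product; secondary products are read off that same solution rather
   than optimized separately (an optional lexicographic pass can be added
   per product, but a single primary objective matches the intended
   chylomicron-first use).

Pushing *ranges* rather than point fluxes is deliberate: reference flux
distributions of genome-scale models are degenerate, but variability
ranges are robust, and a relative push encodes "this enzyme can carry
more/less flux" without inventing absolute rates.

If the tightened bounds make a copy infeasible, the result is flagged and
an elastic re-solve (non-negative slack on each tightened bound, minimize
total slack, scipy/HiGHS) reports the minimal set of conflicting bounds.
Bounds are never silently relaxed — a conflict is information about the
model, not noise to be repaired.

`sensitivity_scan` repeats the run over a list of α values (default
{0.1, 0.2, 0.3}) and flags stability when the sign of
(condition − reference) agrees across all α for every product. The α
default is arbitrary by construction; the scan is the guard against that
arbitrariness.

## Flux sampling and regulation calls

The sampler is an artificial-centering hit-and-run walk. Bound-pinned
fluxes (ub = lb) are folded into the equality system, so the null-space
projection preserves them exactly and determined fluxes have strictly zero
sample variance. Warmup points are the FVA vertex witnesses (padded with
seeded convex combinations up to `warmup`, default 200); each step runs
from the running center through a randomly chosen stored point, the step
length is uniform over the feasible chord, and every `thinning`-th point
(default 10) is kept. Points are re-projected onto the null space each
step, so the steady-state residual never accumulates (‖Sv‖∞ < 1e-6 for
every row is asserted in tests). Given a seed the sample matrix is bitwise
reproducible. The walk is approximately uniform — exactly uniform in one
dimension, adequate for the mean/spread summaries used downstream; no
uniformity guarantee is claimed for high-dimensional polytopes, and loop
laws are not enforced.

A reaction's flux is called shifted when
`|µ_cond − µ_ref| > separation × (σ_ref + σ_cond)` — non-overlap of the
mean ± separation·σ intervals — and *transcriptionally regulated* when the
shift's sign matches the reaction's expression direction. The methodology
this follows states no numeric criterion; `separation` defaults to 1.0 in
the library and is exposed in every caller. The pipeline's synthetic study
uses 0.5, because a ±20 % push of a flux interval moves a uniform
marginal's mean by roughly half the summed spreads; 1.0 would demand a
larger expression effect than the study conditions encode.

## Ensemble comparison

Distances are raw symmetric-difference counts between element-id sets
(reactions, metabolites, genes), never normalized by union size. The
directed decomposition |A\B| / |B\A| is always reported as a labelled
ordered pair, since "changes required to transform A into B" is otherwise
ambiguous. The heterogeneity degree is mean pairwise distance divided by
maximum pairwise distance — the only dimensionless [0, 1] combination of
exactly those two statistics — with degree 0 for a fully uniform ensemble.
Core = present in every model; unique = present in exactly one; the core
percentage is rounded to one decimal to match how such figures are
conventionally printed.

## Diet partitioning and community simulation

The diet is grams/day per component in four classes. Defaults: bacteria
receive at most 40 % of protein and digestible carbohydrate and 5 % of
non-digestible carbohydrate; the colon receives 5 % of protein and
digestible carbohydrate; the small-intestine epithelium takes the protein
and digestible-carbohydrate remainder (55 %). The class splits not fixed
by those constraints are package choices: fat is routed entirely to the
epithelium (long-chain fatty acids are absorbed in the small intestine),
and the non-digestible remainder (95 %) passes to the colon, which is
where resistant fiber ends up. Protein mass is expanded into amino acids
by an explicit weight-fraction profile; every gram→mmol conversion
requires an explicit molar mass (g/mmol) — there is no internal lookup
table, so unit errors fail loudly.

The community scheme is round-robin: members are processed in input order
(documented as significant); each member receives a share of every pool
nutrient, maximizes biomass by FBA, has its fluxes fixed by pFBA, and its
secretions join the shared pool. Contested nutrients are split
proportionally to each waiting member's demand, probed per member by an
FVA max-uptake query against the current pool — proportional sharing is
the one order-free rule within a round. Accounting across rounds is
Gauss–Seidel: the round starts with every member's previous-round
secretions in the pool, and a member's stale secretion is swapped for its
fresh one when its turn comes, so production is never consumed twice.
Rounds repeat until every growth value changes by less than `tolerance`
(default 1e-6) or `max_rounds` (default 20) is hit, in which case the
result carries `converged = False` and the growth trace. Daily amounts act
directly as flux caps for a single simulated day at unit biomass; there is
no dynamic biomass integration and no fixed abundance ratio between
members.

## Reporter metabolites and statistics

Gene p-values are clamped into [1e-15, 1 − 1e-15] before the
normal-quantile transform, keeping every z finite. A metabolite's neighbor
genes are those in the GPR of any reaction touching it; scoring uses
two-sided p-values without sign (a signed variant would score up- and
down-regulation separately; the unsigned form is the classical one).
The size-k background (µ_k, σ_k) is estimated from 10,000 seeded draws per
distinct k out of the scored model genes; under null scores the corrected
z is approximately standard normal. One calibration caveat: genes shared
among many metabolites leave a common component of ±~0.15 in the
metabolite-mean of a *single* null score table; the calibration tests
therefore pool several independent null tables, which averages that
component out without touching the statistic itself.

The greedy subnetwork grows from the best-scoring metabolite through the
reaction–metabolite bipartite graph, at each step adding the adjacent
scored metabolite that maximizes the mean corrected z of the set. A strict
mean-improvement stop would never grow past the seed (the mean cannot rise
by adding to its own maximum), so expansion stops when the best candidate
no longer carries positive corrected evidence (z ≤ 0) or `size_limit` is
reached; ties break lexicographically. This is a deliberately simple
expansion, not the full simulated-annealing subnetwork search of the
original reporter framework.

Welch's t statistic uses the Welch–Satterthwaite df; it equals the pooled
t-test when variances and group sizes match. Zero variance in both groups
with equal means returns p = 1; with unequal means it is rejected as
degenerate. BH-FDR goes through statsmodels' step-up implementation.
Per-segment DE tables are merged by lowest Q per gene, and genes
significant in opposite directions across segments are dropped entirely —
conflicting evidence is worse than none.

## Synthetic data: what it emulates, and what passing tests show

The generators emulate the *structure* of the real inputs at hand-checkable
scale: toy GEMs with analytically known optima (linear chain, two-route
diamond, futile cycle); an "epithelium" sketch with diet uptakes, a
glutathione-synthesis chain (glutamate + cysteine → γ-glutamylcysteine,
+ glycine → GSH, with a two-subunit ligase complex in the GPR) and
chylomicron/HDL assembly competing for a shared lipid pool; a
producer/consumer pair reproducing the saccharolytic-acetogen /
butyrogenic-acetate-consumer motif; DE tables with controlled up/down
fractions (sub-threshold Q uniform on [0.001, 0.04], null on [0.06, 1])
and exact reaction-level ground truth; and log-normal two-group
metabolomics (base log-mean 2.0, noise σ 0.25 log-units, n = 6 + 6 as in a
typical germ-free comparison, planted log-fold effects). Effect-size
defaults were fixed once so that recovery tests hold with high power at
these sizes.

What they do **not** emulate: genome-scale network density and degeneracy,
probe-level microarray noise, compositional coupling between diet
components, thermodynamic or crowding constraints, or realistic biomass
stoichiometries. Passing tests therefore demonstrate that the algorithms
are implemented correctly and behave as specified on controlled inputs —
not that the biological conclusions transfer to any particular organism.
The published genome-scale figures (e.g. ensemble heterogeneity degrees
near 0.77, or absolute chylomicron levels) require the deposited mouse and
bacterial GEMs plus the original expression and diet datasets, which the
package accepts as optional external inputs in the same formats.

## Problem sizes and reproducibility

Default study sizes — 2,000 sample points at thinning 5 on ≤ 13-reaction
models, 2,000–10,000 background draws for reporter scoring, 1,000-analyte
null panels — were chosen so every property is measured with comfortable
Monte-Carlo margins while a full run stays in seconds. A single global
seed fans out to stages by SHA-256 hashing of the stage name (all derived
seeds < 2³¹), so stages are independently reproducible and TSV outputs are
byte-identical across runs with the same config and seed.

## Known limitations

* The sampler trades exact-uniformity guarantees for determinism and
  simplicity; use longer thinning for publication-grade marginals.
* The regulation call is a stand-in for an unspecified significance rule;
  its `separation` threshold is a free parameter and should be reported
  with any result.
* Round-robin member order matters when demands collide; the proportional
  split removes the worst of it, but results for > 2 members should be
  checked under permuted order.
* The greedy reporter subnetwork is a local search; it can miss disjoint
  high-scoring regions by construction.
* SBML round-trips preserve element sets, bounds, objectives and GPR truth
  tables, not annotation-level metadata.
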