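# Methods

This note documents the models and procedures implemented in `absflow`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Knowledge representation and reasoning

An ontology is the five-tuple O = (C, R, H^C, H^R, I): concepts, relations,
the two subsumption hierarchies and the instantiation assertions.  We store
it as a flat list of axioms over named entities in a line-oriented text
format (one axiom per line, tab-separated); six axiom forms are supported —
subclass, subproperty, existential restriction C ⊑ ∃P.D, class assertion,
object-property assertion and data-property assertion.  This is a
deliberately small fragment: no negation, no cardinality, no nominals, no
tableau reasoning.  It is exactly the fragment the workflow queries need
(conjunction and existential restriction over named fillers), and it keeps
classification decidable by plain graph closure — the "reasoner" is the
reflexive-transitive closure of the subclass/subproperty relations, with
cycles rejected as errors.

**Merging.** Both inputs are rewritten into a fresh namespace; entities
with the same local name unify (that shared vocabulary is how domain
knowledge hooks into data-mining knowledge), and a shared name with two
different kinds is an error rather than a silent rename.  Byte-identical
axioms are deduplicated in one linear pass; nothing else is, so the merge
is conservative: every input axiom is present in the output.

**Restriction-path extraction.** The kept set is a least fixed point of
four rules seeded at the task entity: (i) superclasses and superproperties
of kept entities are kept; (ii) an outbound restriction from a kept class
keeps the property, the filler, and the filler's whole subclass subtree —
the filler names the *kind* of resource the task needs, so its
specializations must remain queryable; (iii) an inbound restriction into a
kept class keeps its subject one step, after which rule (i) applies again;
(iv) individuals typed by kept classes are kept.  Axioms survive iff their
full signature is kept (data-property annotations travel with their
subject).  The traversal is deliberately asymmetric in the subclass
direction (up always, down only through restriction fillers): this is what
excludes sibling subtrees — classification and clustering algorithms — while
keeping the descriptive algorithms that the consistency-analysis task
reaches through its `employs` restriction.  The fixed-point rule is an
interpretation of a "bottom-up restriction path"; it is validated by the
extraction outcome (descriptive algorithms kept, induction algorithms
dropped) and by the invariant that workflow construction on the extracted
sub-ontology equals construction on the full merge.

**Query semantics.** A named class X satisfies the atom `C` iff X ⊑ C in
the closure, and `P some C` iff some asserted restriction X' ⊑ ∃P'.C'
exists with X ⊑ X', P' ⊑ P, C' ⊑ C.  Individuals satisfy atoms through
their asserted types and property assertions.  Answers are sorted
lexicographically, so they are deterministic.  Definitional competency
questions ("what are the outputs of ...") are filler lookups — restrictions
inherited from superclasses included — and one numeric definition (the
long-time-series threshold, 700) is a typed data-property literal.

**Packaged content.** The DM Core knowledge base covers the six CRISP-DM
stages chained by `hasPostprocess`, their sub-processes, process
input/output restrictions (missing-value processing consumes
`DataWithMissingValue` and produces `DataWithoutMissingValue`; modelling
requires the latter), the algorithm taxonomy, and the entities needed by
the nine competency questions.  The medical domain knowledge base adds the
medical analysis tasks and the two domain-specific descriptive algorithms.
The fixture contains the minimal axioms that support the competency suite
and the workflow — characteristics whose derivation the source material
does not axiomatize (e.g. the three characteristics of the Bayesian
algorithm) are asserted directly.  Data characteristics are modelled as
classes, not individuals, because restriction fillers and query atoms
range over named classes in this fragment.

## Workflow construction

`profile_data` estimates the characteristics used for selection:
continuous vs integer-valued data; presence of missing values; the
missingness mechanism; long-time-series and small-sample flags (the
long-series threshold is looked up in the knowledge base, not hard-coded).
The MNAR screen is a logistic regression of the per-entry missingness
indicator on the mean absolute standardized value of the same parameter at
adjacent observed time points; a significantly positive slope (p < 0.05)
flags `Missing_not_Random`, otherwise `Missing_at_Random`.  The screen has
leverage only when values correlate across time — patients with stable
individual baselines — which the generator provides through a patient
random effect; on data without any cross-time correlation the screen is
conservative (it cannot see the mechanism and reports MAR).

`build_workflow` follows the four query steps — stages, available
processes per stage, suitable processes, suitable algorithms — then the
query-execute-estimate cycle: applying a selected data-transforming
process replaces its consumed input characteristics by its outputs in the
profile state, and readiness of later stages is checked against the
updated state.  A process is *suitable* when all its declared input
characteristics are satisfied; among applicable processes the most
specific is kept.  Candidate algorithms are those declared `employedBy`
the process; the suitability score of a candidate is the number of profile
characteristics (plus the task itself) it is `suitableFor`, and **all**
co-optimal candidates are selected — the consistency-analysis task
legitimately selects two data-processing algorithms.  Deployment is
omitted: the pipeline ends at evaluation.  Process order is the
lexicographically smallest linear extension of the precedence relation
(post-process edges plus output-feeds-input edges), so it is deterministic.

## Synthetic cohorts

The generator emulates the *structure* of the clinical data, not its
physiological ranges or units.  Defaults are the study conditions: 391
patients in three groups (131/130/130), six time points, 21 parameters in
four planted blocks of sizes 6/6/5/4.

For group g at time t, a patient's parameter vector is

    x = μ[g,t] + τ_p · ( √φ·L₀ u_p + √(1−φ)·L[g,t] ε )

with L₀, L[g,t] Cholesky factors of equicorrelated block matrices
(within-block ρ_in per the schedule, cross-block ρ_out = 0.1), u_p a
patient random effect shared across time (weight φ = 0.15, giving the MNAR
screen its leverage), ε fresh noise, and τ_p a lognormal patient
instability scale.  Equicorrelated blocks keep the oracle checks analytic;
a heavier-tailed option (Student-t innovations) sits behind a config flag.
Because of the φ-mixture the realized within-block correlation at time t is
φ·ρ_base + (1−φ)·ρ_in[g,t], slightly damping the scheduled swings.

Scheduled conditions (defaults): group 1 holds ρ_in = 0.70 through point 5
and drops to 0.48 at point 6; group 2 wobbles (0.59–0.73) and drops to
0.30 at point 6; group 3 is constant.  Mean shifts follow the same
pattern (largest 5→6 step in groups 1 and 2).  Instability scales are
σ = 0.10 / 1.00 / 0.10 for groups 1/2/3: group 2's wide lognormal spread
is what shifts its per-patient CF distribution and makes the group 1 vs 2
contrast detectable.  Missingness is MNAR: an entry is masked with
probability expit(α + β·|z|) where z is its within-cell standardized value
and β = 1.5; α is solved per dataset so the marginal rate matches the
configured 8%.  Group sizes within the total are not dictated by the data
description, so near-equal thirds are the default.

What passing tests on this generator do *not* show: robustness to
non-Gaussian marginals, unequal block correlation levels, drifting block
membership over time, or informative dropout of whole visits — real
clinical data may have all of these.

## Imputation

KNN with Euclidean distance over jointly observed coordinates, rescaled by
√(p/#shared) so records with different overlap sizes are comparable; the
missing entry is the mean (optionally inverse-distance-weighted) of the
k = 5 nearest donors observed in that column, ties broken by donor row
index.  Columns are standardized before the distance computation because
the ABS parameters live on wildly different scales; imputed values return
to the original scale, which makes the imputer scale-equivariant.  Donors
are all patients at the same time point (cross-group, never cross-time:
post-operative dynamics must not leak into the fill-ins).  Hard
preconditions are errors, not warnings: a row with no observed values, or
a column with fewer than k usable donors.  The neighbour count k is an
implementer's default (5), configurable.

## Criteria function

CF(A_m) = X_mᵀ S_m⁻¹ X_m with X_m the standardized parameter vector and
S_m the Pearson correlation matrix of the reference sample, ridge-
regularized (λ = 1e−6) only when the condition number exceeds 1e10.  Two
properties organize everything else:

* **Monotonicity** — for nested subsets A ⊂ B, CF_A(x) ≤ CF_B(x) for every
  x (Schur-complement argument).  This makes the superset value an upper
  bound for all subsets, so depth-first removal with pruning strictly below
  the incumbent is an exact branch-and-bound; a greedy backward-elimination
  warm start strengthens the pruning.  The removal tree is exponential in
  the parameter count, so the pipeline applies a marginal-screening
  candidate pool (default 10) inside which the search stays exact.
* **The trace identity** — when S_m is estimated from the very rows being
  scored, the *average* CF equals m(n−1)/n exactly, for every m-subset.
  Consequently the per-cell CF table has mean ≈ m by construction, and the
  subset-search objective is only informative against a separate
  evaluation sample (the pipeline estimates on time point 1 and evaluates
  on time point 6).  This is not a defect but a property of the quadratic
  form worth stating plainly, and it is unit-tested as such.

Per-cell estimation (each group × time cell standardized against itself)
makes CF a *within-cell* consistency measure; pooling options exist in the
API.  Group contrasts on per-patient CF then reflect distribution shape —
a heterogeneous group has a heavier-tailed, lower-median CF distribution —
which the rank-based Mann–Whitney test detects.

## Partition functional

F(a, R) = Σ_s Σ_{i<j∈R_s} (a_ij − a) over unordered within-class pairs
(counting each pair once makes the all-singleton baseline exactly zero).
Links a_ij default to |Pearson r| — a strong negative physiological
coupling is still a coupling — with a signed mode exposed.  Optimization is
greedy agglomeration from singletons followed by steepest-ascent local
search (single-element relocations, splits to fresh singletons, and class
merges) to a certified 1-move optimum, best of 20 seeded restarts.  Exact
enumeration of set partitions is used as an oracle up to n = 10; beyond
that the objective is NP-hard and only local optimality is claimed.

**Threshold selection.** For each grid value of a the optimized class
count is recorded; the reported a* is the midpoint of the widest grid run
with a constant, non-trivial class count (a stability plateau — for
planted blocks this sits roughly midway between the cross-block and
within-block correlation levels).  F and the class count at a* complete
the three indicators.

**Dynamics and critical periods.** Indicators are computed per group and
time point.  Because F at the *selected* threshold confounds correlation
change with threshold movement, between-point comparisons use F re-
evaluated at a common per-group reference threshold (the grid point
nearest the median selected a*); the critical period is the consecutive
pair of time points with the largest |ΔF| at that reference (and,
separately, the largest |Δa*|).  The threshold grid is 0–0.90 in steps of
0.02; restarts default to 10 inside the scan for runtime.

## Group comparisons

U counts pairs with x > y plus half the ties, so U_x + U_y = n₁n₂ always.
For pooled sizes ≤ 20 the p-value is exact by full enumeration of the
permutation distribution conditional on the pooled values (ties included);
larger samples use the tie-corrected normal approximation.  The suite
mirrors the conclusions format: pairwise group contrasts on per-patient
mean CF (per-patient values are the only statistically coherent unit), and
time point 1 vs each later point within each group and overall.  No
multiplicity correction by default — matching the reporting style of the
analysis this package reproduces — with Holm adjustment behind a flag.

## Problem sizes and determinism

Every stochastic component takes a seed, and a pipeline rerun with the
same configuration is byte-identical.  The test suite and the acceptance
script use moderate simulation sizes chosen to make the checked properties
comfortably detectable: exhaustive oracles run at n = 10/m = 4 (subset
search), n = 7 (Bell(7) = 877 partitions), 100 random knowledge bases;
recovery and benchmark checks use 20 cohort seeds and 100 imputation
replicates; the qualitative cohort findings are recomputed on three
replicate cohorts and summarized by majority/mean, since six time points
give variance estimates with few degrees of freedom.

## Known limitations

* The DL fragment is minimal by design; importing full OWL ontologies is
  out of scope, and the axiom file format is package-specific.
* The packaged knowledge base contains the fragments the competency suite
  and the ABS workflow exercise, not a complete data-mining ontology.
* Partition optimization is heuristic beyond n = 10, with a 1-move
  optimality certificate rather than global optimality.
* The MNAR screen needs cross-time association to have power; mechanisms
  invisible to adjacent-time magnitudes are reported as MAR.
* CF per-cell means are pinned by the trace identity; CF-based *level*
  dynamics across time are therefore flat by construction under the
  default estimation scheme, and group differences live in the
  distribution shape, not the mean.
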