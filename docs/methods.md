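# Methods

`cadnet` reconstructs a co-occurrence analysis of diagnoses and
comorbidities in a hospitalized coronary-artery-disease (CAD) cohort:
per-term detection rates and sex-stratified odds ratios, weighted
co-occurrence networks over the term sets, community structure by
modularity maximization and map-equation minimization, and an edge-weight
filtering sensitivity sweep. The record-level source data are not public;
only the marginal top-20 tables (counts by sex for 138 male and 57 female
hospitalizations, 195 total) are. The package therefore pairs the
statistics that *can* be recomputed exactly from those printed counts with
a synthetic cohort generator that emulates the cohort's marginal structure
for everything that cannot.

## Statistical model

**Detection rate.** For term *t*, DR(t) = 100 · N_t / N, the percentage of
hospitalization records containing *t*. Rates are rendered to 2 decimals
(half-up); full precision is kept internally. Binomial CIs use the Wilson
score interval by default (Wald available); the published tables print no
DR intervals, so nothing constrains this choice beyond standard practice —
Wilson behaves correctly at the small per-stratum counts involved.

**Sex association.** Each term's 2×2 sex-by-condition table is summarized
by the odds ratio with the Haldane–Anscombe correction — +0.5 added to
*every* cell, not only on zero cells — and a Wald CI on the log scale from
the corrected cells, z = 1.959964:

    OR = ((a+½)(d+½)) / ((b+½)(c+½)),
    CI = exp( ln OR ± z·√(1/(a+½)+1/(b+½)+1/(c+½)+1/(d+½)) ).

Always-on correction is not a matter of taste here: recomputing the
published tables from their printed counts reproduces every finite OR/CI
pair to 2 decimals only under this convention (e.g. renal cysts at 21/138
vs 2/57 gives 4.94 uncorrected but the printed 4.06 corrected). When one
sex has zero events the result is the sentinel INF (no affected females),
ZERO (no affected males) or UNDEFINED (neither), matching the tables'
"INF" convention, rather than a finite corrected estimate.

**Age binning.** Decade bins [30,40), …, [80,90) labelled "30–39" …
"80–89", the convention of the published stratified tables; ages outside
map to "other". Top-k strata rank terms by descending record count with
alphabetical tie-break and pad short strata with "/".

## Co-occurrence networks

One hospitalization record is the co-occurrence unit. Within a record,
every unordered pair of distinct same-category terms (monopartite) or
every diagnosis×comorbidity pair (bipartite) contributes exactly 1 to the
pair's edge weight; node frequency is the number of records containing the
term. Terms are sets per record, so duplicate mentions never inflate
weights. Edge filtering at threshold *w* removes edges below *w* but keeps
all nodes: isolates remain countable, which is what makes the
weak-component count rise monotonically under filtering.

## Community structure

**Modularity.** Weighted Newman–Girvan modularity
Q = Σ_c [W_c/W − (S_c/2W)²], maximized by a Louvain-style optimizer
implemented in the package (greedy local moves to the neighboring
community of largest gain, then aggregation, repeated to convergence).
Node visit order is a seeded shuffle, so results are reproducible given a
seed; the returned Q is always recomputed exactly from the final partition.
Resolution defaults to 1.0. Bipartite networks are scored with the same
unipartite formula applied to the bipartite adjacency (the behavior of
common network GUIs); Barber's bipartite modularity is out of scope.

**Map equation.** Two-level description length in bits for an undirected
weighted network without teleportation:
L(M) = q·H(Q) + Σ_i p_i·H(P^i), with node visit rates p_α =
strength(α)/2W (the stationary distribution of the weighted walk) and
module exit probabilities proportional to module boundary weight.
Minimization uses seeded greedy local moves from the singleton partition
plus community-merge passes; on an edgeless network L = 0 by convention,
and isolate-only modules contribute nothing. The implementation is
validated against hand-evaluated closed forms (single-module triangle:
log₂3 bits; the two-triangle bridge graph under its triangle partition)
and the minimization property L(optimum) ≤ L(single module).

The sensitivity table reports both the Louvain Q and the map-equation
minimum, each for its own partition, so either notion of community
sharpening under filtering can be inspected.

Plain structural metrics are unweighted by design — path length is "number
of steps", betweenness is Brandes on unweighted shortest paths
(unnormalized, endpoints excluded, each unordered pair counted once) — and
delegate to networkx. Average path length averages over connected pairs
only; a network with no connected pair has no path length (rendered "NA").
The hub is the node of maximal *weighted* degree, ties alphabetical.

## Synthetic cohort generator

Presence of condition *c* in patient *i* follows a logistic model with a
single shared Gaussian frailty:

    P(y_ic = 1 | z_i) = logit⁻¹(α_c + β_c·1[male_i] + λ_c·z_i),
    z_i ~ N(0, σ²).

* α_c: per-condition intercept, solved numerically (Gauss–Hermite
  quadrature + Brent root-finding) so the frailty-integrated expected rate
  per sex equals the published rate (male count/138, female count/57;
  all-male or all-female conditions use the half-count-corrected rate so
  the logit stays finite). The sex-mixture-averaged rate then equals the
  printed overall rate by construction.
* β_c: male-vs-female log odds ratio, the difference of the two solved
  intercepts.
* λ_c ≥ 0: frailty loading. σ = 0 makes conditions independent given sex;
  σ > 0 induces positive co-occurrence concentrated on high-loading
  conditions. The calibrated config uses σ = 1.0 with loadings 1.6 for
  hypertension and 1.3 for unstable angina (the two empirical hubs) and
  0.6 elsewhere: one interpretable knob that reproduces the qualitative
  hub structure without pretending to know the unpublished pairwise
  co-occurrence table.
* Ages: per-sex truncated normals on [30, 89] years (male mean 60 sd 11,
  female mean 66 sd 10), matching the reported sex-specific age peaks and
  the stratified tables' 30–89 span; admission years uniform on 2013–2020.

What the generator does **not** emulate: the real cohort's exact pairwise
co-occurrence weights, any higher-order dependence beyond one latent
factor, within-patient repeat hospitalizations, temporal trends, and
city-level heterogeneity. Tests passing on synthetic cohorts therefore
validate the *computations* (counting, estimation, network construction,
community scoring) and the qualitative structure (hubs, monotone
sparsification), not the numerical network metrics of the original data,
which are unrecoverable without the raw records.

## Numerical choices and problem sizes

* Rendered tables round half-up to 2 decimals; comparisons against the
  printed tables happen at that precision, internal values at full float
  precision.
* Louvain and map-equation searches use strict-improvement thresholds of
  1e-15/1e-12 to keep tie-breaking deterministic under a recorded seed.
* Monte-Carlo checks run at n = 20 000 patients (point recovery of a
  known generative odds ratio, tolerance band 1.85–2.15 around 2.0) and
  500 replicates of n = 2 000 (Wald CI coverage, threshold 92%); the
  sensitivity sweep property checks use n = 1 000 cohorts and thresholds
  {1, 2, 3, 5, 10}, a grid spanning unit weights to the ≥10 regime of the
  published pair tables. These sizes give comfortable statistical margins
  while keeping the whole suite fast.
* The default threshold grid {1, 2, 3, 5, 10} is a package choice; the
  original analysis does not publish its grid.

## Known limitations

* The raw→canonical term maps used in the tests are illustrative; the
  original normalization was manual and clinician-reviewed and its full
  table is unpublished. Matching is exact (case-insensitive, trimmed) —
  no fuzzy matching.
* Modularity/description-length trends under filtering are data-dependent
  and are reported, not asserted, as monotone.
* One record = one hospitalization; no patient-level linkage is attempted.
* The map equation is the two-level undirected form; hierarchical
  (multi-level) coding is not implemented.
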