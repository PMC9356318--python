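# Methods

## Contact model

The unit of observation is the *admission* (one hospitalization); a
readmitted patient contributes separate nodes. Two admissions recorded in
the same hospital unit on the same calendar day are taken to be in contact
for that day — a proxy for direct contact and for indirect exposure
mediated by staff, instruments and the shared environment. A unit-day
roster with *k* patients therefore yields C(k, 2) pairwise contact events,
and repeated colocation on later days adds linearly: the weight of an edge
between two admissions is the number of (unit, day) cells containing both.

Dates are day-granular; stay intervals are inclusive on both ends (a stay
`[d, d]` contributes the single day `d`). Two consequences are worth
stating explicitly:

* **Transfer boundary days.** When one stay ends the day the next begins,
  the patient is on both units' rosters that day. A pair co-located in two
  different units on the same day yields two contact events, one per unit,
  keeping unit-level matrices additive; `dedupe_same_day=True` collapses
  this to one event per pair per day for sensitivity analysis.
* **Isolates.** Admissions with roster days but no co-located partner stay
  in the network with degree 0; node counts are census-like.

Networks are always per-hospital; shared patient identities never create
cross-hospital edges.

## Network measures

Mean degree, degree SD, density, diameter, mean betweenness and mean
closeness are computed on the simple unweighted graph; diameter,
betweenness and closeness on its largest connected component, since
windowed networks are often disconnected and an infinite diameter is
uninformative. Betweenness is unnormalized (raw shortest-path counts);
closeness is the standard inverse-farness in [0, 1]. Modularity is
computed on the weighted graph with greedy modularity maximization
(Clauset–Newman–Moore, as implemented in networkx); no particular
community-detection algorithm is canonical for these networks, so the
method name is recorded in every result for comparability. A single-node
graph reports density and diameter 0; an edgeless graph reports modularity
as missing.

The association of each measure with hospital size (unique patients in
the window) is a Gaussian-family identity-link GLM — ordinary least
squares — with the slope rescaled per 100 patients, a t-based 95% CI and a
two-sided p-value. When the residual variance is zero up to floating-point
fuzz the fit is treated as exact: a noise-free line reports p = 0 with a
zero-width CI, a constant response reports slope 0 and p = 1.

## Mixing matrices

Cell (i, j) of a mixing matrix counts contact events between a class-i
and a class-j patient. Each unordered event adds 1 to (i, j) *and* 1 to
(j, i) — same-class events add 2 to the diagonal — so every matrix is
symmetric by construction, the total count is twice the number of
classified events, and row i's sum is the total contact exposure of
class-i patients (equal to the summed weighted degree of those nodes,
an identity the test suite checks). Axes:

* **age** — 91 single-year classes, 0..90, ages top-coded at 90;
* **elixhauser** — 17 classes, scores 0..16. The score range 0–16
  requires 17 levels even where a 16×16 table is colloquially described;
  the full 17-level axis is used;
* **abx** — the four spectrum ranks narrow < broad < extended <
  protected. An admission's class on a day is the *set* of ranks with an
  exposure record that day (`per_day`, default) or during the whole
  admission (`whole_stay`); which timing the field's convention intends
  is ambiguous, so both are implemented. A multi-rank day contributes the
  full cross-product of the two sets, which is what lets combination
  empirical therapy (e.g. ampicillin + gentamicin in neonatal units)
  produce heavy narrow–extended off-diagonal mass; collapsing each set to
  its broadest rank is available as an option. Events where either side
  has no active rank are excluded from the 4×4 matrix and tallied; the
  companion none-ratio (contacts with neither patient exposed ÷ contacts
  with at least one exposed) accounts for them separately.

Because contacts accrue per day, all matrices are length-of-stay-weighted:
a small group with long stays dominates cells out of proportion to its
headcount. Normalization is cellwise min–max over the whole matrix,
`(x − min)/(max − min)`, so the least-mixed cell maps to 0 and the
most-mixed to 1; a constant matrix is returned as all zeros with a
degeneracy flag, preserving "min maps to 0" where the formula itself is
0/0.

## Significance testing

Contingency tables are tested with the chi-squared test of independence
without continuity correction. When any expected cell count is below 5
(Cochran's rule; the threshold is strict `< 5`), 2×2 tables fall back to
Fisher's exact test and larger tables to a seeded conditional Monte Carlo
permutation test (column labels shuffled within the observed margins,
chi-squared statistic, add-one p-value estimator). All tests are
two-sided at α = 0.05. No multiple-testing correction is applied — the
intended use is descriptive comparison of a handful of pre-specified
tables, and this is deliberately left to the caller. An independent
exhaustive hypergeometric enumeration of the Fisher p-value is kept in
the package for cross-checking.

## Synthetic encounter generator

The generator emulates the *structure* of multi-hospital
admission/discharge/transfer data — not any particular hospital system's
magnitudes. Per unit it draws:

* **arrivals** — a homogeneous Poisson process, conditioned on the
  hospital total, with per-unit rates proportional to target census ÷
  mean LOS so that `bed_pressure` is interpretable as mean daily census;
* **length of stay** — log-normal (heavy right tail), per-unit μ/σ on the
  log scale; mixture components may carry an LOS multiplier (see below);
* **age** — a truncated-normal mixture on [0, 90], rounded to integer
  years and top-coded at 90;
* **Elixhauser score** — zero-inflated Poisson truncated to [0, 16],
  matching the empirical pattern that most admissions have score 0 while
  critical-care units shift the distribution upward;
* **antibiotic exposure** — independent Bernoulli per rank per day with
  unit-specific probabilities, under the profile of the unit occupied
  that day. Independence across ranks is what allows one patient to carry
  two ranks the same day, the mechanism behind combination-therapy
  mixing patterns;
* **transfers** — at stay end, with unit-specific probability, the
  patient moves to another uniformly chosen unit, entering on the exit
  day (shared boundary day); chains are capped at 6 stays and truncated
  at the window end. A 1-day hop that would revisit a unit left the same
  day is suppressed rather than emitting a duplicate stay row.

Randomness is one stream per hospital split deterministically per unit
(`default_rng([seed, unit_index])`), so editing one unit's profile leaves
the other units' draws unchanged and every bundle is byte-reproducible
from its config.

Four archetypes fix the study conditions. `uniform_adult`: 8 units, flat
adult age mixture. `young_skew`: 6 units, age mass at 20–40
(obstetric-heavy). `elderly_small`: 5 units; non-ED units draw ages from
a 92%/8% mixture of N(72, 8) and N(90, 0.5), the age-90 component
carrying a 10× LOS multiplier — few patients, very long stays, which is
what produces the (90, 90) hotspot by exposure weighting rather than
headcount. `academic_pediatric`: 12 units including neonatal critical
care with high daily narrow (0.55) and extended (0.50) probabilities and
deliberately small broad (0.03) and protected (0.01) use, so the dominant
whole-stay exposure combination is narrow+extended as under combination
empirical sepsis therapy; pediatric units carry nonzero narrow, broad and
extended use. The default window is 90 days (2017-01-01 to 2017-03-31),
with monthly sub-windows used for network snapshots. Census, LOS and
prescribing figures per unit type are plausibility choices — no public
per-unit reference values exist — and are labeled as such here.

What the generator does *not* emulate: readmissions (each admission is an
independent patient, consistent with per-admission nodes), occupancy or
capacity constraints, seasonal or weekday structure, within-unit spatial
structure (rooms/bays), correlated antibiotic courses (each day is an
independent draw rather than a multi-day course), and agent-level
prescribing. Passing tests therefore demonstrate that the pipeline's
counting, weighting and inference machinery is correct and that the
qualitative mechanisms (LOS-driven hotspots, combination-therapy
off-diagonals) emerge under the stated conditions — not that any
particular real hospital's magnitudes are reproduced.

## Problem sizes and numerical choices

Default test and acceptance runs use hospitals of 400–600 admissions over
90 days and monthly network snapshots of roughly 100–250 nodes — a scale
chosen so the brute-force oracles (all-pairs/all-days/all-units edge
reconstruction; explicit BFS centrality enumeration) remain tractable
while all the mechanisms of interest are well expressed. The
size-regression study uses 24 simulated hospitals per replicate and 100
replicates; test calibration uses 1000 null tables of two multinomial
rows (n = 150 each). Ties in the modal-age and modal-category lookups are
broken by first index / largest count then lexicographic label. The
permutation test is seeded (default 0) and reports the add-one estimator
(hits + 1)/(n + 1), which cannot return p = 0.

## Known limitations

Unit types are free-text NHSN-style labels and are trusted as given; the
package neither validates nor harmonizes them. Elixhauser scores and
spectrum ranks are inputs — deriving them from diagnosis codes or drug
names is out of scope. The colocation definition has no sub-day
resolution, so brief unit visits weigh as full days; conversely same-day
transfers double-place patients by design. Greedy modularity maximization
is one of several defensible community-detection choices and can differ
from Louvain/Leiden partitions on the same graph.
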