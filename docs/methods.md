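# Methods

## Data model

Visual fields are represented as total-deviation (TD) vectors over the
analysis locations of a Humphrey test grid. Grids are stored in right-eye
format: x in degrees positive toward the temporal field, y positive
superior; locations are ordered superior→inferior and, within a row,
nasal→temporal. The 24-2 grid has 54 points of which the two on the
physiologic blind spot at (15, ±3) are excluded, giving analysis dimension
52; the 30-2 grid has 76 points and dimension 74. The 30-2 layout is the
10×10 offset grid minus the six outermost corner points per quadrant, which
makes every 24-2 location coincide with a 30-2 location; 30-2 fields are
converted to 24-2 by coordinate selection.

Left eyes are measured on the mirror image of the grid. A left-eye record
stores its vector in the mirrored layout (same ordering rule applied to the
mirrored coordinates), and conversion to right-eye format is the index
permutation pairing (x, y) with (−x, y). This permutation is an involution
and preserves the multiset of values. Note the analysis sets are mirror
images of each other, not identical: the right grid's nasal column at
x = −27 maps to the mirrored layout's x = +27, and the mirrored blind spot
sits at (−15, ±3).

MD is computed as the unweighted mean of the TD vector, PSD as the
unweighted sample standard deviation about MD. The perimeter vendor's
proprietary per-location variance weights are deliberately not emulated: the
synthetic data are generated and analyzed under one consistent definition,
and no claim is made that these equal instrument-reported indices for real
exports. TD derivation from raw sensitivities uses a supplied normative map;
the packaged synthetic map is age-free, 32 dB at fixation sloping 0.1 dB per
degree of eccentricity.

Reliability filtering uses strict inequalities ("less than"), so boundary
values fail. Records missing an index fail closed by default (configurable).
The trial policy is fixation loss < 20% and false positives/negatives
< 33%; the control policy tightens the false-response limits to < 10%.

## Archetypal analysis

The engine fits the classic two-simplex factorization: X ≈ A·Z with
Z = B·X, rows of A on the k-simplex and rows of B on the n-simplex, by
alternating minimization:

* **Coefficient step.** With Z fixed, all n rows of A solve independent
  simplex-constrained least-squares problems. These are solved jointly by
  FISTA with step 1/L, L = ‖Z Zᵀ‖₂, and Euclidean projection of each row
  onto the simplex (sort-based algorithm), warm-started from the previous A.
  Default 80 inner iterations with a 1e-7 step-change exit.
* **Archetype step.** With A fixed, the unconstrained optimum
  Ẑ = argmin ‖X − A Z‖² is computed by least squares and each row of Ẑ is
  projected back onto the convex hull of the data rows by an exact
  penalized non-negative least squares solve (Lawson–Hanson on the system
  augmented with a sum-to-one row of weight M = 200, then renormalized).
  The same penalized-NNLS primitive is the public `simplex_ls` used for all
  single-field decompositions, so decomposition is deterministic to the bit.

The archetype projection step may transiently increase RSS (a known
property of this decoupled update), so the fit tracks the incumbent best
(A, B, Z) triple and records the incumbent's RSS after each iteration; the
reported trace is therefore non-increasing by construction, and iteration
stops after two consecutive steps with relative improvement below `rel_tol`
(default 1e-6) or at `max_iter` (default 200).

Initialization: the first restart seeds B with k rows chosen by furthest-sum
(greedily adding the row with maximal summed distance to the current
selection, then discarding the random starting row); remaining restarts use
k distinct rows drawn uniformly. Furthest-sum starts land near hull
vertices and empirically remove most of the local-minimum variance that
random starts show at small restart counts. Default 5 restarts; the best
final RSS is kept. All randomness flows from an explicit integer seed
recorded in the model provenance.

No standardization is applied to TD inputs: they are already
deviation-referenced and share units (dB).

After fitting, relative weights (RW) are computed by freshly decomposing
every training row and averaging, rescaled to sum to 100%; archetypes are
renumbered by descending RW (AT1 = most frequent), with ties broken by
ascending average TD and then fit-time index. Decomposition of held-out
fields uses the same fresh simplex projection, so training and new data are
treated identically.

## Model-order selection

Rows are partitioned into 10 folds by a seeded shuffle; for each candidate
k, a model is fitted on the training folds and every held-out row is
decomposed onto it; held-out RSS is normalized by the held-out cell count
(rows × locations) and averaged over folds. The automated elbow rule
returns the smallest k after which every consecutive relative improvement
stays below ε (default 0.05); a curve that never flattens returns the
largest k with a warning, and the CLI emits the curve as CSV so a human can
override. Cross-validation fits use reduced settings (1 restart, max 100
iterations, rel_tol 1e-5, k range 2–8 in the shipped benchmarks) — a
problem-size choice that keeps the 700-fit suite tractable on one CPU
without changing the selected order on the benchmark generator.

## Threshold calibration

For each archetype, absolute weight changes between consecutive visits of
each control eye are pooled across eyes and visit pairs (a
baseline-referenced mode is available); the mean and its 95% t-interval are
reported per AT. Eyes are treated as exchangeable and changes pooled — the
CI is over pooled changes, a documented choice among the defensible
variants. The meaningful-weight threshold is the smallest integer percent
strictly greater than both the largest upper CI limit over abnormal ATs
(all but the designated normal AT) and the uniform-mixture floor 100/k.
With the published control limit of 4.1% and k = 16 (floor 6.25%) the rule
yields 7%.

## Cohort analyses

Meaningful-AT counts use an inclusive threshold (≥). A dominant AT carries
≥ 50% weight; an exact 50/50 tie has no dominant AT (at most one AT can
exceed 50%). Spearman correlations use midranks with two-sided t-based
p-values and Bonferroni correction with m recorded in the report; χ² tests
on arm × (weight ≥ threshold) tables are computed without continuity
correction, and Kruskal–Wallis compares weight values across arms. The
"worst eight" AT grouping ranks archetypes by ascending average TD and is
exposed as an explicit index set rather than hard-coded.

## Classification matching

The full/partial match criteria between the 16 optic-neuritis archetypes
and descriptive defect classes ship as editable YAML data, not code. Labels
are parsed into a base class plus optional vertical (superior/inferior) and
horizontal (nasal/temporal) qualifiers; a label that omits a position is a
wildcard (historic expert classifications often did not record position),
while two stated positions must agree. Multi-component expert labels are
matched per component and the best outcome kept. "Within normal limits"
fully matches only the normal archetype and has no partial set.

## Synthetic cohorts

The generator defines the study conditions. The pattern library places
canonical defects on the 24-2 grid by coordinate masks (altitudinal and
hemianopic half-fields, arcuate band 9–21° eccentricity, nasal step,
temporal wedge, quadrants, central/centrocecal, enlarged blind spot,
peripheral rim, cloverleaf, diffuse −30 dB, normal 0 dB; regional depth
default −25 dB).

The optic-neuritis cohort simulates 456 eyes on the trial visit schedule
(duplicate tests at entry and at 6 months; visits at 4, 15, 30, 49, 91,
133, 180, 365 days). Initial mixing weights are Dirichlet with
concentrations 1.3 (diffuse-severe), 0.4 (normal), 0.035 (each regional
pattern): heavily diffuse, widely dispersed, giving simulated baseline
MD −19.6 ± 7.2 dB and a mean of 2.9 meaningful ATs per baseline field —
the severe, heterogeneous presentation the trial describes. Weights relax
exponentially toward the normal vertex with an eye-specific lognormal time
constant (median 60 days), which stays on the simplex by construction.
Measured TD adds homoscedastic Gaussian noise (σ = 2 dB per location); real
perimetric noise is eccentricity- and depth-dependent, which this generator
does not emulate. About 7% of eyes receive projected baselines (all
sensitivities 0, TD = −normative), 5% of records draw failing reliability
indices to exercise filtering, lateralities alternate to exercise
mirroring, and acuity/contrast are monotone functions of MD plus noise
(logMAR = 2·max(0, −MD)/30, letters = 16·(1 − max(0, −MD)/35)) so their
correlations carry clinically signed structure. Expert labels are emitted
for eyes whose true baseline weights have a ≥ 50% component.

Controls simulate 61 eyes × 9 visits of near-zero fields: a per-visit
global offset (σ = 0.5 dB) plus per-location noise (σ = 1 dB), reliability
drawn to pass the control policy.

Because the generator mixes ideal patterns with simple noise, passing
recovery tests shows the estimator is correct under its own assumptions; it
does not certify performance on real perimetry, where noise is structured
and patterns are not exact convex mixtures.

The recovery and model-order benchmarks mix six well-separated library
patterns (normal, diffuse, both altitudinals, central, peripheral rim) —
all vertices of their convex hull, so archetype recovery is well-posed.
These six are nevertheless affinely *dependent* (superior + inferior
altitudinal equals a normal/diffuse blend exactly), which makes convex
decomposition weights non-unique; benchmarks that must recover the
generating weights therefore use an affinely independent set instead
(normal, diffuse, superior altitudinal, inferior arcuate, central, temporal
wedge). Noise-free end-to-end weight recovery additionally includes one
exactly pure field per pattern, since archetypes are constrained to the
data hull and cannot reach vertices no sampled field attains.

## Numerical choices and limitations

* Simplex projection follows the sort-based algorithm; FISTA restarts are
  not used (momentum is reset per coefficient step call).
* `simplex_ls` penalization biases the sum constraint at most O(1/M²) and
  the final renormalization removes the residual; targets exactly inside
  the hull are recovered to machine precision.
* Degenerate inputs: rank-0 data matrices are fitted but flagged in
  provenance; empty TD vectors, k = 0, n < k, and non-finite inputs raise.
* The elbow rule is an explicit automated stand-in for a visual judgment;
  ε = 0.05 is a default, not a discovered constant, and the CLI exposes it.
* Model-order selection near the noise floor is sensitive to fit quality;
  with single-restart CV fits the curve tail can fluctuate by the size of
  a local-minimum gap, which the furthest-sum initialization largely
  removes.
* The pipeline's fitted archetypes on synthetic data need not correspond
  one-to-one to a clinically derived 16-AT model; analyses that need a
  "normal" or "diffuse" archetype identify them from the fitted model (the
  highest-RW near-normal archetype, and the archetype with the most
  negative average TD, respectively).
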