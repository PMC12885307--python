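# Methods

This note documents the models and procedures implemented in
`biradsrules`, the parameters that matter, the numerical choices made
where the procedure definitions were open, and what the synthetic-data
experiments do and do not show.

## Data model

A sample is a vector of 14 discrete BI-RADS descriptor scores plus a
binary label.  The default schema (`schema_io.default_schema`) encodes the
standard lexicon: Shape (3 levels), Echo pattern (6), Posterior feature
(4), Calcification in mass (4), Ducts changes (3), and nine binary
descriptors (Orientation, margin properties, Angular, Microlobulated,
Spiculated, Architectural distortion, Skin thickening, Edema).  Levels are
consecutive integers from 0.  Labels are encoded internally as +1 (benign)
and −1 (malignant) for the boosting arithmetic; files use the tokens
`benign`/`malignant` or 0/1 (0 = benign).

**Normalization.**  Each feature column of the training matrix is min-max
scaled to [0, 1] using the *observed* extrema, not the schema's
theoretical ranges — the same extrema later serve as the range
denominators of the rule distances, which is only coherent if they
describe the matrix actually mined.  Constant columns map to zero (a
convention; any constant would do, since such columns carry no contrast).
Test samples are scaled with the training extrema and clipped to [0, 1].

## Discrete-safe oversampling

Classic SMOTE interpolates linearly between minority neighbours; on a
discrete scale this produces non-existent scores.  The implementation
instead:

1. clusters *all* samples (labels excluded) with affinity propagation —
   exemplar-based, number of clusters not predetermined, similarity
   = negative squared Euclidean on normalized features;
2. keeps the *safe* clusters, where minority strictly outnumber majority
   members (strict: a 2/2 cluster is unsafe);
3. computes the generation ratio r = (N_maj − N_min)/N_csmin and, per safe
   cluster with n minority members, generates round-half-up(n·r) rows,
   each built by copying, feature by feature, the modal value among the
   seed sample's k nearest minority neighbours.

Parameters: `k_neighbors` (default 5, the neighbourhood of the modal
vote), `damping` (0.9) and `preference` (median similarity, scikit-learn's
default) for affinity propagation, `max_iter` 1000.

Open points resolved here: the neighbour pool is the seed's *own cluster's
minority members*, excluding the seed (keeping synthesis inside the safe
area that motivated the clustering); distances use normalized features;
modal ties go to the value held by the nearest neighbour (deterministic);
seed samples are drawn without replacement unless more rows are requested
than members exist; a lone minority member contributes copies of itself.
Balance is therefore restored only up to one row per safe cluster
(rounding slack), which the tests assert as |ΔN| ≤ |Cs|.

If the message passing does not converge, the implementation retries once
at higher damping and then falls back to a single all-rows cluster with a
logged warning.  (Intermediate exemplars are not exposed by the underlying
solver, so a nearest-exemplar reassignment is not available at that
point; the single-cluster fallback keeps the run alive and is loud.)

## Cocluster mining under the mean entropy score

The object of interest is the column-nearly-constant cocluster: a row and
column subset of the normalized matrix in which each selected column is
(nearly) constant.  Quality is the mean entropy score (MES): group each
column's entries by **exact value equality**, take the Shannon entropy of
the group proportions in natural log, and average over columns.  Exact
grouping (rather than re-clustering within the column) is deterministic
and is the natural limit for discrete features, whose normalized values
remain discrete; delta is therefore on a nats scale, with ln 2 ≈ 0.693 the
entropy of a 50/50 binary split.

Mining:

- **Seeding.**  For each feature column, 1-D agglomerative clustering
  with complete linkage, cut at height *Mic* — each seed group has
  diameter ≤ Mic.  The linkage runs on the column's distinct values (the
  diameter criterion is multiplicity-invariant) and maps back to rows.
  Groups below `min_rows` are discarded immediately, since they could
  never survive the final size filter.  With the default Mic = 0.1 —
  below the smallest normalized level gap of 0.2 — seeding reduces to
  exact value groups.
- **Refinement.**  The seed's rows are paired with *all* 14 columns; then,
  while MES > delta, every single-row and single-column deletion that
  respects the size floors (5 rows × 3 columns) is evaluated and the one
  minimizing the resulting MES is applied.  Ties prefer row deletion,
  then the lowest index.  If the floors block all deletions while
  MES > delta, nothing is emitted.  Deleted rows/columns are never
  re-inserted.  The per-step evaluation is O(r·c) via an incremental
  entropy identity (e = ln r − Σ n ln n / r), so refinement of a seed is
  O(r²·c) overall.
- **Dedup.**  Identical (row-set, column-set) results from different
  seeds are merged.  Overlapping coclusters are permitted.

Mic and delta are data-dependent; `grid_search_params` picks them by
cross-validated accuracy of the full downstream pipeline, breaking ties
toward the smaller delta, then the smaller Mic (preferring the stricter,
more conservative rule set).  Defaults Mic = 0.1, delta = 0.05 suit the
discrete schema: exact-equality seeds and near-constant blocks.

**Greedy geometry, for interpretation.**  The greedy trades rows against
columns: deleting one noisy column often lowers MES faster than deleting
the many rows that pollute it, so refinement tends toward wide-row,
narrow-column blocks at the `min_cols` floor.  Consequently a planted
block is recovered *exactly* when its pattern dominates: in the recovery
experiments the planted blocks have exactly 3 columns on high-arity
descriptors, background-rare pattern values, and cover two-thirds of
their class.  Weaker or wider blocks are still found but may surface as
an equivalent zero-MES variant (a subset of columns with a superset of
matching rows) — a genuine ambiguity of the objective, not a defect of
the search.  Ground truth for exact-recovery checks is the
*pattern-matching row set* (`synthetic_data.matching_rows`): rows that
match a planted pattern by chance extend the same column-constant block
and are indistinguishable in principle.

## Rules, weak classifiers, boosting

A cocluster becomes a rule by column averaging; its label is the majority
class of its rows, required to exceed a 0.65 winning rate *strictly* (a
purity of exactly 0.65 discards).  Whether the vote should count only the
cocluster's rows or all matching rows in the matrix is ambiguous; the
cocluster's own rows are used.

Weak classifiers are all l·k (benign, malignant) rule pairs.  The
distance from a sample to a rule is the Euclidean norm of the difference
on the rule's columns, divided by ‖f_max − f_min‖₂ of those columns in
the training matrix (√c after normalization, unless columns are
constant); a pair whose denominator vanishes is skipped with a warning.
Benign wins on a strictly smaller benign distance; ties go to malignant —
for a screening tool the conservative direction is toward flagging.

Boosting is discrete two-class AdaBoost over the *fixed* pool: weak
classifiers are never re-fit; each of T = pool-size rounds selects (with
replacement) the member with minimal weighted error ε_t, weights it
w_t = ½·ln((1−ε_t)/ε_t) (ε clamped to [1e−10, 1−1e−10]), and re-weights
the sample distribution.  A round whose best ε_t ≥ 0.5 ends training; if
that happens in round one, fitting fails (`fallback="majority"` degrades
to majority-class prediction instead, which the parameter grid search
uses to score rule-free configurations).  Duplicate selections merge by
summing weights.  A weighted vote of exactly zero reads as benign
(documented tie-break; the margin is exposed via `vote_margin`).

## Evaluation harness

Malignant is the positive class for precision/recall.  Degenerate
denominators yield 0 with a warning, not NaN.  The hold-out split is
stratified (preserving the source's majority share, hence ≥ 60% whenever
the source is at least that imbalanced); cross-validation uses stratified
folds and re-runs the entire pipeline — including oversampling — on each
training fold only, so synthetic rows never derive from test samples.

The imbalance ratio is IR = (N_max − N_min)/N_min.  `imbalanced_subset`
keeps the smallest majority count whose ratio is at least the target
(the ceiling of N_min·(1+IR)), drawn uniformly without replacement; the
realized ratio is within one sample of the target.  The IR sweep fixes
one test set (either held out or supplied separately), down-samples the
training majority per grid value, retrains, and evaluates on the fixed
set.

## Synthetic data: what it emulates, what it does not

The generator plants label-coherent column-constant blocks in a uniform
categorical background: block cells carry the pattern independently with
probability `coherence`; labels flip with probability `label_noise`.
Default study conditions (`default_config`): 487 benign / 210 malignant
(the composition of the larger public breast-ultrasound collection this
package targets), two blocks per class encoding clinically typical
co-occurrences (oval/parallel/circumscribed/distinct margins and absent
edema in benign lesions; irregular/non-parallel/spiculated, hypoechoic
with microlobulation in malignant ones), each covering 45% of its class,
coherence 0.9 and 3% label noise to emulate inter-reader variability.

The sweep experiments use these conditions with label noise off: label
flips change the class totals, and the sweep's bookkeeping (exact
477…238 majority training counts at the ten published ratios) is defined
on exact class sizes.  Problem sizes throughout the test suite (tables of
tens to hundreds of rows, ten sweep seeds) are chosen as the smallest at
which the checked properties are informative.

What passing these tests shows: the mining objective and search behave as
specified, oversampling preserves the discrete closed world and restores
balance, boosting obeys its classical error bound, and the full pipeline
recovers planted structure and tracks imbalance bookkeeping exactly.
What they do not show: performance on doctor-scored clinical tables.
Real BI-RADS features carry correlated, graded deviations from a
phenotype, not i.i.d. uniform background noise; inter-feature correlation
outside planted blocks, reader-specific scoring styles, and covariate
shift between centres are all absent here.  Accuracy figures on synthetic
tables therefore characterise the implementation, not clinical utility.

## Known limitations

- Greedy refinement is myopic (see above); no re-insertion or beam search.
- Rules store normalized means; the raw-scale display rounds to the
  nearest level for readability and is not used in classification.
- The strong classifier's margins are uncalibrated vote sums, not
  probabilities.
- Affinity propagation is O(N²) in memory and time per iteration;
  tables beyond ~10⁴ rows would need a different exemplar method.
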