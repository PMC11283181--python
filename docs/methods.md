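# Methods

`obsdq` scores the quality of obstetric delivery records along the three
harmonized data-quality dimensions — **completeness** (are values present),
**plausibility** (are values believable given the rest of the record), and
**conformance** (do values respect formats and value sets) — and fuses the
sub-scores into one number in [0, 1] per record, 1 being best. This note
documents the models, their assumptions, the defaults, and what the
synthetic cohort does and does not establish.

## Record model and preprocessing

Input is a tabular export: one row per delivery episode, described by a
data dictionary (column kind, units, value set, null tokens, date format).
Normalization maps all configured null spellings to a single sentinel and
parses numeric cells; unparseable numeric text is **kept as the raw string
and flagged malformed** rather than coerced to null — a malformed cell is a
conformance problem and must stay visible to the rule engine, while a null
is a completeness problem. The two are never conflated.

Training-time preprocessing, replayed identically at scoring time:

1. **Drop** columns whose training missing rate is strictly above 0.80.
2. **Impute** nulls with the training median (numeric) or the reserved
   `NULLIMP` category (categorical). Malformed numeric cells are also
   median-imputed and marked imputed so numeric models never see strings.
3. **Discretize** numeric columns into at most 3 bins cut at the 1/3 and
   2/3 linear-interpolation quantiles of observed training values. Bins are
   right-closed (a value equal to a cut point falls in the lower bin), the
   mapping is total (below/above the edges maps to the extreme bins), and
   duplicate edges on heavily tied columns (count variables with mode 0)
   collapse to fewer bins instead of erroring.

Imputed cells are **never scored for plausibility** — the tool must not
judge its own imputations; their absence is already priced into the
completeness dimension.

## Completeness

Each column's completeness is 1 − its training missing rate. A record's
completeness is 1 − the training-completeness-weighted fraction of its null
cells: missing a habitually well-filled column (maternal age) costs more
than missing a structurally sparse one (vacuum-delivery count, recorded
only for vacuum deliveries). An unweighted variant is available via
`record_completeness(..., weighted=False)`.

## Bayesian-network plausibility

A discrete Bayesian network over the imputed, discretized columns captures
the dependency structure of the table (Robson group ↔ parity, previous
cesarean, presentation, onset; delivery type ↔ Robson group; serial fetal
weight estimates ↔ each other).

* **Structure**: greedy hill-climbing on the BIC score with add, remove and
  reverse moves, `max_parents=3`, 3 restarts (restart 0 from the empty
  graph, the rest from random seeded DAGs), and a fixed candidate scan
  order so ties resolve deterministically. Identifier and date columns, and
  any column with more than 30 distinct states, stay out of the network
  (CPT size explodes and identifiers carry no structure; dates belong to
  the rule engine).
* **Parameters**: Laplace-smoothed maximum likelihood,
  `P(x|pa) = (count + α)/(count(pa) + α·|states|)` with α = 1; an unseen
  parent configuration yields the uniform distribution. Smoothing is not
  optional: 3-bin × many-column products guarantee unseen configurations.
* **Inference**: exact. Variable elimination with a greedy min-size
  elimination order in general; when every non-target column of a row is
  observed, the posterior reduces to a Markov-blanket product, computed in
  log space as a fast path. Both paths are property-tested against
  brute-force enumeration of the joint (tolerance 1e-9).
* **Cell score**: for each non-imputed, network-covered cell, the posterior
  probability of the registered state given all other observed, non-imputed
  cells, **normalized by the posterior mode's probability**. Raw posteriors
  are incomparable across columns with different state counts (a uniform
  8-state posterior gives every state 0.125); the ratio is 1 whenever the
  registered state is maximally plausible. The record-level BN sub-score is
  the mean over scored cells (1.0 if none). A registered state absent from
  the fitted state space is dropped from all evidence and reported as a
  conformance finding — the network never crashes on novel codes.

## Outlier detectors

Four detectors with complementary granularity and assumptions:

* **IQR bounds** (cell-level, marginal): flag values strictly outside
  [Q1 − 3·IQR, Q3 + 3·IQR], bounds inclusive, quartiles by linear
  interpolation (the same quantile convention as the discretizer). On count
  columns whose quartiles coincide (prior C-sections, mostly 0) the bounds
  degenerate and any non-modal count is flagged; this is the literal
  formula and is deliberately given a small fusion weight.
* **Elliptic envelope** (row-level): plain Gaussian MLE on z-standardized
  numeric columns with a ridge of 1e-6·trace/d on the covariance diagonal;
  flag when squared Mahalanobis distance exceeds the χ² quantile at
  confidence 0.99. The minimum-covariance-determinant refinement is left as
  an extension hook. Calibration is verified: the flag rate on data drawn
  from the fitted Gaussian converges to 1 − confidence.
* **Local outlier factor** (row-level): standard LOF on the standardized
  numeric matrix, k = 20 neighbors, flag threshold 1.5; both exposed on the
  CLI since LOF is known to be parameter-sensitive. The implementation is
  scikit-learn's, verified in tests against a hand-rolled
  reachability-density oracle.
* **Contextual outlier tree** (cell-level, explainable): one greedy
  CART-style tree per target column (variance reduction for numeric
  targets, Gini for categorical), `max_depth=4`, `min_branch=50`. Split
  candidates are exact midpoints between consecutive distinct values
  (numeric, scanned via prefix sums) and one-vs-rest (categorical), ties
  broken by dictionary column order, so fitting is deterministic. Each
  branch is treated as a homogeneous cluster storing its target summary. A
  numeric cell is flagged only when it is outside the branch's confidence
  interval (mean ± z(0.99)·sd) **and** the gap to the nearest in-branch
  training value on the same side is ≥ 1.5 × branch sd — the gap criterion
  suppresses flags in the tails of a well-populated branch. A categorical
  cell is flagged when its within-branch proportion is below 0.01 while the
  branch is dominated by a modal category (proportion ≥ 0.5). Every flag
  carries the conjunction of split conditions that defines its branch; a
  row missing a split feature is evaluated at the deepest branch it can
  reach. The tree never uses its own target as a predictor.

## Expert rules

A declarative rulebook evaluated per record; predicate kinds are value-set
membership, numeric range, date format, cross-column comparison, and
monotone measurement series. The shipped obstetrics book has 17 rules —
8 conformance (d/m/Y date of birth; value sets for Robson group 1–10,
Bishop score 0–13, delivery type, fetal positions, blood group, pregnancy
type; integer-type conformance of count columns) and 9 plausibility
(gestational age at admission and delivery in [20, 44] weeks; maternal
weight, BMI and age ranges; previous deliveries ≤ previous pregnancies;
week-35 fetal weight > week-25; ultrasound estimates more than 5 weeks
apart strictly increasing; admission week ≤ delivery week). Maternal age
[10, 60] years, BMI [12, 70] and weight [30, 250] kg are labelled ASSUMED
in the config: clinically generous bounds a deployment team would tighten.
The whole book is configuration, not code — the engine is the reusable
part.

Semantics: a rule whose referenced cells are all null is `not_applicable`
and does not count against the score (missingness is the completeness
dimension's job; counting it here would double-penalize). Cross-column and
series rules need every operand observed. For numeric-range rules a
malformed cell is evaluable and fails — a non-number violates every numeric
range, which is exactly type conformance. Rules referencing absent columns
are skipped with a warning. Per dimension, the sub-score is
passes/(passes + fails), 1.0 when nothing was applicable.

## Score fusion

The fused score is the weighted arithmetic mean of the eight sub-scores.
Default weights: rules-conformance 0.20, rules-plausibility 0.20, BN 0.25,
context tree 0.15, envelope 0.05, LOF 0.05, IQR 0.05, completeness 0.05 —
the expert rules carry the most weight and the missingness and IQR
components the least, the ordering a deployment would want when the
rulebook encodes hard clinical impossibilities; weights are fully
overridable but must be nonnegative, sum to 1, and keep the rule components
dominant. Fusion is convex (the score lies between the extreme sub-scores)
and monotone: any additional finding can only lower the affected sub-score
and therefore the fused score.

## Evaluation machinery

* **Per-column repeated CV**: 10-fold × 2-repeat stratified
  cross-validation with each column as target, restricted to rows where the
  target was originally observed. Every fold refits the entire pipeline
  (preprocessing, structure, CPTs) on the training rows and predicts the
  held-out posterior from all other observed, non-imputed cells. Multiclass
  targets use one-vs-rest macro-averaged AUROC (classes absent from a
  training fold are excluded from that fold's average); the 95% CI is a
  t-interval over the 20 fold scores. The designed sanity pattern: a column
  independent of all others (blood group) sits at chance, a strongly
  dependent one near 1.
* **Rank agreement**: assessors rank records 1 (best) to n (worst); the
  model ranking is descending score order. Spearman's ρ is computed per
  assessor and averaged; Kendall's τ against the mean assessor ranking;
  both with midrank ties and p-values at α = 0.05.
* **Threshold AUROC**: a record is "bad" when its mean rank ≥ t for
  t ∈ {3, 4, 5, 6}; AUROC of (1 − score) as the bad-record classifier,
  undefined-marked when a threshold yields a single class.

## Synthetic cohort: what it emulates, what it does not

The generator produces a ~27-column multi-hospital delivery table with a
learnable dependency backbone: the Robson group is *derived* from parity,
previous C-section, plurality, presentation, gestational age and onset via
the standard 10-group classification; delivery type is driven by the Robson
group, with a pre-labor cesarean onset forcing a cesarean (making a eutocic
delivery in that context impossible in clean data — the designed contextual
defect); serial fetal weight estimates are strictly increasing; the blood
group is independent of everything (the designed chance-level CV control);
hospital baselines shift ages and BMI. Marginal missingness follows the
habitual-gap pattern of real exports, plus structural gaps (Bishop score
only for induced labors, vacuum count only for vacuum deliveries — the
latter >80% missing to exercise the drop rule). Every fully observed clean
row passes all 17 rules by construction. All randomness flows from one seed
through a named per-column generator, so edits to one column leave the
others byte-identical.

Defect injection corrupts chosen cells with ground truth recorded per cell:
made-missing, value-set violation (Robson "11"), range violation
(gestational age 45), format violation (ISO-reserialized date), contextual
outlier (eutocic delivery in an impossible context), and global outlier
(values far beyond the IQR bounds). Row-level injection (default 3
corrupted cells per defective row, kinds mixed — a genuinely bad record
rarely has a single isolated error) provides the row-level ground truth
used as the synthetic stand-in for clinicians labelling whole records.

What passing tests on this cohort shows: the pipeline detects exactly the
defect classes it models, end to end, through the real FHIR interface. What
it does not show: performance on real hospital exports, whose error
processes (vendor quirks, copy-forward, unit drift, inter-hospital coding
differences) are richer than the six injected kinds, and whose
distributions are not public. The chance-level and near-deterministic CV
patterns transfer; absolute AUROCs and score levels do not.

## Numerical choices and degenerate inputs

CPT rows are validated to sum to 1 within 1e-9; posteriors with zero total
mass (impossible evidence under α = 0) fall back to uniform. Constant
context-tree targets yield an empty tree (no flags possible); zero-sd
branches flag any deviating value. Constant numeric columns standardize to
z = 0. An empty scoring batch returns an empty report list and an
undefined-marked summary; a row that fails to score becomes an error report
without aborting the batch. Reports carry the model's training timestamp
(not wall-clock) so identical inputs and model files produce bit-identical
output.

## Problem sizes used by the checks

The shipped verification uses a 10 000-row training cohort with a
2 000-row held-out set at a 10% defective-row rate for the end-to-end
check; 50 000 Gaussian rows for envelope calibration; 20 000 rows with 200
injected 10σ contaminants for the contextual tree; 100 random ≤6-node
networks against the enumeration oracle; and 10 000 sampled rows for CPT
recovery. These sizes make the binomial/sampling error comfortably smaller
than each check's tolerance.

## Known limitations

No temporal or cross-record rules (duplicate episodes, dataset shift); no
Gaussian/latent-variable networks; network edges are dependencies, not
causes; the FHIR layer validates structure, not terminology bindings
(SNOMED CT/LOINC mapping is the dictionary owner's responsibility); the
rule bounds marked ASSUMED are defaults, not clinical guidance; the
row-level detectors (envelope, LOF) see median-imputed vectors, so heavy
missingness shrinks rows toward the center and lowers their sensitivity.
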