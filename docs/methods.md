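# Methods

## Scope and model

`fluency2ef` implements a comprehensive evaluation of timed semantic verbal
fluency (sVF) sessions and a machine-learning procedure that predicts
executive-function (EF) test scores from the resulting features.  A session
is one participant producing category members for two minutes: two simple
tasks (t1 animals, t2 jobs) and a switching task (t3, alternating
sports/fruits).  Tokens arrive transcribed, time-stamped and manually coded
(`correct`, `repetition_error`, `category_error`).

### The 43-feature set

Per participant the extractor computes:

* **Sum scores (4)** — correct words per task and their total.  Error-coded
  tokens never count.
* **Switch coefficient (1)** — `sum_t3 / ((sum_t1 + sum_t2) / 2)`, switching
  output relative to simple-task output; undefined when `sum_t1 + sum_t2 = 0`.
* **Errors (4)** — repetition errors per task and category errors in t3.
  Repetition errors are counted in all three tasks; this is required for the
  feature total of 43 and matches the downstream report tables, which use
  switching-task repetition errors.
* **Latencies (18)** — inter-word pauses (next onset minus previous offset),
  per task: overall mean, means within the four 30-second intervals
  i1–i4 (a pause belongs to the interval containing its start, i.e. the
  preceding word's offset), and the progression i4 − i1.  Pauses are
  computed over all tokens regardless of code, because errors occupy
  speaking time; a switch restricts them to correct tokens.  The latency
  before the first word is not a pause (the task clock starts at the end of
  the instruction; the first word may start any time after 0).
* **Semantic relatedness (16)** — per task and per backend (taxonomy,
  embeddings): the *sequential* mean over consecutive correct-word pairs in
  production order, the *cumulative* mean over all unordered correct-word
  pairs, and for t3 the sequential means restricted to consecutive pairs
  within each category (sports, fruits).  A pair containing a word absent
  from the backend's lexicon is deleted; its neighbours are *not* spliced
  into a new pair, so a deleted middle word can leave the sequential mean
  undefined while the cumulative mean survives.

Any feature whose definition cannot be evaluated is missing (NaN), never
imputed at extraction time.  The *classical* feature set is the four sum
scores — the standard clinical evaluation the full set is compared against.

### Semantic backends

Two interchangeable relatedness measures:

* **Taxonomy path similarity** over an undirected, unweighted synset graph:
  `sim(s1, s2) = (D − length(s1, s2)) / D`, where `length` counts edges on
  the shortest path and `D` is the longest finite shortest path in the whole
  graph.  Words with several senses resolve to the synset pair with maximal
  similarity; words missing from the lexicon make the pair undefined.  For
  disconnected graphs `D` is taken over finite paths only and
  cross-component pairs are undefined (the formula has no meaning at
  infinite length); they are dropped exactly like missing-lexicon pairs.
* **Embedding cosine** over a word2vec-format vector table.  Cosine can be
  negative for arbitrary vectors; values are averaged as-is (no clipping),
  since only the relative ordering of participants matters downstream.

A bundled toy resource (four category subtrees, 89 words in 18 clusters,
matched 16-dimensional embeddings) serves as demo fixture and as the
vocabulary of the synthetic cohort.  It is generated deterministically in
code; `write_toy_resource` materializes the on-disk formats.

### Prediction procedure

Each of the 68 EF battery variables is predicted independently from the
feature table:

1. **Repeated cross-validation.** 10 folds × 10 repetitions (default), a
   fresh uniform random partition per repetition, no stratification —
   100 fitted models per target.
2. **Fold-safe preprocessing.** Per training fold: median imputation of
   missing features, z-scoring, then ordinary-least-squares removal of the
   sex/age/education confounds per feature.  All parameters come from
   training rows only and are applied frozen to the held-out rows; a
   mutation test asserts that corrupting held-out rows cannot change any
   training-derived parameter.
3. **Learner.** Random-forest regression, 100 trees (default),
   `max_features = 1/3` — the classic regression-forest default — with
   bootstrap resampling; all remaining hyperparameters are scikit-learn
   regression defaults, recorded in the run manifest.
4. **Score.** Pearson r between true and predicted scores per held-out
   fold, averaged over all models (`mean_r`).  Targets are left on their
   raw scale by default (Pearson r is scale-invariant); a flag standardizes
   them.
5. **Screen.** p-value from the two-sided correlation t-test
   `t = r·sqrt(n−2)/sqrt(1−r²)` treating `mean_r` as a correlation observed
   on the n participants; targets with p < 0.01 count as highly predictable.
   A pooled variant (correlating all held-out predictions at once) is
   available via `p_method="pooled"`.
6. **Follow-up.** For predictable targets, Breiman-style out-of-bag
   permutation importance (per tree: MSE increase on out-of-bag rows when
   one feature column is permuted; averaged over trees and models), the
   top-5 features (ties broken by canonical feature-name order), and their
   Spearman rank correlations with the raw target (trend mark at p < 0.1,
   significance mark at p < 0.05).  Raw rather than residualized features
   are used in the follow-up; a flag switches.
7. **Comparison.** The identical procedure runs with the classical
   four-feature set (same seed ⇒ identical fold partitions) and the
   per-target Δmean_r and per-set significant counts are reported.

### Null behaviour of the significance screen — a caveat

The screen's p-value treats the cross-validated `mean_r` as an ordinary
sample correlation.  That is the convention the printed r/p pairs of this
kind of analysis follow (r = 0.41 at n = 230 gives p ≈ 1e−10), but it is not
exactly calibrated: fold correlations share training data, and no unbiased
estimator of the variance of cross-validation estimates exists.  Measured on
the package's own null generator (n = 120, 68 independent targets, 20
cohorts): with one CV repetition the statistic's null spread is 0.100
(vs the 0.092 the t-test assumes) and the screen flags ≈ 2.9% instead of 1%;
with the default ten repetitions the spread shrinks to 0.069 and the screen
flags ≈ 0.1%, i.e. it becomes conservative.  The pooled variant behaves the
same way.  The mean of `mean_r` under the null is −0.0001 — the screen is
unbiased in location, and the leakage guard shows the excess is not
information leakage.  Interpretation: borderline p-values near the 0.01
screen should not be over-read; strongly predictable targets (p ≪ 0.001) are
unaffected.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, at a
deliberately reduced lexical scale, so the pipeline is testable end to end.

* **Latent layer.**  Five correlated abilities (flexibility, working memory,
  inhibition, attention, speed; common correlation 0.3).  Demographics
  follow the emulated study population: n = 230 by default, ages uniform
  20–55, 40% male, education ordinal 1–4 with probabilities 8/63/69/90 out
  of 230.  In the `paper_like` scenario each ability shifts by −0.35 per SD
  of age, +0.15 per SD of education and +0.1 for one sex — producing the raw
  negative age–sum-score correlation (measured ≈ −0.4) that confound removal
  must eliminate.
* **Production layer.**  A cluster-structured retrieval walk over the toy
  taxonomy: stay in the current cluster with probability 0.68 + 0.08·WM,
  otherwise jump, paying a switch penalty on the next pause.  Pauses are
  lognormal (median 4 s, σ = 0.45) with a per-session state intercept
  (SD 0.22 on the log scale — daily form; keeps latency features an
  imperfect measure of speed), −0.15·speed, and a linear time-on-task
  inflation of 0.6 log units across the two minutes, so interval means rise
  from i1 to i4 for ~80% of participants.  Words are drawn without
  replacement, making every repetition a deliberate injection (hazard
  0.035 − 0.015·(inhibition+WM)); t3 alternates categories with compliance
  0.8 + 0.05·flexibility and occasionally emits an out-of-task word as a
  category error (hazard 0.03 − 0.012·flexibility).  With the 89-word toy
  vocabulary this yields ≈ 10–25 words per task rather than a real speaker's
  25–35; all structural relationships are preserved at the smaller scale.
* **Score layer.**  Each battery variable loads on its test's domain ability
  (0.55) plus a speed component, with reaction-time variables
  speed-dominated (0.75), Gaussian noise (SD 1.25), and the schema polarity
  applied (smaller is better for times/errors).
* **Scenarios.**  `null` severs every coupling (features and targets
  independent by construction); `paper_like` is the full model; `planted`
  additionally rewrites two targets from the *realized* features: one as a
  semantic + latency combination residualized against the four sum scores
  (R² = 0.45) — predictable from the full feature set but, by construction,
  carrying no signal linearly recoverable from sum scores — and one driven
  by a single feature (R² = 0.5) for importance-recovery checks.
  `describe_truth` returns the exact planted couplings.

### What the generator does and does not emulate

It reproduces: confounded ability-driven production, cluster structure in
semantic space, slowing latencies, injected error types, noisy multi-variable
EF scores with domain/test structure and polarity.  It does not emulate:
real lexical frequency effects, German morphology or compounds, acoustic
segmentation noise, practice/fatigue across tasks, or realistic inter-test
covariance of a clinical battery — the synthetic battery is somewhat *more*
predictable from speech than a real one (a paper_like run at n = 120 flags
roughly half the variables, vs ≈ 20/68 reported for comparable real
cohorts).  Passing tests therefore demonstrate the pipeline's correctness
and its qualitative contrasts (full > classical, planted-feature recovery),
not real-world effect sizes.

## Numerical and design choices

* Words are trimmed, lower-cased, NFC-normalized; compounds kept verbatim —
  lookup variants are the lexical resource's concern.
* Token occupancy is half-open `[onset, offset)`; overlap is a validation
  error, zero-length gaps are legal pauses of 0 s.
* The 68-variable battery registry is editable (TSV); the default
  distributes 68 variables over the 14 named tests (5 cognitive-flexibility,
  3 working-memory, 3 inhibition, 2 attention, 1 vigilance test) with
  invented variable names, since real batteries enumerate their variables in
  test manuals.
* Education enters the confound model as a single ordinal 1–4 regressor.
* Zero-variance features in a training fold pass through as all-zero columns
  with a warning rather than dividing by zero; all-NaN training columns
  impute 0 and become inert.
* Constant targets and targets with fewer than 20 complete observations are
  skipped with an explicit reason, never silently.
* Fold partitions come from `numpy` generators seeded per repetition from a
  single `SeedSequence`; forest seeds are drawn per model.  Identical seeds
  reproduce every output byte-for-byte.
* Tests and the acceptance script run reduced problem sizes (cohorts of
  120, 1–2 CV repetitions, 10–50 trees) chosen so that each statistical
  property is measurable in minutes on one core; the default protocol
  (10 × 10 × 100 trees) is exercised for its structural contract (model
  count, determinism).

## Known limitations

* The path-similarity `MAXSHORTESTPATH` is a whole-graph constant; adding
  nodes to a taxonomy rescales all similarities.
* OOB permutation importance is biased toward correlated feature groups, as
  all permutation importances are; the top-5 report should be read as a
  group of useful features, not a causal ranking.
* The significance screen's null calibration depends on the repetition
  count (see the caveat above); for strict error control a permutation test
  would be required at a substantially higher computational price.
* The TextGrid reader covers interval tiers of the standard long and short
  text formats only (no binary TextGrids).
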