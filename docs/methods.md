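# Methods

## The model

`semscale` treats severity assessment as a decoding problem: a violent
event experienced by one person is communicated as five keywords, and a
receiver (human or algorithm) maps those keywords back to a severity on a
0–10 scale. The algorithmic receiver is a *semantic scale*: an
unregularized multiple regression from an LSA text embedding to the
rating.

### Semantic space

Co-occurrences are counted over 5-grams with a symmetric ±4 position
window: every ordered pair of distinct positions (i, j) with |i − j| ≤ 4
contributes the n-gram's corpus count to cell (wᵢ, wⱼ). Counting is
therefore direction-symmetric and confined to single n-grams; it is not
weighted by distance (a genuinely open choice — distance kernels such as
GloVe's 1/d would be equally defensible). Row and column vocabularies are
the most frequent corpus words (defaults 120 000 × 50 000, truncated to
the words present; frequency ties break lexicographically so vocabularies
are platform-stable). Cells are normalized as log(count + 1) — natural
log; "log" is otherwise unqualified in the LSA literature — and the matrix
is factorized with a dense SVD. Embeddings are U·S truncated to `n_dims`
(default 512) and row-normalized to unit length; because rows are
renormalized, the U vs U·S scaling choice affects only intermediate
values. Singular-vector sign indeterminacy is fixed by making the
largest-magnitude entry of each left singular vector positive, so spaces
are bit-reproducible across platforms.

Everything is dense and in-memory: the implementation targets desk-scale
corpora (10³–10⁴ words). Out-of-core sparse SVD for terabyte-scale n-gram
collections is out of scope.

### Text embeddings

A response embedding is the normalized sum of its in-vocabulary word
vectors. Out-of-vocabulary words are skipped with a logged warning;
a fully out-of-vocabulary response is an explicit error (never a silent
zero vector). Duplicate words contribute multiply — the sum, not the mean,
is normalized. Word order is irrelevant by construction.

### Semantic scales and cross-validation

Linear scales are ordinary least squares on the first *k* embedding
dimensions plus an intercept (the intercept is standard practice even
where the construct is written y = c·x); binary scales are
maximum-likelihood logistic regression; no regularization anywhere, with
complete separation flagged as a warning since the unregularized MLE then
diverges. Evaluation uses a single fixed grouped 10-fold partition keyed
on the source text (the P1 event), so a model is never evaluated on a
text it saw in training; every record gets exactly one out-of-fold
prediction and the reported r pools all of them.

*k* is selected per training fold from the grid
{2, 4, 8, 16, 32, 64, 96, 128, 192, 256, 384, 512} ∩ [1, d], scored by
inner grouped 5-fold cross-validated Pearson r, ties to the smallest k.
A `train-fit` mode (score = training-set r) is available for fidelity to
descriptions that optimize "the highest fit to the data"; inner CV is the
default because training fit is monotone in k for nested OLS models and
would always select the largest candidate. The mean and SD of the
selected k across folds are reported alongside the cross-validated r.

### Bias statistics

Sign convention: every bias is receiver minus experiencer
(P2 − P1, MP2 − P1). Calibration tests are two-sided independent
two-sample t tests, pooled variance by default (Welch optional). The
human test compares P1 per-event ratings with P2 per-rater means (68 + 20
observations → df 86 per condition); the model test compares P1 per-event
ratings with per-event mean predictions (68 + 68 → df 134), since model
predictions have no rater dimension. These aggregations are a modeling
inference — the level of aggregation behind the emulated study's printed
degrees of freedom is not fully specified — and both are switchable
(`per-rater-means`, `per-event-means`, `raw`).

Accuracy is the per-rater Pearson r between a rater's severities and the
P1 severities of the same events (≥ 3 shared events required; zero
variance is an explicit error, not a NaN). The human-vs-model comparison
is a two-sample t test on raw r values (20 + 20 → df 38 per condition);
Fisher-z transformation is offered but off by default, matching the
raw-r comparison convention. p-values are reported to 3 decimals with no
multiple-testing correction.

On the real paired design (both sides rate the *same* events, receiver
side aggregated per rater) the two-sample calibration test is
conservative: the shared event component correlates the samples and the
per-rater means have smaller variance than the per-event ratings. Its
size is therefore verified where its assumptions hold — two independent
same-distribution samples drawn through the generator's clip-and-round
rating channel — where 1000-replicate simulation puts the rejection rate
at the nominal 0.05 (±0.02).

### Word scores

Word-cloud data are produced by scoring each distinct response keyword on
a trained scale via its single-word embedding and standardizing the raw
scores to z-values over the dataset's distinct scored words — the only
well-defined reference population once the corpus is fixed. Frequencies
are keyword occurrence counts in the response tables. Scales for word
scoring are fit on the full dataset (not cross-validated): word scores
describe the fitted construct, not out-of-sample performance. The
condition scale codes physical = 1, psychological = 0; the bias scale
regresses per-response P2 − P1 differences.

## The synthetic generator

The generator emulates a two-phase IPV communication study: 68 events per
condition, each described and rated once in P1, then rated by 20 raters
per condition in P2 (40 raters total, each rating every event of exactly
one condition: 40 × 68 = 2720 P2 ratings).

Per condition c with parameters (μ_c, σ_c, δ_c, σ_p2c):

| quantity | model |
|---|---|
| latent severity | s_e ~ N(μ_c, σ_c²) |
| P1 rating | round(clip(s_e + ε₁)), ε₁ ~ N(0, σ_p1²) |
| P2 rating | round(clip(s_e + δ_c + u_r + ε₂)), u_r ~ N(0, τ²), ε₂ ~ N(0, σ_p2c²) |
| keywords | 5 words from the (condition, bin) vocabulary of a noisy perception s_e (+ δ_c in P2) + N(0, σ_kw²) |

Defaults: μ/σ = 6.46/1.69 (psychological) and 6.59/1.81 (physical) — the
emulated study's P1 summary statistics; planted shifts δ = −0.61 and
+0.95 — its printed human calibration biases; σ_p1 = 0.8, τ = 0.4,
σ_kw = 0.75; σ_p2 = 2.5 (psychological) and 1.0 (physical). The
condition-specific response noise makes psychological severity markedly
harder for raters to reproduce than physical severity, preserving the
qualitative regime of interest (psychological human accuracy ≪ physical
human accuracy < model accuracy) while keeping ratings on-scale. Pushing
the human accuracy all the way down to the study's r² ≈ 0.06 under this
single-latent model would require response noise of ≈ 6 rating units,
and the resulting clipping at the scale ends would corrupt the planted
calibration shifts by ≈ 0.2 — so the synthetic human correlations sit
above the study's, a deliberate trade-off in favor of clean parameter
recovery.

Ratings are clipped to [0, 10] *then* rounded (an 11-point instrument);
clipping before rounding slightly shrinks conditions whose mean sits near
a scale end, which is why recovered shifts at the defaults sit ~0.05–0.12
below the planted magnitudes.

The keyword vocabulary has disjoint word sets per (condition, severity
bin) — 22 sets of 12 synthetic tokens plus 40 fillers — and the matching
corpus emits 300 5-grams per bin in which tokens stay within their bin
with probability 0.9 (mixing probability 0.1 covers fillers and other
bins). Same-bin words therefore co-occur preferentially and the learned
space clusters them, making severity linearly decodable from embeddings.
The best possible decoder given a response's (condition, bin) is
E[rating | bin, condition], so the attainable cross-validated r² equals
var(E[rating | bin, condition]) / var(rating). This *analytic signal
fraction* is computed by large-sample simulation of the latent channel
alone (200 000 draws, fixed oracle seed, no embeddings or regression) and
is ≈ 0.42 at the defaults; full-pipeline cross-validated r² lands within
0.1 of it.

What the generator does **not** emulate: real English words and their
polysemy, free-text narratives, rater attentiveness drift, attenuated
(regression-toward-own-mean) rating strategies, and non-normal latent
severity distributions. Passing tests on synthetic data therefore
demonstrate the machinery is correct and well-calibrated under the
declared generative model, not that the pipeline reaches any particular
accuracy on real IPV descriptions.

## Numerical and design choices

- OLS via `numpy.linalg.lstsq`, rank-deficiency rejected with the
  achievable rank; logistic fits via scikit-learn's lbfgs with C = ∞,
  tolerance 1e-10, max 2000 iterations (non-convergence is an error with
  the iteration count).
- Fold assignment: groups sorted, shuffled with a seeded generator,
  dealt round-robin; fold sizes differ by at most one group; the plan is
  created once and reused. Out-of-fold predictions are invariant to
  record order (records are internally sorted by id).
- Probability overflow in logistic prediction is handled with the
  log-sigmoid (`scipy.special.expit`).
- Zero-variance outcomes: dimension selection errors on constant
  outcomes; the bias-scale trainer special-cases an all-zero bias dataset
  to a flat scale with a warning (its fit r is undefined).
- All randomness flows from `numpy.random.default_rng` seeded per
  component via `SeedSequence`; identical config + seed reproduce every
  artifact byte-for-byte.
- Stage re-runs: each CLI stage reads persisted plain-text artifacts, and
  determinism guarantees that re-running any stage from cached upstream
  files reproduces downstream outputs exactly; no separate content-hash
  cache layer is kept.
- Problem sizes: tests and the acceptance script run the full 2720-record
  study with a ~300-word corpus and a 128-dimension space (one pipeline
  run ≈ 3 s); batches use 12–20 seeds.

## Known limitations

- The co-occurrence matrix and SVD are dense; vocabularies beyond ~10⁴
  words will be slow and memory-hungry.
- The calibration t tests ignore the event-pairing between P1 and P2 (a
  paired test would be more powerful; the two-sample form mirrors the
  emulated study's reporting).
- Model "MP2" predictions used in the bias report are out-of-fold
  cross-validated predictions, while word-scoring models are full-data
  fits; the two serve different purposes and are not interchangeable.
- Keyword counts other than 5 are supported, but the generator samples
  keywords without replacement within a bin, so `words_per_bin` must be
  at least the keyword count.
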