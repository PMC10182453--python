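# Methods

## Problem and pipeline

The package estimates quarterly incidences of D rare diseases (default 15)
in R regions (default 4) over T seasons (default 16, calendar quarters of
2016–2019) from anonymized search logs. A log record is one query event:
user id, timestamp, region, token list, and clicked (URL-domain, rank)
pairs. The pipeline has two steps with an explicit interface between them
— per-cell session counts by intent class.

### Step 0: keyword matching and sessionization

A three-level lexicon drives query annotation. Level 1 holds
disease-specific terms (names, genes, specific treatments), level 2
disease-linked but non-specific terms (symptoms, pleiotropic treatments),
level 3 general medical vocabulary. A query is marked with the
highest-priority level it contains (1 ≻ 2 ≻ 3); containment is substring
containment on the space-joined query text. Substring matching is
deliberate: it is how keyword filters over commercial logs behave, it is
tokenizer-independent, and it extends unchanged to scripts without word
boundaries. Queries matching level 1 form Query Set Q, partitioned by
keyword category (name / gene / treatment).

Sessions are maximal same-user runs with inter-query gaps ≤ 30 minutes; a
gap of exactly 30:00 keeps the session together (only a strictly greater
interval breaks it). Expanding backward and forward from each level-1
query and merging overlapping expansions is mathematically the same as
keeping each maximal gap-block that contains a key query; the
implementation uses the block form and the test suite proves equivalence
against a literal expand-and-merge oracle on random fixtures. A session's
region and season come from its first key query; its disease set is the
union of its key queries' level-1 matches (multi-disease sessions
increment every matched disease downstream).

### Step 1: session-intent prediction

Each session yields a 38-dim vector (8 statistics — session length,
level-1/2/3 query counts, click count, max/mean click position, mean
word-frequency change — plus 30 binary indicators for intent-specific
words and URL domains) and a per-query sequence of (6 + D)-dim vectors
(query level, length, click statistics, word-frequency change, disease
multi-hot). The word-frequency-change statistic

    C(w, t) = (n(w, t) + α) / (Σⱼ n(w, tⱼ)/K + α),  α = 1

is computed from corpus-wide per-season token counts (all sessions, not
only labeled ones — it is an unsupervised corpus statistic). Uniform and
unseen words score exactly 1; news bursts push C above 1 in their season.

The indicator vocabulary is selected on the labeled *training* split only
(avoiding label leakage): for each word/domain and class,
specificity = freq(class) / (1 + max freq(other classes)), with freq the
fraction of the class's sessions containing the item; each item is
assigned to its argmax class (ties to the lower class index), the top 5
per class are kept, ties broken lexicographically. The +1 in the
denominator smooths zero counts. Frequency is session-level presence
rather than token count, which matches how the indicators are used
(presence bits).

The classifier is an LSTM over the query sequence (final hidden state)
concatenated with the standardized session vector, one ReLU hidden layer,
3-way softmax, cross-entropy loss, Adam. It is implemented directly in
NumPy with hand-derived backpropagation through time (padded steps are
masked out of both recurrence and gradients); the gradients are validated
against central finite differences in the test suite. Defaults: recurrent
hidden 64, MLP hidden 64, learning rate 1e-3, max 200 epochs, patience 20
on validation loss (best epoch restored), batch 64, no class weighting.
Sequences are processed at natural length. Intent classes are indexed
RD=0, NEWS=1, OTHER=2 everywhere.

Labeled data follows an 8:1:1 random split (2400 items → 1920/240/240);
training errors out if any class is absent from the training split.
Annotator agreement for a three-rater labeling protocol is Fleiss' κ
(via statsmodels), with majority-vote consolidation and three-way ties
flagged for adjudication. Averaged pairwise Cohen's κ is a reasonable
alternative; Fleiss is the natural choice for ≥3 raters with a shared
item set.

### Step 2: incidence estimation

Sessions with predicted intents aggregate into a (disease, region,
season) panel: x_sd counts RD-intent sessions per cell, x_sn news-intent
sessions; the query-input baseline aggregates raw level-1 query counts by
category (x_name, x_gene, x_treat) from Q, all intents mixed. Incidence
is rescaled by one global factor so the *training-period* maximum equals
1; the factor is frozen and applied to validation/test.

Three linear variants, in increasing order of expressiveness:

* general: ŷ = α_d·x_sd + α_n·x_sn + β (3 parameters);
* spec_d: per-disease α_d(dᵢ), α_n(dᵢ), β(dᵢ);
* spec_dl: ŷ = α_d(dᵢ)θ_d(lⱼ)x_sd + α_n(dᵢ)θ_n(lⱼ)x_sn + β(dᵢ)Φ(lⱼ).

Query-input variants use three count terms with the same sharing
structure. Counts enter raw (no log/normalization). Fitting is full-batch
Adam on MSE (learning rate 0.02, max 1000 epochs), early stopping with
patience 50 on validation MSE, best epoch restored; the chronological
split is years 1–2 train, year 3 validation, year 4 test. Predictions are
not clipped during fitting (clipping changes gradients); a `clip_negative`
flag exists for presentation.

Numerical choices for the factorized variant: slope factors α initialize
at small positive values (~0.01, seed-jittered to break symmetry); the
region factors θ and Φ initialize at **1** and offsets β at 0. Starting θ
= Φ = 1 makes spec_dl begin exactly at its per-disease reduction, and —
crucially — avoids a dead multiplicative saddle: if β and Φ both started
at 0, both of their gradients would be identically zero forever. The
product form is scale-degenerate (α·θ = (cα)(θ/c)), so tests and analyses
compare predictions and per-cell products, never raw parameter vectors.
The "best-achievable training MSE" used in the nesting check is the
minimum over the recorded optimization trajectory (epoch 0 included).

Metrics: RMSE = √(mean (ŷ−y)²) and RER = Σ|ŷ−y| / Σy over evaluated
cells, on the rescaled incidence scale. The sum-normalized RER weights
cells by incidence magnitude, which is the sensible aggregate when most
cells are near zero; a per-cell mean of relative errors would be dominated
by tiny denominators. RER raises on panels whose true incidences sum to
zero. The news-weight analysis reports the D×R matrix of products
α_n(dᵢ)·θ_n(lⱼ) and the fraction that are negative; per-cell case series
are min–max normalized per series (a constant series maps to zeros).

### Evaluation protocol

Experiments repeat over ≥2 seeds (5 by default); each metric is reported
as mean with a 95% t-distribution CI (mean ± t_{n−1,0.975}·sd/√n — at n=5
the normal approximation would be anticonservative). Query vs session
inputs are compared by a two-sided Welch t-test on per-seed values
(unequal variances are the safe default; a paired variant exists for runs
sharing seeds), alongside the headline statistic
(mean_query − mean_session)/mean_query × 100.

## The synthetic world

The generator emulates the study conditions: 15 diseases × 4 regions × 16
seasons; an intent mixture of 24% RD / 6.5% news / 69.5% other; region
weights (0.384, 0.271, 0.265, 0.078) proportional to a realistic
population gradient (East > West ≈ Central > Northeast); per-disease
lognormal size spread and sinusoidal seasonality (±30%); news burst
events (disease, season, multiplier 5) planted in training, validation
and test years, each also planting a season-specific burst token in its
news sessions. Per-cell session counts are Poisson; other-intent volume
carries an extra lognormal jitter (σ=0.3) so raw query counts are a noisy,
contaminated mixture — the mechanism that makes the query-input baseline
genuinely worse, mirroring the central claim being tested.

Incidence is y = α_d(dᵢ)θ_d(lⱼ)·x_sd + α_n(dᵢ)θ_n(lⱼ)·x_sn + β(dᵢ)Φ(lⱼ)
+ ε, truncated at zero, with ε Gaussian at sd = 5% of the mean incidence
by default. The generating coefficients are deliberately rank-1 products,
so the factorized estimator's model class contains the truth and held-out
parameter recovery is a well-posed check; RD coefficients are positive,
news coefficients negative for 13 of 15 diseases (two small positive
outliers), offsets at the 1e-7 scale against incidences of order 1e-6.
Sessions realize as 1–8 query records (RD sessions longest, other
shortest) with intra-session gaps of 10 s–15 min and same-user sessions
pushed > 30 min apart, so the generated boundaries are exactly
recoverable by the gap rule. Class-specific vocabulary (care / news /
chatter words), click domains (clinic / news / portal) and click-position
ranges make intents learnable from the defined features. Everything
derives from one seed; regeneration is byte-identical.

What the generator does **not** emulate: real linguistic content and
ambiguity (intent classes are cleanly separable by construction, so
perfect synthetic classification says nothing about accuracy on human
annotations), keyword polysemy and false matches, user-level behavior
beyond a simple session-count distribution, reporting lags and
under-registration in the incidence ground truth, and any dependence of
true incidence on search behavior beyond the stated linear link. Passing
tests therefore demonstrate correctness of the machinery and
recoverability under the stated model, not real-world accuracy.

Problem sizes in the test suite and acceptance script (counts-rich panels
from 20 000-user worlds, 2 400-session labeled sets, 5-seed repetitions,
compact classifier hidden sizes of 24) were chosen so the full pipeline
demonstrates every property in seconds per check while keeping per-cell
counts large enough for stable fits.

## Known limitations

* The LSTM+MLP is a deliberately simple architecture; minority-class F1
  on hard, imbalanced real annotations would be the binding constraint.
* spec_dl's loss surface is non-convex; different seeds can land on
  different (prediction-equivalent) scalings, and confidence intervals on
  its metrics are wider than for the linear variants.
* The incidence link is static and non-autoregressive by design; temporal
  carry-over of incidence is out of scope.
* Substring keyword matching trades precision for recall on real text;
  a production deployment would need disambiguation for polysemous
  disease names.
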