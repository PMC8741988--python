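# Methods

`campuspulse` links two monthly signals for a college campus: the rate of
on-campus mental-health consultations and the prevalence of symptomatic
mental-health language in the campus's online community. This note
documents the models, the synthetic data the package is validated on,
the numerical choices, and the known limitations.

## The analysis pipeline

1. **Symptomatic-expression classification.** Five binary linear SVMs —
   one per outcome: depression, anxiety, stress, suicidal ideation,
   psychosis — over unigram/bigram/trigram counts. Each is trained on an
   outcome-enriched positive corpus against a shared control corpus and
   then *transferred* to the campus post stream, labeling every post 0/1
   per outcome at the SVM's natural zero margin (no threshold
   calibration). Tokenization is deliberately simple and reproducible:
   lowercase, split on non-alphanumerics, keep tokens of length ≥ 2.
   N-grams seen in fewer than two training documents are pruned
   (config: `min_df`).

2. **Monthly series.** Consultations are normalized to a rate,
   100 · visits / enrollment (percent of enrolled students per month).
   Post labels are averaged per calendar month into per-outcome
   prevalence series in [0, 1]. Months with zero posts propagate as
   missing and are linearly interpolated at the series-building stage,
   with a warning.

3. **Residualization and lagged association.** Both series carry
   academic-calendar trend and seasonality, so raw correlations would
   mostly reflect the shared calendar. Each series is decomposed
   additively: trend = centered moving average (default window 12
   months, the period of the known seasonality); seasonal =
   per-calendar-month mean of the detrended series, re-centred to sum
   to zero over the year; residual = remainder. Stationarity of the
   residual is verified with an augmented Dickey–Fuller test (lag order
   by AIC up to ⌊(n−1)^{1/3}⌋; stationary iff p < 0.05). The
   association at lag ℓ is the standardized OLS coefficient *e* of the
   expression residual at t−ℓ in a regression of the consultation
   residual at t that controls for both series' previous-month values;
   standardization makes *e* comparable across outcomes. Lags 0–6 are
   scanned by default.

4. **Forecasting.** Consultation rates are forecast with SARIMA
   (seasonal period 12), fit on the normalized rates (the model handles
   seasonality internally, so residualized series are not used here).
   Model **M0** uses the rate series alone; **M1** adds the monthly
   prevalence series of depression, anxiety, stress and suicidal
   ideation as exogenous regressors (psychosis excluded by default,
   available via config). Evaluation uses anchored 10-fold
   cross-validation: the first 12 months are an anchor present in every
   training set, and the remaining months are partitioned into k
   contiguous blocks, each predicted exactly once. Pooled predictions
   are scored with Pearson's r, MAE and SMAPE, compared with a
   1000-permutation null (shuffled predictions) and head-to-head with
   the Williams/Steiger t-test for dependent correlations sharing the
   actual series.

5. **Language characterization.** Months are split at the median rate
   into Hi-MHC and Lo-MHC groups (ties at the median alternate between
   groups so sizes differ by at most one). The two post corpora are
   contrasted with SAGE (below) and profiled against a `.dic`-format
   category lexicon: per document, each category's percentage of
   matching tokens (terminal `*` = prefix wildcard), compared across
   groups with Welch t-tests under Benjamini–Yekutieli FDR correction
   (valid under arbitrary dependence; plain Benjamini–Hochberg via
   config). The per-document unit is the default; per-month averaging
   is available (`profile_unit: month`).

## SAGE

The target group's term distribution is modeled as
p(w) ∝ exp(m_w + η_w), with m the log of the smoothed background term
frequencies and η a sparse deviation vector; large positive η marks
terms characteristic of the target corpus, large negative η terms it
avoids. The fit maximizes the multinomial log-likelihood of the
(add-0.1-smoothed) target counts minus a smoothed-L1 penalty
reg · Σ_w √(η̃_w² + ε²) with ε = 10⁻⁶, applied in the gauge
logsumexp(m + η) = 0. Fixing that gauge makes exp(m + η) itself a
probability distribution, removes the additive-shift indeterminacy of
the softmax, and gives the exact weak-regularization limit
η_w → log f̂_target,w − m_w.

Optimization is majorize–minimize: each outer iteration freezes
per-term quadratic penalty weights reg / √(η_w² + ε²) — the self-tuning
step, which shrinks frequent (large-|η| resistant) terms less than rare
ones — and solves the smooth inner problem by L-BFGS; convergence when
max |Δη| < 10⁻⁶ (error after 500 iterations), followed by one L-BFGS
polish on the exact penalized objective, since MM convergence is linear
and can stall within ~10⁻⁴ of the optimum. Tests verify the fit against
a derivative-free (Powell) maximizer of the same objective on small
vocabularies. An optional background-weighted zero-sum recentering of η
is available for reporting. Ranking ties break toward higher background
frequency, then lexicographically.

The contrast is Hi-months directly versus Lo-months (a single signed
axis), not each group versus a pooled background.

## SMAPE

SMAPE is reported in its [0, 100]-bounded form,
100 · mean(|y−x| / (|x|+|y|)), with a 0/0 term defined as 0 by
continuity. The half-denominator form |y−x| / [(|x|+|y|)/2] that often
appears in print is exactly twice this and ranges over [0, 200] — it
cannot satisfy a [0, 100] bound — so the bounded form is used
throughout; every relative comparison between models is identical under
either scale.

## Synthetic data

Both real inputs (confidential health-center records, a campus subreddit
archive) are private, so a seeded generator emulates their structure at
the scale of the motivating setting: a ~50,000-student university, a
64-month post stream at 33 posts/day, and consultation rates with
academic-calendar seasonality.

* **Calendar.** A period-12 seasonal pattern (unitless, re-centred to
  zero over the year) peaks before exams in April, July and November
  and dips in the December, February and October holidays; amplitude
  1.5 rate points, plus a mild linear trend (0.01 points/month) and a
  small seeded jitter on non-peak months.
* **Consultations.** rate_t = base (5% of enrolled) + trend + seasonal
  + N(0, 0.35), clipped at zero.
* **Posts.** Daily counts are Poisson (mean configurable, 33/day
  default — the simplest count model; overdispersion can be layered on
  later). Tokens are drawn from a mixture of a 2000-word Zipf
  background vocabulary and five 10-word outcome lexicons. Each
  outcome's mixture weight in month t is
  2 · base_mix · σ(link_slope · coupling · load_t), where load combines
  the standardized seasonal pattern (weight `season_gain` = 0.5) with
  the standardized stochastic consultation residual at month t + lag —
  so the stream *leads* consultations by `lag` months. coupling = 0
  freezes the weights entirely, decoupling the stream from both the
  consultation noise and the calendar. The soft link slope (0.35) keeps
  the logistic quasi-linear over typical loads, so prevalence tracks
  the consultation signal proportionally and strengthening the coupling
  monotonically strengthens the correlation rather than saturating it.
* **Training corpora.** Per outcome, 500 positive documents with
  lexicon-token rate 0.3 and a shared 500-document control at rate 0.01
  (drawn from the union of all lexicons), mean length 50 tokens —
  separable by design, mirroring the subreddit-positive /
  collated-control construction the transfer classifiers assume.

All generators are deterministic given the seed; independent substreams
keep the post noise from aliasing the consultation noise. What the
generator does **not** emulate: real Reddit markup, thread structure,
author networks, topic drift, vocabulary burstiness, or irrelevant
content (ads, non-students). Passing tests therefore show that the
pipeline recovers the structure it assumes when that structure is
present — not that real campus data contains it.

## Evaluation design choices

* **Fold fitting.** A SARIMA likelihood needs a contiguous series, but
  cross-validation folds are interior blocks. Fold models are therefore
  fit on the full series with the test block masked as missing: the
  Kalman filter skips masked observations, and their predictions use
  the surrounding data plus the exogenous covariates, which remain
  observed for test months (a nowcasting contract). Orders are selected
  once per model on the full series by AIC over a compact grid
  (p, d, q, P, D, Q ∈ {0, 1}, s = 12; config-exposed), then refit per
  fold; multi-seed power tests fix one airline-style specification,
  (1,0,0)×(0,1,1)₁₂, so the M0/M1 contrast isolates the covariates.
* **Exogenous lag.** When the post stream leads consultations (as the
  generator's `lag` makes explicit and the lag scan detects), M1 can
  shift its covariates back by `exog_lag` months; the default is 0.
* **Irrelevant covariates.** With coupling 0, M1 carries four noise
  regressors and is on average *slightly worse* than M0 — the familiar
  cost of irrelevant covariates. The validated property is the absence
  of a systematic M1 advantage, not exact equality.
* **Problem sizes.** The test suite measures recovery rates on 60-month
  series with ~12 posts/day (10 seeds for coupled recovery, 20 for the
  decoupled null); the acceptance script runs the full 64-month,
  33-posts/day scale. These sizes are the package's validation
  conditions and are stated here so they can be reproduced exactly.

## Numerical details and degenerate inputs

* Decomposition is exactly additive (trend + seasonal + residual equals
  the input to machine precision); the seasonal component is estimated
  only from months where the centered moving average is defined, and
  trend edges are padded with the nearest interior estimate rather than
  discarding a year of a short series. Repeating residualization is an
  identity only for trend-free inputs: the moving-average filter is not
  a projection, so a second pass on a noisy residual shifts it slightly.
* A constant training series short-circuits to a constant forecaster
  (SARIMA maximum likelihood is degenerate there); a constant series
  sent to the ADF test reports non-stationary with a `degenerate` flag.
* The lag-1 regression drops the previous-month expression control,
  which would otherwise duplicate the predictor exactly.
* SARIMA fits prefer the stationarity/invertibility-enforced
  parameterization and fall back to the unconstrained one.
* The Williams/Steiger t uses n − 3 degrees of freedom and returns
  t = 0 for identical prediction vectors.

## Limitations

* Transfer classifiers are only as good as their training corpora; the
  synthetic corpora are linearly separable almost by construction, so
  the ~0.90+ held-out accuracy is a plumbing check, not a claim about
  real mental-health language.
* With 50–80 months, SARIMA order selection is noisy; the AIC winner
  can differ across nearby seeds. The anchored-CV estimate pools only
  ~50 test months, so metric differences of a few percent are within
  fold noise.
* The SAGE penalty strength `reg` trades recall of rare terms against
  stability; the default (10.0) suits corpora of thousands of
  documents, and small corpora warrant smaller values.
* Per-document category t-tests treat posts as independent, ignoring
  author- and thread-level clustering; the per-month unit is the
  conservative alternative.
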