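# campuspulse

Campus mental-health services struggle to anticipate demand: surveys are
slow and sparse, while need ebbs and flows with the academic year. The
language students post in their campus's online community is a passive,
real-time signal of that need. `campuspulse` is a tested, reusable
pipeline for asking — and quantifying — whether that signal actually
predicts on-campus mental-health consultations:

1. **Classify** posts with per-outcome n-gram (n = 1, 2, 3) linear SVMs
   for symptomatic expressions of depression, anxiety, stress, suicidal
   ideation and psychosis (transfer setup: train on labeled corpora,
   apply to the campus stream), and aggregate monthly prevalence series.
2. **Associate**: normalize consultations to a rate (100·visits/
   enrollment), remove moving-window trend and period-12 seasonality
   from both series (verified by augmented Dickey–Fuller tests), and
   regress consultation residuals on lagged expression residuals with
   previous-month controls, reporting a standardized coefficient *e*
   per lag.
3. **Forecast** the consultation rate with SARIMA under anchored 10-fold
   cross-validation — M0 uses the rate series alone, M1 adds the
   prevalence series as exogenous regressors — scoring pooled
   predictions with Pearson's r, MAE and SMAPE, a 1000-permutation
   null, and the Williams/Steiger t-test for dependent correlations.
4. **Characterize** the language of high- vs low-consultation months
   (median split) with a from-scratch SAGE implementation (sparse
   additive generative model: p(w) ∝ exp(m_w + η_w), self-tuned
   sparsity on η) and LIWC-dialect `.dic` lexicon profiling with
   Benjamini–Yekutieli FDR-corrected Welch t-tests.

Because both real inputs are confidential (health-center records) or
non-redistributable (the subreddit archive), the package ships a seeded
synthetic-data module that generates consultation series with
academic-calendar seasonality and post streams whose lexicon prevalence
is coupled to the consultation signal at a configurable lag and
strength — every downstream stage is testable end to end without any
download, and user-supplied CSV/JSONL/`.dic` files drop in wherever the
synthetic data stands.

See `docs/methods.md` for the models, parameter defaults, and what the
synthetic validation does and does not show.

## Worked example

Generate a synthetic campus in which post language leads consultations
by two months, then run the full pipeline:

```python
from campuspulse import synthetic_data as sd, forecasting as fc
from campuspulse.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=7,
    sim=sd.SimConfig(n_months=60, posts_per_day=12, coupling=2.0, lag=2),
    forecast=fc.ForecastConfig(orders=((1, 0, 0), (0, 1, 1, 12)), exog_lag=2),
)
report = run_pipeline(cfg)
```

Printing the headline fields of the report gives:

```
best lag (stress): 2 months, e = 0.90
M0: r = 0.88, SMAPE = 5.07
M1: r = 0.97, SMAPE = 2.39
SMAPE reduction: 52.9%  (dependent-correlation t = -4.38, p = 0.000)
permutation null: mean r = -0.001, prob better than M1 = 0
```

Reading: the lag scan recovers the planted 2-month lead (the
standardized coefficient of the stress-expression residual peaks at
lag 2); adding the social-media covariates cuts the cross-validated
forecast error roughly in half, the dependent-overlapping-correlation
test confirms M1's correlation advantage is significant (negative t
favors M1), and no permutation of the predictions performs as well —
the improvement is not chance.

The same stages are available from the shell:

```bash
campuspulse simulate --out run/ --seed 1
campuspulse train --pos run/corpora/stress --neg run/corpora/negatives \
    --outcome stress --model stress.pkl
campuspulse label --model stress.pkl --posts run/posts.jsonl --out labeled.jsonl
campuspulse run-all --out run/ --seed 1        # full pipeline + report.json
```

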