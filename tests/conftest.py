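"""Shared fixtures: trained classifiers and multi-seed synthetic runs.

The heavier fixtures are session-scoped because several tests measure
recovery rates over the same collection of seeded datasets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from campuspulse import corpus_classifiers as cc
from campuspulse import forecasting as fc
from campuspulse import series_builder as sb
from campuspulse import synthetic_data as sd

# evaluation scale: five years of months, a ~12-posts/day stream
N_MONTHS = 60
POSTS_PER_DAY = 12.0

#: fixed orders used for the multi-seed model comparisons (one airline-style
#: seasonal spec for both models keeps the M0/M1 contrast about the
#: covariates, not about order selection)
CV_CONFIG = fc.ForecastConfig(orders=((1, 0, 0), (0, 1, 1, 12)))
CV_CONFIG_LAG2 = fc.ForecastConfig(orders=((1, 0, 0), (0, 1, 1, 12)), exog_lag=2)


def sim_config(seed: int, **kw) -> sd.SimConfig:
    base = dict(seed=seed, n_months=N_MONTHS, posts_per_day=POSTS_PER_DAY)
    base.update(kw)
    return sd.SimConfig(**base)


@pytest.fixture(scope="session")
def corpora():
    return sd.gen_training_corpora(sd.SimConfig(seed=999))


@pytest.fixture(scope="session")
def classifiers(corpora):
    return cc.train_all(corpora, cc.ClassifierConfig(seed=0))


def _run(classifiers, cfg: sd.SimConfig) -> dict:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile, rate, posts, _ = sd.simulate(cfg)
        labeled = cc.label_posts(classifiers, posts)
        prevalence = cc.monthly_prevalence(labeled, months=profile.months)
    return {
        "cfg": cfg,
        "rate": rate,
        "labeled": labeled,
        "prevalence": prevalence,
    }


@pytest.fixture(scope="session")
def coupled_runs(classifiers):
    """10 seeded datasets with coupling=2 at a 2-month lead."""
    return [
        _run(classifiers, sim_config(seed, coupling=2.0, lag=2))
        for seed in range(10)
    ]


@pytest.fixture(scope="session")
def null_runs(classifiers):
    """20 seeded datasets with the post stream decoupled (coupling=0)."""
    return [
        _run(classifiers, sim_config(seed, coupling=0.0))
        for seed in range(20)
    ]


def cv_smapes(run: dict, cfg_m1: fc.ForecastConfig) -> tuple[float, float]:
    """Pooled SMAPE of M0 and M1 on one synthetic dataset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exog = run["prevalence"][list(fc.DEFAULT_EXOG_OUTCOMES)].apply(
            sb.fill_missing
        )
        rate = run["rate"]
        s0 = fc.metrics(fc.cv_predict(rate, None, CV_CONFIG, "M0")).smape
        s1 = fc.metrics(fc.cv_predict(rate, exog, cfg_m1, "M1")).smape
    return s0, s1


@pytest.fixture(scope="session")
def coupled_cv_smapes(coupled_runs):
    return [cv_smapes(run, CV_CONFIG_LAG2) for run in coupled_runs]


@pytest.fixture(scope="session")
def null_cv_smapes(null_runs):
    return [cv_smapes(run, CV_CONFIG) for run in null_runs]


@pytest.fixture(scope="session")
def example_predictions(coupled_runs):
    """A pooled M0 prediction set from the first coupled dataset."""
    run = coupled_runs[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fc.cv_predict(run["rate"], None, CV_CONFIG, "M0")


@pytest.fixture
def month_index():
    def make(n: int, start: str = "2011-05") -> pd.PeriodIndex:
        return pd.period_range(start, periods=n, freq="M")

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
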