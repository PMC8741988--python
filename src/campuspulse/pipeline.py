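"""End-to-end orchestration: simulate -> classify -> associate -> forecast
-> characterize, from a single seeded config, with a consolidated report.

A run either generates synthetic inputs (default) or ingests user files
(consultation CSV, post-stream JSONL, corpora directory, ``.dic``
lexicon).  The single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` spawn keys, so stages can be re-run in
isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from campuspulse import corpus_classifiers as cc
from campuspulse import forecasting as fc
from campuspulse import language_salience as ls
from campuspulse import series_builder as sb
from campuspulse import synthetic_data as sd

log = logging.getLogger("campuspulse")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    # inputs: either simulate=True, or paths to user-supplied files
    simulate: bool = True
    visits_csv: str | None = None
    posts_jsonl: str | None = None
    corpora_dir: str | None = None
    lexicon_dic: str | None = None
    # per-stage settings
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    classifier: cc.ClassifierConfig = field(default_factory=cc.ClassifierConfig)
    window: int = 12
    max_lag: int = 6
    forecast: fc.ForecastConfig = field(default_factory=fc.ForecastConfig)
    n_perm: int = 1000
    sage_reg: float = 10.0
    sage_min_df: int = 5
    sage_max_features: int | None = 2000
    top_k: int = 25
    fdr_method: str = "fdr_by"
    profile_unit: str = "document"  # or "month"

    def stage_seed(self, stage: int) -> int:
        ss = np.random.SeedSequence(self.seed, spawn_key=(stage,))
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            if "lexicons" in sim:
                sim["lexicons"] = {
                    k: tuple(v) for k, v in sim["lexicons"].items()
                }
            d["sim"] = sd.SimConfig(**sim)
        if "classifier" in d and isinstance(d["classifier"], dict):
            d["classifier"] = cc.ClassifierConfig(**d["classifier"])
        if "forecast" in d and isinstance(d["forecast"], dict):
            fcd = dict(d["forecast"])
            for key in ("orders", "grid", "exog_outcomes"):
                if key in fcd and fcd[key] is not None:
                    fcd[key] = _tuplify(fcd[key])
            d["forecast"] = fc.ForecastConfig(**fcd)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _tuplify(x):
    if isinstance(x, (list, tuple)):
        return tuple(_tuplify(v) for v in x)
    return x


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except Exception as err:
        raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
    log.info("stage %s: done", name)


def _load_visits(path: str) -> tuple[pd.Series, pd.Series]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"visits file not found: {p}")
    df = pd.read_csv(p)
    idx = pd.PeriodIndex(df["month"], freq="M")
    return (
        pd.Series(df["visits"].to_numpy(), idx),
        pd.Series(df["enrollment"].to_numpy(), idx),
    )


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return the run report (JSON-ready).

    When ``out_dir`` is given, intermediate artifacts (series, labeled
    posts, predictions, salience tables) and ``report.json`` are written
    there; partial artifacts are retained if a later stage fails.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "seed": cfg.seed,
            "config_hash": config_hash(cfg),
            "package": "campuspulse",
        }
    }

    with _stage("inputs"):
        if cfg.simulate:
            sim = dataclasses.replace(cfg.sim, seed=cfg.stage_seed(0))
            profile, rate, posts, corpora = sd.simulate(sim)
            visits_df = sd.consultations_frame(rate, sim.enrollment)
            visits = pd.Series(
                visits_df["visits"].to_numpy(),
                pd.PeriodIndex(visits_df["month"], freq="M"),
            )
            enrollment = pd.Series(sim.enrollment, visits.index)
        else:
            if cfg.visits_csv is None or cfg.posts_jsonl is None:
                raise ValueError("visits_csv and posts_jsonl required")
            visits, enrollment = _load_visits(cfg.visits_csv)
            posts = sd.PostStream.from_jsonl(cfg.posts_jsonl)
            if cfg.corpora_dir is None:
                raise ValueError("corpora_dir required to train classifiers")
            base = Path(cfg.corpora_dir)
            manifest = json.loads((base / "manifest.json").read_text())
            corpora = sd.TrainingCorpora(
                positives={
                    o: sd.read_corpus_dir(base / info["dir"])
                    for o, info in manifest["outcomes"].items()
                },
                negatives=sd.read_corpus_dir(
                    base / manifest["negatives"]["dir"]
                ),
            )
        rate = sb.normalize_consultations(visits, enrollment)
        if out is not None:
            sd.consultations_frame(rate, int(enrollment.iloc[0])).to_csv(
                out / "visits.csv", index=False
            )

    with _stage("train"):
        clf_cfg = dataclasses.replace(cfg.classifier, seed=cfg.stage_seed(1))
        classifiers = cc.train_all(corpora, clf_cfg)
        accuracy = {o: c.heldout_accuracy for o, c in classifiers.items()}
        report["classifier_accuracy"] = accuracy

    with _stage("label"):
        labeled = cc.label_posts(classifiers, posts)
        post_months = pd.period_range(
            labeled["month"].min(), labeled["month"].max(), freq="M"
        )
        prevalence = cc.monthly_prevalence(
            labeled, tuple(classifiers), months=post_months
        )
        report["prevalence_summary"] = {
            o: float(labeled[o].mean()) for o in classifiers
        }
        if out is not None:
            prevalence.to_csv(out / "prevalence.csv")

    with _stage("associate"):
        overlap = prevalence.index.intersection(rate.index)
        rate_resid, rate_adf = sb.residualize(rate.loc[overlap], cfg.window)
        lag_rows = []
        for o in classifiers:
            expr = sb.fill_missing(prevalence[o].loc[overlap])
            expr_resid, _ = sb.residualize(expr, cfg.window)
            scan = sb.scan_lags(rate_resid, expr_resid, cfg.max_lag, outcome=o)
            lag_rows.append(scan)
        lag_scan = pd.concat(lag_rows, ignore_index=True)
        best = lag_scan.loc[lag_scan.groupby("outcome")["e"].idxmax()]
        report["stationarity"] = {
            "rate_adf_p": rate_adf.p_value,
            "rate_stationary": rate_adf.stationary,
        }
        report["lag_scan"] = lag_scan.to_dict(orient="records")
        report["best_lag"] = {
            r["outcome"]: {"lag": int(r["lag"]), "e": r["e"], "p": r["p_value"]}
            for r in best.to_dict(orient="records")
        }
        if out is not None:
            lag_scan.to_csv(out / "lag_scan.csv", index=False)

    with _stage("forecast"):
        exog = prevalence[
            [o for o in cfg.forecast.exog_outcomes if o in prevalence.columns]
        ].loc[overlap].apply(sb.fill_missing)
        rate_fc = rate.loc[overlap]
        pred0 = fc.cv_predict(rate_fc, None, cfg.forecast, model_id="M0")
        pred1 = fc.cv_predict(rate_fc, exog, cfg.forecast, model_id="M1")
        comparison = fc.compare_models(pred0, pred1)
        perm_seed = cfg.stage_seed(2)
        perm0 = fc.permutation_test(pred0, cfg.n_perm, perm_seed)
        perm1 = fc.permutation_test(pred1, cfg.n_perm, perm_seed)
        report["forecast"] = {
            "m0": dataclasses.asdict(comparison.metrics_m0),
            "m1": dataclasses.asdict(comparison.metrics_m1),
            "delta_r_percent": comparison.delta_r_percent,
            "delta_smape_percent": comparison.delta_smape_percent,
            "steiger_t": comparison.steiger_t,
            "steiger_p": comparison.steiger_p,
            "permutation": {
                "mean_r": perm0.mean_r,
                "mean_smape": perm0.mean_smape,
                "prob_better_than_m0": perm0.prob_better,
                "prob_better_than_m1": perm1.prob_better,
                "n_perm": cfg.n_perm,
            },
        }
        if out is not None:
            pd.DataFrame({
                "month": pred0.months.astype(str),
                "actual": pred0.actual,
                "pred_m0": pred0.predicted,
                "pred_m1": pred1.predicted,
            }).to_csv(out / "predictions.csv", index=False)

    with _stage("salience"):
        split = ls.median_split(rate_fc)
        hi_docs, lo_docs = ls.split_documents(labeled, split)
        sage = ls.fit_sage(
            hi_docs, lo_docs,
            reg=cfg.sage_reg,
            min_df=cfg.sage_min_df,
            max_features=cfg.sage_max_features,
        )
        top_pos = ls.top_salient(sage, cfg.top_k, "positive")
        top_neg = ls.top_salient(sage, cfg.top_k, "negative")
        lexicon = (
            ls.parse_dic(cfg.lexicon_dic)
            if cfg.lexicon_dic
            else ls.demo_lexicon()
        )
        if cfg.profile_unit == "month":
            hi_prof = ls.monthly_profiles(labeled, split.hi_months, lexicon)
            lo_prof = ls.monthly_profiles(labeled, split.lo_months, lexicon)
        else:
            hi_prof = ls.lexicon_profile(hi_docs, lexicon)
            lo_prof = ls.lexicon_profile(lo_docs, lexicon)
        cats = ls.compare_categories(hi_prof, lo_prof, method=cfg.fdr_method)
        report["salience"] = {
            "threshold": split.threshold,
            "n_hi_months": len(split.hi_months),
            "n_lo_months": len(split.lo_months),
            "top_positive": top_pos,
            "top_negative": top_neg,
        }
        report["categories"] = cats.to_dict(orient="records")
        if out is not None:
            sage.as_frame().to_csv(out / "sage.csv", index=False)
            cats.to_csv(out / "categories.csv", index=False)

    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float) + "\n"
        )
    return report
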