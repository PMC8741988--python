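"""Synthetic campus data: consultation series, coupled post streams, corpora.

Real inputs to this kind of analysis -- confidential health-center
records and a campus subreddit archive -- cannot be redistributed, so
this module generates stand-ins with the statistical structure the
downstream analysis assumes:

* a monthly consultation *rate* (percent of enrolled students) with
  academic-calendar seasonality, a mild trend, and Gaussian noise;
* a timestamped post stream whose mental-health-lexicon token prevalence
  is coupled, at a configurable lag and strength, to the latent load
  driving consultations;
* separable per-outcome training corpora that play the role of the
  mental-health subreddits used to train transfer classifiers.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

OUTCOMES: tuple[str, ...] = (
    "depression",
    "anxiety",
    "stress",
    "suicidal_ideation",
    "psychosis",
)

#: Small disjoint outcome lexicons used both by the generator and, via the
#: demonstration ``.dic`` dictionary, by the profiling stage.
DEFAULT_LEXICONS: dict[str, tuple[str, ...]] = {
    "depression": (
        "depressed", "depression", "hopeless", "worthless", "empty",
        "crying", "numb", "antidepressant", "miserable", "lonely",
    ),
    "anxiety": (
        "anxious", "anxiety", "panic", "worry", "nervous",
        "dread", "restless", "overthinking", "palpitations", "jittery",
    ),
    "stress": (
        "stress", "stressed", "overwhelmed", "deadline", "pressure",
        "burnout", "exams", "cramming", "workload", "exhausted",
    ),
    "suicidal_ideation": (
        "suicide", "suicidal", "selfharm", "overdose", "hotline",
        "goodbye", "lifeless", "burden", "despair", "insomnia",
    ),
    "psychosis": (
        "voices", "hallucination", "paranoid", "delusion", "unreal",
        "shadows", "psychotic", "derealization", "disoriented", "episodes",
    ),
}

# Seasonal shape of the academic year: pre-exam months peak, holidays dip.
DEFAULT_PEAKS: dict[int, float] = {4: 1.0, 7: 0.75, 11: 0.85}
DEFAULT_TROUGHS: dict[int, float] = {12: -1.0, 2: -0.8, 10: -0.55}


@dataclass(frozen=True)
class CalendarProfile:
    """Deterministic academic-calendar structure for ``n_months`` months.

    ``seasonal_load`` is a period-12 pattern (unitless, in consultation-rate
    percent units) whose mean over any 12 consecutive months is zero;
    ``trend`` is a slow drift in the same units.
    """

    months: pd.PeriodIndex
    seasonal_load: np.ndarray
    trend: np.ndarray

    @property
    def n_months(self) -> int:
        return len(self.months)

    @property
    def month_of_year(self) -> np.ndarray:
        return np.asarray(self.months.month)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic campus.

    Defaults emulate the scale of the motivating data: a ~50,000-student
    university, a 64-month post stream averaging 33 posts/day, and an
    84-month consultation history.
    """

    seed: int = 0
    n_months: int = 64
    start_month: str = "2011-05"
    enrollment: int = 50_000
    base_rate: float = 5.0          # percent of enrolled per month
    trend_slope: float = 0.01       # percent per month
    seasonal_amplitude: float = 1.5  # percent, scales the calendar pattern
    noise_sd: float = 0.35          # percent
    coupling: float = 1.0           # strength of latent-load -> lexicon link
    lag: int = 0                    # months by which posts lead consultations
    season_gain: float = 0.5        # seasonal share of the latent load
    link_slope: float = 0.35        # keeps the logistic link quasi-linear
    posts_per_day: float = 33.0
    doc_len_mean: float = 40.0
    doc_len_min: int = 3
    base_mix: float = 0.04          # per-outcome lexicon weight at neutral load
    background_vocab_size: int = 2000
    lexicons: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_LEXICONS)
    )
    # training-corpus knobs
    n_pos: int = 500
    n_neg: int = 500
    p_pos: float = 0.3
    p_neg: float = 0.01
    train_doc_len_mean: float = 50.0


@dataclass(frozen=True)
class Post:
    id: str
    timestamp: datetime
    author: str
    text: str

    def month(self) -> pd.Period:
        return pd.Period(self.timestamp.strftime("%Y-%m"), freq="M")


@dataclass
class PostStream:
    posts: list[Post]

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self):
        return iter(self.posts)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self.posts:
                fh.write(json.dumps({
                    "id": p.id,
                    "timestamp": p.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "author": p.author,
                    "text": p.text,
                }) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "PostStream":
        posts = []
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                ts = datetime.strptime(
                    d["timestamp"], "%Y-%m-%dT%H:%M:%SZ"
                ).replace(tzinfo=timezone.utc)
                posts.append(Post(d["id"], ts, d["author"], d["text"]))
        return cls(posts)


@dataclass
class TrainingCorpora:
    """Per-outcome positive documents plus one shared negative corpus."""

    positives: dict[str, list[str]]
    negatives: list[str]


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent substreams so e.g. post noise never aliases consult noise
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def make_calendar(
    n_months: int,
    seed: int,
    start_month: str = "2011-05",
    peaks: dict[int, float] | None = None,
    troughs: dict[int, float] | None = None,
    amplitude: float = 1.5,
    trend_slope: float = 0.01,
    jitter_sd: float = 0.05,
) -> CalendarProfile:
    """Build the academic-calendar profile.

    The period-12 seasonal pattern takes its configured values at peak and
    trough months, a small seeded jitter elsewhere, and is re-centred so it
    averages exactly zero over a year.
    """
    if n_months < 24:
        raise ValueError("insufficient history for seasonal modeling")
    peaks = DEFAULT_PEAKS if peaks is None else peaks
    troughs = DEFAULT_TROUGHS if troughs is None else troughs
    rng = np.random.default_rng(seed)
    pattern = np.zeros(12)
    jitter = rng.normal(0.0, jitter_sd * amplitude, size=12)
    for m in range(1, 13):
        if m in peaks:
            pattern[m - 1] = peaks[m] * amplitude
        elif m in troughs:
            pattern[m - 1] = troughs[m] * amplitude
        else:
            pattern[m - 1] = jitter[m - 1]
    pattern -= pattern.mean()
    months = pd.period_range(start=start_month, periods=n_months, freq="M")
    seasonal = pattern[np.asarray(months.month) - 1]
    trend = trend_slope * np.arange(n_months, dtype=float)
    return CalendarProfile(months=months, seasonal_load=seasonal, trend=trend)


def gen_consultations(profile: CalendarProfile, cfg: SimConfig) -> pd.Series:
    """Monthly consultation rate (percent of enrolled), clipped at zero.

    rate_t = base_rate + trend_t + seasonal_load_t + N(0, noise_sd).
    """
    if profile.n_months != cfg.n_months:
        raise ValueError(
            f"profile has {profile.n_months} months, config expects {cfg.n_months}"
        )
    if cfg.base_rate < 0:
        raise ValueError("base_rate must be non-negative")
    rng = _rng(cfg.seed, 1)
    noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_months) if cfg.noise_sd > 0 \
        else np.zeros(cfg.n_months)
    rate = cfg.base_rate + profile.trend + profile.seasonal_load + noise
    rate = np.clip(rate, 0.0, None)
    return pd.Series(rate, index=profile.months, name="rate_percent")


def consultations_frame(rate: pd.Series, enrollment: int) -> pd.DataFrame:
    """Integer visit counts and enrollment, as the ingestion CSV expects."""
    visits = np.rint(rate.to_numpy() / 100.0 * enrollment).astype(int)
    return pd.DataFrame(
        {"month": rate.index.strftime("%Y-%m"),
         "visits": visits,
         "enrollment": enrollment}
    )


def _latent_load(
    profile: CalendarProfile, consult: pd.Series, cfg: SimConfig
) -> np.ndarray:
    """Per-month latent load driving lexicon mixture weights.

    load_t = season_gain * standardized seasonal + z_{t+lag}, where z is the
    standardized stochastic residual of the consultation series (rate minus
    its seasonal-plus-trend mean structure).  Months whose lagged partner
    falls outside the consultation range get a zero stochastic term.
    """
    if cfg.lag < 0:
        raise ValueError("lag must be non-negative")
    if cfg.lag >= cfg.n_months:
        raise ValueError("lag must be smaller than the number of months")
    seas = profile.seasonal_load
    s_sd = seas.std()
    s_std = seas / s_sd if s_sd > 0 else np.zeros_like(seas)

    resid = consult.to_numpy() - (
        consult.to_numpy().mean() + seas - seas.mean()
    )
    # remove linear trend from the residual proxy
    t = np.arange(len(resid), dtype=float)
    resid = resid - np.polyval(np.polyfit(t, resid, 1), t)
    r_sd = resid.std()
    z = resid / r_sd if r_sd > 0 else np.zeros_like(resid)

    z_lagged = np.zeros(cfg.n_months)
    for i in range(cfg.n_months):
        j = i + cfg.lag
        if j < len(z):
            z_lagged[i] = z[j]
    return cfg.season_gain * s_std + z_lagged


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _zipf_probs(vocab_size: int, s: float = 1.07) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    p = ranks ** (-s)
    return p / p.sum()


def gen_posts(
    profile: CalendarProfile, consult: pd.Series, cfg: SimConfig
) -> PostStream:
    """Generate the coupled post stream.

    Daily post counts are Poisson(posts_per_day).  Each token is drawn from
    a month-level mixture of the background vocabulary and the outcome
    lexicons; each outcome's mixture weight is
    ``2 * base_mix * sigmoid(link_slope * coupling * load_t)``, so
    ``coupling = 0`` freezes the weights at ``base_mix`` and decouples
    the stream from the consultation series entirely.
    """
    if cfg.coupling < 0:
        raise ValueError("coupling must be non-negative")
    load = _latent_load(profile, consult, cfg)
    # soft slope keeps the link quasi-linear over typical loads, so the
    # lexicon prevalence tracks the consultation signal proportionally
    weights = 2.0 * cfg.base_mix * _sigmoid(cfg.link_slope * cfg.coupling * load)

    rng = _rng(cfg.seed, 2)
    bg_words = np.array([f"w{i:04d}" for i in range(cfg.background_vocab_size)])
    bg_p = _zipf_probs(cfg.background_vocab_size)
    lex_words = {o: np.array(cfg.lexicons[o]) for o in cfg.lexicons}
    outcomes = list(cfg.lexicons)
    n_authors = max(2, int(cfg.posts_per_day * cfg.n_months * 30.4 * 0.28))

    posts: list[Post] = []
    pid = 0
    for i, period in enumerate(profile.months):
        start = period.to_timestamp().to_pydatetime().replace(tzinfo=timezone.utc)
        n_days = period.days_in_month
        counts = rng.poisson(cfg.posts_per_day, size=n_days)
        n_posts = int(counts.sum())
        if n_posts == 0:
            continue
        w_lex = np.full(len(outcomes), weights[i])
        w_bg = max(1.0 - w_lex.sum(), 1e-9)
        mix = np.concatenate([w_lex, [w_bg]])
        mix = mix / mix.sum()

        lengths = np.maximum(
            rng.poisson(cfg.doc_len_mean, size=n_posts), cfg.doc_len_min
        )
        total = int(lengths.sum())
        cats = rng.choice(len(outcomes) + 1, size=total, p=mix)
        toks = np.empty(total, dtype=object)
        bg_mask = cats == len(outcomes)
        toks[bg_mask] = rng.choice(bg_words, size=int(bg_mask.sum()), p=bg_p)
        for k, o in enumerate(outcomes):
            m = cats == k
            if m.any():
                toks[m] = rng.choice(lex_words[o], size=int(m.sum()))

        day_of_post = np.repeat(np.arange(n_days), counts)
        secs = rng.integers(0, 86_400, size=n_posts)
        order = np.argsort(day_of_post * 86_400 + secs, kind="stable")
        bounds = np.concatenate([[0], np.cumsum(lengths)])
        authors = rng.integers(0, n_authors, size=n_posts)
        for j in order:
            text = " ".join(toks[bounds[j]:bounds[j + 1]])
            ts = start + timedelta(
                days=int(day_of_post[j]), seconds=int(secs[j])
            )
            posts.append(
                Post(f"p{pid + j:07d}", ts, f"u{authors[j]:05d}", text)
            )
        pid += n_posts
    return PostStream(posts)


def gen_training_corpora(cfg: SimConfig) -> TrainingCorpora:
    """Separable training corpora: lexicon-enriched positives per outcome,
    one shared low-lexicon negative corpus."""
    if cfg.n_pos <= 0 or cfg.n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    if cfg.p_pos <= cfg.p_neg:
        raise ValueError("corpora not separable as configured")
    for o, words in cfg.lexicons.items():
        if len(words) == 0:
            raise ValueError(f"empty lexicon for outcome {o!r}")

    rng = _rng(cfg.seed, 3)
    bg_words = np.array([f"w{i:04d}" for i in range(cfg.background_vocab_size)])
    bg_p = _zipf_probs(cfg.background_vocab_size)
    all_lex = np.concatenate([np.array(w) for w in cfg.lexicons.values()])

    def make_docs(n: int, p_lex: float, words: np.ndarray) -> list[str]:
        docs = []
        lengths = np.maximum(
            rng.poisson(cfg.train_doc_len_mean, size=n), cfg.doc_len_min
        )
        for L in lengths:
            is_lex = rng.random(L) < p_lex
            toks = np.where(
                is_lex,
                rng.choice(words, size=L),
                rng.choice(bg_words, size=L, p=bg_p),
            )
            docs.append(" ".join(toks))
        return docs

    positives = {
        o: make_docs(cfg.n_pos, cfg.p_pos, np.array(cfg.lexicons[o]))
        for o in cfg.lexicons
    }
    negatives = make_docs(cfg.n_neg, cfg.p_neg, all_lex)
    return TrainingCorpora(positives=positives, negatives=negatives)


def write_corpora(corpora: TrainingCorpora, out_dir: str | Path) -> None:
    """Write corpora as directories of plain-text files plus a manifest."""
    out = Path(out_dir)
    manifest: dict[str, dict] = {"outcomes": {}, "negatives": {}}
    neg_dir = out / "negatives"
    neg_dir.mkdir(parents=True, exist_ok=True)
    for i, doc in enumerate(corpora.negatives):
        (neg_dir / f"doc{i:05d}.txt").write_text(doc + "\n")
    manifest["negatives"] = {"dir": "negatives", "n_docs": len(corpora.negatives)}
    for o, docs in corpora.positives.items():
        d = out / o
        d.mkdir(parents=True, exist_ok=True)
        for i, doc in enumerate(docs):
            (d / f"doc{i:05d}.txt").write_text(doc + "\n")
        manifest["outcomes"][o] = {"dir": o, "n_docs": len(docs)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_corpus_dir(path: str | Path) -> list[str]:
    return [p.read_text().strip() for p in sorted(Path(path).glob("*.txt"))]


def simulate(cfg: SimConfig) -> tuple[CalendarProfile, pd.Series, PostStream, TrainingCorpora]:
    """Run all generators under one config (single fan-out of the seed)."""
    profile = make_calendar(
        cfg.n_months,
        seed=int(_rng(cfg.seed, 0).integers(2**31)),
        start_month=cfg.start_month,
        amplitude=cfg.seasonal_amplitude,
        trend_slope=cfg.trend_slope,
    )
    consult = gen_consultations(profile, cfg)
    posts = gen_posts(profile, consult, cfg)
    corpora = gen_training_corpora(cfg)
    return profile, consult, posts, corpora


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)
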