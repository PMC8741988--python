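"""Per-outcome n-gram SVM classifiers and monthly prevalence aggregation.

Each symptomatic outcome (depression, anxiety, stress, suicidal ideation,
psychosis) gets an independent binary linear SVM over unigram/bigram/
trigram counts, trained on a lexicon-enriched positive corpus against a
shared control corpus -- a transfer-classification setup: the model is
trained on one labeled corpus and applied to the campus post stream.
Posts are labeled 0/1 per outcome at the SVM's natural zero margin, and
labels are averaged per calendar month into prevalence series.
"""

from __future__ import annotations

import json
import pickle
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.model_selection import train_test_split
from sklearn.svm import LinearSVC

from campuspulse.synthetic_data import OUTCOMES, PostStream

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumerics, keep tokens of length >= 2."""
    return [t for t in _TOKEN_RE.split(text.lower()) if len(t) >= 2]


@dataclass(frozen=True)
class ClassifierConfig:
    max_n: int = 3
    min_df: int = 2           # drop n-grams seen in fewer documents
    sublinear: bool = False   # log(1 + count) feature scaling
    C: float = 1.0
    test_size: float = 0.2    # held-out fraction for the reported accuracy
    seed: int = 0


def extract_ngrams(tokens: list[str], max_n: int = 3) -> dict[str, int]:
    """All contiguous n-grams (n = 1..max_n) with counts; joined by '_'."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    out: dict[str, int] = {}
    for n in range(1, max_n + 1):
        for i in range(len(tokens) - n + 1):
            g = "_".join(tokens[i:i + n])
            out[g] = out.get(g, 0) + 1
    return out


@dataclass
class OutcomeClassifier:
    """Fitted linear max-margin model for one outcome."""

    outcome: str
    vectorizer: CountVectorizer
    svm: LinearSVC
    heldout_accuracy: float
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def _features(self, docs: list[str]) -> sparse.csr_matrix:
        X = self.vectorizer.transform(docs)
        if self.config.sublinear:
            X = X.copy()
            X.data = np.log1p(X.data)
        return X

    def decision_values(self, docs: list[str]) -> np.ndarray:
        return self.svm.decision_function(self._features(docs))

    def classify(self, docs: list[str]) -> np.ndarray:
        return (self.decision_values(docs) > 0).astype(int)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "OutcomeClassifier":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _identity(x: str) -> str:
    return x


def _make_vectorizer(cfg: ClassifierConfig) -> CountVectorizer:
    return CountVectorizer(
        tokenizer=tokenize,
        preprocessor=_identity,
        token_pattern=None,
        lowercase=False,
        ngram_range=(1, cfg.max_n),
        min_df=cfg.min_df,
    )


def train_classifier(
    positives: list[str],
    negatives: list[str],
    outcome: str,
    config: ClassifierConfig | None = None,
) -> OutcomeClassifier:
    """Fit the binary SVM for ``outcome`` and report held-out accuracy.

    The held-out split is stratified and seeded; the returned model is
    refit on all documents so downstream labeling uses every example.
    """
    cfg = config or ClassifierConfig()
    if not positives or not negatives:
        raise ValueError("both document classes must be non-empty")

    docs = list(positives) + list(negatives)
    y = np.concatenate([np.ones(len(positives), int), np.zeros(len(negatives), int)])

    vec = _make_vectorizer(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # token_pattern notice
        X = vec.fit_transform(docs)
    if X.shape[1] == 0:
        raise ValueError("vocabulary empty after pruning")
    if cfg.sublinear:
        X.data = np.log1p(X.data)

    idx = np.arange(len(docs))
    tr, te = train_test_split(
        idx, test_size=cfg.test_size, stratify=y, random_state=cfg.seed
    )
    svm = LinearSVC(C=cfg.C, random_state=cfg.seed)
    svm.fit(X[tr], y[tr])
    acc = float((svm.predict(X[te]) == y[te]).mean())

    svm_full = LinearSVC(C=cfg.C, random_state=cfg.seed)
    svm_full.fit(X, y)
    return OutcomeClassifier(outcome, vec, svm_full, acc, cfg)


def train_all(
    corpora, config: ClassifierConfig | None = None
) -> dict[str, OutcomeClassifier]:
    """Train one classifier per outcome from a ``TrainingCorpora``."""
    return {
        o: train_classifier(corpora.positives[o], corpora.negatives, o, config)
        for o in corpora.positives
    }


def label_posts(
    classifiers: dict[str, OutcomeClassifier] | OutcomeClassifier,
    posts: PostStream,
) -> pd.DataFrame:
    """Label every post with 0/1 per outcome.

    Returns a DataFrame indexed like the stream with columns
    ``id, month, text`` plus one integer column per outcome.
    """
    if isinstance(classifiers, OutcomeClassifier):
        classifiers = {classifiers.outcome: classifiers}
    records = {
        "id": [p.id for p in posts],
        "month": pd.PeriodIndex([p.month() for p in posts], freq="M"),
        "text": [p.text for p in posts],
    }
    df = pd.DataFrame(records)
    texts = df["text"].tolist()
    for o, clf in classifiers.items():
        df[o] = clf.classify(texts) if texts else np.array([], dtype=int)
    return df


def monthly_prevalence(
    labeled: pd.DataFrame,
    outcomes: tuple[str, ...] = OUTCOMES,
    months: pd.PeriodIndex | None = None,
) -> pd.DataFrame:
    """Per-month fraction of posts labeled 1, per outcome.

    Months inside the requested range with zero posts get NaN and a
    warning; interpolation is deferred to the series-building stage.
    """
    outcomes = tuple(o for o in outcomes if o in labeled.columns)
    grouped = labeled.groupby("month")[list(outcomes)].mean()
    if months is None:
        months = pd.period_range(grouped.index.min(), grouped.index.max(), freq="M")
    prev = grouped.reindex(months)
    empty = prev.index[prev.isna().all(axis=1)]
    if len(empty):
        warnings.warn(
            f"{len(empty)} month(s) with zero posts left missing: "
            f"{[str(m) for m in empty]}"
        )
    prev.index.name = "month"
    return prev


def write_labeled_jsonl(labeled: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in labeled.columns if c != "month"]
    with open(path, "w") as fh:
        for _, row in labeled.iterrows():
            rec = {c: (int(row[c]) if isinstance(row[c], (np.integer,)) else row[c])
                   for c in cols}
            rec["month"] = str(row["month"])
            fh.write(json.dumps(rec) + "\n")


def read_labeled_jsonl(path: str | Path) -> pd.DataFrame:
    rows = [json.loads(line) for line in open(path)]
    df = pd.DataFrame(rows)
    df["month"] = pd.PeriodIndex(df["month"], freq="M")
    return df


def load_labeled_corpora(pos_dir: str | Path, neg_dir: str | Path) -> tuple[list[str], list[str]]:
    """Loader for user-supplied labeled corpora (directories of .txt files)."""
    from campuspulse.synthetic_data import read_corpus_dir

    return read_corpus_dir(pos_dir), read_corpus_dir(neg_dir)
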