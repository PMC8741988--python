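"""Language characterization of high- vs low-consultation months.

Months are split at the median normalized consultation rate into Hi-MHC
and Lo-MHC groups (MHC = mental-health consultations), and the posts of
the two groups are contrasted in two ways:

* **SAGE** (Sparse Additive Generative Model): the target group's term
  distribution is modeled as ``p(w) | exp(m_w + eta_w)`` where ``m`` is
  the background log-frequency and ``eta`` a sparse per-term deviation;
  terms with the largest positive (negative) ``eta`` are the n-grams most
  characteristic of the target (background) group.  The sparsity penalty
  is self-tuned by iterative re-estimation of per-term penalty weights,
  which trades off frequent against rare terms.

* **Lexicon profiling**: per-document percentages of tokens matching each
  category of a LIWC-dialect ``.dic`` dictionary, compared across groups
  with Welch t-tests under Benjamini-Yekutieli FDR correction (valid
  under arbitrary dependence; plain Benjamini-Hochberg available).

The LIWC dictionary itself is proprietary; a small open demonstration
lexicon built from the synthetic outcome word lists ships with the
package, and any user-supplied ``.dic`` file is accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax
from sklearn.feature_extraction.text import CountVectorizer
from statsmodels.stats.multitest import multipletests

from campuspulse.corpus_classifiers import _identity, tokenize
from campuspulse.synthetic_data import DEFAULT_LEXICONS


# ---------------------------------------------------------------------------
# median split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MedianSplit:
    hi_months: tuple
    lo_months: tuple
    threshold: float


def median_split(rate: pd.Series) -> MedianSplit:
    """Split months at the median rate; ties alternate to balance sizes."""
    if len(rate) < 4:
        raise ValueError("need at least 4 months for a median split")
    x = rate.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate split: all months have equal rate")
    med = float(np.median(x))
    hi = [m for m, v in rate.items() if v > med]
    lo = [m for m, v in rate.items() if v < med]
    for m in rate.index[rate.to_numpy() == med]:
        if len(hi) <= len(lo):
            hi.append(m)
        else:
            lo.append(m)
    return MedianSplit(tuple(sorted(hi)), tuple(sorted(lo)), med)


def split_documents(
    labeled: pd.DataFrame, split: MedianSplit
) -> tuple[list[str], list[str]]:
    """Posts of Hi-MHC months and of Lo-MHC months, as text lists."""
    hi = labeled.loc[labeled["month"].isin(split.hi_months), "text"].tolist()
    lo = labeled.loc[labeled["month"].isin(split.lo_months), "text"].tolist()
    return hi, lo


# ---------------------------------------------------------------------------
# SAGE
# ---------------------------------------------------------------------------

@dataclass
class SageModel:
    vocabulary: list[str]
    m: np.ndarray          # background log-probabilities, logsumexp(m) == 0
    eta: np.ndarray        # gauged so exp(m + eta) is itself a distribution
    reg: float
    penalty_weights: np.ndarray
    n_iter: int
    converged: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.vocabulary, "eta": self.eta, "m": self.m}
        ).sort_values("eta", ascending=False, ignore_index=True)


def _ngram_counts(
    docs: list[str], max_n: int, min_df: int, max_features: int | None,
    vocabulary=None,
):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vec = CountVectorizer(
            tokenizer=tokenize,
            preprocessor=_identity,
            token_pattern=None,
            lowercase=False,
            ngram_range=(1, max_n),
            min_df=min_df,
            max_features=max_features,
            vocabulary=vocabulary,
        )
        X = vec.fit_transform(docs)
    terms = vec.get_feature_names_out()
    return np.asarray(X.sum(axis=0)).ravel().astype(float), list(terms), vec


def sage_objective(
    eta: np.ndarray,
    counts: np.ndarray,
    m: np.ndarray,
    reg: float,
    eps: float = 1e-6,
) -> float:
    """Penalized log-likelihood maximized by SAGE (shift-invariant).

    Multinomial likelihood of the (smoothed) target counts under
    ``softmax(m + eta)`` minus ``reg * sum sqrt(eta_gauged^2 + eps^2)``,
    a smoothed-L1 sparsity penalty applied in the gauge where
    ``logsumexp(m + eta) = 0``.
    """
    L = logsumexp(m + eta)
    eta_g = eta - L
    ll = float(counts @ (m + eta)) - counts.sum() * L
    pen = reg * float(np.sum(np.sqrt(eta_g**2 + eps**2)))
    return ll - pen


def fit_sage(
    target_docs: list[str],
    background_docs: list[str],
    max_n: int = 3,
    reg: float = 10.0,
    smoothing: float = 0.1,
    min_df: int = 1,
    max_features: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    eps: float = 1e-6,
    zero_sum: bool = False,
) -> SageModel:
    """Fit SAGE deviations of the target corpus against the background.

    The smoothed-L1 penalty is maximized by majorize-minimize: each outer
    iteration freezes per-term quadratic penalty weights
    ``reg / sqrt(eta_w^2 + eps^2)`` (the self-tuning step, which shrinks
    common terms less than rare ones) and solves the smooth inner problem
    by L-BFGS; convergence when ``max |delta eta| < tol``.
    """
    if not target_docs or not background_docs:
        raise ValueError("both corpora must be non-empty")
    _, vocab, _ = _ngram_counts(
        list(target_docs) + list(background_docs), max_n, min_df, max_features
    )
    if len(vocab) == 0:
        raise ValueError("shared vocabulary empty")
    c_bg, _, _ = _ngram_counts(background_docs, max_n, 1, None, vocabulary=vocab)
    c_tg_raw, _, _ = _ngram_counts(target_docs, max_n, 1, None, vocabulary=vocab)
    c_bg = c_bg + smoothing
    c_tg = c_tg_raw + smoothing
    m = np.log(c_bg) - np.log(c_bg.sum())
    N = c_tg.sum()

    eta = np.zeros(len(vocab))
    lam = np.full(len(vocab), reg / eps)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        lam = reg / np.sqrt(eta**2 + eps**2)

        def neg_obj(e):
            L = logsumexp(m + e)
            p = softmax(m + e)
            e_g = e - L
            val = -(c_tg @ (m + e) - N * L) + 0.5 * float(lam @ e_g**2)
            grad = -(c_tg - N * p) + lam * e_g - p * float(lam @ e_g)
            return val, grad

        res = minimize(
            neg_obj, eta, jac=True, method="L-BFGS-B",
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-10},
        )
        new_eta = res.x - logsumexp(m + res.x)  # fix the gauge
        delta = float(np.max(np.abs(new_eta - eta)))
        eta = new_eta
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"SAGE did not converge in {max_iter} iterations "
            f"(last max |delta eta| = {delta:.2e})"
        )

    # final polish on the exact smoothed-L1 objective (MM converges
    # linearly and can stall a hair short of the optimum)
    def neg_exact(e):
        L = logsumexp(m + e)
        p = softmax(m + e)
        e_g = e - L
        root = np.sqrt(e_g**2 + eps**2)
        val = -(c_tg @ (m + e) - N * L) + reg * float(root.sum())
        pen_grad = reg * e_g / root
        grad = -(c_tg - N * p) + pen_grad - p * float(pen_grad.sum())
        return val, grad

    res = minimize(
        neg_exact, eta, jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
    )
    eta = res.x - logsumexp(m + res.x)
    if zero_sum:
        p0 = np.exp(m)
        eta = eta - float(p0 @ eta) / p0.sum()
    return SageModel(
        vocabulary=vocab,
        m=m,
        eta=eta,
        reg=reg,
        penalty_weights=lam,
        n_iter=n_iter,
        converged=converged,
    )


def top_salient(model: SageModel, k: int, direction: str = "positive") -> list[str]:
    """k terms with the largest (positive) or smallest (negative) eta.

    Ties break toward higher background frequency, then lexicographic.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    if k > len(model.vocabulary):
        warnings.warn("k exceeds vocabulary size; returning all terms")
        k = len(model.vocabulary)
    sign = 1.0 if direction == "positive" else -1.0
    order = sorted(
        range(len(model.vocabulary)),
        key=lambda i: (-sign * model.eta[i], -model.m[i], model.vocabulary[i]),
    )
    return [model.vocabulary[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# lexicon profiling
# ---------------------------------------------------------------------------

@dataclass
class CategoryLexicon:
    """Psycholinguistic categories mapped to word patterns.

    A pattern is an exact word or a prefix wildcard ``stem*`` (the ``*``
    only terminal, matching any token beginning with ``stem``).
    """

    categories: dict[str, list[str]]

    def __post_init__(self):
        for name, patterns in self.categories.items():
            if not patterns:
                raise ValueError(f"category {name!r} has no patterns")
            for p in patterns:
                if "*" in p[:-1]:
                    raise ValueError(
                        f"wildcard must be terminal in pattern {p!r}"
                    )

    def matchers(self) -> dict[str, tuple[set, tuple[str, ...]]]:
        out = {}
        for name, patterns in self.categories.items():
            exact = {p for p in patterns if not p.endswith("*")}
            prefixes = tuple(p[:-1] for p in patterns if p.endswith("*"))
            out[name] = (exact, prefixes)
        return out


def parse_dic(path: str | Path) -> CategoryLexicon:
    """Read a LIWC-dialect ``.dic`` file.

    Layout: a ``%``-delimited header mapping numeric IDs to category
    names, then one word (or ``stem*``) per line followed by the IDs of
    the categories it belongs to.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "%":
        raise ValueError("missing '%' header block")
    id_to_name: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].strip() != "%":
        parts = lines[i].split()
        if len(parts) >= 2:
            id_to_name[parts[0]] = parts[1]
        i += 1
    if i == len(lines):
        raise ValueError("unterminated '%' header block")
    categories: dict[str, list[str]] = {name: [] for name in id_to_name.values()}
    for line in lines[i + 1:]:
        parts = line.split()
        if not parts:
            continue
        word, ids = parts[0], parts[1:]
        for cid in ids:
            if cid in id_to_name:
                categories[id_to_name[cid]].append(word)
    return CategoryLexicon({k: v for k, v in categories.items() if v})


def demo_lexicon() -> CategoryLexicon:
    """Small open demonstration lexicon over the synthetic vocabulary."""
    cats = {name: list(words) for name, words in DEFAULT_LEXICONS.items()}
    cats["background"] = ["w*"]
    return CategoryLexicon(cats)


def write_dic(lexicon: CategoryLexicon, path: str | Path) -> None:
    """Write a lexicon in the ``.dic`` dialect."""
    names = list(lexicon.categories)
    with open(path, "w") as fh:
        fh.write("%\n")
        for i, name in enumerate(names, start=1):
            fh.write(f"{i}\t{name}\n")
        fh.write("%\n")
        word_ids: dict[str, list[int]] = {}
        for i, name in enumerate(names, start=1):
            for w in lexicon.categories[name]:
                word_ids.setdefault(w, []).append(i)
        for w in sorted(word_ids):
            ids = "\t".join(str(i) for i in word_ids[w])
            fh.write(f"{w}\t{ids}\n")


def lexicon_profile(docs: list[str], lexicon: CategoryLexicon) -> pd.DataFrame:
    """Per-document percentage of tokens matching each category."""
    matchers = lexicon.matchers()
    names = list(matchers)
    out = np.zeros((len(docs), len(names)))
    warned = False
    for i, doc in enumerate(docs):
        toks = tokenize(doc)
        if not toks:
            if not warned:
                warnings.warn("empty document(s): all categories set to 0")
                warned = True
            continue
        for j, name in enumerate(names):
            exact, prefixes = matchers[name]
            hits = sum(
                1 for t in toks
                if t in exact or (prefixes and t.startswith(prefixes))
            )
            out[i, j] = 100.0 * hits / len(toks)
    return pd.DataFrame(out, columns=names)


def monthly_profiles(
    labeled: pd.DataFrame, months, lexicon: CategoryLexicon
) -> pd.DataFrame:
    """Per-month mean category percentages (the per-month analysis unit)."""
    rows = []
    for mth in months:
        docs = labeled.loc[labeled["month"] == mth, "text"].tolist()
        prof = lexicon_profile(docs, lexicon)
        rows.append(prof.mean(axis=0))
    return pd.DataFrame(rows, index=pd.PeriodIndex(months, freq="M"))


def compare_categories(
    hi_profiles: pd.DataFrame,
    lo_profiles: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "fdr_by",
) -> pd.DataFrame:
    """Welch t-test per category with FDR correction across categories.

    Positive t means the category is more prevalent in Hi-MHC months.
    ``method`` is a statsmodels ``multipletests`` method name
    (``fdr_by`` default; ``fdr_bh`` for the independence variant).
    """
    if len(hi_profiles) < 2 or len(lo_profiles) < 2:
        raise ValueError("need at least 2 documents per group")
    cats = [c for c in hi_profiles.columns if c in lo_profiles.columns]
    rows = []
    for c in cats:
        a = hi_profiles[c].to_numpy(dtype=float)
        b = lo_profiles[c].to_numpy(dtype=float)
        if a.std() == 0 and b.std() == 0:
            t_stat, p = (np.nan, np.nan) if a.mean() != b.mean() else (np.nan, np.nan)
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((c, a.mean(), b.mean(), t_stat, p))
    df = pd.DataFrame(
        rows, columns=["category", "mean_hi", "mean_lo", "t", "p_raw"]
    )
    df["p_adj"] = np.nan
    df["significant"] = False
    ok = df["p_raw"].notna()
    if ok.any():
        rej, p_adj, *_ = multipletests(
            df.loc[ok, "p_raw"], alpha=alpha, method=method
        )
        df.loc[ok, "p_adj"] = p_adj
        df.loc[ok, "significant"] = rej
    return df
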