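"""Note-categorization baselines: bag-of-words, small CNN, and an ensemble.

These are desk-scale statistical/ML comparators for the rule-based pipeline
on the binary "documented PROM use" task:

* ``bow`` — an L2-regularized logistic regression over unigram+bigram counts;
* ``cnn`` — a token-embedding model with one 1-D convolution layer, global
  max-pooling and a logistic head, trained by Adam on manual gradients
  (numpy only; sized for corpora of hundreds of documents);
* ``ensemble`` — a convex combination of the two scores with the mixing
  weight tuned on the development set.

All three expose ``scores(texts) -> [0,1]`` probabilities and a 0.5 decision
threshold, and are deterministic given the training seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import spmatrix
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from promdoc.evaluation import LabeledNote, MatchCounts, note_confusion, precision_recall_f

__all__ = [
    "BowFeatures",
    "featurize_bow",
    "BowModel",
    "CnnModel",
    "EnsembleModel",
    "train_model",
    "predict_proba",
]

_TOKEN_PATTERN = r"\S+"  # whitespace tokenization, matching the corpus length measure


@dataclass(frozen=True)
class BowFeatures:
    """Deterministic n-gram count features with a sorted vocabulary."""

    vocabulary: dict[str, int]
    counts: spmatrix
    ngram_range: tuple[int, int]


def _make_vectorizer(ngram_range: tuple[int, int], min_count: int) -> CountVectorizer:
    return CountVectorizer(
        token_pattern=_TOKEN_PATTERN,
        lowercase=True,
        ngram_range=ngram_range,
        min_df=min_count,
    )


def featurize_bow(
    texts: Sequence[str],
    ngram_range: tuple[int, int] = (1, 2),
    min_count: int = 1,
) -> BowFeatures:
    """Count n-gram features over whitespace tokens.

    The vocabulary is lexicographically sorted so two runs over the same
    corpus produce identical feature matrices.
    """
    if not texts or all(not t.split() for t in texts):
        raise ValueError("no tokens in input texts")
    vec = _make_vectorizer(ngram_range, min_count)
    counts = vec.fit_transform(texts)
    vocab_sorted = sorted(vec.vocabulary_)
    index = {term: i for i, term in enumerate(vocab_sorted)}
    perm = np.array([vec.vocabulary_[t] for t in vocab_sorted])
    return BowFeatures(vocabulary=index, counts=counts[:, perm], ngram_range=ngram_range)


@dataclass
class BowModel:
    """Linear bag-of-words classifier (logistic regression on n-gram counts)."""

    ngram_range: tuple[int, int] = (1, 2)
    min_count: int = 1
    C: float = 1.0
    threshold: float = 0.5
    _vec: CountVectorizer | None = field(default=None, repr=False)
    _clf: LogisticRegression | None = field(default=None, repr=False)

    kind: str = "bow"

    def fit(self, train: Sequence[LabeledNote], seed: int = 0) -> "BowModel":
        y = np.array([t.label for t in train], dtype=int)
        if len(set(y.tolist())) < 2:
            raise ValueError("training data contain a single class")
        self._vec = _make_vectorizer(self.ngram_range, self.min_count)
        x = self._vec.fit_transform([t.text for t in train])
        self._clf = LogisticRegression(C=self.C, max_iter=2000, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._clf.fit(x, y)
        return self

    def scores(self, texts: Sequence[str]) -> np.ndarray:
        if self._clf is None or self._vec is None:
            raise RuntimeError("model not trained")
        return self._clf.predict_proba(self._vec.transform(texts))[:, 1]


def _tokenize(text: str, max_len: int) -> list[str]:
    return text.lower().split()[:max_len]


@dataclass
class CnnModel:
    """Token-embedding + 1-D convolution + max-pool + logistic head.

    A deliberately small architecture trained with Adam on manual numpy
    gradients; documents are truncated at ``max_len`` tokens.  Out-of-
    vocabulary tokens map to a shared index 0.
    """

    embed_dim: int = 16
    n_filters: int = 24
    window: int = 3
    max_len: int = 300
    epochs: int = 15
    lr: float = 1e-3
    l2: float = 1e-4
    threshold: float = 0.5
    kind: str = "cnn"

    _vocab: dict[str, int] | None = field(default=None, repr=False)
    _params: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def fit(self, train: Sequence[LabeledNote], seed: int = 0) -> "CnnModel":
        y = np.array([t.label for t in train], dtype=float)
        if len(set(y.tolist())) < 2:
            raise ValueError("training data contain a single class")
        rng = np.random.default_rng(seed)
        docs = [_tokenize(t.text, self.max_len) for t in train]
        vocab: dict[str, int] = {"<unk>": 0}
        for d in docs:
            for tok in d:
                vocab.setdefault(tok, len(vocab))
        self._vocab = vocab
        d_, f_, w_ = self.embed_dim, self.n_filters, self.window
        p = {
            "E": rng.normal(0, 0.1, (len(vocab), d_)),
            "W": rng.normal(0, np.sqrt(2.0 / (w_ * d_)), (w_ * d_, f_)),
            "bW": np.zeros(f_),
            "v": rng.normal(0, 0.1, f_),
            "bv": np.zeros(1),
        }
        m = {k: np.zeros_like(v) for k, v in p.items()}
        u = {k: np.zeros_like(v) for k, v in p.items()}
        ids = [np.array([vocab[t] for t in doc], dtype=int) for doc in docs]
        step = 0
        b1, b2, eps = 0.9, 0.999, 1e-8
        for _ in range(self.epochs):
            for i in rng.permutation(len(ids)):
                step += 1
                g = self._grad(p, ids[i], y[i])
                for k in p:
                    g[k] += self.l2 * p[k]
                    m[k] = b1 * m[k] + (1 - b1) * g[k]
                    u[k] = b2 * u[k] + (1 - b2) * g[k] ** 2
                    mh = m[k] / (1 - b1**step)
                    uh = u[k] / (1 - b2**step)
                    p[k] -= self.lr * mh / (np.sqrt(uh) + eps)
        self._params = p
        return self

    def _forward(self, p: dict[str, np.ndarray], ids: np.ndarray):
        w_ = self.window
        if ids.size < w_:  # pad short/empty docs with <unk>
            ids = np.concatenate([ids, np.zeros(w_ - ids.size, dtype=int)])
        emb = p["E"][ids]  # L x d
        L = ids.size - w_ + 1
        windows = np.stack([emb[i : i + w_].ravel() for i in range(L)])  # L x (w*d)
        z = windows @ p["W"] + p["bW"]  # L x f
        h = np.maximum(z, 0.0)
        pooled = h.max(axis=0)
        argmax = h.argmax(axis=0)
        logit = pooled @ p["v"] + p["bv"][0]
        prob = 1.0 / (1.0 + np.exp(-logit))
        return ids, windows, z, pooled, argmax, prob

    def _grad(self, p: dict[str, np.ndarray], ids: np.ndarray, y: float):
        ids, windows, z, pooled, argmax, prob = self._forward(p, ids)
        d_out = prob - y  # BCE with sigmoid
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["v"] = d_out * pooled
        g["bv"] = np.array([d_out])
        d_pool = d_out * p["v"]  # f
        w_ = self.window
        for f_i, pos in enumerate(argmax):
            if z[pos, f_i] <= 0:
                continue
            g["W"][:, f_i] += d_pool[f_i] * windows[pos]
            g["bW"][f_i] += d_pool[f_i]
            d_win = d_pool[f_i] * p["W"][:, f_i]  # w*d
            for off in range(w_):
                tok = ids[pos + off]
                g["E"][tok] += d_win[off * self.embed_dim : (off + 1) * self.embed_dim]
        return g

    def scores(self, texts: Sequence[str]) -> np.ndarray:
        if self._params is None or self._vocab is None:
            raise RuntimeError("model not trained")
        out = np.empty(len(texts))
        for i, t in enumerate(texts):
            ids = np.array(
                [self._vocab.get(tok, 0) for tok in _tokenize(t, self.max_len)],
                dtype=int,
            )
            out[i] = self._forward(self._params, ids)[-1]
        return out


@dataclass
class EnsembleModel:
    """Convex score combination of the linear BOW and token-embedding models.

    The mixing weight alpha (on the BOW score) is tuned on the development
    set by maximizing F-measure over a coarse grid.
    """

    bow: BowModel
    cnn: CnnModel
    alpha: float = 0.5
    threshold: float = 0.5
    kind: str = "ensemble"

    def tune_alpha(self, dev: Sequence[LabeledNote]) -> "EnsembleModel":
        if not dev:
            return self
        texts = [d.text for d in dev]
        gold = {d.visit_id: d.label for d in dev}
        sb, sc = self.bow.scores(texts), self.cnn.scores(texts)
        best, best_f = self.alpha, -1.0
        for a in np.linspace(0.0, 1.0, 11):
            s = a * sb + (1 - a) * sc
            pred = {d.visit_id: bool(si >= self.threshold) for d, si in zip(dev, s)}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = precision_recall_f(note_confusion(gold, pred)).f_measure
            if f > best_f:
                best, best_f = float(a), f
        self.alpha = best
        return self

    def scores(self, texts: Sequence[str]) -> np.ndarray:
        return self.alpha * self.bow.scores(texts) + (1 - self.alpha) * self.cnn.scores(texts)


def train_model(
    kind: str,
    train_set: Sequence[LabeledNote],
    dev_set: Sequence[LabeledNote],
    hyperparams: dict | None = None,
    seed: int = 0,
):
    """Train one of the three baselines; deterministic given ``seed``.

    ``hyperparams`` override the dataclass defaults of the chosen model.
    The development set is used only where the architecture calls for it
    (ensemble weight tuning); the linear and CNN models ignore it.
    """
    hp = hyperparams or {}
    if kind == "bow":
        return BowModel(**hp).fit(train_set, seed)
    if kind == "cnn":
        return CnnModel(**hp).fit(train_set, seed)
    if kind == "ensemble":
        bow = BowModel(**hp.get("bow", {})).fit(train_set, seed)
        cnn = CnnModel(**hp.get("cnn", {})).fit(train_set, seed + 1)
        return EnsembleModel(bow=bow, cnn=cnn).tune_alpha(dev_set)
    raise ValueError(f"unknown model kind: {kind!r}")


def predict_proba(model, text: str) -> float:
    """Probability that a single note documents PROM use."""
    return float(model.scores([text])[0])
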