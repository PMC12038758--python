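"""Scoring for the three matching tasks, agreement, and cross-validation.

Span-level output is scored two ways against human annotation: strict
boundaries (start, end and measure attribute all equal) and soft boundaries
(character ranges overlap by at least one position and the measure attribute
matches).  Casting both annotation and model output to a per-note binary
label gives the third task, note categorization, scored with a standard 2x2
confusion matrix plus AUC-ROC for probabilistic models.

Cross-validation comes in the two flavours used for the note-categorization
baselines: Monte Carlo (fresh random 75/15/10 splits each cycle) and
repeated k-fold (per repeat, a k-way partition; each cycle takes 1 fold as
test, 1 as development and the rest as training), with or without label
stratification.  Per-cycle metrics are summarized as mean and 95% CI.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from promdoc.matcher import PromSpan

__all__ = [
    "MatchCounts",
    "EvalMetrics",
    "CvSummary",
    "AgreementResult",
    "LabeledNote",
    "pair_spans_strict",
    "pair_spans_soft",
    "note_confusion",
    "precision_recall_f",
    "f_from_pr",
    "auc_roc",
    "interannotator_agreement",
    "monte_carlo_cv",
    "repeated_kfold_cv",
    "make_folds",
    "summarize_cycles",
]


@dataclass(frozen=True)
class MatchCounts:
    """TP/FP/FN counts; TN only exists for the note-level task."""

    tp: int
    fp: int
    fn: int
    tn: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be nonnegative")


@dataclass(frozen=True)
class EvalMetrics:
    """Percent-scale metrics (0-100), one-decimal reporting convention."""

    precision: float
    recall: float
    f_measure: float
    accuracy: float | None = None
    auc_roc: float | None = None


@dataclass(frozen=True)
class AgreementResult:
    pair: tuple[str, str]
    iaa_percent: float
    n_notes: int


@dataclass(frozen=True)
class LabeledNote:
    """A (text, binary label) item for the note-categorization task."""

    visit_id: str
    text: str
    label: bool


def pair_spans_strict(
    gold: Sequence[PromSpan], pred: Sequence[PromSpan]
) -> MatchCounts:
    """Perfect-overlap pairing: start, end and prom_id must all be equal."""
    gold_keys = Counter((s.start, s.end, s.prom_id) for s in gold)
    pred_keys = Counter((s.start, s.end, s.prom_id) for s in pred)
    tp = sum((gold_keys & pred_keys).values())
    return MatchCounts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


def pair_spans_soft(
    gold: Sequence[PromSpan], pred: Sequence[PromSpan]
) -> MatchCounts:
    """Relaxed-boundary pairing: ranges overlap >=1 character, prom_id equal.

    The one-to-one pairing maximizes the number of matches (maximum bipartite
    matching), with total overlap length as the tie-break among equally large
    pairings — solved as an assignment problem, so the count equals the
    brute-force optimum on any instance.
    """
    if not gold or not pred:
        return MatchCounts(tp=0, fp=len(pred), fn=len(gold))
    # score = BIG for any admissible pair (cardinality term) + overlap tie-break
    big = 10 ** 9
    score = np.zeros((len(gold), len(pred)))
    for i, g in enumerate(gold):
        for j, p in enumerate(pred):
            if g.prom_id == p.prom_id:
                ov = g.overlap_len(p)
                if ov > 0:
                    score[i, j] = big + ov
    rows, cols = linear_sum_assignment(score, maximize=True)
    tp = int(sum(score[i, j] > 0 for i, j in zip(rows, cols)))
    return MatchCounts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


def note_confusion(
    gold_labels: Mapping[str, bool], pred_labels: Mapping[str, bool]
) -> MatchCounts:
    """2x2 confusion counts over an identical set of note ids."""
    if set(gold_labels) != set(pred_labels):
        raise ValueError("gold and predicted label id sets differ")
    tp = fp = fn = tn = 0
    for vid, g in gold_labels.items():
        p = pred_labels[vid]
        if g and p:
            tp += 1
        elif not g and p:
            fp += 1
        elif g and not p:
            fn += 1
        else:
            tn += 1
    return MatchCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def precision_recall_f(counts: MatchCounts) -> EvalMetrics:
    """Precision, recall, F-measure (and accuracy when TN exists), percent scale.

    Zero denominators (a corpus with no predicted or no gold positives) are
    reported as 0 with a warning rather than raising, so degenerate folds
    inside cross-validation never abort a run.
    """
    if counts.tp + counts.fp == 0:
        warnings.warn("no predicted positives: precision defined as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = 100.0 * counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        warnings.warn("no gold positives: recall defined as 0", stacklevel=2)
        recall = 0.0
    else:
        recall = 100.0 * counts.tp / (counts.tp + counts.fn)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    accuracy = None
    if counts.tn is not None:
        total = counts.tp + counts.fp + counts.fn + counts.tn
        accuracy = 100.0 * (counts.tp + counts.tn) / total if total else 0.0
    return EvalMetrics(precision=precision, recall=recall, f_measure=f, accuracy=accuracy)


def f_from_pr(precision: float, recall: float) -> float:
    """F-measure from percent-scale precision and recall, to one decimal.

    The harmonic mean 2PR/(P+R); with both inputs zero the F is 0 by the
    same convention as :func:`precision_recall_f`.
    """
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    if precision + recall == 0:
        warnings.warn("precision and recall both zero: F defined as 0", stacklevel=2)
        return 0.0
    return round(2 * precision * recall / (precision + recall), 1)


def auc_roc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC-ROC on the percent scale.

    Equals the Mann-Whitney concordance probability that a random positive
    outscores a random negative, ties counted half.  Only defined for models
    with a probability-score output; both classes must be present.
    """
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("AUC-ROC undefined: only one class present")
    return 100.0 * float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def interannotator_agreement(
    a_spans: Mapping[str, Sequence[PromSpan]],
    b_spans: Mapping[str, Sequence[PromSpan]],
    pair: tuple[str, str] = ("annotator_a", "annotator_b"),
) -> AgreementResult:
    """Span-level agreement between two annotators over a shared note set.

    Computed as the F-measure of soft-boundary, attribute-constrained pairing
    pooled over notes, treating annotator A as reference.  F is symmetric in
    its arguments (swapping annotators swaps precision and recall only), so
    the statistic does not depend on who is called the reference.
    """
    if set(a_spans) != set(b_spans):
        raise ValueError("annotators cover different note sets")
    if not a_spans:
        raise ValueError("empty note set")
    tp = fp = fn = 0
    for vid in a_spans:
        c = pair_spans_soft(list(a_spans[vid]), list(b_spans[vid]))
        tp, fp, fn = tp + c.tp, fp + c.fp, fn + c.fn
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = precision_recall_f(MatchCounts(tp=tp, fp=fp, fn=fn))
    return AgreementResult(pair=pair, iaa_percent=round(m.f_measure, 1), n_notes=len(a_spans))


# ---------------------------------------------------------------------------
# cross-validation


class ScoringModel(Protocol):
    """What a trained note classifier must expose to the CV loop."""

    def scores(self, texts: Sequence[str]) -> np.ndarray: ...

    threshold: float


#: trainer(train_items, dev_items, seed) -> fitted model
Trainer = Callable[[Sequence[LabeledNote], Sequence[LabeledNote], int], ScoringModel]


@dataclass(frozen=True)
class CvSummary:
    scheme: str  # monte_carlo | kfold | stratified_kfold
    cycles: int
    per_cycle: Mapping[str, tuple[float, ...]]
    mean: Mapping[str, float]
    ci95: Mapping[str, tuple[float, float]]
    seed: int | None = None
    per_cycle_seeds: tuple[int, ...] = field(default=())


def summarize_cycles(per_cycle: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Mean and normal-approximation 95% CI (mean +- 1.96 sd/sqrt(n))."""
    vals = np.asarray(per_cycle, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 cycle values")
    mean = float(vals.mean())
    half = 1.96 * float(vals.std(ddof=1)) / np.sqrt(vals.size)
    return mean, (mean - half, mean + half)


def _cycle_metrics(
    model: ScoringModel, test: Sequence[LabeledNote]
) -> dict[str, float]:
    texts = [t.text for t in test]
    y = [t.label for t in test]
    s = model.scores(texts)
    pred = {t.visit_id: bool(si >= model.threshold) for t, si in zip(test, s)}
    gold = {t.visit_id: t.label for t in test}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = precision_recall_f(note_confusion(gold, pred))
    out = {"precision": m.precision, "recall": m.recall, "f_measure": m.f_measure}
    if m.accuracy is not None:
        out["accuracy"] = m.accuracy
    if len(set(y)) == 2:
        out["auc_roc"] = auc_roc(s, y)
    return out


def _collect(scheme: str, rows: list[dict[str, float]], seed: int,
             cycle_seeds: list[int]) -> CvSummary:
    keys = sorted(set().union(*[set(r) for r in rows]))
    per_cycle = {k: tuple(r[k] for r in rows if k in r) for k in keys}
    mean: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    for k, vals in per_cycle.items():
        if len(vals) == 1:  # a single cycle has no spread to summarize
            mean[k], ci[k] = vals[0], (vals[0], vals[0])
        else:
            mean[k], ci[k] = summarize_cycles(vals)
    return CvSummary(
        scheme=scheme,
        cycles=len(rows),
        per_cycle=per_cycle,
        mean=mean,
        ci95=ci,
        seed=seed,
        per_cycle_seeds=tuple(cycle_seeds),
    )


def monte_carlo_cv(
    dataset: Sequence[LabeledNote],
    trainer: Trainer,
    cycles: int = 100,
    split: tuple[float, float, float] = (0.75, 0.15, 0.10),
    seed: int = 0,
) -> CvSummary:
    """Monte Carlo CV: each cycle draws a fresh random train/dev/test split.

    Defaults mirror the validation design: 100 cycles at 75/15/10.  One
    master seed expands to per-cycle seeds by a counter, so reruns with the
    same seed are bit-identical.
    """
    if len(dataset) < 20:
        raise ValueError("dataset too small for Monte Carlo CV (need >= 20)")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split must sum to 1, got {split}")
    n = len(dataset)
    n_train = int(round(split[0] * n))
    n_dev = int(round(split[1] * n))
    rows: list[dict[str, float]] = []
    cycle_seeds: list[int] = []
    for c in range(cycles):
        cseed = (seed * 100_003 + c) % (2**31)
        cycle_seeds.append(cseed)
        rng = np.random.default_rng(cseed)
        order = rng.permutation(n)
        tr = [dataset[i] for i in order[:n_train]]
        dv = [dataset[i] for i in order[n_train : n_train + n_dev]]
        te = [dataset[i] for i in order[n_train + n_dev :]]
        model = trainer(tr, dv, cseed)
        rows.append(_cycle_metrics(model, te))
    return _collect("monte_carlo", rows, seed, cycle_seeds)


def make_folds(
    labels: Sequence[bool], k: int, stratified: bool, seed: int
) -> list[np.ndarray]:
    """One k-way partition of item indices; label-stratified when requested
    (per-fold prevalence then stays within +-1 item of the global rate)."""
    y = np.asarray(labels, dtype=int)
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    return [test_idx for _, test_idx in splitter.split(np.zeros(len(y)), y)]


def repeated_kfold_cv(
    dataset: Sequence[LabeledNote],
    trainer: Trainer,
    k: int = 10,
    repeats: int = 10,
    stratified: bool = False,
    seed: int = 0,
) -> CvSummary:
    """Repeated k-fold CV with train/dev/test fold roles.

    Per repeat the data are partitioned into ``k`` folds (label-stratified
    when requested, preserving prevalence within +-1 item per fold).  Cycle
    ``i`` uses fold ``i`` as test, fold ``i+1 mod k`` as development and the
    remaining ``k-2`` folds as training — 8/1/1 at the k=10 default, for
    k x repeats = 100 cycles total.
    """
    if k < 3:
        raise ValueError("k must be >= 3 (train/dev/test roles)")
    if len(dataset) < k:
        raise ValueError("dataset smaller than k")
    y = [d.label for d in dataset]
    rows: list[dict[str, float]] = []
    cycle_seeds: list[int] = []
    for r in range(repeats):
        rseed = (seed * 100_003 + 7919 * r) % (2**31)
        folds = make_folds(y, k, stratified, rseed)
        for i in range(k):
            cseed = (rseed + i) % (2**31)
            cycle_seeds.append(cseed)
            test_idx = folds[i]
            dev_idx = folds[(i + 1) % k]
            train_idx = np.concatenate(
                [folds[j] for j in range(k) if j not in (i, (i + 1) % k)]
            )
            model = trainer(
                [dataset[j] for j in train_idx],
                [dataset[j] for j in dev_idx],
                cseed,
            )
            rows.append(_cycle_metrics(model, [dataset[j] for j in test_idx]))
    scheme = "stratified_kfold" if stratified else "kfold"
    return _collect(scheme, rows, seed, cycle_seeds)
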