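"""Matching-task scoring, agreement, AUC, and cross-validation accounting."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promdoc.evaluation import (
    LabeledNote,
    MatchCounts,
    auc_roc,
    f_from_pr,
    interannotator_agreement,
    make_folds,
    monte_carlo_cv,
    note_confusion,
    pair_spans_soft,
    pair_spans_strict,
    precision_recall_f,
    repeated_kfold_cv,
    summarize_cycles,
)
from promdoc.matcher import PromSpan


def span(start, end, prom_id="odi", source="human"):
    return PromSpan(start=start, end=end, surface="x" * (end - start), prom_id=prom_id, source=source)


class TestStrictPairing:
    def test_identity(self):
        gold = [span(0, 5), span(10, 20, "ndi")]
        c = pair_spans_strict(gold, gold)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_attribute_mismatch_counts_twice(self):
        c = pair_spans_strict([span(0, 5, "odi")], [span(0, 5, "ndi")])
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_one_character_shift_breaks_strict(self):
        c = pair_spans_strict([span(0, 5)], [span(1, 6)])
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)


def _brute_force_max_matching(gold, pred) -> int:
    """Exhaustive maximum bipartite matching on admissible (overlap+attribute) pairs."""
    edges = [
        (i, j)
        for i, g in enumerate(gold)
        for j, p in enumerate(pred)
        if g.prom_id == p.prom_id and g.overlap_len(p) > 0
    ]

    def best(used_g, used_p, remaining):
        if not remaining:
            return 0
        (i, j), rest = remaining[0], remaining[1:]
        skip = best(used_g, used_p, rest)
        if i in used_g or j in used_p:
            return skip
        take = 1 + best(used_g | {i}, used_p | {j}, rest)
        return max(skip, take)

    return best(frozenset(), frozenset(), edges)


def _random_spans(rng, max_n=6, n_proms=3):
    n = int(rng.integers(0, max_n + 1))
    out = []
    for _ in range(n):
        s = int(rng.integers(0, 80))
        e = s + int(rng.integers(1, 15))
        out.append(span(s, e, f"prom{int(rng.integers(0, n_proms))}"))
    return out


class TestSoftPairing:
    def test_containing_overlap(self):
        c = pair_spans_soft([span(10, 35)], [span(10, 38)])
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_disjoint_same_prom(self):
        c = pair_spans_soft([span(0, 5)], [span(10, 15)])
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_two_gold_one_pred(self):
        c = pair_spans_soft([span(0, 10), span(12, 20)], [span(5, 14)])
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_cross_assignment_found(self):
        # a greedy longest-overlap strategy would pair g1-p1 and strand g2;
        # optimal pairing matches both
        g1, g2 = span(3, 15), span(0, 4)
        p1, p2 = span(0, 10), span(12, 15)
        c = pair_spans_soft([g1, g2], [p1, p2])
        assert c.tp == 2

    def test_equals_brute_force_on_small_instances(self):
        rng = np.random.default_rng(202)
        for _ in range(400):
            gold = _random_spans(rng)
            pred = _random_spans(rng)
            c = pair_spans_soft(gold, pred)
            assert c.tp == _brute_force_max_matching(gold, pred)
            assert c.tp + c.fp == len(pred)
            assert c.tp + c.fn == len(gold)

    def test_relaxation_monotonicity(self):
        rng = np.random.default_rng(303)
        for _ in range(300):
            gold = _random_spans(rng)
            pred = _random_spans(rng)
            assert pair_spans_soft(gold, pred).tp >= pair_spans_strict(gold, pred).tp


class TestNoteConfusion:
    def test_all_equal(self):
        labels = {f"v{i}": i % 2 == 0 for i in range(10)}
        c = note_confusion(labels, labels)
        assert (c.fp, c.fn) == (0, 0)
        assert c.tp + c.tn == 10

    def test_all_false_positive(self):
        gold = {f"v{i}": False for i in range(5)}
        pred = {f"v{i}": True for i in range(5)}
        assert note_confusion(gold, pred).fp == 5

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            note_confusion({"a": True}, {"b": True})

    def test_random_labels_match_brute_tally(self):
        rng = np.random.default_rng(11)
        gold = {f"v{i}": bool(rng.integers(0, 2)) for i in range(200)}
        pred = {f"v{i}": bool(rng.integers(0, 2)) for i in range(200)}
        c = note_confusion(gold, pred)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for k in gold:
            key = ("t" if gold[k] == pred[k] else "f") + ("p" if pred[k] else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (
            tally["tp"], tally["fp"], tally["fn"], tally["tn"],
        )


class TestMetrics:
    def test_degenerate_counts_warn_and_zero(self):
        with pytest.warns(UserWarning):
            m = precision_recall_f(MatchCounts(tp=0, fp=0, fn=0))
        assert (m.precision, m.recall, m.f_measure) == (0.0, 0.0, 0.0)

    def test_closed_form(self):
        m = precision_recall_f(MatchCounts(tp=1, fp=1, fn=0))
        assert m.precision == 50.0
        assert m.recall == 100.0

    def test_accuracy_with_tn(self):
        m = precision_recall_f(MatchCounts(tp=3, fp=1, fn=1, tn=5))
        assert m.accuracy == 80.0

    def test_f_bounds_property(self):
        rng = np.random.default_rng(21)
        import warnings as w

        for _ in range(200):
            counts = MatchCounts(
                tp=int(rng.integers(0, 20)),
                fp=int(rng.integers(0, 20)),
                fn=int(rng.integers(0, 20)),
            )
            with w.catch_warnings():
                w.simplefilter("ignore")
                m = precision_recall_f(counts)
            assert min(m.precision, m.recall) - 1e-9 <= m.f_measure <= max(m.precision, m.recall) + 1e-9
            assert (m.f_measure == 0) == (counts.tp == 0)


class TestFFromPR:
    @pytest.mark.parametrize(
        "p,r,f",
        [
            (47.4, 58.0, 52.2),
            (81.1, 96.7, 88.2),
            (90.3, 99.5, 94.7),
            (75.0, 85.7, 80.0),
            (93.8, 71.4, 81.1),
            (86.4, 90.5, 88.4),
        ],
    )
    def test_published_style_rows(self, p, r, f):
        assert f_from_pr(p, r) == f

    @given(x=st.floats(min_value=0.1, max_value=100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_harmonic_mean_identity(self, x):
        assert f_from_pr(x, x) == pytest.approx(round(x, 1))

    def test_both_zero_warns(self):
        with pytest.warns(UserWarning):
            assert f_from_pr(0, 0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f_from_pr(101, 50)


def _concordance_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return 100.0 * wins / (len(pos) * len(neg))


class TestAucRoc:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 100.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(55)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000).astype(bool)
        assert abs(auc_roc(scores, labels) - 50.0) < 3.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.9], [True, True])

    def test_equals_all_pairs_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.random(n), 2)  # force ties
            assert auc_roc(scores, labels) == pytest.approx(
                _concordance_oracle(scores, labels)
            )


class TestIAA:
    def _spans(self):
        return {
            "n1": [span(0, 5), span(10, 20, "ndi")],
            "n2": [span(3, 9, "bpi")],
        }

    def test_identical_annotations(self):
        r = interannotator_agreement(self._spans(), self._spans())
        assert r.iaa_percent == 100.0
        assert r.n_notes == 2

    def test_empty_versus_nonempty(self):
        a = {"n1": [], "n2": []}
        b = self._spans()
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            r = interannotator_agreement(a, b)
        assert r.iaa_percent == 0.0

    def test_symmetry(self):
        a = self._spans()
        b = {
            "n1": [span(2, 7)],  # partial overlap with a's first span
            "n2": [],
        }
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            assert (
                interannotator_agreement(a, b).iaa_percent
                == interannotator_agreement(b, a).iaa_percent
            )

    def test_disjoint_note_sets_rejected(self):
        with pytest.raises(ValueError):
            interannotator_agreement({"n1": []}, {"n2": []})


def _keyword_dataset(n, seed, flip_labels=False):
    """Toy separable data: positives carry a deterministic keyword."""
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n):
        label = bool(rng.random() < 0.4)
        words = ["alpha", "beta", "gamma", "delta"]
        text = " ".join(rng.choice(words, size=20).tolist())
        if label:
            text += " zeta zeta"
        items.append(LabeledNote(visit_id=f"v{i}", text=text, label=label))
    if flip_labels:
        perm = rng.permutation(n)
        items = [
            LabeledNote(visit_id=it.visit_id, text=it.text, label=items[j].label)
            for it, j in zip(items, perm)
        ]
    return items


def _bow_trainer(train, dev, seed):
    from promdoc.classifiers import train_model

    return train_model("bow", train, dev, seed=seed)


class _ConstantPositive:
    threshold = 0.5

    def scores(self, texts):
        return np.ones(len(texts))


class TestMonteCarloCv:
    def test_constant_positive_trainer_gives_full_recall(self):
        data = _keyword_dataset(40, 1)
        summary = monte_carlo_cv(
            data, lambda tr, dv, s: _ConstantPositive(), cycles=1, seed=3
        )
        assert summary.cycles == 1
        assert summary.per_cycle["recall"][0] == 100.0

    def test_determinism_under_seed(self):
        data = _keyword_dataset(60, 2)
        a = monte_carlo_cv(data, _bow_trainer, cycles=5, seed=9)
        b = monte_carlo_cv(data, _bow_trainer, cycles=5, seed=9)
        assert a == b

    def test_separable_data_high_f(self):
        data = _keyword_dataset(150, 3)
        summary = monte_carlo_cv(data, _bow_trainer, cycles=20, seed=5)
        assert summary.cycles == 20
        assert summary.mean["f_measure"] >= 95.0

    def test_bad_split_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            monte_carlo_cv(_keyword_dataset(40, 1), _bow_trainer, split=(0.5, 0.1, 0.1))


class TestRepeatedKfoldCv:
    def test_every_item_tested_once_per_repeat(self):
        folds = make_folds([i % 5 == 0 for i in range(100)], k=10, stratified=False, seed=1)
        seen = np.concatenate(folds)
        assert sorted(seen.tolist()) == list(range(100))
        assert all(len(f) == 10 for f in folds)

    def test_stratified_fold_prevalence(self):
        # 85 positives over 10 folds -> 8 or 9 per fold
        labels = [i < 85 for i in range(500)]
        folds = make_folds(labels, k=10, stratified=True, seed=2)
        for f in folds:
            assert sum(labels[i] for i in f) in (8, 9)

    def test_cycle_count_and_determinism(self):
        data = _keyword_dataset(80, 4)
        a = repeated_kfold_cv(data, _bow_trainer, k=4, repeats=2, stratified=True, seed=6)
        b = repeated_kfold_cv(data, _bow_trainer, k=4, repeats=2, stratified=True, seed=6)
        assert a.cycles == 8
        assert a == b
        assert a.scheme == "stratified_kfold"

    def test_small_k_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            repeated_kfold_cv(_keyword_dataset(40, 1), _bow_trainer, k=2)


class TestSummarizeCycles:
    def test_constant_list_zero_width(self):
        mean, (lo, hi) = summarize_cycles([80.0] * 10)
        assert mean == 80.0
        assert lo == hi == 80.0

    def test_two_values(self):
        mean, _ = summarize_cycles([80.0, 90.0])
        assert mean == 85.0

    def test_coverage_simulation(self):
        """The normal-approximation CI covers the true mean ~95% of the time."""
        rng = np.random.default_rng(99)
        hits = 0
        reps = 400
        for _ in range(reps):
            vals = rng.normal(85.0, 3.0, 100)
            _, (lo, hi) = summarize_cycles(vals)
            hits += lo <= 85.0 <= hi
        assert 0.90 <= hits / reps <= 0.99

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            summarize_cycles([1.0])
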