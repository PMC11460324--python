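"""Enrichment score, TP/TN logistic classification, FPR cutoff, F1, topN."""

import math

import numpy as np
import pandas as pd
import pytest

from bioidkit.classifier import (
    enrichment_score,
    f1_at_cutoff,
    fit_classifier,
    fpr_cutoff,
    interactor_fraction,
    rank_by_score,
    topn_recovery,
)


def diff_table(proteins, ratios, qs):
    return pd.DataFrame({"protein": proteins, "avg_log2_ratio": ratios, "q_value": qs})


def fpr_cutoff_brute_force(scores: dict, tn: set, alpha: float):
    """Exhaustive threshold search over observed scores."""
    tn_scores = [scores[p] for p in scores if p in tn]
    for c in sorted(set(scores.values())):
        if sum(s >= c for s in tn_scores) / len(tn_scores) < alpha:
            return c
    return math.inf


class TestEnrichmentScore:
    def test_monotone_in_ratio_at_equal_q(self):
        scores = enrichment_score(diff_table(["A", "B"], [1.0, 2.0], [0.01, 0.01]))
        assert scores["B"] > scores["A"]

    def test_monotone_in_q_at_equal_ratio(self):
        scores = enrichment_score(diff_table(["A", "B", "C"], [1.0, 1.0, 1.0], [0.5, 0.01, 0.2]))
        assert scores["B"] > scores["C"] > scores["A"]

    def test_best_protein_scores_two(self):
        scores = enrichment_score(
            diff_table(["best", "mid", "worst"], [4.0, 2.0, 0.0], [0.001, 0.1, 0.9])
        )
        assert scores["best"] == pytest.approx(2.0)
        assert scores["worst"] == pytest.approx(0.0)

    def test_matches_spreadsheet_recomputation(self):
        """Five-protein toy table against an independent min-max recomputation."""
        proteins = ["P1", "P2", "P3", "P4", "P5"]
        ratios = [3.0, -1.0, 0.5, 2.0, 1.0]
        qs = [0.001, 0.9, 0.3, 0.01, 0.05]
        neglog = [-math.log10(q) for q in qs]
        u = [(v - min(neglog)) / (max(neglog) - min(neglog)) for v in neglog]
        v = [(r - min(ratios)) / (max(ratios) - min(ratios)) for r in ratios]
        expected = {p: ui + vi for p, ui, vi in zip(proteins, u, v)}
        scores = enrichment_score(diff_table(proteins, ratios, qs))
        for p in proteins:
            assert scores[p] == pytest.approx(expected[p])

    def test_zero_q_clamped_to_smallest_positive(self):
        scores = enrichment_score(diff_table(["A", "B"], [1.0, 1.0], [0.0, 0.01]))
        assert scores["A"] == scores["B"]  # clamped to same q, same ratio

    def test_degenerate_scaling_gives_ties(self):
        scores = enrichment_score(diff_table(["A", "B"], [1.0, 1.0], [0.05, 0.05]))
        assert scores["A"] == scores["B"] == pytest.approx(1.0)


class TestRanking:
    def test_ranks_are_permutation_with_deterministic_ties(self):
        scores = pd.Series({"A": 1.0, "B": 2.0, "C": 1.0})
        ranks = rank_by_score(scores, {"A": 0.2, "B": 0.1, "C": 0.01})
        assert sorted(ranks) == [1, 2, 3]
        assert ranks["B"] == 1
        assert ranks["C"] == 2  # tie with A broken by smaller q
        assert ranks["A"] == 3


class TestFitClassifier:
    def test_separated_classes_order_probabilities(self):
        scores = pd.Series({f"tp{i}": 2.0 + 0.1 * i for i in range(5)}
                           | {f"tn{i}": 0.1 * i for i in range(5)})
        _, probs = fit_classifier(scores, {f"tp{i}" for i in range(5)}, {f"tn{i}" for i in range(5)})
        assert min(probs[f"tp{i}"] for i in range(5)) > max(probs[f"tn{i}"] for i in range(5))

    def test_rank_by_score_equals_rank_by_probability(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.uniform(0, 2, 30), index=[f"p{i}" for i in range(30)])
        tp = {f"p{i}" for i in range(30) if scores[f"p{i}"] > 1.2}
        tn = {f"p{i}" for i in range(30) if scores[f"p{i}"] < 0.8}
        model, probs = fit_classifier(scores, tp, tn)
        assert model.coef_[0][0] > 0
        assert (scores.sort_values().index == probs.sort_values().index).all()

    def test_shuffled_labels_give_weak_coefficient(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(1.0, 0.5, 200), index=[f"p{i}" for i in range(200)])
        labels = rng.permutation([True] * 100 + [False] * 100)
        tp = {f"p{i}" for i in range(200) if labels[i]}
        tn = {f"p{i}" for i in range(200) if not labels[i]}
        model, probs = fit_classifier(scores, tp, tn)
        strong_model, _ = fit_classifier(
            scores, set(scores.index[scores > 1.2]), set(scores.index[scores < 0.8])
        )
        assert abs(model.coef_[0][0]) < abs(strong_model.coef_[0][0]) / 5
        assert probs.mean() == pytest.approx(0.5, abs=0.1)  # class prior

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.uniform(0, 2, 20), index=[f"p{i}" for i in range(20)])
        tp = {f"p{i}" for i in range(10)}
        tn = {f"p{i}" for i in range(10, 20)}
        _, a = fit_classifier(scores, tp, tn)
        _, b = fit_classifier(scores, tp, tn)
        assert (a == b).all()

    def test_too_few_labeled_is_error(self):
        scores = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 0.5})
        with pytest.raises(ValueError, match=">= 3"):
            fit_classifier(scores, {"a", "b"}, {"c", "d"})


class TestFprCutoff:
    def test_separated_tn_yield_first_tp_score(self):
        scores = pd.Series({f"tn{i}": 1.0 + 0.2 * i for i in range(20)} | {"tp0": 6.0})
        # TN max 4.8 < 6.0: the smallest score with TN FPR < 0.05 is 6.0
        cutoff, fpr = fpr_cutoff(scores, {f"tn{i}" for i in range(20)}, alpha=0.05)
        assert cutoff == pytest.approx(6.0)
        assert fpr == 0.0

    def test_alpha_one_returns_minimum_score(self):
        scores = pd.Series({"a": 1.0, "b": 2.0, "tn": 0.5})
        cutoff, _ = fpr_cutoff(scores, {"tn"}, alpha=1.0)
        assert cutoff == pytest.approx(0.5)

    def test_exact_alpha_rejected_next_score_chosen(self):
        # 19 of 20 TN below c: FPR at the top TN score is 1/20 = 0.05, which is
        # NOT < 0.05, so the next higher observed score must be chosen
        scores = {f"tn{i}": float(i) for i in range(20)}
        scores["tp"] = 25.0
        s = pd.Series(scores)
        cutoff, fpr = fpr_cutoff(s, {f"tn{i}" for i in range(20)}, alpha=0.05)
        assert cutoff == pytest.approx(25.0)
        assert fpr == 0.0

    def test_all_tn_at_max_gives_infinite_cutoff(self):
        scores = pd.Series({"tn0": 5.0, "tn1": 5.0, "tp0": 5.0})
        cutoff, _ = fpr_cutoff(scores, {"tn0", "tn1"}, alpha=0.05)
        assert cutoff == math.inf

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        scores = {f"p{i}": float(np.round(rng.uniform(0, 5), 2)) for i in range(n)}
        tn = {f"p{i}" for i in range(n) if rng.random() < 0.4} or {"p0"}
        alpha = float(rng.choice([0.01, 0.05, 0.2]))
        cutoff, fpr = fpr_cutoff(pd.Series(scores), tn, alpha=alpha)
        assert cutoff == fpr_cutoff_brute_force(scores, tn, alpha)
        if math.isfinite(cutoff):
            assert fpr < alpha


class TestF1:
    def test_perfect_separation(self):
        scores = pd.Series({"tp0": 3.0, "tp1": 2.5, "tn0": 1.0, "tn1": 0.5})
        report = f1_at_cutoff(scores, {"tp0", "tp1"}, {"tn0", "tn1"}, cutoff=2.0)
        assert report.f1 == pytest.approx(1.0)
        assert report.fpr_at_cutoff == 0.0

    def test_partial_recovery_arithmetic(self):
        # 8 of 10 TP and 2 TN above the cutoff -> precision 0.8, recall 0.8
        scores = {f"tp{i}": 2.0 for i in range(8)} | {f"tp{i}": 0.0 for i in range(8, 10)}
        scores |= {f"tn{i}": 2.0 for i in range(2)} | {f"tn{i}": 0.0 for i in range(2, 10)}
        report = f1_at_cutoff(
            pd.Series(scores), {f"tp{i}" for i in range(10)}, {f"tn{i}" for i in range(10)}, 1.0
        )
        assert report.precision == pytest.approx(0.8)
        assert report.recall == pytest.approx(0.8)
        assert report.f1 == pytest.approx(0.8)

    def test_cutoff_above_all_scores_flagged(self):
        scores = pd.Series({"tp0": 1.0, "tp1": 1.5, "tn0": 0.2, "tn1": 0.1, "tn2": 0.0})
        report = f1_at_cutoff(scores, {"tp0", "tp1"}, {"tn0", "tn1", "tn2"}, cutoff=10.0)
        assert report.recall == 0.0
        assert report.f1 == 0.0
        assert report.degenerate


class TestTopN:
    def test_all_tp_ranked_first(self):
        ranked = pd.Series({f"tp{i}": i + 1 for i in range(5)} | {f"x{i}": i + 6 for i in range(5)})
        table = topn_recovery(ranked, {"tp": {f"tp{i}" for i in range(5)}}, [5])
        assert table["count"].tolist() == [5]

    def test_n_zero_gives_zero_counts(self):
        ranked = pd.Series({"a": 1, "b": 2})
        table = topn_recovery(ranked, {"s": {"a", "b"}}, [0])
        assert table["count"].tolist() == [0]

    def test_counts_match_brute_force_and_are_monotone(self):
        rng = np.random.default_rng(6)
        proteins = [f"p{i}" for i in range(50)]
        order = rng.permutation(proteins)
        ranked = pd.Series({p: i + 1 for i, p in enumerate(order)})
        members = {p for p in proteins if rng.random() < 0.3}
        ns = [0, 5, 10, 25, 50, 80]
        table = topn_recovery(ranked, {"s": members}, ns)
        counts = table["count"].tolist()
        for n, count in zip(ns, counts):
            brute = sum(1 for p in proteins if ranked[p] <= min(n, 50) and p in members)
            assert count == brute
        assert counts == sorted(counts)


class TestInteractorFraction:
    @pytest.mark.parametrize(
        "n_known, n_candidates, expected",
        [(262, 1803, 14.5), (77, 432, 17.8)],
    )
    def test_reported_fractions(self, n_known, n_candidates, expected):
        candidates = {f"c{i}" for i in range(n_candidates)}
        known = {f"c{i}" for i in range(n_known)} | {f"other{i}" for i in range(50)}
        assert interactor_fraction(candidates, known) == expected

    def test_disjoint_sets_give_zero(self):
        assert interactor_fraction({"a", "b"}, {"c"}) == 0.0

    def test_empty_candidates_is_error(self):
        with pytest.raises(ValueError):
            interactor_fraction(set(), {"a"})
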