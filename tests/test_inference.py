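"""Top-k combination inference and the evaluation protocol."""

import itertools

import numpy as np
import pytest

from rxncond.chem import NULL_LABEL, ReactionRecord
from rxncond.inference import (
    BeamWidths,
    ConditionPrediction,
    PortfolioConfig,
    USPTO_WIDTHS,
    enumerate_combinations,
    evaluate_split,
    predict_conditions,
    relaxed_topk_accuracy,
    render_report,
    score_stratum,
    slot_topk_accuracy,
    strict_topk_accuracy,
    temperature_mae,
)
from rxncond.synthetic import default_category_map


def make_pred(ranked, temperature=25.0):
    return ConditionPrediction(
        ranked=ranked,
        slot_candidates=[[(lab, 1.0)] for lab in ranked[0][0]],
        temperature=temperature,
    )


class TestEnumeration:
    def test_two_slot_oracle(self):
        candidates = [[("a", 0.6), ("b", 0.4)], [("x", 0.9), ("y", 0.1)]]
        ranked = enumerate_combinations(candidates)
        assert [r[1] for r in ranked] == pytest.approx([0.54, 0.36, 0.06, 0.04])
        assert [r[0] for r in ranked] == [("a", "x"), ("b", "x"), ("a", "y"), ("b", "y")]

    def test_matches_brute_force_product_sort(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sizes = rng.integers(1, 4, size=5)
            candidates = []
            for s in sizes:
                p = np.sort(rng.random(s))[::-1]
                candidates.append([(f"l{i}", float(p[i])) for i in range(s)])
            ranked = enumerate_combinations(candidates)
            assert len(ranked) == int(np.prod(sizes))
            # oracle: exhaustive product scores, sorted descending
            oracle = sorted(
                (
                    float(np.prod([c[1] for c in combo]))
                    for combo in itertools.product(*candidates)
                ),
                reverse=True,
            )
            assert [r[1] for r in ranked] == pytest.approx(oracle)

    def test_model_portfolio_yields_fifteen(self, trained_model, learnability_split):
        _, _, _, _, test_set = learnability_split
        pred = predict_conditions(trained_model, test_set[0], USPTO_WIDTHS)
        assert len(pred.ranked) == 15
        scores = [s for _, s in pred.ranked]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert all(0 < s <= 1 for s in scores)

    def test_single_width_returns_top1_product(self, trained_model, learnability_split):
        _, _, _, _, test_set = learnability_split
        pred = predict_conditions(trained_model, test_set[0], BeamWidths((1, 1, 1, 1, 1)))
        assert len(pred.ranked) == 1
        product = np.prod([c[0][1] for c in pred.slot_candidates])
        assert pred.ranked[0][1] == pytest.approx(product)

    def test_excessive_width_rejected(self, trained_model, learnability_split):
        _, _, _, _, test_set = learnability_split
        with pytest.raises(ValueError, match="vocabulary"):
            predict_conditions(trained_model, test_set[0], BeamWidths((99, 1, 1, 1, 1)))


class TestAccuracies:
    truth = [("c", "s", "t", "r", "q")] * 3

    def preds_hit_at_ranks_1_3_none(self):
        hit = ("c", "s", "t", "r", "q")
        miss = ("c", "s", "t", "r", "zz")
        return [
            make_pred([(hit, 0.9)] + [(miss, 0.01)] * 14),
            make_pred([(miss, 0.9), (miss, 0.5), (hit, 0.3)] + [(miss, 0.01)] * 12),
            make_pred([(miss, 0.9)] * 15),
        ]

    def test_hand_counted_hits(self):
        preds = self.preds_hit_at_ranks_1_3_none()
        assert strict_topk_accuracy(preds, self.truth, 1) == pytest.approx(1 / 3)
        assert strict_topk_accuracy(preds, self.truth, 3) == pytest.approx(2 / 3)
        assert strict_topk_accuracy(preds, self.truth, 15) == pytest.approx(2 / 3)

    def test_monotone_in_k(self):
        preds = self.preds_hit_at_ranks_1_3_none()
        accs = [strict_topk_accuracy(preds, self.truth, k) for k in (1, 2, 3, 5, 15)]
        assert all(a <= b for a, b in zip(accs, accs[1:]))

    def test_identity_category_map_equals_strict(self):
        preds = self.preds_hit_at_ranks_1_3_none()
        labels = {lab for p in preds for combo, _ in p.ranked for lab in combo}
        identity = {lab: lab for lab in labels}
        for k in (1, 3, 15):
            assert relaxed_topk_accuracy(preds, self.truth, k, identity) == (
                strict_topk_accuracy(preds, self.truth, k)
            )

    def test_same_category_solvent_counts_correct(self):
        thf, dioxane = "C1CCOC1", "C1COCCO1"
        cat = {thf: "ether", dioxane: "ether", NULL_LABEL: NULL_LABEL, "r": "r", "q": "q"}
        pred = make_pred([(("c", thf, NULL_LABEL, "r", "q"), 0.9)])
        truth = [("c", dioxane, NULL_LABEL, "r", "q")]
        assert relaxed_topk_accuracy([pred], truth, 1, cat) == 1.0
        assert strict_topk_accuracy([pred], truth, 1) == 0.0

    def test_catalyst_mismatch_stays_incorrect_even_same_class(self):
        cat = {NULL_LABEL: NULL_LABEL, "s": "s", "r": "r"}
        pred = make_pred([(("[Pd]", "s", NULL_LABEL, "r", NULL_LABEL), 0.9)])
        truth = [("[Pt]", "s", NULL_LABEL, "r", NULL_LABEL)]
        assert relaxed_topk_accuracy([pred], truth, 1, cat) == 0.0

    def test_null_only_matches_null(self):
        cat = {NULL_LABEL: "x", "s": "x", "r": "r", "c": "c"}
        pred = make_pred([(("c", "s", NULL_LABEL, "r", NULL_LABEL), 0.9)])
        truth = [("c", NULL_LABEL, NULL_LABEL, "r", NULL_LABEL)]
        assert relaxed_topk_accuracy([pred], truth, 1, cat) == 0.0

    def test_missing_label_raises_naming_it(self):
        pred = make_pred([(("c", "mystery", "t", "r", "q"), 0.9)])
        with pytest.raises(KeyError, match="mystery"):
            relaxed_topk_accuracy([pred], [("c", "x", "t", "r", "q")], 1, {"x": "x"})

    def test_strict_never_exceeds_relaxed_on_model_predictions(
        self, trained_model, learnability_split
    ):
        _, _, _, _, test_set = learnability_split
        preds = [predict_conditions(trained_model, r, USPTO_WIDTHS) for r in test_set[:30]]
        truths = [r.conditions for r in test_set[:30]]
        cat = default_category_map()
        for k in (1, 3, 5, 10, 15):
            strict = strict_topk_accuracy(preds, truths, k)
            relaxed = relaxed_topk_accuracy(preds, truths, k, cat)
            assert strict <= relaxed


class TestTemperature:
    def test_hand_arithmetic(self):
        preds = [make_pred([(("a",) * 5, 1.0)], t) for t in (20.0, 30.0)]
        assert temperature_mae(preds, [25.0, 25.0]) == pytest.approx(5.0)

    def test_perfect_predictions_give_zero(self):
        preds = [make_pred([(("a",) * 5, 1.0)], 42.0)]
        assert temperature_mae(preds, [42.0]) == 0.0

    def test_constant_predictor_folded_normal(self):
        # predictor fixed at the Normal(80, 5) mean: MAE -> 5 * sqrt(2/pi)
        rng = np.random.default_rng(0)
        temps = rng.normal(80.0, 5.0, size=10000)
        preds = [make_pred([(("a",) * 5, 1.0)], 80.0) for _ in temps]
        mae = temperature_mae(preds, list(temps))
        assert mae == pytest.approx(5 * np.sqrt(2 / np.pi), abs=0.15)

    def test_no_truths_rejected(self):
        with pytest.raises(ValueError):
            temperature_mae([make_pred([(("a",) * 5, 1.0)], 1.0)], [None])


class TestStratifiedEvaluation:
    def toy_stratum(self):
        truth_a = ("c", "s", NULL_LABEL, "r", NULL_LABEL)
        records = [
            ReactionRecord("CC>>CC", truth_a, record_id="a"),
            ReactionRecord("CC>>CC", truth_a, record_id="b"),
        ]
        hit = (truth_a, 0.8)
        miss = (("c", "s", NULL_LABEL, "zz", NULL_LABEL), 0.1)
        preds = [make_pred([hit, miss]), make_pred([miss, miss])]
        return preds, records

    def test_hand_scored_stratum(self):
        preds, records = self.toy_stratum()
        entry = score_stratum(
            preds, records, BeamWidths((1, 2, 1, 1, 1)), overall_slots=(0, 1, 3),
            top_ks=(1, 2),
        )
        # record a hits at rank 1, record b never: overall 1/2 at both k
        assert entry["overall_strict"] == {1: 0.5, 2: 0.5}
        assert entry["n"] == 2
        assert entry["per_slot"]["catalyst"][1] == 1.0  # both top-1 catalysts correct
        assert entry["per_slot"]["reagent1"][1] == 0.5  # only record a's reagent1 is

    def test_all_null_catalyst_set_has_no_beta_stratum(self, trained_model, learnability_split):
        _, _, _, _, test_set = learnability_split
        alpha_only = [r for r in test_set if r.conditions[0] == NULL_LABEL][:6]
        report = evaluate_split(trained_model, alpha_only)
        assert "alpha" in report and "beta" not in report

    def test_report_structure_and_monotonicity(self, trained_model, learnability_split):
        _, _, _, _, test_set = learnability_split
        report = evaluate_split(
            trained_model, test_set[:40], category_map=default_category_map()
        )
        for name in ("alpha", "beta"):
            if name not in report:
                continue
            entry = report[name]
            assert set(entry["per_slot"]) == {
                "catalyst", "solvent1", "solvent2", "reagent1", "reagent2"
            }
            ks = sorted(entry["overall_strict"])
            overall = [entry["overall_strict"][k] for k in ks]
            assert all(a <= b for a, b in zip(overall, overall[1:]))
            for k in ks:
                assert entry["overall_strict"][k] <= entry["overall_relaxed"][k]
            assert "temperature_mae" in entry
        text = render_report(report)
        assert "overall" in text and "catalyst" in text

    def test_trained_model_solves_synthetic_task(self, trained_model, learnability_split):
        _, _, _, _, test_set = learnability_split
        preds = [predict_conditions(trained_model, r, USPTO_WIDTHS) for r in test_set[:40]]
        truths = [r.conditions for r in test_set[:40]]
        assert strict_topk_accuracy(preds, truths, 3) >= 0.8
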