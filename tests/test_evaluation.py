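"""Candidate ranking, tie-breaking, and macro/micro accuracy computation."""

import json
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abbrsense.corpus import AbbrevInstance, SenseInventory, build_sense_inventory
from abbrsense.evaluation import (
    AlignmentError,
    EvalReport,
    PredictionResult,
    evaluate,
    predict,
    render_report,
)
from abbrsense.pairs import WhitespaceTokenizer, generate_pairs
from abbrsense.scoring import TrainConfig, train_scorer
from abbrsense.synthetic import SynthConfig, generate_corpus


class _FixedScorer:
    """Stub scorer returning preset per-candidate scores."""

    def __init__(self, table):
        self.table = table

    def score(self, pair):
        return self.table[pair.candidate]


def _instance(idx="1", target="BK", label="below knee", negs=("BK(virus)",)):
    return AbbrevInstance(idx, target, "l", "r", label, negs)


class TestPredict:
    def test_strict_argmax(self, tokenizer):
        inst = _instance()
        inv = build_sense_inventory([inst])
        result = predict(inst, inv, _FixedScorer({"below knee": 0.9, "BK(virus)": 0.1}), tokenizer)
        assert result.chosen == "below knee"
        assert result.correct is True

    def test_exact_tie_goes_to_lexicographically_smaller(self, tokenizer):
        inst = _instance()
        inv = build_sense_inventory([inst])
        result = predict(inst, inv, _FixedScorer({"below knee": 0.5, "BK(virus)": 0.5}), tokenizer)
        assert result.chosen == "BK(virus)"

    def test_single_candidate_chosen_regardless_of_score(self, tokenizer):
        inst = _instance(negs=())
        inv = build_sense_inventory([inst])
        result = predict(inst, inv, _FixedScorer({"below knee": 0.01}), tokenizer)
        assert result.chosen == "below knee"

    def test_candidate_order_invariance(self, tokenizer):
        """Prediction depends on scores only, not candidate presentation order."""
        inst = _instance(negs=("BK(virus)", "bovine kidney"))
        scores = {"below knee": 0.7, "BK(virus)": 0.2, "bovine kidney": 0.1}
        inv_a = SenseInventory({"BK": list(scores)})
        inv_b = SenseInventory({"BK": list(reversed(list(scores)))})
        ra = predict(inst, inv_a, _FixedScorer(scores), tokenizer)
        rb = predict(inst, inv_b, _FixedScorer(scores), tokenizer)
        assert ra.chosen == rb.chosen == "below knee"

    def test_missing_target_is_lookup_error(self, tokenizer):
        with pytest.raises(KeyError):
            predict(_instance(), SenseInventory({"PM": ["x"]}), _FixedScorer({}), tokenizer)

    def test_does_not_require_gold_in_inventory(self, tokenizer):
        """Inference works when the instance's gold sense is unknown to the inventory."""
        inst = _instance(label="some new sense")
        inv = SenseInventory({"BK": ["BK(virus)", "below knee"]})
        result = predict(inst, inv, _FixedScorer({"below knee": 0.8, "BK(virus)": 0.2}), tokenizer)
        assert result.chosen == "below knee"
        assert result.correct is None


def _pred(idx, target, chosen, cands):
    return PredictionResult(
        index=idx, target=target, chosen=chosen,
        scores={c: (0.9 if c == chosen else 0.1) for c in cands},
    )


class TestEvaluate:
    def test_all_correct_gives_100(self):
        gold = [_instance(str(i)) for i in range(4)]
        preds = [_pred(g.index, "BK", "below knee", g.candidates) for g in gold]
        report = evaluate(preds, gold)
        assert report.macro_accuracy == report.micro_accuracy == 100.0
        assert report.per_abbrev["BK"].accuracy == 100.0

    def test_hand_computed_macro_micro(self):
        """A: 1 of 2 correct (50%); B: 8 of 8 (100%) -> macro 75, micro 90."""
        gold_a = [_instance(f"a{i}", "PA", "alpha", ("beta",)) for i in range(2)]
        gold_b = [_instance(f"b{i}", "DM", "gamma", ("delta",)) for i in range(8)]
        preds = [_pred("a0", "PA", "alpha", ("alpha", "beta"))]
        preds += [_pred("a1", "PA", "beta", ("alpha", "beta"))]
        preds += [_pred(f"b{i}", "DM", "gamma", ("gamma", "delta")) for i in range(8)]
        report = evaluate(preds, gold_a + gold_b)
        assert report.per_abbrev["PA"].accuracy == 50.0
        assert report.per_abbrev["DM"].accuracy == 100.0
        assert report.macro_accuracy == 75.0
        assert report.micro_accuracy == 90.0

    def test_single_abbreviation_macro_equals_micro(self):
        gold = [_instance(str(i)) for i in range(5)]
        preds = [_pred(g.index, "BK", "below knee" if int(g.index) < 3 else "BK(virus)", g.candidates) for g in gold]
        report = evaluate(preds, gold)
        assert report.macro_accuracy == report.micro_accuracy == 60.0

    def test_confusion_matrix_cells_sum_to_counts(self):
        gold = [_instance(str(i), label="below knee") for i in range(3)]
        gold += [_instance(str(i + 3), label="BK(virus)", negs=("below knee",)) for i in range(2)]
        preds = [_pred(g.index, "BK", "below knee", ("BK(virus)", "below knee")) for g in gold]
        report = evaluate(preds, gold)
        cm = report.per_abbrev["BK"].confusion
        assert sum(v for row in cm.values() for v in row.values()) == 5
        assert cm["BK(virus)"]["below knee"] == 2

    def test_unmatched_reference_is_alignment_error(self):
        gold = [_instance("1")]
        preds = [_pred("2", "BK", "below knee", ("BK(virus)", "below knee"))]
        with pytest.raises(AlignmentError):
            evaluate(preds, gold)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_loop_and_count_oracle(self, seed):
        rng = random.Random(seed)
        targets = ["ER", "DM", "CVA", "PM", "PA"]
        gold, preds = [], []
        for i in range(rng.randint(1, 120)):
            t = rng.choice(targets)
            cands = ("sense one", "sense two", "sense three")
            label = rng.choice(cands)
            chosen = rng.choice(cands)
            gold.append(AbbrevInstance(str(i), t, "l", "r", label,
                                       tuple(c for c in cands if c != label)))
            preds.append(_pred(str(i), t, chosen, cands))
        report = evaluate(preds, gold)
        # oracle: plain loops
        correct_by, count_by = {}, {}
        for g, p in zip(gold, preds):
            count_by[g.target] = count_by.get(g.target, 0) + 1
            correct_by[g.target] = correct_by.get(g.target, 0) + (g.label == p.chosen)
        accs = [100 * correct_by[t] / count_by[t] for t in count_by]
        assert report.macro_accuracy == pytest.approx(sum(accs) / len(accs))
        assert report.micro_accuracy == pytest.approx(
            100 * sum(correct_by.values()) / sum(count_by.values())
        )
        # algebraic identity: micro equals the count-weighted mean of accuracies
        weighted = sum(
            report.per_abbrev[t].count * report.per_abbrev[t].accuracy
            for t in report.per_abbrev
        ) / sum(report.per_abbrev[t].count for t in report.per_abbrev)
        assert report.micro_accuracy == pytest.approx(weighted)

    def test_macro_invariant_micro_sensitive_to_duplication(self):
        """Duplicating one abbreviation's instances moves micro but not macro."""
        gold_a = [_instance(f"a{i}", "PA", "alpha", ("beta",)) for i in range(2)]
        gold_b = [_instance(f"b{i}", "DM", "gamma", ("delta",)) for i in range(2)]
        preds_a = [_pred("a0", "PA", "alpha", ("alpha", "beta")),
                   _pred("a1", "PA", "beta", ("alpha", "beta"))]
        preds_b = [_pred(f"b{i}", "DM", "gamma", ("gamma", "delta")) for i in range(2)]
        base = evaluate(preds_a + preds_b, gold_a + gold_b)
        dup_gold = gold_a + gold_b + [_instance(f"c{i}", "DM", "gamma", ("delta",)) for i in range(4)]
        dup_preds = preds_a + preds_b + [_pred(f"c{i}", "DM", "gamma", ("gamma", "delta")) for i in range(4)]
        dup = evaluate(dup_preds, dup_gold)
        assert dup.macro_accuracy == base.macro_accuracy
        assert dup.micro_accuracy != base.micro_accuracy


class TestRenderReport:
    def test_json_round_trip_and_two_decimal_table(self, tmp_path):
        gold = [_instance(str(i)) for i in range(3)]
        preds = [_pred(g.index, "BK", "below knee" if int(g.index) else "BK(virus)", g.candidates) for g in gold]
        report = evaluate(preds, gold)
        path = render_report(report, tmp_path / "report.json")
        recovered = EvalReport.from_dict(json.loads(path.read_text()))
        assert recovered.macro_accuracy == report.macro_accuracy
        assert recovered.per_abbrev["BK"].confusion == report.per_abbrev["BK"].confusion
        table = (tmp_path / "report.txt").read_text()
        assert "66.67" in table  # 2 of 3 correct, two decimals
        assert "Macroaccuracy" in table and "Microaccuracy" in table
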