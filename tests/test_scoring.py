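"""Classification head math, scorer training, determinism, persistence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abbrsense.corpus import build_sense_inventory
from abbrsense.pairs import WhitespaceTokenizer, generate_pairs
from abbrsense.scoring import (
    ClassificationHead,
    DegenerateDataError,
    FormatError,
    LexicalScorer,
    TrainConfig,
    head_forward,
    load_scorer,
    save_scorer,
    score_pair,
    train_scorer,
)
from abbrsense.synthetic import SynthConfig, generate_corpus


def brute_force_head(x, w1, b1, w2, b2):
    """Independent oracle: explicit loops, no vectorized reuse of the code under test."""
    hidden = []
    for j in range(len(b1)):
        s = b1[j]
        for i in range(len(x)):
            s += x[i] * w1[i][j]
        hidden.append(max(s, 0.0))
    logits = []
    for k in range(2):
        s = b2[k]
        for j in range(len(hidden)):
            s += hidden[j] * w2[j][k]
        logits.append(s)
    m = max(logits)
    exps = [math.exp(v - m) for v in logits]
    z = sum(exps)
    return exps[0] / z, exps[1] / z


class TestHeadForward:
    def test_all_zero_weights_give_half_half(self):
        head = ClassificationHead(
            w1=np.zeros((3, 50)), b1=np.zeros(50), w2=np.zeros((50, 2)), b2=np.zeros(2)
        )
        assert head_forward([1.0, -2.0, 3.0], head) == (0.5, 0.5)

    def test_hand_set_2x2_head_matches_manual_arithmetic(self):
        # x=(1,-1); W1=[[1,2],[3,4]] -> pre=(1-3, 2-4)=(-2,-2) -> ReLU 0
        # plus b1=(1, 0.5) applied: pre=(-1,-1.5) -> ReLU -> (0,0)
        # so logits = b2 = (0.2, -0.1); softmax by hand
        w1 = [[1.0, 2.0], [3.0, 4.0]]
        b1 = [1.0, 0.5]
        w2 = [[0.7, -0.3], [0.2, 0.9]]
        b2 = [0.2, -0.1]
        head = ClassificationHead(w1=w1, b1=b1, w2=w2, b2=b2)
        expected = brute_force_head([1.0, -1.0], w1, b1, w2, b2)
        got = head_forward([1.0, -1.0], head)
        assert got == pytest.approx(expected, abs=1e-12)
        # with this x every pre-activation is negative: softmax of b2 alone
        z = math.exp(0.2) + math.exp(-0.1)
        assert got == pytest.approx((math.exp(0.2) / z, math.exp(-0.1) / z), abs=1e-12)

    def test_relu_dead_zone_returns_bias_softmax(self):
        rng = np.random.default_rng(0)
        w1 = rng.normal(size=(4, 6))
        b2 = np.array([0.3, -0.2])
        head = ClassificationHead(w1=w1, b1=np.full(6, -1e6), w2=rng.normal(size=(6, 2)), b2=b2)
        z = math.exp(0.3) + math.exp(-0.2)
        assert head_forward([0.1, 0.2, 0.3, 0.4], head) == pytest.approx(
            (math.exp(0.3) / z, math.exp(-0.2) / z), abs=1e-9
        )

    def test_width_mismatch_rejected(self):
        head = ClassificationHead.initialize(4, 50, seed=0)
        with pytest.raises(ValueError, match="width"):
            head_forward([1.0, 2.0], head)

    def test_output_dim_must_be_two(self):
        with pytest.raises(ValueError, match="exactly 2"):
            ClassificationHead(
                w1=np.zeros((3, 5)), b1=np.zeros(5), w2=np.zeros((5, 3)), b2=np.zeros(3)
            )

    @settings(max_examples=200, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_brute_force_oracle_on_random_heads(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(1, 9))
        h = int(rng.integers(1, 9))
        w1 = rng.normal(size=(d, h))
        b1 = rng.normal(size=h)
        w2 = rng.normal(size=(h, 2))
        b2 = rng.normal(size=2)
        x = rng.normal(size=d)
        head = ClassificationHead(w1=w1, b1=b1, w2=w2, b2=b2)
        p0, p1 = head_forward(x, head)
        e0, e1 = brute_force_head(x.tolist(), w1.tolist(), b1.tolist(), w2.tolist(), b2.tolist())
        assert abs(p0 - e0) < 1e-9 and abs(p1 - e1) < 1e-9
        assert p0 > 0 and p1 > 0 and abs(p0 + p1 - 1.0) < 1e-9


def _separable_pairs(seed=0, n_abbrevs=3, m=8):
    config = SynthConfig(seed=seed, n_abbrevs=n_abbrevs, instances_per_sense=m, p_sig=1.0)
    instances, inventory = generate_corpus(config)
    tokenizer = WhitespaceTokenizer(512)
    pairs = [p for i in instances for p in generate_pairs(i, inventory, tokenizer)]
    return instances, inventory, pairs


@pytest.mark.parametrize("backend", ["lexical", "mlp"])
class TestTrainScorer:
    def test_separable_data_trains_to_full_accuracy(self, backend):
        _, _, pairs = _separable_pairs()
        config = TrainConfig(backend=backend, seed=0, epochs=30)
        scorer = train_scorer(pairs, config)
        predicted = [int(score_pair(scorer, p) > 0.5) for p in pairs]
        accuracy = sum(int(g == p) for g, p in zip((q.label for q in pairs), predicted)) / len(pairs)
        assert accuracy == 1.0

    def test_fixed_seed_reproducible_scores(self, backend):
        _, _, pairs = _separable_pairs(seed=2)
        config = TrainConfig(backend=backend, seed=7, epochs=5)
        s1 = train_scorer(pairs, config)
        s2 = train_scorer(pairs, config)
        for p in pairs[:20]:
            assert score_pair(s1, p) == score_pair(s2, p)

    def test_empty_pairs_rejected(self, backend):
        with pytest.raises(DegenerateDataError):
            train_scorer([], TrainConfig(backend=backend, seed=0))

    def test_single_label_rejected(self, backend):
        _, _, pairs = _separable_pairs()
        positives = [p for p in pairs if p.label == 1]
        with pytest.raises(DegenerateDataError, match="both classes"):
            train_scorer(positives, TrainConfig(backend=backend, seed=0))

    def test_scores_in_unit_interval_and_pure(self, backend):
        _, _, pairs = _separable_pairs(seed=3)
        scorer = train_scorer(pairs, TrainConfig(backend=backend, seed=1, epochs=5))
        for p in pairs[:30]:
            s = score_pair(scorer, p)
            assert 0.0 <= s <= 1.0
            assert score_pair(scorer, p) == s  # exact duplicate -> identical score

    def test_save_load_round_trip(self, backend, tmp_path):
        _, _, pairs = _separable_pairs(seed=4)
        config = TrainConfig(backend=backend, seed=5, epochs=5)
        scorer = train_scorer(pairs, config)
        save_scorer(scorer, tmp_path / "scorer")
        loaded = load_scorer(tmp_path / "scorer")
        assert loaded.metadata == scorer.metadata
        assert loaded.config.seed == 5
        for p in pairs[:20]:
            assert score_pair(loaded, p) == score_pair(scorer, p)


class TestScorerBehaviour:
    def test_mlp_training_loss_decreases_on_separable_data(self):
        _, _, pairs = _separable_pairs(seed=5)
        scorer = train_scorer(pairs, TrainConfig(backend="mlp", seed=0, epochs=15))
        assert scorer.loss_history[-1] < scorer.loss_history[0]

    def test_signature_context_scores_above_half(self):
        instances, inventory, pairs = _separable_pairs(seed=6)
        scorer = train_scorer(pairs, TrainConfig(backend="lexical", seed=0))
        gold_pairs = [p for p in pairs if p.label == 1]
        assert all(score_pair(scorer, p) > 0.5 for p in gold_pairs)

    def test_lexical_monotone_in_signature_words(self):
        """Adding a context word whose co-occurrence weight with the candidate
        is non-negative never decreases the class-1 score."""
        from dataclasses import replace

        _, _, pairs = _separable_pairs(seed=7)
        scorer = train_scorer(pairs, TrainConfig(backend="lexical", seed=0))
        pair = next(p for p in pairs if p.label == 1)
        sig_word = pair.tokens[1]
        weight = scorer.feature_weight(f"cooc|{pair.candidate}|{sig_word}")
        assert weight >= 0.0
        grown = replace(
            pair,
            tokens=(pair.tokens[0], sig_word) + pair.tokens[1:],
            segment_boundary=pair.segment_boundary + 1,
            attention_mask=pair.attention_mask + (1,),
        )
        assert score_pair(scorer, grown) >= score_pair(scorer, pair)

    def test_untrained_scorer_is_state_error(self):
        scorer = LexicalScorer(TrainConfig(backend="lexical", seed=0))
        _, _, pairs = _separable_pairs()
        with pytest.raises(RuntimeError, match="untrained"):
            scorer.score(pairs[0])

    def test_corrupted_archive_is_format_error(self, tmp_path):
        _, _, pairs = _separable_pairs()
        scorer = train_scorer(pairs, TrainConfig(backend="lexical", seed=0))
        path = save_scorer(scorer, tmp_path / "scorer")
        (path / "params.json").write_text("{not json")
        with pytest.raises(FormatError):
            load_scorer(path)

    def test_version_mismatch_is_format_error(self, tmp_path):
        import json

        _, _, pairs = _separable_pairs()
        scorer = train_scorer(pairs, TrainConfig(backend="lexical", seed=0))
        path = save_scorer(scorer, tmp_path / "scorer")
        manifest = json.loads((path / "manifest.json").read_text())
        manifest["format_version"] = 99
        (path / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(FormatError, match="version"):
            load_scorer(path)
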