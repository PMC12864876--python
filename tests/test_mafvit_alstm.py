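"""Classifier: adaptive-LSTM cell algebra, attention behavior, smoke training."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pestpyramid import nn
from pestpyramid.mafvit_alstm import (AttentionBlock, ClassifierConfig,
                                      LSTMParams, LSTMState, MAFViTALSTM,
                                      classify, extract_patches, lstm_step,
                                      train_classifier)


def _state(h, rng=None, scale=1.0):
    if rng is None:
        return LSTMState(hidden=np.zeros(h), cell=np.zeros(h))
    return LSTMState(hidden=rng.normal(0, scale, h), cell=rng.normal(0, scale, h))


class TestLstmStep:
    def test_zero_parameter_closed_form(self):
        """All-zero weights, significance 0.5: gates 0.5, cell halves."""
        params = LSTMParams.zeros(d_in=3, hidden_width=5)
        prev = LSTMState(hidden=np.zeros(5), cell=np.full(5, 2.0))
        out = lstm_step(np.ones(3), prev, params, significance=0.5)
        assert np.allclose(out.cell, 1.0, atol=1e-12)          # 0.5 * 2 + 0.5 * 0
        assert np.allclose(out.hidden, 0.5 * np.tanh(1.0), atol=1e-12)
        assert out.step == 1

    def test_saturated_forget_gate_preserves_cell(self, rng):
        params = LSTMParams.zeros(d_in=3, hidden_width=5)
        # forget pre-activation -> +inf; input gate -> 0
        params.weights["forget"][2][:] = 50.0
        params.weights["input"][2][:] = -50.0
        prev = _state(5, rng)
        out = lstm_step(rng.normal(size=3), prev, params, significance=0.5)
        assert np.allclose(out.cell, prev.cell, atol=1e-12)

    def test_significance_shift_is_monotone_in_input_gate(self, rng):
        params = LSTMParams.init(3, 6, rng)
        prev = _state(6, rng)
        y = rng.normal(size=3)

        def input_gate(sig):
            my, mf, a = params.weights["input"]
            z = my @ y + mf @ prev.hidden + a + np.log(sig / (1 - sig))
            return 1 / (1 + np.exp(-z))

        hi = input_gate(0.9)
        lo = input_gate(0.1)
        assert np.all(hi > lo)
        # and the full step writes more to memory under high significance
        c_hi = lstm_step(y, prev, params, 0.9).cell
        c_lo = lstm_step(y, prev, params, 0.1).cell
        my, mf, a = params.weights["candidate"]
        cand = np.tanh(my @ y + mf @ prev.hidden + a)
        assert np.all((c_hi - c_lo) * np.sign(cand) >= 0)

    def test_neutral_significance_equals_textbook_lstm(self, rng):
        """significance 0.5 reduces the step to an independently coded LSTM."""
        params = LSTMParams.init(4, 7, rng)
        prev = _state(7, rng)
        y = rng.normal(size=4)
        out = lstm_step(y, prev, params, significance=0.5)

        def sig(z):
            return 1 / (1 + np.exp(-z))

        w = params.weights
        f = sig(w["forget"][0] @ y + w["forget"][1] @ prev.hidden + w["forget"][2])
        i = sig(w["input"][0] @ y + w["input"][1] @ prev.hidden + w["input"][2])
        o = sig(w["output"][0] @ y + w["output"][1] @ prev.hidden + w["output"][2])
        g = np.tanh(w["candidate"][0] @ y + w["candidate"][1] @ prev.hidden
                    + w["candidate"][2])
        c = f * prev.cell + i * g
        assert np.allclose(out.cell, c, atol=1e-12)
        assert np.allclose(out.hidden, o * np.tanh(c), atol=1e-12)

    @given(st.integers(0, 2 ** 32 - 1), st.floats(0.01, 0.99))
    def test_gate_ranges_for_any_finite_input(self, seed, sig_val):
        r = np.random.default_rng(seed)
        params = LSTMParams.init(3, 5, r)
        prev = _state(5, r, scale=3.0)
        out = lstm_step(r.normal(0, 5, 3), prev, params, significance=sig_val)
        assert np.all(np.isfinite(out.cell)) and np.all(np.isfinite(out.hidden))
        assert np.all(np.abs(out.hidden) < 1.0)    # |k * tanh(c)| < 1

    def test_memory_bound_under_unit_inputs(self, rng):
        """|cell| grows by at most 1 per step when the candidate is bounded by 1."""
        params = LSTMParams.init(3, 5, rng)
        state = LSTMState(hidden=np.zeros(5), cell=rng.normal(size=5))
        c0 = np.abs(state.cell)
        for s in range(6):
            state = lstm_step(rng.uniform(-1, 1, 3), state, params, 0.5)
            assert np.all(np.abs(state.cell) <= c0 + (s + 1) + 1e-12)

    def test_non_finite_input_rejected(self):
        params = LSTMParams.zeros(2, 5)
        with pytest.raises(FloatingPointError):
            lstm_step(np.array([np.nan, 0.0]), _state(5), params)

    def test_hidden_width_range_enforced(self):
        with pytest.raises(ValueError):
            LSTMParams.zeros(3, 4)
        with pytest.raises(ValueError):
            LSTMParams.zeros(3, 300)


class TestPatchEmbed:
    def test_token_count(self):
        crops = np.zeros((2, 32, 32, 3))
        assert extract_patches(crops, 8).shape == (2, 16, 192)

    def test_indivisible_patch_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((1, 32, 32, 3)), 5)

    def test_patches_are_row_major_and_linear(self, rng):
        crops = rng.normal(size=(1, 4, 4, 3))
        p = extract_patches(crops, 2)
        assert p.shape == (1, 4, 12)
        # first patch is the top-left 2x2 block
        assert np.allclose(p[0, 0], crops[0, :2, :2].reshape(-1))
        # second patch is the top-right block (row-major order)
        assert np.allclose(p[0, 1], crops[0, :2, 2:].reshape(-1))
        a, b = rng.normal(size=(2, 1, 4, 4, 3))
        assert np.allclose(extract_patches(a + b, 2),
                           extract_patches(a, 2) + extract_patches(b, 2))


class TestAttention:
    def test_rows_sum_to_one(self, rng):
        blk = AttentionBlock(8, 2, rng)
        _out, attn = blk(nn.Tensor(rng.normal(size=(2, 5, 8))))
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_token_attends_to_itself(self, rng):
        blk = AttentionBlock(8, 2, rng)
        out, attn = blk(nn.Tensor(rng.normal(size=(1, 1, 8))))
        assert attn.shape == (1, 2, 1, 1)
        assert np.allclose(attn, 1.0)
        assert np.all(np.isfinite(out.data))

    def test_identical_tokens_produce_identical_outputs(self, rng):
        blk = AttentionBlock(8, 2, rng)
        tok = rng.normal(size=8)
        x = np.tile(tok, (1, 4, 1))
        out, _ = blk(nn.Tensor(x))
        assert np.allclose(out.data[0], out.data[0, 0], atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            AttentionBlock(9, 2, rng)


class TestFusion:
    def test_fusion_weights_sum_to_one(self, rng):
        model = MAFViTALSTM(ClassifierConfig())
        w = nn.softmax(model.fusion_weights, axis=0).data
        assert w.sum() == pytest.approx(1.0)

    def test_significance_normalized_and_bounded(self, rng):
        model = MAFViTALSTM(ClassifierConfig(seed=1))
        crops = rng.uniform(size=(3, 32, 32, 3))
        fused, sig = model.fuse_tokens(crops)
        assert fused.shape[0] == 3 and fused.shape[2] == 32
        assert sig.shape == fused.shape[:2]
        assert np.all((sig > 0) & (sig < 1))
        assert np.allclose(sig.mean(axis=1), 0.5, atol=1e-9)

    def test_single_scale_reduces_to_plain_attention(self, rng):
        cfg = ClassifierConfig(scales=(32,), seed=2)
        model = MAFViTALSTM(cfg)
        crops = rng.uniform(size=(2, 32, 32, 3))
        fused, _sig = model.fuse_tokens(crops)
        patches = extract_patches(crops, cfg.patch_size)
        tok = nn.Tensor(patches) @ model.embed[0]["proj_w"] \
            + model.embed[0]["proj_b"] + model.embed[0]["pos"]
        tok, _ = model.scale_attn[0](tok)
        expected, _ = model.fusion_attn(tok * 1.0)   # unit fusion weight
        assert np.allclose(fused.data, expected.data, atol=1e-10)


@pytest.fixture(scope="module")
def toy_data():
    """Crops whose mean color encodes the class; trivially separable."""
    r = np.random.default_rng(0)
    base = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
    crops, labels = [], []
    for i in range(90):
        k = i % 3
        crops.append(np.clip(base[k] + r.normal(0, 0.08, (32, 32, 3)), 0, 1))
        labels.append(k)
    return np.array(crops), np.array(labels)


class TestTraining:
    def test_training_learns_and_traces_cost(self, toy_data):
        crops, labels = toy_data
        cfg = ClassifierConfig(epochs=8, hidden_width=16, seed=3)
        model, costs = train_classifier(crops[:60], labels[:60], cfg)
        assert len(costs) == cfg.epochs
        assert costs[-1] < costs[0]
        probs = model.predict_proba(crops[60:])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs.argmax(axis=1) == labels[60:]).mean() >= 0.9

    def test_same_seed_reproduces_trace(self, toy_data):
        crops, labels = toy_data
        cfg = ClassifierConfig(epochs=3, hidden_width=12, seed=4)
        _m1, c1 = train_classifier(crops[:30], labels[:30], cfg)
        _m2, c2 = train_classifier(crops[:30], labels[:30], cfg)
        assert c1 == c2

    def test_single_class_data_rejected(self, toy_data):
        crops, labels = toy_data
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(crops[labels == 0], labels[labels == 0],
                             ClassifierConfig())

    def test_classify_requires_trained_model(self):
        model = MAFViTALSTM(ClassifierConfig())
        with pytest.raises(RuntimeError, match="untrained"):
            classify(np.zeros((32, 32, 3)), model)

    def test_classify_is_deterministic(self, toy_data):
        crops, labels = toy_data
        cfg = ClassifierConfig(epochs=2, hidden_width=12, seed=5)
        model, _ = train_classifier(crops[:30], labels[:30], cfg)
        p1 = classify(crops[0], model)
        p2 = classify(crops[0], model)
        assert np.array_equal(p1, p2)
        assert p1.sum() == pytest.approx(1.0, abs=1e-6)

    def test_checkpoint_round_trip(self, toy_data, tmp_path):
        crops, labels = toy_data
        cfg = ClassifierConfig(epochs=2, hidden_width=12, seed=6)
        model, _ = train_classifier(crops[:30], labels[:30], cfg)
        model.save(tmp_path / "clf.npz")
        back = MAFViTALSTM.load(tmp_path / "clf.npz")
        assert back.config == model.config
        assert np.array_equal(back.predict_proba(crops[:4]),
                              model.predict_proba(crops[:4]))


class TestModelMatchesReferenceCell:
    def test_model_lstm_equals_standalone_step_sequence(self, rng):
        """The trainable LSTM forward agrees with the plain-numpy cell."""
        cfg = ClassifierConfig(hidden_width=9, use_adaptive=True, seed=8)
        model = MAFViTALSTM(cfg)
        n, t, d = 2, 4, cfg.embed_dim
        fused = rng.normal(size=(n, t, d))
        sig = rng.uniform(0.2, 0.8, size=(n, t))
        out = model._lstm_forward(nn.Tensor(fused), sig).data

        weights = {g: (model.lstm[f"{g}_y"].data.T, model.lstm[f"{g}_f"].data.T,
                       model.lstm[f"{g}_b"].data)
                   for g in ("forget", "input", "output", "candidate")}
        params = LSTMParams(weights=weights, hidden_width=9)
        for b in range(n):
            state = LSTMState(hidden=np.zeros(9), cell=np.zeros(9))
            for s in range(t):
                state = lstm_step(fused[b, s], state, params, float(sig[b, s]))
            assert np.allclose(out[b], state.hidden, atol=1e-12)
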