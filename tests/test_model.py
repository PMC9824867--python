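"""The classifier: closed-form identities, hand-unrolled oracles, gradients."""

import numpy as np
import pytest

import stagescreen as ss
from stagescreen import nn
from stagescreen.data import N_STAGES, STAGES
from stagescreen.model import AttentionProfile, class_weights_from_counts


# -- class weights (inverse input-data ratio) --------------------------------

@pytest.mark.parametrize(
    "counts, expected",
    [
        ((1, 1, 1), (3.0, 3.0, 3.0)),
        ((1, 2, 2), (5.0, 2.5, 2.5)),
        ((349, 181, 66), (596 / 349, 596 / 181, 596 / 66)),
    ],
)
def test_class_weights_are_inverse_frequencies(counts, expected):
    np.testing.assert_allclose(
        class_weights_from_counts(counts), expected, rtol=1e-12
    )


def test_class_weights_reject_zero_counts():
    with pytest.raises(ValueError):
        class_weights_from_counts((5, 0, 1))


# -- weighted cross-entropy closed forms -------------------------------------

def test_weighted_ce_perfect_prediction_is_zero():
    p = np.array([[0.0, 1.0, 0.0]])
    assert ss.weighted_cross_entropy(p, [1], np.ones(3)) == pytest.approx(
        0.0, abs=1e-10
    )


def test_weighted_ce_uniform_prediction_is_ln3():
    p = np.full((1, 3), 1 / 3)
    assert ss.weighted_cross_entropy(p, [0], np.ones(3)) == pytest.approx(
        np.log(3), abs=1e-10
    )


def test_weighted_ce_scales_with_class_weight():
    p = np.array([[0.5, 0.25, 0.25]])
    w = np.array([2.0, 1.0, 1.0])
    assert ss.weighted_cross_entropy(p, [0], w) == pytest.approx(
        2 * np.log(2), abs=1e-10
    )


def test_weighted_ce_with_unit_weights_equals_unweighted():
    rng = np.random.default_rng(0)
    logits = rng.normal(size=(10, 3))
    p = nn.softmax(logits)
    y = rng.integers(0, 3, size=10)
    ours = ss.weighted_cross_entropy(p, y, np.ones(3))
    plain = -np.mean(np.log(p[np.arange(10), y]))
    assert ours == pytest.approx(plain, abs=1e-12)


# -- attention block ---------------------------------------------------------

def _small_model(seed=0, hidden=3, layers=1):
    return ss.StageAttentionClassifier(
        ss.ModelConfig(
            hidden_size=hidden,
            num_recurrent_layers=layers,
            head_hidden=5,
            seed=seed,
        )
    )


def test_zero_features_score_at_sigmoid_midpoint():
    m = _small_model()
    profile = m.stage_attention(np.zeros((N_STAGES, 6)))
    np.testing.assert_allclose(profile.raw_scores, 0.5, atol=1e-12)
    np.testing.assert_allclose(
        profile.percent_scores, 100.0 / 11, atol=1e-9
    )


def test_constant_feature_pooling_symmetry():
    """When avg-pool equals max-pool the two MLP branches coincide, so the
    pre-sigmoid score is twice one branch."""
    m = _small_model(seed=4)
    F = np.tile(np.array([0.3]), (N_STAGES, 6))  # constant everywhere
    p = m.params
    pooled = F.mean(axis=1)  # == F.max(axis=1)
    h = np.maximum(pooled @ p["attn.W1"] + p["attn.b1"], 0.0)
    expected = 1 / (1 + np.exp(-2.0 * (h @ p["attn.W2"] + p["attn.b2"])))
    np.testing.assert_allclose(
        m.stage_attention(F).raw_scores, expected, atol=1e-12
    )


def test_attention_matches_hand_computation_with_set_weights():
    m = _small_model(seed=1, hidden=1)  # features of width 2
    rng = np.random.default_rng(3)
    W1 = rng.normal(size=(11, 5))
    W2 = rng.normal(size=(5, 11))
    b1 = rng.normal(size=5)
    b2 = rng.normal(size=11)
    m.params["attn.W1"], m.params["attn.W2"] = W1, W2
    m.params["attn.b1"], m.params["attn.b2"] = b1, b2
    F = rng.normal(size=(11, 2))
    # hand evaluation of sigmoid(MLP(avg) + MLP(max))
    avg, mx = F.mean(axis=1), F.max(axis=1)
    mlp = lambda u: np.maximum(u @ W1 + b1, 0.0) @ W2 + b2
    expected = 1 / (1 + np.exp(-(mlp(avg) + mlp(mx))))
    np.testing.assert_allclose(
        m.stage_attention(F).raw_scores, expected, atol=1e-10
    )


def test_attention_scores_strictly_in_unit_interval():
    m = _small_model(seed=2)
    rng = np.random.default_rng(7)
    scores = m.stage_attention_batch(rng.normal(size=(8, 11, 6), scale=5))
    assert np.all(scores > 0) and np.all(scores < 1)


def test_attention_permutation_equivariance():
    """Permuting the stage axis of the features together with the attention
    block's stage channels permutes the scores identically."""
    m = _small_model(seed=5)
    rng = np.random.default_rng(11)
    F = rng.normal(size=(4, 11, 6))
    scores = m.stage_attention_batch(F)
    perm = rng.permutation(11)
    m.params["attn.W1"] = m.params["attn.W1"][perm]
    m.params["attn.W2"] = m.params["attn.W2"][:, perm]
    m.params["attn.b2"] = m.params["attn.b2"][perm]
    permuted = m.stage_attention_batch(F[:, perm])
    np.testing.assert_allclose(permuted, scores[:, perm], atol=1e-12)


def test_apply_attention_scaling():
    F = np.ones((11, 4))
    ones = AttentionProfile(np.full(11, 1 - 1e-12))
    np.testing.assert_allclose(
        ss.StageAttentionClassifier.apply_attention(F, ones), 1.0
    )
    scores = np.full(11, 0.5)
    out = ss.StageAttentionClassifier.apply_attention(F, scores)
    assert out.shape == (44,)
    np.testing.assert_allclose(out, 0.5)


# -- classification head -----------------------------------------------------

def test_softmax_closed_forms():
    np.testing.assert_allclose(nn.softmax(np.zeros(3)), 1 / 3, atol=1e-12)
    np.testing.assert_allclose(
        nn.softmax(np.array([np.log(2), 0.0, 0.0])),
        [0.5, 0.25, 0.25],
        atol=1e-12,
    )


def test_classify_with_hand_set_head():
    m = _small_model(seed=6, hidden=1)
    d_flat = 11 * 2
    rng = np.random.default_rng(9)
    W1 = rng.normal(size=(d_flat, 5))
    b1 = rng.normal(size=5)
    W2 = rng.normal(size=(5, 3))
    b2 = rng.normal(size=3)
    m.params.update({"head.W1": W1, "head.b1": b1,
                     "head.W2": W2, "head.b2": b2})
    v = rng.normal(size=d_flat)
    logits = np.maximum(v @ W1 + b1, 0.0) @ W2 + b2
    expected = np.exp(logits - logits.max())
    expected /= expected.sum()
    pred = m.classify(v)
    np.testing.assert_allclose(pred.probabilities, expected, atol=1e-12)
    assert pred.predicted_label is ss.Label(
        ["NORMAL", "ADHD_RISK", "ADHD"][int(np.argmax(expected))]
    )


def test_classify_zero_input_zero_weights_is_uniform():
    m = _small_model(seed=0, hidden=1)
    for k in ("head.W1", "head.b1", "head.W2", "head.b2"):
        m.params[k] = np.zeros_like(m.params[k])
    pred = m.classify(np.zeros(22))
    np.testing.assert_allclose(pred.probabilities, 1 / 3, atol=1e-12)


# -- stage encoder -----------------------------------------------------------

def _naive_lstm(x, Wx, Wh, b, hidden):
    """Independent single-sequence LSTM unroll (explicit python loop)."""
    h = np.zeros(hidden)
    c = np.zeros(hidden)
    sig = lambda v: 1 / (1 + np.exp(-v))
    for t in range(x.shape[0]):
        z = x[t] @ Wx + h @ Wh + b
        i = sig(z[:hidden])
        f = sig(z[hidden : 2 * hidden])
        g = np.tanh(z[2 * hidden : 3 * hidden])
        o = sig(z[3 * hidden :])
        c = f * c + i * g
        h = o * np.tanh(c)
    return h


def test_encode_stage_matches_hand_unrolled_recurrence():
    hidden = 2
    m = _small_model(seed=8, hidden=hidden)
    rng = np.random.default_rng(21)
    seq = rng.normal(size=(3, 54))
    stage = 4
    Wxf = m.params["lstm.0.fw.Wx"][stage]
    Whf = m.params["lstm.0.fw.Wh"][stage]
    bf = m.params["lstm.0.fw.b"][stage]
    Wxb = m.params["lstm.0.bw.Wx"][stage]
    Whb = m.params["lstm.0.bw.Wh"][stage]
    bb = m.params["lstm.0.bw.b"][stage]
    expected = np.concatenate(
        [
            _naive_lstm(seq, Wxf, Whf, bf, hidden),
            _naive_lstm(seq[::-1], Wxb, Whb, bb, hidden),
        ]
    )
    feature = m.encode_stage(seq, true_length=3, stage=stage)
    assert feature.shape == (2 * hidden,)
    np.testing.assert_allclose(feature, expected, atol=1e-12)


def test_encoder_zero_sequence_zero_params_gives_zero_feature():
    m = _small_model(seed=0, hidden=2)
    for k in list(m.params):
        if k.startswith("lstm.0."):
            m.params[k] = np.zeros_like(m.params[k])
    feature = m.encode_stage(np.zeros((5, 54)), true_length=5, stage=0)
    np.testing.assert_allclose(feature, 0.0, atol=1e-15)


def test_feature_dimension_is_twice_hidden():
    m = _small_model(seed=0, hidden=7)
    f = m.encode_stage(np.zeros((4, 54)), true_length=4, stage=2)
    assert f.shape == (14,)


# -- end-to-end training mechanics -------------------------------------------

def test_gradients_match_finite_differences(tiny_sessions):
    sessions = tiny_sessions[:2]
    refs = ss.compute_reference_lengths(sessions)
    batch = ss.pad_sessions(sessions, refs)
    m = ss.StageAttentionClassifier(
        ss.ModelConfig(hidden_size=3, num_recurrent_layers=2,
                       head_hidden=4, seed=7)
    )
    w = np.array([1.0, 2.0, 0.5])
    _, grads = m.loss_and_grads(batch, w)
    eps = 1e-6
    rng = np.random.default_rng(0)
    for name in ("attn.W1", "attn.W2", "attn.b1", "attn.b2",
                 "head.W1", "lstm.0.fw.Wx", "lstm.1.bw.Wh"):
        P = m.params[name]
        flat_idx = rng.choice(P.size, size=min(4, P.size), replace=False)
        for fi in flat_idx:
            ix = np.unravel_index(fi, P.shape)
            orig = P[ix]
            P[ix] = orig + eps
            lp, _ = m.loss_and_grads(batch, w)
            P[ix] = orig - eps
            lm, _ = m.loss_and_grads(batch, w)
            P[ix] = orig
            numeric = (lp - lm) / (2 * eps)
            denom = max(abs(numeric), abs(grads[name][ix]))
            # rtol 1e-4 with an absolute floor for gradients too small
            # for central differences at eps=1e-6 to resolve relatively
            assert abs(numeric - grads[name][ix]) < 1e-4 * denom + 1e-9


def test_training_is_deterministic(tiny_sessions, tiny_config):
    refs = ss.compute_reference_lengths(tiny_sessions)
    batch = ss.pad_sessions(tiny_sessions, refs)
    runs = []
    for _ in range(2):
        m = ss.StageAttentionClassifier(tiny_config)
        m.fit(batch)
        runs.append(m.predict_proba(batch))
    np.testing.assert_array_equal(runs[0], runs[1])


def test_checkpoint_roundtrip(tmp_path, tiny_sessions, tiny_config):
    refs = ss.compute_reference_lengths(tiny_sessions)
    batch = ss.pad_sessions(tiny_sessions, refs)
    m = ss.StageAttentionClassifier(tiny_config)
    m.fit(batch)
    path = tmp_path / "model.ckpt"
    m.save(path)
    loaded = ss.StageAttentionClassifier.load(path)
    assert loaded.config == m.config
    np.testing.assert_array_equal(
        loaded.predict_proba(batch), m.predict_proba(batch)
    )


def test_ablation_without_attention_trains_and_predicts(
    tiny_sessions, tiny_config
):
    import dataclasses

    cfg = dataclasses.replace(tiny_config, use_attention=False)
    refs = ss.compute_reference_lengths(tiny_sessions)
    batch = ss.pad_sessions(tiny_sessions, refs)
    m = ss.StageAttentionClassifier(cfg)
    m.fit(batch)
    assert len(m.predict(batch)) == 6
    with pytest.raises(RuntimeError):
        m.attention_profiles(batch)


def test_attention_profiles_percent_normalized(tiny_sessions, tiny_config):
    refs = ss.compute_reference_lengths(tiny_sessions)
    batch = ss.pad_sessions(tiny_sessions, refs)
    m = ss.StageAttentionClassifier(tiny_config)
    m.fit(batch)
    for profile in m.attention_profiles(batch):
        assert np.all(profile.raw_scores > 0)
        assert np.all(profile.raw_scores < 1)
        assert profile.percent_scores.sum() == pytest.approx(100.0, abs=1e-9)
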