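"""Encoder contracts, attention pooling, contrastive scoring and lead
adaptation."""

import numpy as np
import pytest

from ecgtl import (AttentionPoolSpec, ClassifierModel, CpcModel, ModelSpec,
                   adapt_input_channels, build_encoder, classify,
                   cpc_probabilities, load_checkpoint, replace_head,
                   save_checkpoint)
from ecgtl import nn
from ecgtl.models import adapt_encoder_channels, transfer_encoder_weights


def test_encoder_feature_size_scales_with_width_and_depth():
    enc = build_encoder(ModelSpec(depth=18, width_multiplier=0.125),
                        rng=np.random.default_rng(0))
    x = np.random.default_rng(1).standard_normal((2, 1, 1024)).astype(np.float32)
    y = enc.forward(x, train=False)
    assert y.shape == (2, 64)  # 512 * 0.125
    enc50 = build_encoder(ModelSpec(depth=50, width_multiplier=0.125),
                          rng=np.random.default_rng(0))
    assert enc50.out_features == 256  # bottleneck expansion x4


def test_truncated_depth50_outputs_stage3_width():
    enc = build_encoder(ModelSpec(depth=50, width_multiplier=0.125, stages_used=3),
                        rng=np.random.default_rng(0))
    assert enc.out_features == 32 * 4  # stage-3 bottleneck channels
    x = np.random.default_rng(1).standard_normal((1, 1, 512)).astype(np.float32)
    assert enc.forward(x, train=False).shape == (1, 128)


def test_batch_order_equivariance():
    enc = build_encoder(ModelSpec(depth=18, width_multiplier=0.0625),
                        rng=np.random.default_rng(2))
    x = np.random.default_rng(3).standard_normal((4, 1, 512)).astype(np.float32)
    y = enc.forward(x, train=False)
    perm = [2, 0, 3, 1]
    y_perm = enc.forward(x[perm], train=False)
    np.testing.assert_allclose(y_perm, y[perm], atol=1e-5)


def test_parameter_count_grows_with_depth():
    counts = {d: build_encoder(ModelSpec(depth=d, width_multiplier=0.25),
                               rng=np.random.default_rng(0)).n_params()
              for d in (18, 34, 50)}
    assert counts[18] < counts[34] < counts[50]


def test_invalid_depth_rejected():
    with pytest.raises(ValueError):
        ModelSpec(depth=20)


def test_classifier_probabilities_normalise():
    enc = build_encoder(ModelSpec(depth=18, width_multiplier=0.0625),
                        rng=np.random.default_rng(4))
    model = ClassifierModel(enc, 4, rng=np.random.default_rng(5))
    x = np.random.default_rng(6).standard_normal((8, 1, 512)).astype(np.float32)
    p = classify(model, x)
    assert p.shape == (8, 4)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_untrained_classifier_is_at_chance_on_balanced_classes():
    enc = build_encoder(ModelSpec(depth=18, width_multiplier=0.0625),
                        rng=np.random.default_rng(7))
    model = ClassifierModel(enc, 4, rng=np.random.default_rng(8))
    rng = np.random.default_rng(9)
    x = rng.standard_normal((2000, 1, 256)).astype(np.float32)
    y = rng.integers(0, 4, 2000)
    acc = float((model.forward(x, train=False).argmax(axis=1) == y).mean())
    assert abs(acc - 0.25) < 0.05


# ------------------------------------------------------------- attention pool

def test_attention_pool_output_size_and_determinism():
    pool = nn.AttentionPool(64, n_heads=8, n_layers=3, max_len=16,
                            rng=np.random.default_rng(10))
    x = np.random.default_rng(11).standard_normal((3, 8, 64)).astype(np.float32)
    c1 = pool.forward(x, train=False)
    c2 = pool.forward(x, train=False)
    assert c1.shape == (3, 64)
    np.testing.assert_array_equal(c1, c2)


def test_pooling_without_positions_is_permutation_invariant():
    pool = nn.AttentionPool(32, n_heads=4, n_layers=2, max_len=16,
                            use_positional=False, rng=np.random.default_rng(12))
    x = np.random.default_rng(13).standard_normal((2, 6, 32)).astype(np.float64)
    c = pool.forward(x, train=False)
    c_perm = pool.forward(x[:, [3, 1, 5, 0, 4, 2], :], train=False)
    np.testing.assert_allclose(c_perm, c, atol=1e-8)
    # with positions enabled the order matters
    pool_pos = nn.AttentionPool(32, n_heads=4, n_layers=2, max_len=16,
                                use_positional=True, rng=np.random.default_rng(12))
    assert not np.allclose(pool_pos.forward(x, train=False),
                           pool_pos.forward(x[:, ::-1, :], train=False))


def test_empty_context_rejected():
    pool = nn.AttentionPool(16, n_heads=2, n_layers=1,
                            rng=np.random.default_rng(14))
    with pytest.raises(ValueError):
        pool.forward(np.zeros((2, 0, 16)), train=False)


# ------------------------------------------------------------- CPC scoring

def test_identical_candidates_give_uniform_probabilities():
    c = np.random.default_rng(15).standard_normal(32)
    h = np.tile(np.random.default_rng(16).standard_normal(32), (5, 1))
    p = cpc_probabilities(c, h)
    np.testing.assert_allclose(p, 0.2, atol=1e-12)


def test_aligned_candidate_dominates_in_the_limit():
    rng = np.random.default_rng(17)
    c = np.zeros(8)
    c[0] = 50.0
    h = np.zeros((4, 8))
    h[2, 0] = 1.0  # aligned with c
    h[0, 1] = h[1, 2] = h[3, 3] = 1.0  # orthogonal
    p = cpc_probabilities(c, h)
    assert p[2] > 0.999


def test_probabilities_sum_to_one_for_random_inputs():
    rng = np.random.default_rng(18)
    for _ in range(20):
        p = cpc_probabilities(rng.standard_normal((3, 16)),
                              rng.standard_normal((3, 7, 16)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


def test_loss_invariant_to_permuting_negatives():
    rng = np.random.default_rng(19)
    c = rng.standard_normal(16)
    h = rng.standard_normal((6, 16))  # index 0 positive
    p = cpc_probabilities(c, h)
    loss = -np.log(p[0])
    perm = [0, 3, 1, 5, 2, 4]  # positive stays at 0
    p2 = cpc_probabilities(c, h[perm])
    np.testing.assert_allclose(-np.log(p2[0]), loss, atol=1e-12)


def test_cpc_model_end_to_end_shapes():
    enc = build_encoder(ModelSpec(depth=18, width_multiplier=0.0625),
                        rng=np.random.default_rng(20))
    model = CpcModel(enc, context_size=4,
                     pool_spec=AttentionPoolSpec(d_model=enc.out_features,
                                                 n_heads=4, n_layers=1, max_len=8),
                     rng=np.random.default_rng(21))
    frames = np.random.default_rng(22).standard_normal((2, 4 + 1 + 3, 1, 256)
                                                       ).astype(np.float32)
    logits = model.forward(frames, train=False)
    assert logits.shape == (2, 4)
    p = nn.softmax(logits)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


# ------------------------------------------------------------- lead adaptation

def test_filter_duplication_and_scaling():
    w = np.full((1, 1, 1), 0.6)
    w12 = adapt_input_channels(w, 12)
    assert w12.shape == (1, 12, 1)
    np.testing.assert_allclose(w12, 0.05)
    np.testing.assert_allclose(adapt_input_channels(w, 1), w)
    with pytest.raises(ValueError):
        adapt_input_channels(w, 0)


@pytest.mark.parametrize("depth", [18, 34, 50])
def test_replicated_input_through_adapted_layer_matches_original(depth):
    rng = np.random.default_rng(23 + depth)
    enc = build_encoder(ModelSpec(depth=depth, width_multiplier=0.125), rng=rng)
    x = rng.standard_normal((2, 1, 512)).astype(np.float32)
    y1 = enc.stem_conv.forward(x, train=False)
    adapt_encoder_channels(enc, 12)
    y12 = enc.stem_conv.forward(np.repeat(x, 12, axis=1), train=False)
    np.testing.assert_allclose(y12, y1, atol=1e-5)


# ------------------------------------------------------------- heads

def test_replace_head_keeps_encoder_weights_bit_identical():
    enc = build_encoder(ModelSpec(depth=18, width_multiplier=0.0625),
                        rng=np.random.default_rng(30))
    pretrained = ClassifierModel(enc, 4, rng=np.random.default_rng(31))
    before = {i: p.data.copy() for i, p in enumerate(enc.params())}
    new = replace_head(pretrained, 3, output_activation="sigmoid",
                       rng=np.random.default_rng(32))
    assert new.n_classes == 3
    assert new.activation == "sigmoid"
    for i, p in enumerate(new.encoder.params()):
        np.testing.assert_array_equal(p.data, before[i])
    with pytest.raises(ValueError):
        replace_head(pretrained, 1)


def test_sigmoid_head_outputs_independent_unit_interval():
    enc = build_encoder(ModelSpec(depth=18, width_multiplier=0.0625),
                        rng=np.random.default_rng(33))
    model = ClassifierModel(enc, 5, activation="sigmoid",
                            rng=np.random.default_rng(34))
    x = np.random.default_rng(35).standard_normal((4, 1, 256)).astype(np.float32)
    p = model.predict_proba(x)
    assert p.shape == (4, 5)
    assert np.all((p >= 0) & (p <= 1))


def test_truncated_pretrain_leaves_stage4_fresh():
    spec3 = ModelSpec(depth=50, width_multiplier=0.0625, stages_used=3)
    src = build_encoder(spec3, rng=np.random.default_rng(36))
    dst = build_encoder(ModelSpec(depth=50, width_multiplier=0.0625),
                        rng=np.random.default_rng(37))
    stage4_before = [p.data.copy() for b in dst.stages[3] for p in b.params()]
    copied = transfer_encoder_weights(src, dst)
    assert copied == 3
    # stages 1-3 copied
    for bs, bd in zip(src.stages[2], dst.stages[2]):
        for ps, pd in zip(bs.params(), bd.params()):
            np.testing.assert_array_equal(ps.data, pd.data)
    # stage 4 untouched (fresh initialisation)
    for before, p in zip(stage4_before,
                         [p for b in dst.stages[3] for p in b.params()]):
        np.testing.assert_array_equal(before, p.data)


# ------------------------------------------------------------- checkpoints

def test_checkpoint_round_trip(tmp_path):
    spec = ModelSpec(depth=18, width_multiplier=0.0625)
    enc = build_encoder(spec, rng=np.random.default_rng(38))
    save_checkpoint(tmp_path / "enc.npz", enc, spec=spec, extra={"task": "beat"})
    enc2 = build_encoder(spec, rng=np.random.default_rng(39))
    meta = load_checkpoint(tmp_path / "enc.npz", enc2, expect_spec=spec)
    assert meta["extra"]["task"] == "beat"
    x = np.random.default_rng(40).standard_normal((1, 1, 256)).astype(np.float32)
    np.testing.assert_array_equal(enc.forward(x, train=False),
                                  enc2.forward(x, train=False))
    wrong = ModelSpec(depth=34, width_multiplier=0.0625)
    enc3 = build_encoder(wrong, rng=np.random.default_rng(41))
    with pytest.raises(ValueError):
        load_checkpoint(tmp_path / "enc.npz", enc3, expect_spec=wrong)
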