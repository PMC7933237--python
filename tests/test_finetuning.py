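"""Downstream preprocessing, splitting, the finetuning loop and the
repeated-evaluation protocol."""

import numpy as np
import pytest

from ecgtl import (DownstreamRecord, ECGClassifier, FinetuneConfig, ModelSpec,
                   build_encoder, fold_split, generate_downstream_set,
                   preprocess_downstream, prepare_downstream,
                   repeated_evaluation, resample, stratified_split)
from ecgtl.finetuning import downstream_stats


# ------------------------------------------------------------- resampling

def test_resample_lengths():
    x = np.zeros(18000)
    assert resample(x, 300.0, 250.0).shape[-1] == 15000
    y = np.random.default_rng(0).standard_normal(1000)
    np.testing.assert_array_equal(resample(y, 250.0, 250.0), y)
    with pytest.raises(ValueError):
        resample(y, 0.0, 250.0)


def test_resampled_sinusoid_matches_analytic_form():
    t_in = np.arange(3000) / 300.0
    x = np.sin(2 * np.pi * 10.0 * t_in)
    y = resample(x, 300.0, 250.0)
    t_out = np.arange(len(y)) / 250.0
    expect = np.sin(2 * np.pi * 10.0 * t_out)
    trim = 50  # edge effects of the polyphase filter
    assert np.abs(y[trim:-trim] - expect[trim:-trim]).max() < 1e-2


# ------------------------------------------------------------- preprocessing

def _record(duration_s, fs=300.0, leads=1, value=1.0):
    n = int(duration_s * fs)
    return DownstreamRecord(record_id="r", signal=np.full((leads, n), value),
                            fs=fs, labels=["NORMAL"])


def test_short_record_is_zero_padded_to_uniform_length():
    rec = _record(9.0)
    cfg = FinetuneConfig()
    x = preprocess_downstream(rec, cfg, stats=(0.0, 1.0))
    assert x.shape[-1] == 15000  # 60 s at 250 Hz
    assert np.all(x[..., -12750:] == 0.0)  # only the first 9 s carry signal
    assert not np.all(x[..., :2250] == 0.0)


def test_full_length_record_needs_no_padding():
    x = preprocess_downstream(_record(60.0), FinetuneConfig(), stats=(0.0, 1.0))
    assert x.shape[-1] == 15000
    assert x[..., -1] != 0.0


def test_low_rate_profile_keeps_relative_length():
    cfg = FinetuneConfig(target_fs=128.0)
    x = preprocess_downstream(_record(9.0), cfg, stats=(0.0, 1.0))
    assert x.shape[-1] == 7680  # 60 s at 128 Hz


def test_overlong_record_is_tail_truncated():
    cfg = FinetuneConfig(target_len_s=10.0)
    x = preprocess_downstream(_record(30.0), cfg, stats=(0.0, 1.0))
    assert x.shape[-1] == 2500


def test_dataset_stats_pool_all_samples():
    recs = [_record(1.0, value=2.0), _record(1.0, value=4.0)]
    mean, std = downstream_stats(recs)
    assert mean == pytest.approx(3.0)
    assert std == pytest.approx(1.0)


# ------------------------------------------------------------- splitting

def test_single_class_split_fractions():
    tr, va, te = stratified_split(["A"] * 100, (0.75, 0.05, 0.20), seed=0)
    assert (len(tr), len(va), len(te)) == (75, 5, 20)
    assert not set(tr) & set(va) and not set(tr) & set(te) and not set(va) & set(te)
    assert sorted([*tr, *va, *te]) == list(range(100))


def test_split_keeps_class_ratio_within_one_record():
    rng = np.random.default_rng(1)
    labels = rng.choice(list("ABCD"), 200, p=[0.5, 0.25, 0.15, 0.1])
    tr, va, te = stratified_split(labels, (0.75, 0.05, 0.20), seed=2)
    for cls in "ABCD":
        total = (labels == cls).sum()
        for part, frac in ((tr, 0.75), (va, 0.05), (te, 0.20)):
            got = (labels[part] == cls).sum()
            assert abs(got - frac * total) <= 1


def test_too_small_class_is_rejected():
    with pytest.raises(ValueError, match="too few"):
        stratified_split(["A"] * 50 + ["B"], (0.75, 0.05, 0.20), seed=0)


def test_fold_split_partitions_everything():
    tr, va, te = fold_split(103, seed=3)
    assert sorted([*tr, *va, *te]) == list(range(103))
    assert len(va) > 0 and len(te) > 0
    assert len(tr) > len(va) + len(te)


# ------------------------------------------------------------- finetuning loop

@pytest.fixture(scope="module")
def tiny_downstream():
    recs = generate_downstream_set(
        60, "cinc2017", {"NORMAL": 0.5, "AF": 0.3, "OTHER": 0.0, "NOISY": 0.2},
        seed=4, duration_range_s=(9.0, 12.0))
    cfg = FinetuneConfig(target_len_s=12.0, batch_size=8, seed=0)
    X = prepare_downstream(recs, cfg)
    y = np.array([r.labels[0] for r in recs])
    return X, y


def test_early_stop_interrupts_on_training_plateau(tiny_downstream):
    X, y = tiny_downstream
    clf = ECGClassifier(depth=18, width_multiplier=0.03125, max_epochs=100,
                        early_stop_patience=3, batch_size=8,
                        learning_rate=0.0,  # frozen model cannot improve
                        random_state=0)
    clf.fit(X[:32], y[:32], X_val=X[32:40], y_val=y[32:40])
    assert clf.n_epochs_ < 100


def test_checkpoint_integrity_reproduces_best_validation_metric(tiny_downstream):
    from ecgtl.metrics import macro_f1
    X, y = tiny_downstream
    clf = ECGClassifier(depth=18, width_multiplier=0.0625, max_epochs=4,
                        early_stop_patience=3, batch_size=8, random_state=1)
    clf.fit(X[:40], y[:40], X_val=X[40:52], y_val=y[40:52])
    recorded = max(clf.history_["val_metric"])
    pred = clf.predict(X[40:52])
    re_eval, _ = macro_f1(y[40:52], pred, classes=list(clf.classes_))
    assert re_eval == pytest.approx(recorded)


def test_repeated_evaluation_protocol_shape(tiny_downstream):
    X, y = tiny_downstream
    cfg = FinetuneConfig(max_epochs=1, early_stop_patience=0, n_runs=3,
                         target_len_s=12.0, batch_size=8, seed=7)
    spec = ModelSpec(depth=18, width_multiplier=0.03125)
    rep = repeated_evaluation(None, X, y, cfg, model_spec=spec)
    assert len(rep.runs) == 3
    test_idx = rep.config["test_indices"]
    assert len(test_idx) == 12  # 20% of 60
    means, stds = rep.mean(), rep.std()
    for m in rep.metric_names:
        vals = [r[m] for r in rep.runs]
        assert means[m] == pytest.approx(np.mean(vals), abs=1e-12)
        assert stds[m] == pytest.approx(np.std(vals), abs=1e-12)


def test_multi_label_head_and_adaptation_run_end_to_end():
    recs = generate_downstream_set(24, "multilabel12", seed=8)
    vocab = sorted({l for r in recs for l in r.labels})
    y = np.array([[1 if v in r.labels else 0 for v in vocab] for r in recs])
    cfg = FinetuneConfig(target_len_s=10.0, batch_size=8, seed=0)
    X = prepare_downstream(recs, cfg)
    assert X.shape[1] == 12
    enc = build_encoder(ModelSpec(depth=18, width_multiplier=0.03125),
                        rng=np.random.default_rng(9))
    clf = ECGClassifier(init_encoder=enc, depth=18, width_multiplier=0.03125,
                        multi_label=True, max_epochs=2, early_stop_patience=1,
                        batch_size=8, random_state=2)
    clf.fit(X[:16], y[:16], X_val=X[16:20], y_val=y[16:20])
    proba = clf.predict_proba(X[20:])
    assert proba.shape == (4, len(vocab))
    assert np.all((proba >= 0) & (proba <= 1))
    # the adapted stem still satisfies the replication identity
    stem = clf.model_.encoder.stem_conv
    assert stem.in_channels == 12
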