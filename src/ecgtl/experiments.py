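"""Desk-scale reference experiments.

These functions run the package's main computations end-to-end on
synthetic corpora at sizes a workstation CPU handles in minutes: tiny
encoder widths (1/8 of the full stage widths), 20-24 patients upstream,
and a few hundred downstream records. Both the test suite and the
reproduction script call them; all randomness derives from one seed.
"""

from __future__ import annotations

import numpy as np

from .finetuning import (ECGClassifier, FinetuneConfig, prepare_downstream,
                         repeated_evaluation, stratified_split)
from .framing import (Frame, label_beat, label_heart_rate, label_rhythm,
                      sample_frame)
from .models import ModelSpec, build_encoder
from .pretraining import FramePretrainer
from .synth import (GenParams, child_seed, generate_downstream_set,
                    generate_upstream_corpus, render_beat_train)
from .types import BeatClass, Corpus, HeartRateClass, RhythmClass

DESK_WIDTH = 0.125


def labeler_equivalence(n_frames: int = 500, seed: int = 0) -> dict[str, float]:
    """Accuracy of each labeler on frames with a planted class.

    Recordings are rendered with generator parameters that pin the
    label: pure-rhythm plans for the rhythm task, forced abnormal-beat
    rates for the beat task, well-separated heart rates for the rate
    task. Ground-truth beat positions are used for the heart-rate task.
    """
    fs = 250.0
    frame_len = 2048
    base = GenParams(pac_rate=0.0, pvc_rate=0.0, aberration_rate=0.0)

    def frames_of(rec, n, rng):
        return [Frame(rec, int(rng.integers(rec.n_samples - frame_len + 1)),
                      frame_len) for n_ in range(n)]

    rng = np.random.default_rng(child_seed(seed, 50))
    results: dict[str, float] = {}

    # beat task: abnormal-rate 1.0 pins every beat's class
    beat_cases = {
        BeatClass.NORMAL: base,
        BeatClass.PVC: GenParams(pvc_rate=1.0, pac_rate=0.0, aberration_rate=0.0),
        BeatClass.PAC: GenParams(pac_rate=1.0, pvc_rate=0.0, aberration_rate=0.0),
        BeatClass.ABERRATION: GenParams(aberration_rate=1.0, pac_rate=0.0,
                                        pvc_rate=0.0),
    }
    per = -(-n_frames // len(beat_cases))
    correct = total = 0
    for planted, params in beat_cases.items():
        rec = render_beat_train([(RhythmClass.NSR, 60.0)], params, fs=fs, rng=rng)
        for f in frames_of(rec, per, rng):
            correct += label_beat(f) is planted
            total += 1
    results["beat"] = correct / total

    # rhythm task: single-rhythm recordings
    per = -(-n_frames // 4)
    correct = total = 0
    for planted in RhythmClass:
        rec = render_beat_train([(planted, 60.0)], base, fs=fs, rng=rng)
        for f in frames_of(rec, per, rng):
            correct += label_rhythm(f) is planted
            total += 1
    results["rhythm"] = correct / total

    # heart-rate task: rates far from the class boundaries
    rate_cases = {
        HeartRateClass.BRADY: (RhythmClass.NSR, 60.0 / 45.0),
        HeartRateClass.NORMAL: (RhythmClass.NSR, 60.0 / 75.0),
        HeartRateClass.TACHY: (RhythmClass.NSR, 60.0 / 130.0),
        HeartRateClass.NOISE: (RhythmClass.NOISE, None),
    }
    per = -(-n_frames // 4)
    correct = total = 0
    for planted, (rhythm, ibi) in rate_cases.items():
        params = base if ibi is None else GenParams(
            nsr_ibi_mean=ibi, nsr_ibi_jitter=0.02,
            pac_rate=0.0, pvc_rate=0.0, aberration_rate=0.0)
        rec = render_beat_train([(rhythm, 60.0)], params, fs=fs, rng=rng)
        for f in frames_of(rec, per, rng):
            correct += label_heart_rate(f, beat_source="ground_truth") is planted
            total += 1
    results["heart_rate"] = correct / total
    return results


def channel_adaptation_error(depths=(18, 34, 50), width: float = 0.25,
                             n_leads: int = 12, seed: int = 0) -> float:
    """Worst-case deviation of the lead-adaptation identity.

    For every depth, random stem weights are adapted from 1 to
    ``n_leads`` channels and a single-lead input replicated across all
    leads is compared against the original single-channel output.
    """
    from .models import adapt_input_channels
    from . import nn

    worst = 0.0
    for d_i, depth in enumerate(depths):
        rng = np.random.default_rng(child_seed(seed, 60 + d_i))
        enc = build_encoder(ModelSpec(depth=depth, width_multiplier=width),
                            rng=rng)
        x1 = rng.standard_normal((2, 1, 1024)).astype(np.float32)
        y1 = enc.stem_conv.forward(x1, train=False)
        conv12 = nn.Conv1d(n_leads, enc.stem_conv.out_channels, 7, stride=2,
                           rng=rng)
        conv12.w.data = adapt_input_channels(enc.stem_conv.w.data,
                                             n_leads).astype(np.float32)
        y12 = conv12.forward(np.repeat(x1, n_leads, axis=1), train=False)
        worst = max(worst, float(np.abs(y12 - y1).max()))
    return worst


def pretrain_heart_rate(seed: int = 0, n_patients: int = 20, max_steps: int = 600,
                        width: float = DESK_WIDTH) -> FramePretrainer:
    """Supervised heart-rate pretraining on a small synthetic corpus."""
    corpus = generate_upstream_corpus(n_patients, 2, 60.0,
                                      seed=child_seed(seed, 70))
    est = FramePretrainer(task="heart_rate", frame_length=2048, depth=18,
                          width_multiplier=width, batch_size=32,
                          max_steps=max_steps, checkpoint_interval_steps=100,
                          val_frames=128, val_patient_fraction=0.1,
                          random_state=child_seed(seed, 71))
    return est.fit(corpus)


def cpc_untrained_accuracy(seed: int = 0, n_examples: int = 500,
                           width: float = DESK_WIDTH) -> float:
    """Positive-identification accuracy of an untrained contrastive model."""
    corpus = generate_upstream_corpus(12, 2, 60.0, seed=child_seed(seed, 80))
    est = FramePretrainer(task="future_prediction", frame_length=512, depth=18,
                          width_multiplier=width, context_size=8, ns=4, offset=2,
                          batch_size=16, max_steps=1, checkpoint_interval_steps=1,
                          val_frames=n_examples, val_patient_fraction=0.25,
                          random_state=child_seed(seed, 81), learning_rate=0.0)
    est.fit(corpus)
    # learning rate 0: the recorded accuracy is that of the initial weights
    return est.history_.val_accuracy[0]


def pretrain_cpc(seed: int = 0, n_patients: int = 32, max_steps: int = 800,
                 width: float = DESK_WIDTH) -> FramePretrainer:
    """Contrastive future-prediction pretraining (K=8, ns=4, offset=2,
    frame 512) on a small synthetic corpus."""
    corpus = generate_upstream_corpus(n_patients, 2, 60.0,
                                      seed=child_seed(seed, 82))
    est = FramePretrainer(task="future_prediction", frame_length=512, depth=18,
                          width_multiplier=width, context_size=8, ns=4, offset=2,
                          batch_size=16, max_steps=max_steps,
                          checkpoint_interval_steps=100, val_frames=96,
                          val_patient_fraction=0.25,
                          random_state=child_seed(seed, 83))
    return est.fit(corpus)


def make_transfer_data(seed: int = 0, n_records: int = 160,
                       target_len_s: float = 20.0):
    """Synthetic single-lead downstream set, preprocessed, with splits."""
    recs = generate_downstream_set(
        n_records, "cinc2017",
        {"NORMAL": 0.4, "AF": 0.25, "OTHER": 0.25, "NOISY": 0.1},
        seed=child_seed(seed, 90), duration_range_s=(9.0, 20.0))
    cfg = FinetuneConfig(target_len_s=target_len_s, batch_size=16,
                         seed=child_seed(seed, 91))
    X = prepare_downstream(recs, cfg)
    y = np.array([r.labels[0] for r in recs])
    splits = stratified_split(y, (0.75, 0.05, 0.20), seed=child_seed(seed, 92))
    return X, y, splits, cfg


def transfer_comparison(seed: int = 0, pretrain_steps: int = 400,
                        n_seeds: int = 5, eval_epoch: int = 5,
                        width: float = DESK_WIDTH) -> dict:
    """Early-epoch transfer gap: rhythm-pretrained vs random init.

    Both initialisations are finetuned for ``eval_epoch`` epochs with
    ``n_seeds`` seeds each; the validation macro F1 at the final epoch
    is averaged per group.
    """
    corpus = generate_upstream_corpus(20, 2, 60.0, seed=child_seed(seed, 95))
    pre = FramePretrainer(task="rhythm", frame_length=2048, depth=18,
                          width_multiplier=width, batch_size=32,
                          max_steps=pretrain_steps, checkpoint_interval_steps=100,
                          val_frames=128, val_patient_fraction=0.1,
                          random_state=child_seed(seed, 96))
    pre.fit(corpus)
    X, y, (tr, va, te), _ = make_transfer_data(seed)

    def epoch5_f1(init, s):
        clf = ECGClassifier(init_encoder=init, depth=18, width_multiplier=width,
                            max_epochs=eval_epoch, early_stop_patience=eval_epoch - 1,
                            batch_size=16, random_state=child_seed(seed, 97 + s))
        clf.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
        return clf.history_["val_metric"][eval_epoch - 1]

    pre_scores = [epoch5_f1(pre.encoder_, s) for s in range(n_seeds)]
    rnd_scores = [epoch5_f1(None, s) for s in range(n_seeds)]
    return {
        "pretrain_val_accuracy": pre.best_val_accuracy_,
        "pretrained_scores": pre_scores,
        "random_scores": rnd_scores,
        "pretrained_mean": float(np.mean(pre_scores)),
        "random_mean": float(np.mean(rnd_scores)),
        "encoder": pre.encoder_,
        "data": (X, y, (tr, va, te)),
    }


def transfer_smoke_report(encoder, X, y, seed: int = 0, n_runs: int = 3,
                          max_epochs: int = 8, width: float = DESK_WIDTH):
    """Short repeated-evaluation report on the synthetic downstream set."""
    cfg = FinetuneConfig(max_epochs=max_epochs, early_stop_patience=max_epochs - 1,
                         n_runs=n_runs, target_len_s=20.0, batch_size=16,
                         seed=child_seed(seed, 99))
    spec = ModelSpec(depth=18, width_multiplier=width)
    return repeated_evaluation(encoder, X, y, cfg, model_spec=spec)
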