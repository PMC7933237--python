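"""Frame sampling, standardization, the three labeling rules, the QRS
detector and contrastive example geometry."""

import dataclasses

import numpy as np
import pytest

from ecgtl import (AnnotatedRecording, BeatClass, Corpus, Frame, GenParams,
                   HeartRateClass, HeartRateRule, RhythmClass, UnlabelableFrame,
                   detect_beats, estimate_bpm, label_beat, label_heart_rate,
                   label_rhythm, make_cpc_example, render_beat_train,
                   sample_frame, standardize)
from ecgtl.framing import CPC_PRESETS, FRAME_PRESETS, label_frames


def _recording_with(beats, n=10000, rhythms=None, fs=250.0):
    return AnnotatedRecording(
        patient_id="p", segment_id="s", signal=np.zeros(n), fs=fs, beats=beats,
        rhythms=rhythms or [(0, n, RhythmClass.NSR)])


# ------------------------------------------------------------- sampling

def test_single_valid_position_is_always_chosen(rng):
    rec = _recording_with([], n=2048)
    corpus = Corpus([rec])
    for _ in range(10):
        f = sample_frame(corpus, 2048, rng)
        assert f.start == 0 and f.length == 2048


def test_patients_are_sampled_uniformly(rng):
    recs = [_recording_with([], n=4096),
            dataclasses.replace(_recording_with([], n=4096), patient_id="q")]
    corpus = Corpus(recs)
    counts = {"p": 0, "q": 0}
    n = 10000
    for _ in range(n):
        counts[sample_frame(corpus, 512, rng).recording.patient_id] += 1
    sigma = np.sqrt(n * 0.25)
    assert abs(counts["p"] - n / 2) < 3 * sigma


def test_frame_longer_than_every_segment_is_rejected(rng):
    corpus = Corpus([_recording_with([], n=1000)])
    with pytest.raises(ValueError):
        sample_frame(corpus, 2048, rng)


def test_standardize_uses_corpus_level_statistics():
    np.testing.assert_allclose(standardize(np.array([2.0, 4.0]), 2.0, 2.0),
                               [0.0, 1.0])
    with pytest.raises(ValueError):
        standardize(np.ones(4), 1.0, 0.0)


def test_standardizing_corpus_with_own_stats_gives_zero_mean_unit_std(small_corpus):
    mean, std = small_corpus.stats()
    pooled = np.concatenate([standardize(r.signal, mean, std)
                             for r in small_corpus])
    assert abs(pooled.mean()) < 1e-6
    assert abs(pooled.std() - 1.0) < 1e-6


# ------------------------------------------------------------- beat labels

def test_most_frequent_abnormal_beat_wins():
    beats = ([(100 * i, BeatClass.NORMAL) for i in range(1, 6)]
             + [(600, BeatClass.PVC), (700, BeatClass.PVC), (800, BeatClass.PAC)])
    beats.sort()
    rec = _recording_with(beats)
    assert label_beat(Frame(rec, 0, 1000)) is BeatClass.PVC


def test_all_normal_beats_label_normal():
    rec = _recording_with([(100, BeatClass.NORMAL), (400, BeatClass.NORMAL)])
    assert label_beat(Frame(rec, 0, 1000)) is BeatClass.NORMAL


def test_beat_count_tie_uses_documented_priority():
    rec = _recording_with([(100, BeatClass.PAC), (300, BeatClass.PVC)])
    assert label_beat(Frame(rec, 0, 1000)) is BeatClass.PVC
    rec2 = _recording_with([(100, BeatClass.ABERRATION), (300, BeatClass.PAC)])
    assert label_beat(Frame(rec2, 0, 1000)) is BeatClass.PAC


def test_zero_beat_frame_is_unlabelable():
    rec = _recording_with([(5000, BeatClass.NORMAL)])
    with pytest.raises(UnlabelableFrame):
        label_beat(Frame(rec, 0, 1000))


# ------------------------------------------------------------- rhythm labels

def _rhythm_rec(spans):
    n = spans[-1][1]
    return _recording_with([], n=n, rhythms=[(s, e, c) for s, e, c in spans])


def test_afib_beats_longer_sinus_overlap():
    rec = _rhythm_rec([(0, 1500, RhythmClass.NSR), (1500, 2000, RhythmClass.AFIB)])
    assert label_rhythm(Frame(rec, 0, 2000)) is RhythmClass.AFIB


def test_longer_of_afib_and_aflut_wins():
    rec = _rhythm_rec([(0, 500, RhythmClass.AFIB), (500, 1250, RhythmClass.AFLUT),
                       (1250, 2000, RhythmClass.NSR)])
    assert label_rhythm(Frame(rec, 0, 2000)) is RhythmClass.AFLUT


def test_longest_remaining_rhythm_otherwise():
    rec = _rhythm_rec([(0, 1250, RhythmClass.NSR), (1250, 2000, RhythmClass.NOISE)])
    assert label_rhythm(Frame(rec, 0, 2000)) is RhythmClass.NSR


def test_afib_aflut_duration_tie_goes_to_afib():
    rec = _rhythm_rec([(0, 500, RhythmClass.AFIB), (500, 1000, RhythmClass.AFLUT),
                       (1000, 2000, RhythmClass.NSR)])
    assert label_rhythm(Frame(rec, 0, 1000)) is RhythmClass.AFIB


def test_rhythm_label_invariant_to_splitting_intervals():
    whole = _rhythm_rec([(0, 1400, RhythmClass.NSR), (1400, 2000, RhythmClass.AFIB)])
    split = _rhythm_rec([(0, 700, RhythmClass.NSR), (700, 1400, RhythmClass.NSR),
                         (1400, 1700, RhythmClass.AFIB),
                         (1700, 2000, RhythmClass.AFIB)])
    for start in (0, 200, 900):
        assert (label_rhythm(Frame(whole, start, 1000))
                is label_rhythm(Frame(split, start, 1000)))


# ------------------------------------------------------------- QRS detector

def test_detector_finds_clean_sinus_beats_within_40ms(clean_params):
    p = dataclasses.replace(clean_params, nsr_ibi_mean=1.0, nsr_ibi_jitter=0.0,
                            baseline_noise_amp=0.02)
    rec = render_beat_train([(RhythmClass.NSR, 10.0)], p, fs=250.0,
                            rng=np.random.default_rng(2))
    det = detect_beats(rec.signal, 250.0)
    assert len(det) == 10
    tol = int(0.04 * 250)
    for g, _ in rec.beats:
        assert any(abs(d - g) <= tol for d in det)


def test_detector_sensitivity_on_clean_sinus_is_high(clean_params):
    hits = total = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        p = dataclasses.replace(clean_params, nsr_ibi_mean=float(r.uniform(0.5, 1.3)),
                                baseline_noise_amp=0.03)
        rec = render_beat_train([(RhythmClass.NSR, 10.0)], p, fs=250.0, rng=r)
        det = detect_beats(rec.signal, 250.0)
        tol = int(0.04 * 250)
        for g, _ in rec.beats:
            total += 1
            hits += any(abs(d - g) <= tol for d in det)
    assert hits / total >= 0.95


def test_detector_returns_empty_on_most_noise_frames():
    empty = 0
    n = 50
    for seed in range(n):
        rec = render_beat_train([(RhythmClass.NOISE, 4.0)], GenParams(seed=seed),
                                fs=250.0)
        empty += len(detect_beats(rec.signal, 250.0)) == 0
    assert empty / n >= 0.9


def test_detector_on_flat_signal_is_empty():
    assert detect_beats(np.zeros(2500), 250.0) == []


# ------------------------------------------------------------- heart rate

def test_bpm_from_interbeat_intervals():
    assert estimate_bpm([0, 250, 500, 750], 250.0) == pytest.approx(60.0)
    assert estimate_bpm([0, 125, 250], 250.0) == pytest.approx(120.0)
    with pytest.raises(UnlabelableFrame):
        estimate_bpm([100], 250.0)


def _rate_recording(bpm, n=15000, fs=250.0):
    step = int(round(fs * 60.0 / bpm))
    beats = [(i, BeatClass.NORMAL) for i in range(0, n, step)]
    return _recording_with(beats, n=n, fs=fs)


@pytest.mark.parametrize("bpm,expected", [
    (59, HeartRateClass.BRADY),
    (60, HeartRateClass.NORMAL),
    (100, HeartRateClass.NORMAL),
    (101, HeartRateClass.TACHY),
    (120, HeartRateClass.TACHY),
    (45, HeartRateClass.BRADY),
])
def test_heart_rate_boundaries(bpm, expected):
    # beat grid at an exact integer sample step reproduces the BPM when
    # 15000/step is integral; use rates whose step divides evenly
    fs = 250.0
    step = fs * 60.0 / bpm
    rec = AnnotatedRecording(
        patient_id="p", segment_id="s", signal=np.zeros(30000), fs=fs,
        beats=[(int(round(i * step)), BeatClass.NORMAL)
               for i in range(int(30000 / step))],
        rhythms=[(0, 30000, RhythmClass.NSR)])
    assert label_heart_rate(Frame(rec, 5000, 2048)) is expected


def test_noise_frame_labels_noise():
    rec = render_beat_train([(RhythmClass.NOISE, 20.0)], GenParams(seed=4), fs=250.0)
    assert label_heart_rate(Frame(rec, 1000, 2048)) is HeartRateClass.NOISE


def test_pad_is_clipped_at_segment_start():
    rec = _rate_recording(75)
    assert label_heart_rate(Frame(rec, 0, 2048)) is HeartRateClass.NORMAL


def test_heart_rate_with_ground_truth_ignores_amplitude(clean_params):
    p = dataclasses.replace(clean_params, nsr_ibi_mean=0.5)
    rec = render_beat_train([(RhythmClass.NSR, 30.0)], p, fs=250.0,
                            rng=np.random.default_rng(3))
    scaled = AnnotatedRecording(
        patient_id="p", segment_id="s", signal=rec.signal * 137.0, fs=rec.fs,
        beats=rec.beats, rhythms=rec.rhythms)
    for start in (0, 1000, 3000):
        assert (label_heart_rate(Frame(rec, start, 2048))
                is label_heart_rate(Frame(scaled, start, 2048)))


# ------------------------------------------------------------- CPC geometry

def test_positive_frame_position(small_corpus, rng):
    ex = make_cpc_example(small_corpus, 8, 512, 2, 4, rng)
    assert ex.positive.start == ex.context[0].start + (8 + 2) * 512
    assert len(ex.context) == 8
    assert len(ex.negatives) == 4


def test_minimum_segment_length_is_enforced(rng):
    # (16 + 8 + 1) * 512 = 12800 samples needed
    corpus = Corpus([_recording_with([], n=12799)])
    with pytest.raises(ValueError):
        make_cpc_example(corpus, 16, 512, 8, 8, rng)
    ok = Corpus([_recording_with([], n=12800)])
    ex = make_cpc_example(ok, 16, 512, 8, 8, rng)
    assert ex.context[0].start == 0


def test_negatives_never_overlap_the_positive(small_corpus, rng):
    for _ in range(300):
        ex = make_cpc_example(small_corpus, 4, 512, 2, 8, rng)
        for neg in ex.negatives:
            if neg.recording is ex.positive.recording:
                assert (neg.end <= ex.positive.start
                        or neg.start >= ex.positive.end)


def test_table_presets_are_constructible(rng):
    from ecgtl import generate_upstream_corpus
    assert FRAME_PRESETS == (512, 2048, 4096)
    corpus = generate_upstream_corpus(2, 1, 60.0, seed=5)
    for k, ns, offset, frame in CPC_PRESETS:
        ex = make_cpc_example(corpus, k, frame, offset, ns, rng)
        assert len(ex.context) == k
        assert len(ex.negatives) == ns
        assert ex.offset == offset


# ------------------------------------------------------------- manifests

def test_label_frames_manifest(small_corpus, rng):
    df = label_frames(small_corpus, "rhythm", 50, 512, rng)
    assert len(df) == 50
    assert set(df.columns) == {"patient_id", "segment_id", "start", "length",
                               "task", "label"}
    assert set(df["label"]).issubset({c.value for c in RhythmClass})
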