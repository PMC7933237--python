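"""Frame extraction and weak labels for the pretraining tasks.

A frame is a fixed-length half-open sample window ``[start, start+length)``
into a continuous recording. Labels are derived from the recording's
annotations by three rules:

* beat: the most frequent abnormal beat class inside the window, or
  NORMAL if none (ties broken by the fixed priority PVC > PAC >
  ABERRATION);
* rhythm: the class with the longest overlap, prioritising atrial
  fibrillation and flutter over sinus rhythm and noise;
* heart rate: beats-per-minute estimated from interbeat intervals inside
  the window extended by 1 s on each side, bucketed into bradycardia
  (< 60 BPM), normal (60-100 BPM, boundaries inclusive), tachycardia
  (> 100 BPM), and noise when fewer than two beats are found.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import (AnnotatedRecording, BeatClass, Corpus, HeartRateClass,
                    RhythmClass)

FRAME_PRESETS = (512, 2048, 4096)
#: (context size K, negative samples ns, offset) presets for the
#: contrastive future-prediction task, all at frame length 512.
CPC_PRESETS = ((8, 4, 2, 512), (16, 8, 2, 512), (16, 8, 8, 512), (16, 16, 8, 512))

_ABNORMAL_PRIORITY = (BeatClass.PVC, BeatClass.PAC, BeatClass.ABERRATION)


class UnlabelableFrame(Exception):
    """Raised when a frame cannot be labeled (caller should resample)."""


@dataclass(frozen=True)
class Frame:
    recording: AnnotatedRecording
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.length <= 0:
            raise ValueError("frame start must be >= 0 and length positive")
        if self.start + self.length > self.recording.n_samples:
            raise ValueError("frame extends beyond the recording")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def signal(self) -> np.ndarray:
        return self.recording.signal[self.start:self.end]


@dataclass(frozen=True)
class HeartRateRule:
    brady_upper_bpm: float = 60.0   # exclusive lower edge of normal
    tachy_lower_bpm: float = 100.0  # exclusive upper edge of normal
    window_pad_s: float = 1.0

    def __post_init__(self) -> None:
        if self.brady_upper_bpm >= self.tachy_lower_bpm:
            raise ValueError("brady threshold must be below tachy threshold")
        if self.window_pad_s < 0:
            raise ValueError("window pad must be non-negative")


@dataclass
class CpcExample:
    """Context frames, one positive future frame and ns negatives."""

    context: list[Frame]
    positive: Frame
    negatives: list[Frame]
    offset: int

    def __post_init__(self) -> None:
        if not self.context:
            raise ValueError("context must be non-empty")
        if not self.negatives:
            raise ValueError("need at least one negative sample")
        length = self.context[0].length
        for i, f in enumerate(self.context[1:], 1):
            if f.length != length or f.start != self.context[i - 1].end:
                raise ValueError("context frames must be contiguous and equal-length")
        expected = self.context[-1].end + self.offset * length
        if (self.positive.recording is not self.context[0].recording
                or self.positive.start != expected):
            raise ValueError("positive frame must start offset frames after the context")


# ------------------------------------------------------------- sampling

def sample_frame(corpus: Corpus, frame_length: int,
                 rng: np.random.Generator) -> Frame:
    """Draw a frame: uniform patient, then segment, then start position."""
    eligible = {pid: [r for r in corpus.recordings_of(pid)
                      if r.n_samples >= frame_length]
                for pid in corpus.patient_ids}
    eligible = {pid: recs for pid, recs in eligible.items() if recs}
    if not eligible:
        raise ValueError(f"no recording is at least {frame_length} samples long")
    pids = sorted(eligible)
    pid = pids[rng.integers(len(pids))]
    recs = eligible[pid]
    rec = recs[rng.integers(len(recs))]
    start = int(rng.integers(rec.n_samples - frame_length + 1))
    return Frame(rec, start, frame_length)


def standardize(x: np.ndarray, corpus_mean: float, corpus_std: float) -> np.ndarray:
    """Standardize with corpus-level statistics (not per-frame)."""
    if corpus_std <= 0:
        raise ValueError("corpus standard deviation must be positive")
    return (np.asarray(x, dtype=np.float64) - corpus_mean) / corpus_std


# ------------------------------------------------------------- labelers

def label_beat(frame: Frame) -> BeatClass:
    """Most frequent abnormal beat class in the frame, else NORMAL."""
    counts: dict[BeatClass, int] = {}
    n_beats = 0
    for idx, cls in frame.recording.beats:
        if frame.start <= idx < frame.end:
            n_beats += 1
            if cls is not BeatClass.NORMAL:
                counts[cls] = counts.get(cls, 0) + 1
    if n_beats == 0:
        raise UnlabelableFrame("no annotated beats inside the frame")
    if not counts:
        return BeatClass.NORMAL
    best = max(counts.values())
    for cls in _ABNORMAL_PRIORITY:
        if counts.get(cls, 0) == best:
            return cls
    raise AssertionError("unreachable")  # pragma: no cover


def label_rhythm(frame: Frame) -> RhythmClass:
    """Longest-overlap rhythm, prioritising AFib/AFlut over NSR/noise."""
    overlap: dict[RhythmClass, int] = {}
    for start, end, cls in frame.recording.rhythms:
        o = min(end, frame.end) - max(start, frame.start)
        if o > 0:
            overlap[cls] = overlap.get(cls, 0) + o
    if not overlap:
        raise RuntimeError("frame overlaps no rhythm interval (broken tiling)")
    afib = overlap.get(RhythmClass.AFIB, 0)
    aflut = overlap.get(RhythmClass.AFLUT, 0)
    if afib > 0 or aflut > 0:
        # duration ties go to AFib (fixed documented order)
        return RhythmClass.AFIB if afib >= aflut else RhythmClass.AFLUT
    nsr = overlap.get(RhythmClass.NSR, 0)
    noise = overlap.get(RhythmClass.NOISE, 0)
    return RhythmClass.NSR if nsr >= noise else RhythmClass.NOISE


def detect_beats(signal: np.ndarray, fs: float) -> list[int]:
    """Simple energy-based QRS detector.

    Band-pass 5-15 Hz, squared derivative, 150 ms moving-window
    integration, a crest-factor gate that rejects beat-free noise, and
    peak picking with a 200 ms refractory period. Detections are refined
    to the local maximum of the band-passed amplitude.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.asarray(signal, dtype=np.float64)
    if len(x) < int(0.5 * fs):
        return []
    nyq = fs / 2
    b, a = sps.butter(2, [5.0 / nyq, min(15.0 / nyq, 0.99)], btype="band")
    bp = sps.filtfilt(b, a, x)
    energy = np.gradient(bp) ** 2
    win = max(int(0.15 * fs), 1)
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    med = np.median(integ)
    mx = integ.max()
    if mx <= 0 or mx < 8.0 * (med + 1e-12):
        return []  # no dominant QRS energy: treat as beat-free
    thr = med + 0.25 * (mx - med)
    peaks, _ = sps.find_peaks(integ, height=thr, distance=max(int(0.2 * fs), 1))
    refined: list[int] = []
    half = int(0.10 * fs)
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, len(x))
        q = lo + int(np.argmax(np.abs(bp[lo:hi])))
        if not refined or q - refined[-1] >= int(0.2 * fs):
            refined.append(int(q))
    return refined


def estimate_bpm(beat_indices: list[int], fs: float) -> float:
    """BPM from the mean interbeat interval; needs at least two beats."""
    if len(beat_indices) < 2:
        raise UnlabelableFrame("need at least two beats to estimate a rate")
    ibis = np.diff(beat_indices) / fs
    return float(60.0 / ibis.mean())


def label_heart_rate(frame: Frame, rule: HeartRateRule = HeartRateRule(),
                     beat_source: str = "ground_truth") -> HeartRateClass:
    """Heart-rate class of a frame from its padded window.

    The frame is extended by ``window_pad_s`` on each side (clipped to
    the recording). Beats come either from the recording's annotations
    (``ground_truth``) or from the QRS detector (``detector``).
    """
    rec = frame.recording
    pad = int(round(rule.window_pad_s * rec.fs))
    lo = max(frame.start - pad, 0)
    hi = min(frame.end + pad, rec.n_samples)
    if beat_source == "ground_truth":
        beats = [idx for idx, _ in rec.beats if lo <= idx < hi]
    elif beat_source == "detector":
        beats = [lo + i for i in detect_beats(rec.signal[lo:hi], rec.fs)]
    else:
        raise ValueError(f"unknown beat source {beat_source!r}")
    if len(beats) < 2:
        return HeartRateClass.NOISE
    bpm = estimate_bpm(beats, rec.fs)
    if bpm < rule.brady_upper_bpm:
        return HeartRateClass.BRADY
    if bpm > rule.tachy_lower_bpm:
        return HeartRateClass.TACHY
    return HeartRateClass.NORMAL


# ------------------------------------------------------------- CPC

def make_cpc_example(corpus: Corpus, context_size: int, frame_length: int,
                     offset: int, ns: int, rng: np.random.Generator,
                     negative_corpus: Corpus | None = None) -> CpcExample:
    """Assemble a contrastive future-prediction example.

    The positive frame starts ``(context_size + offset) * frame_length``
    samples after the context start, in the same segment. Negatives are
    uniform frames from anywhere in ``negative_corpus`` (default: the
    same corpus), excluding windows that overlap the positive.
    """
    if ns < 1:
        raise ValueError("need at least one negative sample")
    needed = (context_size + offset + 1) * frame_length
    by_patient = {pid: [r for r in corpus.recordings_of(pid) if r.n_samples >= needed]
                  for pid in corpus.patient_ids}
    by_patient = {pid: recs for pid, recs in by_patient.items() if recs}
    if not by_patient:
        raise ValueError(f"no segment is at least {needed} samples long")
    pids = sorted(by_patient)
    pid = pids[rng.integers(len(pids))]
    recs = by_patient[pid]
    rec = recs[rng.integers(len(recs))]
    ctx_start = int(rng.integers(rec.n_samples - needed + 1))
    context = [Frame(rec, ctx_start + i * frame_length, frame_length)
               for i in range(context_size)]
    pos = Frame(rec, ctx_start + (context_size + offset) * frame_length, frame_length)
    negatives: list[Frame] = []
    neg_corpus = negative_corpus if negative_corpus is not None else corpus
    while len(negatives) < ns:
        neg = sample_frame(neg_corpus, frame_length, rng)
        if neg.recording is pos.recording and (neg.start < pos.end
                                               and pos.start < neg.end):
            continue
        negatives.append(neg)
    return CpcExample(context=context, positive=pos, negatives=negatives,
                      offset=offset)


# ------------------------------------------------------------- manifests

def label_frames(corpus: Corpus, task: str, n_frames: int, frame_length: int,
                 rng: np.random.Generator, beat_source: str = "ground_truth",
                 max_attempts_factor: int = 20) -> pd.DataFrame:
    """Sample and label frames; returns a manifest data frame.

    Frames that cannot be labeled (e.g. beat-less frames in the beat
    task) are skipped and resampled.
    """
    labeler = {
        "beat": lambda f: label_beat(f).value,
        "rhythm": lambda f: label_rhythm(f).value,
        "heart_rate": lambda f: label_heart_rate(f, beat_source=beat_source).value,
    }
    if task not in labeler:
        raise ValueError(f"unknown task {task!r}; choose from {sorted(labeler)}")
    rows = []
    attempts = 0
    while len(rows) < n_frames:
        attempts += 1
        if attempts > max_attempts_factor * n_frames:
            raise RuntimeError("too many unlabelable frames; corpus unsuitable")
        frame = sample_frame(corpus, frame_length, rng)
        try:
            lab = labeler[task](frame)
        except UnlabelableFrame:
            continue
        rows.append({
            "patient_id": frame.recording.patient_id,
            "segment_id": frame.recording.segment_id,
            "start": frame.start,
            "length": frame.length,
            "task": task,
            "label": lab,
        })
    return pd.DataFrame(rows)
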