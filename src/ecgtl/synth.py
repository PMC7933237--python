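"""Synthetic annotated-ECG generation with exact ground truth.

The generator is not a physiological simulator: waveforms only need to
carry class-discriminative structure. A beat is a Gaussian QRS bump with
smaller P and T bumps; atrial fibrillation has irregular interbeat
intervals (IBIs) and no P wave; atrial flutter is fast and regular with
a flutter-wave baseline oscillation; the noise class is band-limited
noise with no beats. Premature beats (PAC) arrive early, ventricular
ectopics (PVC) are wide, high-amplitude and followed by a compensatory
pause, and aberrantly conducted beats have altered morphology.

Three corpus shapes are emulated: a continuous 250 Hz upstream corpus
with per-patient segments (beat + rhythm annotations), a short
single-lead 300 Hz record set with one label per record, and a 12-lead
500 Hz multi-label set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .types import (AnnotatedRecording, BeatClass, Corpus, DownstreamRecord,
                    RhythmClass, SINGLE_LABEL_CLASSES)

RHYTHM_ORDER = (RhythmClass.NSR, RhythmClass.AFIB, RhythmClass.AFLUT, RhythmClass.NOISE)


def child_seed(seed: int, *indices: int) -> int:
    """Derive a reproducible child seed (splitmix64-style mixing)."""
    mask = (1 << 64) - 1
    z = seed & mask
    for idx in indices:
        z = (z + 0x9E3779B97F4A7C15 * (idx + 1)) & mask
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        z = z ^ (z >> 31)
    return z % (1 << 31)


@dataclass
class GenParams:
    """Ground-truth parameters of the synthetic generator.

    IBI units are seconds; rates and probabilities are in [0, 1].
    """

    nsr_ibi_mean: float = 0.8
    nsr_ibi_jitter: float = 0.04        # fractional std of NSR IBIs
    afib_ibi_mean: float = 0.7
    afib_ibi_cv: float = 0.30           # coefficient of variation of AFib IBIs
    aflut_ibi_mean: float = 0.35
    aflut_ibi_jitter: float = 0.02
    pac_rate: float = 0.03
    pvc_rate: float = 0.03
    aberration_rate: float = 0.02
    noise_amp: float = 0.35             # amplitude of the NOISE rhythm
    baseline_noise_amp: float = 0.03    # white noise added everywhere
    amp_scale: float = 1.0              # overall signal amplitude
    # first-order Markov chain over rhythm classes (order: NSR, AFIB, AFLUT, NOISE)
    rhythm_start_probs: tuple = (0.7, 0.15, 0.05, 0.1)
    rhythm_transitions: tuple = (
        (0.60, 0.20, 0.10, 0.10),
        (0.40, 0.45, 0.05, 0.10),
        (0.45, 0.10, 0.35, 0.10),
        (0.70, 0.15, 0.05, 0.10),
    )
    rhythm_dwell_range_s: tuple = (20.0, 60.0)
    # per-patient heterogeneity of the upstream corpus: baseline NSR IBI
    # drawn uniformly from this range (about 43-133 BPM)
    nsr_ibi_mean_range: tuple = (0.45, 1.35)
    seed: int | None = None

    def validate(self) -> None:
        for name in ("pac_rate", "pvc_rate", "aberration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("nsr_ibi_mean", "afib_ibi_mean", "aflut_ibi_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.rhythm_start_probs) - 1.0) > 1e-9:
            raise ValueError("rhythm_start_probs must sum to 1")
        for row in self.rhythm_transitions:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError("each rhythm transition row must sum to 1")


# ------------------------------------------------------------- waveform

def _add_bump(signal: np.ndarray, fs: float, t_center: float, sigma_s: float,
              amp: float) -> None:
    half = 4.0 * sigma_s
    lo = max(int(np.floor((t_center - half) * fs)), 0)
    hi = min(int(np.ceil((t_center + half) * fs)) + 1, len(signal))
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    signal[lo:hi] += amp * np.exp(-0.5 * ((t - t_center) / sigma_s) ** 2)


def _render_beat(signal: np.ndarray, fs: float, t: float, cls: BeatClass,
                 rhythm: RhythmClass) -> None:
    with_p = rhythm is RhythmClass.NSR
    if cls is BeatClass.PVC:
        _add_bump(signal, fs, t, 0.030, 1.5)
        _add_bump(signal, fs, t + 0.30, 0.05, -0.30)
    elif cls is BeatClass.ABERRATION:
        _add_bump(signal, fs, t, 0.022, 0.8)
        _add_bump(signal, fs, t + 0.25, 0.035, -0.25)
        if with_p:
            _add_bump(signal, fs, t - 0.16, 0.020, 0.15)
    else:
        _add_bump(signal, fs, t, 0.012, 1.0)
        _add_bump(signal, fs, t + 0.25, 0.035, 0.30)
        if with_p:
            p_off = 0.12 if cls is BeatClass.PAC else 0.16
            _add_bump(signal, fs, t - p_off, 0.020, 0.15)


def _band_limited_noise(n: int, fs: float, amp: float,
                        rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    if n < 30:
        return amp * white
    b, a = sps.butter(2, [0.5 / (fs / 2), min(40.0 / (fs / 2), 0.99)], btype="band")
    x = sps.lfilter(b, a, white)
    sd = x.std()
    return amp * x / sd if sd > 0 else amp * white


def _draw_ibi(rhythm: RhythmClass, params: GenParams,
              rng: np.random.Generator) -> float:
    if rhythm is RhythmClass.NSR:
        ibi = params.nsr_ibi_mean * (1.0 + params.nsr_ibi_jitter * rng.standard_normal())
    elif rhythm is RhythmClass.AFIB:
        cv = max(params.afib_ibi_cv, 1e-6)
        shape = 1.0 / cv**2
        ibi = rng.gamma(shape, params.afib_ibi_mean / shape)
    elif rhythm is RhythmClass.AFLUT:
        ibi = params.aflut_ibi_mean * (1.0 + params.aflut_ibi_jitter * rng.standard_normal())
    else:  # pragma: no cover - NOISE draws no beats
        raise ValueError("noise rhythm has no beats")
    return float(np.clip(ibi, 0.2, 3.0))


def render_beat_train(rhythm_plan: list[tuple[RhythmClass, float]],
                      gen_params: GenParams, fs: float = 250.0,
                      rng: np.random.Generator | None = None,
                      patient_id: str = "p0", segment_id: str = "s0"
                      ) -> AnnotatedRecording:
    """Render a recording from an explicit rhythm plan.

    Each planned rhythm segment starts its beat train at the segment
    start; the returned beats and rhythm intervals exactly describe the
    rendered waveform.
    """
    if not rhythm_plan:
        raise ValueError("rhythm plan must not be empty")
    if fs <= 0:
        raise ValueError("fs must be positive")
    for _, dur in rhythm_plan:
        if dur <= 0:
            raise ValueError("rhythm durations must be positive")
    gen_params.validate()
    if rng is None:
        rng = np.random.default_rng(gen_params.seed)

    # exact segment boundaries in samples from cumulative durations
    cum = np.cumsum([0.0] + [d for _, d in rhythm_plan])
    bounds = [int(round(c * fs)) for c in cum]
    n_total = bounds[-1]
    signal = np.zeros(n_total)
    beats: list[tuple[int, BeatClass]] = []
    rhythms: list[tuple[int, int, RhythmClass]] = []

    for (rhythm, _), start, end in zip(rhythm_plan, bounds[:-1], bounds[1:]):
        rhythms.append((start, end, rhythm))
        seg_dur = (end - start) / fs
        if rhythm is RhythmClass.NOISE:
            signal[start:end] += _band_limited_noise(end - start, fs,
                                                     gen_params.noise_amp, rng)
            continue
        t = 0.0
        while t < seg_dur:
            cls = BeatClass.NORMAL
            if rhythm is not RhythmClass.AFLUT:
                u = rng.random()
                if u < gen_params.pvc_rate:
                    cls = BeatClass.PVC
                elif u < gen_params.pvc_rate + gen_params.pac_rate:
                    cls = BeatClass.PAC
                elif u < (gen_params.pvc_rate + gen_params.pac_rate
                          + gen_params.aberration_rate):
                    cls = BeatClass.ABERRATION
            t_beat = t
            if cls is BeatClass.PAC:
                # premature: arrives early relative to the running grid
                t_beat = max(t - 0.25 * _draw_ibi(rhythm, gen_params, rng), 0.0)
            idx = start + int(round(t_beat * fs))
            if idx >= end:
                break
            if not beats or idx > beats[-1][0]:
                beats.append((idx, cls))
                _render_beat(signal[start:end], fs, t_beat, cls, rhythm)
            ibi = _draw_ibi(rhythm, gen_params, rng)
            if cls is BeatClass.PVC:
                ibi *= 1.5  # compensatory pause
            t += ibi
        if rhythm is RhythmClass.AFLUT:
            # flutter-wave baseline oscillation
            tt = np.arange(end - start) / fs
            signal[start:end] += 0.1 * sps.sawtooth(2 * np.pi * 5.0 * tt)

    if gen_params.baseline_noise_amp > 0:
        signal += gen_params.baseline_noise_amp * rng.standard_normal(n_total)
    signal *= gen_params.amp_scale

    rec = AnnotatedRecording(patient_id=patient_id, segment_id=segment_id,
                             signal=signal, fs=fs, beats=beats, rhythms=rhythms)
    rec.validate()
    return rec


# ------------------------------------------------------------- corpora

def _markov_rhythm_plan(total_s: float, params: GenParams,
                        rng: np.random.Generator) -> list[tuple[RhythmClass, float]]:
    plan: list[tuple[RhythmClass, float]] = []
    state = int(rng.choice(4, p=np.asarray(params.rhythm_start_probs)))
    remaining = total_s
    trans = np.asarray(params.rhythm_transitions)
    lo, hi = params.rhythm_dwell_range_s
    while remaining > 1e-9:
        dwell = min(float(rng.uniform(lo, hi)), remaining)
        plan.append((RHYTHM_ORDER[state], dwell))
        remaining -= dwell
        state = int(rng.choice(4, p=trans[state]))
    return plan


def generate_upstream_corpus(n_patients: int, segments_per_patient: int = 2,
                             segment_duration_s: float = 60.0,
                             gen_params: GenParams | None = None,
                             seed: int = 0, fs: float = 250.0) -> Corpus:
    """Generate a continuous-monitoring corpus with per-patient segments.

    Each patient gets a reproducible child seed derived from ``seed``,
    a baseline sinus IBI drawn from ``nsr_ibi_mean_range`` and up to 50
    segments rendered from a Markov rhythm plan.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    if not 1 <= segments_per_patient <= 50:
        raise ValueError("segments_per_patient must be in 1..50")
    params = gen_params or GenParams()
    params.validate()
    recordings = []
    for p in range(n_patients):
        prng = np.random.default_rng(child_seed(seed, p))
        patient_params = replace(
            params,
            nsr_ibi_mean=float(prng.uniform(*params.nsr_ibi_mean_range)),
            afib_ibi_mean=float(prng.uniform(0.5, 0.9)),
            amp_scale=float(prng.uniform(0.8, 1.2)),
        )
        for s in range(segments_per_patient):
            srng = np.random.default_rng(child_seed(seed, p, s))
            plan = _markov_rhythm_plan(segment_duration_s, patient_params, srng)
            rec = render_beat_train(plan, patient_params, fs=fs, rng=srng,
                                    patient_id=f"p{p:05d}", segment_id=f"s{s:02d}")
            recordings.append(rec)
    return Corpus(recordings)


def _allocate(n: int, ratios: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``n`` items to classes."""
    total = sum(ratios.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class ratios must sum to 1, got {total}")
    raw = {k: n * v for k, v in ratios.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    by_rem = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts

DEFAULT_MULTILABEL_VOCAB = ("NSR", "AFIB", "AFLUT", "PVC", "PAC")


def _record_plan(label: str, duration: float, params: GenParams,
                 rng: np.random.Generator) -> tuple[list, GenParams]:
    if label == "NORMAL" or label == "NSR":
        p = replace(params, nsr_ibi_mean=float(rng.uniform(0.6, 1.0)),
                    pac_rate=0.0, pvc_rate=0.0, aberration_rate=0.0)
        return [(RhythmClass.NSR, duration)], p
    if label == "AF" or label == "AFIB":
        p = replace(params, afib_ibi_mean=float(rng.uniform(0.5, 0.9)),
                    pac_rate=0.0, pvc_rate=0.0, aberration_rate=0.0)
        return [(RhythmClass.AFIB, duration)], p
    if label == "AFLUT":
        return [(RhythmClass.AFLUT, duration)], params
    if label == "OTHER":
        # other arrhythmia: flutter or an ectopy-heavy sinus rhythm
        if rng.random() < 0.5:
            return [(RhythmClass.AFLUT, duration)], params
        p = replace(params, nsr_ibi_mean=float(rng.uniform(0.6, 1.0)),
                    pvc_rate=0.3, pac_rate=0.1)
        return [(RhythmClass.NSR, duration)], p
    if label == "NOISY":
        return [(RhythmClass.NOISE, duration)], params
    raise ValueError(f"unknown record label {label!r}")


def generate_downstream_set(n_records: int, profile: str = "cinc2017",
                            class_ratios: dict[str, float] | None = None,
                            seed: int = 0, gen_params: GenParams | None = None,
                            duration_range_s: tuple[float, float] = (9.0, 60.0),
                            ) -> list[DownstreamRecord]:
    """Generate a labeled downstream record set.

    ``cinc2017``: single-lead 300 Hz records of 9-60 s, one label among
    NORMAL / AF / OTHER / NOISY, allocated exactly by largest remainder.
    ``multilabel12``: 12-lead 500 Hz 10 s records with a non-empty label
    subset of {NSR, AFIB, AFLUT, PVC, PAC}.

    AF records are rendered from atrial-fibrillation beat trains, so the
    AF-vs-normal distinction is carried by IBI irregularity by design.
    """
    params = gen_params or GenParams()
    params.validate()
    if profile == "cinc2017":
        ratios = class_ratios or {"NORMAL": 0.6, "AF": 0.1, "OTHER": 0.2, "NOISY": 0.1}
        unknown = set(ratios) - set(SINGLE_LABEL_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")
        counts = _allocate(n_records, ratios)
        fs = 300.0
        records = []
        i = 0
        for label in SINGLE_LABEL_CLASSES:
            for _ in range(counts.get(label, 0)):
                rng = np.random.default_rng(child_seed(seed, i))
                duration = float(rng.uniform(*duration_range_s))
                plan, p = _record_plan(label, duration, params, rng)
                rec = render_beat_train(plan, p, fs=fs, rng=rng,
                                        patient_id=f"r{i:05d}", segment_id="s00")
                ibis = np.diff([b[0] for b in rec.beats]) / fs if len(rec.beats) > 1 else np.array([])
                records.append(DownstreamRecord(
                    record_id=f"r{i:05d}", signal=rec.signal[None, :], fs=fs,
                    labels=[label],
                    meta={"ibis_s": ibis, "beats": rec.beats, "rhythms": rec.rhythms}))
                i += 1
        return records
    if profile == "multilabel12":
        fs, duration, n_leads = 500.0, 10.0, 12
        records = []
        for i in range(n_records):
            rng = np.random.default_rng(child_seed(seed, i))
            rhythm = str(rng.choice(["NSR", "AFIB", "AFLUT"], p=[0.5, 0.3, 0.2]))
            ectopy = rhythm == "NSR" and rng.random() < 0.4
            p = params
            if ectopy:
                p = replace(params, pvc_rate=0.25, pac_rate=0.15)
            plan, p = _record_plan(rhythm, duration, p, rng) if not ectopy else (
                [(RhythmClass.NSR, duration)],
                replace(p, nsr_ibi_mean=float(rng.uniform(0.6, 1.0))))
            rec = render_beat_train(plan, p, fs=fs, rng=rng,
                                    patient_id=f"r{i:05d}", segment_id="s00")
            labels = [rhythm]
            present = {cls for _, cls in rec.beats}
            if BeatClass.PVC in present:
                labels.append("PVC")
            if BeatClass.PAC in present:
                labels.append("PAC")
            # 12 leads: scaled projections of the rendered lead plus lead noise
            scales = rng.uniform(0.3, 1.2, size=n_leads) * rng.choice(
                [1.0, -1.0], size=n_leads, p=[0.85, 0.15])
            scales[0] = 1.0
            sig = scales[:, None] * rec.signal[None, :]
            sig += 0.02 * rng.standard_normal(sig.shape)
            ibis = np.diff([b[0] for b in rec.beats]) / fs if len(rec.beats) > 1 else np.array([])
            records.append(DownstreamRecord(
                record_id=f"r{i:05d}", signal=sig, fs=fs, labels=labels,
                meta={"ibis_s": ibis, "beats": rec.beats, "rhythms": rec.rhythms}))
        return records
    raise ValueError(f"unknown profile {profile!r}")
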