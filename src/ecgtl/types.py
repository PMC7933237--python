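"""Core domain types: annotated recordings, downstream records, corpora.

Conventions used everywhere: sample indices are 0-based, intervals are
half-open ``[start, end)``, and annotation positions are in samples at
the recording's own sampling frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class BeatClass(str, Enum):
    NORMAL = "NORMAL"
    PAC = "PAC"
    PVC = "PVC"
    ABERRATION = "ABERRATION"


class RhythmClass(str, Enum):
    NSR = "NSR"
    AFIB = "AFIB"
    AFLUT = "AFLUT"
    NOISE = "NOISE"


class HeartRateClass(str, Enum):
    BRADY = "BRADY"
    NORMAL = "NORMAL"
    TACHY = "TACHY"
    NOISE = "NOISE"


#: Record-level classes of the short single-lead downstream profile.
SINGLE_LABEL_CLASSES = ("NORMAL", "AF", "OTHER", "NOISY")


@dataclass
class AnnotatedRecording:
    """Continuous single-lead ECG with beat and rhythm annotations."""

    patient_id: str
    segment_id: str
    signal: np.ndarray
    fs: float
    beats: list[tuple[int, BeatClass]]
    rhythms: list[tuple[int, int, RhythmClass]]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)

    @property
    def n_samples(self) -> int:
        return len(self.signal)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signal.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        n = self.n_samples
        prev = -1
        for idx, cls in self.beats:
            if not 0 <= idx < n:
                raise ValueError(f"beat index {idx} outside [0, {n})")
            if idx <= prev:
                raise ValueError("beat indices must be strictly increasing")
            if not isinstance(cls, BeatClass):
                raise ValueError(f"bad beat class {cls!r}")
            prev = idx
        if not self.rhythms:
            raise ValueError("rhythm intervals must cover the recording")
        pos = 0
        for start, end, cls in self.rhythms:
            if start != pos:
                raise ValueError(f"rhythm intervals must tile: gap/overlap at {start}")
            if end <= start:
                raise ValueError("rhythm interval must be non-empty")
            if not isinstance(cls, RhythmClass):
                raise ValueError(f"bad rhythm class {cls!r}")
            pos = end
        if pos != n:
            raise ValueError(f"rhythm intervals end at {pos}, expected {n}")


@dataclass
class DownstreamRecord:
    """Short record with one or more record-level labels.

    ``signal`` has shape (n_leads, n_samples). ``meta`` carries the
    generator's ground truth (interbeat intervals etc.) for testing.
    """

    record_id: str
    signal: np.ndarray
    fs: float
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.labels:
            raise ValueError("label set must be non-empty")


class Corpus:
    """A collection of annotated recordings grouped by patient."""

    def __init__(self, recordings: list[AnnotatedRecording]) -> None:
        if not recordings:
            raise ValueError("corpus must contain at least one recording")
        self.recordings = list(recordings)
        self._by_patient: dict[str, list[int]] = {}
        for i, rec in enumerate(self.recordings):
            self._by_patient.setdefault(rec.patient_id, []).append(i)
        self._stats: tuple[float, float] | None = None

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    @property
    def patient_ids(self) -> list[str]:
        return list(self._by_patient)

    def recordings_of(self, patient_id: str) -> list[AnnotatedRecording]:
        return [self.recordings[i] for i in self._by_patient[patient_id]]

    def subset(self, patient_ids) -> "Corpus":
        wanted = set(patient_ids)
        recs = [r for r in self.recordings if r.patient_id in wanted]
        return Corpus(recs)

    def stats(self) -> tuple[float, float]:
        """Pooled mean and standard deviation over every sample in the corpus."""
        if self._stats is None:
            n = sum(r.n_samples for r in self.recordings)
            mean = sum(float(r.signal.sum()) for r in self.recordings) / n
            sq = sum(float(((r.signal - mean) ** 2).sum()) for r in self.recordings)
            self._stats = (mean, float(np.sqrt(sq / n)))
        return self._stats

    def validate(self) -> None:
        for rec in self.recordings:
            rec.validate()
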