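"""Readers and writers for the on-disk corpus layout.

Recordings are stored as WFDB records (text header ``.hea`` + 16-bit
little-endian ``.dat``), beat annotations in the MIT binary annotation
format (``.atr``), and rhythm intervals plus record-level labels in a
JSON-lines manifest (``manifest.jsonl``, one object per recording).
All sample indices are 0-based and intervals half-open.

The WFDB subset implemented here covers exactly what the corpus needs:
format 16, one or more signals, a gain chosen per record so the float
signal round-trips within quantisation error.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .types import (AnnotatedRecording, BeatClass, Corpus, DownstreamRecord,
                    RhythmClass)

# MIT annotation codes for the beat classes (bijective)
BEAT_TO_CODE = {BeatClass.NORMAL: 1, BeatClass.ABERRATION: 4,
                BeatClass.PVC: 5, BeatClass.PAC: 8}
CODE_TO_BEAT = {v: k for k, v in BEAT_TO_CODE.items()}
_SKIP = 59


# ------------------------------------------------------------- WFDB signal

def _write_dat(path: Path, signal2d: np.ndarray, gain: float) -> np.ndarray:
    ints = np.clip(np.round(signal2d * gain), -32768, 32767).astype("<i2")
    # format 16: samples interleaved across signals
    ints.T.reshape(-1).tofile(path)
    return ints


def write_wfdb(record_name: str, signal: np.ndarray, fs: float,
               out_dir: Path) -> dict[str, str]:
    """Write a (n_leads, n_samples) float signal as a WFDB record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    n_sig, n_samp = sig.shape
    max_abs = np.abs(sig).max()
    gain = 32000.0 / max_abs if max_abs > 0 else 1000.0
    dat = out_dir / f"{record_name}.dat"
    ints = _write_dat(dat, sig, gain)
    hea = out_dir / f"{record_name}.hea"
    lines = [f"{record_name} {n_sig} {fs:g} {n_samp}"]
    for ch in range(n_sig):
        checksum = int(np.sum(ints[ch], dtype=np.int64) % 65536)
        lines.append(f"{record_name}.dat 16 {gain:.6f}(0)/mV 16 0 "
                     f"{int(ints[ch, 0])} {checksum} 0 ECG{ch}")
    hea.write_text("\n".join(lines) + "\n")
    return {"header": str(hea), "signal": str(dat)}


def read_wfdb(out_dir: Path, record_name: str) -> tuple[np.ndarray, float]:
    out_dir = Path(out_dir)
    hea = out_dir / f"{record_name}.hea"
    if not hea.exists():
        raise FileNotFoundError(f"missing header file {hea}")
    lines = hea.read_text().strip().splitlines()
    head = lines[0].split()
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    gain = float(lines[1].split()[2].split("(")[0])
    dat = out_dir / f"{record_name}.dat"
    if not dat.exists():
        raise FileNotFoundError(f"missing signal file {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise ValueError(f"signal file {dat} has {raw.size} samples, "
                         f"header promises {n_sig * n_samp}")
    sig = raw.reshape(n_samp, n_sig).T.astype(np.float64) / gain
    return sig, fs


# ------------------------------------------------------------- annotations

def write_annotations(path: Path, beats: list[tuple[int, BeatClass]]) -> None:
    """MIT annotation format: 6-bit code + 10-bit time increment words,
    with SKIP escapes for large increments; zero word terminates."""
    out = bytearray()
    prev = 0
    for idx, cls in beats:
        delta = idx - prev
        if delta < 0:
            raise ValueError("beat indices must be non-decreasing")
        if delta > 1023:
            out += struct.pack("<H", _SKIP << 10)
            # 4-byte interval, PDP-11 order: high 16 bits then low 16 bits
            out += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (BEAT_TO_CODE[cls] << 10) | delta)
        prev = idx
    out += struct.pack("<H", 0)
    Path(path).write_bytes(bytes(out))


def read_annotations(path: Path) -> list[tuple[int, BeatClass]]:
    data = Path(path).read_bytes()
    beats: list[tuple[int, BeatClass]] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            hi, lo = struct.unpack_from("<HH", data, i)
            i += 4
            pending_skip = (hi << 16) | lo
            continue
        if code not in CODE_TO_BEAT:
            raise ValueError(f"unknown annotation code {code} in {path}")
        t += delta + pending_skip
        pending_skip = 0
        beats.append((t, CODE_TO_BEAT[code]))
    return beats


# ------------------------------------------------------------- recordings

def _record_name(rec: AnnotatedRecording) -> str:
    return f"{rec.patient_id}_{rec.segment_id}"


def write_annotated_recording(rec: AnnotatedRecording, out_dir: Path) -> dict:
    """Write signal, annotations and return the manifest entry."""
    rec.validate()
    name = _record_name(rec)
    paths = write_wfdb(name, rec.signal[None, :], rec.fs, out_dir)
    atr = Path(out_dir) / f"{name}.atr"
    write_annotations(atr, rec.beats)
    paths["annotations"] = str(atr)
    return {
        "patient_id": rec.patient_id,
        "segment_id": rec.segment_id,
        "record": name,
        "fs": rec.fs,
        "n_samples": rec.n_samples,
        "rhythms": [[s, e, c.value] for s, e, c in rec.rhythms],
    }


def read_annotated_recording(out_dir: Path, entry: dict) -> AnnotatedRecording:
    """Read one recording back from its manifest entry; validates the
    annotated-recording invariants on load."""
    name = entry["record"]
    sig, fs = read_wfdb(out_dir, name)
    if abs(fs - entry["fs"]) > 1e-9:
        raise ValueError(f"fs mismatch for {name}: header {fs}, manifest {entry['fs']}")
    beats = read_annotations(Path(out_dir) / f"{name}.atr")
    rec = AnnotatedRecording(
        patient_id=entry["patient_id"], segment_id=entry["segment_id"],
        signal=sig[0], fs=fs,
        beats=[(i, c) for i, c in beats],
        rhythms=[(s, e, RhythmClass(c)) for s, e, c in entry["rhythms"]])
    try:
        rec.validate()
    except ValueError as err:
        raise ValueError(f"invalid recording {name}: {err}") from err
    return rec


# ------------------------------------------------------------- corpora

def save_corpus(corpus: Corpus, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.jsonl"
    with open(manifest, "w") as fh:
        for rec in corpus:
            entry = write_annotated_recording(rec, out_dir)
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return manifest


def load_corpus(out_dir: Path) -> Corpus:
    out_dir = Path(out_dir)
    manifest = out_dir / "manifest.jsonl"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.jsonl in {out_dir}")
    recs = []
    with open(manifest) as fh:
        for line in fh:
            if line.strip():
                recs.append(read_annotated_recording(out_dir, json.loads(line)))
    return Corpus(recs)


def save_downstream_set(records: list[DownstreamRecord], out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.jsonl"
    with open(manifest, "w") as fh:
        for rec in records:
            rec.validate()
            write_wfdb(rec.record_id, rec.signal, rec.fs, out_dir)
            entry = {"record": rec.record_id, "fs": rec.fs,
                     "n_leads": rec.n_leads, "labels": rec.labels}
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return manifest


def load_downstream_set(out_dir: Path) -> list[DownstreamRecord]:
    out_dir = Path(out_dir)
    manifest = out_dir / "manifest.jsonl"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.jsonl in {out_dir}")
    records = []
    with open(manifest) as fh:
        for line in fh:
            if not line.strip():
                continue
            entry = json.loads(line)
            sig, fs = read_wfdb(out_dir, entry["record"])
            records.append(DownstreamRecord(record_id=entry["record"], signal=sig,
                                            fs=fs, labels=entry["labels"]))
    return records


# ------------------------------------------------------------- logs/config

def save_config(config: dict, path: Path) -> None:
    """Write a run configuration as YAML (or JSON by extension)."""
    import yaml
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))


def load_config(path: Path) -> dict:
    import yaml
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_jsonl(path: Path, rows: list[dict]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write(json.dumps(row, sort_keys=True) + "\n")


def append_jsonl(path: Path, row: dict) -> None:
    with open(path, "a") as fh:
        fh.write(json.dumps(row, sort_keys=True) + "\n")
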