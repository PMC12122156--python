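"""Recording segmentation: fixed 10-s chunks and silence removal.

Each recording is sliced into consecutive non-overlapping 10-s chunks (a
trailing remainder of at least 3 s is kept as a shorter chunk). Within each
chunk, frame-level voice activity detection labels 25-ms frames (10-ms hop)
as speech or silence; silent frames are excised and chunks left with less
than 2 s of voiced audio are discarded.

The VAD is a linear max-margin classifier (SVM) over three frame features —
log RMS energy, zero-crossing rate and spectral flatness — trained once per
run on synthetic frames labelled by the waveform generator's own
speech/silence mask. If the training frames are degenerate (single class)
the detector falls back to an energy threshold and warns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from . import synth_cohort
from .synth_cohort import SAMPLE_RATE, CohortSpec, PatientRecord

VAD_FRAME_MS = 25.0
VAD_HOP_MS = 10.0


@dataclass
class Chunk:
    """A (possibly silence-stripped) slice of one patient's recording."""

    patient_id: str
    chunk_index: int
    samples: np.ndarray
    sr: int = SAMPLE_RATE
    start_s: float = 0.0
    end_s: float = 0.0
    voiced_fraction: float = 1.0

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sr

    @property
    def voiced_s(self) -> float:
        return self.duration_s * self.voiced_fraction


def slice_chunks(
    waveform: np.ndarray,
    sr: int = SAMPLE_RATE,
    patient_id: str = "",
    chunk_s: float = 10.0,
    min_keep_s: float = 3.0,
) -> list[Chunk]:
    """Cut a recording into consecutive chunks of at most ``chunk_s`` seconds.

    The trailing remainder is kept as its own chunk when it lasts at least
    ``min_keep_s`` seconds, otherwise dropped. An empty waveform yields an
    empty list.
    """
    if chunk_s <= 0:
        raise ValueError("chunk_s must be positive")
    x = np.asarray(waveform, dtype=np.float64)
    n_chunk = int(round(chunk_s * sr))
    chunks: list[Chunk] = []
    for idx, start in enumerate(range(0, len(x), n_chunk)):
        seg = x[start : start + n_chunk]
        if len(seg) < int(min_keep_s * sr) and len(seg) < n_chunk:
            break
        chunks.append(
            Chunk(
                patient_id=patient_id,
                chunk_index=idx,
                samples=seg,
                sr=sr,
                start_s=start / sr,
                end_s=(start + len(seg)) / sr,
            )
        )
    return chunks


def frame_signal(
    x: np.ndarray, sr: int, frame_ms: float = VAD_FRAME_MS, hop_ms: float = VAD_HOP_MS
) -> np.ndarray:
    """View a signal as overlapping frames, shape (n_frames, frame_len)."""
    frame = int(round(frame_ms / 1000.0 * sr))
    hop = int(round(hop_ms / 1000.0 * sr))
    if len(x) < frame:
        return np.empty((0, frame))
    n = 1 + (len(x) - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def vad_features(x: np.ndarray, sr: int = SAMPLE_RATE) -> np.ndarray:
    """Per-frame VAD features: log RMS energy, ZCR, spectral flatness."""
    frames = frame_signal(np.asarray(x, dtype=np.float64), sr)
    if frames.shape[0] == 0:
        return np.empty((0, 3))
    rms = np.sqrt(np.mean(frames**2, axis=1))
    log_rms = np.log(rms + 1e-10)
    zcr = np.mean(np.abs(np.diff(np.signbit(frames), axis=1)), axis=1)
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2 + 1e-12
    flatness = np.exp(np.mean(np.log(spec), axis=1)) / np.mean(spec, axis=1)
    return np.column_stack([log_rms, zcr, flatness])


def mask_to_frame_labels(mask: np.ndarray, sr: int = SAMPLE_RATE) -> np.ndarray:
    """Reduce a per-sample speech mask to per-frame labels (majority rule)."""
    frames = frame_signal(mask.astype(np.float64), sr)
    return (frames.mean(axis=1) > 0.5).astype(int)


@dataclass
class VadModel:
    """Frame speech/silence classifier with an energy-threshold fallback."""

    svm: Optional[object] = None
    energy_threshold: float = -7.0  # log RMS fallback cut
    method: str = "svm"

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "VadModel":
        labels = np.asarray(labels)
        if np.unique(labels).size < 2:
            warnings.warn(
                "degenerate VAD training set (single class); "
                "falling back to an energy threshold"
            )
            self.svm = None
            self.method = "energy"
            return self
        self.svm = make_pipeline(
            StandardScaler(), LinearSVC(C=1.0, random_state=0)
        ).fit(features, labels)
        self.method = "svm"
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        if features.shape[0] == 0:
            return np.empty(0, dtype=int)
        if self.svm is not None:
            return np.asarray(self.svm.predict(features), dtype=int)
        return (features[:, 0] > self.energy_threshold).astype(int)


def train_vad(
    spec: Optional[CohortSpec] = None, n_train_patients: int = 4
) -> VadModel:
    """Train the run-level VAD on generator-labelled synthetic frames."""
    spec = spec or CohortSpec(n_patients=max(n_train_patients, 2), seed=90)
    records, _ = synth_cohort.generate_cohort(spec)
    feats, labels = [], []
    for rec in records[:n_train_patients]:
        wave, mask = synth_cohort.synth_waveform(rec, spec, return_mask=True)
        if spec.noise_snr_db is not None:
            wave = synth_cohort.add_noise(wave, spec.noise_snr_db, seed=spec.seed)
        f = vad_features(wave)
        y = mask_to_frame_labels(mask)
        m = min(len(f), len(y))
        feats.append(f[:m])
        labels.append(y[:m])
    return VadModel().fit(np.vstack(feats), np.concatenate(labels))


def vad_frames(
    x: np.ndarray, sr: int = SAMPLE_RATE, model: Optional[VadModel] = None
) -> np.ndarray:
    """Per-frame speech(1)/silence(0) labels for a waveform."""
    feats = vad_features(x, sr)
    model = model or VadModel(svm=None, method="energy")
    return model.predict(feats)


def remove_silence(
    chunk: Chunk, model: Optional[VadModel] = None
) -> Chunk:
    """Excise silent frames from a chunk by concatenating its speech frames.

    The returned chunk's ``voiced_fraction`` is the retained share of the
    original duration; total voiced duration is conserved up to one hop at
    each speech/silence boundary.
    """
    labels = vad_frames(chunk.samples, chunk.sr, model)
    hop = int(round(VAD_HOP_MS / 1000.0 * chunk.sr))
    frame = int(round(VAD_FRAME_MS / 1000.0 * chunk.sr))
    if labels.size == 0:
        kept = chunk.samples if len(chunk.samples) == 0 else np.empty(0)
        return Chunk(
            chunk.patient_id, chunk.chunk_index, kept, chunk.sr,
            chunk.start_s, chunk.end_s, voiced_fraction=0.0,
        )
    # Each frame owns its hop-span; the last frame also owns the tail.
    sample_mask = np.zeros(len(chunk.samples), dtype=bool)
    for i, lab in enumerate(labels):
        if lab:
            end = i * hop + (frame if i == len(labels) - 1 else hop)
            sample_mask[i * hop : min(end, len(sample_mask))] = True
    kept = chunk.samples[sample_mask]
    vf = len(kept) / max(len(chunk.samples), 1)
    return Chunk(
        chunk.patient_id, chunk.chunk_index, kept, chunk.sr,
        chunk.start_s, chunk.end_s, voiced_fraction=float(vf),
    )


def filter_chunks(chunks: Sequence[Chunk], min_voiced_s: float = 2.0) -> list[Chunk]:
    """Drop chunks whose voiced (retained) duration is below ``min_voiced_s``."""
    return [c for c in chunks if c.duration_s >= min_voiced_s and len(c.samples) > 0]


def chunk_recording(
    waveform: np.ndarray,
    patient_id: str,
    sr: int = SAMPLE_RATE,
    vad_model: Optional[VadModel] = None,
    chunk_s: float = 10.0,
    min_keep_s: float = 3.0,
    min_voiced_s: float = 2.0,
) -> list[Chunk]:
    """Slice, de-silence and filter one recording: fixed-length slicing
    first, then silence removal within each chunk."""
    raw = slice_chunks(waveform, sr, patient_id, chunk_s, min_keep_s)
    cleaned = [remove_silence(c, vad_model) for c in raw]
    return filter_chunks(cleaned, min_voiced_s)


def chunk_manifest(chunks: Sequence[Chunk]) -> pd.DataFrame:
    """Manifest table: patient_id, chunk_index, start_s, end_s, voiced_s."""
    return pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in chunks],
            "chunk_index": [c.chunk_index for c in chunks],
            "start_s": [c.start_s for c in chunks],
            "end_s": [c.end_s for c in chunks],
            "voiced_s": [c.duration_s for c in chunks],
        }
    )
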