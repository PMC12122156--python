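"""End-to-end glue: cohort -> (noise) -> enhancement -> chunks -> features.

Convenience functions that run the full preprocessing chain on a synthetic
cohort (or on WAV files listed in a cohort table) and return the chunk-level
feature table used for training and evaluation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from . import features as feat
from . import segment as seg
from . import synth_cohort as sc
from .enhance import enhance as _logmmse


def patient_chunks(
    record: sc.PatientRecord,
    spec: sc.CohortSpec,
    vad_model: Optional[seg.VadModel] = None,
    denoise: bool = False,
) -> list[seg.Chunk]:
    """Generate one patient's waveform and run it through the preprocessing
    chain. Noise is added when the cohort spec asks for a noisy rendition;
    ``denoise`` additionally applies log-MMSE enhancement before chunking."""
    wave = sc.synth_waveform(record, spec)
    if spec.noise_snr_db is not None:
        wave = sc.add_noise(wave, spec.noise_snr_db, seed=spec.seed)
    if denoise:
        wave = _logmmse(wave)
    return seg.chunk_recording(wave, record.patient_id, vad_model=vad_model)


def cohort_feature_table(
    records: Sequence[sc.PatientRecord],
    spec: sc.CohortSpec,
    vad_model: Optional[seg.VadModel] = None,
    denoise: bool = False,
) -> pd.DataFrame:
    """Chunk-level feature table (one row per retained chunk) for a cohort."""
    if vad_model is None:
        vad_model = seg.train_vad()
    chunks: list[seg.Chunk] = []
    for rec in records:
        chunks.extend(patient_chunks(rec, spec, vad_model, denoise))
    return feat.feature_table(chunks)
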