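"""Synthetic patient cohorts with voice-like recordings.

The real clinical data behind voice-based depression screening (outpatient
recordings plus CES-D / SUDs / PHQ-15 scores) is private, so this module
generates cohorts with the statistical structure the downstream analysis
assumes:

* per-patient recordings of roughly one minute (mean 66.73 s, sd 17.819 s),
* a latent depression severity that drives the binary label (fixed quantile
  cut-off, emulating a validated questionnaire cut-off), a 1-10 SUDs
  self-report correlated with the label, and a 0-30 somatic-symptom (PHQ-15)
  score correlated with severity,
* voice-like waveforms: harmonic glottal-pulse source with per-cycle jitter
  and shimmer, formant (all-pole resonator) filtering, gender-banded base F0
  and interleaved silent pauses,
* a depression effect expressed in standardised units: lower mean F0 and F0
  variability, lower energy, higher jitter/shimmer, more pausing,
* within-patient correlation of chunk-level features via a per-patient
  random offset shared by all segments of a recording (intraclass
  correlation ``chunk_icc``).

All randomness flows from one integer seed through ``numpy`` seed sequences;
per-patient substreams are keyed by patient id, so a cohort is reproducible
bit-for-bit and individual waveforms can be regenerated in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

SAMPLE_RATE = 16_000

# Base F0 bands per gender (Hz), standard adult phonetics ranges.
MALE_F0_BAND = (85.0, 155.0)
FEMALE_F0_BAND = (165.0, 255.0)

# Vowel formant targets (F1, F2, F3 in Hz), loosely /a/ /e/ /i/ /o/.
VOWEL_FORMANTS = (
    (730.0, 1090.0, 2440.0),
    (530.0, 1840.0, 2480.0),
    (390.0, 1990.0, 2550.0),
    (570.0, 840.0, 2410.0),
)
FORMANT_BANDWIDTHS = (90.0, 110.0, 170.0)

# SUDs map: suds = clip(round(5 + SUDS_SCALE * (severity + noise)), 1, 10).
# Scale and default noise sd calibrated once against the target population
# structure (corr(SUDs, label) ~ 0.75, heavy 1 and 9-10 tails covering ~40%
# of patients, mean SUDs ~ 5).
SUDS_CENTER = 5.0
SUDS_SCALE = 4.5

# Acoustic parameter population model: (mean, population sd, direction of the
# depression shift). The shift applied to a depressed patient is
# effect_size * sd * direction; the between/within split of the remaining
# variance is governed by chunk_icc.
PARAM_MODEL = {
    "f0_shift": (0.0, 18.0, -1.0),      # Hz, added to the gender-band base F0
    "f0_wobble": (0.030, 0.010, -1.0),  # relative slow F0 modulation depth
    "log_amp": (np.log(0.1), 0.25, -1.0),
    "jitter": (0.010, 0.004, +1.0),     # cycle-to-cycle period perturbation
    "shimmer": (0.050, 0.020, +1.0),    # cycle-to-cycle amplitude perturbation
    "pause_frac": (0.30, 0.06, +1.0),
}

ASPIRATION_DB = -26.0  # aspiration-noise level relative to the voiced source


class CohortSpecError(ValueError):
    """Raised when a cohort specification violates its invariants."""


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of a synthetic cohort.

    Defaults reproduce the published cohort: 143 patients, 86% women,
    62.5% depression prevalence, recordings of 66.73 (17.819) s.
    """

    n_patients: int = 143
    female_fraction: float = 0.86
    prevalence: float = 0.625
    effect_size: float = 1.0
    chunk_icc: float = 0.5
    suds_noise_sd: float = 0.35
    mean_duration_s: float = 66.73
    duration_sd_s: float = 17.819
    noise_snr_db: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise CohortSpecError("n_patients must be >= 2")
        for name in ("female_fraction", "prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortSpecError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.chunk_icc < 1.0:
            raise CohortSpecError("chunk_icc must lie in [0, 1)")
        if self.mean_duration_s <= 10.0:
            raise CohortSpecError("mean_duration_s must exceed 10 s")
        if self.duration_sd_s < 0.0:
            raise CohortSpecError("duration_sd_s must be non-negative")
        if self.suds_noise_sd < 0.0:
            raise CohortSpecError("suds_noise_sd must be non-negative")


@dataclass
class PatientRecord:
    """One synthetic patient: metadata plus a handle to their recording."""

    patient_id: str
    gender: str  # "F" or "M"
    severity: float
    depressed: int
    suds: int
    phq15: int
    waveform_ref: Optional[str] = None
    params: dict = field(default_factory=dict, repr=False)


def _patient_seed_seq(spec_seed: int, patient_id: str) -> np.random.SeedSequence:
    """Per-patient substream keyed by the patient id (stable CRC32 hash)."""
    return np.random.SeedSequence([spec_seed, zlib.crc32(patient_id.encode())])


def generate_cohort(spec: CohortSpec) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate patient metadata for a cohort.

    The binary label derives from the latent severity via a quantile cut-off,
    so the depressed fraction equals ``spec.prevalence`` up to rounding to a
    whole patient. SUDs is a clipped, rounded affine map of severity plus
    Gaussian noise; PHQ-15 comes from a pain latent correlated with severity
    at r = 0.5.

    Returns the records and a metadata table with columns
    ``patient_id, gender, depressed, severity, suds, phq15, wav_path``.
    """
    if not isinstance(spec, CohortSpec):
        raise CohortSpecError("generate_cohort expects a CohortSpec")
    n = spec.n_patients
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC047]))

    severity = rng.standard_normal(n)
    n_dep = int(round(n * spec.prevalence))
    order = np.argsort(severity)
    depressed = np.zeros(n, dtype=int)
    if n_dep > 0:
        depressed[order[n - n_dep:]] = 1

    n_f = int(round(n * spec.female_fraction))
    gender = np.array(["M"] * n)
    gender[rng.permutation(n)[:n_f]] = "F"

    suds_noise = rng.standard_normal(n) * spec.suds_noise_sd
    suds_raw = SUDS_CENTER + SUDS_SCALE * (severity + suds_noise)
    suds = np.clip(np.rint(suds_raw), 1, 10).astype(int)

    pain = 0.5 * severity + np.sqrt(1 - 0.25) * rng.standard_normal(n)
    phq15 = np.clip(np.rint(15.0 + 7.0 * pain), 0, 30).astype(int)

    records = [
        PatientRecord(
            patient_id=f"P{i:04d}",
            gender=str(gender[i]),
            severity=float(severity[i]),
            depressed=int(depressed[i]),
            suds=int(suds[i]),
            phq15=int(phq15[i]),
        )
        for i in range(n)
    ]
    table = cohort_table(records)
    return records, table


def cohort_table(records: list[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "gender": [r.gender for r in records],
            "depressed": [r.depressed for r in records],
            "severity": [r.severity for r in records],
            "suds": [r.suds for r in records],
            "phq15": [r.phq15 for r in records],
            "wav_path": [r.waveform_ref or "" for r in records],
        }
    )


def patient_voice_params(record: PatientRecord, spec: CohortSpec) -> dict:
    """Draw the per-patient acoustic parameter offsets (deterministic)."""
    rng = np.random.default_rng(_patient_seed_seq(spec.seed, record.patient_id))
    icc = spec.chunk_icc
    params: dict = {}
    for name, (mu, sd, direction) in PARAM_MODEL.items():
        shift = direction * spec.effect_size * sd * record.depressed
        offset = np.sqrt(icc) * sd * rng.standard_normal()
        params[name] = mu + shift + offset
        params[name + "_within_sd"] = np.sqrt(1.0 - icc) * sd
    if record.gender == "F":
        lo, hi = FEMALE_F0_BAND
    else:
        lo, hi = MALE_F0_BAND
    params["f0_base"] = rng.uniform(lo + 15.0, hi - 15.0)
    return params


def _voiced_segment(
    rng: np.random.Generator,
    n_samples: int,
    f0: float,
    f0_wobble: float,
    amp: float,
    jitter: float,
    shimmer: float,
    sr: int,
) -> np.ndarray:
    """Glottal-pulse train with jitter/shimmer through a formant filter."""
    f0 = float(np.clip(f0, 60.0, 400.0))
    # Per-cycle periods with jitter and a slow wobble contour.
    n_cycles = int(np.ceil(n_samples * f0 / sr)) + 4
    wob = np.cumsum(rng.standard_normal(n_cycles))
    wob = wob - wob.mean()
    wob = wob / (np.abs(wob).max() + 1e-12)
    periods = sr / f0 * (1.0 + max(f0_wobble, 0.002) * wob) * (
        1.0 + max(jitter, 1e-4) * rng.standard_normal(n_cycles)
    )
    periods = np.clip(periods, 0.3 * sr / f0, 3.0 * sr / f0)
    positions = np.cumsum(periods)
    positions = positions[positions < n_samples - 1].astype(int)
    amps = 1.0 + max(shimmer, 1e-3) * rng.standard_normal(positions.size)
    source = np.zeros(n_samples)
    source[positions] = np.clip(amps, 0.1, None)
    # Aspiration noise keeps HNR finite and realistic.
    source += 10 ** (ASPIRATION_DB / 20.0) * rng.standard_normal(n_samples)

    formants = VOWEL_FORMANTS[rng.integers(len(VOWEL_FORMANTS))]
    out = source
    for fc, bw in zip(formants, FORMANT_BANDWIDTHS):
        r = np.exp(-np.pi * bw / sr)
        theta = 2.0 * np.pi * fc / sr
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        b = [1.0 - r]
        out = sps.lfilter(b, a, out)
    rms = np.sqrt(np.mean(out**2)) + 1e-12
    out = out / rms * amp
    # 10 ms raised-cosine edges avoid clicks at segment boundaries.
    edge = min(int(0.010 * sr), n_samples // 2)
    if edge > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(edge) / edge))
        out[:edge] *= ramp
        out[-edge:] *= ramp[::-1]
    return out


def synth_waveform(
    record: PatientRecord,
    spec: CohortSpec,
    return_mask: bool = False,
    sr: int = SAMPLE_RATE,
):
    """Synthesise the patient's voice-like recording.

    The recording alternates voiced vowel-like segments with silent pauses;
    segment-level acoustic parameters are the patient's offsets plus
    within-patient noise, which is what induces the chunk-level intraclass
    correlation. With ``return_mask=True`` also returns the boolean
    speech/silence sample mask (ground truth for VAD training).
    """
    params = patient_voice_params(record, spec)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, zlib.crc32(record.patient_id.encode()), 1])
    )
    dur = rng.normal(spec.mean_duration_s, spec.duration_sd_s)
    dur = float(max(dur, 15.0))
    n_total = int(round(dur * sr))

    pause_frac = float(np.clip(params["pause_frac"], 0.05, 0.70))
    wave = np.zeros(n_total)
    mask = np.zeros(n_total, dtype=bool)
    # Interview-style leading/trailing silence around the narrative. It is
    # part of the patient's total silence budget, so the inter-phrase pause
    # rate is deflated accordingly and the realised silent fraction of the
    # recording tracks the pause_frac parameter.
    lead = int(rng.uniform(1.0, 2.0) * sr)
    tail = int(rng.uniform(2.5, 5.5) * sr)
    edge_frac = (lead + tail) / n_total
    pf_eff = float(np.clip((pause_frac - edge_frac) / (1.0 - edge_frac), 0.02, 0.7))
    pos = lead
    n_speech_end = max(n_total - tail, pos + int(0.05 * sr))
    while pos < n_speech_end:
        seg_s = rng.uniform(1.5, 3.5)
        n_seg = min(int(seg_s * sr), n_speech_end - pos)
        if n_seg < int(0.05 * sr):
            break
        w = params["f0_wobble_within_sd"]
        seg = _voiced_segment(
            rng,
            n_seg,
            f0=params["f0_base"]
            + params["f0_shift"]
            + params["f0_shift_within_sd"] * rng.standard_normal(),
            f0_wobble=params["f0_wobble"] + w * rng.standard_normal(),
            amp=np.exp(
                params["log_amp"]
                + params["log_amp_within_sd"] * rng.standard_normal()
            ),
            jitter=params["jitter"]
            + params["jitter_within_sd"] * rng.standard_normal(),
            shimmer=params["shimmer"]
            + params["shimmer_within_sd"] * rng.standard_normal(),
            sr=sr,
        )
        wave[pos : pos + n_seg] = seg
        mask[pos : pos + n_seg] = True
        pos += n_seg
        # inter-phrase pauses: mostly short, occasionally a long hesitation
        # (mixture mean 1, so the silence budget is preserved)
        if rng.random() < 0.12:
            factor = rng.uniform(2.5, 4.5)
        else:
            factor = rng.uniform(0.44, 0.88)
        pause_s = seg_s * pf_eff / (1.0 - pf_eff) * factor
        pos += int(pause_s * sr)

    peak = np.abs(wave).max()
    if peak > 0.99:
        wave *= 0.99 / peak
    if return_mask:
        return wave, mask
    return wave


def add_noise(
    waveform: np.ndarray, snr_db: Optional[float], seed: int = 0
) -> np.ndarray:
    """Add white Gaussian noise at an exact empirical SNR (dB).

    ``snr_db=None`` or ``inf`` is the no-noise sentinel and returns the input
    unchanged. A zero-power input has no defined SNR and is rejected.
    """
    if snr_db is None or np.isinf(snr_db):
        return waveform.copy()
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite or the no-noise sentinel")
    p_sig = float(np.mean(np.asarray(waveform) ** 2))
    if p_sig <= 0.0:
        raise ValueError("zero-power waveform: SNR is undefined")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(waveform))
    noise *= np.sqrt(p_sig * 10 ** (-snr_db / 10.0) / np.mean(noise**2))
    return waveform + noise


def write_wav(path: str | Path, waveform: np.ndarray, sr: int = SAMPLE_RATE) -> None:
    """Write a mono RIFF PCM-16 WAV file."""
    x = np.clip(waveform, -1.0, 1.0)
    wavfile.write(str(path), sr, (x * 32767.0).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    sr, data = wavfile.read(str(path))
    x = data.astype(np.float64)
    if data.dtype == np.int16:
        x /= 32768.0
    elif data.dtype == np.int32:
        x /= 2147483648.0
    if x.ndim > 1:
        x = x.mean(axis=1)
    return x, int(sr)


def write_cohort(
    records: list[PatientRecord],
    spec: CohortSpec,
    outdir: str | Path,
) -> pd.DataFrame:
    """Render every patient's WAV to ``outdir`` and write ``cohort.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        wav = synth_waveform(rec, spec)
        if spec.noise_snr_db is not None:
            wav = add_noise(wav, spec.noise_snr_db, seed=spec.seed)
        path = outdir / f"{rec.patient_id}.wav"
        write_wav(path, wav)
        rec.waveform_ref = str(path)
    table = cohort_table(records)
    table.to_csv(outdir / "cohort.csv", index=False)
    return table
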