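"""Low-level acoustic descriptors and per-chunk functionals.

A compact eGeMAPS-style feature set. Frame-level low-level descriptors
(LLDs): fundamental frequency (autocorrelation tracker with parabolic
interpolation, 60-400 Hz), RMS energy, harmonics-to-noise ratio,
cycle-to-cycle jitter and shimmer, spectral slope of the 0-500 Hz band
(voiced and unvoiced frames pooled separately), LPC formant frequencies
F1-F3 with amplitudes relative to the fundamental, and MFCC 1-12
(26 mel bands). Each chunk is summarised by functionals — the arithmetic
mean and the coefficient of variation ``stddevNorm = sd / |mean|`` —
yielding one fixed-schema row per chunk for the m x f training table.

Voice-quality LLDs (F0, HNR, formants, slopes on voiced frames) are pooled
over voiced frames only. Descriptors that cannot be measured (e.g. formants
without enough qualifying poles, jitter with fewer than three periods) are
NaN in the row; imputation is deferred to training time, where the
training-fold column median is used so no test information leaks in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.fft import dct
from scipy.signal import find_peaks, get_window

from .segment import Chunk, frame_signal
from .synth_cohort import SAMPLE_RATE

F0_MIN = 60.0
F0_MAX = 400.0
F0_FRAME_MS = 40.0
LLD_FRAME_MS = 25.0
LLD_HOP_MS = 10.0
VOICING_THRESHOLD = 0.45
EPS_MEAN = 1e-9  # floor for |mean| in stddevNorm


# ---------------------------------------------------------------- F0 tracking


def f0_track(
    x: np.ndarray,
    sr: int = SAMPLE_RATE,
    fmin: float = F0_MIN,
    fmax: float = F0_MAX,
    frame_ms: float = F0_FRAME_MS,
    hop_ms: float = LLD_HOP_MS,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-level F0 (Hz) and voicing flags.

    Normalised autocorrelation per frame; the strongest peak in the
    [sr/fmax, sr/fmin] lag range decides the pitch, refined by parabolic
    interpolation. A frame is voiced when the normalised peak reaches the
    voicing threshold and carries non-negligible energy. Unvoiced frames
    report F0 = 0.
    """
    frames = frame_signal(np.asarray(x, dtype=np.float64), sr, frame_ms, hop_ms)
    n_frames, flen = frames.shape
    if n_frames == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    frames = frames - frames.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * flen)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, :flen]
    r0 = ac[:, 0].copy()
    r0[r0 <= 0] = np.inf
    lag_min = max(int(np.floor(sr / fmax)), 2)
    lag_max = min(int(np.ceil(sr / fmin)), flen - 2)
    # unbiased normalisation: undo the (N - k)/N taper of the raw estimate
    lags = np.arange(lag_min, lag_max + 1)
    band = ac[:, lag_min : lag_max + 1] / r0[:, None] * (flen / (flen - lags))
    # subharmonic (octave) suppression: among local maxima within 10% of the
    # frame's best value, take the shortest lag rather than the global argmax
    best = band.max(axis=1, keepdims=True)
    left = np.pad(band[:, :-1], ((0, 0), (1, 0)), constant_values=-np.inf)
    right = np.pad(band[:, 1:], ((0, 0), (0, 1)), constant_values=-np.inf)
    is_peak = (band >= left) & (band >= right) & (band >= 0.9 * best)
    peak_rel = np.argmax(is_peak, axis=1)
    peak = peak_rel + lag_min
    # parabolic refinement around the peak lag
    l0 = np.clip(peak - 1, 0, flen - 1)
    l2 = np.clip(peak + 1, 0, flen - 1)
    y0 = ac[np.arange(n_frames), l0]
    y1 = ac[np.arange(n_frames), peak]
    y2 = ac[np.arange(n_frames), l2]
    denom = y0 - 2 * y1 + y2
    safe = np.where(np.abs(denom) > 1e-12, denom, 1.0)
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / safe, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    lag = peak + shift
    f0 = sr / lag
    strength = band[np.arange(n_frames), peak_rel]
    energy = np.sqrt(np.mean(frames**2, axis=1))
    voiced = (strength >= voicing_threshold) & (energy > 1e-6)
    voiced &= (f0 >= fmin) & (f0 <= fmax)
    f0 = np.where(voiced, f0, 0.0)
    return f0, voiced


# -------------------------------------------------------- jitter and shimmer


def jitter_shimmer(
    x: np.ndarray,
    sr: int,
    f0: np.ndarray,
    voiced: np.ndarray,
    hop_ms: float = LLD_HOP_MS,
) -> tuple[float, float]:
    """Chunk-level local jitter and shimmer.

    Cycle peaks are picked inside each contiguous voiced region with a
    minimum spacing of ~70% of the local period. Jitter is
    mean |T_i - T_{i-1}| / mean T over consecutive periods; shimmer the same
    functional over cycle peak amplitudes. Regions with fewer than three
    periods contribute nothing; if no region qualifies both are NaN.
    """
    hop = int(round(hop_ms / 1000.0 * sr))
    period_diffs: list[np.ndarray] = []
    periods_all: list[np.ndarray] = []
    amp_diffs: list[np.ndarray] = []
    amps_all: list[np.ndarray] = []
    v = np.asarray(voiced, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], v.view(np.int8), [0]])))
    for a, b in zip(edges[::2], edges[1::2]):
        start, end = a * hop, min(b * hop + hop, len(x))
        seg = np.asarray(x[start:end], dtype=np.float64)
        med_f0 = np.median(f0[a:b][f0[a:b] > 0]) if np.any(f0[a:b] > 0) else 0.0
        if med_f0 <= 0 or len(seg) < 3 * sr / med_f0:
            continue
        if np.max(seg, initial=0.0) < np.max(-seg, initial=0.0):
            seg = -seg
        dist = max(int(0.7 * sr / med_f0), 1)
        peaks, _ = find_peaks(seg, distance=dist, height=0.2 * np.max(seg))
        if peaks.size < 4:
            continue
        t = np.diff(peaks) / sr
        ok = (t > 0.4 / med_f0) & (t < 2.5 / med_f0)  # reject octave errors
        t = t[ok]
        if t.size < 3:
            continue
        amp = seg[peaks][1:][ok]
        periods_all.append(t)
        period_diffs.append(np.abs(np.diff(t)))
        amps_all.append(amp)
        amp_diffs.append(np.abs(np.diff(amp)))
    if not periods_all:
        return float("nan"), float("nan")
    mean_t = np.concatenate(periods_all).mean()
    mean_a = np.concatenate(amps_all).mean()
    jit = np.concatenate(period_diffs).mean() / mean_t if mean_t > 0 else np.nan
    shim = np.concatenate(amp_diffs).mean() / mean_a if mean_a > 0 else np.nan
    return float(jit), float(shim)


# ------------------------------------------------------------------------ HNR


def hnr(
    x: np.ndarray,
    sr: int,
    f0: np.ndarray,
    voiced: np.ndarray,
    frame_ms: float = F0_FRAME_MS,
    hop_ms: float = LLD_HOP_MS,
) -> np.ndarray:
    """Per-frame harmonics-to-noise ratio in dB.

    HNR = 10 log10(r / (1 - r)) with r the normalised autocorrelation at the
    pitch lag (parabolic-refined). NaN on unvoiced frames.
    """
    frames = frame_signal(np.asarray(x, dtype=np.float64), sr, frame_ms, hop_ms)
    n_frames, flen = frames.shape
    out = np.full(min(n_frames, len(f0)), np.nan)
    if n_frames == 0:
        return out
    frames = frames - frames.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * flen)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, :flen]
    for i in range(len(out)):
        if not voiced[i] or f0[i] <= 0 or ac[i, 0] <= 0:
            continue
        lag = sr / f0[i]
        k = int(round(lag))
        if k < 2 or k > flen - 2:
            continue
        y0, y1, y2 = ac[i, k - 1], ac[i, k], ac[i, k + 1]
        denom = y0 - 2 * y1 + y2
        sh = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        r = (y1 - 0.25 * (y0 - y2) * np.clip(sh, -1, 1)) / ac[i, 0]
        r *= flen / (flen - k)  # unbiased lag normalisation
        r = float(np.clip(r, 1e-6, 1.0 - 1e-6))
        out[i] = 10.0 * np.log10(r / (1.0 - r))
    return out


# -------------------------------------------------------------- spectral slope


def spectral_slope_band(
    x: np.ndarray,
    sr: int = SAMPLE_RATE,
    lo: float = 0.0,
    hi: float = 500.0,
    frame_ms: float = LLD_FRAME_MS,
    hop_ms: float = LLD_HOP_MS,
) -> np.ndarray:
    """Per-frame spectral slope (dB/octave) of the [lo, hi] Hz band.

    Linear regression of the log-magnitude spectrum on log2 frequency over
    the band's positive-frequency bins. Invariant to overall gain.
    """
    frames = frame_signal(np.asarray(x, dtype=np.float64), sr, frame_ms, hop_ms)
    if frames.shape[0] == 0:
        return np.empty(0)
    w = get_window("hann", frames.shape[1], fftbins=True)
    spec = np.abs(np.fft.rfft(frames * w, axis=1))
    freqs = np.fft.rfftfreq(frames.shape[1], 1.0 / sr)
    sel = (freqs > max(lo, 1e-9)) & (freqs <= hi)
    if sel.sum() < 3:
        raise ValueError("band too narrow for the frame's frequency resolution")
    f_oct = np.log2(freqs[sel])
    mag_db = 20.0 * np.log10(spec[:, sel] + 1e-12)
    f_c = f_oct - f_oct.mean()
    return (mag_db @ f_c) / np.dot(f_c, f_c)


# -------------------------------------------------------------------- formants


def _lpc_batch(frames: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method LPC for a batch of frames (Levinson-Durbin,
    vectorised across frames). Returns coefficient array (n, order + 1)."""
    n, flen = frames.shape
    w = get_window("hann", flen, fftbins=True)
    fw = frames * w
    nfft = int(2 ** np.ceil(np.log2(2 * flen)))
    spec = np.abs(np.fft.rfft(fw, n=nfft, axis=1)) ** 2
    r = np.fft.irfft(spec, axis=1)[:, : order + 1]
    a = np.zeros((n, order + 1))
    a[:, 0] = 1.0
    err = r[:, 0].copy()
    err[err <= 0] = np.inf
    for i in range(1, order + 1):
        acc = np.einsum("nj,nj->n", a[:, 1:i], r[:, i - 1 : 0 : -1]) if i > 1 else 0.0
        k = -(r[:, i] + acc) / err
        k = np.clip(np.nan_to_num(k), -0.9999, 0.9999)
        a_new = a.copy()
        a_new[:, 1 : i + 1] = a[:, 1 : i + 1] + k[:, None] * a[:, i - 1 :: -1][:, :i]
        a = a_new
        err = err * (1.0 - k**2)
    return a


def formants_lpc(
    x: np.ndarray,
    sr: int,
    f0: np.ndarray,
    voiced: np.ndarray,
    order: Optional[int] = None,
    frame_ms: float = LLD_FRAME_MS,
    hop_ms: float = LLD_HOP_MS,
    max_bandwidth: float = 400.0,
    frame_stride: int = 2,
) -> dict[str, np.ndarray]:
    """Formant frequencies F1-F3 and their amplitudes relative to F0.

    Pre-emphasised frames -> LPC (order 2 + sr/1000) -> polynomial roots;
    roots with bandwidth -(sr/pi) ln|r| below ``max_bandwidth`` and frequency
    in (90 Hz, sr/2 - 200) are formant candidates, sorted by frequency.
    The relative amplitude is ln|S(F_k)| - ln|S(F0)| measured on the frame
    spectrum at the harmonic peaks nearest the formant and the fundamental.
    Frames that are unvoiced or yield fewer than three candidates are NaN.
    Formants vary slowly, so only every ``frame_stride``-th voiced frame is
    analysed (the rest stay NaN and are skipped by the functionals).
    """
    order = order or (2 + sr // 1000)
    xe = np.asarray(x, dtype=np.float64)
    xe = np.concatenate([[0.0], xe[1:] - 0.97 * xe[:-1]])  # pre-emphasis
    frames_pe = frame_signal(xe, sr, frame_ms, hop_ms)
    frames_raw = frame_signal(np.asarray(x, dtype=np.float64), sr, frame_ms, hop_ms)
    n_frames = min(frames_pe.shape[0], len(f0))
    out = {
        k: np.full(n_frames, np.nan)
        for k in ("F1", "F2", "F3", "F1_rel_amp", "F2_rel_amp", "F3_rel_amp")
    }
    if n_frames == 0:
        return out
    vidx = np.flatnonzero(np.asarray(voiced[:n_frames], dtype=bool))
    vidx = vidx[:: max(frame_stride, 1)]
    if vidx.size == 0:
        return out
    a = _lpc_batch(frames_pe[vidx], order)
    # batched companion eigenvalues
    comp = np.zeros((len(vidx), order, order))
    comp[:, 1:, :-1] = np.eye(order - 1)
    comp[:, 0, :] = -a[:, 1:]
    roots = np.linalg.eigvals(comp)

    w = get_window("hann", frames_raw.shape[1], fftbins=True)
    nfft = int(2 ** np.ceil(np.log2(2 * frames_raw.shape[1])))
    spec = np.abs(np.fft.rfft(frames_raw[vidx] * w, n=nfft, axis=1))
    df = sr / nfft
    n_bins = spec.shape[1]

    def band_peak(s: np.ndarray, target: float, half_width: float) -> float:
        lo_i = max(int(np.ceil((target - half_width) / df)), 0)
        hi_i = min(int(np.floor((target + half_width) / df)) + 1, n_bins)
        return float(s[lo_i:hi_i].max()) if hi_i > lo_i else float("nan")

    for j, fi in enumerate(vidx):
        r = roots[j]
        pos = r[np.imag(r) > 1e-6]
        freq = np.angle(pos) * sr / (2 * np.pi)
        bw = -sr / np.pi * np.log(np.abs(pos) + 1e-12)
        ok = (freq > 90.0) & (freq < sr / 2 - 200.0) & (bw < max_bandwidth)
        cand = np.sort(freq[ok])
        if cand.size < 3:
            continue
        s = spec[j]
        f0i = f0[fi]
        a0 = band_peak(s, f0i, 0.6 * f0i)
        for k in range(3):
            out[f"F{k + 1}"][fi] = cand[k]
            ak = band_peak(s, cand[k], max(0.6 * f0i, 50.0))
            if a0 > 0 and ak > 0:
                out[f"F{k + 1}_rel_amp"][fi] = float(np.log(ak) - np.log(a0))
    return out


# ----------------------------------------------------------------------- MFCC


def _mel(f: np.ndarray) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + f / 700.0)


def _mel_inv(m: np.ndarray) -> np.ndarray:
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def mel_filterbank(
    sr: int, nfft: int, n_mels: int = 26, fmin: float = 0.0, fmax: Optional[float] = None
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, nfft // 2 + 1)."""
    fmax = fmax or sr / 2.0
    pts = _mel_inv(np.linspace(_mel(np.array(fmin)), _mel(np.array(fmax)), n_mels + 2))
    bins = np.fft.rfftfreq(nfft, 1.0 / sr)
    fb = np.zeros((n_mels, bins.size))
    for i in range(n_mels):
        left, center, right = pts[i], pts[i + 1], pts[i + 2]
        up = (bins - left) / max(center - left, 1e-9)
        down = (right - bins) / max(right - center, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mfcc(
    x: np.ndarray,
    sr: int = SAMPLE_RATE,
    n_coeffs: int = 12,
    n_mels: int = 26,
    frame_ms: float = LLD_FRAME_MS,
    hop_ms: float = LLD_HOP_MS,
) -> np.ndarray:
    """MFCC 1..n_coeffs per frame (26 mel bands, DCT-II, c0 excluded)."""
    frames = frame_signal(np.asarray(x, dtype=np.float64), sr, frame_ms, hop_ms)
    if frames.shape[0] == 0:
        return np.empty((0, n_coeffs))
    w = get_window("hann", frames.shape[1], fftbins=True)
    nfft = int(2 ** np.ceil(np.log2(frames.shape[1])))
    power = np.abs(np.fft.rfft(frames * w, n=nfft, axis=1)) ** 2
    fb = mel_filterbank(sr, nfft, n_mels)
    mel_power = power @ fb.T
    # gain-relative floor keeps c1..c12 invariant to overall signal gain
    floor = 1e-8 * mel_power.max(axis=1, keepdims=True) + 1e-300
    logmel = np.log(np.maximum(mel_power, floor))
    cc = dct(logmel, type=2, norm="ortho", axis=1)
    return cc[:, 1 : n_coeffs + 1]


# ---------------------------------------------------------------- functionals


@dataclass
class LldFrameSeries:
    """Frame-aligned low-level descriptors of one chunk (10 ms hop)."""

    f0: np.ndarray
    voiced: np.ndarray
    energy: np.ndarray
    hnr_db: np.ndarray
    slope: np.ndarray
    mfcc: np.ndarray
    formants: dict[str, np.ndarray]
    jitter_local: float
    shimmer_local: float
    voiced_fraction: float


def extract_llds(chunk: Chunk) -> LldFrameSeries:
    """Compute all frame-level descriptors for one chunk."""
    x, sr = chunk.samples, chunk.sr
    f0, voiced = f0_track(x, sr)
    frames = frame_signal(np.asarray(x, dtype=np.float64), sr)
    energy = (
        np.sqrt(np.mean(frames**2, axis=1)) if frames.size else np.empty(0)
    )
    n = min(len(f0), len(energy))
    f0, voiced, energy = f0[:n], voiced[:n], energy[:n]
    h = hnr(x, sr, f0, voiced)[:n]
    slope = spectral_slope_band(x, sr)[:n] if n else np.empty(0)
    cc = mfcc(x, sr)[:n] if n else np.empty((0, 12))
    fmts = formants_lpc(x, sr, f0, voiced)
    fmts = {k: v[:n] for k, v in fmts.items()}
    jit, shim = jitter_shimmer(x, sr, f0, voiced)
    vf = float(np.mean(voiced)) if n else 0.0
    return LldFrameSeries(
        f0=f0, voiced=voiced, energy=energy, hnr_db=h, slope=slope, mfcc=cc,
        formants=fmts, jitter_local=jit, shimmer_local=shim, voiced_fraction=vf,
    )


def _amean(v: np.ndarray) -> float:
    v = v[np.isfinite(v)]
    return float(v.mean()) if v.size else float("nan")


def _stddev_norm(v: np.ndarray) -> float:
    """Coefficient of variation: population sd over |mean| (floored)."""
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    return float(v.std() / max(abs(v.mean()), EPS_MEAN))


#: fixed feature schema (column order is part of the table contract)
FEATURE_COLUMNS = [
    "F0_amean", "F0_stddevNorm",
    "energy_amean", "energy_stddevNorm",
    "jitterLocal", "shimmerLocal",
    "HNR_amean", "HNR_stddevNorm",
    "slopeV0-500_amean", "slopeV0-500_stddevNorm",
    "slopeUV0-500_amean",
    "F1frequency_amean", "F2frequency_amean", "F3frequency_amean",
    "F2amplitudeLogRelF0_amean", "F2amplitudeLogRelF0_stddevNorm",
    "F3amplitudeLogRelF0_amean", "F3amplitudeLogRelF0_stddevNorm",
    "mfcc1_amean", "mfcc2_amean", "mfcc3_amean", "mfcc4_amean",
    "voicedFraction",
]


def functionals(lld: LldFrameSeries) -> dict[str, float]:
    """Summarise a chunk's LLD series into the fixed functional row."""
    v = lld.voiced.astype(bool)
    uv = ~v
    f0v = lld.f0[v]
    row = {
        "F0_amean": _amean(f0v),
        "F0_stddevNorm": _stddev_norm(f0v),
        "energy_amean": _amean(lld.energy),
        "energy_stddevNorm": _stddev_norm(lld.energy),
        "jitterLocal": lld.jitter_local,
        "shimmerLocal": lld.shimmer_local,
        "HNR_amean": _amean(lld.hnr_db[v]),
        "HNR_stddevNorm": _stddev_norm(lld.hnr_db[v]),
        "slopeV0-500_amean": _amean(lld.slope[v]),
        "slopeV0-500_stddevNorm": _stddev_norm(lld.slope[v]),
        "slopeUV0-500_amean": _amean(lld.slope[uv]),
        "F1frequency_amean": _amean(lld.formants["F1"][v]),
        "F2frequency_amean": _amean(lld.formants["F2"][v]),
        "F3frequency_amean": _amean(lld.formants["F3"][v]),
        "F2amplitudeLogRelF0_amean": _amean(lld.formants["F2_rel_amp"][v]),
        "F2amplitudeLogRelF0_stddevNorm": _stddev_norm(lld.formants["F2_rel_amp"][v]),
        "F3amplitudeLogRelF0_amean": _amean(lld.formants["F3_rel_amp"][v]),
        "F3amplitudeLogRelF0_stddevNorm": _stddev_norm(lld.formants["F3_rel_amp"][v]),
        "voicedFraction": lld.voiced_fraction,
    }
    for k in range(4):
        col = lld.mfcc[:, k] if lld.mfcc.size else np.empty(0)
        row[f"mfcc{k + 1}_amean"] = _amean(col)
    return row


def chunk_feature_row(chunk: Chunk) -> dict[str, float]:
    row = {"patient_id": chunk.patient_id, "chunk_index": chunk.chunk_index}
    row.update(functionals(extract_llds(chunk)))
    return row


def feature_table(chunks: Sequence[Chunk]) -> pd.DataFrame:
    """One row per chunk, fixed column order: patient_id, chunk_index, LLD
    functionals."""
    rows = [chunk_feature_row(c) for c in chunks]
    df = pd.DataFrame(rows)
    return df[["patient_id", "chunk_index"] + FEATURE_COLUMNS]


def impute_train_median(
    train: pd.DataFrame, test: Optional[pd.DataFrame] = None
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Fill missing feature values with the training-table column median.

    The median is computed on the training rows only and applied to both
    tables, so test-fold information never leaks into training. An
    all-missing column falls back to zero.
    """
    cols = [c for c in train.columns if c in FEATURE_COLUMNS]
    med = train[cols].median()
    med = med.fillna(0.0)
    train = train.copy()
    train[cols] = train[cols].fillna(med)
    if test is not None:
        test = test.copy()
        test[cols] = test[cols].fillna(med)
    return train, test
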