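"""Single-channel speech enhancement: log-spectral-amplitude MMSE.

The classic log-MMSE estimator: the noisy signal is taken to the short-time
spectral domain, each time-frequency bin is attenuated by the gain

    G = xi / (1 + xi) * exp(0.5 * E1(v)),   v = xi * gamma / (1 + xi),

where ``gamma`` is the a-posteriori SNR against a running noise power
estimate, ``xi`` the a-priori SNR tracked by the decision-directed rule with
smoothing constant ``alpha``, and ``E1`` the exponential integral. The noise
PSD is initialised from the leading frames and updated on frames judged to
contain no speech. The enhanced signal is reconstructed by windowed
overlap-add, trimmed to the input length.

Defaults: 32 ms Hann frames, 8 ms hop, alpha = 0.98, gain floor 1e-3.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import get_window
from scipy.special import exp1

from .synth_cohort import SAMPLE_RATE

#: a-priori SNR floor, -25 dB (keeps residual noise natural)
XI_MIN = 10.0 ** (-25.0 / 10.0)


def stft(
    x: np.ndarray, frame: int = 512, hop: int = 128, window: str = "hann"
) -> np.ndarray:
    """Short-time spectra, shape (n_frames, frame // 2 + 1).

    ``hop`` must divide the analysis into overlapping frames (hop <= frame),
    otherwise perfect reconstruction is impossible and a ValueError is raised.
    """
    x = np.asarray(x, dtype=np.float64)
    if hop <= 0 or hop > frame:
        raise ValueError(f"hop must satisfy 0 < hop <= frame ({hop} vs {frame})")
    if x.size < frame:
        raise ValueError("input shorter than one analysis frame")
    w = get_window(window, frame, fftbins=True)
    n_frames = 1 + (x.size - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return np.fft.rfft(x[idx] * w, axis=1)


def istft(
    spectra: np.ndarray,
    frame: int = 512,
    hop: int = 128,
    window: str = "hann",
    length: int | None = None,
) -> np.ndarray:
    """Overlap-add inverse of :func:`stft` (synthesis window = analysis window,
    normalised by the summed squared window)."""
    if hop <= 0 or hop > frame:
        raise ValueError(f"hop must satisfy 0 < hop <= frame ({hop} vs {frame})")
    spectra = np.asarray(spectra)
    if spectra.ndim != 2 or spectra.shape[1] != frame // 2 + 1:
        raise ValueError("spectra shape does not match the frame length")
    w = get_window(window, frame, fftbins=True)
    frames = np.fft.irfft(spectra, n=frame, axis=1) * w
    n_frames = frames.shape[0]
    n = frame + hop * (n_frames - 1)
    out = np.zeros(n)
    norm = np.zeros(n)
    for i in range(n_frames):
        out[i * hop : i * hop + frame] += frames[i]
        norm[i * hop : i * hop + frame] += w * w
    # Floor the normaliser: at the extreme edges the summed squared window
    # vanishes and the quotient would explode for any non-identity spectral
    # modification. Interior samples are unaffected.
    out /= np.maximum(norm, 1e-3 * norm.max())
    if length is not None:
        out = out[:length] if length <= n else np.pad(out, (0, length - n))
    return out


def enhance(
    waveform: np.ndarray,
    sr: int = SAMPLE_RATE,
    frame_ms: float = 32.0,
    hop_ms: float = 8.0,
    alpha: float = 0.98,
    noise_frames: int = 6,
    gain_floor: float = 1e-3,
) -> np.ndarray:
    """Denoise a waveform with the log-MMSE estimator.

    Deterministic; output has the same length as the input. An all-zero
    input yields an all-zero output. The per-bin gain is bounded in
    (gain_floor, 1], so no bin is ever amplified.
    """
    x = np.asarray(waveform, dtype=np.float64)
    frame = int(round(frame_ms / 1000.0 * sr))
    hop = int(round(hop_ms / 1000.0 * sr))
    if x.size < frame:
        raise ValueError("input shorter than one analysis frame")
    if not np.any(x):
        return np.zeros_like(x)

    spectra = stft(x, frame=frame, hop=hop)
    power = np.abs(spectra) ** 2
    n_frames, n_bins = power.shape

    # Minimum-statistics initialisation: average the lowest-energy frames
    # (at least `noise_frames`, up to 5% of the signal). Robust to recordings
    # that open mid-speech, unlike a strictly leading-frame estimate.
    n_init = min(n_frames, max(noise_frames, n_frames // 20))
    quiet = np.argsort(power.mean(axis=1))[:n_init]
    noise_psd = np.maximum(power[quiet].mean(axis=0), 1e-12)

    gains = np.empty_like(power)
    prev_clean = power[0]  # running |amplitude|^2 estimate for decision-directed xi
    for t in range(n_frames):
        gamma = np.minimum(power[t] / noise_psd, 1e4)
        if t == 0:
            xi = np.maximum(gamma - 1.0, 0.0)
        else:
            xi = alpha * prev_clean / noise_psd + (1.0 - alpha) * np.maximum(
                gamma - 1.0, 0.0
            )
        xi = np.maximum(xi, XI_MIN)
        v = np.clip(xi * gamma / (1.0 + xi), 1e-8, 700.0)
        g = xi / (1.0 + xi) * np.exp(0.5 * exp1(v))
        g = np.clip(g, gain_floor, 1.0)
        gains[t] = g
        prev_clean = (g**2) * power[t]
        # Speech-absence test: mean log-likelihood ratio under the Gaussian
        # model; near zero when the frame is noise only.
        llr = np.mean(gamma * xi / (1.0 + xi) - np.log1p(xi))
        if llr < 0.15:
            noise_psd = 0.9 * noise_psd + 0.1 * power[t]
            noise_psd = np.maximum(noise_psd, 1e-12)

    out = istft(spectra * gains, frame=frame, hop=hop, length=x.size)
    return out
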