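"""Per-epoch EEG/EMG feature extraction.

The spectral scheme mirrors the study protocol: each 10-s epoch is the mean
of five consecutive 2-s FFT windows (256 points at 128 Hz, so 0.5 Hz bins).
Windows are Hann-tapered with power normalisation: the reported per-bin
powers sum to the taper-weighted variance of the (mean-removed) window, so
Parseval-style conservation holds exactly per window.

Beyond band powers and EMG tone, the module provides the signal-irregularity
(sample entropy) and signal-fractality (detrended fluctuation analysis)
features used as scoring cues, and the theta-regularity index (sharpness of
the theta spectral peak) that separates REM sleep from theta-poor states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import StudyConfig, ValidationError

__all__ = [
    "EpochSpectrum",
    "EpochFeatures",
    "epoch_spectrum",
    "band_power",
    "emg_tone",
    "sample_entropy",
    "dfa_alpha",
    "theta_regularity",
    "relative_power",
    "notch_50hz",
    "windowed_periodograms",
]


@dataclass
class EpochSpectrum:
    """One-sided power spectrum of an epoch (uV^2 per frequency bin)."""

    frequencies: np.ndarray
    power: np.ndarray
    epoch_index: int = 0
    stage: int | None = None

    @property
    def resolution_hz(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class EpochFeatures:
    """Scoring features of one analysis window."""

    delta_power: float
    theta_power: float
    theta_regularity: float
    emg_tone: float
    entropy: float = np.nan
    dfa_alpha: float = np.nan

    def __post_init__(self):
        if self.delta_power < 0 or self.theta_power < 0:
            raise ValidationError("band powers must be non-negative")


def _hann_power_periodogram(segments: np.ndarray) -> np.ndarray:
    """Power spectra of (n_windows, n_points) segments, Hann-tapered.

    Each window is mean-removed before tapering. Normalisation is chosen so
    that the one-sided bins sum to sum(w^2 x^2)/sum(w^2) — the
    taper-weighted mean square of the window (exact Parseval conservation).
    """
    n = segments.shape[-1]
    w = np.hanning(n)
    demeaned = segments - segments.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(demeaned * w, axis=-1)
    p = (np.abs(spec) ** 2) / (n * np.sum(w ** 2))
    p[..., 1:] *= 2.0
    if n % 2 == 0:
        p[..., -1] /= 2.0
    return p


def windowed_periodograms(x: np.ndarray, n_points: int, hop: int) -> np.ndarray:
    """Hann power spectra of windows of ``n_points`` samples every ``hop``.

    Returns an array of shape (n_windows, n_points//2 + 1). Used both by
    the epoch spectra (hop = window length) and by the sliding per-second
    staging features (hop = 1 s of samples).
    """
    x = np.asarray(x, dtype=float)
    n_windows = (len(x) - n_points) // hop + 1
    if n_windows < 1:
        raise ValidationError("signal shorter than one FFT window")
    idx = np.arange(n_points)[None, :] + hop * np.arange(n_windows)[:, None]
    return _hann_power_periodogram(x[idx])


def epoch_spectrum(eeg_segment: np.ndarray, cfg: StudyConfig | None = None,
                   epoch_index: int = 0) -> EpochSpectrum:
    """Spectrum of one scoring epoch: mean of the consecutive 2-s windows.

    The segment must be exactly one epoch long (10 s at the configured
    sampling rate); the five 2-s windows tile it without overlap.
    """
    cfg = cfg or StudyConfig()
    expected = int(round(cfg.epoch_s * cfg.sampling_rate))
    eeg_segment = np.asarray(eeg_segment, dtype=float)
    if len(eeg_segment) != expected:
        raise ValidationError(
            f"epoch segment must have {expected} samples, got {len(eeg_segment)}")
    p = windowed_periodograms(eeg_segment, cfg.fft_points, cfg.fft_points)
    assert p.shape[0] == cfg.windows_per_epoch
    freqs = np.fft.rfftfreq(cfg.fft_points, d=1.0 / cfg.sampling_rate)
    return EpochSpectrum(frequencies=freqs, power=p.mean(axis=0),
                         epoch_index=epoch_index)


def band_power(spec: EpochSpectrum, lo: float, hi: float) -> float:
    """Total power in [lo, hi) Hz (sum over bins with lo <= f < hi)."""
    nyq = spec.frequencies[-1]
    # hi may extend one bin past Nyquist so [0, nyq + df) covers the full grid
    if not 0 <= lo < hi <= nyq + spec.resolution_hz + 1e-9:
        raise ValidationError(f"invalid band [{lo}, {hi}) for Nyquist {nyq}")
    mask = (spec.frequencies >= lo) & (spec.frequencies < hi)
    return float(spec.power[mask].sum())


def relative_power(spec: EpochSpectrum, lo: float = 0.5, hi: float = 30.0) -> np.ndarray:
    """Per-bin power over [lo, hi) normalised to sum to 1 over that range."""
    mask = (spec.frequencies >= lo) & (spec.frequencies < hi)
    total = spec.power[mask].sum()
    if total == 0:
        return np.zeros(mask.sum())
    return spec.power[mask] / total


def emg_tone(emg_segment: np.ndarray) -> float:
    """Muscle tone: RMS of the mean-removed EMG window (uV)."""
    x = np.asarray(emg_segment, dtype=float)
    if x.size == 0:
        raise ValidationError("empty EMG segment")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -log of the conditional template-match ratio.

    Templates of length ``m`` that match within Chebyshev tolerance ``r``
    (default 0.2 x SD of the series) are checked for whether they still
    match at length m+1; self-matches are excluded. Returns ``inf`` when no
    template pair matches at length m+1 (flagging, not an error).
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 100:
        raise ValidationError("sample entropy needs at least 100 samples")
    if r is None:
        r = 0.2 * float(np.std(x))

    def match_count(mm: int) -> int:
        n_t = len(x) - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        total = 0
        step = 512
        for a in range(0, n_t, step):
            block = emb[a:a + step]
            d = np.abs(block[:, None, :] - emb[None, :, :]).max(axis=-1)
            hits = (d <= r).sum()
            # remove self-matches on the diagonal of this block
            total += int(hits) - block.shape[0]
        return total

    b = match_count(m)
    a = match_count(m + 1)
    if a == 0 or b == 0:
        return float("inf")
    return float(-np.log(a / b))


def dfa_alpha(series: np.ndarray, scales: np.ndarray | None = None) -> float:
    """Detrended fluctuation analysis scaling exponent.

    The series is integrated after mean removal; for each scale n the
    integrated profile is cut into non-overlapping windows of n samples,
    each linearly detrended, and F(n) is the RMS residual. The exponent is
    the slope of log F(n) on log n (0.5 for white noise, 1.5 for its
    cumulative sum).
    """
    x = np.asarray(series, dtype=float)
    if scales is None:
        scales = np.unique(np.geomspace(16, 512, 8).astype(int))
    scales = np.asarray(scales, dtype=int)
    if len(scales) < 3:
        raise ValidationError("need at least 3 scales for a DFA fit")
    if len(x) < 4 * scales.max():
        raise ValidationError(
            f"series too short for DFA: need >= {4 * scales.max()} samples")
    profile = np.cumsum(x - x.mean())
    fluct = np.empty(len(scales))
    for i, n in enumerate(scales):
        n_win = len(profile) // n
        seg = profile[:n_win * n].reshape(n_win, n)
        t = np.arange(n)
        # closed-form linear detrend per window
        tm = t.mean()
        denom = ((t - tm) ** 2).sum()
        slope = ((seg - seg.mean(axis=1, keepdims=True)) * (t - tm)).sum(axis=1) / denom
        resid = seg - (seg.mean(axis=1, keepdims=True) + slope[:, None] * (t - tm))
        fluct[i] = np.sqrt(np.mean(resid ** 2))
    coeffs = np.polyfit(np.log(scales), np.log(fluct), 1)
    return float(coeffs[0])


def theta_regularity(spec: EpochSpectrum, band: tuple[float, float] = (6.0, 9.0)) -> float:
    """Sharpness of the theta peak: peak-bin power (+-0.5 Hz) over band power.

    1 for a pure narrow-band theta rhythm, about 3 bins / n_bins for a flat
    spectrum, and 0 by convention when the band carries no power.
    """
    mask = (spec.frequencies >= band[0]) & (spec.frequencies < band[1])
    p = spec.power[mask]
    total = p.sum()
    if total <= 0:
        return 0.0
    peak = int(np.argmax(p))
    lo, hi = max(0, peak - 1), min(len(p), peak + 2)
    return float(np.clip(p[lo:hi].sum() / total, 0.0, 1.0))


def notch_50hz(x: np.ndarray, fs: float) -> np.ndarray:
    """2nd-order 49-51 Hz band-stop, for parity with mains-filtered data."""
    if fs <= 102:
        raise ValidationError("50 Hz notch requires sampling rate above 102 Hz")
    sos = sps.butter(2, [49.0, 51.0], btype="bandstop", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)
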