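"""Rule-based vigilance staging.

Reproduces the expert labelling procedure this pipeline mirrors: the
dominant vigilance state is decided for 25-s windows from EEG delta and
theta power, theta regularity, and EMG tone; the windows are shifted in 1-s
increments to give per-second labels, which are then aggregated to 10-s
epochs by majority vote.

Decision rule (in order, per window):

1. **Wake** if EMG tone exceeds the subject's adaptive threshold (a
   quantile of that subject's own EMG-tone distribution);
2. else **NREM** if the delta ratio delta/(delta+theta) is high;
3. else **REM** if the theta peak is regular (sharp);
4. else **NREM** (fallback).

Thresholds are adaptive per subject to mimic scorer adaptation; the window
at second t covers [t-12, t+13) seconds, clipped at the record boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import EpochFeatures, windowed_periodograms
from .types import (
    NREM,
    REM,
    WAKE,
    Hypnogram,
    SignalRecord,
    StudyConfig,
    ValidationError,
)

__all__ = [
    "StagingThresholds",
    "score_window",
    "per_second_features",
    "fit_thresholds",
    "per_second_labels",
    "aggregate_epochs",
    "stage_record",
    "staging_confusion",
]

WINDOW_S = 25
_HALF_BEFORE, _HALF_AFTER = 12, 13  # [t-12, t+13) covers 25 s


@dataclass
class StagingThresholds:
    """Adaptive per-subject staging cut-offs.

    ``emg_wake_quantile`` positions the wake threshold on the subject's own
    EMG-tone distribution; ``emg_wake_uv`` is the resolved absolute value
    once fitted. The delta-ratio and theta-regularity cuts are fixed.
    """

    emg_wake_quantile: float = 0.60
    delta_ratio_cut: float = 0.55
    theta_reg_cut: float = 0.50
    emg_wake_uv: float | None = None

    def __post_init__(self):
        for name in ("emg_wake_quantile", "delta_ratio_cut", "theta_reg_cut"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1)")


def score_window(features: EpochFeatures, thr: StagingThresholds) -> int:
    """Stage one 25-s window. Requires fitted (absolute) EMG threshold."""
    if thr.emg_wake_uv is None:
        raise ValidationError("thresholds not fitted: emg_wake_uv is unset")
    if features.emg_tone > thr.emg_wake_uv:
        return WAKE
    denom = features.delta_power + features.theta_power
    delta_ratio = features.delta_power / denom if denom > 0 else 1.0
    if delta_ratio >= thr.delta_ratio_cut:
        return NREM
    if features.theta_regularity >= thr.theta_reg_cut:
        return REM
    return NREM


def per_second_features(record: SignalRecord, cfg: StudyConfig | None = None) -> pd.DataFrame:
    """Sliding 25-s window features, one row per second of recording.

    Spectral features come from averaging the 2-s FFT windows (1-s hop)
    whose span lies inside the 25-s window; EMG tone is the RMS of the raw
    window. Columns: delta_power, theta_power, theta_regularity, emg_tone.
    """
    cfg = cfg or StudyConfig(sampling_rate=record.sampling_rate)
    record.validate_for_staging()
    fs = record.sampling_rate
    if fs != int(fs):
        raise ValidationError("staging requires an integer sampling rate")
    fs = int(fs)
    total_s = int(record.duration_s)
    if total_s < WINDOW_S:
        raise ValidationError(f"record shorter than one {WINDOW_S}-s staging window")

    eeg = record.get("EEG").samples
    emg = record.get("EMG").samples

    # 2-s Hann periodograms hopped by 1 s: spectrum k covers [k, k+2) s
    spectra = windowed_periodograms(eeg, cfg.fft_points, fs)
    freqs = np.fft.rfftfreq(cfg.fft_points, d=1.0 / fs)
    delta_mask = (freqs >= cfg.swa_band[0]) & (freqs < cfg.swa_band[1])
    theta_mask = (freqs >= cfg.theta_band[0]) & (freqs < cfg.theta_band[1])
    delta_w = spectra[:, delta_mask].sum(axis=1)
    theta_bins = spectra[:, theta_mask]

    # prefix sums for O(1) window averages over subwindow ranges
    c_delta = np.concatenate([[0.0], np.cumsum(delta_w)])
    c_theta_bins = np.vstack([np.zeros(theta_bins.shape[1]),
                              np.cumsum(theta_bins, axis=0)])
    sq = np.concatenate([[0.0], np.cumsum(emg.astype(float) ** 2)])
    sm = np.concatenate([[0.0], np.cumsum(emg.astype(float))])

    t = np.arange(total_s)
    a = np.maximum(t - _HALF_BEFORE, 0)
    b = np.minimum(t + _HALF_AFTER, total_s)
    # subwindows fully inside [a, b): starts a .. b-2
    k_lo, k_hi = a, np.minimum(b - 1, spectra.shape[0])  # exclusive hi
    n_sub = (k_hi - k_lo).astype(float)

    delta = (c_delta[k_hi] - c_delta[k_lo]) / n_sub
    theta_mat = (c_theta_bins[k_hi] - c_theta_bins[k_lo]) / n_sub[:, None]
    theta = theta_mat.sum(axis=1)

    # theta regularity on the averaged window spectrum
    tot = theta_mat.sum(axis=1)
    peak = np.argmax(theta_mat, axis=1)
    nb = theta_mat.shape[1]
    reg = np.zeros(total_s)
    for off in (-1, 0, 1):
        j = np.clip(peak + off, 0, nb - 1)
        valid = (peak + off >= 0) & (peak + off < nb)
        reg[valid] += theta_mat[np.arange(total_s), j][valid]
    nz = tot > 0
    reg[nz] = np.clip(reg[nz] / tot[nz], 0.0, 1.0)
    reg[~nz] = 0.0

    sa, sb = a * fs, b * fs
    n = (sb - sa).astype(float)
    mean = (sm[sb] - sm[sa]) / n
    var = (sq[sb] - sq[sa]) / n - mean ** 2
    emg_rms = np.sqrt(np.maximum(var, 0.0))

    return pd.DataFrame({
        "second": t,
        "delta_power": delta,
        "theta_power": theta,
        "theta_regularity": reg,
        "emg_tone": emg_rms,
    })


def fit_thresholds(features: pd.DataFrame,
                   thr: StagingThresholds | None = None) -> StagingThresholds:
    """Resolve the adaptive EMG threshold on this subject's distribution."""
    thr = thr or StagingThresholds()
    emg_cut = float(np.quantile(features["emg_tone"], thr.emg_wake_quantile))
    return StagingThresholds(emg_wake_quantile=thr.emg_wake_quantile,
                             delta_ratio_cut=thr.delta_ratio_cut,
                             theta_reg_cut=thr.theta_reg_cut,
                             emg_wake_uv=emg_cut)


def _score_frame(features: pd.DataFrame, thr: StagingThresholds) -> np.ndarray:
    delta = features["delta_power"].to_numpy()
    theta = features["theta_power"].to_numpy()
    reg = features["theta_regularity"].to_numpy()
    emg = features["emg_tone"].to_numpy()
    denom = delta + theta
    ratio = np.where(denom > 0, delta / np.where(denom > 0, denom, 1.0), 1.0)
    labels = np.full(len(features), NREM, dtype=np.int8)
    labels[(ratio < thr.delta_ratio_cut) & (reg >= thr.theta_reg_cut)] = REM
    labels[emg > thr.emg_wake_uv] = WAKE
    return labels


def per_second_labels(record: SignalRecord, thr: StagingThresholds | None = None,
                      cfg: StudyConfig | None = None) -> np.ndarray:
    """Per-second vigilance labels for a record (length = floor(duration))."""
    feats = per_second_features(record, cfg)
    thr = thr if thr is not None and thr.emg_wake_uv is not None \
        else fit_thresholds(feats, thr)
    return _score_frame(feats, thr)


def aggregate_epochs(per_second: np.ndarray, epoch_s: float = 10.0,
                     start_zt: float = 0.0, subject_id: str = "subject",
                     genotype: str = "WT", sex: str = "M") -> Hypnogram:
    """Aggregate per-second labels to epochs by modal label.

    A trailing partial epoch is truncated. Ties break by the fixed priority
    W > N > R (wake wins, then NREM).
    """
    per_second = np.asarray(per_second)
    k = int(epoch_s)
    n_epochs = len(per_second) // k
    sec = per_second[:n_epochs * k].reshape(n_epochs, k)
    counts = np.stack([(sec == s).sum(axis=1) for s in (WAKE, NREM, REM)], axis=1)
    labels = counts.argmax(axis=1).astype(np.int8)  # argmax tie-break = W > N > R
    return Hypnogram(labels=labels, epoch_s=epoch_s, start_zt=start_zt,
                     subject_id=subject_id, genotype=genotype, sex=sex)


def stage_record(record: SignalRecord, cfg: StudyConfig | None = None,
                 thr: StagingThresholds | None = None,
                 overrides: dict[int, int] | None = None) -> Hypnogram:
    """EDF-to-hypnogram convenience path, with optional manual overrides
    (epoch_index -> state code) standing in for post-hoc scorer correction."""
    cfg = cfg or StudyConfig(sampling_rate=record.sampling_rate)
    sec = per_second_labels(record, thr, cfg)
    hyp = aggregate_epochs(sec, cfg.epoch_s, start_zt=record.start_zt,
                           subject_id=record.subject_id)
    if overrides:
        for idx, state in overrides.items():
            hyp.labels[int(idx)] = state
    return hyp


def staging_confusion(pred: Hypnogram, truth: Hypnogram) -> dict:
    """Confusion counts (rows = truth, cols = predicted) and per-state recall."""
    if len(pred) != len(truth) or pred.epoch_s != truth.epoch_s:
        raise ValidationError("hypnograms differ in length or epoch size")
    matrix = np.zeros((3, 3), dtype=int)
    for t, p in zip(truth.labels, pred.labels):
        matrix[t, p] += 1
    row = matrix.sum(axis=1)
    recall = np.divide(np.diag(matrix), row, out=np.full(3, np.nan), where=row > 0)
    accuracy = np.trace(matrix) / max(matrix.sum(), 1)
    return {"matrix": matrix, "recall": recall, "accuracy": float(accuracy)}
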