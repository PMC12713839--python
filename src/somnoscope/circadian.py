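"""Locomotor-activity rhythm metrics.

Activity profiles and phase totals summarise entrained (LD) days on the ZT
grid; the chi-square periodogram (the Sokolove-Bushell statistic Qp)
quantifies rhythmicity and estimates the free-running period from
constant-darkness (DD) days; actogram matrices support the usual
double-plotted raster displays.

For a candidate period P binned into K columns over N complete cycles,

    Qp = N * sum_h (M_h - M)^2 / s^2,    s^2 = sum_i (x_i - M)^2 / (K N)

where M_h are the K column means of the data folded at P and the sums run
over the K*N bins used (incomplete trailing cycles are dropped). Under the
no-rhythm null each M_h has variance s^2/N, so Qp is approximately
chi-square with K-1 degrees of freedom, giving the per-candidate
significance line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ActivitySeries, ValidationError, rebin_activity

__all__ = [
    "activity_profile",
    "phase_totals",
    "chi_square_periodogram",
    "PeriodogramResult",
    "actogram_matrix",
    "activity_onsets",
]


def _require_ld_whole_days(act: ActivitySeries) -> ActivitySeries:
    if act.light_schedule.dd:
        raise ValidationError("ZT-referenced summaries require entrained (LD) data")
    ld = act.ld_part()
    if len(ld) == 0 or len(ld) % ld.bins_per_day:
        raise ValidationError("need whole recorded LD days")
    return ld


def activity_profile(act: ActivitySeries, bin_h: float = 1.0) -> pd.DataFrame:
    """Mean counts per ZT bin across LD days (one row per bin)."""
    ld = _require_ld_whole_days(act)
    if (bin_h * 60) % ld.bin_min:
        raise ValidationError("profile bin must be a multiple of the data bin")
    if 24.0 % bin_h != 0:
        raise ValidationError("profile bin must divide 24 h")
    coarse = rebin_activity(ld, bin_h * 60)
    days = int(coarse.n_days)
    per_day = coarse.counts.reshape(days, -1)
    zt = (coarse.start_zt + np.arange(per_day.shape[1]) * bin_h) % 24.0
    order = np.argsort(zt)
    return pd.DataFrame({
        "zt_start": zt[order],
        "mean_counts": per_day.mean(axis=0)[order],
    })


def phase_totals(act: ActivitySeries) -> dict[str, float]:
    """Mean daily activity totals: 24 h, light 12 h, dark 12 h (LD days).

    Light + dark equals the 24-h total exactly.
    """
    ld = _require_ld_whole_days(act)
    light = np.asarray(ld.light_schedule.is_light(ld.bin_zt))
    days = ld.n_days
    total = ld.counts.sum() / days
    light_total = ld.counts[light].sum() / days
    return {"total": float(total), "light": float(light_total),
            "dark": float(total - light_total)}


@dataclass
class PeriodogramResult:
    """Chi-square periodogram over a candidate-period grid."""

    periods_h: np.ndarray
    qp: np.ndarray
    threshold: np.ndarray
    best_period_h: float
    best_qp: float
    #: peak Qp minus its significance threshold ("Qp above significance")
    best_qp_excess: float
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"period_h": self.periods_h, "qp": self.qp,
                             "threshold": self.threshold})


def chi_square_periodogram(act: ActivitySeries, p_min_h: float = 20.0,
                           p_max_h: float = 28.0, alpha: float = 0.05,
                           min_cycles: int = 2) -> PeriodogramResult:
    """Sokolove-Bushell chi-square periodogram of an activity series.

    Candidate periods run from ``p_min_h`` to ``p_max_h`` in steps of one
    data bin (the finest step the folding supports). Requires at least
    ``min_cycles`` complete cycles at the longest candidate. Both the raw
    peak Qp and its excess over the significance line are reported, since
    different analysis packages print either.
    """
    x = np.asarray(act.counts, dtype=float)
    bin_h = act.bin_min / 60.0
    if len(x) * bin_h < min_cycles * p_max_h:
        raise ValidationError(
            f"need at least {min_cycles} complete cycles at {p_max_h} h")
    k_min = int(np.ceil(p_min_h / bin_h))
    k_max = int(np.floor(p_max_h / bin_h))
    periods, qps, thresholds = [], [], []
    for k in range(k_min, k_max + 1):
        n_cyc = len(x) // k
        if n_cyc < min_cycles:
            continue
        used = x[:n_cyc * k]
        folded = used.reshape(n_cyc, k)
        col_means = folded.mean(axis=0)
        grand = used.mean()
        denom = ((used - grand) ** 2).sum()
        if denom == 0:
            qp = 0.0
        else:
            # N * sum_h (M_h - M)^2 / s^2 with s^2 = denom / (K N)
            qp = k * n_cyc ** 2 * ((col_means - grand) ** 2).sum() / denom
        periods.append(k * bin_h)
        qps.append(qp)
        thresholds.append(stats.chi2.ppf(1 - alpha, df=k - 1))
    if not periods:
        raise ValidationError("no candidate periods in range")
    periods = np.array(periods)
    qps = np.array(qps)
    thresholds = np.array(thresholds)
    best = int(np.argmax(qps))
    return PeriodogramResult(
        periods_h=periods, qp=qps, threshold=thresholds,
        best_period_h=float(periods[best]), best_qp=float(qps[best]),
        best_qp_excess=float(qps[best] - thresholds[best]), alpha=alpha)


def actogram_matrix(act: ActivitySeries, double_plot: bool = True) -> np.ndarray:
    """Day-by-day activity raster: rows are days, columns time-of-day bins.

    When double-plotted, each row concatenates day d with day d+1 (48 h per
    row), the standard display for spotting free-running drift.
    """
    bpd = act.bins_per_day
    if len(act.counts) % bpd:
        raise ValidationError("actogram requires whole recorded days")
    days = len(act.counts) // bpd
    mat = act.counts.reshape(days, bpd)
    if not double_plot:
        return mat
    nxt = np.vstack([mat[1:], np.zeros((1, bpd))])
    return np.hstack([mat, nxt])


def activity_onsets(act: ActivitySeries, frac_of_max: float = 0.2,
                    min_quiet_h: float = 4.0) -> pd.DataFrame:
    """Daily activity onset times (QC aid for free-running drift).

    Onset of a day = first bin of the longest run of bins above
    ``frac_of_max`` of that day's maximum that follows at least
    ``min_quiet_h`` hours below it. Returns hours from each day's start;
    days without a qualifying run yield NaN.
    """
    bpd = act.bins_per_day
    days = len(act.counts) // bpd
    quiet_bins = int(min_quiet_h * 60 / act.bin_min)
    rows = []
    for d in range(days):
        day = act.counts[d * bpd:(d + 1) * bpd]
        thr = frac_of_max * day.max() if day.max() > 0 else np.inf
        above = day > thr
        onset = np.nan
        best_len = 0
        i = 0
        while i < bpd:
            if above[i]:
                j = i
                while j < bpd and above[j]:
                    j += 1
                quiet = i - np.max(np.nonzero(above[:i])[0], initial=-1) - 1
                if quiet >= quiet_bins and (j - i) > best_len:
                    best_len = j - i
                    onset = i * act.bin_min / 60.0
                i = j
            else:
                i += 1
        rows.append({"day": d, "onset_h": onset})
    return pd.DataFrame(rows)
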