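"""Hypnogram-derived sleep architecture statistics.

Everything here is computed from the per-epoch label sequence (plus epoch
spectra for the slow-wave-activity time course): state-time profiles in ZT
bins, episode (bout) counts and durations, the five analysed state
transitions with their conditional probabilities, REM-latency histograms,
and the SWA time course.

Conventions (documented, conservation-friendly):

* episodes are maximal runs, no minimum-bout smoothing;
* an episode belongs to the ZT bin containing its onset;
* a transition belongs to the bin containing the post-transition epoch;
* any phase (light/dark) assignment uses the event's onset ZT;
* multi-day recordings are folded onto the 24-h ZT grid, and per-bin
  quantities that scale with time (minutes, counts) are reported per day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    NREM,
    REM,
    STATE_NAMES,
    TRANSITION_TYPES,
    WAKE,
    Hypnogram,
    LightSchedule,
    ValidationError,
)

__all__ = [
    "Episode",
    "find_episodes",
    "state_time_profile",
    "transition_table",
    "TransitionTable",
    "rem_latencies",
    "rem_latency_histogram",
    "episode_summary",
    "swa_timecourse",
    "stage_mean_spectra",
]


@dataclass(frozen=True)
class Episode:
    """A maximal run of consecutive epochs in one vigilance state."""

    state: int
    start_epoch: int
    length_epochs: int
    start_zt: float
    duration_s: float


def find_episodes(hyp: Hypnogram) -> list[Episode]:
    """Split a hypnogram into its maximal constant-state runs."""
    if len(hyp) == 0:
        raise ValidationError("empty hypnogram")
    labels = hyp.labels
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(labels)]])
    zt = hyp.epoch_zt
    return [
        Episode(state=int(labels[a]), start_epoch=int(a),
                length_epochs=int(b - a), start_zt=float(zt[a]),
                duration_s=float((b - a) * hyp.epoch_s))
        for a, b in zip(starts, stops)
    ]


def _bin_index(zt: np.ndarray, bin_h: float) -> np.ndarray:
    if 24.0 % bin_h != 0:
        raise ValidationError("bin width must divide 24 h")
    return (np.mod(zt, 24.0) // bin_h).astype(int)


def state_time_profile(hyp: Hypnogram, bin_h: float = 1.0) -> pd.DataFrame:
    """Minutes per day spent in each state per ZT bin.

    The recording must tile whole bins (enforced via whole days here: the
    profile is ZT-folded, averaging across recorded days). Per bin, minutes
    sum to the bin length across the three states.
    """
    n_per_day = int(round(86400 / hyp.epoch_s))
    if len(hyp) % n_per_day or hyp.start_zt % bin_h:
        raise ValidationError("profiles require whole recorded days starting on a bin edge")
    days = len(hyp) / n_per_day
    bins = _bin_index(hyp.epoch_zt, bin_h)
    rows = []
    for b in range(int(24 / bin_h)):
        in_bin = bins == b
        for s in (WAKE, NREM, REM):
            minutes = (in_bin & (hyp.labels == s)).sum() * hyp.epoch_s / 60.0 / days
            rows.append({"bin": b, "zt_start": b * bin_h, "state": STATE_NAMES[s],
                         "minutes": minutes})
    return pd.DataFrame(rows)


@dataclass
class TransitionTable:
    """Counts and conditional probabilities of the five analysed transitions.

    ``counts`` has one row per (ZT bin, transition type) with per-day counts;
    ``conditional`` holds, per phase (light/dark), each transition's count
    divided by the total transitions leaving its pre-state — e.g.
    P(NREM->REM) = #(N->R) / (#(N->W) + #(N->R)). Direct wake-to-REM
    occurrences are excluded from the table and surfaced as a QC count.
    """

    counts: pd.DataFrame
    conditional: pd.DataFrame
    w_to_r_qc: int


def transition_table(hyp: Hypnogram, bin_h: float = 6.0,
                     schedule: LightSchedule | None = None) -> TransitionTable:
    """Count state transitions at epoch boundaries, per ZT bin and phase."""
    schedule = schedule or LightSchedule()
    labels = hyp.labels
    if len(labels) < 2:
        raise ValidationError("need at least two epochs")
    n_per_day = int(round(86400 / hyp.epoch_s))
    days = max(len(hyp) / n_per_day, 1e-12)
    pre, post = labels[:-1], labels[1:]
    moved = pre != post
    zt_post = hyp.epoch_zt[1:]
    bins = _bin_index(zt_post, bin_h)

    w_to_r = int(((pre == WAKE) & (post == REM) & moved).sum())
    rows = []
    for b in range(int(24 / bin_h)):
        for s_from, s_to in TRANSITION_TYPES:
            n = int(((bins == b) & (pre == s_from) & (post == s_to)).sum())
            rows.append({
                "bin": b, "zt_start": b * bin_h,
                "transition": f"{STATE_NAMES[s_from]}->{STATE_NAMES[s_to]}",
                "count": n, "count_per_day": n / days,
            })
    counts = pd.DataFrame(rows)

    light_post = np.asarray(schedule.is_light(zt_post))
    cond_rows = []
    for phase, mask in (("light", light_post), ("dark", ~light_post)):
        totals = {}
        for s_from, s_to in TRANSITION_TYPES:
            n = int((mask & (pre == s_from) & (post == s_to)).sum())
            totals[(s_from, s_to)] = n
        for s_from in (WAKE, NREM, REM):
            out = {k: v for k, v in totals.items() if k[0] == s_from}
            denom = sum(out.values())
            for (sf, st), n in out.items():
                cond_rows.append({
                    "phase": phase,
                    "transition": f"{STATE_NAMES[sf]}->{STATE_NAMES[st]}",
                    "count": n,
                    "probability": n / denom if denom else np.nan,
                })
    return TransitionTable(counts=counts, conditional=pd.DataFrame(cond_rows),
                           w_to_r_qc=w_to_r)


def rem_latencies(hyp: Hypnogram, wake_reset_min_epochs: int = 1,
                  schedule: LightSchedule | None = None) -> pd.DataFrame:
    """REM latency (seconds from NREM onset to REM onset) per REM episode.

    The latency clock starts at a wake-to-NREM transition and is reset by
    any wake episode of at least ``wake_reset_min_epochs`` epochs. REM
    episodes entered through NREM after an R->N return (no intervening
    wake) keep the original post-wake NREM onset. REM at the recording
    start with no preceding NREM onset is excluded and counted as QC.
    Columns: latency_s, onset_zt, phase.
    """
    schedule = schedule or LightSchedule()
    episodes = find_episodes(hyp)
    rows = []
    excluded = 0
    nrem_onset_s: float | None = None
    for i, ep in enumerate(episodes):
        t_start = ep.start_epoch * hyp.epoch_s
        if ep.state == WAKE:
            if ep.length_epochs >= wake_reset_min_epochs:
                nrem_onset_s = None
        elif ep.state == NREM:
            if nrem_onset_s is None:
                # only a wake-to-NREM (or recording-start) onset arms the clock
                prev = episodes[i - 1] if i else None
                if prev is None or prev.state == WAKE:
                    nrem_onset_s = t_start
        else:  # REM
            if nrem_onset_s is None:
                excluded += 1
                continue
            zt = float(np.mod(ep.start_zt, 24.0))
            rows.append({
                "latency_s": t_start - nrem_onset_s,
                "onset_zt": zt,
                "phase": "light" if schedule.is_light(zt) else "dark",
            })
    df = pd.DataFrame(rows, columns=["latency_s", "onset_zt", "phase"])
    df.attrs["qc_excluded"] = excluded
    return df


def rem_latency_histogram(hyp: Hypnogram, bin_s: float = 50.0,
                          max_s: float = 600.0,
                          wake_reset_min_epochs: int = 1,
                          schedule: LightSchedule | None = None) -> pd.DataFrame:
    """Histogram of REM latencies in fixed bins per phase.

    Bins are [0, bin_s), [bin_s, 2 bin_s), ... up to ``max_s`` plus a final
    open-ended overflow bin. Counts are totals over the recording; the sum
    of counts plus the QC-excluded episodes equals the number of REM
    episodes.
    """
    lat = rem_latencies(hyp, wake_reset_min_epochs, schedule)
    edges = np.arange(0.0, max_s + bin_s, bin_s)
    rows = []
    for phase in ("light", "dark"):
        values = lat.loc[lat["phase"] == phase, "latency_s"].to_numpy()
        hist, _ = np.histogram(values, bins=edges)
        for i, c in enumerate(hist):
            rows.append({"phase": phase, "bin_lo_s": edges[i],
                         "bin_hi_s": edges[i + 1], "count": int(c)})
        rows.append({"phase": phase, "bin_lo_s": max_s, "bin_hi_s": np.inf,
                     "count": int((values >= max_s).sum())})
    out = pd.DataFrame(rows)
    out.attrs["qc_excluded"] = lat.attrs["qc_excluded"]
    return out


def episode_summary(episodes: list[Episode], hyp: Hypnogram,
                    bin_h: float = 6.0) -> pd.DataFrame:
    """Episode count (per day) and mean duration per ZT bin and state.

    Episodes are assigned to the bin containing their onset. Empty cells
    report count 0 and a missing mean duration.
    """
    n_per_day = int(round(86400 / hyp.epoch_s))
    days = max(len(hyp) / n_per_day, 1e-12)
    rows = []
    onset_bins = _bin_index(np.array([e.start_zt for e in episodes]), bin_h)
    for b in range(int(24 / bin_h)):
        for s in (WAKE, NREM, REM):
            durs = [e.duration_s for e, eb in zip(episodes, onset_bins)
                    if eb == b and e.state == s]
            rows.append({
                "bin": b, "zt_start": b * bin_h, "state": STATE_NAMES[s],
                "count": len(durs), "count_per_day": len(durs) / days,
                "mean_duration_s": float(np.mean(durs)) if durs else np.nan,
            })
    return pd.DataFrame(rows)


def swa_timecourse(swa_per_epoch: np.ndarray, hyp: Hypnogram,
                   bin_h: float = 6.0) -> pd.DataFrame:
    """Slow-wave activity time course, % of the 24-h mean NREM SWA.

    ``swa_per_epoch`` is the 0.5-4 Hz EEG band power of each epoch; only
    NREM epochs contribute. Normalisation is per subject: the mean SWA over
    all NREM epochs defines 100%. Bins without NREM epochs are missing.
    """
    swa = np.asarray(swa_per_epoch, dtype=float)
    if len(swa) != len(hyp):
        raise ValidationError("SWA vector and hypnogram differ in length")
    nrem = hyp.labels == NREM
    if not nrem.any():
        raise ValidationError("no NREM epochs: SWA time course undefined")
    ref = swa[nrem].mean()
    bins = _bin_index(hyp.epoch_zt, bin_h)
    rows = []
    for b in range(int(24 / bin_h)):
        sel = nrem & (bins == b)
        rows.append({
            "bin": b, "zt_start": b * bin_h,
            "swa_percent": 100.0 * swa[sel].mean() / ref if sel.any() else np.nan,
            "n_nrem_epochs": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def stage_mean_spectra(rel_power: np.ndarray, freqs: np.ndarray,
                       hyp: Hypnogram) -> pd.DataFrame:
    """Mean relative EEG spectrum per vigilance state (long format)."""
    rel_power = np.asarray(rel_power)
    if rel_power.shape[0] != len(hyp):
        raise ValidationError("spectra and hypnogram differ in length")
    rows = []
    for s in (WAKE, NREM, REM):
        sel = hyp.labels == s
        if not sel.any():
            continue
        mean = rel_power[sel].mean(axis=0)
        for f, p in zip(freqs, mean):
            rows.append({"stage": STATE_NAMES[s], "frequency_hz": float(f),
                         "relative_power": float(p)})
    return pd.DataFrame(rows)
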