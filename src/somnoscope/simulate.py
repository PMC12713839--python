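"""Synthetic cohort generator.

Emulates the three data streams of a mouse sleep/circadian study:

* **Hypnograms** — a first-order Markov chain over (W, N, R) stepped once per
  10-s epoch, with separate transition matrices for the light and dark
  phases (and optionally a third matrix for a mid-dark "napping" window,
  ZT19-21, seen in wild-type animals). Direct wake-to-REM transitions are
  structurally impossible, matching their near-absence in rodents.
* **EEG/EMG signals** — per vigilance state, narrow-band oscillations
  (delta-dominant NREM around 2 Hz, theta-dominant REM around 7 Hz) riding
  on 1/f background noise, with EMG as white noise whose RMS is high in
  wake and minimal in REM. Oscillator phase is continuous within an episode
  and reset at episode boundaries.
* **Activity counts** — negative-binomial counts per 1-min bin around a
  nocturnal waveform with an early-dark peak; entrained at 24.0 h during LD
  days, free-running at ``period_h`` (near 23.7 h) during DD days.

The genotype presets inject the qualitative effects this pipeline is meant
to recover: relative to ``WT``, the ``MUT`` preset has a lower NREM-to-REM
transition rate in the light phase, a higher one in the dark phase (hence
more dark-phase REM and fewer short-latency REM entries in the light), no
mid-dark nap, and reduced, less sharply peaked nocturnal activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    NREM,
    REM,
    WAKE,
    ActivitySeries,
    Channel,
    Hypnogram,
    LightSchedule,
    SignalRecord,
    ValidationError,
)

__all__ = [
    "VigilanceKinetics",
    "SpectralRecipe",
    "ActivityModel",
    "simulate_hypnogram",
    "synthesize_signals",
    "simulate_activity",
    "genotype_presets",
    "preset_recipe",
    "stationary_distribution",
]


def _check_matrix(P: np.ndarray, name: str) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.shape != (3, 3):
        raise ValidationError(f"{name} must be 3x3")
    if (P < 0).any():
        raise ValidationError(f"{name} has negative entries")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValidationError(f"{name} rows must sum to 1")
    if P[WAKE, REM] != 0:
        raise ValidationError(f"{name}: direct W->R transitions must have probability 0")
    return P


@dataclass
class VigilanceKinetics:
    """Per-epoch transition matrices of the vigilance-state chain.

    Rows/columns are ordered (W, N, R); ``P[i, j]`` is the probability of
    being in state j at the next epoch given state i now.
    """

    P_light: np.ndarray
    P_dark: np.ndarray
    #: optional matrix for the mid-dark napping window; None disables it
    P_nap: np.ndarray | None = None
    nap_window_zt: tuple[float, float] = (19.0, 21.0)
    pi: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self):
        self.P_light = _check_matrix(self.P_light, "P_light")
        self.P_dark = _check_matrix(self.P_dark, "P_dark")
        if self.P_nap is not None:
            self.P_nap = _check_matrix(self.P_nap, "P_nap")
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (3,) or not np.isclose(self.pi.sum(), 1.0):
            raise ValidationError("pi must be a 3-vector summing to 1")

    def matrix_at(self, zt: float, schedule: LightSchedule) -> np.ndarray:
        zt24 = zt % 24.0
        if self.P_nap is not None and self.nap_window_zt[0] <= zt24 < self.nap_window_zt[1]:
            return self.P_nap
        return self.P_light if schedule.is_light(zt24) else self.P_dark


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 3-state transition matrix."""
    w, v = np.linalg.eig(np.asarray(P, dtype=float).T)
    vec = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    return vec / vec.sum()


@dataclass
class OscillationBand:
    """A narrow-band EEG oscillation: carrier frequency jittered per episode."""

    center_hz: float
    bandwidth_hz: float
    amplitude_uv: float

    def __post_init__(self):
        if self.amplitude_uv < 0:
            raise ValidationError("oscillation amplitude must be non-negative")


@dataclass
class SpectralRecipe:
    """State-conditioned signal statistics for EEG/EMG synthesis.

    ``bands[state]`` lists the oscillations present in that state;
    ``background_scale_uv[state]`` sets the RMS of the 1/f background and
    ``emg_rms_uv[state]`` the EMG white-noise RMS. ``nrem_delta_light_gain``
    multiplies the NREM delta amplitude during the light phase (1.0 = no
    phase modulation), used to emulate time-of-day slow-wave-activity
    gradients.
    """

    bands: dict[int, list[OscillationBand]]
    background_exponent: float = 1.0
    background_scale_uv: dict[int, float] = field(
        default_factory=lambda: {WAKE: 15.0, NREM: 10.0, REM: 8.0})
    emg_rms_uv: dict[int, float] = field(
        default_factory=lambda: {WAKE: 25.0, NREM: 6.0, REM: 2.5})
    nrem_delta_light_gain: float = 1.0

    def validate_preset_ordering(self) -> None:
        """Preset sanity: NREM delta dominates REM delta; wake EMG dominates sleep."""
        def band_amp(state, lo, hi):
            return max((b.amplitude_uv for b in self.bands.get(state, [])
                        if lo <= b.center_hz < hi), default=0.0)
        if not band_amp(NREM, 0.5, 4.0) > band_amp(REM, 0.5, 4.0):
            raise ValidationError("recipe must have NREM delta amplitude > REM delta amplitude")
        if not (self.emg_rms_uv[WAKE] > self.emg_rms_uv[NREM]
                and self.emg_rms_uv[WAKE] > self.emg_rms_uv[REM]):
            raise ValidationError("recipe must have wake EMG tone above sleep EMG tone")


@dataclass
class ActivityModel:
    """Generative model of home-cage activity counts.

    ``mean_counts_per_min`` is the all-day average; the waveform allocates
    ``dark_fraction`` of daily activity to the (subjective) dark phase, with
    ``early_dark_peak_weight`` boosting the first 3 h after (subjective)
    dark onset. Counts are negative-binomial with dispersion ``k`` (variance
    mu + mu^2/k), reflecting over-dispersed beam-break counts.
    """

    period_h: float = 23.7
    dark_fraction: float = 0.9
    early_dark_peak_weight: float = 2.0
    mean_counts_per_min: float = 20.0
    dispersion: float = 5.0
    days_ld: int = 7
    days_dd: int = 10

    def __post_init__(self):
        if not 20.0 <= self.period_h <= 28.0:
            raise ValidationError("period_h must lie in [20, 28] h")
        if not 0.0 <= self.dark_fraction <= 1.0:
            raise ValidationError("dark_fraction must lie in [0, 1]")


def simulate_hypnogram(kin: VigilanceKinetics, days: float, epoch_s: float = 10.0,
                       seed: int | np.random.Generator = 0, start_zt: float = 0.0,
                       subject_id: str = "sim", genotype: str = "WT",
                       sex: str = "M") -> Hypnogram:
    """Simulate a hypnogram by stepping the Markov chain once per epoch.

    The matrix applied at each step is chosen by the zeitgeber time of the
    epoch being entered (light, dark, or nap window). Deterministic for a
    fixed (kinetics, days, seed).
    """
    if days <= 0:
        raise ValidationError("days must be positive")
    rng = np.random.default_rng(seed)
    n_epochs = int(round(days * 86400 / epoch_s))
    schedule = LightSchedule()
    labels = np.empty(n_epochs, dtype=np.int8)
    state = int(rng.choice(3, p=kin.pi))
    # precompute per-epoch regime index to avoid rebuilding matrices
    zt = (start_zt + np.arange(n_epochs) * epoch_s / 3600.0) % 24.0
    regime = np.where(np.asarray(schedule.is_light(zt)), 0, 1)
    if kin.P_nap is not None:
        lo, hi = kin.nap_window_zt
        regime[(zt >= lo) & (zt < hi)] = 2
    mats = [kin.P_light, kin.P_dark,
            kin.P_nap if kin.P_nap is not None else kin.P_dark]
    cum = [np.cumsum(m, axis=1) for m in mats]
    u = rng.random(n_epochs)
    for i in range(n_epochs):
        labels[i] = state
        state = int(np.searchsorted(cum[regime[i]][state], u[i], side="right"))
        state = min(state, 2)
    return Hypnogram(labels=labels, epoch_s=epoch_s, start_zt=start_zt,
                     subject_id=subject_id, genotype=genotype, sex=sex)


def _colored_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape, n)
    return out / max(out.std(), 1e-12)


def synthesize_signals(hyp: Hypnogram, recipe: SpectralRecipe, fs: float = 128.0,
                       seed: int | np.random.Generator = 0, n_eeg: int = 2,
                       n_emg: int = 2) -> SignalRecord:
    """Synthesize an EEG/EMG record consistent with a hypnogram.

    Per EEG channel: for each episode, one sinusoid per recipe band with a
    carrier drawn from N(center, bandwidth/2) and a random initial phase
    (phase continuous across the episode), plus 1/f background scaled by the
    per-sample state. EMG channels are white noise at the state RMS.
    """
    if fs < 64:
        raise ValidationError("sampling rate must be at least 64 Hz for staging features")
    rng = np.random.default_rng(seed)
    spe = int(round(hyp.epoch_s * fs))  # samples per epoch
    n = len(hyp) * spe
    state_per_sample = np.repeat(hyp.labels, spe)
    light_per_sample = np.repeat(hyp.phase_mask(), spe)
    t = np.arange(n) / fs

    # episode boundaries (index ranges of constant state)
    change = np.flatnonzero(np.diff(hyp.labels)) + 1
    starts = np.concatenate([[0], change]) * spe
    stops = np.concatenate([change, [len(hyp)]]) * spe
    ep_states = hyp.labels[np.concatenate([[0], change])]

    channels = []
    for k in range(n_eeg):
        bg = _colored_noise(n, recipe.background_exponent, rng)
        scale = np.array([recipe.background_scale_uv[s] for s in (WAKE, NREM, REM)])
        eeg = bg * scale[state_per_sample]
        for a, b, s in zip(starts, stops, ep_states):
            for band in recipe.bands.get(int(s), []):
                f = rng.normal(band.center_hz, band.bandwidth_hz / 2.0)
                f = float(np.clip(f, 0.1, fs / 2 - 0.5))
                phase = rng.uniform(0, 2 * np.pi)
                amp = band.amplitude_uv
                osc = amp * np.sin(2 * np.pi * f * t[a:b] + phase)
                if (int(s) == NREM and band.center_hz < 4.0
                        and recipe.nrem_delta_light_gain != 1.0):
                    gain = np.where(light_per_sample[a:b],
                                    recipe.nrem_delta_light_gain, 1.0)
                    osc = osc * gain
                eeg[a:b] += osc
        channels.append(Channel(f"EEG{k + 1}", "EEG", eeg))
    emg_scale = np.array([recipe.emg_rms_uv[s] for s in (WAKE, NREM, REM)])
    for k in range(n_emg):
        emg = rng.standard_normal(n) * emg_scale[state_per_sample]
        channels.append(Channel(f"EMG{k + 1}", "EMG", emg))
    return SignalRecord(channels=channels, sampling_rate=fs, start_zt=hyp.start_zt,
                        subject_id=hyp.subject_id)


def _activity_waveform(model: ActivityModel, phase: np.ndarray) -> np.ndarray:
    """Expected counts/min as a function of circadian phase in [0, 1).

    Phase 0 = (subjective) lights-on; the active period occupies the second
    half-cycle [0.5, 1.0), with the early-dark peak in its first quarter.
    """
    dark = phase >= 0.5
    w = np.empty_like(phase)
    # relative weights: light bins share (1 - dark_fraction), dark bins share
    # dark_fraction, early dark boosted by the peak weight
    w[~dark] = (1.0 - model.dark_fraction) / 0.5
    w[dark] = model.dark_fraction / 0.5
    early = dark & (phase < 0.625)  # first 3 h of a 24-h-scaled cycle
    base_dark = model.dark_fraction / 0.5
    boost = model.early_dark_peak_weight
    # renormalise so the dark-phase total is preserved
    frac_early = 0.25
    denom = frac_early * boost + (1 - frac_early)
    w[dark] = base_dark * (1 - frac_early + frac_early * boost) / denom  # late dark level
    w[dark & ~early] = base_dark / denom
    w[early] = base_dark * boost / denom
    return w * model.mean_counts_per_min


def simulate_activity(model: ActivityModel, seed: int | np.random.Generator = 0,
                      bin_min: float = 1.0, subject_id: str = "sim",
                      noise: bool = True) -> ActivitySeries:
    """Simulate LD-entrained then free-running activity counts.

    During the LD days the waveform repeats at exactly 24 h; from the first
    DD day onward circadian phase advances at ``period_h`` per cycle, so
    activity onset drifts by (24 - period_h) hours per day. With
    ``noise=False`` the expected waveform is returned (useful for oracles).
    """
    rng = np.random.default_rng(seed)
    bins_per_day = int(round(24 * 60 / bin_min))
    n_ld = model.days_ld * bins_per_day
    n_dd = model.days_dd * bins_per_day
    t_h = np.arange(n_ld + n_dd) * bin_min / 60.0
    phase = np.empty(n_ld + n_dd)
    phase[:n_ld] = (t_h[:n_ld] / 24.0) % 1.0
    t_dd = t_h[n_ld:] - model.days_ld * 24.0
    phase[n_ld:] = (t_dd / model.period_h) % 1.0
    mu = _activity_waveform(model, phase) * bin_min
    if noise:
        k = model.dispersion
        lam = rng.gamma(shape=k, scale=np.maximum(mu, 1e-12) / k)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = mu
    return ActivitySeries(counts=counts, bin_min=bin_min, start_zt=0.0,
                          subject_id=subject_id,
                          dd_start_day=model.days_ld if model.days_dd else None)


# ---------------------------------------------------------------------------
# Genotype presets. Numeric values are the package's study conditions: they
# give realistic murine state fractions (about 48% wake per 24 h, light-phase
# REM near 60 min/12 h in WT) and inject the mutant phenotype through the
# NREM->REM rates and the activity waveform.

_WT_LIGHT = np.array([
    [0.928, 0.072, 0.000],
    [0.043, 0.932, 0.025],
    [0.060, 0.100, 0.840],
])
_WT_DARK = np.array([
    [0.968, 0.032, 0.000],
    [0.052, 0.938, 0.010],
    [0.055, 0.105, 0.840],
])
_MUT_LIGHT = np.array([
    [0.928, 0.072, 0.000],
    [0.043, 0.943, 0.014],
    [0.060, 0.100, 0.840],
])
_MUT_DARK = np.array([
    [0.960, 0.040, 0.000],
    [0.045, 0.937, 0.018],
    [0.055, 0.105, 0.840],
])


def genotype_presets() -> dict[str, tuple[VigilanceKinetics, ActivityModel]]:
    """Documented numeric presets for the two genotypes.

    ``MUT`` relative to ``WT``: lower light-phase and higher dark-phase
    NREM->REM rate, shorter dark wake bouts, no mid-dark nap window, a
    slightly shorter free-running period, and reduced nocturnal activity
    with a flatter early-dark peak.
    """
    wt_kin = VigilanceKinetics(P_light=_WT_LIGHT, P_dark=_WT_DARK,
                               P_nap=_WT_LIGHT.copy())
    mut_kin = VigilanceKinetics(P_light=_MUT_LIGHT, P_dark=_MUT_DARK)
    wt_act = ActivityModel(period_h=23.75, dark_fraction=0.90,
                           early_dark_peak_weight=2.5, mean_counts_per_min=20.0)
    mut_act = ActivityModel(period_h=23.68, dark_fraction=0.88,
                            early_dark_peak_weight=1.4, mean_counts_per_min=13.0)
    return {"WT": (wt_kin, wt_act), "MUT": (mut_kin, mut_act)}


def preset_recipe(genotype: str = "WT") -> SpectralRecipe:
    """Spectral recipe used with the genotype presets.

    NREM carries a strong ~2 Hz delta oscillation, REM a narrow ~7 Hz theta
    rhythm, wake a weaker broad theta on a desynchronised background. The
    mutant preset has mildly elevated NREM delta amplitude (its NREM
    spectrum is shifted toward low frequencies).
    """
    nrem_delta = 50.0 if genotype == "MUT" else 45.0
    recipe = SpectralRecipe(bands={
        WAKE: [OscillationBand(7.5, 2.0, 15.0)],
        NREM: [OscillationBand(2.0, 0.8, nrem_delta)],
        REM: [OscillationBand(7.0, 0.4, 35.0)],
    })
    recipe.validate_preset_ordering()
    return recipe
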