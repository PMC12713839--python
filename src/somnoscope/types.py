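"""Shared data model for polysomnography and circadian-activity analysis.

The package works with three kinds of recordings from a mouse sleep study:

* multichannel EEG/EMG signals (:class:`SignalRecord`),
* vigilance-state hypnograms scored in fixed epochs (:class:`Hypnogram`),
* locomotor/wheel activity counts in fixed time bins (:class:`ActivitySeries`).

All timing is expressed in zeitgeber time (ZT): hours since lights-on, so
ZT0-12 is the light phase and ZT12-24 the dark phase under a 12:12 LD cycle.
Vigilance states use the integer codes ``W=0`` (wake), ``N=1`` (NREM sleep)
and ``R=2`` (REM sleep) everywhere in the package; this module is the single
source of truth for those codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

# Vigilance-state codes. Order matters: it is also the row/column order of
# every transition matrix in the package.
WAKE, NREM, REM = 0, 1, 2
STATE_CODES = {"W": WAKE, "N": NREM, "R": REM}
STATE_NAMES = {WAKE: "W", NREM: "N", REM: "R"}
N_STATES = 3

#: The five transition types analysed (wake-to-REM transitions are excluded
#: as physiologically negligible in healthy rodents).
TRANSITION_TYPES = (
    (WAKE, NREM),
    (NREM, WAKE),
    (NREM, REM),
    (REM, NREM),
    (REM, WAKE),
)


class ValidationError(ValueError):
    """Raised when an input violates the data-model invariants."""


@dataclass(frozen=True)
class LightSchedule:
    """Lighting regime of a recording.

    ``lights_on_zt`` is 0 by definition of zeitgeber time; ``lights_off_zt``
    marks the start of the dark phase. ``dd=True`` flags constant darkness
    (free-running conditions), in which case ZT is interpreted as nominal
    clock time carried over from the preceding entrained cycle.
    """

    lights_on_zt: float = 0.0
    lights_off_zt: float = 12.0
    dd: bool = False

    def is_light(self, zt: np.ndarray | float) -> np.ndarray | bool:
        """Whether a ZT value (hours, any real) falls in the light phase.

        Under DD this is always False. Bins are half-open: ZT 12.0 is dark.
        """
        zt24 = np.mod(zt, 24.0)
        if self.dd:
            return np.zeros_like(np.asarray(zt24), dtype=bool) if np.ndim(zt24) else False
        return (zt24 >= self.lights_on_zt) & (zt24 < self.lights_off_zt)


@dataclass(frozen=True)
class Channel:
    """One recorded signal trace, in microvolts."""

    name: str
    role: str  # "EEG" or "EMG"
    samples: np.ndarray

    def __post_init__(self):
        if self.role not in ("EEG", "EMG"):
            raise ValidationError(f"channel {self.name!r}: role must be EEG or EMG, got {self.role!r}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))


@dataclass
class SignalRecord:
    """Multichannel EEG/EMG recording at a fixed sampling rate.

    Parameters
    ----------
    channels
        Ordered channels; at least one EEG and one EMG channel are required
        for staging (enforced by :func:`SignalRecord.validate_for_staging`).
    sampling_rate
        Hz. The study digitised at 128 Hz.
    start_zt
        Zeitgeber time of the first sample, hours in [0, 24).
    light_schedule
        Lighting regime; defaults to 12:12 LD.
    meta
        Free-form acquisition metadata (e.g. analog filter bands, notch).
        The hardware band-pass quoted for such recordings (EEG 0.5-250 Hz)
        exceeds the digital Nyquist limit and is therefore kept as metadata
        only, never re-applied digitally.
    """

    channels: list[Channel]
    sampling_rate: float
    start_zt: float = 0.0
    light_schedule: LightSchedule = field(default_factory=LightSchedule)
    subject_id: str = "subject"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if not self.channels:
            raise ValidationError("record has no channels")
        n = {len(c.samples) for c in self.channels}
        if len(n) != 1:
            raise ValidationError(f"channels differ in length: {sorted(n)}")
        if not 0 <= self.start_zt < 24:
            raise ValidationError("start_zt must lie in [0, 24)")

    @property
    def n_samples(self) -> int:
        return len(self.channels[0].samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def get(self, role: str, index: int = 0) -> Channel:
        """Return the index-th channel with the given role."""
        matches = [c for c in self.channels if c.role == role]
        if not matches:
            raise ValidationError(f"record has no {role} channel")
        return matches[index]

    def validate_for_staging(self) -> None:
        roles = {c.role for c in self.channels}
        if not {"EEG", "EMG"} <= roles:
            raise ValidationError(
                "staging requires at least one EEG and one EMG channel; "
                f"got roles {sorted(roles)}"
            )


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels on a fixed grid aligned to zeitgeber time."""

    labels: np.ndarray
    epoch_s: float = 10.0
    start_zt: float = 0.0
    subject_id: str = "subject"
    genotype: str = "WT"
    sex: str = "M"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.epoch_s <= 0:
            raise ValidationError("epoch_s must be positive")
        if self.labels.size and not np.isin(self.labels, [WAKE, NREM, REM]).all():
            bad = sorted(set(self.labels.tolist()) - {WAKE, NREM, REM})
            raise ValidationError(f"labels outside the 3-state alphabet: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.epoch_s

    @property
    def epoch_zt(self) -> np.ndarray:
        """ZT (hours, unwrapped over days) of each epoch onset."""
        return self.start_zt + np.arange(len(self.labels)) * self.epoch_s / 3600.0

    def phase_mask(self, schedule: LightSchedule | None = None) -> np.ndarray:
        """Boolean mask, True where the epoch onset falls in the light phase."""
        schedule = schedule or LightSchedule()
        return np.asarray(schedule.is_light(self.epoch_zt))


@dataclass
class ActivitySeries:
    """Locomotor or wheel-running counts per fixed time bin."""

    counts: np.ndarray
    bin_min: float = 1.0
    start_zt: float = 0.0
    light_schedule: LightSchedule = field(default_factory=LightSchedule)
    subject_id: str = "subject"
    #: index (in days from recording start) of the first constant-darkness
    #: day; None when the whole series is entrained LD.
    dd_start_day: int | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_min <= 0 or 60.0 % self.bin_min != 0:
            raise ValidationError("bin_min must be positive and divide 60")
        if self.counts.size and (self.counts < 0).any():
            raise ValidationError("activity counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def bins_per_day(self) -> int:
        return int(round(24 * 60 / self.bin_min))

    @property
    def n_days(self) -> float:
        return len(self.counts) / self.bins_per_day

    @property
    def bin_zt(self) -> np.ndarray:
        """ZT (hours, unwrapped) of each bin onset."""
        return self.start_zt + np.arange(len(self.counts)) * self.bin_min / 60.0

    def ld_part(self) -> "ActivitySeries":
        """The entrained (LD) prefix of the series."""
        if self.dd_start_day is None:
            return self
        n = int(self.dd_start_day * self.bins_per_day)
        return replace(self, counts=self.counts[:n])

    def dd_part(self) -> "ActivitySeries":
        """The constant-darkness suffix of the series."""
        if self.dd_start_day is None:
            raise ValidationError("series has no DD segment")
        n = int(self.dd_start_day * self.bins_per_day)
        return replace(self, counts=self.counts[n:],
                       light_schedule=LightSchedule(dd=True), dd_start_day=None)


def rebin_activity(act: ActivitySeries, new_bin_min: float) -> ActivitySeries:
    """Sum counts into coarser bins. ``new_bin_min`` must be a multiple of the
    current bin width and the series length must tile the new bins."""
    k = new_bin_min / act.bin_min
    if k != int(k) or k < 1:
        raise ValidationError("new bin width must be a whole multiple of the old")
    k = int(k)
    if len(act.counts) % k:
        raise ValidationError("series length does not tile the requested bins")
    counts = act.counts.reshape(-1, k).sum(axis=1)
    return replace(act, counts=counts, bin_min=new_bin_min)


@dataclass
class StudyConfig:
    """Analysis parameters, with the study's defaults.

    The FFT scheme (2-s windows, 256 points at 128 Hz, hence 0.5 Hz
    resolution; five consecutive windows per 10-s epoch) and the slow-wave
    band come from the recording protocol this pipeline mirrors.
    """

    epoch_s: float = 10.0
    sampling_rate: float = 128.0
    fft_window_s: float = 2.0
    fft_points: int = 256
    swa_band: tuple[float, float] = (0.5, 4.0)
    theta_band: tuple[float, float] = (6.0, 9.0)
    spectral_range: tuple[float, float] = (0.5, 30.0)
    rem_latency_bin_s: float = 50.0
    rem_latency_max_s: float = 600.0
    periodogram_range_h: tuple[float, float] = (20.0, 28.0)
    alpha: float = 0.05
    apply_notch_50hz: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.fft_points != int(self.fft_window_s * self.sampling_rate):
            raise ValidationError(
                "fft_points must equal fft_window_s * sampling_rate "
                f"({self.fft_window_s} s at {self.sampling_rate} Hz != {self.fft_points})"
            )
        n_win = self.epoch_s / self.fft_window_s
        if n_win != int(n_win):
            raise ValidationError("fft windows must tile the epoch exactly")

    @property
    def freq_resolution_hz(self) -> float:
        """Spectral bin spacing of the epoch FFT scheme (Hz)."""
        return self.sampling_rate / self.fft_points

    @property
    def windows_per_epoch(self) -> int:
        return int(self.epoch_s / self.fft_window_s)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ValidationError(f"unknown config keys: {sorted(extra)}")
        for key in ("swa_band", "theta_band", "spectral_range", "periodogram_range_h"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def labels_from_strings(symbols: Sequence[str]) -> np.ndarray:
    """Map 'W'/'N'/'R' symbols to integer codes, validating each row."""
    out = np.empty(len(symbols), dtype=np.int8)
    bad = []
    for i, s in enumerate(symbols):
        code = STATE_CODES.get(str(s).strip().upper())
        if code is None:
            bad.append((i, s))
        else:
            out[i] = code
    if bad:
        rows = ", ".join(f"row {i}: {s!r}" for i, s in bad[:10])
        raise ValidationError(f"unknown vigilance labels ({rows})")
    return out


def labels_to_strings(labels: np.ndarray) -> list[str]:
    return [STATE_NAMES[int(c)] for c in labels]
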