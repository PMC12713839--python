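"""Reading and writing the study's file formats.

Signals travel as EDF (European Data Format, 16-bit); hypnograms and
activity series as headered CSV. EDF headers have no fields for zeitgeber
time, light schedule or channel roles, so each EDF gets a small JSON sidecar
(``<file>.json``) carrying that metadata; reading falls back to sensible
defaults when the sidecar is absent.

EDF reading goes through MNE. Writing is done directly here: the format is a
fixed-layout ASCII header followed by little-endian 16-bit data records.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ActivitySeries,
    Channel,
    Hypnogram,
    LightSchedule,
    SignalRecord,
    ValidationError,
    labels_from_strings,
    labels_to_strings,
)

__all__ = [
    "write_signal_record",
    "read_signal_record",
    "write_hypnogram",
    "read_hypnogram",
    "write_activity",
    "read_activity",
]

_EDF_DIGITAL_MAX = 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValidationError(f"EDF header field too long: {s!r} (max {width})")
    return s.ljust(width).encode("ascii")


def write_signal_record(record: SignalRecord, path) -> None:
    """Write a :class:`SignalRecord` as a 16-bit EDF file plus JSON sidecar.

    Samples are quantised to 16 bits over a symmetric physical range per
    channel, so the round-trip error is at most ``max|x| / 32767`` per
    channel. The recording must span a whole number of seconds (EDF data
    records here are 1 s long).
    """
    path = Path(path)
    fs = record.sampling_rate
    if fs != int(fs):
        raise ValidationError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_records, rem = divmod(record.n_samples, fs)
    if rem:
        raise ValidationError("recording must span a whole number of seconds")

    ns = len(record.channels)
    header_bytes = 256 * (ns + 1)
    phys_max = []
    digital = []
    for ch in record.channels:
        pm = float(np.max(np.abs(ch.samples))) if ch.samples.size else 0.0
        pm = max(np.ceil(pm), 1.0)
        phys_max.append(pm)
        dig = np.clip(np.round(ch.samples / pm * _EDF_DIGITAL_MAX),
                      -_EDF_DIGITAL_MAX, _EDF_DIGITAL_MAX).astype("<i2")
        digital.append(dig)

    with open(path, "wb") as fh:
        fh.write(_ascii_field("0", 8))
        fh.write(_ascii_field(record.subject_id, 80))
        fh.write(_ascii_field("somnoscope", 80))
        fh.write(_ascii_field("01.01.00", 8))
        fh.write(_ascii_field("00.00.00", 8))
        fh.write(_ascii_field(header_bytes, 8))
        fh.write(_ascii_field("", 44))
        fh.write(_ascii_field(n_records, 8))
        fh.write(_ascii_field(1, 8))  # record duration, seconds
        fh.write(_ascii_field(ns, 4))
        for ch in record.channels:
            fh.write(_ascii_field(ch.name, 16))
        for _ in record.channels:
            fh.write(_ascii_field("", 80))  # transducer
        for _ in record.channels:
            fh.write(_ascii_field("uV", 8))
        for pm in phys_max:
            fh.write(_ascii_field(int(-pm), 8))
        for pm in phys_max:
            fh.write(_ascii_field(int(pm), 8))
        for _ in record.channels:
            fh.write(_ascii_field(-_EDF_DIGITAL_MAX, 8))
        for _ in record.channels:
            fh.write(_ascii_field(_EDF_DIGITAL_MAX, 8))
        for _ in record.channels:
            fh.write(_ascii_field("", 80))  # prefiltering
        for _ in record.channels:
            fh.write(_ascii_field(fs, 8))
        for _ in record.channels:
            fh.write(_ascii_field("", 32))
        # data records: per record, each signal's samples consecutively
        for r in range(n_records):
            sl = slice(r * fs, (r + 1) * fs)
            for dig in digital:
                fh.write(dig[sl].tobytes())

    sidecar = {
        "subject_id": record.subject_id,
        "start_zt": record.start_zt,
        "lights_off_zt": record.light_schedule.lights_off_zt,
        "dd": record.light_schedule.dd,
        "roles": {ch.name: ch.role for ch in record.channels},
        "meta": record.meta,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def _infer_role(label: str, overrides: dict[str, str] | None) -> str | None:
    if overrides and label in overrides:
        return overrides[label]
    up = label.upper()
    if up.startswith("EEG"):
        return "EEG"
    if up.startswith("EMG"):
        return "EMG"
    return None


def _edf_samples_per_record(path) -> list[int]:
    """Parse the per-signal samples-per-record field from an EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        ns = int(header[252:256].decode("ascii"))
        fh.seek(256 + ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80))
        raw = fh.read(ns * 8)
    return [int(raw[i * 8:(i + 1) * 8].decode("ascii")) for i in range(ns)]


def read_signal_record(path, channel_roles: dict[str, str] | None = None) -> SignalRecord:
    """Read an EDF file into a :class:`SignalRecord` (samples in microvolts).

    Channel roles are inferred from the label prefix (``EEG``/``EMG``),
    overridable per label via ``channel_roles``. Files mixing sampling rates
    across channels are rejected. A ``<file>.json`` sidecar written by
    :func:`write_signal_record` restores zeitgeber/light-schedule metadata.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spr = _edf_samples_per_record(path)
    if len(set(spr)) > 1:
        raise ValidationError(
            f"unsupported EDF: channels have mixed sampling rates {sorted(set(spr))}"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data(units="uV")
    labels = list(raw.ch_names)

    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    roles_map = dict(sidecar.get("roles", {}))
    if channel_roles:
        roles_map.update(channel_roles)

    channels, unassigned = [], []
    for label, samples in zip(labels, data_uv):
        role = _infer_role(label, roles_map)
        if role is None:
            unassigned.append(label)
        else:
            channels.append(Channel(label, role, samples))
    if unassigned:
        raise ValidationError(
            "cannot assign EEG/EMG roles to channel(s) "
            f"{unassigned}; pass channel_roles to disambiguate"
        )

    schedule = LightSchedule(
        lights_off_zt=float(sidecar.get("lights_off_zt", 12.0)),
        dd=bool(sidecar.get("dd", False)),
    )
    return SignalRecord(
        channels=channels,
        sampling_rate=float(raw.info["sfreq"]),
        start_zt=float(sidecar.get("start_zt", 0.0)),
        light_schedule=schedule,
        subject_id=str(sidecar.get("subject_id", path.stem)),
        meta=dict(sidecar.get("meta", {})),
    )


# ---------------------------------------------------------------------------
# CSV formats: metadata as leading '# key=value' comment lines, then a header
# row. This keeps the files self-describing while staying plain CSV.

def _write_meta(fh, meta: dict) -> None:
    for key, value in meta.items():
        fh.write(f"# {key}={value}\n")


def _read_meta(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    return meta


def write_hypnogram(hyp: Hypnogram, path) -> None:
    """Write a hypnogram as CSV (epoch_index, zt_start, label)."""
    with open(path, "w") as fh:
        _write_meta(fh, {
            "epoch_s": hyp.epoch_s,
            "start_zt": hyp.start_zt,
            "subject_id": hyp.subject_id,
            "genotype": hyp.genotype,
            "sex": hyp.sex,
        })
        fh.write("epoch_index,zt_start,label\n")
        zt = hyp.epoch_zt
        for i, sym in enumerate(labels_to_strings(hyp.labels)):
            fh.write(f"{i},{zt[i]:.6f},{sym}\n")


def read_hypnogram(path) -> Hypnogram:
    """Read a hypnogram CSV, validating label alphabet and epoch contiguity."""
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    required = {"epoch_index", "zt_start", "label"}
    if not required <= set(df.columns):
        raise ValidationError(f"hypnogram CSV needs columns {sorted(required)}")
    idx = df["epoch_index"].to_numpy()
    expected = np.arange(len(df))
    if len(df) and not np.array_equal(idx, expected):
        bad = np.nonzero(idx != expected)[0][:10]
        raise ValidationError(
            f"epoch_index must be contiguous from 0; first offending rows: {bad.tolist()}"
        )
    labels = labels_from_strings(df["label"].tolist())
    return Hypnogram(
        labels=labels,
        epoch_s=float(meta.get("epoch_s", 10.0)),
        start_zt=float(meta.get("start_zt", 0.0)),
        subject_id=meta.get("subject_id", Path(path).stem),
        genotype=meta.get("genotype", "WT"),
        sex=meta.get("sex", "M"),
    )


def write_activity(act: ActivitySeries, path) -> None:
    """Write an activity series as CSV (elapsed_h, counts)."""
    with open(path, "w") as fh:
        _write_meta(fh, {
            "bin_min": act.bin_min,
            "start_zt": act.start_zt,
            "subject_id": act.subject_id,
            "lights_off_zt": act.light_schedule.lights_off_zt,
            "dd": act.light_schedule.dd,
            "dd_start_day": "" if act.dd_start_day is None else act.dd_start_day,
        })
        fh.write("elapsed_h,counts\n")
        hours = np.arange(len(act.counts)) * act.bin_min / 60.0
        for h, c in zip(hours, act.counts):
            fh.write(f"{h:.6f},{c:.6f}\n")


def read_activity(path) -> ActivitySeries:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    if not {"elapsed_h", "counts"} <= set(df.columns):
        raise ValidationError("activity CSV needs columns elapsed_h, counts")
    counts = df["counts"].to_numpy(dtype=float)
    if (counts < 0).any():
        rows = np.nonzero(counts < 0)[0][:10]
        raise ValidationError(f"negative activity counts at rows {rows.tolist()}")
    dd_start = meta.get("dd_start_day", "")
    return ActivitySeries(
        counts=counts,
        bin_min=float(meta.get("bin_min", 1.0)),
        start_zt=float(meta.get("start_zt", 0.0)),
        light_schedule=LightSchedule(
            lights_off_zt=float(meta.get("lights_off_zt", 12.0)),
            dd=meta.get("dd", "False") == "True",
        ),
        subject_id=meta.get("subject_id", Path(path).stem),
        dd_start_day=int(dd_start) if dd_start else None,
    )
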