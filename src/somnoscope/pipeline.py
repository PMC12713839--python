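"""End-to-end orchestration: simulate -> stage -> architecture/circadian -> compare.

A run is driven by one YAML config and a master seed; per-subject seeds are
derived by stable hashing of the subject id, so cohorts can grow without
reshuffling existing subjects. Every stage writes tidy CSVs into the output
directory and the run closes with a JSON manifest (config hash, seeds, row
counts per output) for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import architecture as arch
from . import circadian as circ
from . import io as sio
from . import simulate as sim
from . import staging
from . import stats as gstats
from .features import band_power, epoch_spectrum, relative_power
from .types import NREM, REM, Hypnogram, StudyConfig, ValidationError

__all__ = ["RunManifest", "run_pipeline", "subject_metrics", "compare_cohort",
           "derive_seed", "default_config", "report"]

log = logging.getLogger("somnoscope")


def derive_seed(master_seed: int, subject_id: str) -> int:
    """Stable per-subject seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{subject_id}".encode()).hexdigest()
    return int(digest[:8], 16) % (2 ** 31)


def config_hash(config: dict) -> str:
    """Hash of the config, stable under key reordering."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def default_config() -> dict:
    """Demo run: small synthetic cohort, two recorded days per subject."""
    return {
        "seed": 0,
        "days": 2,
        "epoch_s": 10.0,
        "cohort": [
            {"genotype": "WT", "n": 4, "sex": "M"},
            {"genotype": "MUT", "n": 4, "sex": "M"},
        ],
        "signals": {"enabled": False, "sampling_rate": 128.0},
        "activity": {"enabled": True},
    }


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    subject_seeds: dict[str, int]
    outputs: dict[str, int] = field(default_factory=dict)

    def add(self, path: Path, n_rows: int) -> None:
        self.outputs[str(path)] = int(n_rows)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=1, default=str))


def subject_metrics(hyp: Hypnogram, act=None) -> dict[str, float]:
    """Headline per-subject measures used by the group comparisons.

    REM minutes (per day) in ZT12-18, count of light-phase REM bouts with
    latency under 150 s (per day), the dark-phase conditional NREM-to-REM
    transition probability, and (when activity is supplied) the mean daily
    dark-phase activity total.
    """
    days = hyp.duration_s / 86400.0
    zt = np.mod(hyp.epoch_zt, 24.0)
    rem_zt12_18 = float(((hyp.labels == REM) & (zt >= 12) & (zt < 18)).sum()
                        * hyp.epoch_s / 60.0 / days)
    lat = arch.rem_latencies(hyp)
    short_light = float(((lat["phase"] == "light")
                         & (lat["latency_s"] < 150)).sum() / days)
    tt = arch.transition_table(hyp)
    cond = tt.conditional
    row = cond[(cond["phase"] == "dark") & (cond["transition"] == "N->R")]
    p_nr_dark = float(row["probability"].iloc[0]) if len(row) else np.nan
    out = {
        "rem_min_zt12_18": rem_zt12_18,
        "short_latency_rem_light_per_day": short_light,
        "p_n_to_r_dark": p_nr_dark,
    }
    if act is not None:
        out["dark_activity_total"] = circ.phase_totals(act)["dark"]
    return out


def compare_cohort(metrics: pd.DataFrame) -> pd.DataFrame:
    """Genotype comparisons (unpaired t, Cohen's d) of per-subject measures."""
    rows = []
    for col in metrics.columns.drop(["subject_id", "genotype"], errors="ignore"):
        a = metrics.loc[metrics["genotype"] == "WT", col].dropna().to_numpy()
        b = metrics.loc[metrics["genotype"] == "MUT", col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        res = gstats.unpaired_t(a, b)
        rows.append({
            "measure": col,
            "mean_wt": a.mean(), "mean_mut": b.mean(),
            "t": res.effects["statistic"].iloc[0],
            "p": res.effects["p"].iloc[0],
            "cohens_d": res.effect_size,
        })
    return pd.DataFrame(rows)


def _simulate_subject(subject_id, genotype, sex, days, epoch_s, seed, signals_cfg):
    presets = sim.genotype_presets()
    kin, act_model = presets[genotype]
    hyp = sim.simulate_hypnogram(kin, days=days, epoch_s=epoch_s, seed=seed,
                                 subject_id=subject_id, genotype=genotype, sex=sex)
    act = sim.simulate_activity(act_model, seed=seed + 1, subject_id=subject_id)
    record = None
    if signals_cfg.get("enabled"):
        record = sim.synthesize_signals(
            hyp, sim.preset_recipe(genotype),
            fs=float(signals_cfg.get("sampling_rate", 128.0)), seed=seed + 2)
    return hyp, act, record


def run_pipeline(config: dict | str | Path, outdir: str | Path,
                 seed: int | None = None) -> RunManifest:
    """Execute the full pipeline for a (synthetic) cohort config.

    Deterministic for a fixed (config, seed). Raises with the stage name
    and subject id on failure.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if "seed" not in config and seed is None:
        raise ValidationError("config must provide a master seed")
    master_seed = int(seed if seed is not None else config["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = []
    for group in config["cohort"]:
        for i in range(int(group["n"])):
            sid = f"{group['genotype']}_{group.get('sex', 'M')}_{i + 1:02d}"
            cohort.append((sid, group["genotype"], group.get("sex", "M")))
    manifest = RunManifest(
        config_hash=config_hash(config), master_seed=master_seed,
        subject_seeds={sid: derive_seed(master_seed, sid) for sid, _, _ in cohort})

    days = float(config.get("days", 2))
    epoch_s = float(config.get("epoch_s", 10.0))
    signals_cfg = config.get("signals", {"enabled": False})
    cfg = StudyConfig(epoch_s=epoch_s,
                      sampling_rate=float(signals_cfg.get("sampling_rate", 128.0)),
                      fft_points=int(float(signals_cfg.get("sampling_rate", 128.0)) * 2))

    metric_rows, profile_frames, episode_frames = [], [], []
    transition_frames, latency_frames, swa_frames = [], [], []
    activity_rows, periodogram_rows = [], []

    for sid, genotype, sex in cohort:
        sseed = manifest.subject_seeds[sid]
        try:
            hyp, act, record = _simulate_subject(
                sid, genotype, sex, days, epoch_s, sseed, signals_cfg)
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed for subject {sid}: {exc}") from exc
        sio.write_hypnogram(hyp, outdir / f"{sid}_hypnogram.csv")
        sio.write_activity(act, outdir / f"{sid}_activity.csv")
        log.info("simulate %s: %d epochs, %d activity bins", sid, len(hyp), len(act))

        analysed = hyp
        if record is not None:
            sio.write_signal_record(record, outdir / f"{sid}.edf")
            try:
                staged = staging.stage_record(record, cfg)
                staged.genotype, staged.sex = genotype, sex
            except Exception as exc:
                raise RuntimeError(f"stage 'stage' failed for subject {sid}: {exc}") from exc
            sio.write_hypnogram(staged, outdir / f"{sid}_hypnogram_staged.csv")
            analysed = staged

            # epoch spectra for SWA (from the synthesized EEG)
            eeg = record.get("EEG").samples
            spe = int(epoch_s * record.sampling_rate)
            swa = np.array([
                band_power(epoch_spectrum(eeg[i * spe:(i + 1) * spe], cfg), *cfg.swa_band)
                for i in range(len(analysed))])
            swa_df = arch.swa_timecourse(swa, analysed)
            swa_df.insert(0, "subject_id", sid)
            swa_df.insert(1, "genotype", genotype)
            swa_frames.append(swa_df)

        try:
            prof = arch.state_time_profile(analysed, bin_h=1.0)
            episodes = arch.find_episodes(analysed)
            epi = arch.episode_summary(episodes, analysed, bin_h=6.0)
            tt = arch.transition_table(analysed, bin_h=6.0)
            lat = arch.rem_latency_histogram(analysed)
        except Exception as exc:
            raise RuntimeError(f"stage 'architecture' failed for subject {sid}: {exc}") from exc
        for df in (prof, epi, tt.counts, lat):
            df.insert(0, "subject_id", sid)
            df.insert(1, "genotype", genotype)
        cond = tt.conditional.copy()
        cond.insert(0, "subject_id", sid)
        cond.insert(1, "genotype", genotype)
        profile_frames.append(prof)
        episode_frames.append(epi)
        transition_frames.append(pd.concat([tt.counts, cond], axis=0, ignore_index=True))
        latency_frames.append(lat)

        if config.get("activity", {}).get("enabled", True):
            try:
                totals = circ.phase_totals(act)
                pg = circ.chi_square_periodogram(act.dd_part())
            except Exception as exc:
                raise RuntimeError(f"stage 'circadian' failed for subject {sid}: {exc}") from exc
            activity_rows.append({"subject_id": sid, "genotype": genotype, **totals})
            periodogram_rows.append({
                "subject_id": sid, "genotype": genotype,
                "best_period_h": pg.best_period_h, "best_qp": pg.best_qp,
                "best_qp_excess": pg.best_qp_excess})
            metric_rows.append({"subject_id": sid, "genotype": genotype,
                                **subject_metrics(analysed, act)})
        else:
            metric_rows.append({"subject_id": sid, "genotype": genotype,
                                **subject_metrics(analysed)})

    tables = {
        "profiles.csv": pd.concat(profile_frames, ignore_index=True),
        "episodes.csv": pd.concat(episode_frames, ignore_index=True),
        "transitions.csv": pd.concat(transition_frames, ignore_index=True),
        "rem_latency.csv": pd.concat(latency_frames, ignore_index=True),
        "subject_metrics.csv": pd.DataFrame(metric_rows),
    }
    if swa_frames:
        tables["swa.csv"] = pd.concat(swa_frames, ignore_index=True)
    if activity_rows:
        tables["activity_totals.csv"] = pd.DataFrame(activity_rows)
        tables["periodogram.csv"] = pd.DataFrame(periodogram_rows)

    metrics = tables["subject_metrics.csv"]
    if metrics["genotype"].nunique() == 2:
        try:
            tables["comparisons.csv"] = compare_cohort(metrics)
        except Exception as exc:
            raise RuntimeError(f"stage 'compare' failed: {exc}") from exc

    for name, df in tables.items():
        path = outdir / name
        df.to_csv(path, index=False)
        manifest.add(path, len(df))
    for sid, _, _ in cohort:
        manifest.add(outdir / f"{sid}_hypnogram.csv", -1)
        manifest.add(outdir / f"{sid}_activity.csv", -1)
    manifest.write(outdir / "manifest.json")
    return manifest


def report(outdir: str | Path) -> list[Path]:
    """Render figure-analog plots from a completed run's CSV tables.

    One PNG per figure family (state-time profiles, actogram of the first
    subject, transition probabilities, REM-latency histograms); the
    underlying data are already on disk as the tidy CSVs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written = []

    prof = pd.read_csv(outdir / "profiles.csv")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3), sharex=True)
    for ax, state in zip(axes, ("W", "N", "R")):
        sub = prof[prof["state"] == state]
        for genotype, g in sub.groupby("genotype"):
            mean = g.groupby("zt_start")["minutes"].mean()
            ax.plot(mean.index, mean.values, label=genotype)
        ax.set_title({"W": "Wake", "N": "NREM", "R": "REM"}[state])
        ax.set_xlabel("ZT (h)")
    axes[0].set_ylabel("min / h")
    axes[0].legend()
    p = outdir / "fig_profiles.png"
    fig.tight_layout(); fig.savefig(p, dpi=120); plt.close(fig)
    written.append(p)

    act_files = sorted(outdir.glob("*_activity.csv"))
    if act_files:
        act = sio.read_activity(act_files[0])
        mat = circ.actogram_matrix(act, double_plot=True)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(mat, aspect="auto", cmap="Greys", interpolation="nearest")
        ax.set_xlabel("time of day (bins, double-plotted)")
        ax.set_ylabel("day")
        p = outdir / "fig_actogram.png"
        fig.tight_layout(); fig.savefig(p, dpi=120); plt.close(fig)
        written.append(p)

    lat = pd.read_csv(outdir / "rem_latency.csv")
    finite = lat[np.isfinite(lat["bin_hi_s"])]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3), sharey=True)
    for ax, phase in zip(axes, ("light", "dark")):
        sub = finite[finite["phase"] == phase]
        for genotype, g in sub.groupby("genotype"):
            mean = g.groupby("bin_lo_s")["count"].mean()
            ax.step(mean.index, mean.values, where="post", label=genotype)
        ax.set_title(f"{phase} phase")
        ax.set_xlabel("REM latency (s)")
    axes[0].set_ylabel("episodes / subject")
    axes[0].legend()
    p = outdir / "fig_rem_latency.png"
    fig.tight_layout(); fig.savefig(p, dpi=120); plt.close(fig)
    written.append(p)
    return written
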