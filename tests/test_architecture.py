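"""Hypnogram statistics: episodes, profiles, transitions, REM latency, SWA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from somnoscope import architecture as arch
from somnoscope import simulate as sim
from somnoscope.types import NREM, REM, WAKE, Hypnogram, ValidationError


def _hyp(codes, **kw):
    return Hypnogram(labels=np.asarray(codes, dtype=np.int8), **kw)


def _full_day(codes_pattern):
    reps = int(np.ceil(8640 / len(codes_pattern)))
    return _hyp((codes_pattern * reps)[:8640])


class TestFindEpisodes:
    def test_single_state_day(self):
        eps = arch.find_episodes(_hyp([NREM] * 8640))
        assert len(eps) == 1
        assert eps[0].length_epochs == 8640
        assert eps[0].duration_s == 86400

    def test_four_episode_sequence(self):
        eps = arch.find_episodes(_hyp([WAKE, NREM, REM, NREM]))
        assert [e.state for e in eps] == [WAKE, NREM, REM, NREM]
        assert all(e.length_epochs == 1 for e in eps)

    def test_episode_count_equals_changes_plus_one(self):
        kin, _ = sim.genotype_presets()["WT"]
        hyp = sim.simulate_hypnogram(kin, days=1, seed=17)
        eps = arch.find_episodes(hyp)
        assert len(eps) == 1 + int((np.diff(hyp.labels) != 0).sum())
        # concatenation reconstructs the hypnogram
        rebuilt = np.concatenate([[e.state] * e.length_epochs for e in eps])
        assert np.array_equal(rebuilt, hyp.labels)


class TestStateTimeProfile:
    def test_all_wake_day(self):
        prof = arch.state_time_profile(_hyp([WAKE] * 8640), bin_h=1.0)
        wake = prof[prof["state"] == "W"]["minutes"]
        assert (wake == 60.0).all()
        assert (prof[prof["state"] != "W"]["minutes"] == 0).all()

    def test_per_bin_conservation(self):
        kin, _ = sim.genotype_presets()["MUT"]
        hyp = sim.simulate_hypnogram(kin, days=2, seed=3)
        prof = arch.state_time_profile(hyp, bin_h=1.0)
        sums = prof.groupby("bin")["minutes"].sum()
        assert np.allclose(sums, 60.0)

    def test_wt_light_nrem_exceeds_dark_nrem(self):
        kin, _ = sim.genotype_presets()["WT"]
        hyp = sim.simulate_hypnogram(kin, days=2, seed=5)
        prof = arch.state_time_profile(hyp, bin_h=12.0)
        n = prof[prof["state"] == "N"].set_index("bin")["minutes"]
        assert n[0] > n[1]  # light bin 0, dark bin 1

    def test_partial_day_rejected(self):
        with pytest.raises(ValidationError):
            arch.state_time_profile(_hyp([WAKE] * 100), bin_h=1.0)


class TestTransitionTable:
    def test_alternating_wake_nrem(self):
        hyp = _full_day([WAKE, NREM])
        tt = arch.transition_table(hyp, bin_h=6.0)
        counts = tt.counts.groupby("transition")["count"].sum()
        assert abs(counts["W->N"] - counts["N->W"]) <= 1
        assert counts[["N->R", "R->N", "R->W"]].sum() == 0

    def test_conditional_probability_formula(self):
        # 3 N->R and 7 N->W transitions: P(N->R)=0.3, P(N->W)=0.7
        seq = []
        for _ in range(3):
            seq += [NREM, REM, NREM]
        for _ in range(7):
            seq += [NREM, WAKE, NREM]
        # pad to a whole day with trailing wake (adds one final N->W)
        hyp = _hyp(seq + [WAKE] * (8640 - len(seq)))
        tt = arch.transition_table(hyp, bin_h=12.0)
        cond = tt.conditional.set_index(["phase", "transition"])
        assert cond.loc[("light", "N->R"), "count"] == 3
        assert cond.loc[("light", "N->W"), "count"] == 8
        assert cond.loc[("light", "N->R"), "probability"] == pytest.approx(3 / 11)
        probs = tt.conditional[(tt.conditional["phase"] == "light")
                               & tt.conditional["transition"].str.startswith("N")]
        assert probs["probability"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_counts_match_brute_force_scan(self):
        kin, _ = sim.genotype_presets()["WT"]
        hyp = sim.simulate_hypnogram(kin, days=1, seed=23)  # 8640 epochs
        tt = arch.transition_table(hyp, bin_h=6.0)
        # oracle: explicit pairwise scan
        brute = {}
        for i in range(len(hyp) - 1):
            a, b = int(hyp.labels[i]), int(hyp.labels[i + 1])
            if a != b:
                brute[(a, b)] = brute.get((a, b), 0) + 1
        names = {0: "W", 1: "N", 2: "R"}
        table = tt.counts.groupby("transition")["count"].sum()
        for (a, b), n in brute.items():
            key = f"{names[a]}->{names[b]}"
            if key == "W->R":
                assert tt.w_to_r_qc == n
            else:
                assert table[key] == n

    def test_recovery_within_binomial_ci(self):
        kin, _ = sim.genotype_presets()["WT"]
        for seed in (1, 2, 3):
            hyp = sim.simulate_hypnogram(kin, days=30, seed=seed)
            pre, post = hyp.labels[:-1], hyp.labels[1:]
            light = hyp.phase_mask()[1:]
            # dark phase excludes the WT nap window (its own third matrix)
            zt = np.mod(hyp.epoch_zt[1:], 24.0)
            dark = ~light & ~((zt >= 19) & (zt < 21))
            n_from_n = ((pre == NREM) & dark).sum()
            f = ((pre == NREM) & (post == REM) & dark).sum() / n_from_n
            p = kin.P_dark[NREM, REM]
            half = 1.96 * np.sqrt(p * (1 - p) / n_from_n)
            assert abs(f - p) <= half + 1e-12


class TestRemLatency:
    def test_simple_latency(self):
        hyp = _hyp([WAKE, NREM, NREM, REM])
        lat = arch.rem_latencies(hyp)
        assert len(lat) == 1
        assert lat["latency_s"].iloc[0] == 20.0
        hist = arch.rem_latency_histogram(hyp)
        light = hist[hist["phase"] == "light"]
        assert light[light["bin_lo_s"] == 0]["count"].iloc[0] == 1

    def test_longer_latency_bin_assignment(self):
        hyp = _hyp([WAKE] + [NREM] * 14 + [REM])
        lat = arch.rem_latencies(hyp)
        assert lat["latency_s"].iloc[0] == 140.0
        hist = arch.rem_latency_histogram(hyp)
        row = hist[(hist["phase"] == "light") & (hist["bin_lo_s"] == 100.0)]
        assert row["count"].iloc[0] == 1

    def test_wake_resets_clock_but_rem_return_does_not(self):
        # W N R N R : second REM measures from the original W->N onset
        hyp = _hyp([WAKE, NREM, REM, NREM, REM])
        lat = arch.rem_latencies(hyp)
        assert list(lat["latency_s"]) == [10.0, 30.0]
        # W N R W N R : wake resets; second latency restarts
        hyp2 = _hyp([WAKE, NREM, REM, WAKE, NREM, REM])
        lat2 = arch.rem_latencies(hyp2)
        assert list(lat2["latency_s"]) == [10.0, 10.0]

    def test_rem_at_start_excluded_as_qc(self):
        hyp = _hyp([REM, NREM, WAKE, NREM, REM])
        lat = arch.rem_latencies(hyp)
        assert len(lat) == 1
        assert lat.attrs["qc_excluded"] == 1

    def test_histogram_counts_conserved(self):
        kin, _ = sim.genotype_presets()["MUT"]
        hyp = sim.simulate_hypnogram(kin, days=2, seed=31)
        hist = arch.rem_latency_histogram(hyp)
        n_rem_eps = sum(1 for e in arch.find_episodes(hyp) if e.state == REM)
        assert hist["count"].sum() + hist.attrs["qc_excluded"] == n_rem_eps

    def test_mut_has_fewer_short_latency_light_bouts(self):
        presets = sim.genotype_presets()
        counts = {}
        for g in ("WT", "MUT"):
            per_subject = []
            for i in range(12):
                hyp = sim.simulate_hypnogram(presets[g][0], days=2, seed=1000 + i,
                                             genotype=g)
                lat = arch.rem_latencies(hyp)
                per_subject.append(((lat["phase"] == "light")
                                    & (lat["latency_s"] < 150)).sum())
            counts[g] = np.mean(per_subject)
        assert counts["MUT"] < counts["WT"]


class TestEpisodeSummary:
    def test_single_long_episode(self):
        hyp = _hyp([NREM] * 8640)
        eps = arch.find_episodes(hyp)
        summ = arch.episode_summary(eps, hyp, bin_h=6.0)
        n = summ[summ["state"] == "N"]
        assert n["count"].sum() == 1
        assert n[n["bin"] == 0]["count"].iloc[0] == 1

    def test_alternating_single_epoch_episodes(self):
        hyp = _full_day([WAKE, NREM])
        eps = arch.find_episodes(hyp)
        summ = arch.episode_summary(eps, hyp, bin_h=6.0)
        means = summ.dropna(subset=["mean_duration_s"])["mean_duration_s"]
        assert (means == 10.0).all()

    def test_mean_nrem_duration_matches_geometric_oracle(self):
        # uniform kinetics: mean episode length = epoch_s / (1 - P[N->N])
        P = np.array([[0.92, 0.08, 0.00],
                      [0.06, 0.90, 0.04],
                      [0.08, 0.08, 0.84]])
        kin = sim.VigilanceKinetics(P_light=P, P_dark=P)
        hyp = sim.simulate_hypnogram(kin, days=30, seed=2)
        eps = [e for e in arch.find_episodes(hyp) if e.state == NREM]
        mean_dur = np.mean([e.duration_s for e in eps])
        assert mean_dur == pytest.approx(10.0 / (1 - 0.90), rel=0.05)


class TestSwaTimecourse:
    def test_constant_swa_is_100_percent(self):
        kin, _ = sim.genotype_presets()["WT"]
        hyp = sim.simulate_hypnogram(kin, days=1, seed=4)
        tc = arch.swa_timecourse(np.ones(len(hyp)), hyp)
        assert np.allclose(tc["swa_percent"].dropna(), 100.0)

    def test_scale_invariance(self):
        kin, _ = sim.genotype_presets()["WT"]
        hyp = sim.simulate_hypnogram(kin, days=1, seed=4)
        rng = np.random.default_rng(0)
        swa = rng.uniform(50, 150, len(hyp))
        t1 = arch.swa_timecourse(swa, hyp)
        t2 = arch.swa_timecourse(4.0 * swa, hyp)  # doubling amplitudes = 4x power
        assert np.allclose(t1["swa_percent"], t2["swa_percent"], equal_nan=True)

    def test_light_delta_gain_raises_light_bins(self):
        # recipe with doubled light-phase NREM delta: light bins above 100%
        kin, _ = sim.genotype_presets()["WT"]
        hyp = sim.simulate_hypnogram(kin, days=0.5, seed=6)  # ZT0-12, all light
        recipe = sim.preset_recipe()
        recipe.nrem_delta_light_gain = 2.0
        rec = sim.synthesize_signals(hyp, recipe, seed=6, n_eeg=1, n_emg=1)
        from somnoscope.features import band_power, epoch_spectrum
        from somnoscope.types import StudyConfig
        cfg = StudyConfig()
        eeg = rec.get("EEG").samples
        swa_gain = [band_power(epoch_spectrum(eeg[i * 1280:(i + 1) * 1280], cfg), 0.5, 4.0)
                    for i in range(len(hyp))]
        rec0 = sim.synthesize_signals(hyp, sim.preset_recipe(), seed=6, n_eeg=1, n_emg=1)
        eeg0 = rec0.get("EEG").samples
        swa_plain = [band_power(epoch_spectrum(eeg0[i * 1280:(i + 1) * 1280], cfg), 0.5, 4.0)
                     for i in range(len(hyp))]
        nrem = hyp.labels == NREM
        assert np.mean(np.asarray(swa_gain)[nrem]) > 2 * np.mean(np.asarray(swa_plain)[nrem])

    def test_length_mismatch_rejected(self):
        hyp = _hyp([NREM] * 10)
        with pytest.raises(ValidationError):
            arch.swa_timecourse(np.ones(5), hyp)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=2), min_size=2, max_size=300))
def test_episode_durations_conserve_recording_length(codes):
    hyp = _hyp(codes)
    eps = arch.find_episodes(hyp)
    assert sum(e.length_epochs for e in eps) == len(hyp)
    assert all(a.state != b.state for a, b in zip(eps, eps[1:]))
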