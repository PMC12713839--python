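"""Group-comparison battery: t-tests, two-way ANOVA, post-hocs, checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sst

from somnoscope import simulate as sim
from somnoscope import stats as gs
from somnoscope.types import REM, ValidationError


class TestUnpairedT:
    def test_identical_groups(self):
        res = gs.unpaired_t([1, 2, 3], [1, 2, 3])
        assert res.effects["statistic"].iloc[0] == 0.0
        assert res.effects["p"].iloc[0] == 1.0
        assert res.effect_size == 0.0

    def test_separated_groups_drive_p_to_zero(self):
        a = [1.0, 1.001, 0.999, 1.0002]
        b = [11.0, 11.001, 10.999, 11.0002]
        res = gs.unpaired_t(a, b)
        assert res.effects["p"].iloc[0] < 1e-10

    def test_cohens_d_matches_formula_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 15)
        b = rng.normal(1.0, 1.0, 14)
        res = gs.unpaired_t(a, b)
        sp = np.sqrt(((14 * a.var(ddof=1)) + (13 * b.var(ddof=1))) / 27)
        oracle = (a.mean() - b.mean()) / sp
        assert res.effect_size == pytest.approx(oracle, abs=1e-12)

    def test_minimum_group_size(self):
        with pytest.raises(ValidationError):
            gs.unpaired_t([1.0], [1.0, 2.0])


class TestTwoWayAnova:
    def _balanced(self, rng, effect_a=0.0, effect_ab=0.0, n=10):
        rows = []
        for a in (0, 1):
            for b in (0, 1):
                mu = effect_a * a + effect_ab * a * b
                for y in rng.normal(mu, 1.0, n):
                    rows.append({"y": y, "a": f"a{a}", "b": f"b{b}"})
        return pd.DataFrame(rows)

    def test_constant_data_gives_zero_f(self):
        df = pd.DataFrame({"y": [5.0] * 12,
                           "a": ["x", "y"] * 6,
                           "b": ["u"] * 6 + ["v"] * 6})
        res = gs.two_way_anova(df, "y", "a", "b")
        f = res.effects.set_index("effect")["F"].drop("residual")
        assert np.allclose(f.fillna(0), 0.0)

    def test_pure_main_effect(self, rng):
        df = self._balanced(rng, effect_a=2.0)
        res = gs.two_way_anova(df, "y", "a", "b")
        eff = res.effects.set_index("effect")
        assert eff.loc["a", "p"] < eff.loc["b", "p"]
        assert eff.loc["a x b", "F"] < eff.loc["a", "F"]
        # closed-form balanced oracle for the A sum of squares
        ya = df.groupby("a")["y"].mean()
        ss_a = 20 * ((ya - df["y"].mean()) ** 2).sum()
        assert eff.loc["a", "ss"] == pytest.approx(ss_a, rel=1e-8)

    def test_balanced_ss_decomposition(self, rng):
        df = self._balanced(rng, effect_a=1.0, effect_ab=0.5)
        res = gs.two_way_anova(df, "y", "a", "b")
        ss_total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert res.effects["ss"].sum() == pytest.approx(ss_total, rel=1e-8)

    def test_empty_cell_named(self):
        df = pd.DataFrame({"y": [1, 2, 3.0], "a": ["x", "x", "y"],
                           "b": ["u", "v", "u"]})
        with pytest.raises(ValidationError, match="empty design cell"):
            gs.two_way_anova(df, "y", "a", "b")

    def test_interaction_power_on_preset_rem_data(self):
        # genotype x phase interaction injected by the presets must be
        # detected in most replicate cohorts (n=12 per genotype, 2 days)
        presets = sim.genotype_presets()
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rows = []
            for g in ("WT", "MUT"):
                for i in range(12):
                    hyp = sim.simulate_hypnogram(
                        presets[g][0], days=2, seed=rep * 1000 + i + (0 if g == "WT" else 500))
                    light = hyp.phase_mask()
                    for phase, mask in (("light", light), ("dark", ~light)):
                        rem_min = ((hyp.labels == REM) & mask).sum() * 10 / 60 / 2
                        rows.append({"rem": rem_min, "genotype": g, "phase": phase})
            res = gs.two_way_anova(pd.DataFrame(rows), "rem", "genotype", "phase")
            p = res.effects.set_index("effect").loc["genotype x phase", "p"]
            hits += p < 0.05
        assert hits >= 0.8 * n_rep


class TestSidak:
    def test_endpoints_and_identity(self):
        assert gs.sidak_posthoc([0.0], 5)[0] == 0.0
        assert gs.sidak_posthoc([0.05], 1)[0] == pytest.approx(0.05)

    def test_direct_evaluation(self):
        assert gs.sidak_posthoc([0.01], 24)[0] == pytest.approx(1 - 0.99 ** 24,
                                                                abs=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            gs.sidak_posthoc([1.5], 2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=st.floats(min_value=0.0, max_value=1.0),
           m1=st.integers(min_value=1, max_value=50),
           m2=st.integers(min_value=1, max_value=50))
    def test_dominance_and_monotonicity(self, p, m1, m2):
        adj1 = gs.sidak_posthoc([p], max(m1, 1))[0]
        assert adj1 >= p - 1e-15
        lo, hi = sorted((m1, m2))
        assert gs.sidak_posthoc([p], lo)[0] <= gs.sidak_posthoc([p], hi)[0] + 1e-15


class TestFisherLsd:
    def test_matches_pairwise_pooled_t_on_balanced_2x2(self, rng):
        rows = []
        for a in ("x", "y"):
            for b in ("u", "v"):
                for y in rng.normal(1.0 if a == "y" else 0.0, 1.0, 8):
                    rows.append({"y": y, "a": a, "b": b})
        df = pd.DataFrame(rows)
        res = gs.two_way_anova(df, "y", "a", "b")
        lsd = gs.fisher_lsd(res, [(("x", "u"), ("y", "u"))])
        m1 = df.query("a=='x' and b=='u'")["y"].mean()
        m2 = df.query("a=='y' and b=='u'")["y"].mean()
        t_oracle = (m1 - m2) / np.sqrt(res.mse * (2 / 8))
        assert lsd["t"].iloc[0] == pytest.approx(t_oracle, rel=1e-12)
        assert lsd["df"].iloc[0] == 28  # 32 - 4 cells

    def test_doubling_mse_scales_t(self, rng):
        res = gs.two_way_anova(self_df(rng), "y", "a", "b")
        lsd1 = gs.fisher_lsd(res, [(("x", "u"), ("y", "u"))])
        res.mse *= 2
        lsd2 = gs.fisher_lsd(res, [(("x", "u"), ("y", "u"))])
        assert lsd2["t"].iloc[0] == pytest.approx(lsd1["t"].iloc[0] / np.sqrt(2))

    def test_missing_cell_rejected(self, rng):
        res = gs.two_way_anova(self_df(rng), "y", "a", "b")
        with pytest.raises(ValidationError):
            gs.fisher_lsd(res, [(("x", "u"), ("z", "u"))])


def self_df(rng):
    rows = []
    for a in ("x", "y"):
        for b in ("u", "v"):
            for y in rng.normal(0.0, 1.0, 6):
                rows.append({"y": y, "a": a, "b": b})
    return pd.DataFrame(rows)


class TestAssumptionChecks:
    def test_brown_forsythe_null_p_uniform(self):
        # equal-variance normal groups: BF p-values uniform over seeds
        ps = []
        for s in range(200):
            rng = np.random.default_rng(s)
            out = gs.normality_and_variance(
                {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20)})
            ps.append(out["brown_forsythe"]["p"])
        assert sst.kstest(ps, "uniform").pvalue > 0.01

    def test_brown_forsythe_detects_variance_ratio(self):
        hits = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            out = gs.normality_and_variance(
                {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 4, 30)})
            hits += out["brown_forsythe"]["p"] < 0.05
        assert hits >= 40

    def test_constant_group_flagged(self):
        out = gs.normality_and_variance({"a": np.ones(10), "b": np.arange(10.0)})
        sw = out["shapiro"].set_index("group")
        assert bool(sw.loc["a", "skipped"])
        assert not bool(sw.loc["b", "skipped"])


class TestSummarize:
    def test_known_values(self):
        table = gs.summarize({"g": np.array([1.0, 2.0, 3.0])})
        assert table["mean"].iloc[0] == 2.0
        assert table["sem"].iloc[0] == pytest.approx(1 / np.sqrt(3))

    def test_single_value_sem_missing(self):
        table = gs.summarize({"g": np.array([4.2])})
        assert np.isnan(table["sem"].iloc[0])

    def test_matches_textbook_oracle(self, rng):
        v = rng.normal(2, 3, 50)
        table = gs.summarize({"g": v})
        assert table["sem"].iloc[0] == pytest.approx(v.std(ddof=1) / np.sqrt(50))


def test_type_one_error_calibration():
    # null simulations: pooled t rejects at ~alpha (200 reps)
    rej = 0
    n_rep = 200
    for s in range(n_rep):
        rng = np.random.default_rng(s)
        res = gs.unpaired_t(rng.normal(0, 1, 12), rng.normal(0, 1, 11))
        rej += res.effects["p"].iloc[0] < 0.05
    rate = rej / n_rep
    half = 2.58 * np.sqrt(0.05 * 0.95 / n_rep)  # 99% Monte-Carlo CI
    assert abs(rate - 0.05) <= half
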