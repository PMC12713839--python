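"""Group-comparison battery for tidy result tables.

Implements the statistical toolkit typical of rodent sleep studies:
unpaired two-tailed t-tests with Cohen's d, two-way fixed-effects ANOVA
with interaction (Type III sums of squares via effect coding, robust to
unbalanced group sizes), Sidak and Fisher-LSD post-hoc comparisons, and the
Shapiro-Wilk / Brown-Forsythe assumption checks.

Time-course designs are analysed as fixed-effects two-way ANOVA on
subject-by-bin values; that choice (rather than a repeated-measures model)
is stamped into every result's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .types import ValidationError

__all__ = [
    "ComparisonResult",
    "unpaired_t",
    "two_way_anova",
    "sidak_posthoc",
    "fisher_lsd",
    "normality_and_variance",
    "summarize",
]

_ANOVA_NOTE = "fixed-effects two-way ANOVA, Type III SS (effect coding)"


@dataclass
class ComparisonResult:
    """Container for one comparison: statistics, p-values, effect sizes."""

    effects: pd.DataFrame
    group_summary: pd.DataFrame
    effect_size: float | None = None
    posthoc: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)
    #: internal handles for post-hoc tests
    mse: float | None = None
    df_error: float | None = None
    cell_stats: pd.DataFrame | None = None


def summarize(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean +- SEM per group (SEM = SD/sqrt(n), sample SD; missing at n=1)."""
    rows = []
    for name, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 1:
            raise ValidationError(f"group {name!r} is empty")
        sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
        rows.append({"group": name, "n": v.size, "mean": float(v.mean()), "sem": sem})
    return pd.DataFrame(rows)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled SD: (mean_a - mean_b) / s_pooled."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def unpaired_t(group_a: np.ndarray, group_b: np.ndarray,
               welch: bool = False) -> ComparisonResult:
    """Unpaired two-tailed t-test with Cohen's d.

    Pooled-variance by default; ``welch=True`` drops the equal-variance
    assumption (useful when Brown-Forsythe rejects). Two groups with zero
    variance and equal means return t = 0, p = 1 by convention.
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        t, p, df = 0.0, 1.0, len(a) + len(b) - 2
    else:
        t, p = sst.ttest_ind(a, b, equal_var=not welch)
        df = (len(a) + len(b) - 2) if not welch else np.nan
    effects = pd.DataFrame([{"effect": "A vs B", "statistic": float(t),
                             "df": df, "p": float(p)}])
    return ComparisonResult(
        effects=effects,
        group_summary=summarize({"A": a, "B": b}),
        effect_size=cohens_d(a, b),
        meta={"test": "unpaired two-tailed t" + (" (Welch)" if welch else " (pooled)")},
    )


def two_way_anova(df: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str) -> ComparisonResult:
    """Two-way fixed-effects ANOVA with interaction (Type III SS).

    Requires at least two levels per factor and at least one observation in
    every cell of the design (empty cells are reported by name).
    """
    for col in (value, factor_a, factor_b):
        if col not in df.columns:
            raise ValidationError(f"column {col!r} not in data")
    data = df[[value, factor_a, factor_b]].dropna().copy()
    data.columns = ["y", "fa", "fb"]
    la, lb = data["fa"].unique(), data["fb"].unique()
    if len(la) < 2 or len(lb) < 2:
        raise ValidationError("each factor needs at least 2 levels")
    cells = data.groupby(["fa", "fb"], observed=True).size()
    full = pd.MultiIndex.from_product([la, lb])
    missing = full.difference(cells.index)
    if len(missing):
        raise ValidationError(f"empty design cell(s): {list(missing)}")

    ss_total = float(((data["y"] - data["y"].mean()) ** 2).sum())
    degenerate = ss_total <= 1e-12 * len(data) * (1.0 + data["y"].mean() ** 2)

    model = smf.ols("y ~ C(fa, Sum) * C(fb, Sum)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=3)
    if degenerate:  # constant response: all effects are exactly null
        table.loc[table.index != "Residual", "F"] = 0.0
        table.loc[table.index != "Residual", "PR(>F)"] = 1.0
    name_map = {"C(fa, Sum)": factor_a, "C(fb, Sum)": factor_b,
                "C(fa, Sum):C(fb, Sum)": f"{factor_a} x {factor_b}",
                "Residual": "residual"}
    rows = []
    for idx, row in table.iterrows():
        if idx == "Intercept":
            continue
        rows.append({"effect": name_map.get(idx, idx), "ss": row["sum_sq"],
                     "df": row["df"], "F": row.get("F", np.nan),
                     "p": row.get("PR(>F)", np.nan)})
    effects = pd.DataFrame(rows)

    resid = table.loc["Residual"]
    mse = resid["sum_sq"] / resid["df"]
    cell_stats = (data.groupby(["fa", "fb"], observed=True)["y"]
                  .agg(["mean", "count"]).reset_index())
    summary = summarize({f"{a}/{b}": data.query("fa == @a and fb == @b")["y"].to_numpy()
                         for a, b in cells.index})
    return ComparisonResult(
        effects=effects, group_summary=summary,
        meta={"test": _ANOVA_NOTE, "factors": (factor_a, factor_b)},
        mse=float(mse), df_error=float(resid["df"]), cell_stats=cell_stats,
    )


def sidak_posthoc(raw_p, m: int | None = None) -> np.ndarray:
    """Sidak adjustment: p_adj = 1 - (1 - p)^m, clipped to 1.

    ``m`` is the family size (defaults to the number of p-values); it must
    be at least the number of comparisons supplied.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size or m < 1:
        raise ValidationError("family size m must be >= number of p-values and >= 1")
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def fisher_lsd(anova: ComparisonResult,
               pairs: list[tuple[tuple, tuple]]) -> pd.DataFrame:
    """Fisher's LSD pairwise comparisons after a fitted two-way ANOVA.

    Each pair is ((levelA1, levelB1), (levelA2, levelB2)) naming two design
    cells; t = (mean1 - mean2) / sqrt(MSE (1/n1 + 1/n2)) with p from the
    t distribution at the ANOVA error df. P-values are unadjusted (that is
    the LSD procedure).
    """
    if anova.cell_stats is None or anova.mse is None:
        raise ValidationError("fisher_lsd requires a fitted two-way ANOVA result")
    cells = anova.cell_stats.set_index(["fa", "fb"])
    rows = []
    for c1, c2 in pairs:
        for c in (c1, c2):
            if tuple(c) not in cells.index:
                raise ValidationError(f"design cell {c} not present")
        m1, n1 = cells.loc[tuple(c1), ["mean", "count"]]
        m2, n2 = cells.loc[tuple(c2), ["mean", "count"]]
        se = np.sqrt(anova.mse * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se if se > 0 else 0.0
        p = 2 * sst.t.sf(abs(t), anova.df_error)
        rows.append({"cell_1": tuple(c1), "cell_2": tuple(c2),
                     "diff": float(m1 - m2), "t": float(t),
                     "df": anova.df_error, "p": float(p)})
    return pd.DataFrame(rows)


def normality_and_variance(groups: dict[str, np.ndarray]) -> dict:
    """Shapiro-Wilk per group plus a Brown-Forsythe homogeneity test.

    Shapiro-Wilk is skipped (flagged) for groups with n < 3 or zero
    variance. Brown-Forsythe is the Levene test on absolute deviations from
    group medians.
    """
    shapiro = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3 or np.ptp(v) == 0:
            shapiro.append({"group": name, "W": np.nan, "p": np.nan,
                            "skipped": True})
        else:
            w, p = sst.shapiro(v)
            shapiro.append({"group": name, "W": float(w), "p": float(p),
                            "skipped": False})
    arrays = [np.asarray(v, float) for v in groups.values()]
    if len(arrays) >= 2 and all(len(a) >= 2 for a in arrays):
        f, p = sst.levene(*arrays, center="median")
        bf = {"F": float(f), "p": float(p)}
    else:
        bf = {"F": np.nan, "p": np.nan}
    return {"shapiro": pd.DataFrame(shapiro), "brown_forsythe": bf}
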