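"""Group-comparison layer for pipeline outputs.

Implements the decision tree used for the imaging read-outs: per-group
Shapiro-Wilk normality screening at alpha = 0.05; if every group passes,
one-way ANOVA with Dunnett's test against the control (or an unpaired
t-test when there are exactly two groups); otherwise Kruskal-Wallis with
Dunn's test against the control (Sidak family correction over the
control-vs-treatment contrasts).  Tables with a second factor (e.g.
external calcium level) go to two-way ANOVA with Sidak-corrected
within-condition contrasts.  Alpha is fixed at 0.05 and no outlier
removal is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTable",
    "TestPlan",
    "StatsReport",
    "choose_test",
    "run_tests",
    "dunn_test",
    "analyze",
]

ALPHA = 0.05


@dataclass
class GroupTable:
    """Long-format per-unit results with a designated control group.

    ``data`` needs columns ``condition`` and ``value``; optional
    ``experiment`` and ``unit_id`` identify units, and ``factor`` names a
    second-factor column (two-way designs).
    """

    data: pd.DataFrame
    control: str = "CTRL"
    factor: str | None = None

    def __post_init__(self) -> None:
        for col in ("condition", "value"):
            if col not in self.data.columns:
                raise ValueError(f"GroupTable data needs a {col!r} column")
        conditions = self.data["condition"].unique()
        if len(conditions) < 2:
            raise ValueError("need at least 2 conditions")
        if self.control not in conditions:
            raise ValueError(f"control {self.control!r} not among conditions "
                             f"{sorted(conditions)}")
        if self.factor is not None and self.factor not in self.data.columns:
            raise ValueError(f"factor column {self.factor!r} missing")

    def groups(self) -> dict[str, np.ndarray]:
        return {c: g["value"].to_numpy(dtype=float)
                for c, g in self.data.groupby("condition", sort=True)}


@dataclass
class TestPlan:
    name: str            # anova_dunnett | ttest | kruskal_dunn | twoway_sidak
    reasons: list[str] = field(default_factory=list)


@dataclass
class StatsReport:
    plan: str
    omnibus_stat: float
    omnibus_df: tuple
    omnibus_p: float
    comparisons: pd.DataFrame     # condition, statistic, p_unadjusted, p_adjusted

    def to_dict(self) -> dict:
        return {
            "plan": self.plan,
            "omnibus": {"statistic": self.omnibus_stat,
                        "df": list(self.omnibus_df), "p": self.omnibus_p},
            "comparisons": self.comparisons.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path


def choose_test(table: GroupTable, alpha: float = ALPHA) -> TestPlan:
    """Pick the test route for a table (see module docstring)."""
    if table.factor is not None:
        return TestPlan("twoway_sidak", ["second factor present"])
    groups = table.groups()
    reasons = []
    for name, vals in groups.items():
        if len(vals) < 3:
            return TestPlan(
                "kruskal_dunn",
                [f"group {name!r} has n={len(vals)} < 3; normality cannot be "
                 "assessed, falling back to nonparametric tests"],
            )
    for name, vals in groups.items():
        if np.ptp(vals) == 0:
            reasons.append(f"group {name!r} is constant; treated as "
                           "non-normal")
            return TestPlan("kruskal_dunn", reasons)
        p = sps.shapiro(vals).pvalue
        if p < alpha:
            reasons.append(f"Shapiro-Wilk rejected normality for {name!r} "
                           f"(p={p:.3g})")
            return TestPlan("kruskal_dunn", reasons)
    reasons.append("all groups pass Shapiro-Wilk")
    if len(groups) == 2:
        return TestPlan("ttest", reasons + ["exactly two groups"])
    return TestPlan("anova_dunnett", reasons)


def dunn_test(groups: dict[str, np.ndarray], control: str,
              sidak: bool = True) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z tests of each group against the
    control, with tie correction and (optionally) Sidak family control
    limited to the control-vs-treatment contrasts."""
    names = list(groups)
    all_vals = np.concatenate([groups[n] for n in names])
    N = len(all_vals)
    ranks = sps.rankdata(all_vals)
    mean_ranks, sizes, start = {}, {}, 0
    for n in names:
        k = len(groups[n])
        mean_ranks[n] = ranks[start:start + k].mean()
        sizes[n] = k
        start += k
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    others = [n for n in names if n != control]
    m = len(others)
    for n in others:
        se = np.sqrt(var_base * (1.0 / sizes[control] + 1.0 / sizes[n]))
        z = (mean_ranks[n] - mean_ranks[control]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = 1.0 - (1.0 - p) ** m if sidak else p
        rows.append({"condition": n, "statistic": z, "p_unadjusted": p,
                     "p_adjusted": min(1.0, p_adj)})
    return pd.DataFrame(rows)


def _anova_dunnett(groups: dict[str, np.ndarray], control: str) -> StatsReport:
    names = list(groups)
    vals = [groups[n] for n in names]
    if all(np.ptp(v) == 0 for v in vals):
        raise ValueError("zero within-group variance in all groups")
    k = len(names)
    N = sum(len(v) for v in vals)
    f = sps.f_oneway(*vals)
    others = [n for n in names if n != control]
    res = sps.dunnett(*[groups[n] for n in others], control=groups[control])
    df_resid = N - k
    p_unadj = 2.0 * sps.t.sf(np.abs(res.statistic), df_resid)
    comp = pd.DataFrame({
        "condition": others,
        "statistic": res.statistic,
        "p_unadjusted": p_unadj,
        "p_adjusted": res.pvalue,
    })
    return StatsReport("anova_dunnett", float(f.statistic), (k - 1, df_resid),
                       float(f.pvalue), comp)


def _ttest(groups: dict[str, np.ndarray], control: str) -> StatsReport:
    others = [n for n in groups if n != control]
    name = others[0]
    res = sps.ttest_ind(groups[name], groups[control])
    df = len(groups[name]) + len(groups[control]) - 2
    comp = pd.DataFrame({
        "condition": [name], "statistic": [float(res.statistic)],
        "p_unadjusted": [float(res.pvalue)], "p_adjusted": [float(res.pvalue)],
    })
    return StatsReport("ttest", float(res.statistic), (df,), float(res.pvalue),
                       comp)


def _kruskal_dunn(groups: dict[str, np.ndarray], control: str) -> StatsReport:
    vals = list(groups.values())
    if all(np.ptp(v) == 0 for v in vals):
        raise ValueError("zero within-group variance in all groups")
    h = sps.kruskal(*vals)
    comp = dunn_test(groups, control)
    return StatsReport("kruskal_dunn", float(h.statistic), (len(groups) - 1,),
                       float(h.pvalue), comp)


def _twoway_sidak(table: GroupTable) -> StatsReport:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.data.rename(columns={table.factor: "factor2"})
    model = smf.ols("value ~ C(condition) * C(factor2)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    inter = aov.loc["C(condition):C(factor2)"]
    levels = sorted(df["factor2"].unique())
    if len(levels) != 2:
        raise ValueError("two-way route expects exactly 2 factor levels")
    conditions = sorted(df["condition"].unique())
    m = len(conditions)
    rows = []
    for cond in conditions:
        a = df.loc[(df.condition == cond) & (df.factor2 == levels[0]), "value"]
        b = df.loc[(df.condition == cond) & (df.factor2 == levels[1]), "value"]
        res = sps.ttest_ind(a, b)
        p_adj = 1.0 - (1.0 - res.pvalue) ** m
        rows.append({"condition": cond, "statistic": float(res.statistic),
                     "p_unadjusted": float(res.pvalue),
                     "p_adjusted": float(min(1.0, p_adj))})
    return StatsReport(
        "twoway_sidak", float(inter["F"]),
        (int(inter["df"]), int(aov.loc["Residual", "df"])),
        float(inter["PR(>F)"]), pd.DataFrame(rows),
    )


def run_tests(table: GroupTable, plan: TestPlan) -> StatsReport:
    """Execute a test plan from :func:`choose_test`."""
    if plan.name == "twoway_sidak":
        return _twoway_sidak(table)
    groups = table.groups()
    if plan.name == "anova_dunnett":
        return _anova_dunnett(groups, table.control)
    if plan.name == "ttest":
        return _ttest(groups, table.control)
    if plan.name == "kruskal_dunn":
        return _kruskal_dunn(groups, table.control)
    raise ValueError(f"unknown plan {plan.name!r}")


def analyze(table: GroupTable) -> StatsReport:
    """choose_test + run_tests in one call."""
    return run_tests(table, choose_test(table))
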