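"""Cohort statistics: percent changes and repeated-measures two-way ANOVA.

Each parameter (concentration, intra-stick diffusivity, ADC, kurtosis) is
analysed with a classical univariate repeated-measures two-way ANOVA in
which both factors — disease stage (week 0 vs week 6) and metabolite — are
within-subject and the subject is the blocking factor. Each effect is
tested against its own subject-interaction mean square; the Prism-style
"subject-matching" line tests the subject mean square against the residual
(three-way) term. No sphericity correction is applied.

Post-hoc per-metabolite disease comparisons are Bonferroni-corrected with
the number of comparisons equal to the number of retained metabolites. Two
error variants are available: "pooled" (default) pools the disease×subject
and residual sums of squares across metabolites, "paired" is the ordinary
per-metabolite paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

PARAMETERS = ("conc", "d_intra", "adc", "kurtosis")


@dataclass(frozen=True)
class AnovaLine:
    ss: float
    df: int
    ms: float
    f: float
    p: float


@dataclass(frozen=True)
class PosthocLine:
    metabolite: str
    mean_diff: float
    t: float
    df: float
    p_raw: float
    p_adj: float
    pct_change_mean: float
    pct_change_sd: float


@dataclass(frozen=True)
class StatsReport:
    parameter: str
    anova: dict[str, AnovaLine]
    posthoc: list[PosthocLine] = field(default_factory=list)
    n_comparisons: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"effect": k, "SS": v.ss, "df": v.df, "MS": v.ms, "F": v.f, "p": v.p}
                for k, v in self.anova.items()
            ]
        )


def _check_balanced(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    sub = table[table["parameter"] == parameter]
    if sub.empty:
        raise ValueError(f"no rows for parameter {parameter!r}")
    if not np.isfinite(sub["value"]).all():
        raise ValueError("non-finite values in cohort table")
    counts = sub.groupby(["animal", "timepoint", "metabolite"]).size()
    if (counts != 1).any():
        dup = counts[counts != 1].index.tolist()
        raise ValueError(f"cells not uniquely filled: {dup}")
    pivot = sub.pivot_table(
        index="animal", columns=["timepoint", "metabolite"], values="value"
    )
    if pivot.isna().any().any():
        missing = [
            (a, tp, m)
            for a in pivot.index
            for (tp, m) in pivot.columns[pivot.loc[a].isna()]
        ]
        raise ValueError(f"unbalanced table; missing cells: {missing}")
    return sub


def percent_change(
    table: pd.DataFrame, metabolite: str, parameter: str
) -> tuple[float, float]:
    """Across-animal mean ± SD of the per-animal percent change
    100·(week6 − week0)/week0."""
    sub = table[
        (table["parameter"] == parameter) & (table["metabolite"] == metabolite)
    ]
    piv = sub.pivot_table(index="animal", columns="timepoint", values="value")
    if "week0" not in piv or "week6" not in piv or len(piv.dropna()) < 2:
        raise ValueError("need paired week0/week6 values for >= 2 animals")
    piv = piv.dropna()
    if (piv["week0"] <= 0).any():
        raise ValueError("non-positive week0 value; percent change undefined")
    pct = 100.0 * (piv["week6"] - piv["week0"]) / piv["week0"]
    return float(pct.mean()), float(pct.std(ddof=1))


def _anova_cells(sub: pd.DataFrame) -> tuple[np.ndarray, list, list, list]:
    animals = sorted(sub["animal"].unique())
    tps = sorted(sub["timepoint"].unique())
    mets = sorted(sub["metabolite"].unique())
    Y = np.empty((len(animals), len(tps), len(mets)))
    piv = sub.set_index(["animal", "timepoint", "metabolite"])["value"]
    for i, a in enumerate(animals):
        for j, t in enumerate(tps):
            for k, m in enumerate(mets):
                Y[i, j, k] = piv[(a, t, m)]
    return Y, animals, tps, mets


def rm_anova(
    table: pd.DataFrame,
    parameter: str,
    n_comparisons: int | None = None,
    posthoc: str = "pooled",
) -> StatsReport:
    """Two-way repeated-measures ANOVA with Bonferroni post-hoc.

    ``table`` is the long cohort table with columns (animal, timepoint,
    metabolite, parameter, value); ``timepoint`` must take the two levels
    week0/week6. All tests are two-tailed.
    """
    sub = _check_balanced(table, parameter)
    Y, animals, tps, mets = _anova_cells(sub)
    n, q, m = Y.shape  # subjects, disease levels, metabolites
    if q != 2:
        raise ValueError("expected exactly two timepoints")

    grand = Y.mean()
    mean_s = Y.mean(axis=(1, 2))
    mean_d = Y.mean(axis=(0, 2))
    mean_m = Y.mean(axis=(0, 1))
    mean_sd = Y.mean(axis=2)
    mean_sm = Y.mean(axis=1)
    mean_dm = Y.mean(axis=0)

    ss_s = q * m * np.sum((mean_s - grand) ** 2)
    ss_d = n * m * np.sum((mean_d - grand) ** 2)
    ss_m = n * q * np.sum((mean_m - grand) ** 2)
    ss_sd = m * np.sum((mean_sd - mean_s[:, None] - mean_d[None, :] + grand) ** 2)
    ss_sm = q * np.sum((mean_sm - mean_s[:, None] - mean_m[None, :] + grand) ** 2)
    ss_dm = n * np.sum((mean_dm - mean_d[:, None] - mean_m[None, :] + grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_res = ss_tot - ss_s - ss_d - ss_m - ss_sd - ss_sm - ss_dm

    df_s, df_d, df_m = n - 1, q - 1, m - 1
    df_sd, df_sm, df_dm = df_s * df_d, df_s * df_m, df_d * df_m
    df_res = df_s * df_d * df_m

    def line(ss_eff, df_eff, ss_err, df_err) -> AnovaLine:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        f = ms_eff / ms_err
        return AnovaLine(
            ss=float(ss_eff), df=int(df_eff), ms=float(ms_eff), f=float(f),
            p=float(sps.f.sf(f, df_eff, df_err)),
        )

    anova = {
        "disease": line(ss_d, df_d, ss_sd, df_sd),
        "metabolite": line(ss_m, df_m, ss_sm, df_sm),
        "interaction": line(ss_dm, df_dm, ss_res, df_res),
        "subject-matching": line(ss_s, df_s, ss_res, df_res),
    }

    n_cmp = int(n_comparisons) if n_comparisons is not None else m
    i6 = tps.index("week6") if "week6" in tps else 1
    i0 = tps.index("week0") if "week0" in tps else 0
    lines: list[PosthocLine] = []
    if posthoc == "pooled":
        ms_pool = (ss_sd + ss_res) / (df_sd + df_res)
        df_err = df_sd + df_res
    elif posthoc != "paired":
        raise ValueError("posthoc must be 'pooled' or 'paired'")
    for k, met in enumerate(mets):
        diff = Y[:, i6, k] - Y[:, i0, k]
        dbar = diff.mean()
        if posthoc == "pooled":
            se = np.sqrt(2.0 * ms_pool / n)
            dfh = df_err
        else:
            se = diff.std(ddof=1) / np.sqrt(n)
            dfh = n - 1
        t = dbar / se if se > 0 else np.inf
        p_raw = float(2.0 * sps.t.sf(abs(t), dfh))
        pc_mean, pc_sd = percent_change(table, met, parameter)
        lines.append(
            PosthocLine(
                metabolite=met, mean_diff=float(dbar), t=float(t), df=float(dfh),
                p_raw=p_raw, p_adj=float(min(1.0, p_raw * n_cmp)),
                pct_change_mean=pc_mean, pct_change_sd=pc_sd,
            )
        )
    return StatsReport(parameter=parameter, anova=anova, posthoc=lines, n_comparisons=n_cmp)
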