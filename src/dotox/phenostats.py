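"""Descriptive and comparative statistics for micronucleus rates.

Micronucleated-cell counts are normalized to rates per 1,000 cells scored and
treated as log-normal: group summaries are geometric means with a +/- 2
log-SD interval back-transformed to the response scale.  Exposure and cohort
effects are assessed by two-way fixed-effects ANOVA on log2-transformed
rates, pairwise group differences by Tukey's honest significant difference,
and pre/post-exposure tracking by Pearson correlation within exposure group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


@dataclass
class GroupSummary:
    """Geometric mean and +/- 2 log-SD interval of one group."""

    group: object
    n: int
    geometric_mean: float
    ci_low: float
    ci_high: float


def normalize_counts(mn_count, cells_scored) -> np.ndarray:
    """Micronucleated-cell rate per 1,000 cells scored."""
    cells = np.asarray(cells_scored, dtype=float)
    if np.any(cells <= 0):
        raise ValueError("cells_scored must be positive")
    return 1000.0 * np.asarray(mn_count, dtype=float) / cells


def positive_offset(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Zero-rate policy: add half the minimum positive value before logs.

    Returns (adjusted values, flag) where the flag records that an offset was
    applied; negative values are rejected outright.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("rates must be non-negative")
    if np.all(v > 0):
        return v, False
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("all values are zero; no scale for the log transform")
    return v + pos.min() / 2.0, True


def geometric_summary(values, group: object = None) -> GroupSummary:
    """Geometric mean with the antilog of (log-mean +/- 2 log-SD)."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("geometric summary requires positive values")
    logs = np.log(v)
    m = logs.mean()
    s = logs.std(ddof=1) if len(v) > 1 else 0.0
    return GroupSummary(
        group=group,
        n=len(v),
        geometric_mean=float(np.exp(m)),
        ci_low=float(np.exp(m - 2 * s)),
        ci_high=float(np.exp(m + 2 * s)),
    )


def group_summaries(values, labels) -> pd.DataFrame:
    frame = pd.DataFrame({"value": np.asarray(values, float), "group": labels})
    rows = []
    for g, sub in frame.groupby("group", sort=True):
        s = geometric_summary(sub["value"].to_numpy(), group=g)
        rows.append(
            {
                "group": g,
                "n": s.n,
                "geometric_mean": s.geometric_mean,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
        )
    return pd.DataFrame(rows)


def two_way_anova_log(values, cohort, exposure, interaction: bool = True) -> dict:
    """Two-way fixed-effects ANOVA on log2 values.

    Returns p-values for the cohort and exposure main effects and (by
    default) their interaction.  Every cohort x exposure cell must be
    occupied; an empty cell is reported by name.
    """
    frame = pd.DataFrame(
        {
            "logv": np.log2(np.asarray(values, dtype=float)),
            "cohort": pd.Categorical(cohort),
            "exposure": pd.Categorical(exposure),
        }
    )
    if frame["cohort"].nunique() < 2 or frame["exposure"].nunique() < 2:
        raise ValueError("both factors need at least 2 levels")
    counts = frame.groupby(["cohort", "exposure"], observed=False).size()
    empty = counts[counts == 0]
    if len(empty):
        cell = empty.index[0]
        raise ValueError(f"empty cell: cohort={cell[0]}, exposure={cell[1]}")
    formula = (
        "logv ~ C(cohort) * C(exposure)" if interaction else "logv ~ C(cohort) + C(exposure)"
    )
    model = smf.ols(formula, data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {
        "p_cohort": float(table.loc["C(cohort)", "PR(>F)"]),
        "p_exposure": float(table.loc["C(exposure)", "PR(>F)"]),
    }
    if interaction:
        out["p_interaction"] = float(table.loc["C(cohort):C(exposure)", "PR(>F)"])
    return out


def tukey_hsd(log_values, group_labels) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons on (already log-transformed) values.

    Returns a tidy table (group1, group2, p_adj) from the studentized-range
    distribution.
    """
    frame = pd.DataFrame({"v": np.asarray(log_values, float), "g": group_labels})
    groups = sorted(frame["g"].unique(), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = []
    for g in groups:
        v = frame.loc[frame["g"] == g, "v"].to_numpy()
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        samples.append(v)
    res = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group1": groups[i],
                    "group2": groups[j],
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def correlate_pre_post(pre, post, group) -> pd.DataFrame:
    """Pearson correlation between paired pre- and post-exposure values,
    per exposure group."""
    frame = pd.DataFrame(
        {
            "pre": np.asarray(pre, float),
            "post": np.asarray(post, float),
            "group": group,
        }
    ).dropna()
    rows = []
    for g, sub in frame.groupby("group", sort=True):
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 complete pairs")
        r, p = stats.pearsonr(sub["pre"], sub["post"])
        rows.append({"group": g, "n": len(sub), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
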