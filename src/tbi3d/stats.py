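"""Group statistics: IQR outlier removal, one-way ANOVA with Fisher's LSD,
and 2^−ΔΔCt qPCR fold changes.

The grouping unit is one value per animal per layer; metrics are compared
across treatment groups within each layer.  Outliers beyond 1.5×IQR of each
group are removed before testing.  Fisher's LSD uses the ANOVA pooled
within-group variance and applies no multiplicity adjustment (that is its
definition); in the two-group case it reduces exactly to the pooled
two-sample t test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaReport",
    "FoldChangeResult",
    "remove_outliers_iqr",
    "oneway_anova",
    "fisher_lsd",
    "fold_change_ddct",
    "fold_change_table",
    "DegenerateDataError",
]

ALPHA = 0.05  # significance level used throughout


class DegenerateDataError(ValueError):
    """All observations identical: no variance to test."""


def remove_outliers_iqr(values: Sequence[float], k: float = 1.5) -> list[float]:
    """Drop values outside the closed interval [Q1 − k·IQR, Q3 + k·IQR].

    Quartiles use linear interpolation.  Fewer than four values are returned
    unchanged (quartiles too unstable to fence on).
    """
    vals = [float(v) for v in values]
    if len(vals) < 4:
        return vals
    q1, q3 = np.percentile(vals, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return [v for v in vals if lo <= v <= hi]


@dataclass
class AnovaReport:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    group_means: dict[str, float]
    group_ns: dict[str, int]
    lsd: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


def oneway_anova(groups: Mapping[str, Sequence[float]]) -> AnovaReport:
    """Classical one-way ANOVA between/within decomposition.

    ``groups`` maps group name to per-animal observations.  Requires at
    least two groups with at least two observations each.  Zero within-group
    variance with unequal means reports p = 0 with a warning; fully
    identical data raises :class:`DegenerateDataError`.
    """
    arrs = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(arrs) < 2 or any(a.size < 2 for a in arrs.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    allv = np.concatenate(list(arrs.values()))
    grand = allv.mean()
    n_total = allv.size
    k = len(arrs)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs.values())
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs.values())
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0 and ss_between == 0.0:
        raise DegenerateDataError("all observations identical")
    if ss_within == 0.0:
        warnings.warn("zero within-group variance with unequal means; p reported as 0", stacklevel=2)
        F, p = math.inf, 0.0
        ms_w = 0.0
    else:
        ms_b = ss_between / df_b
        ms_w = ss_within / df_w
        F = ms_b / ms_w
        p = float(sps.f.sf(F, df_b, df_w))
    return AnovaReport(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        ms_within=ms_w,
        group_means={g: float(a.mean()) for g, a in arrs.items()},
        group_ns={g: int(a.size) for g, a in arrs.items()},
    )


def fisher_lsd(groups: Mapping[str, Sequence[float]], anova: AnovaReport) -> dict[tuple[str, str], tuple[float, float]]:
    """Pairwise LSD comparisons: (mean difference, two-tailed p) per pair.

    t = (mean_i − mean_j) / sqrt(MS_within · (1/n_i + 1/n_j)) on the ANOVA
    within-group degrees of freedom; unadjusted by definition.
    """
    out: dict[tuple[str, str], tuple[float, float]] = {}
    names = list(groups.keys())
    for gi, gj in combinations(names, 2):
        ni, nj = anova.group_ns[gi], anova.group_ns[gj]
        if ni < 1 or nj < 1:
            warnings.warn(f"pair ({gi}, {gj}) skipped: empty group", stacklevel=2)
            continue
        diff = anova.group_means[gi] - anova.group_means[gj]
        if anova.ms_within == 0.0:
            p = 0.0 if diff != 0 else 1.0
        else:
            se = math.sqrt(anova.ms_within * (1.0 / ni + 1.0 / nj))
            t = diff / se
            p = float(2.0 * sps.t.sf(abs(t), anova.df_within))
        out[(gi, gj)] = (float(diff), p)
    anova.lsd = out
    return out


@dataclass
class FoldChangeResult:
    fold_change: float
    ddct: float
    t_stat: float
    p: float
    n_treated: int
    n_control: int


def fold_change_ddct(
    treated_dct: Sequence[float],
    control_dct: Sequence[float],
) -> FoldChangeResult:
    """Relative expression by the ΔΔCt method.

    Inputs are per-animal ΔCt values (Ct_target − Ct_reference).  The point
    estimate is the group-mean ΔΔCt = mean ΔCt(treated) − mean ΔCt(control),
    fold change = 2^(−ΔΔCt); the group difference is tested by a two-tailed
    unpaired t test on the per-animal ΔCt values.
    """
    t_arr = np.asarray(treated_dct, dtype=float)
    c_arr = np.asarray(control_dct, dtype=float)
    if t_arr.size == 0 or c_arr.size == 0:
        raise ValueError("both groups must be nonempty")
    ddct = float(t_arr.mean() - c_arr.mean())
    fc = 2.0 ** (-ddct)
    if t_arr.size > 1 and c_arr.size > 1:
        t_stat, p = sps.ttest_ind(t_arr, c_arr)
        t_stat, p = float(t_stat), float(p)
    else:
        t_stat, p = math.nan, math.nan
    return FoldChangeResult(fc, ddct, t_stat, p, int(t_arr.size), int(c_arr.size))


def delta_ct(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``dct`` column (ct_target − ct_reference) to a qPCR table."""
    out = df.copy()
    if (out["ct_target"] <= 0).any() or (out["ct_reference"] <= 0).any():
        raise ValueError("Ct values must be positive")
    out["dct"] = out["ct_target"] - out["ct_reference"]
    return out


def fold_change_table(qpcr: pd.DataFrame, control_group: str = "sham") -> pd.DataFrame:
    """Per gene, side and treatment group: fold change vs the control group.

    ``qpcr`` needs columns animal, group, side, gene, ct_target,
    ct_reference.  Returns a tidy table with fold_change, ddct, t, p per
    (gene, side, group).
    """
    df = delta_ct(qpcr)
    rows = []
    for (gene, side), sub in df.groupby(["gene", "side"]):
        ctrl = sub[sub["group"] == control_group]["dct"].to_numpy()
        if ctrl.size == 0:
            warnings.warn(f"no {control_group} samples for gene={gene}, side={side}", stacklevel=2)
            continue
        for grp, gsub in sub.groupby("group"):
            if grp == control_group:
                continue
            res = fold_change_ddct(gsub["dct"].to_numpy(), ctrl)
            rows.append(
                dict(gene=gene, side=side, group=grp, fold_change=res.fold_change,
                     ddct=res.ddct, t=res.t_stat, p=res.p,
                     n=res.n_treated, n_control=res.n_control)
            )
    return pd.DataFrame(rows)
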