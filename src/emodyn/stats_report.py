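"""Between-group comparison statistics: one-way ANOVA with effect size.

The decomposition is the textbook one: SS_between over group means,
SS_within pooled, F = MS_between / MS_within, p from the upper tail of the
F distribution, and partial eta squared SS_between/(SS_between+SS_within)
(for a one-way design this equals F*df1/(F*df1 + df2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaResult", "one_way_anova", "f_upper_tail", "shapiro_normality",
           "anova_report"]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_p2: float

    def as_dict(self) -> dict:
        return {"F": self.F, "df_between": self.df_between,
                "df_within": self.df_within, "p": self.p, "eta_p2": self.eta_p2}


def one_way_anova(groups: Sequence[np.ndarray]) -> AnovaResult:
    """One-way between-subjects ANOVA over two or more samples."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_x.size - len(groups)
    if ss_within == 0 and ss_between == 0:
        raise ValueError("zero variance everywhere; F undefined")
    if ss_within == 0:
        return AnovaResult(np.inf, df_b, df_w, 0.0, 1.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    eta = ss_between / (ss_between + ss_within)
    return AnovaResult(float(F), df_b, df_w, f_upper_tail(F, df_b, df_w), float(eta))


def f_upper_tail(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution (survival function)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    return float(stats.f.sf(F, df1, df2))


def shapiro_normality(groups: Sequence[np.ndarray]) -> list[float]:
    """Shapiro-Wilk p-value per group (screening only, never gating).

    Groups with fewer than 3 values return nan (test undefined).
    """
    out = []
    for g in groups:
        g = np.asarray(g, float)
        out.append(float(stats.shapiro(g).pvalue) if g.size >= 3 else float("nan"))
    return out


def anova_report(feature_groups: dict[str, Sequence[np.ndarray]]) -> pd.DataFrame:
    """Per-feature ANOVA summary table (F, df, p, eta_p2, normality)."""
    rows = []
    for name, groups in feature_groups.items():
        res = one_way_anova(groups)
        sw = shapiro_normality(groups)
        rows.append({"feature": name, **res.as_dict(),
                     "shapiro_p_min": min(sw)})
    return pd.DataFrame(rows).set_index("feature")
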