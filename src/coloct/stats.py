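"""Study-level statistics: two-way group × day ANOVA and summaries.

The longitudinal design crosses treatment group (challenged/unchallenged)
with imaging day (baseline, inflammation peak, recovery).  Evidence for a
disease effect is the group × day *interaction*: inflammation changes the
challenged group's thickness/attenuation at the peak day only.

By default each mouse-day contributes its mean over pullback locations
(``unit="mouse_mean"``): the 10 locations are repeated measurements of the
same colon, and treating them as independent replicates inflates the
effective sample size.  ``unit="location"`` is available and labeled for
comparison.  Type II sums of squares are used so unbalanced tables are
handled sensibly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .phantom import StudyDesign  # noqa: F401  (design type lives with the generator)

__all__ = [
    "StudyDesign",
    "two_way_anova",
    "interaction_pvalue",
    "summarize",
    "significance_stars",
]

RESPONSES = ("thickness_um", "mu_A_mm", "pct_change")


def two_way_anova(
    table: pd.DataFrame,
    response: str = "thickness_um",
    unit: str = "mouse_mean",
    layer: str | None = None,
) -> pd.DataFrame:
    """Two-way ANOVA of ``response`` on group, day and their interaction.

    Returns the Type II ANOVA table (sum_sq, df, F, PR(>F)) indexed by
    ``C(group)``, ``C(day)``, ``C(group):C(day)`` and ``Residual``.
    Raises if a group × day cell has no observations (named in the error).
    """
    if response not in table.columns:
        raise ValueError(f"response {response!r} not in table")
    if unit not in ("mouse_mean", "location"):
        raise ValueError(f"unknown analysis unit {unit!r}")
    data = table.copy()
    if layer is not None:
        data = data[data["layer"] == layer]
    data = data.dropna(subset=[response])
    for factor in ("group", "day"):
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")
    counts = data.groupby(["group", "day"], observed=True).size()
    for g in data["group"].unique():
        for d in data["day"].unique():
            if (g, d) not in counts.index or counts[(g, d)] == 0:
                raise ValueError(f"empty design cell: group={g!r}, day={d}")
    if unit == "mouse_mean":
        data = (
            data.groupby(["mouse", "group", "day"], observed=True)[response]
            .mean()
            .reset_index()
        )
    model = ols(f"{response} ~ C(group) * C(day)", data=data).fit()
    return sm.stats.anova_lm(model, typ=2)


def interaction_pvalue(anova_table: pd.DataFrame) -> float:
    """p-value of the group × day interaction from an ANOVA table."""
    return float(anova_table.loc["C(group):C(day)", "PR(>F)"])


def summarize(table: pd.DataFrame, value_col: str = "thickness_um") -> pd.DataFrame:
    """Per group × day × layer mean, SD and n (box-plot-ready).

    SD is reported missing (NaN) for single observations; empty cells are
    absent from the output.
    """
    if table.empty:
        raise ValueError("empty quantification table")
    keys = [c for c in ("group", "day", "layer") if c in table.columns]
    out = (
        table.dropna(subset=[value_col])
        .groupby(keys, observed=True)[value_col]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def significance_stars(p: float) -> str:
    """Annotation convention: *** for p <= 0.001, ** <= 0.01, * <= 0.05."""
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""
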