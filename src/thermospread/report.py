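"""Report tables: group summaries, subgroup rank tests, correlations and
regression fits over an analysis manifest.

The manifest is a DataFrame with at least ``power_w``, ``duration_s`` and the
measured columns (``spread_area_mm2``, ``macro_area_mm2``); dropped samples
are excluded upstream.
"""

from __future__ import annotations

import pandas as pd

from .stats import linear_fit, median_iqr, spearman, wilcoxon_ranksum

__all__ = [
    "group_summary_table",
    "pairwise_test_table",
    "correlation_table",
    "regression_table",
]

_GROUP_COLS = ["power_w", "duration_s"]


def _groups(df: pd.DataFrame):
    for (power, duration), sub in df.groupby(_GROUP_COLS, sort=True):
        yield (float(power), float(duration)), sub


def group_summary_table(df: pd.DataFrame, value_col: str = "spread_area_mm2") -> pd.DataFrame:
    """Per-group N / median / IQR (the shape of the study's summary table)."""
    rows = []
    for (power, duration), sub in _groups(df):
        s = median_iqr(sub[value_col].to_numpy(), group=(power, duration))
        rows.append(
            {
                "power_w": power,
                "duration_s": duration,
                "n": s.n,
                "median_mm2": s.median,
                "q1_mm2": s.q1,
                "q3_mm2": s.q3,
                "iqr_mm2": s.iqr,
            }
        )
    return pd.DataFrame(rows)


def pairwise_test_table(df: pd.DataFrame, value_col: str = "spread_area_mm2") -> pd.DataFrame:
    """Rank-sum tests for the study's subgroup contrasts.

    30-vs-60 W within each application time, and 2-vs-4 s within each power.
    """
    rows = []

    def _contrast(label, fixed_col, fixed_val, var_col, a, b):
        xa = df[(df[fixed_col] == fixed_val) & (df[var_col] == a)][value_col].to_numpy()
        xb = df[(df[fixed_col] == fixed_val) & (df[var_col] == b)][value_col].to_numpy()
        if len(xa) == 0 or len(xb) == 0:
            return
        res = wilcoxon_ranksum(xa, xb)
        rows.append(
            {
                "contrast": label,
                "n1": res.n1,
                "n2": res.n2,
                "rank_sum_w": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )

    for duration in sorted(df["duration_s"].unique()):
        _contrast(f"30W_vs_60W_at_{duration:g}s", "duration_s", duration, "power_w", 30.0, 60.0)
    for power in sorted(df["power_w"].unique()):
        _contrast(f"2s_vs_4s_at_{power:g}W", "power_w", power, "duration_s", 2.0, 4.0)
    return pd.DataFrame(rows)


def correlation_table(
    df: pd.DataFrame,
    x_col: str = "spread_area_mm2",
    y_col: str = "macro_area_mm2",
) -> pd.DataFrame:
    """Per-group Spearman correlation between two measured areas.

    Groups with fewer than 3 pairs or a constant variable get r = NaN with
    the N recorded.
    """
    rows = []
    for (power, duration), sub in _groups(df):
        x = sub[x_col].to_numpy()
        y = sub[y_col].to_numpy()
        try:
            res = spearman(x, y)
            r, n = res.r, res.n
        except ValueError:
            r, n = float("nan"), len(x)
        rows.append({"power_w": power, "duration_s": duration, "n": n, "spearman_r": r})
    return pd.DataFrame(rows)


def regression_table(
    df: pd.DataFrame,
    x_col: str = "spread_area_mm2",
    y_col: str = "macro_area_mm2",
) -> pd.DataFrame:
    """Per-group OLS fit of y on x (slope, intercept, r²)."""
    rows = []
    for (power, duration), sub in _groups(df):
        x = sub[x_col].to_numpy()
        y = sub[y_col].to_numpy()
        try:
            fit = linear_fit(x, y)
            slope, intercept, r2, n = fit.slope, fit.intercept, fit.r_squared, fit.n
        except ValueError:
            slope = intercept = r2 = float("nan")
            n = len(x)
        rows.append(
            {
                "power_w": power,
                "duration_s": duration,
                "n": n,
                "slope": slope,
                "intercept": intercept,
                "r_squared": r2,
            }
        )
    return pd.DataFrame(rows)
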