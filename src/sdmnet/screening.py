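"""Outlier screening and variance-stabilising transform.

Outliers are flagged with Rosner's generalized extreme studentized
deviate (ESD) test — an iterative test for up to k outliers in roughly
normal data — and replaced by missing values before the log10(x+1)
transform that the downstream parametric analyses assume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError

__all__ = ["gesd_flag", "log_transform", "screen_columns", "screen_long"]


def gesd_flag(values, alpha: float = 0.05, max_frac: float = 0.2) -> np.ndarray:
    """Indices of outliers by the generalized ESD (Rosner) procedure.

    For i = 1..k with k = floor(max_frac * n): compute the extreme
    studentized deviate R_i = max|x - mean| / sd over the values still in
    play, remove that point, and compare against the two-sided critical
    value

        lambda_i = (n_i - 1) * t / sqrt((n_i - 2 + t^2) * n_i),

    where n_i is the current sample size and t is the upper
    alpha / (2 n_i) Student-t quantile with n_i - 2 df.  The declared
    number of outliers is the largest i with R_i > lambda_i.  Missing
    values are ignored; a zero SD at any step stops the search; fewer than
    three values yield no flags.
    """
    if not (0.0 < max_frac < 1.0):
        raise ConfigError(f"max_frac must lie in (0, 1), got {max_frac}")
    if not (0.0 < alpha < 1.0):
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    x = np.asarray(values, dtype=float)
    live = np.flatnonzero(np.isfinite(x))
    n = live.size
    k = int(np.floor(max_frac * n))
    if n < 3 or k < 1:
        return np.array([], dtype=int)

    removed: list[int] = []
    stat_exceeds: list[bool] = []
    for i in range(1, k + 1):
        vals = x[live]
        sd = vals.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(vals - vals.mean())
        j = int(np.argmax(dev))
        r_i = dev[j] / sd
        n_i = n - i + 1
        t = stats.t.ppf(1.0 - alpha / (2.0 * n_i), n_i - 2)
        lam_i = (n_i - 1) * t / np.sqrt((n_i - 2 + t**2) * n_i)
        removed.append(int(live[j]))
        stat_exceeds.append(bool(r_i > lam_i))
        live = np.delete(live, j)

    n_out = 0
    for i, exceeded in enumerate(stat_exceeds, start=1):
        if exceeded:
            n_out = i
    return np.sort(np.array(removed[:n_out], dtype=int))


def log_transform(x):
    """log10(x + 1); zero maps to zero, missing propagates, x < 0 is a domain error."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ConfigError("log_transform requires non-negative values")
    out = np.log10(arr + 1.0)
    return float(out) if np.isscalar(x) else out


def screen_columns(
    df: pd.DataFrame,
    columns: list[str],
    group_col: str | None = "treatment",
    alpha: float = 0.05,
    max_frac: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GESD-screen wide-format columns, per group unless ``group_col`` is None.

    Returns (screened copy with outliers set to NaN, outlier report with
    variable, fish_id/group, original value).
    """
    out = df.copy()
    report = []
    group_iter = [(None, df)] if group_col is None else df.groupby(group_col, sort=False)
    for gname, sub in group_iter:
        for col in columns:
            flagged = gesd_flag(sub[col].to_numpy(), alpha=alpha, max_frac=max_frac)
            for pos in flagged:
                row = sub.iloc[pos]
                out.loc[row.name, col] = np.nan
                report.append(
                    {
                        "variable": col,
                        "group": gname,
                        "fish_id": row.get("fish_id", row.name),
                        "value": sub[col].iloc[pos],
                    }
                )
    return out, pd.DataFrame(report, columns=["variable", "group", "fish_id", "value"])


def screen_long(
    expr: pd.DataFrame,
    value_col: str = "relative_expression",
    cell_cols: tuple[str, ...] = ("gene", "region", "treatment"),
    alpha: float = 0.05,
    max_frac: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GESD-screen a long table within each (gene, region, treatment) cell."""
    out = expr.copy()
    report = []
    for key, sub in expr.groupby(list(cell_cols), sort=False):
        flagged = gesd_flag(sub[value_col].to_numpy(), alpha=alpha, max_frac=max_frac)
        for pos in flagged:
            row = sub.iloc[pos]
            out.loc[row.name, value_col] = np.nan
            report.append(
                {
                    "variable": "/".join(map(str, key)),
                    "group": key[-1],
                    "fish_id": row.get("fish_id", row.name),
                    "value": sub[value_col].iloc[pos],
                }
            )
    return out, pd.DataFrame(report, columns=["variable", "group", "fish_id", "value"])
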