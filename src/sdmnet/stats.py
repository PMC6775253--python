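"""Treatment comparisons: omnibus F, pairwise post hocs, FDR, effect sizes.

With a single observation per fish for each response, the treatment
comparison reduces to a one-way fixed-effects analysis: an omnibus F-test
followed by pairwise two-sample t-tests, Benjamini-Hochberg adjustment
within each family of comparisons, and Cohen's d effect sizes.  Hormone
responses are analysed as within-fish deltas (post minus baseline).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import STEROIDS, ConfigError

__all__ = [
    "ComparisonResult",
    "PairwiseResult",
    "omnibus_treatment_test",
    "pairwise_posthoc",
    "bh_adjust",
    "cohens_d",
    "compare_groups",
    "hormone_deltas",
    "hormone_deltas_and_tests",
    "correlation_report",
]


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    t: float
    p_raw: float
    p_adj: float
    d: float


@dataclass
class ComparisonResult:
    variable: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)


def _groups(values, treatments) -> dict[str, np.ndarray]:
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "treatment": np.asarray(treatments)})
    df = df.dropna(subset=["value"])
    return {t: g["value"].to_numpy() for t, g in df.groupby("treatment", sort=False)}


def omnibus_treatment_test(values, treatments) -> tuple[float, float]:
    """One-way fixed-effects F-test of a treatment difference.

    Zero between-group variance gives (0, 1) by convention, even when the
    within-group variance is also zero.
    """
    groups = _groups(values, treatments)
    if len(groups) < 2 or any(len(g) < 2 for g in groups.values()):
        raise ConfigError("need >= 2 groups with >= 2 non-missing values each")
    F, p = stats.f_oneway(*groups.values())
    if not np.isfinite(F):  # degenerate: no variance anywhere
        F, p = 0.0, 1.0
    return float(F), float(p)


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("each group needs >= 2 values")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ConfigError("zero pooled SD: effect size undefined")
    return float((a.mean() - b.mean()) / pooled)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ConfigError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def pairwise_posthoc(values, treatments, welch: bool = False) -> list[PairwiseResult]:
    """Pairwise two-sample t-tests with BH adjustment and Cohen's d.

    The three (or C(k,2)) pairwise p-values form one adjustment family.
    Pooled-variance t by default; Welch via ``welch=True``.  The tabled d
    is the absolute standardized difference.
    """
    groups = _groups(values, treatments)
    pairs = list(itertools.combinations(groups.keys(), 2))
    results = []
    for a_name, b_name in pairs:
        a, b = groups[a_name], groups[b_name]
        if len(a) < 2 or len(b) < 2:
            raise ConfigError(f"pair {(a_name, b_name)}: each group needs >= 2 values")
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        if not np.isfinite(t):  # identical constant groups
            t, p = 0.0, 1.0
        try:
            d = abs(cohens_d(a, b))
        except ConfigError:
            d = 0.0 if np.isclose(a.mean(), b.mean()) else float("nan")
        results.append(PairwiseResult((a_name, b_name), float(t), float(p), float("nan"), d))
    adj = bh_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
    return results


def compare_groups(values, treatments, variable: str = "", welch: bool = False) -> ComparisonResult:
    """Omnibus + pairwise post hoc comparison for one response variable."""
    F, p = omnibus_treatment_test(values, treatments)
    return ComparisonResult(variable, F, p, pairwise_posthoc(values, treatments, welch=welch))


def hormone_deltas(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-fish steroid response: post minus baseline.

    Fish missing either measurement are excluded (delta left missing).
    Input columns: fish_id, treatment, steroid, baseline, post.
    """
    required = {"fish_id", "treatment", "steroid", "baseline", "post"}
    if missing := required - set(panel.columns):
        raise ConfigError(f"hormone panel missing columns: {sorted(missing)}")
    out = panel.copy()
    out["delta"] = out["post"] - out["baseline"]
    return out[["fish_id", "treatment", "steroid", "delta"]]


def hormone_deltas_and_tests(panel: pd.DataFrame, welch: bool = False) -> dict[str, ComparisonResult]:
    """Unpaired treatment comparisons of the androgen deltas, per steroid."""
    deltas = hormone_deltas(panel)
    present = set(deltas["steroid"].unique())
    ordered = [s for s in STEROIDS if s in present] + sorted(present - set(STEROIDS))
    results = {}
    for steroid in ordered:
        sub = deltas[deltas["steroid"] == steroid]
        results[steroid] = compare_groups(
            sub["delta"], sub["treatment"], variable=f"delta_{steroid}", welch=welch
        )
    return results


def correlation_report(variables: dict[str, pd.Series]) -> pd.DataFrame:
    """Pairwise Pearson correlations (r, p, n) over named per-fish series.

    Series are aligned on their index (fish); each pair uses its complete
    cases.  Used for the gnrh1 / IEG / androgen association checks.
    """
    names = list(variables)
    df = pd.DataFrame(variables)
    rows = []
    for a, b in itertools.combinations(names, 2):
        sub = df[[a, b]].dropna()
        n = len(sub)
        if n < 3:
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(sub[a], sub[b])
        rows.append({"var_a": a, "var_b": b, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)
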