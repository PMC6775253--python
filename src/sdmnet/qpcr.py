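"""Efficiency-corrected qPCR quantification.

Relative expression of a target gene against the housekeeping reference is

    x = (1 + E_hk)^CT_hk / (1 + E_gene)^CT_gene

where CT is the mean of the triplicate cycle thresholds and E is the
per-gene amplification efficiency on the 0-1 scale (E = 1 is perfect
doubling).  Efficiency estimation from reaction kinetics is out of scope:
efficiencies are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import HK_GENE, ConfigError

__all__ = [
    "aggregate_replicates",
    "normalize_expression",
    "normalize_table",
    "reference_stability",
    "ReferenceStabilityReport",
]

QC_OK = "ok"
QC_HIGH_SD = "high_replicate_sd"
QC_MISSING = "missing"


def aggregate_replicates(replicate_cts, sd_threshold: float = 0.5) -> tuple[float, str]:
    """Mean CT over non-missing replicates, with a replicate-scatter QC flag.

    Returns ``(nan, "missing")`` when every replicate is missing, and flags
    ``high_replicate_sd`` when the replicate SD (ddof=1) exceeds
    ``sd_threshold`` cycles.
    """
    x = np.asarray(replicate_cts, dtype=float)
    ok = np.isfinite(x)
    if not ok.any():
        return float("nan"), QC_MISSING
    vals = x[ok]
    mean = float(vals.mean())
    if vals.size >= 2 and float(vals.std(ddof=1)) > sd_threshold:
        return mean, QC_HIGH_SD
    return mean, QC_OK


def normalize_expression(ct_gene: float, e_gene: float, ct_hk: float, e_hk: float) -> float:
    """Relative expression ``(1+e_hk)**ct_hk / (1+e_gene)**ct_gene``.

    Missing (non-finite) CTs propagate as NaN.  Efficiencies must lie in
    (0, 1]; values above 1 usually mean percent-scale input and are rejected.
    """
    for name, e in (("e_gene", e_gene), ("e_hk", e_hk)):
        if not (0.0 < e <= 1.0):
            raise ConfigError(f"{name} must lie in (0, 1], got {e}")
    if not (np.isfinite(ct_gene) and np.isfinite(ct_hk)):
        return float("nan")
    if ct_gene <= 0 or ct_hk <= 0:
        raise ConfigError("CT values must be positive")
    # evaluate in log space to dodge overflow at high CT
    return float(np.exp(ct_hk * np.log1p(e_hk) - ct_gene * np.log1p(e_gene)))


def normalize_table(qpcr: pd.DataFrame, sd_threshold: float = 0.5) -> pd.DataFrame:
    """Raw qPCR table -> tidy relative expression per fish x region x gene.

    Input columns: fish_id, treatment, region, gene, rep1..rep3, efficiency.
    Each target-gene reaction is normalised against the housekeeping
    reaction of the same fish x region sample.  A missing or QC-failing
    housekeeping reaction marks every target of that sample missing.
    """
    required = {"fish_id", "treatment", "region", "gene", "rep1", "rep2", "rep3", "efficiency"}
    if missing := required - set(qpcr.columns):
        raise ConfigError(f"qPCR table missing columns: {sorted(missing)}")

    agg = qpcr.copy()
    means, flags = zip(
        *(aggregate_replicates(row, sd_threshold) for row in agg[["rep1", "rep2", "rep3"]].to_numpy())
    )
    agg["mean_ct"] = means
    agg["qc_flag"] = flags

    hk = agg[agg["gene"] == HK_GENE].set_index(["fish_id", "region"])
    targets = agg[agg["gene"] != HK_GENE]
    rows = []
    for rec in targets.itertuples(index=False):
        key = (rec.fish_id, rec.region)
        flag = rec.qc_flag
        expr = float("nan")
        if key not in hk.index:
            flag = QC_MISSING
        else:
            h = hk.loc[key]
            if h["qc_flag"] == QC_MISSING or flag == QC_MISSING:
                flag = QC_MISSING
            else:
                expr = normalize_expression(rec.mean_ct, rec.efficiency, h["mean_ct"], h["efficiency"])
                if h["qc_flag"] == QC_HIGH_SD:
                    flag = QC_HIGH_SD
        rows.append(
            {
                "fish_id": rec.fish_id,
                "treatment": rec.treatment,
                "region": rec.region,
                "gene": rec.gene,
                "relative_expression": expr,
                "qc_flag": flag,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReferenceStabilityReport:
    F: float
    p: float
    group_means: dict[str, float]
    passed: bool  # reference gene suitable (no treatment difference)


def reference_stability(
    hk_values: pd.Series | np.ndarray,
    treatments: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> ReferenceStabilityReport:
    """One-way comparison of the housekeeping signal across treatments.

    The reference gene is suitable when its level does not differ between
    groups (p >= alpha).  Identical values everywhere give F = 0, p = 1 by
    convention.
    """
    df = pd.DataFrame({"value": np.asarray(hk_values, float), "treatment": np.asarray(treatments)})
    df = df.dropna()
    groups = [g["value"].to_numpy() for _, g in df.groupby("treatment")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ConfigError("need >= 2 groups with >= 2 values each")
    means = df.groupby("treatment")["value"].mean().to_dict()
    grand = df["value"].to_numpy()
    if np.ptp(grand) == 0 or all(np.ptp(g) == 0 for g in groups):
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*groups)
        if not np.isfinite(F):
            F, p = 0.0, 1.0
    return ReferenceStabilityReport(float(F), float(p), means, bool(p >= alpha))
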