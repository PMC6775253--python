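"""Synthetic cohort generator.

Emulates the three-treatment mirror-fight study: a design table of focal
fish, a raw qPCR table (triplicate cycle thresholds per fish x region x
gene, plus the housekeeping gene), a six-variable aggression ethogram
table, and a paired baseline/post androgen panel.  The statistical
structure the downstream analysis assumes is planted explicitly:
treatment-specific inter-region correlation of log IEG expression, a
treatment shift on the overt-aggression latent factor, and (by default)
no treatment effect on hormones.

Each generator operation draws from its own RNG stream derived from
``(master seed, operation name)``, so adding an operation never shifts
the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .config import (
    BEHAVIOR_VARIABLES,
    GENE_REGIONS,
    HK_GENE,
    STEROIDS,
    SimulationConfig,
    ConfigError,
)

__all__ = [
    "generate_design",
    "generate_expression",
    "generate_behavior",
    "generate_hormones",
    "generate_cohort",
]


def _rng(seed: int, operation: str) -> np.random.Generator:
    """Independent stream per (seed, operation name)."""
    key = zlib.crc32(operation.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def generate_design(group_sizes: dict[str, int], seed: int = 0) -> pd.DataFrame:
    """One row per focal fish: fish_id, treatment.

    Fish ids are assigned deterministically in treatment order; the seed is
    accepted for interface symmetry (the design itself is non-random).
    """
    for t, n in group_sizes.items():
        if n < 2:
            raise ConfigError(f"group {t!r}: need at least 2 fish, got {n}")
    rows = []
    i = 1
    for treatment, n in group_sizes.items():
        for _ in range(n):
            rows.append({"fish_id": f"fish{i:03d}", "treatment": treatment})
            i += 1
    return pd.DataFrame(rows)


def _log_expression_draws(
    design: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Latent per-fish log10 relative expression, long format."""
    rows = []
    for treatment, sub in design.groupby("treatment", sort=False):
        for gene in config.gene_names:
            regions = GENE_REGIONS.get(gene, config.region_names)
            mu = config.mean_log(treatment, gene)
            if len(regions) > 1:
                key = (treatment, gene)
                if key not in config.target_correlation:
                    raise ConfigError(f"no target correlation configured for {key}")
                R = np.asarray(config.target_correlation[key], dtype=float)
                cov = R * config.expression_sd**2
                draws = rng.multivariate_normal(
                    np.full(len(regions), mu), cov, size=len(sub), method="cholesky"
                )
            else:
                draws = rng.normal(mu, config.expression_sd, size=(len(sub), 1))
            for (fish, _), vals in zip(sub.itertuples(index=False), draws):
                for region, v in zip(regions, vals):
                    rows.append(
                        {
                            "fish_id": fish,
                            "treatment": treatment,
                            "region": region,
                            "gene": gene,
                            "log10_expression": v,
                        }
                    )
    return pd.DataFrame(rows)


def generate_expression(
    design: pd.DataFrame, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Raw qPCR table: triplicate CTs per fish x region x gene (+ housekeeping).

    Region-level log10 expression is drawn from a multivariate normal with
    the planted treatment-specific correlation matrix, then converted to a
    target-gene CT by inverting the efficiency-corrected normalisation ratio

        x = (1 + E_hk)^CT_hk / (1 + E_gene)^CT_gene

    against an independent housekeeping CT draw for the same sample.
    Triplicate replicates add ``ct_replicate_sd`` cycles of noise.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "expression")
    latent = _log_expression_draws(design, config, rng)

    e_hk = config.efficiencies[HK_GENE]
    log1p_hk = np.log(1.0 + e_hk)
    rows = []
    # one housekeeping reaction per fish x region sample
    samples = latent[["fish_id", "treatment", "region"]].drop_duplicates()
    hk_ct = {}
    for fish, treatment, region in samples.itertuples(index=False):
        ct = rng.normal(config.hk_mean_ct, config.hk_ct_sd)
        hk_ct[(fish, region)] = ct
        reps = ct + rng.normal(0.0, config.ct_replicate_sd, size=3) if config.ct_replicate_sd > 0 else np.full(3, ct)
        rows.append(
            {
                "fish_id": fish,
                "treatment": treatment,
                "region": region,
                "gene": HK_GENE,
                "rep1": reps[0],
                "rep2": reps[1],
                "rep3": reps[2],
                "efficiency": e_hk,
            }
        )
    for fish, treatment, region, gene, logx in latent[
        ["fish_id", "treatment", "region", "gene", "log10_expression"]
    ].itertuples(index=False):
        e_gene = config.efficiencies[gene]
        # invert x = (1+E_hk)^CT_hk / (1+E_gene)^CT_gene with x = 10^logx
        ct_gene = (hk_ct[(fish, region)] * log1p_hk - logx * np.log(10.0)) / np.log(1.0 + e_gene)
        reps = (
            ct_gene + rng.normal(0.0, config.ct_replicate_sd, size=3)
            if config.ct_replicate_sd > 0
            else np.full(3, ct_gene)
        )
        rows.append(
            {
                "fish_id": fish,
                "treatment": treatment,
                "region": region,
                "gene": gene,
                "rep1": reps[0],
                "rep2": reps[1],
                "rep3": reps[2],
                "efficiency": e_gene,
            }
        )
    out = pd.DataFrame(rows)
    if not np.all(np.isfinite(out[["rep1", "rep2", "rep3"]])) or (out[["rep1", "rep2", "rep3"]] <= 0).any().any():
        raise ConfigError("generated CT values must be finite and positive; check hk_mean_ct / expression scale")
    return out.sort_values(["fish_id", "region", "gene"], kind="stable").reset_index(drop=True)


def generate_behavior(
    design: pd.DataFrame, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Six-variable aggression table from a two-latent-factor model.

    Latent factor 1 (overt aggression) is shifted by the configured
    treatment effect; observed z-scores are ``loadings @ factors`` plus
    residual noise with variance ``1 - communality``, then mapped to raw
    counts (truncated at zero) and latencies (clipped to the trial
    duration, which doubles as the censoring value for fish that never
    performed the behaviour).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "behavior")
    L = np.asarray(config.behavior_loading_matrix, dtype=float)
    resid_var = np.clip(1.0 - (L**2).sum(axis=1), 0.0, None)

    n = len(design)
    factors = rng.standard_normal((n, 2))
    shifts = design["treatment"].map(config.behavior_effects).to_numpy(dtype=float)
    factors[:, 0] += shifts
    z = factors @ L.T + rng.standard_normal((n, len(BEHAVIOR_VARIABLES))) * np.sqrt(resid_var)

    out = design.copy()
    means = np.asarray(config.behavior_means)
    scales = np.asarray(config.behavior_scales)
    raw = means + scales * z
    for j, var in enumerate(BEHAVIOR_VARIABLES):
        col = raw[:, j]
        if var.startswith("freq"):
            out[var] = np.round(np.clip(col, 0.0, None), 1)
        else:
            out[var] = np.round(np.clip(col, 1.0, config.trial_duration), 1)
    return out


def generate_hormones(
    design: pd.DataFrame, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Paired baseline/post androgen panel (T and 11-KT, ng/ml scale).

    A per-fish random effect makes baseline and post levels consistent
    within individuals; the treatment effect on the post level is zero
    under the default (null) configuration.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "hormones")
    rows = []
    for fish, treatment in design[["fish_id", "treatment"]].itertuples(index=False):
        for steroid in STEROIDS:
            mu = config.hormone_means[steroid]
            fish_eff = rng.normal(0.0, config.hormone_fish_sd[steroid])
            base = mu + fish_eff + rng.normal(0.0, config.hormone_sd[steroid])
            post = (
                mu
                + config.hormone_effects[steroid][treatment]
                + fish_eff
                + rng.normal(0.0, config.hormone_sd[steroid])
            )
            rows.append(
                {
                    "fish_id": fish,
                    "treatment": treatment,
                    "steroid": steroid,
                    "baseline": max(base, 0.01),
                    "post": max(post, 0.01),
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Full synthetic cohort: design, qpcr, behavior and hormone tables."""
    config.validate()
    seed = config.seed if seed is None else seed
    design = generate_design(config.group_sizes, seed)
    return {
        "design": design,
        "qpcr": generate_expression(design, config, seed),
        "behavior": generate_behavior(design, config, seed),
        "hormones": generate_hormones(design, config, seed),
    }
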