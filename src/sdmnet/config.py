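"""Study design constants and configuration objects.

The experimental design modelled throughout the package: territorial male
cichlids fight their mirror image for 15 min, after which the last two
minutes present either the mirror again (MM), a just-won dominant male (MD)
or a just-lost subordinate male (MS).  Immediate-early-gene (IEG) expression
is then measured by qPCR in five nuclei of the social decision-making
network (SDMN), aggression is scored from video, and circulating androgens
are assayed before and after the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

TREATMENTS: tuple[str, ...] = ("MM", "MD", "MS")
REGIONS: tuple[str, ...] = ("VVm", "Vs", "PPa", "TA", "GC")
IEG_GENES: tuple[str, ...] = ("c-fos", "egr-1")
TARGET_GENES: tuple[str, ...] = ("c-fos", "egr-1", "gnrh1")
HK_GENE: str = "eef1A"
STEROIDS: tuple[str, ...] = ("T", "KT")

#: Regions in which each target gene is assayed.  The IEGs are activity
#: reporters measured across the whole SDMN; gnrh1 is only meaningful in the
#: preoptic area where the GnRH1 neurons sit.
GENE_REGIONS: dict[str, tuple[str, ...]] = {
    "c-fos": REGIONS,
    "egr-1": REGIONS,
    "gnrh1": ("PPa",),
}

BEHAVIOR_VARIABLES: tuple[str, ...] = (
    "freq_displays",
    "freq_bites",
    "freq_attacks",
    "lat_display",
    "lat_bite",
    "lat_attack",
)

#: Published two-component loading pattern for the six aggression variables
#: (rows follow BEHAVIOR_VARIABLES; columns are PC1 "overt aggression" and
#: PC2, whose reflection reads as "aggressive motivation").  Used both as the
#: default planted factor structure of the behaviour simulator and as the
#: reference input for the eigenvalue-from-loadings consistency check.
REFERENCE_LOADINGS: np.ndarray = np.array(
    [
        [0.793, -0.443],
        [0.915, -0.161],
        [0.923, 0.122],
        [-0.595, 0.717],
        [-0.887, -0.293],
        [-0.896, -0.287],
    ]
)

# Planted two-factor loadings (rows follow REGIONS) defining the default
# inter-region correlation matrix of log-expression for each treatment and
# IEG.  Chosen so the implied valued network densities and the qualitative
# centrality contrasts (e.g. TA-central / PPa-peripheral egr-1 network under
# MM, the reverse under MD/MS, densest egr-1 network under MS) match the
# published network summary, while keeping every matrix positive definite by
# construction (unit diagonal, row norms < 1).
_NETWORK_FACTORS: dict[tuple[str, str], list[list[float]]] = {
    ("MM", "c-fos"): [[0.795, 0.159], [0.583, -0.371], [0.700, 0.212], [0.827, -0.159], [0.880, 0.106]],
    ("MD", "c-fos"): [[0.737, 0.297], [0.749, -0.356], [0.832, 0.178], [0.499, -0.416], [0.297, 0.535]],
    ("MS", "c-fos"): [[0.671, -0.216], [0.757, 0.270], [0.692, 0.162], [0.714, -0.270], [0.866, 0.108]],
    ("MM", "egr-1"): [[0.558, 0.215], [0.408, -0.322], [0.161, 0.376], [0.773, -0.215], [0.644, 0.161]],
    ("MD", "egr-1"): [[0.328, 0.351], [0.773, -0.234], [0.867, 0.176], [0.586, -0.351], [0.679, 0.234]],
    ("MS", "egr-1"): [[0.751, 0.161], [0.665, -0.268], [0.816, 0.215], [0.687, -0.215], [0.837, 0.107]],
}


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


def factor_correlation(loadings: np.ndarray) -> np.ndarray:
    """Correlation matrix implied by a factor model.

    ``R = L L' + diag(1 - ||l_i||^2)`` — unit diagonal and positive
    semidefinite whenever every row norm is at most 1.
    """
    L = np.asarray(loadings, dtype=float)
    norms = (L**2).sum(axis=1)
    if np.any(norms > 1.0 + 1e-12):
        raise ConfigError("factor loading row norms must be <= 1")
    R = L @ L.T
    np.fill_diagonal(R, 1.0)
    return R


def default_network_targets() -> dict[tuple[str, str], np.ndarray]:
    """Default planted inter-region correlation matrix per (treatment, IEG)."""
    return {key: factor_correlation(np.array(L)) for key, L in _NETWORK_FACTORS.items()}


def validate_correlation_target(R: np.ndarray, name: str = "target_correlation") -> None:
    R = np.asarray(R, dtype=float)
    if R.shape != (len(REGIONS), len(REGIONS)):
        raise ConfigError(f"{name}: expected a {len(REGIONS)}x{len(REGIONS)} matrix, got {R.shape}")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ConfigError(f"{name}: matrix is not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ConfigError(f"{name}: diagonal must be 1")
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ConfigError(f"{name}: matrix is not positive semidefinite")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Expression is simulated as log10 relative expression (multivariate normal
    across regions with the planted treatment-specific correlation), then
    converted to cycle thresholds by inverting the efficiency-corrected
    normalisation ratio against a housekeeping draw.  Behaviour comes from a
    two-latent-factor model with the published loading pattern; hormones are
    paired baseline/post draws with a configurable (default null) treatment
    effect on the post-fight level.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {"MM": 8, "MD": 6, "MS": 6})
    region_names: tuple[str, ...] = REGIONS
    gene_names: tuple[str, ...] = TARGET_GENES
    target_correlation: dict[tuple[str, str], np.ndarray] = field(default_factory=default_network_targets)
    # mean log10 relative expression; per (treatment, gene) overrides allowed
    mean_log_expression: float | Mapping[tuple[str, str], float] = 1.2
    expression_sd: float = 0.3
    ct_replicate_sd: float = 0.15
    efficiencies: dict[str, float] = field(
        default_factory=lambda: {"c-fos": 0.92, "egr-1": 0.90, "gnrh1": 0.88, HK_GENE: 0.95}
    )
    hk_mean_ct: float = 20.0
    hk_ct_sd: float = 0.25
    # shift (in latent-factor SD units) applied to the overt-aggression factor
    behavior_effects: dict[str, float] = field(default_factory=lambda: {"MM": 0.0, "MD": 0.0, "MS": -1.5})
    behavior_loading_matrix: np.ndarray = field(default_factory=lambda: REFERENCE_LOADINGS.copy())
    # raw-scale location/scale for the six behaviour variables
    behavior_means: tuple[float, ...] = (25.0, 40.0, 30.0, 60.0, 120.0, 150.0)
    behavior_scales: tuple[float, ...] = (10.0, 18.0, 14.0, 80.0, 120.0, 140.0)
    trial_duration: float = 900.0  # seconds; censoring value for latencies
    # hormone model: ng/ml-scale means and SDs, per-fish consistency, and an
    # additive treatment effect on the post-fight level (default null)
    hormone_means: dict[str, float] = field(default_factory=lambda: {"T": 2.5, "KT": 5.0})
    hormone_sd: dict[str, float] = field(default_factory=lambda: {"T": 0.8, "KT": 1.5})
    hormone_fish_sd: dict[str, float] = field(default_factory=lambda: {"T": 0.6, "KT": 1.0})
    hormone_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: {t: 0.0 for t in TREATMENTS} for s in STEROIDS}
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ConfigError("group_sizes is empty")
        for t, n in self.group_sizes.items():
            if n < 2:
                raise ConfigError(f"group {t!r}: need at least 2 fish, got {n}")
        for key, R in self.target_correlation.items():
            validate_correlation_target(np.asarray(R), name=f"target_correlation[{key}]")
        for gene, e in self.efficiencies.items():
            if not (0.0 < e <= 1.0):
                raise ConfigError(f"efficiency for {gene!r} must lie in (0, 1], got {e}")
        if self.expression_sd <= 0:
            raise ConfigError("expression_sd must be > 0")
        if self.ct_replicate_sd < 0:
            raise ConfigError("ct_replicate_sd must be >= 0")
        L = np.asarray(self.behavior_loading_matrix)
        if L.shape != (len(BEHAVIOR_VARIABLES), 2):
            raise ConfigError(f"behavior_loading_matrix must be {len(BEHAVIOR_VARIABLES)}x2, got {L.shape}")
        if self.trial_duration <= 0:
            raise ConfigError("trial_duration must be > 0")

    def mean_log(self, treatment: str, gene: str) -> float:
        if isinstance(self.mean_log_expression, Mapping):
            return float(self.mean_log_expression[(treatment, gene)])
        return float(self.mean_log_expression)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``simulate`` is set (synthetic cohort, written to ``outdir``) or
    all four input paths point at existing CSV files.
    """

    outdir: Path = Path("sdmnet_run")
    simulate: SimulationConfig | None = None
    qpcr_path: Path | None = None
    behavior_path: Path | None = None
    hormone_path: Path | None = None
    design_path: Path | None = None
    seed: int = 0
    alpha: float = 0.05
    sd_threshold: float = 0.5  # qPCR replicate-SD QC threshold, cycles
    esd_alpha: float = 0.05
    esd_max_frac: float = 0.2
    esd_pooled: bool = False  # outlier screening per treatment by default
    n_perm: int = 5000
    n_boot: int = 5000
    density_mode: str = "valued"  # "valued" (mean |r|) or "binary"
    edge_alpha: float = 0.01  # adjusted-p threshold for significant edges
    welch: bool = False

    def validate(self) -> None:
        if self.n_perm < 1 or self.n_boot < 1:
            raise ConfigError("n_perm and n_boot must be >= 1")
        if self.density_mode not in ("valued", "binary"):
            raise ConfigError(f"unknown density_mode {self.density_mode!r}")
        if self.simulate is None:
            missing = [
                str(p)
                for p in (self.qpcr_path, self.behavior_path, self.hormone_path, self.design_path)
                if p is None or not Path(p).exists()
            ]
            if missing:
                raise ConfigError(f"input files missing or not set: {missing}")
        else:
            self.simulate.validate()


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file.

    A ``simulate:`` block (possibly empty) selects synthetic mode and may
    override scalar generator parameters; otherwise ``inputs:`` must give the
    four CSV paths.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    if "simulate" in raw:
        sim = SimulationConfig()
        for key, val in (raw["simulate"] or {}).items():
            if not hasattr(sim, key):
                raise ConfigError(f"unknown simulate option {key!r}")
            setattr(sim, key, val)
        cfg.simulate = sim
    for key, val in (raw.get("inputs") or {}).items():
        attr = f"{key}_path"
        if not hasattr(cfg, attr):
            raise ConfigError(f"unknown input {key!r}")
        setattr(cfg, attr, Path(val))
    for key, val in raw.items():
        if key in ("simulate", "inputs"):
            continue
        if not hasattr(cfg, attr := key):
            raise ConfigError(f"unknown option {key!r}")
        setattr(cfg, attr, Path(val) if attr == "outdir" else val)
    cfg.validate()
    return cfg
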