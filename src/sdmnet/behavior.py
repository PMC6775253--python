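"""Principal-component reduction of the six aggression variables.

The ethogram yields frequencies and latencies of displays, bites and
attacks.  A PCA of their correlation matrix (loadings scaled by the
square root of the eigenvalue, the SPSS output convention) reduces them
to two components: PC1, with high positive loadings of bite and attack
frequency, reads as "overt aggression"; the reflection of PC2, dominated
by latency to display, reads as "aggressive motivation".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BEHAVIOR_VARIABLES, ConfigError

__all__ = [
    "ComponentModel",
    "fit_pca",
    "component_scores",
    "orient_components",
    "eigenvalues_from_loadings",
    "loading_table",
]


@dataclass
class ComponentModel:
    variable_names: tuple[str, ...]
    loadings: np.ndarray  # p x 2, eigenvector * sqrt(eigenvalue)
    eigenvalues: np.ndarray  # first two
    pct_variance: np.ndarray  # first two, percent of p
    scores: pd.DataFrame  # per-fish PC1/PC2, unit variance
    means: np.ndarray = field(repr=False, default=None)
    sds: np.ndarray = field(repr=False, default=None)
    all_eigenvalues: np.ndarray = field(repr=False, default=None)

    @property
    def pct_variance_total(self) -> float:
        return float(self.pct_variance.sum())


def eigenvalues_from_loadings(loadings: np.ndarray) -> np.ndarray:
    """Eigenvalue of each component from its loading column.

    With loadings defined as eigenvector * sqrt(eigenvalue), the column sum
    of squared loadings recovers the eigenvalue; dividing by the number of
    variables gives the fraction of variance explained.
    """
    L = np.asarray(loadings, dtype=float)
    return (L**2).sum(axis=0)


def fit_pca(behavior: pd.DataFrame, variables: tuple[str, ...] = BEHAVIOR_VARIABLES) -> ComponentModel:
    """Correlation-matrix PCA of the (transformed) behaviour variables.

    Rows with any missing variable are dropped (listwise).  Loadings are
    eigenvector * sqrt(eigenvalue); per-fish scores are projections of the
    standardized data scaled to unit variance.  The fitted model is
    oriented by :func:`orient_components`.
    """
    missing = [v for v in variables if v not in behavior.columns]
    if missing:
        raise ConfigError(f"behavior table missing variables: {missing}")
    complete = behavior.dropna(subset=list(variables))
    X = complete[list(variables)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ConfigError(f"need >= 3 complete rows, got {X.shape[0]}")
    sds = X.std(axis=0, ddof=1)
    for v, s in zip(variables, sds):
        if s == 0:
            raise ConfigError(f"variable {v!r} is constant; cannot standardize")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    R = np.corrcoef(X, rowvar=False)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    loadings = V[:, :2] * np.sqrt(w[:2])
    scale = np.sqrt(np.clip(w[:2], 0.0, None))
    scores = np.where(scale > 1e-12, (Z @ V[:, :2]) / np.where(scale > 1e-12, scale, 1.0), 0.0)
    score_df = pd.DataFrame(scores, columns=["PC1", "PC2"], index=complete.index)
    if "fish_id" in complete.columns:
        score_df.insert(0, "fish_id", complete["fish_id"].to_numpy())
    if "treatment" in complete.columns:
        score_df.insert(1, "treatment", complete["treatment"].to_numpy())
    model = ComponentModel(
        variable_names=tuple(variables),
        loadings=loadings,
        eigenvalues=w[:2].copy(),
        pct_variance=w[:2] / len(variables) * 100.0,
        scores=score_df,
        means=means,
        sds=sds,
        all_eigenvalues=w.copy(),
    )
    return orient_components(model)


def orient_components(model: ComponentModel, anchor_pc1: str = "freq_attacks", anchor_pc2: str = "lat_display") -> ComponentModel:
    """Fix the arbitrary eigenvector signs with a deterministic convention.

    PC1 is oriented so the attack-frequency loading is positive (high score
    = overt aggression); PC2 so the latency-to-display loading is positive
    (its reflection is then the "aggressive motivation" reading).  Applying
    the convention twice is a no-op.
    """
    names = list(model.variable_names)
    L = model.loadings.copy()
    S = model.scores.copy()
    for col, anchor in ((0, anchor_pc1), (1, anchor_pc2)):
        if anchor in names and L[names.index(anchor), col] < 0:
            L[:, col] = -L[:, col]
            S[f"PC{col + 1}"] = -S[f"PC{col + 1}"]
    model.loadings = L
    model.scores = S
    return model


def component_scores(model: ComponentModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Score new rows on the fitted components.

    Rows are standardized with the training means/SDs and projected onto
    the component directions; any missing variable yields missing scores.
    """
    X = rows[list(model.variable_names)].to_numpy(dtype=float)
    Z = (X - model.means) / model.sds
    ev = np.where(model.eigenvalues > 1e-12, model.eigenvalues, np.inf)
    directions = model.loadings / ev  # eigenvector / sqrt(eigenvalue); degenerate axis scores 0
    scores = Z @ directions
    scores[~np.isfinite(Z).all(axis=1)] = np.nan
    return pd.DataFrame(scores, columns=["PC1", "PC2"], index=rows.index)


def loading_table(model: ComponentModel) -> pd.DataFrame:
    """Loadings, eigenvalues and percent variance in report shape."""
    rows = [
        {"variable": v, "PC1": model.loadings[i, 0], "PC2": model.loadings[i, 1]}
        for i, v in enumerate(model.variable_names)
    ]
    rows.append({"variable": "eigenvalue", "PC1": model.eigenvalues[0], "PC2": model.eigenvalues[1]})
    rows.append(
        {"variable": "pct_variance", "PC1": model.pct_variance[0], "PC2": model.pct_variance[1]}
    )
    return pd.DataFrame(rows)
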