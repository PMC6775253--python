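"""Functional-connectivity networks over the SDMN nuclei.

Functional connectivity is the Pearson correlation of (log) IEG
expression between two brain regions across the fish of one treatment.
The resulting 5x5 matrices are compared between treatments with a
quadratic assignment procedure (QAP) — a permutation test that relabels
the nodes of one matrix — and summarised as valued networks: density
(mean absolute tie strength), a bootstrap t-test for density
differences, and eigenvector centrality of the |r| weight matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import REGIONS, ConfigError
from .stats import bh_adjust

__all__ = [
    "ConnectivityMatrix",
    "QapResult",
    "BootstrapDensityResult",
    "build_connectivity",
    "qap_association",
    "network_density",
    "bootstrap_density_compare",
    "eigenvector_centrality",
    "export_network",
]


@dataclass
class ConnectivityMatrix:
    treatment: str
    gene: str
    regions: tuple[str, ...]
    r: np.ndarray  # symmetric, unit diagonal
    p_raw: np.ndarray
    p_adj: np.ndarray  # BH over the 10 upper-triangle cells
    n_pairs: np.ndarray
    notes: list[str] = field(default_factory=list)


@dataclass
class QapResult:
    r_obs: float
    p: float
    n_perm: int
    seed: int
    tail: str


@dataclass
class BootstrapDensityResult:
    density_a: float
    density_b: float
    t: float
    p: float
    n_boot: int
    seed: int
    n_redrawn: int


def _check_square_symmetric(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ConfigError(f"{name} must be square, got {M.shape}")
    if M.shape[0] < 3:
        raise ConfigError(f"{name} must be at least 3x3")
    finite = np.isfinite(M) & np.isfinite(M.T)
    if not np.allclose(M[finite & finite.T], M.T[finite & finite.T], atol=1e-10):
        raise ConfigError(f"{name} is not symmetric")
    return M


def build_connectivity(
    expression: pd.DataFrame,
    treatment: str,
    gene: str,
    value_col: str = "value",
    regions: tuple[str, ...] = REGIONS,
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of expression across regions, one treatment.

    ``expression`` is long format (fish_id, treatment, region, gene, value).
    Each region pair uses its pairwise-complete fish; cells with fewer than
    three complete pairs are left missing and logged.  The 10 upper-triangle
    p-values form one BH adjustment family.
    """
    sub = expression[(expression["treatment"] == treatment) & (expression["gene"] == gene)]
    wide = sub.pivot_table(index="fish_id", columns="region", values=value_col, aggfunc="first")
    for reg in regions:
        if reg not in wide.columns:
            wide[reg] = np.nan
    X = wide[list(regions)].to_numpy(dtype=float)
    k = len(regions)
    r = np.eye(k)
    p = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    np.fill_diagonal(n_pairs, np.isfinite(X).sum(axis=0))
    notes = []
    for i, j in itertools.combinations(range(k), 2):
        ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
        n = int(ok.sum())
        n_pairs[i, j] = n_pairs[j, i] = n
        if n < 3:
            r[i, j] = r[j, i] = np.nan
            notes.append(f"{regions[i]}-{regions[j]}: only {n} complete pairs, cell left missing")
            continue
        if np.ptp(X[ok, i]) == 0 or np.ptp(X[ok, j]) == 0:
            r[i, j] = r[j, i] = np.nan
            notes.append(f"{regions[i]}-{regions[j]}: zero variance, cell left missing")
            continue
        rij, pij = sps.pearsonr(X[ok, i], X[ok, j])
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij
    iu = np.triu_indices(k, 1)
    p_adj = np.full((k, k), np.nan)
    p_adj[iu] = bh_adjust(p[iu])
    p_adj.T[iu] = p_adj[iu]
    return ConnectivityMatrix(treatment, gene, tuple(regions), r, p, p_adj, n_pairs, notes)


def _offdiag_vectors(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple]:
    iu = np.triu_indices(A.shape[0], 1)
    return A[iu], B[iu], iu


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        return float("nan")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def qap_association(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    tail: str = "two",
) -> QapResult:
    """QAP permutation test of association between two connectivity matrices.

    The observed statistic is the Pearson correlation of the corresponding
    off-diagonal upper-triangle entries.  The null distribution relabels
    the nodes of B (simultaneous row+column permutation) ``n_perm`` times;
    p = (#extreme + 1) / (n_perm + 1), two-tailed by default, so p is never
    exactly zero.  The standard null is no association between matrices: a
    non-significant p reads as distinct connectivity patterns.
    """
    A = _check_square_symmetric(A, "A")
    B = _check_square_symmetric(B, "B")
    if A.shape != B.shape:
        raise ConfigError(f"matrix sizes differ: {A.shape} vs {B.shape}")
    if tail not in ("two", "greater", "less"):
        raise ConfigError(f"unknown tail {tail!r}")
    a, b, iu = _offdiag_vectors(A, B)
    r_obs = _pearson(a, b)
    if not np.isfinite(r_obs):
        raise ConfigError("observed QAP correlation undefined (constant or too-sparse matrices)")

    rng = np.random.default_rng(seed)
    k = A.shape[0]
    perms = np.argsort(rng.random((n_perm, k)), axis=1)
    Bp = B[perms[:, :, None], perms[:, None, :]]  # (n_perm, k, k)
    bp = Bp[:, iu[0], iu[1]]  # (n_perm, m)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.all() and np.isfinite(bp).all():
        ac = a - a.mean()
        bc = bp - bp.mean(axis=1, keepdims=True)
        denom = np.sqrt((ac**2).sum() * (bc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r_perm = (bc @ ac) / denom
    else:
        r_perm = np.array([_pearson(a, row) for row in bp])
    r_perm = r_perm[np.isfinite(r_perm)]
    eps = 1e-12
    if tail == "two":
        extreme = np.abs(r_perm) >= np.abs(r_obs) - eps
    elif tail == "greater":
        extreme = r_perm >= r_obs - eps
    else:
        extreme = r_perm <= r_obs + eps
    p = (int(extreme.sum()) + 1) / (len(r_perm) + 1)
    return QapResult(r_obs, float(p), n_perm, seed, tail)


def network_density(
    matrix: ConnectivityMatrix | np.ndarray,
    mode: str = "valued",
    threshold: float = 0.05,
    use_abs: bool = True,
) -> float:
    """Network cohesion: the proportion of possible connection present.

    Valued mode (default) is the mean absolute tie strength |r| over the
    off-diagonal pairs — appropriate for fully-connected correlation
    networks, where negative co-activation still constitutes a connection.
    Binary mode is the fraction of pairs significant at adjusted
    p < ``threshold`` (requires a ConnectivityMatrix).
    """
    if mode not in ("valued", "binary"):
        raise ConfigError(f"unknown density mode {mode!r}")
    if isinstance(matrix, ConnectivityMatrix):
        r, p_adj = matrix.r, matrix.p_adj
    else:
        r = _check_square_symmetric(np.asarray(matrix, dtype=float), "matrix")
        p_adj = None
    iu = np.triu_indices(r.shape[0], 1)
    ties = r[iu]
    if mode == "binary":
        if p_adj is None:
            raise ConfigError("binary density needs a ConnectivityMatrix with adjusted p-values")
        sig = p_adj[iu] < threshold
        return float(np.mean(np.where(np.isfinite(p_adj[iu]), sig, False)))
    vals = np.abs(ties) if use_abs else ties
    if not np.isfinite(vals).any():
        raise ConfigError("all ties missing; density undefined")
    return float(np.nanmean(vals))


def _density_from_data(X: np.ndarray) -> float:
    """Valued density of the correlation matrix of a complete fish x region array."""
    R = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices(R.shape[0], 1)
    return float(np.abs(R[iu]).mean())


def _batch_densities(X: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """Valued densities of correlation matrices over bootstrap resamples.

    ``X`` is (n, k) with no missing values; ``draws`` is (B, n) row indices.
    Returns (B,) densities with NaN where a resample is degenerate.
    """
    Xb = X[draws]  # (B, n, k)
    Xc = Xb - Xb.mean(axis=1, keepdims=True)
    cov = np.einsum("bnk,bnl->bkl", Xc, Xc)
    sd = np.sqrt(np.einsum("bkk->bk", cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = cov / (sd[:, :, None] * sd[:, None, :])
    iu = np.triu_indices(X.shape[1], 1)
    return np.abs(R[:, iu[0], iu[1]]).mean(axis=1)


def bootstrap_density_compare(
    expr_a: pd.DataFrame | np.ndarray,
    expr_b: pd.DataFrame | np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
) -> BootstrapDensityResult:
    """Bootstrap t-test for a difference in valued network density.

    Inputs are fish x region expression arrays (or DataFrames), one per
    treatment.  Fish are resampled with replacement within each group,
    the correlation matrices rebuilt and their densities recomputed;
    t = (observed difference) / (bootstrap SE of the difference) and the
    two-tailed p comes from the centered bootstrap distribution with the
    (+1)/(n+1) correction.  Degenerate resamples (zero-variance column)
    are redrawn and counted.
    """
    Xa = np.asarray(expr_a if isinstance(expr_a, np.ndarray) else expr_a.to_numpy(), dtype=float)
    Xb = np.asarray(expr_b if isinstance(expr_b, np.ndarray) else expr_b.to_numpy(), dtype=float)
    for name, X in (("expr_a", Xa), ("expr_b", Xb)):
        if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 3:
            raise ConfigError(f"{name} must be (>=3 fish) x (>=3 regions)")
        if not np.isfinite(X).all():
            raise ConfigError(f"{name} contains missing values; complete cases required here")
    d_a, d_b = _density_from_data(Xa), _density_from_data(Xb)
    d_obs = d_a - d_b

    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    filled = 0
    redrawn = 0
    while filled < n_boot:
        want = n_boot - filled
        da = _batch_densities(Xa, rng.integers(0, Xa.shape[0], size=(want, Xa.shape[0])))
        db = _batch_densities(Xb, rng.integers(0, Xb.shape[0], size=(want, Xb.shape[0])))
        batch = da - db
        ok = np.isfinite(batch)
        redrawn += int((~ok).sum())
        take = batch[ok]
        diffs[filled : filled + len(take)] = take
        filled += len(take)
        if redrawn > 100 * n_boot:
            raise ConfigError("bootstrap cannot find non-degenerate resamples")
    se = diffs.std(ddof=1)
    if se == 0:
        t = 0.0 if d_obs == 0 else float("inf")
    else:
        t = d_obs / se
    centered = diffs - diffs.mean()
    p = (int((np.abs(centered) >= abs(d_obs) - 1e-12).sum()) + 1) / (n_boot + 1)
    return BootstrapDensityResult(d_a, d_b, float(t), float(p), n_boot, seed, redrawn)


def _connected(W: np.ndarray) -> bool:
    k = W.shape[0]
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in np.flatnonzero(W[i] > 0):
            if j not in seen:
                seen.add(int(j))
                frontier.append(int(j))
    return len(seen) == k


def eigenvector_centrality(
    matrix: ConnectivityMatrix | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> dict[str, float]:
    """Eigenvector centrality of the valued network.

    Power iteration on the |r| weight matrix with zeroed diagonal; the
    principal eigenvector is oriented non-negative and scaled to unit
    Euclidean norm (so the squared centralities sum to one).  Weighted
    centrality rewards nodes whose strong ties are themselves to
    well-connected nodes.
    """
    if isinstance(matrix, ConnectivityMatrix):
        r = matrix.r
        labels = matrix.regions
    else:
        r = _check_square_symmetric(np.asarray(matrix, dtype=float), "matrix")
        labels = tuple(str(i) for i in range(r.shape[0]))
    W = np.abs(np.where(np.isfinite(r), r, 0.0))
    np.fill_diagonal(W, 0.0)
    if not W.any():
        raise ConfigError("empty network: centrality undefined")
    if not _connected(W):
        raise ConfigError("network disconnected under |r| weights; centrality not comparable")
    k = W.shape[0]
    v = np.full(k, 1.0 / np.sqrt(k))
    # shift guarantees convergence to the Perron vector even when the
    # leading eigenvalues of W are +/- pairs
    shift = np.abs(W).sum(axis=1).max()
    M = W + shift * np.eye(k)
    for _ in range(max_iter):
        v_new = M @ v
        v_new /= np.linalg.norm(v_new)
        if np.linalg.norm(v_new - v) < tol:
            v = v_new
            break
        v = v_new
    else:
        w = np.sort(np.linalg.eigvalsh(W))
        raise ConfigError(
            f"power iteration did not converge; leading eigenvalue gap {w[-1] - w[-2]:.3e}"
        )
    v = np.abs(v)
    v /= np.linalg.norm(v)
    return {lab: float(c) for lab, c in zip(labels, v)}


def export_network(
    conn: ConnectivityMatrix,
    region_activity: dict[str, float],
    behavior_scores: pd.DataFrame | None = None,
    expression_wide: pd.DataFrame | None = None,
    edge_alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for the treatment network diagram.

    Brain nodes carry their mean activity level; optional PC1/PC2 behaviour
    nodes carry the mean component score.  Edges carry r, its sign, the
    adjusted p and a significance flag at adjusted p < ``edge_alpha``.
    When behaviour scores and per-fish expression are supplied, brain-PC
    and PC-PC edges are added with their own BH family.
    """
    nodes = [
        {"node": reg, "kind": "region", "size": region_activity.get(reg, float("nan"))}
        for reg in conn.regions
    ]
    edges = []
    k = len(conn.regions)
    for i, j in itertools.combinations(range(k), 2):
        rij = conn.r[i, j]
        edges.append(
            {
                "node_a": conn.regions[i],
                "node_b": conn.regions[j],
                "r": rij,
                "sign": "positive" if rij >= 0 else "negative",
                "p_adj": conn.p_adj[i, j],
                "significant": bool(np.isfinite(conn.p_adj[i, j]) and conn.p_adj[i, j] < edge_alpha),
            }
        )
    if behavior_scores is not None and expression_wide is not None:
        merged = expression_wide.join(behavior_scores[["PC1", "PC2"]], how="inner")
        for pc in ("PC1", "PC2"):
            nodes.append({"node": pc, "kind": "behavior", "size": float(merged[pc].mean())})
        extra = []
        pairs = [(reg, pc) for reg in conn.regions for pc in ("PC1", "PC2")] + [("PC1", "PC2")]
        for a, b in pairs:
            sub = merged[[a, b]].dropna()
            if len(sub) < 3 or np.ptp(sub[a]) == 0 or np.ptp(sub[b]) == 0:
                extra.append({"node_a": a, "node_b": b, "r": float("nan"), "p": float("nan")})
                continue
            r, p = sps.pearsonr(sub[a], sub[b])
            extra.append({"node_a": a, "node_b": b, "r": float(r), "p": float(p)})
        padj = bh_adjust([e["p"] for e in extra])
        for e, pa in zip(extra, padj):
            edges.append(
                {
                    "node_a": e["node_a"],
                    "node_b": e["node_b"],
                    "r": e["r"],
                    "sign": "positive" if (np.isfinite(e["r"]) and e["r"] >= 0) else "negative",
                    "p_adj": float(pa),
                    "significant": bool(np.isfinite(pa) and pa < edge_alpha),
                }
            )
    return pd.DataFrame(nodes), pd.DataFrame(edges)
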