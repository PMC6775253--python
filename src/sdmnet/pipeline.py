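"""End-to-end orchestration: simulate/load -> qPCR -> screening -> PCA ->
group statistics -> networks -> hormones, with a machine-readable manifest.

Every stochastic stage draws its seed deterministically from the master
seed and the stage name, so a fixed configuration reproduces its output
files byte for byte.
"""

from __future__ import annotations

import itertools
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import fit_pca, loading_table
from .config import (
    BEHAVIOR_VARIABLES,
    GENE_REGIONS,
    HK_GENE,
    IEG_GENES,
    REGIONS,
    STEROIDS,
    TREATMENTS,
    ConfigError,
    RunConfig,
)
from .network import (
    bootstrap_density_compare,
    build_connectivity,
    eigenvector_centrality,
    export_network,
    network_density,
    qap_association,
)
from .qpcr import aggregate_replicates, normalize_table, reference_stability
from .screening import log_transform, screen_columns, screen_long
from .simulate import generate_cohort
from .stats import compare_groups, correlation_report, hormone_deltas, hormone_deltas_and_tests

__all__ = ["run_pipeline", "validate_inputs", "stage_seed"]

_FLOAT_FMT = "%.10g"


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return int((int(master) ^ zlib.crc32(stage.encode())) % (2**31))


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def validate_inputs(
    qpcr: pd.DataFrame,
    behavior: pd.DataFrame,
    hormones: pd.DataFrame,
    design: pd.DataFrame,
) -> list[str]:
    """Schema and cross-table consistency checks; returns itemized issues."""
    issues: list[str] = []

    def check_cols(df, cols, name):
        for c in cols:
            if c not in df.columns:
                issues.append(f"{name}: missing column {c!r}")

    check_cols(design, ("fish_id", "treatment"), "design")
    check_cols(qpcr, ("fish_id", "treatment", "region", "gene", "rep1", "rep2", "rep3", "efficiency"), "qpcr")
    check_cols(behavior, ("fish_id", "treatment") + BEHAVIOR_VARIABLES, "behavior")
    check_cols(hormones, ("fish_id", "treatment", "steroid", "baseline", "post"), "hormones")
    if issues:
        return issues

    if design["fish_id"].duplicated().any():
        issues.append("design: duplicate fish_id")
    known_fish = set(design["fish_id"])
    for name, df in (("qpcr", qpcr), ("behavior", behavior), ("hormones", hormones)):
        unknown = set(df["fish_id"]) - known_fish
        if unknown:
            issues.append(f"{name}: fish not in design: {sorted(unknown)}")
    for i, t in design["treatment"].items():
        if t not in TREATMENTS:
            issues.append(f"design row {i}: unknown treatment {t!r}")
    for i, reg in qpcr["region"].items():
        if reg not in REGIONS:
            issues.append(f"qpcr row {i}: unknown region {reg!r}")
    known_genes = set(GENE_REGIONS) | {HK_GENE}
    for i, g in qpcr["gene"].items():
        if g not in known_genes:
            issues.append(f"qpcr row {i}: unknown gene {g!r}")
    bad_eff = qpcr[(qpcr["efficiency"] <= 0) | (qpcr["efficiency"] > 1)]
    for i in bad_eff.index:
        issues.append(f"qpcr row {i}: efficiency outside (0, 1]")
    reps = qpcr[["rep1", "rep2", "rep3"]].to_numpy(dtype=float)
    if np.any(reps[np.isfinite(reps)] <= 0):
        issues.append("qpcr: non-positive CT values present")
    for i, s in hormones["steroid"].items():
        if s not in STEROIDS:
            issues.append(f"hormones row {i}: unknown steroid {s!r}")
    sizes = design.groupby("treatment").size()
    for t in TREATMENTS:
        if sizes.get(t, 0) < 2:
            issues.append(f"design: treatment {t} has fewer than 2 fish")
    return issues


def _load_inputs(cfg: RunConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    if cfg.simulate is not None:
        cohort = generate_cohort(cfg.simulate, seed=stage_seed(cfg.seed, "simulate"))
        inputs_dir = outdir / "inputs"
        inputs_dir.mkdir(parents=True, exist_ok=True)
        for name, df in cohort.items():
            _write(df, inputs_dir / f"{name}.csv")
        return cohort
    return {
        "design": pd.read_csv(cfg.design_path),
        "qpcr": pd.read_csv(cfg.qpcr_path),
        "behavior": pd.read_csv(cfg.behavior_path),
        "hormones": pd.read_csv(cfg.hormone_path),
    }


def _stage(manifest: dict, name: str):
    class _Ctx:
        def __enter__(self):
            return None

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise ConfigError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(name)
            return False

    return _Ctx()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write all output tables + manifest.

    Returns the manifest dict.  Any stage failure raises ConfigError naming
    the stage.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "master_seed": cfg.seed,
        "stages": [],
        "seeds": {},
        "n_perm": cfg.n_perm,
        "n_boot": cfg.n_boot,
        "density_mode": cfg.density_mode,
    }

    with _stage(manifest, "load_inputs"):
        data = _load_inputs(cfg, outdir)

    with _stage(manifest, "validate"):
        issues = validate_inputs(data["qpcr"], data["behavior"], data["hormones"], data["design"])
        if issues:
            raise ConfigError("; ".join(issues))
        manifest["group_sizes"] = data["design"].groupby("treatment").size().to_dict()

    with _stage(manifest, "qpcr"):
        expr = normalize_table(data["qpcr"], sd_threshold=cfg.sd_threshold)
        _write(expr, outdir / "expression.csv")
        hk = data["qpcr"][data["qpcr"]["gene"] == HK_GENE]
        hk_ct = hk.apply(
            lambda row: aggregate_replicates(row[["rep1", "rep2", "rep3"]].to_numpy())[0], axis=1
        )
        per_fish = pd.DataFrame({"fish_id": hk["fish_id"], "treatment": hk["treatment"], "ct": hk_ct})
        per_fish = per_fish.groupby(["fish_id", "treatment"], as_index=False)["ct"].mean()
        ref = reference_stability(per_fish["ct"], per_fish["treatment"], alpha=cfg.alpha)
        manifest["reference_stability"] = {"F": ref.F, "p": ref.p, "passed": ref.passed}
        manifest["qc_flags"] = expr["qc_flag"].value_counts().to_dict()

    with _stage(manifest, "screening"):
        group_cols = ("gene", "region") if cfg.esd_pooled else ("gene", "region", "treatment")
        screened, expr_report = screen_long(
            expr, cell_cols=group_cols, alpha=cfg.esd_alpha, max_frac=cfg.esd_max_frac
        )
        screened["value"] = log_transform(screened["relative_expression"].to_numpy())
        _write(screened, outdir / "expression_screened.csv")

        behav, behav_report = screen_columns(
            data["behavior"],
            list(BEHAVIOR_VARIABLES),
            group_col=None if cfg.esd_pooled else "treatment",
            alpha=cfg.esd_alpha,
            max_frac=cfg.esd_max_frac,
        )
        for var in BEHAVIOR_VARIABLES:
            behav[var] = log_transform(behav[var].to_numpy())
        frames = [f for f in (expr_report, behav_report) if not f.empty]
        report = pd.concat(frames, ignore_index=True) if frames else expr_report
        _write(report, outdir / "outlier_report.csv")
        manifest["n_outliers"] = {"expression": len(expr_report), "behavior": len(behav_report)}

    with _stage(manifest, "behavior_pca"):
        model = fit_pca(behav)
        _write(loading_table(model), outdir / "pca_loadings.csv")
        _write(model.scores.reset_index(drop=True), outdir / "pca_scores.csv")
        manifest["pca"] = {
            "eigenvalues": [float(x) for x in model.eigenvalues],
            "pct_variance": [float(x) for x in model.pct_variance],
            "pct_variance_total": model.pct_variance_total,
            "n_fish": int(len(model.scores)),
        }

    with _stage(manifest, "group_stats"):
        rows = []
        for pc in ("PC1", "PC2"):
            res = compare_groups(model.scores[pc], model.scores["treatment"], variable=pc, welch=cfg.welch)
            for pw in res.pairwise:
                rows.append(
                    {
                        "variable": pc,
                        "gene": "",
                        "region": "",
                        "F": res.omnibus_stat,
                        "p_omnibus": res.omnibus_p,
                        "pair": f"{pw.pair[0]} vs {pw.pair[1]}",
                        "t": pw.t,
                        "p_raw": pw.p_raw,
                        "p_adj": pw.p_adj,
                        "d": pw.d,
                    }
                )
        for gene, regions in GENE_REGIONS.items():
            for region in regions:
                cell = screened[(screened["gene"] == gene) & (screened["region"] == region)]
                try:
                    res = compare_groups(cell["value"], cell["treatment"], welch=cfg.welch)
                except ConfigError:
                    continue
                for pw in res.pairwise:
                    rows.append(
                        {
                            "variable": f"{gene}/{region}",
                            "gene": gene,
                            "region": region,
                            "F": res.omnibus_stat,
                            "p_omnibus": res.omnibus_p,
                            "pair": f"{pw.pair[0]} vs {pw.pair[1]}",
                            "t": pw.t,
                            "p_raw": pw.p_raw,
                            "p_adj": pw.p_adj,
                            "d": pw.d,
                        }
                    )
        _write(pd.DataFrame(rows), outdir / "group_stats.csv")

    with _stage(manifest, "networks"):
        conns = {}
        summary_rows = []
        for gene in IEG_GENES:
            for treatment in TREATMENTS:
                conn = build_connectivity(screened, treatment, gene, value_col="value")
                conns[(treatment, gene)] = conn
                density = network_density(conn, mode=cfg.density_mode, threshold=cfg.alpha)
                cent = eigenvector_centrality(conn)
                row = {"gene": gene, "treatment": treatment, "density": density}
                row.update({f"centrality_{reg}": cent[reg] for reg in REGIONS})
                summary_rows.append(row)
                mat = pd.DataFrame(conn.r, index=REGIONS, columns=REGIONS)
                mat.insert(0, "region", REGIONS)
                _write(mat, outdir / f"connectivity_{gene}_{treatment}.csv")
        _write(pd.DataFrame(summary_rows), outdir / "network_summary.csv")

        qap_rows = []
        boot_rows = []
        for gene in IEG_GENES:
            for a, b in itertools.combinations(TREATMENTS, 2):
                qseed = stage_seed(cfg.seed, f"qap/{gene}/{a}-{b}")
                qr = qap_association(conns[(a, gene)].r, conns[(b, gene)].r, n_perm=cfg.n_perm, seed=qseed)
                qap_rows.append(
                    {"gene": gene, "pair": f"{a} vs {b}", "r": qr.r_obs, "p": qr.p, "n_perm": qr.n_perm, "seed": qseed}
                )
                wide = {
                    t: screened[(screened["gene"] == gene) & (screened["treatment"] == t)]
                    .pivot_table(index="fish_id", columns="region", values="value", aggfunc="first")
                    .reindex(columns=list(REGIONS))
                    .dropna()
                    for t in (a, b)
                }
                bseed = stage_seed(cfg.seed, f"boot/{gene}/{a}-{b}")
                br = bootstrap_density_compare(wide[a], wide[b], n_boot=cfg.n_boot, seed=bseed)
                boot_rows.append(
                    {
                        "gene": gene,
                        "pair": f"{a} vs {b}",
                        "density_a": br.density_a,
                        "density_b": br.density_b,
                        "t": br.t,
                        "p": br.p,
                        "n_boot": br.n_boot,
                        "seed": bseed,
                        "n_redrawn": br.n_redrawn,
                    }
                )
        _write(pd.DataFrame(qap_rows), outdir / "qap_tests.csv")
        _write(pd.DataFrame(boot_rows), outdir / "density_tests.csv")
        manifest["seeds"]["qap"] = {r["gene"] + "/" + r["pair"]: r["seed"] for r in qap_rows}
        manifest["seeds"]["bootstrap"] = {r["gene"] + "/" + r["pair"]: r["seed"] for r in boot_rows}

        node_frames, edge_frames = [], []
        for gene in IEG_GENES:
            for treatment in TREATMENTS:
                conn = conns[(treatment, gene)]
                sub = screened[(screened["gene"] == gene) & (screened["treatment"] == treatment)]
                activity = sub.groupby("region")["value"].mean().to_dict()
                wide = sub.pivot_table(index="fish_id", columns="region", values="value", aggfunc="first")
                scores = model.scores[model.scores["treatment"] == treatment].set_index("fish_id")
                nodes, edges = export_network(
                    conn, activity, behavior_scores=scores, expression_wide=wide, edge_alpha=cfg.edge_alpha
                )
                nodes.insert(0, "gene", gene)
                nodes.insert(1, "treatment", treatment)
                edges.insert(0, "gene", gene)
                edges.insert(1, "treatment", treatment)
                node_frames.append(nodes)
                edge_frames.append(edges)
        _write(pd.concat(node_frames, ignore_index=True), outdir / "network_nodes.csv")
        _write(pd.concat(edge_frames, ignore_index=True), outdir / "network_edges.csv")

    with _stage(manifest, "hormones"):
        deltas = hormone_deltas(data["hormones"])
        screened_deltas, hreport = screen_columns(
            deltas.rename(columns={"delta": "value"}),
            ["value"],
            group_col=None,
            alpha=cfg.esd_alpha,
            max_frac=cfg.esd_max_frac,
        )
        panel = data["hormones"].copy()
        results = hormone_deltas_and_tests(panel, welch=cfg.welch)
        hrows = []
        for steroid, res in results.items():
            for pw in res.pairwise:
                hrows.append(
                    {
                        "steroid": steroid,
                        "F": res.omnibus_stat,
                        "p_omnibus": res.omnibus_p,
                        "pair": f"{pw.pair[0]} vs {pw.pair[1]}",
                        "t": pw.t,
                        "p_raw": pw.p_raw,
                        "p_adj": pw.p_adj,
                        "d": pw.d,
                    }
                )
        _write(pd.DataFrame(hrows), outdir / "hormone_stats.csv")

        # gnrh1 (PPa) vs PPa IEG activity and post-trial androgen levels
        ppa = screened[screened["region"] == "PPa"]
        series = {}
        for gene in ("gnrh1",) + IEG_GENES:
            s = ppa[ppa["gene"] == gene].set_index("fish_id")["value"]
            if len(s):
                series[f"{gene}_PPa" if gene != "gnrh1" else "gnrh1"] = s
        for steroid in STEROIDS:
            s = (
                data["hormones"][data["hormones"]["steroid"] == steroid]
                .set_index("fish_id")["post"]
            )
            series[f"{steroid}_post"] = s
        _write(correlation_report(series), outdir / "correlations.csv")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
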