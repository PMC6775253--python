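"""Synthetic cohort generator: determinism, planted structure, invariants."""

import numpy as np
import pandas as pd
import pytest

from sdmnet import (
    ConfigError,
    REGIONS,
    SimulationConfig,
    generate_behavior,
    generate_cohort,
    generate_design,
    generate_expression,
    generate_hormones,
    normalize_table,
)
from sdmnet.config import BEHAVIOR_VARIABLES


class TestDesign:
    def test_default_cohort_is_twenty_fish(self):
        design = generate_design({"MM": 8, "MD": 6, "MS": 6})
        assert len(design) == 20
        assert design.groupby("treatment").size().to_dict() == {"MM": 8, "MD": 6, "MS": 6}
        assert design["fish_id"].is_unique

    def test_minimal_cohort(self):
        assert len(generate_design({"MM": 2, "MD": 2, "MS": 2})) == 6

    def test_invalid_group_size_rejected(self):
        with pytest.raises(ConfigError):
            generate_design({"MM": 8, "MD": 1, "MS": 6})


class TestDeterminism:
    def test_same_seed_gives_byte_identical_tables(self):
        cfg = SimulationConfig(seed=21)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for name in a:
            assert a[name].to_csv(index=False) == b[name].to_csv(index=False)

    def test_different_seeds_differ(self):
        a = generate_cohort(SimulationConfig(seed=1))
        b = generate_cohort(SimulationConfig(seed=2))
        assert not a["qpcr"]["rep1"].equals(b["qpcr"]["rep1"])

    def test_operation_streams_independent(self, design, default_config):
        # behaviour draws must not depend on whether expression was generated
        b1 = generate_behavior(design, default_config, seed=5)
        generate_expression(design, default_config, seed=5)
        b2 = generate_behavior(design, default_config, seed=5)
        assert b1.equals(b2)


class TestExpression:
    def test_zero_replicate_noise_gives_identical_replicates(self, design):
        cfg = SimulationConfig(seed=2, ct_replicate_sd=0.0)
        q = generate_expression(design, cfg)
        assert np.allclose(q["rep1"], q["rep2"])
        assert np.allclose(q["rep1"], q["rep3"])

    def test_ct_values_finite_positive(self, cohort):
        reps = cohort["qpcr"][["rep1", "rep2", "rep3"]].to_numpy()
        assert np.isfinite(reps).all()
        assert (reps > 0).all()

    def test_identity_target_gives_near_zero_correlations(self):
        cfg = SimulationConfig(
            seed=8,
            group_sizes={"MM": 200, "MD": 2, "MS": 2},
            target_correlation={
                (t, g): np.eye(5) for t in ("MM", "MD", "MS") for g in ("c-fos", "egr-1")
            },
        )
        design = generate_design(cfg.group_sizes)
        expr = normalize_table(generate_expression(design, cfg))
        wide = (
            expr[(expr["treatment"] == "MM") & (expr["gene"] == "c-fos")]
            .pivot_table(index="fish_id", columns="region", values="relative_expression")
        )
        R = np.corrcoef(np.log10(wide.to_numpy()), rowvar=False)
        iu = np.triu_indices(5, 1)
        assert np.abs(R[iu]).max() < 0.2

    def test_planted_edge_recovered_within_sampling_tolerance(self):
        R = np.eye(5)
        i, j = REGIONS.index("TA"), REGIONS.index("GC")
        R[i, j] = R[j, i] = 0.9
        cfg = SimulationConfig(
            seed=9,
            group_sizes={"MM": 200, "MD": 2, "MS": 2},
            target_correlation={
                (t, g): R for t in ("MM", "MD", "MS") for g in ("c-fos", "egr-1")
            },
        )
        design = generate_design(cfg.group_sizes)
        expr = normalize_table(generate_expression(design, cfg))
        wide = (
            expr[(expr["treatment"] == "MM") & (expr["gene"] == "c-fos")]
            .pivot_table(index="fish_id", columns="region", values="relative_expression")
            .reindex(columns=list(REGIONS))
        )
        Rhat = np.corrcoef(np.log10(wide.to_numpy()), rowvar=False)
        assert 0.85 <= Rhat[i, j] <= 0.95

    def test_non_psd_target_rejected(self, design):
        bad = np.eye(5)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = 0.9
        bad[1, 2] = bad[2, 1] = -0.9
        cfg = SimulationConfig(
            target_correlation={(t, g): bad for t in ("MM", "MD", "MS") for g in ("c-fos", "egr-1")}
        )
        with pytest.raises(ConfigError):
            generate_expression(design, cfg)


class TestBehavior:
    def test_zero_noise_exact_linear_image_of_factors(self, design):
        # full-communality loadings leave no residual variance
        L = np.zeros((6, 2))
        L[:3, 0] = 1.0
        L[3:, 1] = 1.0
        cfg = SimulationConfig(
            seed=4,
            behavior_loading_matrix=L,
            behavior_effects={"MM": 0.0, "MD": 0.0, "MS": 0.0},
            behavior_means=(0.0,) * 6,
            behavior_scales=(1.0,) * 6,
            trial_duration=1e9,
        )
        behav = generate_behavior(design, cfg)
        # frequencies are clipped at zero, so compare where positive
        f = behav[["freq_displays", "freq_bites", "freq_attacks"]].to_numpy()
        pos = (f > 0).all(axis=1)
        assert np.allclose(f[pos, 0], f[pos, 1], atol=0.06)  # same factor, rounding only
        assert np.allclose(f[pos, 1], f[pos, 2], atol=0.06)

    def test_planted_group_contrast_on_overt_aggression(self):
        cfg = SimulationConfig(seed=6, group_sizes={"MM": 200, "MD": 200, "MS": 200})
        design = generate_design(cfg.group_sizes)
        behav = generate_behavior(design, cfg)
        means = behav.groupby("treatment")["freq_attacks"].mean()
        assert means["MS"] < means["MM"]
        assert means["MS"] < means["MD"]
        lat = behav.groupby("treatment")["lat_attack"].mean()
        assert lat["MS"] > lat["MM"]  # less aggressive fish attack later

    @pytest.mark.parametrize("seed", range(25))
    def test_frequencies_never_negative_latencies_within_trial(self, design, default_config, seed):
        behav = generate_behavior(design, default_config, seed=seed)
        for var in BEHAVIOR_VARIABLES:
            if var.startswith("freq"):
                assert (behav[var] >= 0).all()
            else:
                assert ((behav[var] > 0) & (behav[var] <= default_config.trial_duration)).all()


class TestHormones:
    def test_null_configuration_mean_delta_near_zero(self):
        cfg = SimulationConfig(seed=10, group_sizes={"MM": 300, "MD": 300, "MS": 300})
        design = generate_design(cfg.group_sizes)
        panel = generate_hormones(design, cfg)
        delta = panel["post"] - panel["baseline"]
        se = delta.std() / np.sqrt(len(delta))
        assert abs(delta.mean()) < 4 * se + 0.01

    def test_planted_effect_shifts_post_levels(self):
        effects = {"T": {"MM": 0.0, "MD": 2.0, "MS": 0.0}, "KT": {"MM": 0.0, "MD": 0.0, "MS": 0.0}}
        cfg = SimulationConfig(seed=12, group_sizes={"MM": 200, "MD": 200, "MS": 200}, hormone_effects=effects)
        design = generate_design(cfg.group_sizes)
        panel = generate_hormones(design, cfg)
        t_panel = panel[panel["steroid"] == "T"]
        deltas = (t_panel["post"] - t_panel["baseline"]).groupby(t_panel["treatment"].values).mean()
        assert deltas["MD"] == pytest.approx(2.0, abs=0.3)
        assert abs(deltas["MM"]) < 0.3

    def test_same_seed_identical_panel(self, design, default_config):
        p1 = generate_hormones(design, default_config, seed=3)
        p2 = generate_hormones(design, default_config, seed=3)
        assert p1.equals(p2)
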