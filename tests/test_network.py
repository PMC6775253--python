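"""QAP association, valued density, bootstrap density test, centrality."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sdmnet import (
    ConfigError,
    REGIONS,
    bootstrap_density_compare,
    build_connectivity,
    eigenvector_centrality,
    export_network,
    network_density,
    qap_association,
)


def random_correlation(rng, n_fish=10, k=5):
    """Empirical correlation matrix of independent Gaussian data."""
    return np.corrcoef(rng.standard_normal((n_fish, k)), rowvar=False)


def qap_exact_p(A, B):
    """Exhaustive QAP oracle: all node relabelings of B (two-tailed)."""
    k = A.shape[0]
    iu = np.triu_indices(k, 1)
    a = A[iu]
    r_obs = np.corrcoef(a, B[iu])[0, 1]
    hits = 0
    total = 0
    for perm in itertools.permutations(range(k)):
        Bp = B[np.ix_(perm, perm)]
        r = np.corrcoef(a, Bp[iu])[0, 1]
        hits += abs(r) >= abs(r_obs) - 1e-12
        total += 1
    return hits / total


def long_expression(rng, R, n_fish, treatment="MM", gene="c-fos"):
    X = rng.multivariate_normal(np.zeros(5), R, size=n_fish, method="cholesky")
    rows = []
    for i in range(n_fish):
        for j, region in enumerate(REGIONS):
            rows.append(
                {"fish_id": f"{treatment}{i}", "treatment": treatment, "region": region,
                 "gene": gene, "value": X[i, j]}
            )
    return pd.DataFrame(rows)


class TestBuildConnectivity:
    def test_duplicated_region_signal_gives_unit_correlation(self, rng):
        df = long_expression(rng, np.eye(5), 12)
        vs = df[df["region"] == "Vs"].set_index("fish_id")["value"]
        df.loc[df["region"] == "TA", "value"] = vs.loc[
            df.loc[df["region"] == "TA", "fish_id"]
        ].to_numpy()
        conn = build_connectivity(df, "MM", "c-fos")
        i, j = REGIONS.index("Vs"), REGIONS.index("TA")
        assert conn.r[i, j] == pytest.approx(1.0)

    def test_null_structure_yields_no_adjusted_significance(self, rng):
        df = long_expression(rng, np.eye(5), 200)
        conn = build_connectivity(df, "MM", "c-fos")
        iu = np.triu_indices(5, 1)
        assert np.nanmax(np.abs(conn.r[iu])) < 0.25
        assert not (conn.p_adj[iu] < 0.05).any()

    def test_planted_edge_detected(self, rng):
        R = np.eye(5)
        i, j = REGIONS.index("TA"), REGIONS.index("GC")
        R[i, j] = R[j, i] = 0.9
        df = long_expression(rng, R, 200)
        conn = build_connectivity(df, "MM", "c-fos")
        assert conn.p_adj[i, j] < 0.01
        assert 0.85 <= conn.r[i, j] <= 0.95

    def test_symmetry_and_pairwise_complete_missing(self, rng):
        df = long_expression(rng, np.eye(5), 10)
        df.loc[(df["fish_id"] == "MM0") & (df["region"] == "GC"), "value"] = np.nan
        conn = build_connectivity(df, "MM", "c-fos")
        assert np.allclose(conn.r, conn.r.T, equal_nan=True)
        assert np.allclose(np.diag(conn.r), 1.0)
        gc = REGIONS.index("GC")
        assert conn.n_pairs[gc, 0] == 9
        iu = np.triu_indices(5, 1)
        ok = np.isfinite(conn.p_adj[iu]) & np.isfinite(conn.p_raw[iu])
        assert np.all(conn.p_adj[iu][ok] >= conn.p_raw[iu][ok] - 1e-12)

    def test_too_few_complete_pairs_leaves_cell_missing(self, rng):
        df = long_expression(rng, np.eye(5), 4)
        mask = (df["region"] == "GC") & df["fish_id"].isin(["MM0", "MM1"])
        df.loc[mask, "value"] = np.nan
        conn = build_connectivity(df, "MM", "c-fos")
        gc = REGIONS.index("GC")
        assert np.isnan(conn.r[gc, 0])
        assert conn.notes


class TestQap:
    def test_identical_matrices_maximal_association(self, rng):
        A = random_correlation(rng)
        res = qap_association(A, A, n_perm=999, seed=1)
        assert res.r_obs == pytest.approx(1.0)
        assert res.p < 0.05  # smallest attainable region given automorphism hits

    def test_joint_relabeling_invariance(self, rng):
        A, B = random_correlation(rng), random_correlation(rng)
        perm = rng.permutation(5)
        r1 = qap_association(A, B, n_perm=99, seed=0).r_obs
        r2 = qap_association(A[np.ix_(perm, perm)], B[np.ix_(perm, perm)], n_perm=99, seed=0).r_obs
        assert r1 == pytest.approx(r2)

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        A, B = random_correlation(rng), random_correlation(rng)
        exact = qap_exact_p(A, B)
        mc = qap_association(A, B, n_perm=4999, seed=3).p
        assert mc == pytest.approx(exact, abs=0.02)

    def test_p_never_zero_and_deterministic(self, rng):
        A, B = random_correlation(rng), random_correlation(rng)
        r1 = qap_association(A, B, n_perm=500, seed=9)
        r2 = qap_association(A, B, n_perm=500, seed=9)
        assert r1.p > 0
        assert (r1.r_obs, r1.p) == (r2.r_obs, r2.p)

    def test_shape_and_symmetry_validated(self, rng):
        A = random_correlation(rng)
        with pytest.raises(ConfigError):
            qap_association(A, A[:4, :4])
        bad = A.copy()
        bad[0, 1] += 0.3
        with pytest.raises(ConfigError):
            qap_association(A, bad)


class TestDensity:
    def test_saturated_network(self):
        R = np.ones((5, 5))
        assert network_density(R) == pytest.approx(1.0)

    def test_three_node_mean(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.2
        R[0, 2] = R[2, 0] = -0.4
        R[1, 2] = R[2, 1] = 0.6
        assert network_density(R) == pytest.approx(0.4)  # mean |r|

    def test_bounded_by_extreme_ties(self, rng):
        R = random_correlation(rng)
        iu = np.triu_indices(5, 1)
        d = network_density(R)
        assert np.abs(R[iu]).min() <= d <= np.abs(R[iu]).max()

    def test_binary_mode_counts_significant_edges(self, rng):
        df = long_expression(rng, np.eye(5), 20)
        conn = build_connectivity(df, "MM", "c-fos")
        assert network_density(conn, mode="binary", threshold=1e-6) == pytest.approx(0.0)
        assert network_density(conn, mode="binary", threshold=1.01) == pytest.approx(1.0)

    def test_signed_option(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = -0.5
        R[0, 2] = R[2, 0] = 0.5
        R[1, 2] = R[2, 1] = 0.5
        assert network_density(R, use_abs=False) == pytest.approx(0.5 / 3)


class TestBootstrapDensity:
    def test_identical_inputs_give_null_result(self, rng):
        X = rng.standard_normal((8, 5))
        res = bootstrap_density_compare(X, X.copy(), n_boot=300, seed=4)
        assert res.density_a == pytest.approx(res.density_b)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self, rng):
        Xa, Xb = rng.standard_normal((8, 5)), rng.standard_normal((6, 5))
        r1 = bootstrap_density_compare(Xa, Xb, n_boot=200, seed=7)
        r2 = bootstrap_density_compare(Xa, Xb, n_boot=200, seed=7)
        assert (r1.t, r1.p) == (r2.t, r2.p)

    def test_planted_density_difference_detected(self, rng):
        dense = np.full((5, 5), 0.8)
        np.fill_diagonal(dense, 1.0)
        Xa = rng.multivariate_normal(np.zeros(5), dense, size=60, method="cholesky")
        Xb = rng.standard_normal((60, 5))
        res = bootstrap_density_compare(Xa, Xb, n_boot=500, seed=2)
        assert res.density_a > res.density_b
        assert res.p < 0.05

    def test_rejects_incomplete_or_tiny_input(self, rng):
        X = rng.standard_normal((8, 5))
        Y = X.copy()
        Y[0, 0] = np.nan
        with pytest.raises(ConfigError):
            bootstrap_density_compare(X, Y)
        with pytest.raises(ConfigError):
            bootstrap_density_compare(X[:2], X)


class TestEigenvectorCentrality:
    def test_complete_equal_weight_graph_uniform(self):
        R = np.full((5, 5), 0.6)
        np.fill_diagonal(R, 1.0)
        cent = eigenvector_centrality(R)
        assert np.allclose(list(cent.values()), 1 / np.sqrt(5), atol=1e-9)

    def test_star_graph_closed_form(self):
        # hub-and-spoke with unit weights: center 1/sqrt(2), leaves 1/(2 sqrt(2))
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        cent = eigenvector_centrality(W)
        vals = np.array(list(cent.values()))
        assert vals[0] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
        assert np.allclose(vals[1:], 1 / (2 * np.sqrt(2)), atol=1e-9)
        assert vals[0] / vals[1] == pytest.approx(2.0, abs=1e-8)  # sqrt(n-1)

    def test_matches_dense_eigensolver(self, rng):
        for _ in range(20):
            R = random_correlation(rng)
            W = np.abs(R)
            np.fill_diagonal(W, 0.0)
            w, V = np.linalg.eigh(W)
            ref = np.abs(V[:, -1])
            got = np.array(list(eigenvector_centrality(R).values()))
            assert np.allclose(got, ref / np.linalg.norm(ref), atol=1e-8)

    def test_unit_norm_convention(self, rng):
        got = np.array(list(eigenvector_centrality(random_correlation(rng)).values()))
        assert np.linalg.norm(got) == pytest.approx(1.0)

    def test_disconnected_network_errors(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(ConfigError):
            eigenvector_centrality(W)


class TestExportNetwork:
    def test_seven_nodes_twenty_one_edges(self, rng):
        df = long_expression(rng, np.eye(5), 12)
        conn = build_connectivity(df, "MM", "c-fos")
        wide = df.pivot_table(index="fish_id", columns="region", values="value")
        scores = pd.DataFrame(
            rng.standard_normal((12, 2)), columns=["PC1", "PC2"], index=wide.index
        )
        activity = df.groupby("region")["value"].mean().to_dict()
        nodes, edges = export_network(conn, activity, behavior_scores=scores, expression_wide=wide)
        assert len(nodes) == 7
        assert len(edges) == 21
        assert set(edges["sign"]) <= {"positive", "negative"}

    def test_no_significant_edges_all_flags_false(self, rng):
        df = long_expression(rng, np.eye(5), 12)
        conn = build_connectivity(df, "MM", "c-fos")
        nodes, edges = export_network(conn, {}, edge_alpha=1e-9)
        assert not edges["significant"].any()
        assert len(nodes) == 5 and len(edges) == 10
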