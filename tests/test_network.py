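import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexmod import (
    NetworkConfig,
    SimulationConfig,
    SoftThresholdNetwork,
    beta_curve,
    correlation_adjacency,
    phi_statistic,
    scale_free_fit,
    select_beta,
    simulate_modular_expression,
    tom_similarity,
)


def _two_gene_expr(r):
    """Two genes with exact Pearson correlation r (plus padding gene)."""
    n = 200
    rng = np.random.default_rng(0)
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    y = y - np.polyval(np.polyfit(x, y, 1), x)  # orthogonalize
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    g2 = r * x + np.sqrt(1 - r**2) * y
    return pd.DataFrame(
        [x, g2, rng.standard_normal(n)], index=["A", "B", "C"],
    )


class TestAdjacency:
    def test_unsigned_power(self):
        expr = _two_gene_expr(-0.8)
        adj = correlation_adjacency(expr, 2, NetworkConfig(network_type="unsigned"))
        assert adj[0, 1] == pytest.approx(0.64, abs=1e-9)

    def test_signed_power(self):
        expr = _two_gene_expr(-0.8)
        adj = correlation_adjacency(
            expr, 2, NetworkConfig(network_type="signed")
        )
        assert adj[0, 1] == pytest.approx(0.01, abs=1e-9)

    def test_beta_one_is_abs_correlation(self):
        expr = _two_gene_expr(0.6)
        adj = correlation_adjacency(expr, 1)
        r = np.corrcoef(expr.to_numpy())
        np.testing.assert_allclose(adj, np.abs(r), atol=1e-12)

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            correlation_adjacency(_two_gene_expr(0.5), 0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.standard_normal((8, 20)))
        perm = rng.permutation(8)
        a1 = correlation_adjacency(expr, 3)
        a2 = correlation_adjacency(expr.iloc[perm], 3)
        np.testing.assert_allclose(a1[np.ix_(perm, perm)], a2, atol=1e-12)


def _adjacency_from_degrees(k, seed=0):
    """Diagonal-block-free random symmetric adjacency with given row sums —
    here we only need the connectivity vector, so build a star-free
    surrogate whose row sums equal k via outer-product scaling."""
    k = np.asarray(k, dtype=float)
    w = np.outer(k, k) / k.sum()
    np.fill_diagonal(w, 0.0)
    # rescale iteratively so row sums match k closely
    for _ in range(50):
        s = w.sum(axis=1)
        w *= np.sqrt(np.outer(k / s, k / s))
        w = (w + w.T) / 2
    return w


class TestScaleFreeFit:
    def test_power_law_degrees_score_high(self):
        rng = np.random.default_rng(1)
        k = rng.zipf(1.5, size=2000).astype(float)
        k = k[k < 1000][:1500]
        # independent oracle: log-log regression on the binned histogram
        edges = np.linspace(k.min(), k.max(), 11)
        hist, _ = np.histogram(k, bins=edges)
        centers = [
            k[(k >= edges[i]) & (k <= edges[i + 1] if i == 9 else k < edges[i + 1])].mean()
            for i in range(10) if hist[i] > 0
        ]
        freq = hist[hist > 0] / k.size
        slope, _, r, *_ = stats.linregress(np.log10(centers), np.log10(freq))
        assert -np.sign(slope) * r**2 > 0.8  # oracle confirms the fixture
        adj = _adjacency_from_degrees(k)
        r2, mean_k = scale_free_fit(adj)
        assert r2 > 0.8
        assert mean_k == pytest.approx(np.mean(adj.sum(axis=1)), rel=1e-9)

    def test_poisson_degrees_score_lower(self):
        rng = np.random.default_rng(2)
        k_pois = rng.poisson(20, size=1500).astype(float) + 1
        r2_pois, _ = scale_free_fit(_adjacency_from_degrees(k_pois))
        k_pl = rng.zipf(1.5, size=2000).astype(float)
        k_pl = k_pl[k_pl < 1000][:1500]
        r2_pl, _ = scale_free_fit(_adjacency_from_degrees(k_pl))
        assert r2_pois < r2_pl

    def test_identical_connectivities_warn_and_zero(self):
        a = np.full((5, 5), 0.5)
        np.fill_diagonal(a, 1.0)
        with pytest.warns(UserWarning):
            r2, _ = scale_free_fit(a)
        assert r2 == 0.0


class TestSelectBeta:
    CURVE = [0.30, 0.70, 0.82, 0.90, 0.95, 0.96, 0.96, 0.96]

    @staticmethod
    def _oracle(r2, betas, tau, eps):
        """Exhaustive suffix enumeration."""
        for i in range(len(betas)):
            if r2[i] > tau and all(
                abs(r2[j] - r2[k]) < eps
                for j in range(i, len(betas))
                for k in range(i, len(betas))
            ):
                return betas[i]
        return None

    def _curve(self, r2, betas=None):
        betas = betas or list(range(1, len(r2) + 1))
        return pd.DataFrame({"beta": betas, "r2": r2, "mean_connectivity": 0.0})

    def test_hand_crafted_sequence(self):
        cfg = NetworkConfig(beta_grid=tuple(range(1, 9)), tau=0.8, epsilon=0.05)
        assert self._oracle(self.CURVE, list(range(1, 9)), 0.8, 0.05) == 5
        assert select_beta(self._curve(self.CURVE), cfg) == 5

    def test_epsilon_inf_reduces_to_first_over_tau(self):
        cfg = NetworkConfig(beta_grid=tuple(range(1, 9)), tau=0.8, epsilon=np.inf)
        assert select_beta(self._curve(self.CURVE), cfg) == 3

    def test_constant_sequence_gives_first_beta(self):
        cfg = NetworkConfig(beta_grid=tuple(range(1, 6)), tau=0.8, epsilon=0.05)
        assert select_beta(self._curve([0.9] * 5), cfg) == 1

    def test_all_below_tau_gives_none(self):
        cfg = NetworkConfig(beta_grid=tuple(range(1, 6)), tau=0.8, epsilon=0.05)
        assert select_beta(self._curve([0.5] * 5), cfg) is None

    def test_matches_exhaustive_oracle_on_random_curves(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            r2 = list(np.round(rng.uniform(0, 1, size=8), 3))
            eps = float(rng.uniform(0.02, 0.3))
            cfg = NetworkConfig(beta_grid=tuple(range(1, 9)), tau=0.8, epsilon=eps)
            assert select_beta(self._curve(r2), cfg) == self._oracle(
                r2, list(range(1, 9)), 0.8, eps
            )


class TestPhi:
    def test_constant_one(self):
        c = pd.DataFrame({"beta": range(1, 21), "r2": 1.0})
        assert phi_statistic(c) == pytest.approx(1.0)

    def test_linear_ramp_is_half(self):
        c = pd.DataFrame({"beta": range(1, 21), "r2": np.linspace(0, 1, 20)})
        assert phi_statistic(c) == pytest.approx(0.5)

    def test_constant_point_eight(self):
        c = pd.DataFrame({"beta": range(1, 21), "r2": 0.8})
        assert phi_statistic(c) == pytest.approx(0.8)

    def test_negative_r2_clamped(self):
        c = pd.DataFrame({"beta": range(1, 21), "r2": -0.5})
        assert phi_statistic(c) == 0.0

    def test_single_point(self):
        c = pd.DataFrame({"beta": [3], "r2": [0.7]})
        assert phi_statistic(c) == pytest.approx(0.7)


def brute_force_tom(a):
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return out


class TestTom:
    def test_three_node_closed_form(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        # l = 0.25, k = 1 -> (0.25 + 0.5)/(1 + 1 - 0.5) = 0.5
        off = tom[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-12)

    def test_zero_adjacency_gives_identity(self):
        a = np.zeros((4, 4))
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(tom_similarity(a), np.eye(4), atol=1e-12)

    def test_complete_graph_all_ones(self):
        n = 6
        a = np.ones((n, n))
        np.testing.assert_allclose(tom_similarity(a), np.ones((n, n)), atol=1e-12)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.uniform(0, 1, size=(10, 10))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            np.testing.assert_allclose(
                tom_similarity(a), brute_force_tom(a), atol=1e-12
            )

    def test_asymmetric_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.9
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        perm = rng.permutation(8)
        t1 = tom_similarity(a)
        t2 = tom_similarity(a[np.ix_(perm, perm)])
        np.testing.assert_allclose(t1[np.ix_(perm, perm)], t2, atol=1e-12)


class TestBetaCurve:
    def test_mean_connectivity_weakly_decreasing(self, planted):
        expr, _, _ = planted
        curve = beta_curve(expr.iloc[:150], NetworkConfig(beta_grid=tuple(range(1, 11))))
        mk = curve["mean_connectivity"].to_numpy()
        assert np.all(np.diff(mk) <= 1e-9)

    def test_points_match_single_beta_recomputation(self, planted):
        expr, _, _ = planted
        sub = expr.iloc[:100]
        cfg = NetworkConfig(beta_grid=(2, 5))
        curve = beta_curve(sub, cfg)
        for _, row in curve.iterrows():
            adj = correlation_adjacency(sub, int(row["beta"]), cfg)
            r2, mk = scale_free_fit(adj, cfg.n_bins)
            assert row["r2"] == pytest.approx(r2, abs=1e-12)
            assert row["mean_connectivity"] == pytest.approx(mk, abs=1e-9)

    def test_permutation_destroys_connectivity(self, planted):
        # shuffling each gene's samples independently removes co-expression;
        # the soft-thresholded network loses nearly all its connectivity
        expr, _, _ = planted
        rng = np.random.default_rng(8)
        permuted = expr.copy()
        for i in range(permuted.shape[0]):
            permuted.iloc[i] = rng.permutation(permuted.iloc[i].to_numpy())
        cfg = NetworkConfig(beta_grid=(6,))
        real_k = beta_curve(expr, cfg)["mean_connectivity"].iloc[0]
        perm_k = beta_curve(permuted, cfg)["mean_connectivity"].iloc[0]
        assert perm_k < 0.2 * real_k

    def test_estimator_front_end(self, planted):
        expr, _, _ = planted
        net = SoftThresholdNetwork(beta_max=10, force_beta=6).fit(expr.to_numpy().T)
        assert net.tom_.shape == (expr.shape[0],) * 2
        assert 0.0 <= net.phi_ <= 1.0
        assert net.beta_ in range(1, 21)
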