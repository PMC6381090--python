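import numpy as np
import pytest

import symptomnet as sn
from symptomnet import (
    AnalysisConfig,
    ItemResponseMatrix,
    ValidationError,
    bootstrap_edges,
    cs_coefficient,
    split_replication,
    subset_stability,
)


def constant_estimator(weights):
    """Seam: ignores the data, always returns the same network."""

    def est(data):
        p = data.values.shape[1]
        return weights[:p, :p]

    return est


def empirical_pcorr_estimator(data):
    """Cheap seam estimator: partial correlations from the inverse of the
    sample covariance (no regularization)."""
    v = data.values.astype(float)
    theta = np.linalg.pinv(np.cov(v, rowvar=False))
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return 0.5 * (pc + pc.T)


def corr_weight_estimator(data):
    """Seam: absolute-free correlation weights; deterministic in data."""
    w = np.corrcoef(data.values.astype(float), rowvar=False)
    np.fill_diagonal(w, 0.0)
    return w


@pytest.fixture
def seam_network():
    rng = np.random.default_rng(0)
    w = np.zeros((10, 10))
    iu = np.triu_indices(10, 1)
    w[iu] = rng.uniform(0.1, 0.9, len(iu[0])) * (rng.random(len(iu[0])) < 0.4)
    return w + w.T


@pytest.fixture
def ordinal_data():
    params, _, _ = sn.planted_gaussian_truth(5, n_blocks=2)
    vals = sn.sample_latent_ordinal(params, 500, seed=1)
    return ItemResponseMatrix(vals, [f"s{i}" for i in range(5)], "severity")


class TestBootstrapEdges:
    def test_constant_estimator_zero_width_cis(self, seam_network, ordinal_data):
        cfg = AnalysisConfig(bootstrap_B=60, seed=3)
        data = ItemResponseMatrix(
            ordinal_data.values[:, :5], ordinal_data.symptom_codes, "severity"
        )
        eb, ed = bootstrap_edges(data, cfg, estimator=constant_estimator(seam_network))
        assert np.allclose(eb.ci_lower, eb.ci_upper)
        assert not ed.significant.any()

    def test_diagonal_never_significant(self, ordinal_data):
        cfg = AnalysisConfig(bootstrap_B=60, seed=4)
        _, ed = bootstrap_edges(ordinal_data, cfg,
                                estimator=empirical_pcorr_estimator)
        assert not ed.significant.diagonal().any()
        assert np.array_equal(ed.significant, ed.significant.T)

    def test_ci_bounds_ordered_and_contain_boot_mean(self, ordinal_data):
        cfg = AnalysisConfig(bootstrap_B=80, seed=5)
        eb, _ = bootstrap_edges(ordinal_data, cfg, estimator=empirical_pcorr_estimator)
        assert np.all(eb.ci_lower <= eb.ci_upper)
        assert np.all(eb.boot_mean >= eb.ci_lower - 1e-12)
        assert np.all(eb.boot_mean <= eb.ci_upper + 1e-12)

    def test_strong_vs_null_edge_flagged_different(self):
        """Power check: an edge with true partial correlation ~0.4 is
        declared different from a null edge in most replicates."""
        a = np.zeros((5, 5))
        a[0, 1] = a[1, 0] = 0.4
        a[2, 3] = a[3, 2] = 0.05
        theta = np.eye(5) - a
        sigma = np.linalg.inv(theta)
        dd = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(dd, dd)
        chol = np.linalg.cholesky(corr)
        hits = 0
        n_rep = 10
        for r in range(n_rep):
            rng = np.random.default_rng(900 + r)
            z = rng.standard_normal((500, 5)) @ chol.T
            vals = (z > 0).astype(int) + (z > 0.8).astype(int)
            data = ItemResponseMatrix(vals, [f"s{i}" for i in range(5)], "severity")
            cfg = AnalysisConfig(bootstrap_B=200, seed=r)
            eb, ed = bootstrap_edges(data, cfg, estimator=empirical_pcorr_estimator)
            pairs = {e: i for i, e in enumerate(ed.edges)}
            if (0, 1) in pairs and (2, 3) in pairs:
                hits += bool(ed.significant[pairs[(0, 1)], pairs[(2, 3)]])
        assert hits >= 0.8 * n_rep

    def test_small_b_refused(self, ordinal_data):
        with pytest.raises(ValidationError):
            bootstrap_edges(ordinal_data, AnalysisConfig(bootstrap_B=10))

    def test_reproducible_under_seed(self, ordinal_data):
        cfg = AnalysisConfig(bootstrap_B=60, seed=11)
        a, _ = bootstrap_edges(ordinal_data, cfg, estimator=empirical_pcorr_estimator)
        b, _ = bootstrap_edges(ordinal_data, cfg, estimator=empirical_pcorr_estimator)
        assert np.array_equal(a.samples, b.samples)

    def test_ci_width_shrinks_with_n(self):
        params, _, _ = sn.planted_gaussian_truth(5, n_blocks=2)
        widths = {}
        for n in (250, 1000):
            med = []
            for s in range(5):
                vals = sn.sample_latent_ordinal(params, n, seed=50 + s)
                data = ItemResponseMatrix(vals, [f"s{i}" for i in range(5)], "severity")
                cfg = AnalysisConfig(bootstrap_B=100, seed=s)
                eb, _ = bootstrap_edges(data, cfg, estimator=empirical_pcorr_estimator)
                med.append(np.median(eb.ci_upper - eb.ci_lower))
            widths[n] = np.median(med)
        assert widths[1000] < widths[250]


class TestCsCoefficient:
    def test_threshold_semantics_constructed_table(self):
        """94% passing at q=0.5 misses the 95% certainty bar; 96% at
        q=0.25 clears it, so CS = 0.25."""
        corrs = {
            0.25: np.array([0.9] * 96 + [0.1] * 4),
            0.5: np.array([0.9] * 94 + [0.1] * 6),
        }
        assert cs_coefficient(corrs, 0.7, 0.95) == 0.25

    def test_no_qualifying_proportion_gives_zero(self):
        assert cs_coefficient({0.1: np.array([0.1, 0.2])}) == 0.0

    def test_nonincreasing_in_required_correlation(self):
        rng = np.random.default_rng(1)
        corrs = {q: rng.uniform(0.4, 1.0, 100) for q in (0.1, 0.3, 0.5, 0.7)}
        cs_values = [cs_coefficient(corrs, thr, 0.95) for thr in (0.5, 0.7, 0.9)]
        assert cs_values == sorted(cs_values, reverse=True)


class TestSubsetStability:
    def test_constant_estimator_max_cs(self, seam_network, ordinal_data):
        cfg = AnalysisConfig(seed=2, drop_proportions=(0.1, 0.3, 0.5, 0.7))
        rep = subset_stability(
            ordinal_data, cfg, mode="case",
            estimator=constant_estimator(seam_network), B_sub=20,
        )
        for idx in ("strength", "closeness", "betweenness"):
            assert all(np.allclose(c, 1.0) for c in rep.correlations[idx].values())
            assert rep.cs[idx] == 0.7

    def test_pure_noise_binary_data_detected_unstable(self):
        """Independent coins give no stable centrality ordering."""
        cfg = AnalysisConfig(seed=0, drop_proportions=(0.25, 0.5), n_lambda=25)
        unstable = 0
        n_seeds = 5
        for s in range(n_seeds):
            rng = np.random.default_rng(600 + s)
            vals = (rng.random((150, 10)) < 0.5).astype(int)
            data = ItemResponseMatrix(vals, [f"s{i}" for i in range(10)], "occurrence")
            rep = subset_stability(data, cfg, mode="case", B_sub=25)
            unstable += rep.cs["strength"] <= 0.25
        assert unstable >= 0.8 * n_seeds

    def test_node_dropping_small_p_refused(self, ordinal_data):
        small = ItemResponseMatrix(
            ordinal_data.values[:, :3], ordinal_data.symptom_codes[:3], "severity"
        )
        with pytest.raises(ValidationError):
            subset_stability(small, AnalysisConfig(), mode="node")

    def test_node_dropping_runs_and_reports_grid_cs(self, ordinal_data):
        cfg = AnalysisConfig(seed=8, drop_proportions=(0.2, 0.4))
        rep = subset_stability(
            ordinal_data, cfg, mode="node",
            estimator=empirical_pcorr_estimator, B_sub=15,
        )
        for idx in ("strength", "closeness", "betweenness"):
            assert rep.cs[idx] in {0.0, 0.2, 0.4}
            for q, c in rep.correlations[idx].items():
                assert np.all(c >= -1.0) and np.all(c <= 1.0)

    def test_reproducible_under_seed(self, ordinal_data):
        cfg = AnalysisConfig(seed=9, drop_proportions=(0.3,))
        a = subset_stability(ordinal_data, cfg, estimator=empirical_pcorr_estimator, B_sub=10)
        b = subset_stability(ordinal_data, cfg, estimator=empirical_pcorr_estimator, B_sub=10)
        assert np.array_equal(a.correlations["strength"][0.3], b.correlations["strength"][0.3])


class TestSplitReplication:
    def test_identical_blocks_correlate_perfectly(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 2, size=(50, 6))
        vals = np.vstack([block] * 4)
        data = ItemResponseMatrix(vals, [f"s{i}" for i in range(6)], "occurrence")
        partition = np.repeat(np.arange(4), 50)
        out = split_replication(
            data, AnalysisConfig(), k=4,
            estimator=corr_weight_estimator, partition=partition,
        )
        assert np.allclose(out, 1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 2, size=(200, 5))
        data = ItemResponseMatrix(vals, [f"s{i}" for i in range(5)], "occurrence")
        out = split_replication(data, AnalysisConfig(seed=1), k=2,
                                estimator=corr_weight_estimator)
        assert np.allclose(out, out.T)
        assert np.allclose(np.diag(out), 1.0)

    def test_structured_data_replicates_across_splits(self):
        """Heterogeneous coupling strengths give a node-strength ordering
        that replicates across independent quarters."""
        beta = np.zeros((8, 8))
        for (a, b), v in {
            (0, 1): 1.2, (1, 2): 0.9, (2, 3): 0.6, (3, 4): 1.0,
            (4, 5): 0.4, (0, 5): 0.7, (2, 6): 1.1, (6, 7): 0.5,
        }.items():
            beta[a, b] = beta[b, a] = v
        params = sn.IsingParams(beta, -0.5 * beta.sum(axis=1))
        means = []
        for s in range(3):
            vals = sn.sample_ising(params, 4000, seed=40 + s)
            data = ItemResponseMatrix(vals, [f"s{i}" for i in range(8)], "occurrence")
            cfg = AnalysisConfig(seed=s, n_lambda=25)
            out = split_replication(data, cfg, k=4)
            means.append(out[np.triu_indices(4, 1)].mean())
        assert np.mean(means) >= 0.7

    def test_k_below_two_rejected(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 2, size=(100, 4))
        data = ItemResponseMatrix(vals, list("abcd"), "occurrence")
        with pytest.raises(ValidationError):
            split_replication(data, AnalysisConfig(), k=1)
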