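import numpy as np
import pandas as pd
import pytest

from netconsensus import (DataError, ScoreVector, SyntheticSpec,
                          entropy_indegree_correlation,
                          generate_decorrelated_network, generate_outcomes,
                          generate_signaling_network, prediction_profile,
                          quartile_subsets, redistribution_sweep,
                          score_correlation_matrix, score_distribution_report,
                          shannon_consensus, observed_minus_expected)


def make_scores(values, algorithm="test"):
    ids = tuple(f"v{i:02d}" for i in range(len(values)))
    return ScoreVector(ids, np.asarray(values, float), algorithm)


class TestQuartileSubsets:
    def test_sizes_n8(self):
        subs = quartile_subsets(make_scores(np.arange(8)))
        assert [len(subs[k]) for k in
                ("Q1", "Q1-2", "Q1-3", "all", "Q2-4", "Q3-4", "Q4")] == \
            [2, 4, 6, 8, 6, 4, 2]

    def test_sizes_n5_ceiling_cuts(self):
        subs = quartile_subsets(make_scores(np.arange(5)))
        assert [len(subs[k]) for k in
                ("Q1", "Q1-2", "Q1-3", "all", "Q2-4", "Q3-4", "Q4")] == \
            [2, 3, 4, 5, 3, 2, 1]

    def test_ties_broken_by_node_id(self):
        subs = quartile_subsets(make_scores(np.zeros(8)))
        assert subs["Q1"] == ["v00", "v01"]
        assert subs["Q4"] == ["v06", "v07"]

    def test_nesting_and_unions(self):
        subs = quartile_subsets(make_scores(np.arange(11)[::-1]))
        assert set(subs["Q1"]) <= set(subs["Q1-2"]) <= set(subs["Q1-3"]) \
            <= set(subs["all"])
        assert set(subs["Q4"]) <= set(subs["Q3-4"]) <= set(subs["Q2-4"])
        assert set(subs["Q1"]) | set(subs["Q2-4"]) == set(subs["all"])
        assert set(subs["Q1-3"]) | set(subs["Q4"]) == set(subs["all"])

    def test_too_few_nodes_rejected(self):
        with pytest.raises(DataError):
            quartile_subsets(make_scores([1, 2, 3]))


class TestPredictionProfile:
    def test_perfect_affine_outcome_r2_one(self):
        sv = make_scores(np.arange(16, dtype=float))
        outcomes = pd.DataFrame({"y": 3 * sv.values + 5}, index=list(sv.node_ids))
        prof = prediction_profile(sv, outcomes)
        np.testing.assert_allclose(prof.r2["y"].astype(float), 1, atol=1e-12)
        np.testing.assert_allclose(prof.multivariate_r2.astype(float), 1,
                                   atol=1e-12)

    def test_constant_outcome_r2_zero_with_warning(self):
        sv = make_scores(np.arange(16, dtype=float))
        outcomes = pd.DataFrame({"y": np.full(16, 2.0)}, index=list(sv.node_ids))
        with pytest.warns(UserWarning, match="zero-variance"):
            prof = prediction_profile(sv, outcomes)
        assert prof.r2.loc["all", "y"] == 0

    def test_r2_invariant_under_affine_transforms(self):
        rng = np.random.default_rng(0)
        sv = make_scores(rng.normal(size=30))
        y = 2 * sv.values + rng.normal(size=30)
        p1 = prediction_profile(sv, pd.DataFrame({"y": y}, index=list(sv.node_ids)))
        sv2 = ScoreVector(sv.node_ids, 10 * sv.values - 4, "scaled")
        p2 = prediction_profile(sv2, pd.DataFrame({"y": -3 * y + 1},
                                                  index=list(sv.node_ids)))
        np.testing.assert_allclose(p1.r2.loc["all", "y"], p2.r2.loc["all", "y"])

    def test_missing_values_dropped_pairwise(self):
        sv = make_scores(np.arange(16, dtype=float))
        y = 2.0 * sv.values
        y[3] = np.nan
        prof = prediction_profile(sv, pd.DataFrame({"y": y},
                                                   index=list(sv.node_ids)))
        assert prof.r2.loc["all", "y"] == pytest.approx(1.0)

    def test_no_overlap_rejected(self):
        sv = make_scores(np.arange(8, dtype=float))
        outcomes = pd.DataFrame({"y": [1.0]}, index=["zzz"])
        with pytest.raises(DataError):
            prediction_profile(sv, outcomes)

    def test_stochastic_recovery_of_population_r2(self):
        net = generate_signaling_network(SyntheticSpec(kind="signaling",
                                                       n=200, seed=3))
        sv = shannon_consensus(net)
        sd = np.sqrt(np.var(2.0 * sv.values) * (1 - 0.8) / 0.8)
        outcomes, meta = generate_outcomes(sv, slope=2.0, noise_sd=sd,
                                           n_outcomes=1, seed=11)
        assert meta["population_r2"] == pytest.approx(0.8)
        prof = prediction_profile(sv, outcomes)
        assert abs(prof.r2.loc["all", "outcome_1"] - 0.8) < 0.05


class TestRedistributionSweep:
    def test_singleton_grid(self, t1):
        res = redistribution_sweep(t1, [0.4])
        assert res.selected_epsilon == 0.4

    def test_symmetric_graph_constant_criterion_first_wins(self, t2):
        res = redistribution_sweep(t2, [0.1, 0.2, 0.3])
        np.testing.assert_allclose(res.table["criterion"],
                                   res.table["criterion"].iloc[0], atol=1e-9)
        assert res.selected_epsilon == 0.1

    def test_invalid_grid_rejected(self, t1):
        from netconsensus import ConfigError
        with pytest.raises(ConfigError):
            redistribution_sweep(t1, [0.0, 0.5])
        with pytest.raises(ConfigError):
            redistribution_sweep(t1, [])

    def test_recovers_planted_epsilon(self):
        from netconsensus import ECConfig, eigenvector_centrality, noise_sd_for_r2
        net = generate_signaling_network(SyntheticSpec(kind="signaling",
                                                       n=60, seed=5))
        ec = eigenvector_centrality(net, ECConfig(epsilon=0.3))
        sd = noise_sd_for_r2(ec.values, 1.0, 0.95)
        outcomes, _ = generate_outcomes(ec, slope=1.0, noise_sd=sd,
                                        n_outcomes=3, seed=6)
        grid = [round(0.05 * i, 2) for i in range(1, 20)]
        res = redistribution_sweep(net, grid, outcomes)
        assert abs(res.selected_epsilon - 0.3) <= 0.05 + 1e-9
        assert res.criterion == "multivariate_r2"


class TestDistributionReport:
    def test_lognormal_scores_pass_log_normality(self):
        rng = np.random.default_rng(21)
        rep = score_distribution_report(
            make_scores(rng.lognormal(0, 1, 500)))
        assert rep["shapiro_log"]["pvalue"] > 0.01
        assert rep["n_nonpositive_excluded"] == 0

    def test_constant_scores_skip_tests(self):
        rep = score_distribution_report(make_scores(np.full(10, 3.0)))
        assert rep["skewness"] == 0
        assert "shapiro_raw" not in rep

    def test_mirrored_sample_has_zero_skewness(self):
        x = np.arange(1, 11, dtype=float)
        rep = score_distribution_report(make_scores(np.concatenate([x, -x])))
        assert rep["skewness"] == pytest.approx(0, abs=1e-12)

    def test_too_few_positive_scores_skips_log_branch(self):
        v = np.concatenate([np.zeros(10), [1, 2, 3.0]])
        rep = score_distribution_report(make_scores(v))
        assert "shapiro_log" not in rep
        assert any("log branch skipped" in n for n in rep["notes"])


class TestCorrelationHelpers:
    def test_pairwise_matrix_symmetric_unit_diagonal(self, t1):
        from netconsensus import simple_consensus, weighted_in_degree
        mat = score_correlation_matrix([simple_consensus(t1),
                                        weighted_in_degree(t1),
                                        shannon_consensus(t1)])
        assert mat.shape == (3, 3)
        np.testing.assert_allclose(np.diag(mat), 1)
        np.testing.assert_allclose(mat.values, mat.values.T)

    def test_decorrelated_network_breaks_coupling(self):
        net = generate_decorrelated_network(
            SyntheticSpec(kind="decorrelated", n=30, seed=2))
        rho, _ = entropy_indegree_correlation(net)
        assert rho <= 0

    def test_observed_minus_expected(self):
        obs = pd.DataFrame({"y": [3.0, 4.0]}, index=["a", "b"])
        exp = pd.DataFrame({"y": [1.0, 1.0]}, index=["a", "b"])
        out = observed_minus_expected(obs, exp)
        np.testing.assert_allclose(out["y"], [2, 3])
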