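"""Survey generator: ground-truth structure, prevalence and determinism."""

import numpy as np
import pytest

from geoadd.spatial import AdjacencyGraph, icar_precision
from geoadd.synthetic import (
    AGE_DOMAIN,
    MAB_DOMAIN,
    SimulationConfig,
    default_truth,
    read_truth,
    sample_icar_effect,
    simulate_survey,
    write_truth,
)


def _flat(graph, intercept):
    from geoadd.synthetic import SyntheticTruth

    return SyntheticTruth(
        intercept=intercept,
        gamma=np.zeros(13),
        f_age=lambda x: np.zeros_like(np.asarray(x, float)),
        f_mab=lambda x: np.zeros_like(np.asarray(x, float)),
        spatial_str=np.zeros(graph.n_regions),
        spatial_unstr=np.zeros(graph.n_regions),
        tau2_str=1.0,
        tau2_unstr=0.0,
    )


class TestFixtureGraphOp:
    def test_ten_labelled_provinces_single_component(self, graph):
        assert graph.n_regions == 10
        assert "Harare" in graph.labels and "Midlands" in graph.labels
        # breadth-first search oracle over the fixture file
        seen, frontier = {0}, [0]
        while frontier:
            i = frontier.pop()
            for j in graph.neighbours[i]:
                if j not in seen:
                    seen.add(j)
                    frontier.append(j)
        assert seen == set(range(10))

    def test_symmetry(self, graph):
        for i, nbrs in enumerate(graph.neighbours):
            for j in nbrs:
                assert i in graph.neighbours[j]


class TestSimulateSurvey:
    def test_row_count_matches_survey_scale(self, graph):
        cfg = SimulationConfig(n=5055, graph=graph, seed=1)
        table, _ = simulate_survey(cfg, _flat(graph, 0.0))
        assert len(table) == 5055
        assert set(table.columns) >= {"outcome", "cca_months", "mabfc_years", "province"}

    def test_null_truth_gives_half_prevalence(self, graph):
        n = 5000
        table, _ = simulate_survey(
            SimulationConfig(n=n, graph=graph, seed=2), _flat(graph, 0.0)
        )
        se = np.sqrt(0.25 / n)
        assert abs(table.outcome.mean() - 0.5) < 3 * se

    def test_intercept_only_prevalence_binomial_check(self, graph):
        from scipy.special import logit

        n = 10_000
        table, _ = simulate_survey(
            SimulationConfig(n=n, graph=graph, seed=3), _flat(graph, float(logit(0.14)))
        )
        assert abs(table.outcome.mean() - 0.14) < 3 * np.sqrt(0.14 * 0.86 / n)

    def test_identical_seed_identical_table(self, graph):
        truth = default_truth(graph, seed=5, prevalence_target=0.2)
        cfg = SimulationConfig(n=400, graph=graph, seed=5)
        t1, _ = simulate_survey(cfg, truth)
        t2, _ = simulate_survey(cfg, truth)
        assert t1.equals(t2)

    def test_invalid_frequency_rejected(self, graph):
        freqs = np.full(13, 0.5)
        freqs[4] = 1.0
        with pytest.raises(ValueError, match="strictly in"):
            SimulationConfig(n=100, graph=graph, seed=0, covariate_freqs=freqs)

    def test_n_smaller_than_provinces_rejected(self, graph):
        with pytest.raises(ValueError, match="at least the number of provinces"):
            SimulationConfig(n=5, graph=graph, seed=0)

    def test_prevalence_monotone_in_intercept(self, graph):
        prevs = []
        for b0 in (-1.5, 0.0, 1.5):
            table, _ = simulate_survey(
                SimulationConfig(n=4000, graph=graph, seed=7), _flat(graph, b0)
            )
            prevs.append(table.outcome.mean())
        assert prevs[0] < prevs[1] < prevs[2]

    def test_seed_invariance_of_prevalence(self, graph):
        truth = default_truth(graph, seed=9, prevalence_target=0.25)
        n = 4000
        p = []
        for seed in (21, 22):
            table, _ = simulate_survey(SimulationConfig(n=n, graph=graph, seed=seed), truth)
            p.append(table.outcome.mean())
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(p[0] - p[1]) < 4 * np.sqrt(2) * se

    def test_covariate_ranges(self, small_survey):
        table, _ = small_survey
        assert table.cca_months.between(*AGE_DOMAIN).all()
        assert table.mabfc_years.between(*MAB_DOMAIN).all()

    def test_calibrated_intercept_hits_target(self, graph):
        truth = default_truth(graph, seed=13, prevalence_target=0.3)
        table, _ = simulate_survey(
            SimulationConfig(n=8000, graph=graph, seed=13), truth
        )
        assert abs(table.outcome.mean() - 0.3) < 4 * np.sqrt(0.3 * 0.7 / 8000)


class TestIcarEffect:
    def test_sums_to_zero(self, graph):
        f = sample_icar_effect(graph, 0.5, 1)
        assert abs(f.sum()) < 1e-10

    def test_deterministic(self, graph):
        assert np.array_equal(sample_icar_effect(graph, 1.0, 4), sample_icar_effect(graph, 1.0, 4))

    def test_disconnected_graph_rejected(self):
        g = AdjacencyGraph(
            ("a", "b", "c", "d"),
            (frozenset({1}), frozenset({0}), frozenset({3}), frozenset({2})),
        )
        with pytest.raises(ValueError, match="connected components"):
            sample_icar_effect(g, 1.0, 0)

    def test_path_graph_covariance_matches_pseudoinverse(self):
        # oracle: tau2 * Moore-Penrose pseudo-inverse of the ICAR precision
        nbrs = (frozenset({1}), frozenset({0, 2}), frozenset({1, 3}), frozenset({2}))
        g = AdjacencyGraph(("a", "b", "c", "d"), nbrs)
        tau2 = 1.0
        sigma = tau2 * np.linalg.pinv(icar_precision(g).matrix)
        draws = np.stack([sample_icar_effect(g, tau2, 1000 + i) for i in range(10_000)])
        emp = np.cov(draws.T, bias=True)
        assert np.allclose(emp, sigma, atol=0.05 * np.abs(sigma).max())

    def test_variance_vanishes_with_tau2(self, graph):
        f = sample_icar_effect(graph, 1e-12, 3)
        assert f.var() < 1e-10


class TestTruthSerialization:
    def test_flat_key_value_round_trip(self, graph, tmp_path):
        truth = default_truth(graph, seed=3, prevalence_target=0.2)
        p = tmp_path / "truth.txt"
        write_truth(truth, graph, p)
        got = read_truth(p)
        assert np.isclose(got["intercept"], truth.intercept)
        assert np.isclose(got["gamma.sex_of_child"], truth.gamma[0])
        assert np.isclose(got["spatial_str.Harare"], truth.spatial_str[graph.index_of("Harare")])
        assert np.isclose(got["f_age.13"], float(truth.f_age(13.0)))

    def test_uncentred_spatial_truth_rejected(self, graph):
        from geoadd.synthetic import SyntheticTruth

        with pytest.raises(ValueError, match="sum to zero"):
            SyntheticTruth(
                intercept=0.0,
                gamma=np.zeros(13),
                f_age=lambda x: np.zeros_like(np.asarray(x, float)),
                f_mab=lambda x: np.zeros_like(np.asarray(x, float)),
                spatial_str=np.ones(graph.n_regions),
                spatial_unstr=np.zeros(graph.n_regions),
                tau2_str=1.0,
                tau2_unstr=0.0,
            )
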