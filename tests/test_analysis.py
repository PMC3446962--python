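"""Cluster detection, sweeps, linear fits, critical fraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hkopinion.analysis import (
    ExperimentConfig,
    NoConsensusRegionError,
    SweepRecord,
    detect_clusters,
    estimate_critical_fraction,
    fit_linear_scaling,
    stabilization_time,
    sweep_close_minded_fraction,
    sweep_group_size,
)
from hkopinion.dynamics import RunParams, run_simulation
from hkopinion.population import InitialOpinionSpec, SubgroupSpec, build_population


def single_linkage_components(x, gap):
    """Brute-force oracle: connected components of the threshold graph.

    Two opinions are linked when they differ by at most ``gap``; cluster
    count is the number of components (union-find, O(n^2) edges).
    """
    n = len(x)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(x[i] - x[j]) <= gap:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


class TestDetectClusters:
    def test_all_equal_is_one_cluster(self):
        cs = detect_clusters(np.full(30, 0.5))
        assert cs.n_clusters == 1
        assert list(cs.sizes) == [30]
        np.testing.assert_allclose(cs.centers, [0.5])

    def test_gap_dominates_tiny_spread(self):
        cs = detect_clusters(np.array([0.1, 0.1 + 1e-9, 0.9]), gap=1e-4)
        assert cs.n_clusters == 2
        assert list(cs.sizes) == [2, 1]

    def test_transitive_chaining(self):
        # ends are pairwise distant but joined through the middle
        cs = detect_clusters(np.array([0.0, 0.2, 0.4]), gap=0.25)
        assert cs.n_clusters == 1

    def test_membership_and_centers_are_consistent(self):
        x = np.array([0.9, 0.1, 0.11, 0.89, 0.5])
        cs = detect_clusters(x, gap=0.05)
        assert cs.n_clusters == 3
        assert np.all(np.diff(cs.centers) > cs.gap)
        for c in range(cs.n_clusters):
            np.testing.assert_allclose(x[cs.membership == c].mean(), cs.centers[c])
        assert cs.sizes.sum() == len(x)

    def test_rejects_empty_and_bad_gap(self):
        with pytest.raises(ValueError):
            detect_clusters(np.array([]))
        with pytest.raises(ValueError):
            detect_clusters(np.array([0.5]), gap=0.0)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_single_linkage_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 100))
        # mix of smooth draws and near-duplicates to exercise ties
        x = np.round(rng.uniform(0, 1, n), int(rng.integers(1, 6)))
        gap = float(rng.choice([1e-4, 0.01, 0.1, 0.25]))
        assert detect_clusters(x, gap).n_clusters == single_linkage_components(x, gap)

    def test_invariance_under_permutation_and_shift(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 0.8, 60)
        base = detect_clusters(x, gap=0.02).n_clusters
        assert detect_clusters(rng.permutation(x), gap=0.02).n_clusters == base
        assert detect_clusters(x + 0.2, gap=0.02).n_clusters == base


class TestStabilizationTime:
    def test_two_agent_example(self):
        spec = SubgroupSpec.homogeneous(0.2)
        init = InitialOpinionSpec(kind="explicit", values=(0.4, 0.5))
        res = run_simulation(build_population(2, spec, init, seed=0))
        assert stabilization_time(res) == 2

    def test_identical_initials(self):
        spec = SubgroupSpec.homogeneous(0.2)
        init = InitialOpinionSpec(kind="explicit", values=(0.7, 0.7, 0.7))
        res = run_simulation(build_population(3, spec, init, seed=0))
        assert stabilization_time(res) == 1

    def test_unconverged_run_signals_unavailable(self):
        spec = SubgroupSpec.homogeneous(0.2)
        init = InitialOpinionSpec(kind="explicit", values=(0.1, 0.25))
        res = run_simulation(build_population(2, spec, init, seed=0), RunParams(t_max=1))
        with pytest.raises(ValueError, match="stabilise"):
            stabilization_time(res)


class TestLinearFit:
    def test_exact_on_collinear_points(self):
        recs = [
            SweepRecord("group_size", v, (0,), (int(c),))
            for v, c in [(0, 1), (1, 2), (2, 3)]
        ]
        fit = fit_linear_scaling(recs)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_rejects_degenerate_input(self):
        recs = [SweepRecord("group_size", 5.0, (0,), (2,))] * 3
        with pytest.raises(ValueError, match="distinct"):
            fit_linear_scaling(recs)

    def test_recovers_known_slope_under_noise(self):
        rng = np.random.default_rng(11)
        a, b, sd = 0.01, 1.5, 0.3
        xs = np.arange(100, 1100, 100)
        recs = [
            SweepRecord("group_size", float(x), (0,), tuple(
                int(max(1, round(a * x + b + rng.normal(0, sd)))) for _ in range(25)
            ))
            for x in xs
        ]
        fit = fit_linear_scaling(recs)
        se = sd / np.sqrt(25) / np.std(xs) / np.sqrt(len(xs))
        assert abs(fit.slope - a) < 3 * max(se, 1e-4)


class TestCriticalFraction:
    def test_direct_scan(self):
        recs = [
            SweepRecord("close_minded_fraction", f, (0,), (c,))
            for f, c in [(0.01, 1), (0.02, 1), (0.05, 3), (0.10, 8)]
        ]
        assert estimate_critical_fraction(recs, consensus_tol=0.05) == 0.02

    def test_no_consensus_region(self):
        recs = [SweepRecord("close_minded_fraction", 0.1, (0,), (4, 5))]
        with pytest.raises(NoConsensusRegionError):
            estimate_critical_fraction(recs)


class TestSweeps:
    def test_single_point_single_replicate(self):
        base = ExperimentConfig(n=50, epsilons=(0.01, 0.2, 0.45), fractions=(0.1, 0.7, 0.2))
        recs = sweep_close_minded_fraction(base, fractions=(0.1,), replicates=1, base_seed=0)
        assert len(recs) == 1
        assert len(recs[0].counts) == 1
        assert recs[0].mean_count == recs[0].counts[0]

    def test_zero_close_minded_fraction_consensus_prone(self):
        # both surviving levels have eps >= 0.2: at most mild polarization
        base = ExperimentConfig(n=100, epsilons=(0.01, 0.2, 0.45), fractions=(0.0, 0.8, 0.2))
        recs = sweep_close_minded_fraction(base, fractions=(0.0,), replicates=5, base_seed=1)
        assert recs[0].mean_count <= 2.0

    def test_shared_initials_reuse_opinion_vector(self):
        base = ExperimentConfig(n=100, epsilons=(0.01, 0.2, 0.45), fractions=(0.05, 0.75, 0.2))
        # the mechanism behind shared initials: same replicate seed and a
        # different subgroup split must yield the same opinion draw
        from hkopinion.analysis import _replicate_seed

        init = InitialOpinionSpec()
        a = build_population(100, SubgroupSpec([(0.01, 0.05), (0.2, 0.75), (0.45, 0.2)]), init, _replicate_seed(7, 0))
        b = build_population(100, SubgroupSpec([(0.01, 0.10), (0.2, 0.70), (0.45, 0.2)]), init, _replicate_seed(7, 0))
        np.testing.assert_array_equal(a.initial_opinions, b.initial_opinions)

    def test_infeasible_fraction_rejected(self):
        base = ExperimentConfig(n=50, epsilons=(0.01, 0.2, 0.45), fractions=(0.05, 0.75, 0.2))
        with pytest.raises(ValueError):
            sweep_close_minded_fraction(base, fractions=(0.9,), replicates=1, base_seed=0)

    def test_size_sweep_means(self):
        base = ExperimentConfig(epsilons=(0.25,), fractions=(1.0,))
        recs = sweep_group_size(base, sizes=(50,), replicates=2, base_seed=3)
        assert len(recs) == 1
        assert recs[0].mean_count == pytest.approx(np.mean(recs[0].counts))

    def test_homogeneous_consensus_independent_of_size(self):
        base = ExperimentConfig(epsilons=(0.25,), fractions=(1.0,))
        recs = sweep_group_size(base, sizes=(50, 100, 200), replicates=5, base_seed=5)
        for rec in recs:
            assert rec.mean_count <= 2.0

    def test_size_rejected_below_subgroup_count(self):
        base = ExperimentConfig(epsilons=(0.01, 0.2, 0.45), fractions=(0.05, 0.75, 0.2))
        with pytest.raises(ValueError):
            sweep_group_size(base, sizes=(2,), replicates=1, base_seed=0)


class TestStochasticTrends:
    def test_homogeneous_cluster_count_non_increasing_in_confidence(self):
        medians = []
        for eps in (0.01, 0.15, 0.25):
            counts = []
            for s in range(20):
                pop = build_population(
                    200, SubgroupSpec.homogeneous(eps), InitialOpinionSpec(), seed=s
                )
                res = run_simulation(pop)
                counts.append(detect_clusters(res.final_state.x).n_clusters)
            medians.append(np.median(counts))
        assert medians[0] >= medians[1] >= medians[2]

    def test_mean_count_non_decreasing_in_close_minded_fraction(self):
        base = ExperimentConfig(n=200, epsilons=(0.01, 0.2, 0.45), fractions=(0.05, 0.75, 0.2))
        recs = sweep_close_minded_fraction(
            base, fractions=(0.01, 0.02, 0.05, 0.10, 0.30), replicates=20, base_seed=0
        )
        means = [r.mean_count for r in recs]
        assert all(b >= a for a, b in zip(means, means[1:]))
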