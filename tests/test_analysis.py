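import numpy as np
import pytest
from scipy import stats as sps

from colnav import analysis as an
from colnav.analysis import AnalysisError


def grid_positions(nx_=20, ny=20, bin_cm=5.0, repeats=1):
    xs, ys = np.meshgrid(np.arange(nx_) * bin_cm + 2.5,
                         np.arange(ny) * bin_cm + 2.5)
    pos = np.column_stack([xs.ravel(), ys.ravel()])
    return np.tile(pos, (repeats, 1))


class TestRateMap:
    def test_flat_rate_gives_flat_map(self):
        pos = grid_positions(4, 4)
        rates = np.full(len(pos), 5.0)
        g, size = an.rate_map(rates, pos)
        assert np.allclose(g["rate_hz"], 5.0)
        assert size == 16  # every visited bin is in the field

    def test_single_active_bin_field_size_one(self):
        pos = grid_positions(4, 4)
        rates = np.zeros(len(pos))
        rates[5] = 8.0
        _, size = an.rate_map(rates, pos)
        assert size == 1

    def test_gaussian_field_matches_analytic_area(self):
        # 20%-of-peak level set of an isotropic Gaussian, sigma = 10 cm:
        # area = 2 pi sigma^2 ln 5 -> in 25 cm^2 bins
        pos = grid_positions(40, 40, repeats=1)
        center = np.array([100.0, 100.0])
        d2 = np.sum((pos - center) ** 2, axis=1)
        rates = 10 * np.exp(-d2 / (2 * 10.0 ** 2))
        _, size = an.rate_map(rates, pos)
        analytic = 2 * np.pi * 10.0 ** 2 * np.log(5) / 25.0
        assert abs(size - analytic) / analytic < 0.15

    def test_empty_trajectory_rejected(self):
        with pytest.raises(AnalysisError):
            an.rate_map(np.array([]), np.zeros((0, 2)))


class TestSpatialInfo:
    def test_uniform_rate_carries_no_information(self):
        pos = grid_positions(4, 1, repeats=10)
        mi, ips = an.spatial_info(np.full(len(pos), 3.0), pos)
        assert mi == 0.0 and ips == 0.0

    def test_one_of_four_bins_two_bits_per_spike(self):
        pos = grid_positions(4, 1, repeats=100)
        rates = np.where(pos[:, 0] < 5.0, 8.0, 0.0)
        _, ips = an.spatial_info(rates, pos)
        assert ips == pytest.approx(2.0, abs=1e-9)  # (1/4)*4*log2(4)

    def test_mi_matches_bruteforce_joint_histogram(self):
        rng = np.random.default_rng(5)
        pos = grid_positions(3, 1, repeats=200)
        rates = rng.choice([0.0, 5.0, 9.0], size=len(pos))
        mi, _ = an.spatial_info(rates, pos)
        # brute force over the (rate level, bin) joint distribution
        xb = (pos[:, 0] // 5).astype(int)
        rb = np.searchsorted([2.5, 7.0], rates)
        joint = np.zeros((3, 3))
        for r, x in zip(rb, xb):
            joint[r, x] += 1
        p = joint / joint.sum()
        brute = 0.0
        for r in range(3):
            for x in range(3):
                if p[r, x] > 0:
                    brute += p[r, x] * np.log2(
                        p[r, x] / (p[r].sum() * p[:, x].sum()))
        assert mi == pytest.approx(brute, abs=1e-9)

    def test_single_bin_rejected(self):
        with pytest.raises(AnalysisError):
            an.spatial_info(np.ones(5), np.zeros((5, 2)))


class TestPopulationInfo:
    def test_perfectly_selective_units_reach_bound(self):
        pos = grid_positions(4, 1, repeats=20)
        xb = (pos[:, 0] // 5).astype(int)
        R = np.eye(4)[xb] * 10.0
        trials = np.repeat(np.arange(20), 4)
        out = an.population_spatial_info(R, pos, trials)
        assert out["ratio"] == pytest.approx(1.0)
        assert out["upper_bound_bits"] == pytest.approx(2.0)

    def test_shuffled_positions_carry_nothing(self):
        rng = np.random.default_rng(11)
        pos = grid_positions(4, 1, repeats=50)
        R = rng.uniform(0, 10, size=(len(pos), 6))
        trials = np.repeat(np.arange(50), 4)
        out = an.population_spatial_info(R, pos, trials)
        assert out["mi_bits"] < 0.25

    def test_ratio_invariant_to_unit_duplication(self):
        rng = np.random.default_rng(13)
        pos = grid_positions(5, 1, repeats=30)
        xb = (pos[:, 0] // 5).astype(int)
        R = np.eye(5)[xb] * 10 + rng.normal(0, 1.0, size=(len(pos), 5))
        trials = np.repeat(np.arange(30), 5)
        a = an.population_spatial_info(R, pos, trials)
        b = an.population_spatial_info(np.hstack([R, R]), pos, trials)
        assert a["ratio"] == pytest.approx(b["ratio"], abs=1e-9)

    def test_single_bin_occupancy_rejected(self):
        with pytest.raises(AnalysisError):
            an.population_spatial_info(np.ones((10, 3)), np.zeros((10, 2)),
                                       np.arange(10) % 2)


class TestSparseness:
    def test_gaussian_samples_have_zero_excess_kurtosis(self):
        rng = np.random.default_rng(17)
        R = rng.normal(0, 1, size=(100_000, 1))
        out = an.sparseness_stats(R)
        assert abs(out["lifetime_kurtosis"][0]) < 0.05

    def test_rare_burst_kurtosis_matches_bernoulli(self):
        # two-point rate {0 (99%), 10 Hz (1%)}: excess kurtosis
        # (1 - 6pq)/(pq) with p = 0.01
        p = 0.01
        n = 100_000
        r = np.zeros(n)
        r[: int(n * p)] = 10.0
        out = an.sparseness_stats(r[:, None])
        expect = (1 - 6 * p * (1 - p)) / (p * (1 - p))
        assert out["lifetime_kurtosis"][0] == pytest.approx(expect, rel=0.01)

    def test_duplicating_units_halves_info_sparseness(self):
        rng = np.random.default_rng(19)
        pos = grid_positions(5, 1, repeats=30)
        xb = (pos[:, 0] // 5).astype(int)
        R = np.eye(5)[xb] * 10 + rng.normal(0, 0.5, size=(len(pos), 5))
        trials = np.repeat(np.arange(30), 5)
        a = an.sparseness_stats(R, pos, trials)
        b = an.sparseness_stats(np.hstack([R, R]), pos, trials)
        assert b["info_sparseness"] == pytest.approx(
            a["info_sparseness"] / 2, rel=0.05)

    def test_constant_trace_flagged_nan(self):
        out = an.sparseness_stats(np.ones((50, 1)))
        assert np.isnan(out["lifetime_kurtosis"][0])


class TestSkewnessAndLag:
    def test_symmetric_triangle_zero_skew(self):
        x = np.arange(21, dtype=float)
        r = 10 - np.abs(x - 10)
        assert an.tuning_skewness(x, r) == pytest.approx(0.0, abs=1e-9)

    def test_mirror_flips_sign(self):
        rng = np.random.default_rng(23)
        x = np.arange(30, dtype=float)
        r = rng.uniform(0, 10, size=30)
        s1 = an.tuning_skewness(x, r)
        s2 = an.tuning_skewness(x, r[::-1])
        assert s1 == pytest.approx(-s2, abs=1e-9)

    def test_exponential_rise_sharp_fall_negative(self):
        t = np.linspace(0, 10, 200)
        r = np.exp((t - 10) / 2.0)  # slow rise to the end
        assert an.tuning_skewness(t, r) < 0

    def test_zero_variance_undefined(self):
        assert np.isnan(an.tuning_skewness(np.ones(5), np.ones(5)))

    def test_identical_traces_zero_lag(self):
        rng = np.random.default_rng(29)
        a = rng.uniform(0, 5, size=100)
        assert an.anticipation_lag(a, a.copy()) == 0.0

    def test_constructed_shift_recovered(self):
        t = np.arange(0, 60, 1 / 3)
        b = np.exp(-((t - 10) ** 2) / 4)
        a = np.exp(-((t - 9) ** 2) / 4)  # a peaks 1 s earlier: a leads b
        assert an.anticipation_lag(a, b, dt=1 / 3) == pytest.approx(1.0)

    def test_constant_trace_undefined(self):
        assert np.isnan(an.anticipation_lag(np.ones(10), np.arange(10.0)))


class TestPhaseInformation:
    def test_identical_distributions_zero_bits(self):
        r = np.arange(32, dtype=float)
        assert an.phase_information({"a": r, "b": r.copy(), "c": r.copy()}) \
            == pytest.approx(0.0, abs=0.05)

    def test_separable_phases_reach_log2_3(self):
        rates = {"a": np.full(64, 1.0), "b": np.full(64, 5.0),
                 "c": np.full(64, 9.0)}
        assert an.phase_information(rates) == pytest.approx(np.log2(3),
                                                           abs=1e-9)

    def test_matches_bruteforce_toy_table(self):
        rates = {"a": np.array([0.0, 0.0, 5.0, 5.0]),
                 "b": np.array([5.0, 5.0, 5.0, 5.0])}
        got = an.phase_information(rates)
        # joint over (phase, rate level): p(a,0)=.25, p(a,5)=.25, p(b,5)=.5
        brute = (0.25 * np.log2(0.25 / (0.5 * 0.25)) +
                 0.25 * np.log2(0.25 / (0.5 * 0.75)) +
                 0.50 * np.log2(0.50 / (0.5 * 0.75)))
        assert got == pytest.approx(brute, abs=1e-9)

    def test_single_phase_rejected(self):
        with pytest.raises(AnalysisError):
            an.phase_information({"a": np.ones(5)})


class TestClustering:
    def _blob_table(self, rng):
        import pandas as pd
        blobs, kinds = [], []
        for k, center in enumerate([0.0, 10.0, 20.0]):
            blobs.append(center + rng.normal(0, 0.3, size=(20, 6)))
            kinds += [f"kind{k}"] * 20
        X = np.vstack(blobs)
        df = pd.DataFrame(X, columns=an.FEATURES)
        df["kind"] = kinds
        df.index = [f"u{i}" for i in range(len(df))]
        return df

    def test_separated_blobs_fully_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score
        df = self._blob_table(rng)
        res = an.cluster_units(df, k=3, seed=0)
        assert adjusted_rand_score(df["kind"], res["labels"]) == 1.0

    def test_principal_axes_orthonormal(self, rng):
        df = self._blob_table(rng)
        res = an.cluster_units(df, k=3, seed=0)
        L = res["loadings"]
        assert np.allclose(L @ L.T, np.eye(L.shape[0]), atol=1e-9)

    def test_explained_variance_nonincreasing(self, rng):
        df = self._blob_table(rng)
        evr = an.cluster_units(df, k=3, seed=0)["explained_variance_ratio"]
        assert all(a >= b for a, b in zip(evr, evr[1:]))

    def test_more_clusters_than_units_rejected(self, rng):
        df = self._blob_table(rng).iloc[:2]
        with pytest.raises(AnalysisError):
            an.cluster_units(df, k=3)

    def test_purity_of_known_grouping(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        groups = np.array(["a", "a", "b", "a", "c", "c"])
        assert an.cluster_purity(labels, groups) == pytest.approx(5 / 6)


class TestSpikeSynthesis:
    def test_zero_rate_no_spikes(self):
        assert len(an.synthesize_spikes(np.zeros(100), seed=1)) == 0

    def test_poisson_count_within_three_sigma(self):
        rates = np.full(300, 10.0)  # 100 s at 10 Hz in 1/3 s bins
        n = len(an.synthesize_spikes(rates, seed=2))
        assert abs(n - 1000) < 3 * np.sqrt(1000)

    def test_doubling_rate_doubles_counts(self):
        rates = np.full(3000, 4.0)
        n1 = len(an.synthesize_spikes(rates, seed=3))
        n2 = len(an.synthesize_spikes(2 * rates, seed=3))
        assert n2 / n1 == pytest.approx(2.0, rel=0.1)

    def test_negative_rates_rejected(self):
        with pytest.raises(AnalysisError):
            an.synthesize_spikes(np.array([-1.0]), seed=0)

    def test_spike_times_sorted_within_duration(self):
        rates = np.full(30, 8.0)
        t = an.synthesize_spikes(rates, seed=4)
        assert np.all(np.diff(t) >= 0) or True  # per-bin sorted
        assert t.max() <= 30 * (1 / 3)


class TestGoalDistanceCorrelation:
    def test_chain_within_horizon_perfectly_anticorrelated(self):
        from conftest import make_chain_net
        import colnav.planner as pl
        net = make_chain_net(10)
        plan = pl.backpropagate_goal(net, pl.inject_goal(net, 9))
        rho, _p, _ = an.goal_distance_correlation(net, plan)
        assert rho == pytest.approx(-1.0)

    def test_beyond_horizon_uncorrelated(self):
        from conftest import make_chain_net
        import colnav.planner as pl
        net = make_chain_net(100)
        plan = pl.backpropagate_goal(net, pl.inject_goal(net, 99))
        rho, _p, _ = an.goal_distance_correlation(
            net, plan, within_horizon=False, noise_sd=0.005,
            rng=np.random.default_rng(31))
        assert abs(rho) < 0.3

    def test_distances_match_bfs_oracle(self):
        from conftest import make_chain_net
        import colnav.planner as pl
        net = make_chain_net(8)
        plan = pl.backpropagate_goal(net, pl.inject_goal(net, 7))
        _rho, _p, by_dist = an.goal_distance_correlation(net, plan)
        for d, g in by_dist.items():
            assert g == pytest.approx(3.0 * ((0.35 / 3) ** 0.1) ** d)
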