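"""Dispersion statistic, adaptive stopping rule, and the firefly swarm."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fssmr.fss import (
    EarlyStopState,
    Firefly,
    SwarmConfig,
    compute_threshold,
    firefly_step,
    loss_stddev,
    optimize,
    should_stop,
    update_attractiveness,
    update_threshold,
)


class TestLossStddev:
    def test_constant_series_is_zero(self):
        assert loss_stddev([0.5, 0.5, 0.5], 3) == 0.0

    def test_population_sd_by_hand(self):
        assert loss_stddev([0.0, 2.0], 2) == pytest.approx(1.0)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_two_pass_oracle(self, values):
        w = len(values)
        mean = sum(values) / w
        want = (sum((v - mean) ** 2 for v in values) / w) ** 0.5
        assert loss_stddev(values, w) == pytest.approx(want, abs=1e-12)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            loss_stddev([1.0], 0)
        with pytest.raises(ValueError):
            loss_stddev([1.0], 2)


class TestThreshold:
    def test_product(self):
        s = EarlyStopState(sigma_mult=2.0)
        assert compute_threshold(s, 0.05) == pytest.approx(0.1)
        assert compute_threshold(s, 0.0) == 0.0

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(EarlyStopState(), -0.01)

    def test_update_threshold(self):
        s = EarlyStopState(theta=0.1, eta_theta=0.5)
        update_threshold(s, 0.0)
        assert s.theta == pytest.approx(0.1)
        update_threshold(s, 0.1)
        assert s.theta == pytest.approx(0.05)
        update_threshold(s, 1e9)
        assert s.theta == 0.0  # clamps, never negative


class TestShouldStop:
    def test_improving_trace_continues(self):
        state = EarlyStopState(sigma_mult=0.1, min_delta=0.01, patience=10)
        trace = list(np.linspace(2.0, 1.0, 21))  # decrease 0.05 per epoch
        stop, reason = should_stop(state, trace)
        assert not stop and reason == "continue"

    def test_constant_trace_stops_by_patience(self):
        state = EarlyStopState(min_delta=0.01, patience=10)
        stop, reason = should_stop(state, [1.0] * 11)
        assert stop and reason == "patience"
        stop, _ = should_stop(state, [1.0] * 10)
        assert not stop

    def test_never_fires_before_patience(self):
        state = EarlyStopState(min_delta=0.01, patience=10)
        for n in range(1, 11):
            stop, _ = should_stop(state, [1.0] * n)
            assert not stop

    def test_threshold_rule_boundary_flips_when_truncated(self):
        """Decreases below theta for exactly `patience` epochs stop the run;
        one epoch fewer does not."""
        state = EarlyStopState(sigma_mult=1.0, min_delta=0.0, patience=10)
        # plateau, one big drop (a decrease well above theta), then ten
        # epochs of tiny improvement: each decrease sits below the theta
        # its own loss window implies
        prefix = [2.0] * 9 + [1.0]
        tail = [1.0 - 0.001 * k for k in range(1, 11)]
        stop, reason = should_stop(state, prefix + tail)
        assert stop and reason == "fss_threshold"
        stop, _ = should_stop(state, prefix + tail[:-1])
        assert not stop

    def test_monotone_in_sigma_mult(self):
        """Raising theta never converts a threshold-rule stop into continue."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            trace = list(np.abs(rng.normal(1, 0.5, size=15)).cumsum()[::-1])
            lo = EarlyStopState(sigma_mult=1.0, min_delta=0.0, patience=5)
            hi = EarlyStopState(sigma_mult=3.0, min_delta=0.0, patience=5)
            stop_lo, reason_lo = should_stop(lo, trace)
            stop_hi, _ = should_stop(hi, trace)
            if stop_lo and reason_lo == "fss_threshold":
                assert stop_hi


class TestAttractiveness:
    def test_examples(self):
        assert update_attractiveness(2.0, 1.0, 0.0) == pytest.approx(2.0)
        assert update_attractiveness(2.0, 0.0, 5.0) == pytest.approx(2.0)
        assert update_attractiveness(1.0, 1.0, np.log(2)) == pytest.approx(0.5)

    def test_monotone_nonincreasing_in_distance(self):
        ds = np.linspace(0, 5, 20)
        vals = [update_attractiveness(1.5, 0.7, d) for d in ds]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert all(v <= 1.5 for v in vals)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            update_attractiveness(1.0, 1.0, -0.1)


class TestFireflyStep:
    def _cfg(self, **kw):
        defaults = dict(bounds=((0.0, 10.0),), population=2, iterations=1,
                        gamma_rand=0.0, seed=0)
        defaults.update(kw)
        return SwarmConfig(**defaults)

    def test_identical_positions_no_movement(self):
        cfg = self._cfg()
        rng = np.random.default_rng(0)
        swarm = [Firefly(np.array([4.0]), 1.0), Firefly(np.array([4.0]), 1.0)]
        firefly_step(swarm, cfg, rng, lambda x: 1.0)
        assert all(f.position[0] == 4.0 for f in swarm)

    def test_dimmer_approaches_brighter(self):
        cfg = self._cfg(beta=0.5)
        rng = np.random.default_rng(0)
        obj = lambda x: (x[0] - 2.0) ** 2
        swarm = [Firefly(np.array([2.0]), obj([2.0])),
                 Firefly(np.array([6.0]), obj([6.0]))]
        d0 = abs(swarm[1].position[0] - swarm[0].position[0])
        firefly_step(swarm, cfg, rng, obj)
        d1 = abs(swarm[1].position[0] - swarm[0].position[0])
        assert d1 < d0

    def test_fixed_seed_bit_identical(self):
        def run():
            cfg = self._cfg(gamma_rand=0.4, population=5)
            rng = np.random.default_rng(7)
            obj = lambda x: (x[0] - 3.0) ** 2
            swarm = [Firefly(np.array([float(i)]), obj([float(i)]))
                     for i in range(5)]
            for _ in range(3):
                firefly_step(swarm, cfg, rng, obj)
            return [f.position.copy() for f in swarm]

        a, b = run(), run()
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_empty_swarm_rejected(self):
        with pytest.raises(ValueError):
            firefly_step([], self._cfg(), np.random.default_rng(0), lambda x: 0.0)


class TestOptimize:
    def test_convex_toy_problem(self):
        cfg = SwarmConfig(bounds=((0.0, 10.0),), population=15, iterations=50,
                          seed=42)
        res = optimize(lambda x: (x[0] - 3.0) ** 2, cfg)
        assert abs(res["best_position"][0] - 3.0) < 0.1

    def test_constant_objective(self):
        cfg = SwarmConfig(bounds=((0.0, 1.0),), population=4, iterations=5, seed=0)
        res = optimize(lambda x: 2.5, cfg)
        assert res["best_value"] == 2.5

    def test_best_so_far_monotone(self):
        cfg = SwarmConfig(bounds=((-5.0, 5.0), (-5.0, 5.0)), population=8,
                          iterations=20, seed=3)
        res = optimize(lambda x: float(np.sum(np.abs(x))), cfg)
        vals = [r["best_value"] for r in res["trace"]]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_nonfinite_objective_penalized(self):
        cfg = SwarmConfig(bounds=((0.0, 1.0),), population=4, iterations=5, seed=1)
        res = optimize(lambda x: np.nan if x[0] > 0.5 else x[0], cfg)
        assert np.isfinite(res["best_value"])

    @pytest.mark.parametrize("dim", [2, 3])
    def test_separable_convex_within_two_percent_of_diameter(self, dim):
        """Lands within 2% of the box diameter of the optimum for >= 9/10 seeds."""
        bounds = tuple((0.0, 10.0) for _ in range(dim))
        center = np.full(dim, 3.0)
        diameter = np.sqrt(dim) * 10.0
        hits = 0
        for seed in range(10):
            cfg = SwarmConfig(bounds=bounds, population=15, iterations=50,
                              seed=seed)
            res = optimize(lambda x: float(np.sum((x - center) ** 2)), cfg)
            if np.linalg.norm(res["best_position"] - center) < 0.02 * diameter:
                hits += 1
        assert hits >= 9
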