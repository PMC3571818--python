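"""Martingale detector: strangeness, p-values, updates, null calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirview import martingale as mg
from pirview import sensor_sim as sim
from pirview import virtual_camera as vc


class TestStrangeness:
    def test_single_point_is_its_own_mean(self):
        assert mg.strangeness(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_identical_points_have_zero_strangeness(self):
        pts = np.tile([0.3, 0.7], (10, 1))
        assert mg.strangeness(pts) == pytest.approx(0.0, abs=1e-12)

    def test_empty_history_defined_as_zero(self):
        assert mg.strangeness(np.empty((0, 20))) == 0.0

    def test_matches_mean_then_distance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(120):
            pts = rng.normal(size=(rng.integers(1, 8), 5))
            expect = np.sqrt(((pts[-1] - pts.mean(axis=0)) ** 2).sum())
            assert mg.strangeness(pts) == pytest.approx(expect)


class TestPhat:
    def test_all_ties_give_theta(self):
        assert mg.phat([1.0] * 10, theta=0.5) == pytest.approx(0.5)

    def test_strict_maximum_gives_theta_over_t(self):
        svals = [0.1, 0.2, 0.3, 0.9]
        assert mg.phat(svals, theta=0.25) == pytest.approx(0.25 / 4)

    @settings(deadline=None, max_examples=120, derandomize=True)
    @given(
        st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.7]), min_size=1, max_size=30),
        st.floats(0.0, 1.0),
    )
    def test_matches_counting_oracle_with_ties(self, svals, theta):
        cur = svals[-1]
        greater = sum(v > cur for v in svals)
        equal = sum(v == cur for v in svals)
        expect = (greater + theta * equal) / len(svals)
        assert mg.phat(svals, theta) == pytest.approx(expect)

    def test_theta_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            mg.phat([0.1], theta=1.5)


class TestMartingaleUpdate:
    def test_initial_value_is_one(self):
        det = mg.MartingaleDetector(seed=0)
        assert det.martingale == 1.0

    def test_epsilon_one_freezes_the_martingale(self):
        m = 1.0
        for q in [0.01, 0.5, 0.99]:
            m = mg.martingale_update(m, q, epsilon=1.0)
        assert m == pytest.approx(1.0)

    def test_incremental_equals_full_product(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            qs = 1.0 - rng.random(10)
            m = 1.0
            for q in qs:
                m = mg.martingale_update(m, q, 0.92)
            full = np.prod(0.92 * qs ** (0.92 - 1.0))
            assert m == pytest.approx(full, rel=1e-9)

    def test_qhat_zero_rejected(self):
        with pytest.raises(ValueError, match="qhat"):
            mg.martingale_update(1.0, 0.0)


class TestDetect:
    def test_constant_zero_stream_is_exactly_the_exchangeable_null(self):
        # all strangeness values tie at zero, so qhat = theta is uniform:
        # the martingale path coincides with the closed-form null walk and
        # the alarm rate is governed by the Doob bound alone
        vectors = np.zeros((400, 20))
        _, trace = mg.detect(vectors, lam=1e15, seed=0)
        assert trace["s_t"].abs().max() == 0.0
        np.testing.assert_allclose(trace["qhat"], 1.0 - np.random.default_rng(0).random(400))
        null_path = mg.power_martingale_paths(1, 400, 0.92, np.random.default_rng(0))
        np.testing.assert_allclose(np.log(trace["M"]), null_path[0], rtol=1e-9)

    def test_deterministic_given_seed(self, walk_fall_stream):
        series = vc.pixelize_stream(walk_fall_stream, "trailing")
        v = series.values[::4]
        a = mg.detect(v, lam=15, seed=9)
        b = mg.detect(v, lam=15, seed=9)
        assert [e.t for e in a[0]] == [e.t for e in b[0]]
        assert a[1].equals(b[1])

    def test_trace_martingale_incremental_product_equivalence(self):
        rng = np.random.default_rng(2)
        vectors = rng.random((120, 20))
        _, trace = mg.detect(vectors, lam=1e12, seed=3)
        # no resets at this lambda: M must equal the full product of steps
        full = np.cumprod(0.92 * trace["qhat"].to_numpy() ** (0.92 - 1.0))
        np.testing.assert_allclose(trace["M"].to_numpy(), full, rtol=1e-8)

    def test_reset_makes_state_equal_to_fresh_detector(self):
        rng = np.random.default_rng(4)
        pre = rng.random((50, 20))
        spike = np.ones((30, 20)) * 10  # force a detection
        post = rng.random((60, 20))
        det = mg.MartingaleDetector(lam=5.0, seed=11)
        t_reset = None
        for x in np.vstack([pre, spike]):
            rec = det.step(x)
            if rec.detected:
                t_reset = rec.t
                break
        assert t_reset is not None
        recs_after = [det.step(x) for x in post]
        # replay on a fresh detector whose theta stream is aligned
        fresh = mg.MartingaleDetector(lam=5.0, seed=11)
        for _ in range(t_reset):
            fresh._rng.random()
        recs_fresh = [fresh.step(x) for x in post]
        for a, b in zip(recs_after, recs_fresh):
            assert a.strangeness == pytest.approx(b.strangeness)
            assert a.qhat == pytest.approx(b.qhat)
            assert a.martingale == pytest.approx(b.martingale)

    def test_warmup_withholds_alarms_but_collects_history(self):
        rng = np.random.default_rng(5)
        vectors = np.vstack([rng.random((40, 20)), np.ones((20, 20)) * 5])
        armed, _ = mg.detect(vectors, lam=2.0, seed=6, warmup=0)
        unarmed, _ = mg.detect(vectors, lam=2.0, seed=6, warmup=len(vectors))
        assert len(armed) > 0
        assert unarmed == []


class TestNullCalibration:
    """Exchangeable no-change behaviour of the randomized power martingale."""

    def test_monte_carlo_mean_of_M100_is_one(self):
        # E(M_n) = E(M_0) = 1 under uniform p-values
        rng = np.random.default_rng(123)
        logm = mg.power_martingale_paths(10_000, 100, 0.92, rng)
        m100 = np.exp(logm[:, -1])
        se = m100.std(ddof=1) / math.sqrt(len(m100))
        assert abs(m100.mean() - 1.0) <= 3 * se

    @pytest.mark.parametrize("lam", [4.0, 10.0, 20.0])
    def test_doob_maximal_inequality_on_uniform_pvalues(self, lam):
        rng = np.random.default_rng(321)
        logm = mg.power_martingale_paths(2000, 400, 0.92, rng)
        frac = float((logm.max(axis=1) >= math.log(lam)).mean())
        bound = 1.0 / lam
        se = math.sqrt(bound * (1 - bound) / 2000)
        assert frac <= bound + 3 * se

    def test_doob_bound_holds_for_full_detector_on_noise_frames(self, grid):
        # end-to-end: raw exchangeable binary frames through the detector
        crossed = 0
        lam = 10.0
        n_runs = 150
        for s in range(n_runs):
            stream = sim.simulate_null(grid, 250, 20, p=0.05, seed=s)
            _, trace = mg.detect(stream.flat.astype(float), lam=1e15, seed=1000 + s)
            crossed += bool((trace["M"] >= lam).any())
        bound = 1.0 / lam
        se = math.sqrt(bound * (1 - bound) / n_runs)
        assert crossed / n_runs <= bound + 3 * se
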