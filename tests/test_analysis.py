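"""Population traces, burst detection, MPC, dW summaries, lin-log scale."""

import numpy as np
import pytest

from achnet.analysis import (BurstTrain, population_trace, detect_bursts,
                             directional_mpc, mean_phase_coherence,
                             median_volley_lag, weight_change,
                             linlog_display, bursting_frequency,
                             module_burst_train)
from achnet.experiments import VolleyFixtureSpec, generate_volley_fixture


def mpc_literal(top: np.ndarray, bottom: np.ndarray) -> float:
    """Independent transcription of the phase-coherence formula.

    For each burst k of the top train, the phase of the bottom burst
    falling in [t_top,k, t_top,k+1) relative to that interval; modulus of
    the phasor mean.
    """
    phasors = []
    for k in range(len(top) - 1):
        in_interval = [tb for tb in bottom if top[k] <= tb < top[k + 1]]
        if in_interval:
            phi = 2 * np.pi * (in_interval[0] - top[k]) / (top[k + 1] - top[k])
            phasors.append(complex(np.cos(phi), np.sin(phi)))
    if not phasors:
        return float("nan")
    return abs(sum(phasors) / len(phasors))


class TestPopulationTrace:
    def test_no_spikes_all_zero(self):
        t, tr = population_trace([], 100.0)
        assert np.all(tr == 0.0)

    def test_single_spike_peak_location(self):
        t, tr = population_trace([100.0], 200.0)
        assert t[np.argmax(tr)] == pytest.approx(100.0, abs=0.1)
        assert tr.max() == pytest.approx(1.0, rel=1e-6)

    def test_synchronous_spikes_scale_linearly(self):
        t, tr1 = population_trace([50.0], 100.0)
        t, trN = population_trace([50.0] * 400, 100.0)
        assert trN.max() == pytest.approx(400 * tr1.max(), rel=1e-9)

    def test_integral_equals_count_times_gaussian_mass(self):
        spikes = [20.0, 40.0, 60.0, 80.0]
        t, tr = population_trace(spikes, 100.0)
        integral = np.trapezoid(tr, t)
        assert integral == pytest.approx(len(spikes) * 1.0 * np.sqrt(2 * np.pi),
                                         rel=1e-3)


class TestDetectBursts:
    def test_three_ideal_volleys(self):
        spikes = np.concatenate([np.full(400, t) for t in (100., 200., 300.)])
        t, tr = population_trace(spikes, 400.0)
        bt = detect_bursts(t, tr, 0.1 * 400)
        np.testing.assert_allclose(bt.times, [100.0, 200.0, 300.0], atol=0.1)

    def test_flat_trace_empty(self):
        t = np.arange(0, 100, 0.1)
        bt = detect_bursts(t, np.zeros_like(t), 1.0)
        assert len(bt) == 0

    def test_jittered_volleys_recovered_within_2ms(self):
        """Fixture suite: >=95% of half-participation volleys recovered."""
        hits = total = 0
        for seed in range(20):
            spec = VolleyFixtureSpec(participation=0.5, jitter_sd=2.0,
                                     seed=seed)
            fx = generate_volley_fixture(spec)
            bt = module_burst_train(fx[1][1], 1000.0)
            for tv in fx["truth"][1]:
                total += 1
                if np.any(np.abs(bt.times - tv) <= 2.0):
                    hits += 1
        assert hits / total >= 0.95

    def test_burst_times_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            BurstTrain(np.array([10.0, 10.0, 20.0]))


class TestMPC:
    def test_constant_lag_gives_unity(self):
        a = BurstTrain(np.arange(0.0, 1000.0, 25.0))
        b = BurstTrain(np.arange(0.0, 1000.0, 25.0) + 7.0)
        assert mean_phase_coherence(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_phase_null_is_small(self, rng):
        n = 10_000
        ref = np.arange(n + 1, dtype=float) * 100.0
        other = ref[:-1] + rng.uniform(0.0, 100.0, size=n)
        mpc = directional_mpc(BurstTrain(ref), BurstTrain(np.sort(other)))
        assert mpc < 0.02

    def test_hand_built_example_matches_literal_formula(self):
        top = np.array([0.0, 100.0, 210.0, 330.0])
        bottom = np.array([30.0, 160.0, 240.0, 380.0])
        assert directional_mpc(BurstTrain(top), BurstTrain(bottom)) == \
            pytest.approx(mpc_literal(top, bottom), rel=1e-12)
        sym = 0.5 * (mpc_literal(top, bottom) + mpc_literal(bottom, top))
        assert mean_phase_coherence(BurstTrain(top), BurstTrain(bottom)) == \
            pytest.approx(sym, rel=1e-12)

    def test_global_time_shift_invariance(self):
        a = BurstTrain([10.0, 40.0, 90.0, 130.0])
        b = BurstTrain([22.0, 55.0, 101.0, 148.0])
        shifted = mean_phase_coherence(BurstTrain(a.times + 500.0),
                                       BurstTrain(b.times + 500.0))
        assert shifted == pytest.approx(mean_phase_coherence(a, b), rel=1e-12)

    def test_empty_train_flagged(self):
        assert np.isnan(mean_phase_coherence(BurstTrain([]),
                                             BurstTrain([1.0, 2.0])))

    def test_range(self, rng):
        for _ in range(20):
            a = np.sort(rng.uniform(0, 1000, size=12))
            b = np.sort(rng.uniform(0, 1000, size=12))
            if np.any(np.diff(a) <= 0) or np.any(np.diff(b) <= 0):
                continue
            m = mean_phase_coherence(BurstTrain(a), BurstTrain(b))
            assert np.isnan(m) or 0.0 <= m <= 1.0


class TestWeightChange:
    def test_identity_gives_zero(self, rng):
        w = rng.uniform(0.001, 0.01, size=(4, 4))
        mask = np.ones((4, 4), dtype=bool)
        wc = weight_change(w, w, mask)
        assert np.all(wc.delta_pct[mask] == 0.0)
        assert wc.module_average == 0.0

    @pytest.mark.parametrize("w_f,expected", [(0.01, 100.0), (0.0, -100.0)])
    def test_doubling_and_vanishing(self, w_f, expected):
        w_i = np.array([[0.005]])
        mask = np.ones((1, 1), dtype=bool)
        wc = weight_change(w_i, np.array([[w_f]]), mask)
        assert wc.delta_pct[0, 0] == expected

    def test_per_cell_aggregates_to_module_average(self, rng):
        mask = rng.random((50, 50)) < 0.3
        mask[0, :] = True   # ensure every column has an edge
        w_i = np.where(mask, 0.005, 0.0)
        w_f = np.where(mask, rng.uniform(0.0, 0.01, size=mask.shape), 0.0)
        wc = weight_change(w_i, w_f, mask)
        in_deg = mask.sum(axis=0)
        weighted = np.nansum(wc.per_cell_incoming * in_deg) / in_deg.sum()
        # equal-weight mean over cells is the reported statistic; the
        # in-degree-weighted mean must equal the plain edge mean
        assert weighted == pytest.approx(np.nanmean(wc.delta_pct), rel=1e-9)

    def test_zero_initial_weight_rejected(self):
        mask = np.ones((1, 1), dtype=bool)
        with pytest.raises(ValueError):
            weight_change(np.zeros((1, 1)), np.ones((1, 1)), mask)


class TestLinLog:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.0), (2.0, 2.0), (-2.0, -2.0), (20.0, 3.0), (-20.0, -3.0),
        (100.0, 2.0 + np.log10(50.0)),
    ])
    def test_anchor_points(self, x, expected):
        assert linlog_display(x) == pytest.approx(expected, rel=1e-12)

    def test_odd_and_monotone(self):
        x = np.linspace(-100.0, 100.0, 2001)
        y = linlog_display(x)
        np.testing.assert_allclose(y, -linlog_display(-x), atol=1e-12)
        assert np.all(np.diff(y) > 0)

    def test_continuous_at_junction(self):
        eps = 1e-9
        assert linlog_display(2.0 + eps) == pytest.approx(2.0, abs=1e-6)


class TestBurstingFrequency:
    def test_regular_40hz(self):
        bt = BurstTrain(np.arange(0.0, 5000.0, 25.0))
        assert bursting_frequency(bt) == pytest.approx(40.0)

    def test_two_bursts_one_second_apart(self):
        assert bursting_frequency(BurstTrain([0.0, 1000.0])) == 1.0

    def test_single_burst_flagged(self):
        assert np.isnan(bursting_frequency(BurstTrain([100.0])))

    def test_jittered_fixture_recovered_within_2pct(self):
        spec = VolleyFixtureSpec(
            volley_times=tuple(np.arange(100.0, 4000.0, 40.0)),
            participation=0.8, jitter_sd=1.5, seed=5)
        fx = generate_volley_fixture(spec)
        bt = module_burst_train(fx[1][1], 4000.0)
        assert bursting_frequency(bt) == pytest.approx(25.0, rel=0.02)


class TestVolleyLag:
    def test_constant_lag_recovered(self):
        fx = generate_volley_fixture(VolleyFixtureSpec(lag=5.0))
        bt1 = module_burst_train(fx[1][1], 1100.0)
        bt2 = module_burst_train(fx[2][1], 1100.0)
        assert median_volley_lag(bt1, bt2) == pytest.approx(5.0, abs=0.2)
        assert mean_phase_coherence(bt1, bt2) == pytest.approx(1.0, abs=1e-6)
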