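"""Engine behavior: determinism, bounds, quiescence, plasticity toggles."""

import numpy as np
import pytest

from achnet.engine import (SimulationConfig, run_simulation, run_trials,
                           SimulationError, DISPLAY_INDEX,
                           MODULE1_E, MODULE2_E)
from achnet.synapses import NoiseParams


def short_config(**kw):
    defaults = dict(duration=400.0, seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestQuiescence:
    def test_subthreshold_network_goes_silent(self):
        # DC below rheobase at gKs = 1.5: after the initial-condition
        # transient settles, the network is permanently quiescent
        cfg = short_config(gks={1: 1.5, 2: 1.5}, dc={1: 0.5, 2: 0.5})
        res = run_simulation(cfg)
        assert not np.any(res.spike_times > 100.0)

    def test_no_drive_no_nans(self):
        cfg = short_config(gks={1: 1.5, 2: 1.5}, dc={1: 0.0, 2: 0.0},
                           duration=1000.0)
        res = run_simulation(cfg)
        assert np.all(np.isfinite(res.population_trace[1]))
        assert np.all(np.isfinite(res.population_trace[2]))


class TestPlasticityToggle:
    def test_stdp_off_freezes_weights(self):
        cfg = short_config(stdp_enabled=False, dc={1: 3.0, 2: 2.0})
        res = run_simulation(cfg)
        assert len(res.spike_times) > 100   # network is active
        np.testing.assert_array_equal(res.wiring_final.w_1to2,
                                      res.wiring_initial.w_1to2)
        np.testing.assert_array_equal(res.wiring_final.w_2to1,
                                      res.wiring_initial.w_2to1)

    def test_weights_stay_in_bounds_with_stdp(self):
        cfg = short_config(dc={1: 3.0, 2: 2.0}, duration=600.0)
        res = run_simulation(cfg)
        for w in (res.wiring_final.w_1to2, res.wiring_final.w_2to1):
            assert w.min() >= 0.0
            assert w.max() <= 0.01 + 1e-15

    def test_unwired_edges_never_gain_weight(self):
        cfg = short_config(dc={1: 3.0, 2: 2.0}, duration=600.0)
        res = run_simulation(cfg)
        assert np.all(res.wiring_final.w_1to2[~res.wiring_final.mask_1to2]
                      == 0.0)


class TestDeterminism:
    def test_identical_seed_bitwise_identical(self):
        cfg = short_config(dc={1: 3.0, 2: 2.0},
                           noise=NoiseParams(rate=5.0), duration=500.0)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        np.testing.assert_array_equal(a.spike_times, b.spike_times)
        np.testing.assert_array_equal(a.spike_cells, b.spike_cells)
        np.testing.assert_array_equal(a.wiring_final.w_1to2,
                                      b.wiring_final.w_1to2)

    def test_different_trial_indices_differ(self):
        cfg = short_config(dc={1: 3.0, 2: 2.0}, duration=500.0)
        a = run_simulation(cfg, trial_index=0)
        b = run_simulation(cfg, trial_index=1)
        assert len(a.spike_times) != len(b.spike_times) or \
            not np.array_equal(a.spike_times, b.spike_times)


class TestGammaRhythm:
    def test_reference_module_produces_periodic_gamma_volleys(self):
        """An isolated module at gKs=0.6, DC=2.0 PINGs rhythmically.

        The population volleys are periodic and gamma-band, and across any
        150 ms stretch they recruit over 90% of the module's E cells
        (individual volleys rotate through sub-clusters of the module, so
        every cell takes part within a few cycles).
        """
        from achnet import analysis
        from achnet.maps import homogeneous_map

        cfg = SimulationConfig(
            gks={1: 0.6, 2: 1.5}, dc={1: 2.0, 2: 0.0},
            stdp_enabled=False, duration=1200.0, seed=3)
        res = run_simulation(cfg)
        cells, ts = res.module_e_spikes(1)
        bt = analysis.module_burst_train(ts, cfg.duration)
        settled = bt.times[bt.times > 300.0]
        assert len(settled) > 10
        intervals = np.diff(settled)
        assert intervals.std() / intervals.mean() < 0.2   # periodic
        freq = analysis.bursting_frequency(analysis.BurstTrain(settled))
        assert 20.0 <= freq <= 60.0                        # gamma band
        for t_lo in np.arange(300.0, 1050.0, 50.0):
            sel = (ts >= t_lo) & (ts < t_lo + 150.0)
            assert len(np.unique(cells[sel])) >= 0.9 * 400


class TestTrials:
    def test_single_trial_average_equals_trial(self):
        cfg = short_config(dc={1: 3.0, 2: 2.0}, n_trials=1, duration=400.0)
        s = run_trials(cfg)
        assert s.mean_dw_into_module2 == s.dw_into_module2[0]
        assert s.se_dw_into_module2 == 0.0

    def test_multi_trial_se_finite(self):
        cfg = short_config(dc={1: 3.0, 2: 2.0}, n_trials=2, duration=400.0)
        s = run_trials(cfg)
        assert len(s.results) == 2
        assert np.isfinite(s.se_dw_into_module2)
        assert np.isfinite(s.se_dw_into_module1)


class TestRecords:
    def test_spike_times_within_horizon(self):
        cfg = short_config(dc={1: 3.0, 2: 2.0})
        res = run_simulation(cfg)
        assert np.all(res.spike_times >= 0.0)
        # step times accumulate dt, so allow float round-off at the end
        assert np.all(res.spike_times <= cfg.duration + 1e-6)

    def test_display_index_layout(self):
        # module 2 E cells occupy display 1-400, module 1 E cells 501-900
        assert DISPLAY_INDEX[0] == 501
        assert DISPLAY_INDEX[499] == 1000
        assert DISPLAY_INDEX[500] == 1
        assert DISPLAY_INDEX[999] == 500

    def test_snapshots_recorded(self):
        cfg = short_config(dc={1: 3.0, 2: 2.0}, duration=300.0,
                           weight_snapshot_interval=100.0)
        res = run_simulation(cfg)
        times = [t for t, *_ in res.weight_snapshots]
        assert times[0] == 0.0
        assert len(times) >= 3

    def test_instability_guard_raises(self):
        # a coarse step with strong drive makes RK4 blow up; the guard
        # must abort with a diagnostic instead of returning NaNs
        cfg = short_config(dc={1: 50.0, 2: 50.0}, dt=1.0, duration=100.0)
        with pytest.raises(SimulationError, match="diverged"):
            run_simulation(cfg)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            run_simulation(short_config(method="verlet"))
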