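"""Case registry, sweeps and the synthetic volley fixture generator."""

import numpy as np
import pytest

from achnet import analysis
from achnet.experiments import (CASES, BINDING_CASES, case_config,
                                run_example, SweepSpec, run_sweep,
                                VolleyFixtureSpec, generate_volley_fixture)


# Independent transcription of the case parameters (module-1 gKs mS/cm^2,
# DC uA/cm^2, module-2 preset, wiring) against which the registry is checked.
CASE_TABLE = {
    "E": (0.3, 0.5, "homogeneous_reference", "random", 40),
    "F": (0.6, 3.0, "homogeneous_reference", "random", 40),
    "G": (1.2, 2.0, "homogeneous_reference", "random", 40),
    "H": (1.2, 3.5, "homogeneous_reference", "random", 40),
    "ach_low": (0.2, 2.0, "homogeneous_reference", "random", 40),
    "ach_matched": (0.6, 2.0, "homogeneous_reference", "random", 40),
    "ach_high": (1.1, 2.0, "homogeneous_reference", "random", 40),
    "hotspot_moderate_a": (0.9, 1.5, "hotspot_moderate", "random", 40),
    "hotspot_moderate_b": (0.3, 3.5, "hotspot_moderate", "random", 40),
    "hotspot_moderate_c": (0.9, 3.5, "hotspot_moderate", "random", 40),
    "hotspot_strong_a": (0.6, 1.5, "hotspot_strong", "random", 40),
    "hotspot_strong_b": (0.0, 3.5, "hotspot_strong", "random", 40),
    "hotspot_strong_c": (1.2, 3.0, "hotspot_strong", "random", 40),
    "hotspot_topo_a": (0.9, 1.0, "hotspot_strong", "topographic", 5),
    "hotspot_topo_b": (0.3, 3.0, "hotspot_strong", "topographic", 5),
    "hotspot_topo_c": (1.5, 2.5, "hotspot_strong", "topographic", 5),
}


class TestCaseRegistry:
    def test_registry_matches_reference_table(self):
        assert set(CASES) == set(CASE_TABLE)
        for name, (gks1, dc1, m2, mode, k) in CASE_TABLE.items():
            c = CASES[name]
            assert c["m1_gks"] == gks1, name
            assert c["m1_dc"] == dc1, name
            assert c["m2_preset"] == m2, name
            assert c["mode"] == mode, name
            assert c["in_degree"] == k, name

    def test_case_config_resolves_maps(self):
        cfg = case_config("F", noise_rate=5.0)
        gks, dc = cfg.resolved_maps()
        assert np.all(gks[1].e_values == 0.6)
        assert np.all(dc[1].e_values == 3.0)
        assert np.all(gks[2].e_values == 0.6)
        assert np.all(dc[2].e_values == 2.0)
        assert cfg.noise.rate == 5.0

    def test_binding_cases_are_topographic_sparse(self):
        for name in BINDING_CASES:
            cfg = case_config(name)
            assert cfg.intermodule_mode == "topographic"
            assert cfg.intermodule_in_degree == 5
            gks, dc = cfg.resolved_maps()
            assert np.all(dc[1].e_values == 3.0)
            assert gks[1].e_values.min() < 0.3
            assert gks[1].e_values.max() > 1.4

    def test_unknown_case_rejected(self):
        with pytest.raises(KeyError):
            case_config("Z")


class TestVolleyFixture:
    def test_ideal_volleys_exact(self):
        fx = generate_volley_fixture(VolleyFixtureSpec(
            n_cells=50, volley_times=(100.0, 200.0), participation=1.0,
            jitter_sd=0.0))
        cells, times = fx[1]
        assert len(times) == 100
        assert set(np.unique(times)) == {100.0, 200.0}
        assert np.all(np.bincount(cells, minlength=50) == 2)

    def test_participation_subsampling(self):
        fx = generate_volley_fixture(VolleyFixtureSpec(
            n_cells=400, volley_times=tuple(range(100, 2000, 100)),
            participation=0.3, seed=2))
        cells, times = fx[1]
        frac = len(times) / (400 * 19)
        assert frac == pytest.approx(0.3, abs=0.03)

    def test_lagged_modules_ground_truth(self):
        fx = generate_volley_fixture(VolleyFixtureSpec(lag=5.0))
        np.testing.assert_allclose(fx["truth"][2] - fx["truth"][1], 5.0)

    def test_noisy_fixture_recovered_by_detector(self):
        spec = VolleyFixtureSpec(participation=0.3, jitter_sd=2.0, seed=9)
        fx = generate_volley_fixture(spec)
        bt = analysis.module_burst_train(fx[1][1], 1100.0)
        for tv in fx["truth"][1]:
            assert np.min(np.abs(bt.times - tv)) <= 2.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            VolleyFixtureSpec(participation=0.0)
        with pytest.raises(ValueError):
            VolleyFixtureSpec(jitter_sd=-1.0)


@pytest.fixture(scope="module")
def example_f():
    return run_example("F", n_trials=1, duration=1500.0, seed=11)


class TestRunExample:

    def test_leader_module_potentiates_outgoing(self, example_f):
        # module 1 (higher DC) leads, so 1->2 potentiates, 2->1 depresses
        assert example_f.summary.mean_dw_into_module2 > 0
        assert example_f.summary.mean_dw_into_module1 < 0

    def test_per_cell_maps_shape(self, example_f):
        assert example_f.per_cell_dw["into_module2"].shape == (20, 20)
        assert np.isfinite(example_f.per_cell_dw["into_module2"]).all()

    def test_summary_statistics_present(self, example_f):
        assert 0.0 <= example_f.mpc <= 1.0
        assert example_f.burst_frequency[1] > 10.0


class TestSweep:
    def test_single_point_sweep_table(self):
        spec = SweepSpec(gks_values=(0.6,), dc_values=(3.0,),
                         noise_rates=(0.0,), n_trials=1, duration=1000.0,
                         seed=5)
        df = run_sweep(spec)
        assert len(df) == 1
        row = df.iloc[0]
        assert {"gks1", "dc1", "noise_rate", "dw_into_module2",
                "dw_into_module1", "mpc", "freq_diff"} <= set(df.columns)
        assert row.dw_into_module2 > 0    # module 1 more excitable
        assert row.error == ""

    def test_noise_attenuates_potentiation(self):
        """Poisson noise scales down the net inter-module weight change."""
        spec0 = SweepSpec(gks_values=(0.6,), dc_values=(3.0,),
                          noise_rates=(0.0, 10.0), n_trials=1,
                          duration=2000.0, seed=7)
        df = run_sweep(spec0)
        quiet = df[df.noise_rate == 0.0].iloc[0].dw_into_module2
        noisy = df[df.noise_rate == 10.0].iloc[0].dw_into_module2
        assert noisy < quiet

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            SweepSpec(gks_values=())
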