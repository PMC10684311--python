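"""Scripted protocols: case studies, parameter sweeps and test fixtures.

The case-study registry pins the (gKs, DC) configurations of the model's
named scenarios: homogeneous modules with mismatched excitability (cases
E-H), ACh-only mismatches, single-hotspot modules under random or
topographic coupling, and hotspot-pair binding.  Sweeps vary module 1's
gKs and DC on a grid while module 2 is held fixed, across noise rates,
and tabulate trial-averaged weight-change, phase-coherence and
volley-frequency statistics.

``generate_volley_fixture`` draws synthetic spike rasters (volleys with
known times, participation, jitter and inter-module lag) so the analysis
stack can be validated against ground truth without running the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import analysis
from .engine import SimulationConfig, run_trials, TrialSummary
from .maps import SpatialScalarMap, homogeneous_map, hotspot_map, preset
from .synapses import NoiseParams

__all__ = [
    "CASES", "case_config", "run_example",
    "SweepSpec", "run_sweep",
    "VolleyFixtureSpec", "generate_volley_fixture",
]


def _case(m1_gks, m1_dc, *, m2="homogeneous_reference", mode="random",
          in_degree=40, note=""):
    return {
        "m1_gks": m1_gks, "m1_dc": m1_dc, "m2_preset": m2,
        "mode": mode, "in_degree": in_degree, "note": note,
    }


#: Case registry: module-1 (gKs, DC) against a fixed module-2 preset.
#: All gKs in mS/cm^2, DC in uA/cm^2.
CASES: dict[str, dict] = {
    # homogeneous modules, random coupling; module 2 at gKs 0.6 / DC 2.0
    "E": _case(0.3, 0.5, note="module 1 far less excitable (low DC)"),
    "F": _case(0.6, 3.0, note="module 1 more excitable via DC"),
    "G": _case(1.2, 2.0, note="module 1 less excitable via gKs"),
    "H": _case(1.2, 3.5, note="high gKs but high DC in module 1"),
    # ACh-only mismatch: DC = 2.0 in both modules
    "ach_low": _case(0.2, 2.0, note="module 1 high ACh (low gKs)"),
    "ach_matched": _case(0.6, 2.0, note="matched excitability"),
    "ach_high": _case(1.1, 2.0, note="module 1 low ACh (high gKs)"),
    # module 2 carries a moderately modulated hotspot (random coupling)
    "hotspot_moderate_a": _case(0.9, 1.5, m2="hotspot_moderate"),
    "hotspot_moderate_b": _case(0.3, 3.5, m2="hotspot_moderate"),
    "hotspot_moderate_c": _case(0.9, 3.5, m2="hotspot_moderate"),
    # module 2 carries a strongly modulated hotspot (random coupling)
    "hotspot_strong_a": _case(0.6, 1.5, m2="hotspot_strong"),
    "hotspot_strong_b": _case(0.0, 3.5, m2="hotspot_strong"),
    "hotspot_strong_c": _case(1.2, 3.0, m2="hotspot_strong"),
    # strong hotspot with sparse topographic coupling
    "hotspot_topo_a": _case(0.9, 1.0, m2="hotspot_strong",
                            mode="topographic", in_degree=5),
    "hotspot_topo_b": _case(0.3, 3.0, m2="hotspot_strong",
                            mode="topographic", in_degree=5),
    "hotspot_topo_c": _case(1.5, 2.5, m2="hotspot_strong",
                            mode="topographic", in_degree=5),
}

#: Hotspot-pair binding scenarios: hotspots in both modules, topographic
#: sparse coupling, uniform DC 3.0, hotspot gKs 0.2 on background 1.5.
BINDING_CASES: dict[str, dict] = {
    # single aligned hotspot in each module
    "binding_aligned": {"m1": "hotspot_strong", "m2": "hotspot_strong"},
    # two hotspots in each module, both aligned across modules
    "binding_two_shared": {"m1": "two_hotspots", "m2": "two_hotspots"},
    # one hotspot each, at opposite corners (no shared connections)
    "binding_disjoint": {"m1": "hotspot_strong_offset_a",
                         "m2": "hotspot_strong_offset_b"},
    # two hotspots in module 2, one in module 1 aligned with the first
    "binding_mixed": {"m1": "hotspot_strong_offset_a", "m2": "two_hotspots"},
}


def case_config(name: str, *, noise_rate: float = 0.0,
                **config_overrides) -> SimulationConfig:
    """Build the :class:`SimulationConfig` for a registered case."""
    if name in CASES:
        c = CASES[name]
        m2 = preset(c["m2_preset"])
        cfg = SimulationConfig(
            gks={1: homogeneous_map(c["m1_gks"]), 2: m2["gks"]},
            dc={1: homogeneous_map(c["m1_dc"]), 2: m2["dc"]},
            intermodule_mode=c["mode"],
            intermodule_in_degree=c["in_degree"],
        )
    elif name in BINDING_CASES:
        c = BINDING_CASES[name]
        m1, m2 = preset(c["m1"]), preset(c["m2"])
        cfg = SimulationConfig(
            gks={1: m1["gks"], 2: m2["gks"]},
            dc={1: m1["dc"], 2: m2["dc"]},
            intermodule_mode="topographic",
            intermodule_in_degree=5,
        )
    else:
        raise KeyError(f"unknown case {name!r}; available: "
                       f"{sorted(CASES) + sorted(BINDING_CASES)}")
    cfg.noise = replace(cfg.noise, rate=noise_rate)
    return replace(cfg, **config_overrides)


@dataclass
class ExampleResult:
    """Bundle returned by :func:`run_example`."""

    name: str
    config: SimulationConfig
    summary: TrialSummary
    per_cell_dw: dict        # direction -> (20, 20) per-target-cell dW grid
    mpc: float
    burst_frequency: dict    # module -> Hz (first trial)


def run_example(name: str, *, noise_rate: float = 0.0,
                **config_overrides) -> ExampleResult:
    """Run a registered case and compute its summary statistics.

    Returns trial-averaged directional weight changes, the per-target-cell
    incoming-dW lattice maps (first trial, for hotspot-localization
    displays), the symmetrized mean phase coherence and per-module volley
    frequencies.
    """
    cfg = case_config(name, noise_rate=noise_rate, **config_overrides)
    summary = run_trials(cfg)
    res = summary.results[0]
    wc12 = analysis.weight_change(res.wiring_initial.w_1to2,
                                  res.wiring_final.w_1to2,
                                  res.wiring_initial.mask_1to2)
    wc21 = analysis.weight_change(res.wiring_initial.w_2to1,
                                  res.wiring_final.w_2to1,
                                  res.wiring_initial.mask_2to1)
    trains = {m: analysis.module_burst_train(res.module_e_spikes(m)[1],
                                             cfg.duration)
              for m in (1, 2)}
    return ExampleResult(
        name=name,
        config=cfg,
        summary=summary,
        per_cell_dw={
            "into_module2": wc12.per_cell_incoming.reshape(20, 20),
            "into_module1": wc21.per_cell_incoming.reshape(20, 20),
        },
        mpc=analysis.mean_phase_coherence(trains[1], trains[2]),
        burst_frequency={m: analysis.bursting_frequency(trains[m])
                         for m in (1, 2)},
    )


@dataclass
class SweepSpec:
    """Grid sweep of module-1 excitability against a fixed module 2.

    The default grid is deliberately coarse (a 5 x 5 reduced version of the
    full parameter plane) so a sweep completes at desk scale; pass denser
    grids for production maps.
    """

    gks_values: tuple = (0.0, 0.375, 0.75, 1.125, 1.5)
    dc_values: tuple = (0.0, 1.0, 2.0, 3.0, 4.0)
    noise_rates: tuple = (0.0,)
    module2_preset: str = "homogeneous_reference"
    mode: str = "random"
    in_degree: int = 40
    n_trials: int = 2
    duration: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gks_values or not self.dc_values:
            raise ValueError("sweep grids must be non-empty")


def run_sweep(spec: SweepSpec, *, progress: bool = False) -> pd.DataFrame:
    """Evaluate every (gKs, DC, noise) grid point and tabulate statistics.

    Returns a tidy DataFrame with one row per grid point: trial-averaged
    module-average incoming weight changes (with standard errors), the
    symmetrized MPC and the module-2 minus module-1 volley-frequency
    difference.  A grid point whose simulation diverges is recorded with
    NaN statistics and the sweep continues.
    """
    from .engine import SimulationError

    m2 = preset(spec.module2_preset)
    rows = []
    for noise_rate in spec.noise_rates:
        for gks1 in spec.gks_values:
            for dc1 in spec.dc_values:
                cfg = SimulationConfig(
                    gks={1: homogeneous_map(gks1), 2: m2["gks"]},
                    dc={1: homogeneous_map(dc1), 2: m2["dc"]},
                    intermodule_mode=spec.mode,
                    intermodule_in_degree=spec.in_degree,
                    noise=NoiseParams(rate=noise_rate),
                    n_trials=spec.n_trials,
                    duration=spec.duration,
                    seed=spec.seed,
                )
                row = {"gks1": gks1, "dc1": dc1, "noise_rate": noise_rate}
                try:
                    summary = run_trials(cfg)
                except SimulationError as exc:
                    row.update(dw_into_module2=np.nan, dw_into_module1=np.nan,
                               se_into_module2=np.nan, se_into_module1=np.nan,
                               mpc=np.nan, freq_diff=np.nan, error=str(exc))
                    rows.append(row)
                    continue
                mpcs, fdiffs = [], []
                for res in summary.results:
                    trains = {
                        m: analysis.module_burst_train(
                            res.module_e_spikes(m)[1], cfg.duration)
                        for m in (1, 2)}
                    mpcs.append(analysis.mean_phase_coherence(trains[1],
                                                              trains[2]))
                    fdiffs.append(
                        analysis.bursting_frequency(trains[2])
                        - analysis.bursting_frequency(trains[1]))
                row.update(
                    dw_into_module2=summary.mean_dw_into_module2,
                    dw_into_module1=summary.mean_dw_into_module1,
                    se_into_module2=summary.se_dw_into_module2,
                    se_into_module1=summary.se_dw_into_module1,
                    mpc=float(np.nanmean(mpcs)),
                    freq_diff=float(np.nanmean(fdiffs)),
                    error="",
                )
                rows.append(row)
                if progress:
                    print(f"gks1={gks1} dc1={dc1} noise={noise_rate}: "
                          f"dW->2={row['dw_into_module2']:+.1f}% "
                          f"dW->1={row['dw_into_module1']:+.1f}%")
    return pd.DataFrame(rows)


@dataclass
class VolleyFixtureSpec:
    """Synthetic two-module volley raster with known ground truth."""

    n_cells: int = 400
    volley_times: tuple = tuple(float(t) for t in range(100, 1000, 100))
    participation: float = 1.0
    jitter_sd: float = 0.0       # ms
    lag: float = 0.0             # ms, module-2 volleys trail module 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.participation <= 1.0):
            raise ValueError("participation must be in (0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if len(self.volley_times) == 0:
            raise ValueError("at least one volley time is required")


def generate_volley_fixture(spec: VolleyFixtureSpec) -> dict:
    """Draw spike rasters for two modules of ideal, jittered volleys.

    For each volley a Bernoulli(participation) subset of cells fires once
    at the volley time plus Gaussian jitter; module 2 repeats module 1's
    volley schedule shifted by ``spec.lag``.  Returns a dict with per-module
    ``(cells, times)`` arrays and the ground-truth volley times.
    """
    rng = np.random.default_rng(spec.seed)
    truth1 = np.asarray(spec.volley_times, dtype=float)
    truth2 = truth1 + spec.lag
    out = {"truth": {1: truth1, 2: truth2}, "spec": spec}
    for module, truth in ((1, truth1), (2, truth2)):
        cells, times = [], []
        for tv in truth:
            fire = rng.random(spec.n_cells) < spec.participation
            idx = np.nonzero(fire)[0]
            jit = rng.normal(0.0, spec.jitter_sd, size=idx.size) \
                if spec.jitter_sd > 0 else np.zeros(idx.size)
            cells.append(idx)
            times.append(tv + jit)
        cells = np.concatenate(cells)
        times = np.concatenate(times)
        order = np.argsort(times, kind="stable")
        out[module] = (cells[order], times[order])
    return out
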