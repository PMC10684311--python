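"""Time-stepped co-simulation of the two coupled E-I modules.

State for all 1,000 cells (two modules of 400 E + 100 I) advances on a
fixed grid (RK4, dt = 0.05 ms by default).  Within each step the order of
operations is: integrate membranes (synaptic conductances decaying
analytically across substeps) -> detect threshold crossings -> append to
the spike record -> deliver spikes to synaptic conductances -> apply STDP
to the inter-module weights.  All randomness (wiring, initial conditions,
noise) derives from one master seed through named substreams, so runs are
bit-reproducible.

Internal cell layout: module 1 E cells occupy indices 0-399, module 1
I cells 400-499, module 2 E cells 500-899, module 2 I cells 900-999.
Raster display indices (1-based, module 2 first) are provided alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import network as net
from .maps import SpatialScalarMap, homogeneous_map
from .neuron import NeuronParams, steady_state_gates, gate_time_constants, TAU_Z
from .stdp import STDPParams
from .synapses import NoiseParams, PoissonPulseTrains, SynapseParams

__all__ = [
    "SimulationConfig", "SimulationResult", "TrialSummary",
    "run_simulation", "run_trials", "SimulationError",
    "MODULE1_E", "MODULE1_I", "MODULE2_E", "MODULE2_I",
]

logger = logging.getLogger(__name__)

MODULE1_E = slice(0, 400)
MODULE1_I = slice(400, 500)
MODULE2_E = slice(500, 900)
MODULE2_I = slice(900, 1000)
N_CELLS = 1000

#: Abort threshold for the numerical-instability guard (mV).
V_GUARD = 200.0

SPIKE_THRESHOLD = -20.0
SPIKE_LOCKOUT = 2.0


class SimulationError(RuntimeError):
    """Raised when the integration becomes unstable (diverging voltage)."""


def _internal_to_display() -> np.ndarray:
    """Map internal cell index -> 1-based raster display index."""
    disp = np.empty(N_CELLS, dtype=np.int64)
    disp[MODULE1_E] = 501 + np.arange(400)
    disp[MODULE1_I] = 901 + np.arange(100)
    disp[MODULE2_E] = 1 + np.arange(400)
    disp[MODULE2_I] = 401 + np.arange(100)
    return disp


DISPLAY_INDEX = _internal_to_display()


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one simulation.

    Maps are per-module scalar fields (module number -> map); a plain float
    is promoted to a homogeneous map.  ``seed`` is the master seed; trial
    seeds and all internal streams derive from it deterministically.
    """

    gks: dict = field(default_factory=lambda: {1: 0.6, 2: 0.6})
    dc: dict = field(default_factory=lambda: {1: 2.0, 2: 2.0})
    intermodule_mode: str = "random"
    intermodule_in_degree: int = 40
    noise: NoiseParams = field(default_factory=NoiseParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    stdp_enabled: bool = True
    synapse: SynapseParams = field(default_factory=SynapseParams)
    dt: float = 0.05
    duration: float = 5000.0
    n_trials: int = 4
    seed: int = 0
    method: str = "rk4"
    dc_to_i_cells: bool = False   # constant drive targets E cells by default
    include_ii_self: bool = False
    share_wiring_across_trials: bool = False
    record_population_trace: bool = True
    weight_snapshot_interval: float | None = None  # ms; None = endpoints only

    def resolved_maps(self) -> tuple[dict, dict]:
        def resolve(d):
            out = {}
            for m in (1, 2):
                v = d[m]
                out[m] = v if isinstance(v, SpatialScalarMap) \
                    else homogeneous_map(float(v))
            return out
        return resolve(self.gks), resolve(self.dc)


@dataclass
class SimulationResult:
    """Spike records, initial/final plastic weights and bookkeeping."""

    spike_cells: np.ndarray       # internal indices, time order
    spike_times: np.ndarray       # ms
    wiring_initial: net.InterModuleWiring
    wiring_final: net.InterModuleWiring
    config: SimulationConfig
    seed_info: dict
    population_trace: dict | None = None   # {"t": ..., 1: V-sum, 2: V-sum}
    weight_snapshots: list | None = None   # [(t, w_1to2, w_2to1), ...]

    @property
    def spike_display_ids(self) -> np.ndarray:
        return DISPLAY_INDEX[self.spike_cells]

    def module_e_spikes(self, module: int):
        """(cell_offset, time) arrays for one module's E cells."""
        sl = MODULE1_E if module == 1 else MODULE2_E
        m = (self.spike_cells >= sl.start) & (self.spike_cells < sl.stop)
        return self.spike_cells[m] - sl.start, self.spike_times[m]


def _expand_field(emap: SpatialScalarMap, out: np.ndarray, module: int) -> None:
    e_sl = MODULE1_E if module == 1 else MODULE2_E
    i_sl = MODULE1_I if module == 1 else MODULE2_I
    out[e_sl] = emap.e_values
    out[i_sl] = emap.i_values


def _build_wiring(config: SimulationConfig, rng: np.random.Generator):
    topo1 = net.build_module(rng, include_ii_self=config.include_ii_self)
    topo2 = net.build_module(rng, include_ii_self=config.include_ii_self)
    inter = net.build_intermodule(config.intermodule_mode,
                                  config.intermodule_in_degree, rng)
    return topo1, topo2, inter


def run_simulation(config: SimulationConfig, *,
                   wiring: tuple | None = None,
                   trial_index: int = 0) -> SimulationResult:
    """Run one trial and return its full result.

    ``wiring`` (a ``(topo1, topo2, inter)`` tuple) can be injected to share
    connectivity across runs; otherwise it is drawn from the wiring
    substream of the master seed.  ``trial_index`` selects the per-trial
    substreams for initial conditions and noise.
    """
    ss = np.random.SeedSequence(config.seed)
    wiring_ss, trials_ss = ss.spawn(2)
    if wiring is None:
        wiring_rng = np.random.default_rng(
            wiring_ss if config.share_wiring_across_trials
            else wiring_ss.spawn(trial_index + 1)[trial_index])
        wiring = _build_wiring(config, wiring_rng)
    topo1, topo2, inter = wiring
    inter = inter.copy()
    w_initial = inter.copy()

    trial_ss = trials_ss.spawn(trial_index + 1)[trial_index]
    init_ss, noise_ss = trial_ss.spawn(2)
    init_rng = np.random.default_rng(init_ss)
    noise_rng = np.random.default_rng(noise_ss)

    gks_maps, dc_maps = config.resolved_maps()
    gks = np.empty(N_CELLS)
    I_drive = np.empty(N_CELLS)
    for m in (1, 2):
        _expand_field(gks_maps[m], gks, m)
        _expand_field(dc_maps[m], I_drive, m)
    if not config.dc_to_i_cells:
        I_drive[MODULE1_I] = 0.0
        I_drive[MODULE2_I] = 0.0

    p = NeuronParams(gKs=gks)
    syn = config.synapse
    stdp = config.stdp
    dt = config.dt
    n_steps = int(round(config.duration / dt))

    # --- state -----------------------------------------------------------
    V = init_rng.uniform(-70.0, -50.0, size=N_CELLS)
    _, h, n, z = steady_state_gates(V)
    h, n, z = h.copy(), n.copy(), z.copy()
    g_exc = np.zeros(N_CELLS)
    g_inh = np.zeros(N_CELLS)
    last_spike = np.full(N_CELLS, -np.inf)

    noise = PoissonPulseTrains(config.noise, N_CELLS, config.duration,
                               noise_rng)
    noise_mask = np.ones(N_CELLS)
    if config.noise.e_cells_only:
        noise_mask[:] = 0.0
        noise_mask[MODULE1_E] = 1.0
        noise_mask[MODULE2_E] = 1.0

    # transposed intra-module operators (target increments per spike vector)
    ee1_T = topo1.ee.T.tocsr()
    ei1_T = topo1.ei.T.tocsr()
    ee2_T = topo2.ee.T.tocsr()
    ei2_T = topo2.ei.T.tocsr()

    decay_half = float(np.exp(-0.5 * dt / syn.tau))
    decay_full = float(np.exp(-dt / syn.tau))
    dec_tp = float(np.exp(-dt / stdp.tau_plus))
    dec_tm = float(np.exp(-dt / stdp.tau_minus))
    tp1 = np.zeros(400)
    tm1 = np.zeros(400)
    tp2 = np.zeros(400)
    tm2 = np.zeros(400)

    gNa, gKdr, gL = p.gNa, p.gKdr, p.gL
    VNa, VK, VL = p.VNa, p.VK, p.VL
    E_inh = syn.E_inh

    def rhs(V_, h_, n_, z_, ge_, gi_, I_ext):
        m_inf, h_inf, n_inf, z_inf = steady_state_gates(V_)
        tau_h, tau_n, _ = gate_time_constants(V_)
        I_ion = (-gNa * m_inf ** 3 * h_ * (V_ - VNa)
                 - gKdr * n_ ** 4 * (V_ - VK)
                 - gks * z_ * (V_ - VK)
                 - gL * (V_ - VL))
        I_syn = ge_ * V_ + gi_ * (V_ - E_inh)
        dV = I_ion + I_ext - I_syn
        return (dV, (h_inf - h_) / tau_h, (n_inf - n_) / tau_n,
                (z_inf - z_) / TAU_Z)

    spike_cells: list[np.ndarray] = []
    spike_times: list[float] = []
    pop_trace = None
    if config.record_population_trace:
        pop_trace = {"t": np.arange(n_steps + 1) * dt,
                     1: np.empty(n_steps + 1), 2: np.empty(n_steps + 1)}
        pop_trace[1][0] = V[MODULE1_E].sum()
        pop_trace[2][0] = V[MODULE2_E].sum()
    snapshots = None
    next_snap = None
    if config.weight_snapshot_interval:
        snapshots = [(0.0, inter.w_1to2.copy(), inter.w_2to1.copy())]
        next_snap = config.weight_snapshot_interval

    A_plus, A_minus = stdp.A_plus, stdp.A_minus
    w_min, w_max = stdp.w_min, stdp.w_max
    nearest = stdp.pairing == "nearest"
    mask12, mask21 = inter.mask_1to2, inter.mask_2to1
    w12, w21 = inter.w_1to2, inter.w_2to1

    use_rk4 = config.method == "rk4"
    if config.method not in ("rk4", "exp_euler"):
        raise ValueError(f"unknown integration method {config.method!r}")

    # overflow in a diverging run is reported via the voltage guard below,
    # not as floating-point warnings
    old_err = np.seterr(over="ignore", invalid="ignore")
    try:
        for i in range(n_steps):
            t0 = i * dt
            t1 = t0 + dt
            I_ext = I_drive + noise_mask * noise.current(t0)
            V_prev = V

            if use_rk4:
                k1 = rhs(V, h, n, z, g_exc, g_inh, I_ext)
                ge_h, gi_h = g_exc * decay_half, g_inh * decay_half
                k2 = rhs(V + 0.5 * dt * k1[0], h + 0.5 * dt * k1[1],
                         n + 0.5 * dt * k1[2], z + 0.5 * dt * k1[3],
                         ge_h, gi_h, I_ext)
                k3 = rhs(V + 0.5 * dt * k2[0], h + 0.5 * dt * k2[1],
                         n + 0.5 * dt * k2[2], z + 0.5 * dt * k2[3],
                         ge_h, gi_h, I_ext)
                ge_f, gi_f = g_exc * decay_full, g_inh * decay_full
                k4 = rhs(V + dt * k3[0], h + dt * k3[1],
                         n + dt * k3[2], z + dt * k3[3],
                         ge_f, gi_f, I_ext)
                V = V + (dt / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
                h = np.clip(h + (dt / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]), 0, 1)
                n = np.clip(n + (dt / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]), 0, 1)
                z = np.clip(z + (dt / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]), 0, 1)
                g_exc, g_inh = ge_f, gi_f
            else:
                m_inf, h_inf, n_inf, z_inf = steady_state_gates(V)
                tau_h, tau_n, _ = gate_time_constants(V)
                I_ion = (-gNa * m_inf ** 3 * h * (V - VNa)
                         - gKdr * n ** 4 * (V - VK)
                         - gks * z * (V - VK)
                         - gL * (V - VL))
                I_syn = g_exc * V + g_inh * (V - E_inh)
                V = V + dt * (I_ion + I_ext - I_syn)
                h = h_inf + (h - h_inf) * np.exp(-dt / tau_h)
                n = n_inf + (n - n_inf) * np.exp(-dt / tau_n)
                z = z_inf + (z - z_inf) * np.exp(-dt / TAU_Z)
                g_exc = g_exc * decay_full
                g_inh = g_inh * decay_full

            if pop_trace is not None:
                pop_trace[1][i + 1] = V[MODULE1_E].sum()
                pop_trace[2][i + 1] = V[MODULE2_E].sum()

            crossed = (V_prev < SPIKE_THRESHOLD) & (V >= SPIKE_THRESHOLD) \
                & (t1 - last_spike >= SPIKE_LOCKOUT)
            if np.any(crossed):
                idx = np.nonzero(crossed)[0]
                last_spike[idx] = t1
                spike_cells.append(idx)
                spike_times.extend([t1] * len(idx))

                s1e = idx[(idx >= 0) & (idx < 400)]
                s1i = idx[(idx >= 400) & (idx < 500)] - 400
                s2e = idx[(idx >= 500) & (idx < 900)] - 500
                s2i = idx[(idx >= 900)] - 900

                # --- synaptic delivery (weights as of this step) -------------
                if s1e.size:
                    vec = np.zeros(400)
                    vec[s1e] = 1.0
                    g_exc[MODULE1_E] += ee1_T @ vec
                    g_exc[MODULE1_I] += ei1_T @ vec
                    g_exc[MODULE2_E] += w12[s1e, :].sum(axis=0)
                if s2e.size:
                    vec = np.zeros(400)
                    vec[s2e] = 1.0
                    g_exc[MODULE2_E] += ee2_T @ vec
                    g_exc[MODULE2_I] += ei2_T @ vec
                    g_exc[MODULE1_E] += w21[s2e, :].sum(axis=0)
                if s1i.size:
                    k = s1i.size
                    g_inh[MODULE1_E] += topo1.ie_weight * k
                    gi = np.full(100, topo1.ii_weight * k)
                    if not topo1.include_ii_self:
                        gi[s1i] -= topo1.ii_weight
                    g_inh[MODULE1_I] += gi
                if s2i.size:
                    k = s2i.size
                    g_inh[MODULE2_E] += topo2.ie_weight * k
                    gi = np.full(100, topo2.ii_weight * k)
                    if not topo2.include_ii_self:
                        gi[s2i] -= topo2.ii_weight
                    g_inh[MODULE2_I] += gi

                # --- STDP on inter-module E->E weights -----------------------
                if config.stdp_enabled and (s1e.size or s2e.size):
                    if s1e.size:   # depression of 1->2 synapses (pre spikes)
                        w12[s1e, :] = np.clip(
                            w12[s1e, :] - A_minus * tm2[None, :] * mask12[s1e, :],
                            w_min, w_max)
                    if s2e.size:   # depression of 2->1 synapses
                        w21[s2e, :] = np.clip(
                            w21[s2e, :] - A_minus * tm1[None, :] * mask21[s2e, :],
                            w_min, w_max)
                    if nearest:
                        tp1[s1e] = 1.0
                        tp2[s2e] = 1.0
                    else:
                        tp1[s1e] += 1.0
                        tp2[s2e] += 1.0
                    if s2e.size:   # potentiation of 1->2 synapses (post spikes)
                        w12[:, s2e] = np.clip(
                            w12[:, s2e] + A_plus * tp1[:, None] * mask12[:, s2e],
                            w_min, w_max)
                    if s1e.size:   # potentiation of 2->1 synapses
                        w21[:, s1e] = np.clip(
                            w21[:, s1e] + A_plus * tp2[:, None] * mask21[:, s1e],
                            w_min, w_max)
                    if nearest:
                        tm1[s1e] = 1.0
                        tm2[s2e] = 1.0
                    else:
                        tm1[s1e] += 1.0
                        tm2[s2e] += 1.0

            tp1 *= dec_tp
            tp2 *= dec_tp
            tm1 *= dec_tm
            tm2 *= dec_tm

            if next_snap is not None and t1 >= next_snap:
                snapshots.append((t1, w12.copy(), w21.copy()))
                next_snap += config.weight_snapshot_interval

            if i % 20000 == 19999:   # once per simulated second at dt=0.05
                logger.info("t=%.0f ms: %d spikes so far", t1,
                            sum(len(s) for s in spike_cells))

            if i % 20 == 0:
                vmax = np.abs(V).max()
                if not np.isfinite(vmax) or vmax > V_GUARD:
                    bad = ~np.isfinite(V) | (np.abs(V) > V_GUARD)
                    cell = int(np.nonzero(bad)[0][0])
                    raise SimulationError(
                        f"voltage diverged at t={t1:.2f} ms, internal cell "
                        f"{cell} (V={V[cell]:.1f} mV); reduce dt or check "
                        f"parameters")

    finally:
        np.seterr(**old_err)

    cells = (np.concatenate(spike_cells) if spike_cells
             else np.empty(0, dtype=np.int64))
    return SimulationResult(
        spike_cells=cells,
        spike_times=np.asarray(spike_times),
        wiring_initial=w_initial,
        wiring_final=inter,
        config=config,
        seed_info={"master_seed": config.seed, "trial_index": trial_index},
        population_trace=pop_trace,
        weight_snapshots=snapshots,
    )


@dataclass
class TrialSummary:
    """Trial-averaged weight-change statistics for one configuration."""

    results: list
    dw_into_module2: np.ndarray   # per-trial module-average dW (%), 1->2
    dw_into_module1: np.ndarray   # per-trial module-average dW (%), 2->1

    @staticmethod
    def _mean_se(x: np.ndarray) -> tuple[float, float]:
        m = float(np.mean(x))
        se = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
        return m, se

    @property
    def mean_dw_into_module2(self) -> float:
        return self._mean_se(self.dw_into_module2)[0]

    @property
    def mean_dw_into_module1(self) -> float:
        return self._mean_se(self.dw_into_module1)[0]

    @property
    def se_dw_into_module2(self) -> float:
        return self._mean_se(self.dw_into_module2)[1]

    @property
    def se_dw_into_module1(self) -> float:
        return self._mean_se(self.dw_into_module1)[1]


def run_trials(config: SimulationConfig) -> TrialSummary:
    """Run ``config.n_trials`` independent trials and average the dW stats.

    Each trial uses its own substreams for wiring (unless shared), initial
    conditions and noise; the summary reports per-trial module-average
    percentage weight changes and their across-trial standard error.
    """
    from .analysis import weight_change

    if config.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    shared = None
    if config.share_wiring_across_trials:
        ss = np.random.SeedSequence(config.seed)
        wiring_ss, _ = ss.spawn(2)
        shared = _build_wiring(config, np.random.default_rng(wiring_ss))
    results = []
    d2, d1 = [], []
    for k in range(config.n_trials):
        res = run_simulation(config, wiring=shared, trial_index=k)
        results.append(res)
        wc12 = weight_change(res.wiring_initial.w_1to2,
                             res.wiring_final.w_1to2,
                             res.wiring_initial.mask_1to2)
        wc21 = weight_change(res.wiring_initial.w_2to1,
                             res.wiring_final.w_2to1,
                             res.wiring_initial.mask_2to1)
        d2.append(wc12.module_average)
        d1.append(wc21.module_average)
    return TrialSummary(results=results,
                        dw_into_module2=np.asarray(d2),
                        dw_into_module1=np.asarray(d1))
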