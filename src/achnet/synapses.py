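"""Synaptic currents and Poisson noise-pulse inputs.

Every chemical synapse in the network shares the same kinetics: each
presynaptic spike instantaneously increments a conductance that then decays
exponentially with ``tau = 3 ms``.  The current onto a target at potential
``V`` is ``I = g * (V - E_syn)`` with ``E_syn = 0 mV`` (excitatory) or
``-75 mV`` (inhibitory); the current-balance equation subtracts this term,
so positive ``I`` is hyperpolarizing.

External noise arrives as rectangular depolarizing current pulses
(amplitude 6 uA/cm^2, width 1 ms) at Poisson-distributed times,
independently per cell.  Overlapping pulses saturate at a single amplitude
by default (a pulse is a stereotyped event, not an additive kernel); a flag
restores additive stacking for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseParams",
    "NoiseParams",
    "ExpDecayConductance",
    "synaptic_current",
    "draw_poisson_events",
    "PoissonPulseTrains",
]


@dataclass
class SynapseParams:
    """Shared synaptic kinetics: decay constant and reversal potentials."""

    tau: float = 3.0          # ms
    E_exc: float = 0.0        # mV
    E_inh: float = -75.0      # mV

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class NoiseParams:
    """Poisson pulse-train parameters (per-cell, independent trains).

    By default pulses target excitatory cells only, matching the treatment
    of the constant drive (external afferents are modelled as contacting
    pyramidal cells); set ``e_cells_only=False`` to drive both populations.
    """

    rate: float = 0.0         # Hz per cell
    amplitude: float = 6.0    # uA/cm^2
    pulse_width: float = 1.0  # ms
    additive: bool = False    # stack overlapping pulses instead of saturating
    e_cells_only: bool = True

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


def synaptic_current(weights, spike_trains, t, V_target, E_syn,
                     tau: float = 3.0) -> float:
    """Literal double-sum synaptic current onto one target cell.

    ``I(t) = (V - E_syn) * sum_j w_j * sum_k exp(-(t - t_jk)/tau)`` over all
    presynaptic spikes ``t_jk <= t``.  This direct evaluation is O(total
    spikes) per call and serves as the reference against which the
    incremental :class:`ExpDecayConductance` state is validated; simulations
    use the incremental form.
    """
    total = 0.0
    for w, train in zip(weights, spike_trains):
        train = np.asarray(train, dtype=float)
        past = train[train <= t]
        if past.size:
            total += w * np.exp(-(t - past) / tau).sum()
    return total * (V_target - E_syn)


class ExpDecayConductance:
    """Incremental per-target conductance with exponential decay.

    Maintains ``g`` for a vector of target cells.  ``decay(dt)`` multiplies
    by ``exp(-dt/tau)``; ``add(increment)`` registers spike-driven jumps.
    Mathematically identical (to round-off) to the literal sum over the
    full spike history.
    """

    def __init__(self, n_targets: int, tau: float = 3.0):
        if tau <= 0:
            raise ValueError("tau must be positive")
        self.tau = tau
        self.g = np.zeros(n_targets)

    def decay_factor(self, dt: float) -> float:
        return float(np.exp(-dt / self.tau))

    def decay(self, dt: float) -> None:
        self.g *= self.decay_factor(dt)

    def add(self, increment) -> None:
        self.g += increment

    def current(self, V, E_syn):
        """Synaptic current ``g * (V - E_syn)`` for the current state."""
        return self.g * (np.asarray(V) - E_syn)


def draw_poisson_events(rate_hz: float, duration_ms: float, n_cells: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Independent Poisson event trains (ms) for ``n_cells`` cells.

    Event counts are Poisson(rate * duration) and event times uniform on
    [0, duration), sorted — the standard conditional construction of a
    homogeneous Poisson process.
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if rate_hz == 0:
        return [np.empty(0) for _ in range(n_cells)]
    lam = rate_hz * duration_ms / 1000.0
    counts = rng.poisson(lam, size=n_cells)
    return [np.sort(rng.uniform(0.0, duration_ms, size=c)) for c in counts]


class PoissonPulseTrains:
    """Pre-drawn noise pulse trains with a cheap per-step current query.

    Events are flattened into one time-sorted list; a pulse started at
    ``t0`` is active on ``[t0, t0 + width)``, so the active set at time
    ``t`` is the slice of events with ``t - width < t0 <= t``, located with
    two binary searches.  Overlaps saturate at one amplitude unless
    ``params.additive`` is set.
    """

    def __init__(self, params: NoiseParams, n_cells: int, duration_ms: float,
                 rng: np.random.Generator):
        self.params = params
        self.n_cells = n_cells
        self.trains = draw_poisson_events(params.rate, duration_ms, n_cells,
                                          rng)
        cells = np.concatenate([
            np.full(len(tr), c, dtype=np.int64)
            for c, tr in enumerate(self.trains)
        ]) if n_cells else np.empty(0, dtype=np.int64)
        times = np.concatenate(self.trains) if n_cells else np.empty(0)
        order = np.argsort(times, kind="stable")
        self._ev_times = times[order]
        self._ev_cells = cells[order]

    def current(self, t: float) -> np.ndarray:
        """Noise current vector (uA/cm^2) at time ``t``."""
        lo = self._ev_times.searchsorted(t - self.params.pulse_width,
                                         side="right")
        hi = self._ev_times.searchsorted(t, side="right")
        if lo == hi:
            return np.zeros(self.n_cells)
        counts = np.bincount(self._ev_cells[lo:hi], minlength=self.n_cells)
        if not self.params.additive:
            counts = counts > 0
        return self.params.amplitude * counts.astype(float)

    def export_events(self, path=None) -> np.ndarray:
        """(cell_id, time_ms) event pairs in time order.

        Written as two-column delimited text when ``path`` is given, for
        reproducibility audits of the noise stream.
        """
        arr = np.stack([self._ev_cells.astype(float), self._ev_times],
                       axis=1)
        if path is not None:
            np.savetxt(path, arr, fmt=["%d", "%.6f"], delimiter="\t",
                       header="cell_id\ttime_ms", comments="")
        return arr

    def export_events(self):
        """(cell_id, time_ms) pairs in time order, for reproducibility audits."""
        return np.stack([self._ev_cells.astype(float), self._ev_times],
                        axis=1)
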