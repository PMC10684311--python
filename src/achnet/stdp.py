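"""Asymmetric pair-based spike-timing-dependent plasticity.

The kernel is the canonical additive exponential pair rule: a post-minus-pre
spike-time difference ``dt >= 0`` potentiates by ``A_plus * exp(-dt/tau_plus)``
and ``dt < 0`` depresses by ``A_minus * exp(dt/tau_minus)``.  The rule is
asymmetric both in time constant (14 ms vs 34 ms) and amplitude (0.0025 vs
0.00125 mS/cm^2), and weights are hard-clipped to [0, 0.01] mS/cm^2.

Two online realizations are provided:

* ``all_pairs`` (default): eligibility traces accumulate one unit per spike,
  so every pre/post spike pair interacts — the trace update is exactly
  equivalent to the explicit double sum over pairs.
* ``nearest``: traces are reset to one at each spike, so only the most
  recent partner spike contributes.

In the network model the rule applies exclusively to the inter-module
excitatory synapses; intra-module weights are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STDPParams",
    "TraceState",
    "pair_delta_w",
    "all_pairs_delta_w",
    "clip_weight",
    "PairSynapse",
]


@dataclass
class STDPParams:
    """Kernel constants and hard weight bounds (conductance in mS/cm^2)."""

    A_plus: float = 0.0025
    A_minus: float = 0.00125
    tau_plus: float = 14.0
    tau_minus: float = 34.0
    w_min: float = 0.0
    w_max: float = 0.01
    pairing: str = "all_pairs"  # or "nearest"

    def __post_init__(self) -> None:
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be positive")
        if self.pairing not in ("all_pairs", "nearest"):
            raise ValueError(f"unknown pairing scheme {self.pairing!r}")


def pair_delta_w(delta_t, params: STDPParams | None = None):
    """Weight change (mS/cm^2) for one spike pair.

    ``delta_t`` is post-minus-pre spike time (ms); ``delta_t = 0`` falls on
    the potentiation branch.
    """
    if params is None:
        params = STDPParams()
    delta_t = np.asarray(delta_t, dtype=float)
    out = np.where(
        delta_t >= 0,
        params.A_plus * np.exp(-delta_t / params.tau_plus),
        -params.A_minus * np.exp(delta_t / params.tau_minus),
    )
    return out if out.ndim else float(out)


def all_pairs_delta_w(pre_times, post_times,
                      params: STDPParams | None = None) -> float:
    """Explicit double sum of the pair kernel over every pre/post pair.

    Brute-force reference (no weight bounds) against which the online trace
    implementation is validated.
    """
    if params is None:
        params = STDPParams()
    pre = np.asarray(pre_times, dtype=float)
    post = np.asarray(post_times, dtype=float)
    if pre.size == 0 or post.size == 0:
        return 0.0
    dts = post[None, :] - pre[:, None]
    return float(np.sum(pair_delta_w(dts, params)))


def clip_weight(w, params: STDPParams | None = None):
    """Clamp ``w`` to the allowed conductance interval."""
    if params is None:
        params = STDPParams()
    return np.clip(w, params.w_min, params.w_max)


@dataclass
class TraceState:
    """Eligibility traces for one synapse.

    ``x_pre`` decays with ``tau_plus`` and is sampled at post spikes
    (potentiation); ``x_post`` decays with ``tau_minus`` and is sampled at
    pre spikes (depression).
    """

    x_pre: float = 0.0
    x_post: float = 0.0
    t_last: float = -np.inf

    def decay_to(self, t: float, params: STDPParams) -> None:
        if self.t_last == -np.inf:
            self.t_last = t
            return
        dt = t - self.t_last
        if dt < 0:
            raise ValueError(f"timestamps must be non-decreasing (got {t} "
                             f"after {self.t_last})")
        if dt > 0:
            self.x_pre *= np.exp(-dt / params.tau_plus)
            self.x_post *= np.exp(-dt / params.tau_minus)
            self.t_last = t


class PairSynapse:
    """One plastic synapse driven by pre/post spike events in time order.

    With ``bounded=False`` the weight accumulates the raw kernel sum, which
    is what the all-pairs oracle computes; simulations keep ``bounded=True``
    so every update respects the hard interval.

    Simultaneous pre and post events in the same time step must be fed as
    ``on_pre_spike(t)`` then ``on_post_spike(t)``: the pair then lands on
    the kernel's ``delta_t = 0`` potentiation branch and contributes no
    depression.
    """

    def __init__(self, w: float = 0.005, params: STDPParams | None = None,
                 *, bounded: bool = True):
        self.params = params if params is not None else STDPParams()
        self.w = float(w)
        self.bounded = bounded
        self.trace = TraceState()

    def _clip(self) -> None:
        if self.bounded:
            self.w = float(clip_weight(self.w, self.params))

    def on_pre_spike(self, t: float) -> float:
        """Register a presynaptic spike at ``t``; returns the new weight."""
        p = self.params
        self.trace.decay_to(t, p)
        self.w -= p.A_minus * self.trace.x_post
        self._clip()
        if p.pairing == "nearest":
            self.trace.x_pre = 1.0
        else:
            self.trace.x_pre += 1.0
        return self.w

    def on_post_spike(self, t: float) -> float:
        """Register a postsynaptic spike at ``t``; returns the new weight."""
        p = self.params
        self.trace.decay_to(t, p)
        self.w += p.A_plus * self.trace.x_pre
        self._clip()
        if p.pairing == "nearest":
            self.trace.x_post = 1.0
        else:
            self.trace.x_post += 1.0
        return self.w

    def run_trains(self, pre_times, post_times) -> float:
        """Process two spike trains (pre before post on exact ties).

        Returns the final weight.
        """
        events = sorted(
            [(t, 0) for t in np.asarray(pre_times, dtype=float)]
            + [(t, 1) for t in np.asarray(post_times, dtype=float)]
        )
        for t, kind in events:
            if kind == 0:
                self.on_pre_spike(t)
            else:
                self.on_post_spike(t)
        return self.w
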