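"""Population statistics: activity traces, volley detection, phase
coherence, weight-change maps and the lin-log display transform.

The module-level unit of timing is the population volley (burst): spike
times are convolved with a narrow Gaussian (sigma = 1 ms), summed over a
module's E cells, and peaks of that trace mark volley times.  Volley trains
of the two modules are then compared by mean phase coherence (MPC), and
plasticity is summarized by the percentage weight-change matrix
``dW = 100% x (Wf - Wi)/Wi`` with per-cell incoming averages and module
averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BurstTrain", "WeightChangeMatrix",
    "population_trace", "detect_bursts", "module_burst_train",
    "mean_phase_coherence", "directional_mpc", "weight_change",
    "linlog_display", "bursting_frequency", "median_volley_lag",
]

#: Trace sampling interval (ms).
GRID_DT = 0.1
#: Gaussian smoothing width for spike convolution (ms).
SIGMA = 1.0
#: Peaks closer than this (ms) are merged into one volley.
MERGE_RADIUS = 5.0


@dataclass
class BurstTrain:
    """Ordered population volley (burst) peak times for one module (ms)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("burst times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def population_trace(spike_times, duration: float, sigma: float = SIGMA,
                     grid_dt: float = GRID_DT):
    """Gaussian-convolved cumulative activity trace of a spike set.

    Returns ``(t, trace)`` where ``trace(t) = sum_s exp(-(t - t_s)^2 /
    (2 sigma^2))``, evaluated on a grid of spacing ``grid_dt``.  Spikes are
    binned to the grid first (sub-bin timing error is below grid_dt/2) and
    the kernel is truncated at 6 sigma.
    """
    if sigma <= 0 or grid_dt <= 0:
        raise ValueError("sigma and grid_dt must be positive")
    spike_times = np.asarray(spike_times, dtype=float)
    n_bins = int(round(duration / grid_dt)) + 1
    t = np.arange(n_bins) * grid_dt
    hist = np.zeros(n_bins)
    if spike_times.size:
        idx = np.clip(np.round(spike_times / grid_dt).astype(int), 0,
                      n_bins - 1)
        np.add.at(hist, idx, 1.0)
    half = int(np.ceil(6 * sigma / grid_dt))
    k = np.arange(-half, half + 1) * grid_dt
    kernel = np.exp(-k ** 2 / (2 * sigma ** 2))
    trace = np.convolve(hist, kernel, mode="same")
    return t, trace


def detect_bursts(t, trace, min_height: float, *,
                  merge_radius: float = MERGE_RADIUS) -> BurstTrain:
    """Volley peak times: local maxima of a population trace above a height.

    ``min_height`` is an absolute trace height (callers typically pass a
    fraction of the module's E-cell count, 0.1 x 400 by default elsewhere);
    peaks closer than ``merge_radius`` are merged, keeping the higher one.
    """
    t = np.asarray(t, dtype=float)
    trace = np.asarray(trace, dtype=float)
    grid = t[1] - t[0] if len(t) > 1 else GRID_DT
    peaks, _ = find_peaks(trace, height=min_height,
                          distance=max(1, int(round(merge_radius / grid))))
    return BurstTrain(times=t[peaks])


def module_burst_train(spike_times, duration: float, n_e_cells: int = 400,
                       min_height_fraction: float = 0.1) -> BurstTrain:
    """Convenience pipeline: trace -> peaks for one module's E spikes."""
    t, trace = population_trace(spike_times, duration)
    return detect_bursts(t, trace, min_height_fraction * n_e_cells)


def directional_mpc(bursts_ref: BurstTrain, bursts_other: BurstTrain) -> float:
    """One-directional mean phase coherence of ``other`` against ``ref``.

    For the k-th reference inter-burst interval, the first other-module
    burst inside it contributes the phase ``2 pi (t_other - t_ref,k) /
    (t_ref,k+1 - t_ref,k)``; the MPC is the modulus of the mean unit
    phasor.  Intervals containing no other-module burst are skipped.
    Returns NaN when no interval can be paired.
    """
    ref = bursts_ref.times
    oth = bursts_other.times
    if len(ref) < 2:
        return float("nan")
    phases = []
    for k in range(len(ref) - 1):
        lo, hi = ref[k], ref[k + 1]
        inside = oth[(oth >= lo) & (oth < hi)]
        if inside.size:
            phases.append(2 * np.pi * (inside[0] - lo) / (hi - lo))
    if not phases:
        return float("nan")
    return float(np.abs(np.mean(np.exp(1j * np.asarray(phases)))))


def mean_phase_coherence(bursts_a: BurstTrain, bursts_b: BurstTrain) -> float:
    """Symmetrized MPC: the mean of the two directional values, in [0, 1].

    1 means the two modules' volleys are locked at a fixed phase; values
    near 0 mean the relative phases are spread uniformly.  NaN when either
    train is too short to define intervals.
    """
    m1 = directional_mpc(bursts_a, bursts_b)
    m2 = directional_mpc(bursts_b, bursts_a)
    if np.isnan(m1) or np.isnan(m2):
        return float("nan")
    return 0.5 * (m1 + m2)


def median_volley_lag(bursts_ref: BurstTrain,
                      bursts_other: BurstTrain) -> float:
    """Median of (paired other-burst time - reference-burst time), ms.

    Pairs each reference burst with the nearest other-module burst.
    Positive values mean the reference module leads.  NaN if either train
    is empty.
    """
    ref, oth = bursts_ref.times, bursts_other.times
    if ref.size == 0 or oth.size == 0:
        return float("nan")
    pos = np.searchsorted(oth, ref)
    lags = np.empty(ref.size)
    for i, (t, j) in enumerate(zip(ref, pos)):
        cand = []
        if j > 0:
            cand.append(oth[j - 1] - t)
        if j < oth.size:
            cand.append(oth[j] - t)
        lags[i] = min(cand, key=abs)
    return float(np.median(lags))


@dataclass
class WeightChangeMatrix:
    """Percentage weight changes of one inter-module direction.

    ``delta_pct`` is (n_pre, n_post) with NaN off the wired graph;
    ``per_cell_incoming`` averages over each target cell's incoming edges
    (rows of the matrix); ``module_average`` averages the per-cell values
    over all target E cells.
    """

    delta_pct: np.ndarray
    mask: np.ndarray
    per_cell_incoming: np.ndarray = field(init=False)
    module_average: float = field(init=False)

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            self.per_cell_incoming = np.nanmean(self.delta_pct, axis=0)
        self.module_average = float(np.nanmean(self.per_cell_incoming))


def weight_change(w_initial: np.ndarray, w_final: np.ndarray,
                  mask: np.ndarray) -> WeightChangeMatrix:
    """Per-edge percentage change ``100 x (Wf - Wi)/Wi`` on wired edges.

    Raises if a wired edge has zero initial weight (the percentage change
    is then undefined); with the standard initialization every edge starts
    at 0.005 mS/cm^2.
    """
    w_initial = np.asarray(w_initial, dtype=float)
    w_final = np.asarray(w_final, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if w_initial.shape != w_final.shape or w_initial.shape != mask.shape:
        raise ValueError("weight matrices and mask must share one shape")
    if np.any(w_initial[mask] == 0):
        raise ValueError("zero initial weight on a wired edge")
    delta = np.full(w_initial.shape, np.nan)
    delta[mask] = 100.0 * (w_final[mask] - w_initial[mask]) / w_initial[mask]
    return WeightChangeMatrix(delta_pct=delta, mask=mask)


def linlog_display(x):
    """Linear-logarithmic display transform for percentage weight changes.

    Identity on [-2, 2] %; beyond that each decade of |x| adds one display
    unit: ``sign(x) * (2 + log10(|x| / 2))``.  Odd, monotone, continuous at
    the +/-2 junctions; compresses the [-100, 100] range to about [-3.7,
    3.7] so small and large changes share one color scale.
    """
    x = np.asarray(x, dtype=float)
    ax = np.abs(x)
    safe = np.where(ax > 2.0, ax, 2.0)   # avoid log of the linear branch
    out = np.where(ax <= 2.0, x, np.sign(x) * (2.0 + np.log10(safe / 2.0)))
    return out if out.ndim else float(out)


def bursting_frequency(bursts: BurstTrain) -> float:
    """Mean volley rate in Hz: (N - 1) / (t_last - t_first).

    NaN when fewer than two volleys were detected.
    """
    t = bursts.times
    if t.size < 2:
        return float("nan")
    return 1000.0 * (t.size - 1) / (t[-1] - t[0])
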