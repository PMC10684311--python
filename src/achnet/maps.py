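"""Spatial maps of ACh modulation (gKs) and DC drive over a module.

Heterogeneous ACh signaling is modelled as one or more circular "hotspots":
inside a hotspot the M-current conductance gKs is low (high ACh, high
excitability) and it rises sigmoidally to a background value outside.  A
map assigns one scalar per cell, over both the 20 x 20 E lattice and the
10 x 10 I lattice; the I lattice is evaluated at doubled coordinates so
both populations share one spatial frame.

The radial profile is

    value(d) = value_min + (value_max - value_min) * S((d - r) / w)

with ``S`` the standard logistic function, ``d`` the wrapped Euclidean
distance to the nearest hotspot center, ``r`` the hotspot radius and ``w``
a steepness scale.  A ``unit_amplitude`` flag drops the amplitude factor
and adds the raw sigmoid to ``value_min`` (a one-unit swing), for
comparison with that simpler parameterization.  DC-drive maps reuse the
same profile so excitability fields stay spatially aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import E_SIDE, N_E, N_I, coords

__all__ = ["SpatialScalarMap", "homogeneous_map", "hotspot_map",
           "preset", "PRESETS", "DEFAULT_RADIUS", "DEFAULT_STEEPNESS"]

#: Default hotspot radius (E-lattice units).  Chosen so a single hotspot
#: covers roughly a fifth of the module's area while leaving a clear
#: surround; the radial profile parameters are free knobs of the model.
DEFAULT_RADIUS = 5.0
#: Default sigmoid steepness (E-lattice units): unit slope scale.
DEFAULT_STEEPNESS = 1.0


@dataclass
class SpatialScalarMap:
    """Per-cell scalar field over one module (400 E values, 100 I values)."""

    e_values: np.ndarray
    i_values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.e_values = np.asarray(self.e_values, dtype=float)
        self.i_values = np.asarray(self.i_values, dtype=float)
        if self.e_values.shape != (N_E,) or self.i_values.shape != (N_I,):
            raise ValueError("map must hold 400 E values and 100 I values")

    @property
    def values(self) -> np.ndarray:
        """All 500 per-cell values, E cells first (internal cell order)."""
        return np.concatenate([self.e_values, self.i_values])

    def e_grid(self) -> np.ndarray:
        """E values as a (20, 20) grid indexed [x, y]."""
        return self.e_values.reshape(E_SIDE, E_SIDE)


def homogeneous_map(value: float) -> SpatialScalarMap:
    """Constant field: the spatially uniform modulation case."""
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    return SpatialScalarMap(
        e_values=np.full(N_E, float(value)),
        i_values=np.full(N_I, float(value)),
        metadata={"kind": "homogeneous", "value": float(value)},
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _nearest_center_dist(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d = np.abs(points[:, None, :] - centers[None, :, :])
    d = np.minimum(d, E_SIDE - d)
    return np.sqrt((d ** 2).sum(axis=2)).min(axis=1)


def hotspot_map(centers, r: float = DEFAULT_RADIUS,
                value_min: float = 0.0, value_max: float = 1.5,
                steepness: float = DEFAULT_STEEPNESS,
                *, unit_amplitude: bool = False) -> SpatialScalarMap:
    """Sigmoid radial field around one or more hotspot centers.

    ``centers`` is a sequence of (x, y) positions on the 20 x 20 frame;
    with several centers each cell takes the value set by its nearest
    center, which makes the field the pointwise minimum of the
    single-center fields.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        raise ValueError("at least one hotspot center is required")
    if r <= 0 or steepness <= 0:
        raise ValueError("radius and steepness must be positive")
    if value_min > value_max:
        raise ValueError("value_min must not exceed value_max")

    def profile(points):
        d = _nearest_center_dist(points, centers)
        s = _sigmoid((d - r) / steepness)
        if unit_amplitude:
            return value_min + s
        return value_min + (value_max - value_min) * s

    e_vals = profile(coords("E").astype(float))
    i_vals = profile(coords("I").astype(float) * 2.0)
    return SpatialScalarMap(
        e_values=e_vals, i_values=i_vals,
        metadata={
            "kind": "hotspot", "centers": centers.tolist(), "radius": r,
            "value_min": value_min, "value_max": value_max,
            "steepness": steepness, "unit_amplitude": unit_amplitude,
        },
    )


def _pair(gks_map: SpatialScalarMap, dc_map: SpatialScalarMap) -> dict:
    return {"gks": gks_map, "dc": dc_map}


_CENTER = (10.0, 10.0)
_OFFSET_A = (5.0, 5.0)
_OFFSET_B = (15.0, 15.0)


def _hotspot_pair(gks_in, gks_out, dc_in, dc_out, centers=(_CENTER,)) -> dict:
    gks = hotspot_map(centers, value_min=gks_in, value_max=gks_out)
    if dc_in == dc_out:
        dc = homogeneous_map(dc_in)
    elif dc_in <= dc_out:
        dc = hotspot_map(centers, value_min=dc_in, value_max=dc_out)
    else:
        # DC higher inside the hotspot: flip the profile by negation
        flipped = hotspot_map(centers, value_min=-dc_in, value_max=-dc_out)
        dc = SpatialScalarMap(-flipped.e_values, -flipped.i_values,
                              metadata={**flipped.metadata,
                                        "value_min": dc_out,
                                        "value_max": dc_in,
                                        "inverted": True})
    return _pair(gks, dc)


#: Named module map configurations used by the scripted experiments.
#: Values give (gKs, DC) in mS/cm^2 and uA/cm^2.
PRESETS: dict[str, dict] = {
    # reference homogeneous module: moderate ACh, moderate drive
    "homogeneous_reference": lambda: _pair(homogeneous_map(0.6),
                                           homogeneous_map(2.0)),
    # single hotspot, moderately modulated: gKs 0.6 / DC 2.0 inside,
    # gKs 1.5 / DC 3.0 outside
    "hotspot_moderate": lambda: _hotspot_pair(0.6, 1.5, 2.0, 3.0),
    # single strongly modulated hotspot: gKs 0.2 inside, uniform DC 3.0
    "hotspot_strong": lambda: _hotspot_pair(0.2, 1.5, 3.0, 3.0),
    # two strongly modulated hotspots on one diagonal, uniform DC 3.0
    "two_hotspots": lambda: _hotspot_pair(
        0.2, 1.5, 3.0, 3.0, centers=(_OFFSET_A, _OFFSET_B)),
    # single strongly modulated hotspot off-center (for misaligned pairs)
    "hotspot_strong_offset_a": lambda: _hotspot_pair(
        0.2, 1.5, 3.0, 3.0, centers=(_OFFSET_A,)),
    "hotspot_strong_offset_b": lambda: _hotspot_pair(
        0.2, 1.5, 3.0, 3.0, centers=(_OFFSET_B,)),
}


def preset(name: str) -> dict:
    """Return ``{"gks": SpatialScalarMap, "dc": SpatialScalarMap}`` by name."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory()
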