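"""Two-module lattice topology: local excitation, global inhibition.

Each module is an E-I network on a pair of square lattices with periodic
boundaries: 400 excitatory cells on a 20 x 20 grid and 100 inhibitory cells
on a 10 x 10 grid (inhibition is 20% of the module, as in cortex).  E cells
project to their 40 nearest E neighbours and 10 nearest I neighbours by
wrapped Euclidean distance (ties at the cut radius broken at random);
I cells project globally, to every E cell and every other I cell.  The two
lattices share one spatial frame: an E cell at (x, y) sits at (x/2, y/2) of
the I grid.

The two modules are coupled by plastic E->E synapses, wired either randomly
(fixed in-degree, 40 by default) or topographically (each cell contacts the
nearest cells of the other module as if the grids were stacked).  All
inter-module weights start at 0.005 mS/cm^2, half of the allowed maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "E_SIDE", "I_SIDE", "N_E", "N_I",
    "INTRA_WEIGHTS", "W_INTER_INITIAL",
    "LatticeCell", "ModuleTopology", "InterModuleWiring",
    "periodic_nearest", "build_module", "build_intermodule",
    "display_index", "coords",
]

E_SIDE = 20   #: E lattice side length
I_SIDE = 10   #: I lattice side length
N_E = E_SIDE * E_SIDE
N_I = I_SIDE * I_SIDE

#: Fixed intra-module synaptic strengths (mS/cm^2).
INTRA_WEIGHTS = {"EE": 0.01, "EI": 0.05, "II": 0.04, "IE": 0.04}

#: Initial strength of every plastic inter-module synapse (mS/cm^2).
W_INTER_INITIAL = 0.005

K_EE = 40   #: intra-module E->E out-degree
K_EI = 10   #: intra-module E->I out-degree


@dataclass(frozen=True)
class LatticeCell:
    """A cell located on one of the module lattices."""

    module: int      # 1 or 2
    kind: str        # "E" or "I"
    x: int
    y: int

    def __post_init__(self) -> None:
        side = E_SIDE if self.kind == "E" else I_SIDE
        if self.module not in (1, 2):
            raise ValueError("module must be 1 or 2")
        if self.kind not in ("E", "I"):
            raise ValueError("kind must be 'E' or 'I'")
        if not (0 <= self.x < side and 0 <= self.y < side):
            raise ValueError(f"coordinates outside the {side}x{side} lattice")


def display_index(cell: LatticeCell) -> int:
    """1-based raster index: column-major within lattice, module 2 first.

    Module-2 E cells occupy 1-400 and its I cells 401-500; module-1 cells
    repeat the pattern at 501-1000.
    """
    side = E_SIDE if cell.kind == "E" else I_SIDE
    within = cell.y + cell.x * side
    base = 0 if cell.module == 2 else 500
    if cell.kind == "I":
        base += N_E
    return 1 + base + within


def coords(kind: str = "E") -> np.ndarray:
    """(n, 2) integer (x, y) coordinates in internal (0-based) cell order.

    Internal cell index i maps to x = i // side, y = i % side, matching the
    display ordering.
    """
    side = E_SIDE if kind == "E" else I_SIDE
    idx = np.arange(side * side)
    return np.stack([idx // side, idx % side], axis=1)


def _wrapped_dist2(points: np.ndarray, center, side: float) -> np.ndarray:
    """Squared torus distance from each row of ``points`` to ``center``."""
    d = np.abs(points - np.asarray(center, dtype=float))
    d = np.minimum(d, side - d)
    return (d ** 2).sum(axis=1)


def periodic_nearest(coord, lattice_side: int, k: int,
                     rng: np.random.Generator, *,
                     candidates: np.ndarray | None = None,
                     exclude_self: bool = True) -> np.ndarray:
    """Indices of the ``k`` nearest lattice cells under periodic boundaries.

    Distance is wrapped Euclidean on the torus.  When several cells tie at
    the cut radius, the required number among them is chosen uniformly at
    random from ``rng``, so repeated builds differ only within tie shells.

    ``coord`` may be fractional (used for cross-lattice overlay searches).
    With ``exclude_self`` a candidate at exactly zero distance is removed
    before selection.
    """
    if candidates is None:
        candidates = coords("E" if lattice_side == E_SIDE else "I")
    d2 = _wrapped_dist2(candidates.astype(float), coord, lattice_side)
    pool = np.arange(len(candidates))
    if exclude_self:
        keep = d2 > 1e-12
        pool, d2 = pool[keep], d2[keep]
    if not (1 <= k <= len(pool)):
        raise ValueError(f"k={k} out of range for {len(pool)} candidates")
    # round squared distances so floating error cannot split a tie shell
    d2r = np.round(d2, 9)
    order = np.argsort(d2r, kind="stable")
    cut = d2r[order[k - 1]]
    inside = pool[order[: np.searchsorted(d2r[order], cut)]]
    shell = pool[order][d2r[order] == cut]
    need = k - len(inside)
    chosen = rng.choice(shell, size=need, replace=False) if need < len(shell) \
        else shell
    return np.sort(np.concatenate([inside, chosen]))


def _neighbor_csr(rows_of_targets, n_sources, n_targets, weight) -> sp.csr_array:
    indptr = np.zeros(n_sources + 1, dtype=np.int64)
    indices = []
    for s, targets in enumerate(rows_of_targets):
        indptr[s + 1] = indptr[s] + len(targets)
        indices.append(targets)
    indices = np.concatenate(indices)
    data = np.full(len(indices), weight)
    return sp.csr_array((data, indices, indptr), shape=(n_sources, n_targets))


@dataclass
class ModuleTopology:
    """Fixed intra-module wiring: four weighted source -> target operators.

    ``ee`` and ``ei`` are sparse (local excitation); inhibition is global
    and dense in effect, so ``ie`` and ``ii`` are stored implicitly by
    their scalar weights (I cells contact every E cell, and every I cell
    but themselves).
    """

    ee: sp.csr_array                  # (N_E, N_E), out-degree 40
    ei: sp.csr_array                  # (N_E, N_I), out-degree 10
    ie_weight: float = INTRA_WEIGHTS["IE"]
    ii_weight: float = INTRA_WEIGHTS["II"]
    include_ii_self: bool = False

    def out_degrees(self, kind: str) -> np.ndarray:
        if kind == "EE":
            return np.diff(self.ee.indptr)
        if kind == "EI":
            return np.diff(self.ei.indptr)
        if kind == "IE":
            return np.full(N_I, N_E)
        if kind == "II":
            return np.full(N_I, N_I if self.include_ii_self else N_I - 1)
        raise KeyError(kind)


def build_module(rng: np.random.Generator, *,
                 include_ii_self: bool = False) -> ModuleTopology:
    """Wire one module's intra-module connectivity.

    E->E: 40 nearest E cells; E->I: 10 nearest I cells with the E cell
    overlaid at half coordinates; I->E and I->I are all-to-all (self
    excluded by default) and represented by scalar weights.
    """
    e_xy = coords("E")
    i_xy = coords("I")
    ee_rows = [
        periodic_nearest(e_xy[s], E_SIDE, K_EE, rng, candidates=e_xy)
        for s in range(N_E)
    ]
    ei_rows = [
        periodic_nearest(e_xy[s] / 2.0, I_SIDE, K_EI, rng,
                         candidates=i_xy, exclude_self=False)
        for s in range(N_E)
    ]
    return ModuleTopology(
        ee=_neighbor_csr(ee_rows, N_E, N_E, INTRA_WEIGHTS["EE"]),
        ei=_neighbor_csr(ei_rows, N_E, N_I, INTRA_WEIGHTS["EI"]),
        include_ii_self=include_ii_self,
    )


@dataclass
class InterModuleWiring:
    """Plastic E->E coupling between the modules.

    ``w_1to2[i, j]`` is the weight of the synapse from E cell ``i`` of
    module 1 onto E cell ``j`` of module 2 (dense (400, 400) with zeros off
    the wired graph); ``mask_*`` mark the wired edges, which never change
    during a simulation — only their weights do.
    """

    w_1to2: np.ndarray
    w_2to1: np.ndarray
    mask_1to2: np.ndarray
    mask_2to1: np.ndarray
    mode: str = "random"
    in_degree: int = 40

    def copy(self) -> "InterModuleWiring":
        return InterModuleWiring(
            self.w_1to2.copy(), self.w_2to1.copy(),
            self.mask_1to2, self.mask_2to1, self.mode, self.in_degree)


def _random_incoming(in_degree: int, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((N_E, N_E), dtype=bool)
    for j in range(N_E):
        src = rng.choice(N_E, size=in_degree, replace=False)
        mask[src, j] = True
    return mask


def _topographic(in_degree: int, rng: np.random.Generator) -> np.ndarray:
    """Each source contacts its ``in_degree`` nearest overlay counterparts.

    The aligned cell (distance 0) is included.  By translation symmetry of
    the torus the construction also gives every target in-degree
    ``in_degree`` up to tie randomization.
    """
    e_xy = coords("E")
    mask = np.zeros((N_E, N_E), dtype=bool)
    for s in range(N_E):
        tgt = periodic_nearest(e_xy[s], E_SIDE, in_degree, rng,
                               candidates=e_xy, exclude_self=False)
        mask[s, tgt] = True
    return mask


def build_intermodule(mode: str, in_degree: int,
                      rng: np.random.Generator) -> InterModuleWiring:
    """Construct the plastic inter-module E->E wiring.

    ``mode="random"`` draws, for every target cell, ``in_degree`` distinct
    source cells of the other module; ``mode="topographic"`` overlays the
    two 20 x 20 grids and connects nearest cells (in-degree 5 variants
    sharpen the topographic specificity).
    """
    if mode not in ("random", "topographic"):
        raise ValueError(f"unknown inter-module mode {mode!r}")
    if not (1 <= in_degree <= N_E):
        raise ValueError("in_degree out of range")
    build = _random_incoming if mode == "random" else _topographic
    mask_1to2 = build(in_degree, rng)
    mask_2to1 = build(in_degree, rng)
    return InterModuleWiring(
        w_1to2=np.where(mask_1to2, W_INTER_INITIAL, 0.0),
        w_2to1=np.where(mask_2to1, W_INTER_INITIAL, 0.0),
        mask_1to2=mask_1to2,
        mask_2to1=mask_2to1,
        mode=mode,
        in_degree=in_degree,
    )
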