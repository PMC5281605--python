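"""Disk-migration packing engine.

Disks (axons with their myelin sheath, plus an inter-fiber gap ``delta``) are
initialized on a grid inside a square domain sized so that no pair overlaps,
then migrate iteratively: non-overlapping disks drift toward the domain
centre at a small constant speed, overlapping disks are pushed apart at a
larger constant speed.  The packing densifies toward a jammed
(maximally-random-jammed) state; density is recorded periodically in a
:class:`DensityTrace`.

Two code paths compute identical trajectories: a plain numpy implementation
(:func:`compute_velocities` / :func:`step`) used as a readable reference, and
a numba cell-list kernel used by :func:`run_packing` for long runs.  The test
suite checks the two agree bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from ._kernel import migrate
from .diameters import AxonPopulation

__all__ = [
    "PackingConfig",
    "PackingState",
    "DensityTrace",
    "initialize_grid",
    "compute_gap_matrix",
    "compute_velocities",
    "step",
    "run_packing",
    "convergence_variation",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PackingConfig:
    """Parameters of the migration loop.

    ``v_att`` (um/iteration) is the constant drift toward the centre,
    ``v_rep`` the repulsion speed applied to overlapping disks; repulsion
    must dominate attraction (``v_rep > v_att``) or overlaps are never
    resolved.  The defaults, 0.01 and 0.1 um/iteration, are small compared
    with the minimum axon diameter (0.2 um) so that disks do not bounce.
    """

    iter_max: int
    trace_every: int = 250
    v_att: float = 0.01
    v_rep: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iter_max < 1 or self.trace_every < 1:
            raise ValueError("iter_max and trace_every must be >= 1")
        if not self.v_rep > self.v_att > 0:
            raise ValueError(
                f"need v_rep > v_att > 0, got v_rep={self.v_rep}, v_att={self.v_att}"
            )


@dataclass
class PackingState:
    """Disk centres and packed diameters at one iteration."""

    positions: np.ndarray  # (N, 2) um
    packing_diameters: np.ndarray  # (N,) um
    delta: float
    iteration: int = 0
    domain_center: tuple[float, float] = (0.0, 0.0)
    domain_side: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.packing_diameters = np.asarray(self.packing_diameters, dtype=float)
        if len(self.positions) != len(self.packing_diameters):
            raise ValueError("positions and packing_diameters must have equal length")

    @property
    def n(self) -> int:
        return len(self.packing_diameters)

    @property
    def effective_radii(self) -> np.ndarray:
        """Packed radius plus half the gap; pairs overlap when the centre
        distance is below the sum of effective radii."""
        return 0.5 * (self.packing_diameters + self.delta)


@dataclass
class DensityTrace:
    """Fiber volume fraction sampled along the migration."""

    iterations: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    fvf: np.ndarray = field(default_factory=lambda: np.empty(0))

    def append(self, iteration: int, value: float) -> None:
        self.iterations = np.append(self.iterations, iteration)
        self.fvf = np.append(self.fvf, value)

    def __len__(self) -> int:
        return len(self.iterations)


def initialize_grid(population: AxonPopulation, config: PackingConfig) -> PackingState:
    """Place disks on a random grid with guaranteed pairwise clearance.

    The square domain has area ``N * (2*max(R) + delta)**2``.  Disks are
    assigned (seeded, without replacement) to distinct cells of a
    ``ceil(sqrt(N))``-by-``ceil(sqrt(N))`` lattice centred on the origin and
    sit at their cell centres.  The lattice pitch is at least the maximum
    effective diameter, so every cell is wider than the disk it holds and no
    pair overlaps at effective diameters.
    """
    n = len(population)
    radii = population.packing_diameters / 2.0
    d_eff_max = 2.0 * radii.max() + population.delta
    side = np.sqrt(n) * d_eff_max  # domain area = N * d_eff_max**2
    g = int(np.ceil(np.sqrt(n)))
    pitch = max(side / g, d_eff_max)
    rng = np.random.default_rng(config.seed)
    cells = rng.choice(g * g, size=n, replace=False)
    ix, iy = cells // g, cells % g
    offset = (g - 1) / 2.0
    positions = np.column_stack(((ix - offset) * pitch, (iy - offset) * pitch))
    return PackingState(
        positions=positions,
        packing_diameters=population.packing_diameters.copy(),
        delta=population.delta,
        iteration=0,
        domain_center=(0.0, 0.0),
        domain_side=float(side),
    )


def compute_gap_matrix(state: PackingState) -> np.ndarray:
    """Pairwise clearance matrix P.

    ``P[i, j] = |c_i - c_j| - (r_i + r_j + delta)``; negative entries flag
    overlap at effective diameters.  The diagonal is set to +inf so a disk
    never overlaps itself.
    """
    diff = state.positions[:, None, :] - state.positions[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    radii = state.packing_diameters / 2.0
    p = dist - (radii[:, None] + radii[None, :] + state.delta)
    np.fill_diagonal(p, np.inf)
    return p


def compute_velocities(state: PackingState, config: PackingConfig) -> np.ndarray:
    """Per-disk displacement (um) for the next iteration; O(N^2) reference.

    Non-overlapping disks move toward the domain centre with norm ``v_att``;
    a disk overlapping one or more neighbours moves along the normalized sum
    of the unit vectors pointing away from each overlapper, with norm
    ``v_rep`` (attraction omitted).  Degenerate directions (disk at the
    centre, or repulsion vectors cancelling) yield zero displacement.
    """
    pos = state.positions
    gaps = compute_gap_matrix(state)
    cx, cy = state.domain_center
    vel = np.zeros_like(pos)
    for k in range(state.n):
        neighbors = np.nonzero(gaps[k] < 0)[0]
        if neighbors.size == 0:
            dx, dy = cx - pos[k, 0], cy - pos[k, 1]
            nrm = np.sqrt(dx * dx + dy * dy)
            if nrm > _EPS:
                vel[k, 0] = config.v_att * dx / nrm
                vel[k, 1] = config.v_att * dy / nrm
        else:
            sx = sy = 0.0
            for j in neighbors:  # ascending order, matching the kernel
                dx, dy = pos[k, 0] - pos[j, 0], pos[k, 1] - pos[j, 1]
                d = np.sqrt(dx * dx + dy * dy)
                if d > _EPS:
                    sx += dx / d
                    sy += dy / d
            nrm = np.sqrt(sx * sx + sy * sy)
            if nrm > _EPS:
                vel[k, 0] = config.v_rep * sx / nrm
                vel[k, 1] = config.v_rep * sy / nrm
    return vel


def step(state: PackingState, config: PackingConfig) -> PackingState:
    """One synchronous migration step (reference path)."""
    vel = compute_velocities(state, config)
    return replace(state, positions=state.positions + vel, iteration=state.iteration + 1)


def run_packing(
    population: AxonPopulation,
    config: PackingConfig,
    metrics_hook: Callable[[PackingState], float] | None = None,
) -> tuple[PackingState, DensityTrace]:
    """Initialize on the grid and run ``iter_max`` migrations.

    ``metrics_hook(state) -> FVF`` is evaluated at iteration 0 and every
    ``trace_every`` iterations thereafter (and at ``iter_max`` if it is not a
    multiple); by default it computes the fiber volume fraction on the
    auto-selected central analysis mask.  Deterministic for a fixed seed.
    """
    if metrics_hook is None:
        from .metrics import fiber_volume_fraction

        def metrics_hook(s: PackingState) -> float:
            return fiber_volume_fraction(s, population)

    state = initialize_grid(population, config)
    trace = DensityTrace()
    trace.append(0, metrics_hook(state))
    pos = np.ascontiguousarray(state.positions)
    eff_r = np.ascontiguousarray(state.effective_radii)
    cx, cy = state.domain_center
    it = 0
    while it < config.iter_max:
        chunk = min(config.trace_every, config.iter_max - it)
        migrate(pos, eff_r, cx, cy, config.v_att, config.v_rep, chunk)
        it += chunk
        state = replace(state, positions=pos.copy(), iteration=it)
        trace.append(it, metrics_hook(state))
    return state, trace


def convergence_variation(trace: DensityTrace, window_start: int, window_end: int) -> float:
    """Max minus min of the FVF trace over ``window_start <= iteration <= window_end``."""
    sel = (trace.iterations >= window_start) & (trace.iterations <= window_end)
    if sel.sum() < 2:
        raise ValueError(
            f"window [{window_start}, {window_end}] covers {int(sel.sum())} trace "
            "points; need at least 2"
        )
    window = trace.fvf[sel]
    return float(window.max() - window.min())
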