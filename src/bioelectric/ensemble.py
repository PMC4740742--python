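"""Gap-junction-coupled square lattice of model cells.

Each cell on a rows x cols lattice carries a dimensionless membrane
potential v_i = V_i/V_T and obeys

    dv_i/dt_hat = -i_total(v_i; ratio_i) + sum_nn g_ij (v_j - v_i)

where the sum runs over the 4 von Neumann neighbors (edge/corner cells
simply have fewer neighbors — a no-flux boundary for a finite tissue
patch), g_ij = G/G_ref is the dimensionless gap-junction conductance of
the edge, and the channel term comes from the single-cell model with a
per-cell conductance ratio G_out/G_in (set globally or by a blocker
field).  Junction capacitance is accepted in the config for fidelity to
the circuit picture but must be zero: the conductance term dominates for
typical junction values, so the capacitive coupling is dropped.

Time stepping is implicit-explicit (IMEX) with a constant matrix: the
linear coupling is treated implicitly through A = I + dt_hat L (L the
weighted graph Laplacian, factorized once per run) while the nonlinear
channel currents are explicit, so each step is a single sparse solve
A dv = B with B = dt_hat [ -i(v^n) - L v^n ].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .single_cell import (
    FixedPoint,
    MembraneModel,
    dimensionless_total_current,
    find_fixed_points,
)

__all__ = [
    "LatticeSpec",
    "CouplingParams",
    "EnsembleState",
    "CellFields",
    "SimConfig",
    "StepMatrix",
    "Trajectory",
    "build_laplacian",
    "channel_rhs",
    "assemble_step_matrix",
    "step",
    "simulate",
    "make_initial_condition",
    "summarize",
    "stable_levels",
    "fixed_points_for_ratio",
]


@dataclass(frozen=True)
class LatticeSpec:
    """A rows x cols square lattice with 4-neighbor connectivity."""

    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"lattice must be at least 1x1, got {self.rows}x{self.cols}")

    @property
    def n(self) -> int:
        return self.rows * self.cols

    def index(self, row: int, col: int) -> int:
        return row * self.cols + col


@dataclass(frozen=True)
class CouplingParams:
    """Per-edge gap-junction parameters.

    ``g`` is the dimensionless junction conductance G/G_ref, either a
    scalar (uniform) or a pair of arrays ``(horizontal, vertical)`` with
    shapes (rows, cols-1) and (rows-1, cols).  ``capacitance_ratio``
    must remain 0 (capacitive junction coupling is omitted).
    """

    g: float | tuple[np.ndarray, np.ndarray] = 0.25
    capacitance_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.capacitance_ratio != 0.0:
            raise ValueError("junction capacitance coupling is not supported; capacitance_ratio must be 0")
        if np.isscalar(self.g):
            if self.g < 0:
                raise ValueError(f"junction conductance must be >= 0, got {self.g}")
        else:
            h, v = self.g
            if np.any(np.asarray(h) < 0) or np.any(np.asarray(v) < 0):
                raise ValueError("junction conductances must be >= 0 everywhere")

    def edge_fields(self, lattice: LatticeSpec) -> tuple[np.ndarray, np.ndarray]:
        """(horizontal, vertical) per-edge conductance arrays."""
        if np.isscalar(self.g):
            h = np.full((lattice.rows, max(lattice.cols - 1, 0)), float(self.g))
            v = np.full((max(lattice.rows - 1, 0), lattice.cols), float(self.g))
            return h, v
        h, v = (np.asarray(a, dtype=float) for a in self.g)
        if h.shape != (lattice.rows, lattice.cols - 1) or v.shape != (lattice.rows - 1, lattice.cols):
            raise ValueError("per-edge conductance arrays do not match the lattice")
        return h, v


@dataclass
class EnsembleState:
    """Per-cell dimensionless potentials at a dimensionless time."""

    v: np.ndarray  # flat, length rows*cols, row-major
    t_hat: float
    lattice: LatticeSpec

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float).ravel()
        if self.v.size != self.lattice.n:
            raise ValueError(f"state length {self.v.size} does not match lattice {self.lattice.rows}x{self.lattice.cols}")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("state contains non-finite potentials")

    @property
    def grid(self) -> np.ndarray:
        """(rows, cols) view of the potentials."""
        return self.v.reshape(self.lattice.rows, self.lattice.cols)

    def potentials_mv(self, model: MembraneModel) -> np.ndarray:
        return self.grid * model.thermal_potential


@dataclass
class CellFields:
    """Per-cell channel fields: the local conductance ratio G_out/G_in.

    Equilibrium potentials, thresholds and gating charges stay global
    (ionic concentrations are buffered on electrical time scales); only
    the outward/inward conductance balance varies in space, via channel
    up/down-regulation or blocker action.
    """

    conductance_ratio: np.ndarray  # (rows, cols)

    def __post_init__(self) -> None:
        self.conductance_ratio = np.asarray(self.conductance_ratio, dtype=float)
        if np.any(self.conductance_ratio < 0):
            raise ValueError("conductance ratio must be >= 0 everywhere")

    @classmethod
    def uniform(cls, lattice: LatticeSpec, ratio: float) -> "CellFields":
        return cls(np.full((lattice.rows, lattice.cols), float(ratio)))


@dataclass(frozen=True)
class SimConfig:
    """Run control: constant dimensionless step, horizon, snapshots."""

    dt_hat: float = 0.01
    t_hat_final: float = 10.0
    snapshot_times: tuple[float, ...] = ()
    steady_state_tol: float | None = None  # max |dv|/dt_hat for early stop

    def __post_init__(self) -> None:
        if self.dt_hat <= 0:
            raise ValueError(f"time step must be > 0, got {self.dt_hat}")
        if self.t_hat_final < 0:
            raise ValueError(f"final time must be >= 0, got {self.t_hat_final}")
        for t in self.snapshot_times:
            if not 0 <= t <= self.t_hat_final:
                raise ValueError(f"snapshot time {t} outside [0, {self.t_hat_final}]")


def build_laplacian(lattice: LatticeSpec, coupling: CouplingParams) -> sp.csr_matrix:
    """Weighted graph Laplacian L of the lattice: (L v)_i = sum_nn g_ij (v_i - v_j).

    Symmetric positive semi-definite, zero row sums; off-diagonals are
    -g_ij on lattice edges.
    """
    h, v = coupling.edge_fields(lattice)
    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    idx = np.arange(lattice.n).reshape(lattice.rows, lattice.cols)
    if lattice.cols > 1:
        i, j, w = idx[:, :-1].ravel(), idx[:, 1:].ravel(), h.ravel()
        rows_i += [i, j]
        rows_j += [j, i]
        vals += [-w, -w]
    if lattice.rows > 1:
        i, j, w = idx[:-1, :].ravel(), idx[1:, :].ravel(), v.ravel()
        rows_i += [i, j]
        rows_j += [j, i]
        vals += [-w, -w]
    if rows_i:
        off = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows_i), np.concatenate(rows_j))),
            shape=(lattice.n, lattice.n),
        ).tocsr()
    else:
        off = sp.csr_matrix((lattice.n, lattice.n))
    deg = -np.asarray(off.sum(axis=1)).ravel()
    return (sp.diags(deg) + off).tocsr()


def channel_rhs(state: EnsembleState, fields: CellFields, model: MembraneModel) -> np.ndarray:
    """The explicit (channel) part of dv/dt_hat: -i_total(v_i) per cell."""
    if fields.conductance_ratio.shape != (state.lattice.rows, state.lattice.cols):
        raise ValueError("cell fields grid does not match the lattice")
    return -dimensionless_total_current(state.v, fields.conductance_ratio.ravel(), model)


@dataclass
class StepMatrix:
    """The constant IMEX matrix A = I + dt_hat L, with a cached LU factor."""

    matrix: sp.csr_matrix
    dt_hat: float
    _lu: object | None = field(default=None, repr=False)

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self._lu is None:
            self._lu = splu(self.matrix.tocsc())
        return self._lu.solve(b)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def assemble_step_matrix(laplacian: sp.spmatrix, dt_hat: float) -> StepMatrix:
    """A = I + dt_hat * L; symmetric positive definite (eigenvalues >= 1),
    assembled once and held constant for the whole run."""
    if dt_hat <= 0:
        raise ValueError(f"time step must be > 0, got {dt_hat}")
    n = laplacian.shape[0]
    return StepMatrix((sp.identity(n, format="csr") + dt_hat * laplacian.tocsr()).tocsr(), dt_hat)


def step(
    state: EnsembleState,
    a: StepMatrix,
    fields: CellFields,
    model: MembraneModel,
    dt_hat: float | None = None,
) -> EnsembleState:
    """One IMEX step: solve A dv = B, B_i = dt [channel + coupling residual at v^n].

    The coupling residual -L v^n is recovered from A itself as
    (v - A v)/dt, so the step needs no separate Laplacian.  At a uniform
    state sitting on a single-cell fixed point both parts of B vanish
    and the state is exactly stationary.
    """
    dt = a.dt_hat if dt_hat is None else dt_hat
    if dt != a.dt_hat:
        raise ValueError(f"step matrix was assembled for dt_hat={a.dt_hat}, got {dt}")
    coupling_residual = state.v - a.matrix @ state.v  # = -dt * L v
    b = dt * channel_rhs(state, fields, model) + coupling_residual
    dv = a.solve(b)
    if not np.all(np.isfinite(dv)):
        raise FloatingPointError("IMEX solve produced non-finite increments")
    return EnsembleState(state.v + dv, state.t_hat + dt, state.lattice)


@dataclass
class Trajectory:
    """Ordered snapshots of an ensemble run."""

    snapshots: list[EnsembleState]
    stopped_early: bool = False
    stop_t_hat: float | None = None

    @property
    def times(self) -> list[float]:
        return [s.t_hat for s in self.snapshots]

    @property
    def final(self) -> EnsembleState:
        return self.snapshots[-1]


def simulate(
    initial: EnsembleState,
    fields: CellFields,
    model: MembraneModel,
    coupling: CouplingParams,
    config: SimConfig,
) -> Trajectory:
    """Integrate the lattice from ``initial`` to t_hat_final.

    Snapshots are taken at the requested times (rounded to the nearest
    step), always including the initial and final states.  If
    ``steady_state_tol`` is set, the run may stop early once
    max|dv|/dt_hat falls below it; the stop time is recorded.
    """
    lattice = initial.lattice
    lap = build_laplacian(lattice, coupling)
    a = assemble_step_matrix(lap, config.dt_hat)
    n_steps = int(round(config.t_hat_final / config.dt_hat))
    want = {int(round(t / config.dt_hat)) for t in config.snapshot_times}
    want |= {0, n_steps}

    state = EnsembleState(initial.v.copy(), initial.t_hat, lattice)
    snaps: list[EnsembleState] = []
    if 0 in want:
        snaps.append(EnsembleState(state.v.copy(), state.t_hat, lattice))
    stopped = False
    stop_t: float | None = None
    for k in range(1, n_steps + 1):
        prev = state.v
        state = step(state, a, fields, model)
        if k in want:
            snaps.append(EnsembleState(state.v.copy(), state.t_hat, lattice))
        if config.steady_state_tol is not None:
            rate = np.max(np.abs(state.v - prev)) / config.dt_hat
            if rate < config.steady_state_tol:
                stopped, stop_t = True, state.t_hat
                if k not in want:
                    snaps.append(EnsembleState(state.v.copy(), state.t_hat, lattice))
                break
    return Trajectory(snaps, stopped, stop_t)


def _fp_cache_key(model: MembraneModel, ratio: float) -> tuple:
    return (
        model.inward, model.outward, model.thermal_potential,
        model.reference_conductance, round(float(ratio), 12),
    )


_FP_CACHE: dict[tuple, list[FixedPoint]] = {}


def fixed_points_for_ratio(model: MembraneModel, ratio: float) -> list[FixedPoint]:
    """Single-cell fixed points with the local G_out/G_in, memoized."""
    key = _fp_cache_key(model, ratio)
    if key not in _FP_CACHE:
        _FP_CACHE[key] = find_fixed_points(model.with_conductance_ratio(float(ratio)))
    return _FP_CACHE[key]


def stable_levels(model: MembraneModel, ratio: float = 1.0) -> tuple[float, float]:
    """(hyperpolarized, depolarized) stable potentials, dimensionless.

    For a monostable cell both entries are the single stable root.
    """
    fps = [fp for fp in fixed_points_for_ratio(model, ratio) if fp.stability == "stable"]
    if not fps:
        raise ValueError("model has no stable fixed point in the scan window")
    vt = model.thermal_potential
    return fps[0].potential / vt, fps[-1].potential / vt


def make_initial_condition(
    lattice: LatticeSpec,
    pattern: Literal["uniform", "central_patch", "mask"],
    levels: tuple[float, float] | float,
    *,
    patch_shape: tuple[int, int] = (10, 10),
    mask: np.ndarray | None = None,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> EnsembleState:
    """Initial potential grids: uniform, centered rectangular patch, or mask.

    ``levels`` is (background, patch) in dimensionless units for
    "central_patch"/"mask" (typically the hyperpolarized and depolarized
    stable roots), or a single level for "uniform".  Optional Gaussian
    jitter requires an explicit ``rng``.
    """
    grid = np.empty((lattice.rows, lattice.cols), dtype=float)
    if pattern == "uniform":
        level = levels if np.isscalar(levels) else levels[0]
        grid[:] = level
    elif pattern == "central_patch":
        background, patch = levels  # type: ignore[misc]
        pr, pc = patch_shape
        if pr > lattice.rows or pc > lattice.cols:
            raise ValueError(f"patch {pr}x{pc} does not fit in lattice {lattice.rows}x{lattice.cols}")
        grid[:] = background
        r0 = (lattice.rows - pr) // 2
        c0 = (lattice.cols - pc) // 2
        grid[r0 : r0 + pr, c0 : c0 + pc] = patch
    elif pattern == "mask":
        if mask is None:
            raise ValueError("mask pattern requires a mask array")
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (lattice.rows, lattice.cols):
            raise ValueError("mask shape does not match the lattice")
        background, patch = levels  # type: ignore[misc]
        grid[:] = background
        grid[mask] = patch
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    if jitter_sd > 0:
        if rng is None:
            raise ValueError("initial-condition jitter requires an explicit random generator")
        grid = grid + rng.normal(0.0, jitter_sd, size=grid.shape)
    return EnsembleState(grid.ravel(), 0.0, lattice)


def summarize(state: EnsembleState, model: MembraneModel, fields: CellFields) -> dict[str, float]:
    """Basin-resolved summary of a potential map.

    A cell counts as depolarized iff its potential exceeds its local
    single-cell unstable root (the basin boundary).  Where the local
    model is monostable the cell inherits the classification of its
    single stable root, judged against the midpoint of the two channel
    equilibrium potentials.
    """
    vt = model.thermal_potential
    ratios = fields.conductance_ratio.ravel()
    v = state.v
    depol = np.zeros(v.shape, dtype=bool)
    midpoint = 0.5 * (model.inward.equilibrium_potential + model.outward.equilibrium_potential) / vt
    for ratio in np.unique(ratios):
        cells = ratios == ratio
        fps = fixed_points_for_ratio(model, float(ratio))
        unstable = [fp for fp in fps if fp.stability == "unstable"]
        if unstable:
            depol[cells] = v[cells] > unstable[0].potential / vt
        else:
            stable = [fp for fp in fps if fp.stability == "stable"]
            depol[cells] = stable[0].potential / vt > midpoint if stable else False
    return {
        "fraction_depolarized": float(np.mean(depol)),
        "mean_potential_mv": float(np.mean(v) * vt),
        "min_potential_mv": float(np.min(v) * vt),
        "max_potential_mv": float(np.max(v) * vt),
    }
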