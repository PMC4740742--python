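"""Channel-blocker fields in the extracellular microenvironment.

A blocker at concentration c reduces the outward-rectifier conductance
through a fast local equilibrium reaction,

    G_out(c) = G_out0 / (1 + K c)       (hyperbolic blocking law)

so the per-cell conductance ratio r = G_out/G_in runs from the unblocked
value r0 = G_out0/G_in at c = 0 down to zero at full blocking.  r0 may
exceed 1 when the outward channel is upregulated.  Only the product K*c
is physically meaningful, so steady profiles can equivalently be
specified directly in ratio space; the built-in axial families (linear,
exponential, logistic in x) and the 2-D "cross" profile are pinned to
prescribed endpoint ratios (0.05 at maximum blocker, 2.5 at minimum by
default).

Blocker transport, when requested, is plain Fickian diffusion with
no-flux boundaries, integrated by forward-time centered-space (FTCS)
under a hard stability guard; its characteristic time is
tau_d = L^2/D, hours-scale for typical tissue lengths — far slower
than the milliseconds-to-seconds electrical relaxation, which is why
the patterning runs assume a fully developed steady profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .ensemble import CellFields, LatticeSpec

__all__ = [
    "BlockingLaw",
    "BlockerProfile",
    "DiffusionConfig",
    "ratio_from_concentration",
    "make_axial_profile",
    "make_2d_profile",
    "diffuse",
    "diffusion_time",
    "couple_to_ensemble",
]

ProfileFamily = Literal["linear", "exponential", "logistic"]


@dataclass(frozen=True)
class BlockingLaw:
    """Hyperbolic blocking: ratio(c) = r0 / (1 + K c)."""

    blocking_constant: float  # K, inverse concentration units
    unblocked_ratio: float  # r0 = G_out0/G_in

    def __post_init__(self) -> None:
        if self.blocking_constant < 0:
            raise ValueError(f"blocking constant must be >= 0, got {self.blocking_constant}")
        if self.unblocked_ratio < 0:
            raise ValueError(f"unblocked ratio must be >= 0, got {self.unblocked_ratio}")


@dataclass
class BlockerProfile:
    """A blocker concentration field sampled on the cell grid."""

    concentration: np.ndarray  # (rows, cols) or (n,), arbitrary units
    law: BlockingLaw

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if np.any(self.concentration < 0):
            raise ValueError("blocker concentration must be >= 0 everywhere")

    def ratio_grid(self) -> np.ndarray:
        return ratio_from_concentration(self.concentration, self.law)


def ratio_from_concentration(c: float | np.ndarray, law: BlockingLaw) -> float | np.ndarray:
    """Local conductance ratio under the hyperbolic blocking law.

    Strictly decreasing in c, from r0 at c = 0 toward 0 (maximum
    blocking) as c grows.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("blocker concentration must be >= 0")
    r = law.unblocked_ratio / (1.0 + law.blocking_constant * c_arr)
    return r if np.ndim(c) else float(r)


def _axial_shape(family: ProfileFamily, x: np.ndarray, steepness: float) -> np.ndarray:
    """Monotone increasing shape on x in [0,1], s(0)=0, s(1)=1."""
    if family == "linear":
        return x
    if family == "exponential":
        return (np.expm1(steepness * x)) / np.expm1(steepness)
    if family == "logistic":
        s = 1.0 / (1.0 + np.exp(-steepness * (x - 0.5)))
        s0 = 1.0 / (1.0 + np.exp(steepness * 0.5))
        s1 = 1.0 / (1.0 + np.exp(-steepness * 0.5))
        return (s - s0) / (s1 - s0)
    raise ValueError(f"unknown profile family {family!r}")


def make_axial_profile(
    family: ProfileFamily,
    lattice: LatticeSpec,
    ratio_endpoints: tuple[float, float] = (0.05, 2.50),
    steepness: float = 4.0,
) -> np.ndarray:
    """Per-cell G_out/G_in grid varying along x (columns), constant in y.

    The first and last columns take the endpoint ratios exactly; the
    three built-in families interpolate monotonically between them.  The
    default endpoints (0.05, 2.50) span maximum blocking on the left to
    an upregulated, unblocked outward channel on the right.
    """
    r_left, r_right = ratio_endpoints
    if r_left <= 0 or r_right <= 0:
        raise ValueError(f"endpoint ratios must be > 0, got {ratio_endpoints}")
    if lattice.cols == 1:
        x = np.zeros(1)
        row = np.array([r_left])
    else:
        x = np.linspace(0.0, 1.0, lattice.cols)
        s = _axial_shape(family, x, steepness)
        row = r_left + (r_right - r_left) * s
        row[0], row[-1] = r_left, r_right  # pin exactly against roundoff
    return np.tile(row, (lattice.rows, 1))


def make_2d_profile(
    lattice: LatticeSpec,
    ratio_min: float = 0.05,
    ratio_max: float = 2.5,
    shape: Literal["cross"] = "cross",
    decay_length: float = 0.25,
) -> np.ndarray:
    """2-D conductance-ratio grid for patterning along both axes.

    The "cross" profile emulates a blocker released along the central
    row and column: concentration decays exponentially away from each
    axis (decay length as a fraction of the half-width), the local
    concentration is the larger of the two, and the blocking law maps it
    to a ratio renormalized so the cross attains ``ratio_min`` exactly
    and the four corners ``ratio_max``.  The construction is even in
    both axes, so the grid is mirror-symmetric about the center.
    """
    if shape != "cross":
        raise ValueError(f"unknown 2-D profile shape {shape!r}")
    if lattice.rows < 3 or lattice.cols < 3:
        raise ValueError("2-D profiles need at least a 3x3 lattice")
    if not 0 < ratio_min <= ratio_max:
        raise ValueError(f"need 0 < ratio_min <= ratio_max, got {(ratio_min, ratio_max)}")
    rc, cc = (lattice.rows - 1) / 2.0, (lattice.cols - 1) / 2.0
    dy = np.abs(np.arange(lattice.rows) - rc)[:, None] / max(rc, 1.0)
    dx = np.abs(np.arange(lattice.cols) - cc)[None, :] / max(cc, 1.0)
    c = np.maximum(np.exp(-dy / decay_length), np.exp(-dx / decay_length))
    # hyperbolic blocking of an unblocked ratio_max, then exact renormalization
    k = (ratio_max / ratio_min - 1.0) / (c.max() - c.min() + np.finfo(float).tiny) if ratio_max > ratio_min else 0.0
    ratio = ratio_max / (1.0 + k * (c - c.min()))
    return ratio


@dataclass(frozen=True)
class DiffusionConfig:
    """FTCS diffusion setup with no-flux boundaries.

    Stability requires D dt (1/dx^2) <= 1/2 in 1-D and
    D dt (1/dx^2 + 1/dy^2) <= 1/2 in 2-D; violation is an error naming
    the bound, never a silent clamp.
    """

    diffusion_coefficient: float  # D, m^2/s
    domain_length: float  # L, m
    grid_spacing: float  # dx, m
    dt: float  # s

    def __post_init__(self) -> None:
        for name in ("diffusion_coefficient", "domain_length", "grid_spacing", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def stability_number(self, ndim: int = 1) -> float:
        return ndim * self.diffusion_coefficient * self.dt / self.grid_spacing**2


def diffuse(c: np.ndarray, config: DiffusionConfig, n_steps: int) -> np.ndarray:
    """Advance a 1-D or 2-D concentration field by n_steps of FTCS.

    No-flux (reflecting) boundaries conserve total mass to machine
    precision; the explicit scheme obeys a discrete maximum principle
    under the stability bound, so no new extrema appear.
    """
    c = np.asarray(c, dtype=float).copy()
    if c.ndim not in (1, 2):
        raise ValueError(f"concentration field must be 1-D or 2-D, got ndim={c.ndim}")
    if n_steps < 0:
        raise ValueError(f"n_steps must be >= 0, got {n_steps}")
    alpha = config.diffusion_coefficient * config.dt / config.grid_spacing**2
    if c.ndim * alpha > 0.5 + 1e-12:
        raise ValueError(
            f"FTCS stability violated: {c.ndim} * D*dt/dx^2 = {c.ndim * alpha:.4g} > 0.5; "
            "reduce dt or coarsen the grid"
        )
    for _ in range(n_steps):
        # reflecting ghost cells = no-flux
        padded = np.pad(c, 1, mode="edge")
        if c.ndim == 1:
            lap = padded[:-2] - 2.0 * c + padded[2:]
        else:
            lap = (
                padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:] - 4.0 * c
            )
        c = c + alpha * lap
    return c


def diffusion_time(length: float, diffusion_coefficient: float) -> float:
    """Characteristic diffusional time tau_d = L^2/D, in seconds.

    For L ~ 1 mm (a hundred cell diameters) and D ~ 1e-10 m^2/s this is
    1e4 s, about three hours — the slow clock of blocker patterning.
    """
    if length <= 0 or diffusion_coefficient <= 0:
        raise ValueError("length and diffusion coefficient must be > 0")
    return length**2 / diffusion_coefficient


def couple_to_ensemble(ratio_grid: np.ndarray, lattice: LatticeSpec | None = None) -> CellFields:
    """Wrap a conductance-ratio grid as per-cell channel fields.

    The channel responds instantaneously to the local blocker (fast
    blocking reaction): no lag state is kept.
    """
    grid = np.asarray(ratio_grid, dtype=float)
    if lattice is not None and grid.shape != (lattice.rows, lattice.cols):
        raise ValueError(f"ratio grid {grid.shape} does not match lattice {lattice.rows}x{lattice.cols}")
    return CellFields(grid)
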