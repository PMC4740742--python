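"""Boltzmann-equilibrium allocation of charged nanoparticles.

A fixed number of particles of valence z_np distributes over the cell
potential map with local density proportional to exp(-z_np V_i / V_T):
cationic particles (z_np > 0) concentrate around hyperpolarized
(strongly negative) cells.  Only ratios of weights are physical; the
integer allocation is a deterministic largest-remainder rounding of the
expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NanoparticleSpec", "boltzmann_weights", "allocate", "allocation_table"]


@dataclass(frozen=True)
class NanoparticleSpec:
    """Particle population: total count and valence (positive = cationic)."""

    total_count: int = 10000
    valence: float = 1.0

    def __post_init__(self) -> None:
        if self.total_count < 0:
            raise ValueError(f"particle count must be >= 0, got {self.total_count}")


def boltzmann_weights(potentials_mv: np.ndarray, valence: float = 1.0, v_t: float = 27.0) -> np.ndarray:
    """Normalized Boltzmann weights w_i proportional to exp(-z V_i/V_T).

    The maximum exponent is shifted out before exponentiation, so the
    result is overflow-safe and exactly invariant to adding a constant
    to all potentials (only potential differences matter).
    """
    v = np.asarray(potentials_mv, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("potential map is empty")
    if not np.all(np.isfinite(v)):
        raise ValueError("potential map contains non-finite values")
    if v_t <= 0:
        raise ValueError(f"thermal potential must be > 0, got {v_t}")
    x = -valence * v / v_t
    w = np.exp(x - x.max())
    return w / w.sum()


def allocate(total_count: int, weights: np.ndarray) -> np.ndarray:
    """Integer particle counts per cell by largest-remainder rounding.

    Counts sum exactly to ``total_count``; each count differs from the
    real-valued quota total_count * w_i by less than 1.  Remainder ties
    break toward the lower cell index, so the result is deterministic.
    """
    if total_count < 0:
        raise ValueError(f"particle count must be >= 0, got {total_count}")
    w = np.asarray(weights, dtype=float).ravel()
    if w.size == 0 or np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must be non-negative and sum to 1")
    quota = total_count * w
    counts = np.floor(quota).astype(np.int64)
    leftover = int(total_count - counts.sum())
    if leftover > 0:
        remainder = quota - counts
        # stable sort descending by remainder -> ties go to lower index
        order = np.argsort(-remainder, kind="stable")
        counts[order[:leftover]] += 1
    return counts


def allocation_table(
    potentials_mv: np.ndarray, spec: NanoparticleSpec, v_t: float = 27.0
) -> pd.DataFrame:
    """Long-format allocation over a (rows, cols) potential map:
    columns cell_row, cell_col, V_mV, weight, count."""
    grid = np.asarray(potentials_mv, dtype=float)
    if grid.ndim != 2:
        raise ValueError(f"potential map must be 2-D, got ndim={grid.ndim}")
    w = boltzmann_weights(grid, spec.valence, v_t)
    counts = allocate(spec.total_count, w)
    rows, cols = np.indices(grid.shape)
    return pd.DataFrame(
        {
            "cell_row": rows.ravel(),
            "cell_col": cols.ravel(),
            "V_mV": grid.ravel(),
            "weight": w,
            "count": counts,
        }
    )
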