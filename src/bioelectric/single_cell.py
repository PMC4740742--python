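"""Single-cell membrane model with two generic voltage-gated channels.

The cell's electrical state is its membrane potential V_m, set by the
competition between an inward-rectifying channel (conducting at
hyperpolarized potentials, pinning V_m near its equilibrium potential
E_in) and an outward-rectifying channel (the mirror image, favoring the
depolarized state near E_out).  Each channel carries a current

    I(V) = G * p(V) * (V - E)

where the open probability ``p`` is a Boltzmann sigmoid of the membrane
potential, steepness set by the gating charge z and the thermal
potential V_T = RT/F.  For suitable parameters the total current has
three zeros: two stable resting potentials (hyperpolarized/"normal" and
depolarized/"abnormal") separated by an unstable one — a two-state
bioelectric memory.

Sign convention: current is positive outward and the isolated-cell
dynamics are C dV/dt = -I_total(V), so a zero of I_total with positive
slope dI/dV is a stable resting potential.

Units: potentials in mV, conductances in nS, currents in pA (so that
G[nS] * V[mV] = I[pA] directly), capacitance in pF, time in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ChannelParams",
    "MembraneModel",
    "FixedPoint",
    "BifurcationResult",
    "thermal_potential",
    "open_probability",
    "channel_current",
    "total_current",
    "total_current_slope",
    "dimensionless_total_current",
    "find_fixed_points",
    "bifurcation_diagram",
    "nondimensionalize",
    "dimensionalize",
    "default_model",
]

GAS_CONSTANT = 8.31446261815324  # J/(mol K)
FARADAY = 96485.33212  # C/mol

Rectification = Literal["inward", "outward"]


def thermal_potential(temperature_k: float = 310.0) -> float:
    """Thermal potential RT/F in mV at the given absolute temperature.

    At a physiological 310 K this is 26.7 mV, conventionally rounded to
    the 27 mV used as the model's literal V_T constant.
    """
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return GAS_CONSTANT * temperature_k / FARADAY * 1e3


@dataclass(frozen=True)
class ChannelParams:
    """One voltage-gated channel.

    Parameters
    ----------
    conductance : float
        Maximum conductance G, nS.
    equilibrium_potential : float
        Reversal potential E, mV; the channel current is zero there.
    threshold : float
        Threshold (half-activation) potential V_th, mV: p(V_th) = 1/2.
    gating_charge : float
        Effective gating charge z > 0; sets the sigmoid steepness.
    rectification : {"inward", "outward"}
        Direction of rectification. The inward rectifier opens at
        hyperpolarized V (p -> 1 as V -> -inf); the outward rectifier is
        its mirror.
    """

    conductance: float
    equilibrium_potential: float
    threshold: float
    gating_charge: float
    rectification: Rectification

    def __post_init__(self) -> None:
        if self.conductance < 0:
            raise ValueError(f"conductance must be >= 0, got {self.conductance}")
        if self.gating_charge <= 0:
            raise ValueError(f"gating charge must be > 0, got {self.gating_charge}")
        if self.rectification not in ("inward", "outward"):
            raise ValueError(f"rectification must be 'inward' or 'outward', got {self.rectification!r}")

    @property
    def gating_sign(self) -> float:
        """+1 for inward (p decreasing in V), -1 for outward."""
        return 1.0 if self.rectification == "inward" else -1.0


@dataclass(frozen=True)
class MembraneModel:
    """The inward/outward channel pair plus reference constants.

    ``thermal_potential`` is stored as a literal model constant (default
    27 mV) rather than recomputed from R, T, F, so worked examples
    reproduce exactly; use :func:`thermal_potential` for RT/F at an
    arbitrary temperature.

    ``reference_conductance`` (default: the inward conductance) and
    ``reference_capacitance`` define the nondimensionalization:
    v = V/V_T, i = I/(G_ref V_T), t_hat = t/tau with tau = C_0/G_ref.
    """

    inward: ChannelParams
    outward: ChannelParams
    thermal_potential: float = 27.0
    reference_conductance: float | None = None
    reference_capacitance: float = 100.0

    def __post_init__(self) -> None:
        if self.thermal_potential <= 0:
            raise ValueError(f"thermal potential must be > 0, got {self.thermal_potential}")
        if self.reference_capacitance <= 0:
            raise ValueError(f"reference capacitance must be > 0, got {self.reference_capacitance}")
        if self.reference_conductance is None:
            object.__setattr__(self, "reference_conductance", self.inward.conductance)
        if self.reference_conductance <= 0:
            raise ValueError(f"reference conductance must be > 0, got {self.reference_conductance}")
        if self.inward.rectification != "inward" or self.outward.rectification != "outward":
            raise ValueError("model channels must be (inward, outward) rectifiers")

    @property
    def conductance_ratio(self) -> float:
        """G_out / G_in."""
        return self.outward.conductance / self.inward.conductance

    @property
    def tau_seconds(self) -> float:
        """Electrical relaxation time tau = C_0/G_ref in seconds."""
        return self.reference_capacitance * 1e-12 / (self.reference_conductance * 1e-9)

    def with_conductance_ratio(self, ratio: float) -> "MembraneModel":
        """A copy with G_out = ratio * G_in (G_ref unchanged)."""
        if ratio < 0:
            raise ValueError(f"conductance ratio must be >= 0, got {ratio}")
        return replace(
            self,
            outward=replace(self.outward, conductance=ratio * self.inward.conductance),
            reference_conductance=self.reference_conductance,
        )


@dataclass(frozen=True)
class FixedPoint:
    """A zero of the total current, classified by the local slope."""

    potential: float  # mV
    stability: Literal["stable", "unstable"]


def default_model(
    conductance_ratio: float = 1.0,
    *,
    g_in: float = 1.0,
    e_in: float = -60.0,
    e_out: float = 0.0,
    v_th: float = -25.0,
    z: float = 3.0,
    v_t: float = 27.0,
    c_0: float = 100.0,
) -> MembraneModel:
    """The reference parameter set: G_in = 1 nS, V_th = -25 mV, z = 3,
    E_in = -60 mV, E_out = 0 mV, V_T = 27 mV, C_0 = 100 pF, with
    G_out = conductance_ratio * G_in."""
    inward = ChannelParams(g_in, e_in, v_th, z, "inward")
    outward = ChannelParams(conductance_ratio * g_in, e_out, v_th, z, "outward")
    return MembraneModel(inward, outward, v_t, g_in, c_0)


def open_probability(v: float | np.ndarray, ch: ChannelParams, v_t: float) -> float | np.ndarray:
    """Boltzmann open probability p(V) of a channel.

    Inward rectifier: p = 1 / (1 + exp[ z (V - V_th) / V_T ]), i.e.
    fully open at strongly hyperpolarized potentials; the outward
    rectifier flips the sign of z.
    """
    if v_t <= 0:
        raise ValueError(f"thermal potential must be > 0, got {v_t}")
    x = ch.gating_sign * ch.gating_charge * (np.asarray(v, dtype=float) - ch.threshold) / v_t
    p = 1.0 / (1.0 + np.exp(np.clip(x, -700, 700)))
    return p if np.ndim(v) else float(p)


def channel_current(v: float | np.ndarray, ch: ChannelParams, v_t: float) -> float | np.ndarray:
    """Channel current I(V) = G p(V) (V - E), in pA."""
    i = ch.conductance * open_probability(v, ch, v_t) * (np.asarray(v, dtype=float) - ch.equilibrium_potential)
    return i if np.ndim(v) else float(i)


def total_current(v: float | np.ndarray, model: MembraneModel) -> float | np.ndarray:
    """Total membrane current I_in(V) + I_out(V), in pA."""
    i = channel_current(v, model.inward, model.thermal_potential) + channel_current(
        v, model.outward, model.thermal_potential
    )
    return i if np.ndim(v) else float(i)


def _channel_slope(v: np.ndarray, ch: ChannelParams, v_t: float) -> np.ndarray:
    p = open_probability(v, ch, v_t)
    dp = -ch.gating_sign * ch.gating_charge / v_t * p * (1.0 - p)
    return ch.conductance * (dp * (v - ch.equilibrium_potential) + p)


def total_current_slope(v: float | np.ndarray, model: MembraneModel) -> float | np.ndarray:
    """Analytic dI_total/dV in nS; positive slope at a zero means stable."""
    va = np.asarray(v, dtype=float)
    s = _channel_slope(va, model.inward, model.thermal_potential) + _channel_slope(
        va, model.outward, model.thermal_potential
    )
    return s if np.ndim(v) else float(s)


def dimensionless_total_current(
    v_hat: np.ndarray, conductance_ratio: float | np.ndarray, model: MembraneModel
) -> np.ndarray:
    """Dimensionless total current i(v) at per-cell conductance ratios.

    ``v_hat`` is V/V_T; ``conductance_ratio`` is the local G_out/G_in
    (scalar or broadcastable array).  Returns I/(G_ref V_T).  Used by
    the lattice right-hand side, where the blocker field makes the
    ratio a per-cell quantity while all other parameters stay global.
    """
    vt = model.thermal_potential
    v = np.asarray(v_hat, dtype=float)
    inw, out = model.inward, model.outward
    z_in, z_out = inw.gating_charge, out.gating_charge
    p_in = 1.0 / (1.0 + np.exp(np.clip(z_in * (v - inw.threshold / vt), -700, 700)))
    p_out = 1.0 / (1.0 + np.exp(np.clip(-z_out * (v - out.threshold / vt), -700, 700)))
    g_in = inw.conductance / model.reference_conductance
    ratio = np.asarray(conductance_ratio, dtype=float)
    return g_in * (p_in * (v - inw.equilibrium_potential / vt) + ratio * p_out * (v - out.equilibrium_potential / vt))


def find_fixed_points(
    model: MembraneModel,
    v_range: tuple[float, float] = (-100.0, 40.0),
    scan_step: float = 0.1,
) -> list[FixedPoint]:
    """All zeros of the total current in ``v_range``, sorted ascending.

    Roots are bracketed on a uniform scan grid and refined by Brent's
    method to 1e-9 mV (well inside the 1e-6 mV contract).  Stability is
    classified by the analytic slope of the total current (positive =>
    stable under C dV/dt = -I).  A degenerate tangential root (slope
    ~ 0 at an isolated grid zero) is reported once with a warning.
    """
    lo, hi = v_range
    if not hi > lo:
        raise ValueError(f"empty potential range {v_range}")
    if scan_step <= 0:
        raise ValueError(f"scan step must be > 0, got {scan_step}")
    if scan_step > 1.0:
        raise ValueError(f"scan step must be <= 1 mV to bracket reliably, got {scan_step}")

    grid = np.arange(lo, hi + scan_step / 2, scan_step)
    f = np.asarray(total_current(grid, model))

    roots: list[float] = []
    for k in range(len(grid) - 1):
        if f[k] == 0.0:
            roots.append(float(grid[k]))
        elif f[k] * f[k + 1] < 0:
            roots.append(brentq(lambda v: total_current(v, model), grid[k], grid[k + 1], xtol=1e-9))
    if f[-1] == 0.0:
        roots.append(float(grid[-1]))

    # merge duplicates from exact grid zeros adjacent to sign changes
    merged: list[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > 10 * scan_step * 1e-6 + 1e-9:
            merged.append(r)

    out: list[FixedPoint] = []
    for r in merged:
        slope = total_current_slope(r, model)
        if abs(slope) < 1e-10:
            warnings.warn(f"degenerate (tangential) fixed point near {r:.4f} mV", stacklevel=2)
        out.append(FixedPoint(r, "stable" if slope > 0 else "unstable"))
    return out


@dataclass(frozen=True)
class BifurcationResult:
    """Fixed points over an (E_in, G_out/G_in) sweep.

    ``table`` has one row per fixed point: columns ratio, e_in, v_star,
    stability, n_roots.  ``folds`` lists the saddle-node boundaries as
    the midpoints of consecutive e_in grid values where the root count
    changes, one row per (ratio, e_in_fold, count_before, count_after).
    """

    table: pd.DataFrame
    folds: pd.DataFrame

    def branch(self, ratio: float) -> pd.DataFrame:
        return self.table[self.table["ratio"] == ratio]


def bifurcation_diagram(
    model: MembraneModel,
    e_in_values: Sequence[float],
    conductance_ratios: Sequence[float],
    v_range: tuple[float, float] = (-100.0, 40.0),
    scan_step: float = 0.1,
) -> BifurcationResult:
    """Resting potentials V_m(E_in) parametrically in G_out/G_in.

    For each conductance ratio the sweep traces the stable branches and
    the unstable branch between them; an E_in window with three roots
    marks the bistable (hysteresis) regime, and the window edges are the
    fold (saddle-node) points.
    """
    ratios = np.asarray(list(conductance_ratios), dtype=float)
    if np.any(ratios < 0):
        raise ValueError("conductance ratios must be >= 0")
    rows = []
    fold_rows = []
    for ratio in ratios:
        m_ratio = model.with_conductance_ratio(float(ratio))
        prev_count: int | None = None
        prev_e: float | None = None
        for e_in in e_in_values:
            m = replace(m_ratio, inward=replace(m_ratio.inward, equilibrium_potential=float(e_in)))
            fps = find_fixed_points(m, v_range, scan_step)
            for fp in fps:
                rows.append((float(ratio), float(e_in), fp.potential, fp.stability, len(fps)))
            if prev_count is not None and len(fps) != prev_count:
                fold_rows.append((float(ratio), 0.5 * (prev_e + float(e_in)), prev_count, len(fps)))
            prev_count, prev_e = len(fps), float(e_in)
    table = pd.DataFrame(rows, columns=["ratio", "e_in", "v_star", "stability", "n_roots"])
    folds = pd.DataFrame(fold_rows, columns=["ratio", "e_in_fold", "count_before", "count_after"])
    return BifurcationResult(table, folds)


_KINDS = ("voltage", "current", "time")


def nondimensionalize(value: float | np.ndarray, kind: str, model: MembraneModel) -> float | np.ndarray:
    """Convert V [mV] -> v = V/V_T, I [pA] -> i = I/(G_ref V_T), or
    t [s] -> t_hat = t/tau with tau = C_0/G_ref."""
    if kind == "voltage":
        return value / model.thermal_potential
    if kind == "current":
        return value / (model.reference_conductance * model.thermal_potential)
    if kind == "time":
        return value / model.tau_seconds
    raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")


def dimensionalize(value: float | np.ndarray, kind: str, model: MembraneModel) -> float | np.ndarray:
    """Inverse of :func:`nondimensionalize`."""
    if kind == "voltage":
        return value * model.thermal_potential
    if kind == "current":
        return value * model.reference_conductance * model.thermal_potential
    if kind == "time":
        return value * model.tau_seconds
    raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
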