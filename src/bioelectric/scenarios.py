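"""End-to-end study scenarios: each runs from its configuration alone.

The registry holds one scenario per qualitative regime of the model:

- ``single_cell_bistability``  — the two stable and one unstable
  resting potentials of the reference cell.
- ``patch_normalization``      — a 50x50 ensemble with a 10x10
  depolarized central patch; strong gap-junction coupling (g = 0.25)
  reverts the patch, weak coupling (g = 0.05) isolates it.
- ``channel_upregulation``     — the same patch with the outward
  channel upregulated everywhere (G_out/G_in = 2.5): the depolarized
  region expands instead of normalizing.
- ``blocker_axial``            — an axial blocker profile pinning
  G_out/G_in between 0.05 (left) and 2.5 (right) patterns the map into
  hyperpolarized and depolarized halves.
- ``blocker_cross``            — a 2-D cross-shaped blocker profile
  imprints a hyperpolarized cross on a depolarized background.
- ``nanoparticles``            — Boltzmann allocation of cationic
  particles over the cross-patterned map.

Every run writes text snapshots plus a JSON run record sufficient to
reproduce it bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np

from . import __version__
from .ensemble import (
    CellFields,
    CouplingParams,
    EnsembleState,
    LatticeSpec,
    SimConfig,
    make_initial_condition,
    simulate,
    stable_levels,
    summarize,
)
from .gridio import parameter_hash, write_grid
from .microenvironment import couple_to_ensemble, make_2d_profile, make_axial_profile
from .nanoparticles import NanoparticleSpec, allocation_table
from .single_cell import MembraneModel, default_model, find_fixed_points

__all__ = ["Scenario", "RunRecord", "SCENARIOS", "run_scenario", "list_scenarios", "render_heatmap"]


@dataclass(frozen=True)
class Scenario:
    name: str
    description: str
    defaults: dict[str, Any]
    runner: Callable[..., dict[str, Any]]


@dataclass
class RunRecord:
    """Everything needed to reproduce a run: scenario, full parameter
    echo, seed, tool version, output files and summary metrics."""

    scenario: str
    parameters: dict[str, Any]
    seed: int | None
    version: str
    files: list[str]
    metrics: dict[str, Any]

    def to_json(self, path: Path | str | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _snapshot_meta(params: dict[str, Any], state: EnsembleState, model: MembraneModel) -> dict[str, Any]:
    return {
        "t_hat": state.t_hat,
        "t_seconds": state.t_hat * model.tau_seconds,
        "rows": state.lattice.rows,
        "cols": state.lattice.cols,
        "units": "dimensionless potential v = V/V_T",
        "V_T_mV": model.thermal_potential,
        "params_hash": parameter_hash(params),
        "tool_version": __version__,
    }


def _run_lattice(
    params: dict[str, Any],
    fields: CellFields,
    initial: EnsembleState,
    model: MembraneModel,
    outdir: Path,
    tag: str,
) -> tuple[list[str], dict[str, Any]]:
    coupling = CouplingParams(g=params["g"])
    config = SimConfig(
        dt_hat=params["dt_hat"],
        t_hat_final=params["t_hat_final"],
        snapshot_times=tuple(t for t in params.get("snapshot_times", ()) if t <= params["t_hat_final"]),
        steady_state_tol=params.get("steady_state_tol"),
    )
    traj = simulate(initial, fields, model, coupling, config)
    files = []
    for snap in traj.snapshots:
        f = outdir / f"{tag}_t{snap.t_hat:07.3f}.txt"
        write_grid(f, snap.grid, _snapshot_meta(params, snap, model))
        files.append(str(f))
    first = summarize(traj.snapshots[0], model, fields)
    last = summarize(traj.final, model, fields)
    metrics = {
        "initial_fraction_depolarized": first["fraction_depolarized"],
        "final_fraction_depolarized": last["fraction_depolarized"],
        "final_mean_potential_mv": last["mean_potential_mv"],
        "final_t_hat": traj.final.t_hat,
        "stopped_early": traj.stopped_early,
    }
    return files, metrics


def _patch_initial(params: dict[str, Any], model: MembraneModel, lattice: LatticeSpec) -> EnsembleState:
    hyper, depol = stable_levels(model, params["ratio"])
    return make_initial_condition(
        lattice, "central_patch", (hyper, depol), patch_shape=tuple(params["patch"])
    )


def _run_single_cell(params: dict[str, Any], outdir: Path, seed: int | None) -> dict[str, Any]:
    model = default_model(params["ratio"])
    fps = find_fixed_points(model, tuple(params["v_range"]), params["scan_step"])
    table = outdir / "fixed_points.txt"
    lines = ["# columns = V_star_mV stability", f"# tool_version = {__version__}"]
    lines += [f"{fp.potential:.9f} {fp.stability}" for fp in fps]
    table.write_text("\n".join(lines) + "\n")
    return {
        "files": [str(table)],
        "metrics": {
            "n_fixed_points": len(fps),
            "fixed_points_mv": [fp.potential for fp in fps],
            "stability": [fp.stability for fp in fps],
        },
    }


def _run_patch(params: dict[str, Any], outdir: Path, seed: int | None) -> dict[str, Any]:
    model = default_model(params["ratio"])
    lattice = LatticeSpec(*params["grid"])
    fields = CellFields.uniform(lattice, params["ratio"])
    initial = _patch_initial(params, model, lattice)
    files, metrics = _run_lattice(params, fields, initial, model, outdir, "patch")
    return {"files": files, "metrics": metrics}


def _run_blocker_axial(params: dict[str, Any], outdir: Path, seed: int | None) -> dict[str, Any]:
    model = default_model()
    lattice = LatticeSpec(*params["grid"])
    ratio_grid = make_axial_profile(params["family"], lattice, tuple(params["endpoints"]))
    fields = couple_to_ensemble(ratio_grid, lattice)
    # start from the uniformly depolarized state: the blocker then
    # drives the axial recovery of the hyperpolarized region
    _, depol = stable_levels(model, 1.0)
    initial = make_initial_condition(lattice, "uniform", depol)
    files, metrics = _run_lattice(params, fields, initial, model, outdir, "axial")
    prof = outdir / "ratio_profile.txt"
    write_grid(prof, ratio_grid, {"field": "G_out/G_in", "family": params["family"]})
    files.append(str(prof))
    return {"files": files, "metrics": metrics}


def _run_blocker_cross(params: dict[str, Any], outdir: Path, seed: int | None) -> dict[str, Any]:
    model = default_model()
    lattice = LatticeSpec(*params["grid"])
    ratio_grid = make_2d_profile(lattice, params["ratio_min"], params["ratio_max"])
    fields = couple_to_ensemble(ratio_grid, lattice)
    _, depol = stable_levels(model, 1.0)
    initial = make_initial_condition(lattice, "uniform", depol)
    files, metrics = _run_lattice(params, fields, initial, model, outdir, "cross")
    prof = outdir / "ratio_profile.txt"
    write_grid(prof, ratio_grid, {"field": "G_out/G_in", "shape": "cross"})
    files.append(str(prof))
    return {"files": files, "metrics": metrics}


def _run_nanoparticles(params: dict[str, Any], outdir: Path, seed: int | None) -> dict[str, Any]:
    cross = _run_blocker_cross({**params, "ratio_min": params["ratio_min"], "ratio_max": params["ratio_max"]}, outdir, seed)
    from .gridio import read_grid

    final_map, meta = read_grid(sorted(f for f in cross["files"] if "cross_t" in f)[-1])
    model = default_model()
    table = allocation_table(
        final_map * model.thermal_potential,
        NanoparticleSpec(params["n_particles"], params["valence"]),
        model.thermal_potential,
    )
    out = outdir / "particles.csv"
    table.to_csv(out, index=False)
    return {
        "files": cross["files"] + [str(out)],
        "metrics": {
            **cross["metrics"],
            "total_particles": int(table["count"].sum()),
            "max_count": int(table["count"].max()),
        },
    }


_GRID = (50, 50)
_SIM = {"dt_hat": 0.01, "t_hat_final": 10.0, "snapshot_times": (0.0, 2.0, 5.0, 10.0)}

SCENARIOS: dict[str, Scenario] = {
    "single_cell_bistability": Scenario(
        "single_cell_bistability",
        "Fixed points and stability of the reference two-channel cell",
        {"ratio": 1.0, "v_range": (-100.0, 40.0), "scan_step": 0.1},
        _run_single_cell,
    ),
    "patch_normalization": Scenario(
        "patch_normalization",
        "Depolarized 10x10 patch on a 50x50 lattice; reverts iff coupling is strong",
        {"grid": _GRID, "patch": (10, 10), "ratio": 1.0, "g": 0.25, **_SIM},
        _run_patch,
    ),
    "channel_upregulation": Scenario(
        "channel_upregulation",
        "Same patch with G_out/G_in = 2.5 everywhere: the depolarized region invades",
        {"grid": _GRID, "patch": (10, 10), "ratio": 2.5, "g": 0.25, **_SIM},
        _run_patch,
    ),
    "blocker_axial": Scenario(
        "blocker_axial",
        "Axial blocker profile (ratio 0.05 left to 2.5 right) patterns the map",
        {"grid": _GRID, "family": "exponential", "endpoints": (0.05, 2.5), "g": 0.25, **_SIM},
        _run_blocker_axial,
    ),
    "blocker_cross": Scenario(
        "blocker_cross",
        "2-D cross blocker profile imprints a hyperpolarized cross",
        {"grid": _GRID, "ratio_min": 0.05, "ratio_max": 2.5, "g": 0.25, **_SIM},
        _run_blocker_cross,
    ),
    "nanoparticles": Scenario(
        "nanoparticles",
        "Boltzmann allocation of cationic particles over the cross-patterned map",
        {"grid": _GRID, "ratio_min": 0.05, "ratio_max": 2.5, "g": 0.25,
         "n_particles": 10000, "valence": 1.0, **_SIM},
        _run_nanoparticles,
    ),
}


def list_scenarios() -> list[str]:
    return sorted(SCENARIOS)


def run_scenario(
    name: str,
    outdir: Path | str = "runs",
    overrides: dict[str, Any] | None = None,
    seed: int | None = None,
) -> RunRecord:
    """Run a registered scenario and write its outputs under ``outdir``."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {', '.join(list_scenarios())}")
    sc = SCENARIOS[name]
    params = dict(sc.defaults)
    for key, value in (overrides or {}).items():
        if key not in params:
            raise KeyError(f"unknown override {key!r} for scenario {name!r}")
        params[key] = value
    outdir = Path(outdir) / name
    outdir.mkdir(parents=True, exist_ok=True)
    result = sc.runner(params, outdir, seed)
    record = RunRecord(
        scenario=name,
        parameters=params,
        seed=seed,
        version=__version__,
        files=result["files"],
        metrics=result["metrics"],
    )
    record.to_json(outdir / "run_record.json")
    return record


def render_heatmap(
    grid: np.ndarray,
    path: Path | str,
    model: MembraneModel | None = None,
    particle_counts: np.ndarray | None = None,
) -> Path:
    """Best-effort heatmap of a potential map (dimensionless values).

    The colour scale is anchored at the two stable resting potentials of
    the reference cell so hyperpolarized and depolarized regions keep
    fixed colours across frames.  Optionally overlays particle counts.
    Uses the Agg backend; safe on headless machines.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    model = model or default_model()
    hyper, depol = stable_levels(model, 1.0)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(np.atleast_2d(grid), vmin=hyper, vmax=depol, cmap="RdBu", origin="lower")
    fig.colorbar(im, ax=ax, label="v = V/V_T")
    if particle_counts is not None:
        counts = np.atleast_2d(particle_counts)
        yy, xx = np.nonzero(counts)
        ax.scatter(xx, yy, s=2.0 * counts[yy, xx], c="k", alpha=0.5, linewidths=0)
    ax.set_xlabel("cell column")
    ax.set_ylabel("cell row")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
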