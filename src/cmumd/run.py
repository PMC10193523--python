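"""MD run loop: LJ + control forces -> Langevin step -> sink/source ->
periodic diagnostics (profiles, interface tracking, control record).

Every run is reproducible from its seed: one NumPy Generator drives the
thermostat noise and the sink/source events in a fixed order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analysis import control_diagnostics, density_profile
from .control import CmuController, ControlRecord
from .engine import (
    FROZEN,
    SOLVENT,
    LJParams,
    ParticleState,
    SinkSourceSpec,
    frozen_extent,
    lj_forces,
    sink_source_step,
    step_langevin,
)
from .errors import SimulationStop
from .regions import InterfaceTracker, locate_interface
from .xyz import write_extxyz

__all__ = ["RunSetup", "RunResult", "run_simulation", "save_checkpoint", "load_checkpoint"]


@dataclass
class RunSetup:
    """Everything a run needs, as live objects (see cmumd.config for the
    file-based front end)."""

    state: ParticleState
    lj: LJParams = field(default_factory=LJParams)
    steps: int = 0
    dt: float = 0.005
    gamma: float = 1.0
    temperature: float = 0.85
    seed: int = 0
    controller: CmuController | None = None
    sink: SinkSourceSpec | None = None
    diag_every: int = 50
    dump_every: int = 0  # extxyz frame cadence; 0 keeps only diagnostics
    profile_bin: float = 0.5
    iface_window_steps: int = 100  # EMA span of the interface tracker
    outdir: str | Path | None = None


@dataclass
class RunResult:
    state: ParticleState
    record: ControlRecord | None
    frames: list[ParticleState]
    frozen_series: list[tuple[int, int]]  # (step, frozen count)
    summary: dict
    stopped: bool = False


def save_checkpoint(path, state: ParticleState, seed: int) -> None:
    """Single-file binary checkpoint (NumPy .npz: positions, velocities,
    species, box, step, seed)."""
    np.savez(
        path,
        positions=state.positions,
        velocities=state.velocities,
        species=state.species,
        box=state.box,
        step=state.step,
        seed=seed,
    )


def load_checkpoint(path) -> tuple[ParticleState, int]:
    d = np.load(path)
    state = ParticleState(
        d["positions"], d["velocities"], d["species"], d["box"], step=int(d["step"])
    )
    return state, int(d["seed"])


def _solvent_interface(state, tracker, bin_width):
    """Raw solvent-profile interface faces, EMA-smoothed by the tracker."""
    prof = density_profile([state], bin_width, species=("solvent",))
    lo, hi = frozen_extent(state)
    area = state.box[0] * state.box[1]
    v_fluid = area * (state.box[2] - (hi - lo))
    bulk = state.count("solvent") / v_fluid
    raw = locate_interface(prof.bin_centers, prof["solvent"], bulk, step=state.step)
    return tracker.update(raw)


def run_simulation(setup: RunSetup) -> RunResult:
    """Run the loop; returns the final state, the control record, any dumped
    frames, the frozen-count time series, and a JSON-able summary.

    A :class:`~cmumd.errors.SimulationStop` from the sink/source (slab
    exhausted) ends the run cleanly and is flagged in the result.
    """
    rng = np.random.default_rng(setup.seed)
    state = setup.state.copy()
    ctrl = setup.controller
    record = None
    if ctrl is not None:
        record = ControlRecord(
            [leg.name for leg in ctrl.legs], [leg.c0 for leg in ctrl.legs]
        )
    tracker = InterfaceTracker(
        max(int(setup.iface_window_steps / max(setup.diag_every, 1)), 1)
    )
    frames: list[ParticleState] = []
    frozen_series: list[tuple[int, int]] = []
    last = {"c": None, "fext_total": 0.0}

    def total_force(st: ParticleState) -> np.ndarray:
        f, _ = lj_forces(st, setup.lj)
        if ctrl is not None:
            f_ext, c = ctrl.forces(st)
            f += f_ext
            last["c"] = c
            last["fext_total"] = float(np.sum(np.abs(f_ext)))
        return f

    def diagnose(st: ParticleState):
        faces = ()
        if (st.species == FROZEN).any():
            try:
                iface = _solvent_interface(st, tracker, setup.profile_bin)
                faces = iface.faces
                if ctrl is not None and ctrl.adaptive and len(faces) == 2:
                    ctrl.reanchor(faces[0], faces[1], box_hi=float(st.box[2]))
            except SimulationStop:
                raise
            except Exception:
                faces = ()  # interface not resolvable this step; keep regions
        if record is not None and last["c"] is not None:
            record.append(st.step, last["c"], last["fext_total"], faces)
        frozen_series.append((st.step, int(np.sum(st.species == FROZEN))))

    if setup.dump_every or setup.outdir:
        frames.append(state.copy())
    stopped = False
    force = total_force(state)
    diagnose(state)
    for _ in range(setup.steps):
        state, force = step_langevin(
            state, force, setup.dt, setup.gamma, setup.temperature, rng,
            force_fn=total_force,
        )
        if setup.sink is not None and setup.sink.rate > 0:
            try:
                new = sink_source_step(state, setup.sink, rng)
            except SimulationStop:
                stopped = True
                break
            if not np.array_equal(new.species, state.species):
                state = new
                force = total_force(state)  # species changed: forces stale
            else:
                state = new
        if setup.diag_every and state.step % setup.diag_every == 0:
            diagnose(state)
        if setup.dump_every and state.step % setup.dump_every == 0:
            frames.append(state.copy())

    summary = {
        "seed": setup.seed,
        "steps_run": state.step,
        "stopped_early": stopped,
        "kinetic_temperature": state.kinetic_temperature(),
        "n_frozen_initial": frozen_series[0][1] if frozen_series else 0,
        "n_frozen_final": int(np.sum(state.species == FROZEN)),
    }
    if record is not None and len(record):
        window = max(min(200, len(record) // 2), 1)
        summary["control"] = control_diagnostics(record, window=window)

    if setup.outdir is not None:
        out = Path(setup.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_extxyz(out / "trajectory.extxyz", frames if frames else [state])
        if record is not None:
            record.to_csv(out / "control.csv")
        if frozen_series:
            np.savetxt(
                out / "frozen.csv", np.asarray(frozen_series, dtype=int),
                fmt="%d", delimiter=",", header="step,n_frozen", comments="",
            )
        save_checkpoint(out / "checkpoint.npz", state, setup.seed)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return RunResult(
        state=state,
        record=record,
        frames=frames,
        frozen_series=frozen_series,
        summary=summary,
        stopped=stopped,
    )
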