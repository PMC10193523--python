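"""Seeded scenario generators: every test setup in one place.

Each generator returns a :class:`ScenarioSpec` that fully determines the
initial particle configuration and run setup; regenerating from the same
spec and seed reproduces the inputs bit for bit, and the spec serializes to
the flat run-config dialect with a stamped content hash.

Default geometry and rates place the fluid in a supercritical Lennard-Jones
regime (T = 1.5, total density ~0.45 reduced) that is single-phase and
homogeneous by construction -- below the critical temperature this density
would slowly demix into liquid and vapor, superimposing density drifts on
the concentrations under study -- and mobile enough that depletion, control
response and membrane transport are all observable in runs of 10^4 steps on
one CPU.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .control import (
    CmuController,
    ControlLeg,
    asymmetric_pair,
    cannibalistic_pair,
    face_leg,
    spherical_controller,
    symmetric_pair,
)
from .engine import (
    LJParams,
    ParticleState,
    SinkSourceSpec,
    build_crystal_slab,
    build_membrane,
    fill_region,
    merge_states,
)
from .errors import ParameterError, SizingError
from .run import RunSetup

__all__ = [
    "ScenarioSpec",
    "make_growth_scenario",
    "make_membrane_scenario",
    "make_cannibalistic_scenario",
    "make_spherical_scenario",
    "make_synthetic_trajectory",
    "build_setup",
    "SCENARIOS",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Name + parameters + seed; hash-stamped, serializable, deterministic."""

    name: str
    params: dict
    seed: int

    def canonical(self) -> str:
        lines = [f"scenario = {self.name}", f"seed = {self.seed}"]
        lines += [f"{k} = {self.params[k]!r}" for k in sorted(self.params)]
        return "\n".join(lines) + "\n"

    @property
    def content_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:12]

    def build(self, steps: int = 0, **run_kwargs) -> RunSetup:
        return build_setup(self, steps=steps, **run_kwargs)


# ---------------------------------------------------------------- growth

GROWTH_DEFAULTS = dict(
    c0=0.15,          # target solute concentration in each CR  [1/sigma^3]
    sink_rate=0.001,  # freeze probability per eligible solute per step
    box_xy=7.0,
    box_z=44.0,       # deep reservoirs on both sides of the slab
    slab_lo=20.0,
    slab_hi=24.0,
    density=0.45,     # total fluid number density
    cr_gap=1.5,       # TR width: face -> inner CR edge
    cr_width=3.0,
    fr_gap=6.5,       # face -> FR center
    fr_width=0.8,
    k=600.0,          # restraint force constant  [eps sigma^3 per particle]
    capture=1.2,      # sink eligibility layer beyond each crystal face
    standoff=0.2,     # sink window keeps this gap from the face
    temperature=1.5,  # supercritical: keeps the solution single-phase
    gamma=1.0,
    window_steps=12000,  # measurement window the reservoir must sustain
)


def make_growth_scenario(c0=None, sink_rate=None, seed=0, **overrides) -> ScenarioSpec:
    """Central frozen slab with mirrored CR/FR pairs and a stochastic sink.

    The solute reservoir is sized against the expected sink consumption over
    ``window_steps``; an infeasible request raises
    :class:`~cmumd.errors.SizingError` with suggested counts.
    """
    p = dict(GROWTH_DEFAULTS)
    if c0 is not None:
        p["c0"] = float(c0)
    if sink_rate is not None:
        p["sink_rate"] = float(sink_rate)
    p.update(overrides)
    _check_growth_budget(p)
    return ScenarioSpec("growth", p, int(seed))


def _growth_counts(p) -> tuple[int, int]:
    a = p["box_xy"] ** 2
    v_fluid = a * (p["box_z"] - (p["slab_hi"] - p["slab_lo"]))
    n_solute = int(round(p["c0"] * v_fluid))
    n_solvent = int(round((p["density"] - p["c0"]) * v_fluid))
    if n_solvent < 0:
        raise ParameterError("c0 exceeds the total fluid density")
    return n_solute, n_solvent


def _check_growth_budget(p) -> None:
    a = p["box_xy"] ** 2
    n_solute, _ = _growth_counts(p)
    # expected freezes: rate x mean sink-layer occupancy x window; the
    # eligibility window spans capture - standoff beyond each face
    occupancy = p["c0"] * a * (p["capture"] - p["standoff"]) * 2
    expected = p["sink_rate"] * occupancy * p["window_steps"]
    cr_solute = 2 * p["c0"] * a * p["cr_width"]
    reservoir = n_solute - cr_solute
    if reservoir < 1.2 * expected:
        needed = int(np.ceil(1.2 * expected + cr_solute))
        raise SizingError(
            f"reservoir of {reservoir:.0f} solute cannot sustain ~{expected:.0f} "
            f"sink events over {p['window_steps']} steps; need >= {needed} solute "
            "(enlarge the box, lower sink_rate, or shorten window_steps)"
        )


def _build_growth(spec: ScenarioSpec) -> RunSetup:
    p = spec.params
    rng = np.random.default_rng(spec.seed)
    box = np.array([p["box_xy"], p["box_xy"], p["box_z"]])
    n_solute, n_solvent = _growth_counts(p)
    slab = build_crystal_slab(box, p["slab_lo"], p["slab_hi"], spacing=1.05)
    gap = 0.75  # clearance between crystal faces and first fluid layer
    v_lo = p["slab_lo"] - gap
    v_hi = p["box_z"] - p["slab_hi"] - gap
    frac_lo = v_lo / (v_lo + v_hi)
    n_lo = {
        "solute": int(round(n_solute * frac_lo)),
        "solvent": int(round(n_solvent * frac_lo)),
    }
    n_hi = {
        "solute": n_solute - n_lo["solute"],
        "solvent": n_solvent - n_lo["solvent"],
    }
    lo_fluid = fill_region(
        n_lo, box, np.zeros(3), np.array([*box[:2], p["slab_lo"] - gap]),
        p["temperature"], rng,
    )
    hi_fluid = fill_region(
        n_hi, box, np.array([0, 0, p["slab_hi"] + gap]), box,
        p["temperature"], rng,
    )
    state = merge_states(slab, lo_fluid, hi_fluid)
    center = 0.5 * (p["slab_lo"] + p["slab_hi"])
    # k = 0 keeps the controller as a pure recorder (zero force, depletion
    # runs); regions are anchored to the tracked solvent interface so the
    # TR gap stays fixed as the crystal face advances
    ctrl = symmetric_pair(
        center, 0.5 * (p["slab_hi"] - p["slab_lo"]),
        p["cr_gap"], p["cr_width"], p["fr_gap"], p["fr_width"],
        c0=p["c0"], k=p["k"], anchored=True,
    )
    sink = SinkSourceSpec(
        mode="sink", rate=p["sink_rate"], capture=p["capture"],
        standoff=p["standoff"], temperature=p["temperature"],
    ) if p["sink_rate"] > 0 else None
    return RunSetup(
        state=state, lj=LJParams(), dt=0.005, gamma=p["gamma"],
        temperature=p["temperature"], seed=spec.seed, controller=ctrl, sink=sink,
    )


# ---------------------------------------------------------------- membrane

MEMBRANE_DEFAULTS = dict(
    c_mean=0.45,      # mean of inlet and outlet targets
    dc=0.25,          # inlet minus outlet target
    pores=2,
    pore_radius=1.3,
    box_xy=6.0,
    box_z=30.0,
    memb_lo=13.5,
    memb_hi=16.5,
    cr_gap=0.5,
    cr_width=4.0,
    fr_gap=8.0,
    fr_width=0.8,
    k=300.0,
    temperature=1.5,  # supercritical: keeps the solution single-phase
    gamma=1.0,
)


def make_membrane_scenario(dc=None, pores=None, seed=0, **overrides) -> ScenarioSpec:
    """Porous wall between an inlet CR and an outlet CR with distinct targets
    (single-species fluid; recirculation happens through the z boundary)."""
    p = dict(MEMBRANE_DEFAULTS)
    if dc is not None:
        p["dc"] = float(dc)
    if pores is not None:
        p["pores"] = int(pores)
    p.update(overrides)
    if p["dc"] < 0 or p["c_mean"] - 0.5 * p["dc"] < 0:
        raise ParameterError("targets must be nonnegative with inlet >= outlet")
    return ScenarioSpec("membrane", p, int(seed))


def _build_membrane(spec: ScenarioSpec) -> RunSetup:
    p = spec.params
    rng = np.random.default_rng(spec.seed)
    box = np.array([p["box_xy"], p["box_xy"], p["box_z"]])
    wall, _ = build_membrane(
        box, p["memb_lo"], p["memb_hi"], p["pores"], p["pore_radius"], spacing=1.0
    )
    gap = 0.75
    v_per_side = box[0] * box[1]
    n_lo = int(round(p["c_mean"] * v_per_side * (p["memb_lo"] - gap)))
    n_hi = int(round(p["c_mean"] * v_per_side * (p["box_z"] - p["memb_hi"] - gap)))
    lo = fill_region(
        {"solute": n_lo}, box, np.zeros(3),
        np.array([*box[:2], p["memb_lo"] - gap]), p["temperature"], rng,
    )
    hi = fill_region(
        {"solute": n_hi}, box, np.array([0, 0, p["memb_hi"] + gap]), box,
        p["temperature"], rng,
    )
    state = merge_states(wall, lo, hi)
    c_in = p["c_mean"] + 0.5 * p["dc"]
    c_out = p["c_mean"] - 0.5 * p["dc"]
    inlet = face_leg(
        p["memb_lo"], -1, p["cr_gap"], p["cr_width"], p["fr_gap"], p["fr_width"],
        c0=c_in, k=p["k"], name="inlet",
    )
    outlet = face_leg(
        p["memb_hi"], +1, p["cr_gap"], p["cr_width"], p["fr_gap"], p["fr_width"],
        c0=c_out, k=p["k"], name="outlet",
    )
    import warnings

    with warnings.catch_warnings():
        if p["dc"] == 0:
            warnings.simplefilter("ignore")
        ctrl = asymmetric_pair(inlet, outlet)
    return RunSetup(
        state=state, lj=LJParams(), dt=0.005, gamma=p["gamma"],
        temperature=p["temperature"], seed=spec.seed, controller=ctrl,
    )


# ---------------------------------------------------------------- cannibalistic

CANNIBAL_DEFAULTS = dict(
    # targets and CR size are chosen so each CR holds enough particles
    # (c0 * V_CR ~ 50-80) that the relative counting noise of the
    # instantaneous concentration stays well below the control deviations
    # being measured; small low-concentration CRs fluctuate too much
    c0_s=0.25,        # supersaturated target (low-z, growing face)
    c0_u=0.15,        # undersaturated target (high-z, dissolving face)
    # growth and dissolution fluxes are balanced: freeze events draw from the
    # S-side contact layer (~c0_s * A * (capture - standoff) eligible) at
    # sink_rate, release events emit from one crystal layer (~A eligible)
    # at source_rate, both ~0.0015 events/step, so neither side's solute
    # inventory drains over the run
    sink_rate=8e-5,
    source_rate=2.8e-5,  # per-particle release probability at the U face
    capture=1.6,  # must reach past the crystal contact layer to the fluid
    standoff=0.4,  # freeze window stays clear of the CR side of the TR
    box_xy=8.0,
    box_z=36.0,
    slab_lo=15.5,
    slab_hi=20.5,
    density=0.45,
    cr_gap=1.5,
    cr_width=5.0,
    fr_gap=8.0,
    fr_width=0.8,
    k=300.0,
    temperature=1.5,  # supercritical: keeps the solution single-phase
    gamma=1.0,
)


def make_cannibalistic_scenario(c0_s=None, c0_u=None, seed=0, **overrides) -> ScenarioSpec:
    """Crystal slab growing at its supersaturated face and dissolving at its
    undersaturated face; both CRs anchored to their own tracked interface."""
    p = dict(CANNIBAL_DEFAULTS)
    if c0_s is not None:
        p["c0_s"] = float(c0_s)
    if c0_u is not None:
        p["c0_u"] = float(c0_u)
    p.update(overrides)
    if not p["c0_s"] > p["c0_u"]:
        raise ParameterError("supersaturated target must exceed undersaturated")
    return ScenarioSpec("cannibalistic", p, int(seed))


def _build_cannibalistic(spec: ScenarioSpec) -> RunSetup:
    p = spec.params
    rng = np.random.default_rng(spec.seed)
    box = np.array([p["box_xy"], p["box_xy"], p["box_z"]])
    slab = build_crystal_slab(box, p["slab_lo"], p["slab_hi"], spacing=1.05)
    gap = 0.75
    a = p["box_xy"] ** 2
    # each side starts at its own target concentration (same total density)
    fluids = []
    for c0, lo, hi in (
        (p["c0_s"], 0.0, p["slab_lo"] - gap),
        (p["c0_u"], p["slab_hi"] + gap, p["box_z"]),
    ):
        v = a * (hi - lo)
        counts = {
            "solute": int(round(c0 * v)),
            "solvent": int(round((p["density"] - c0) * v)),
        }
        fluids.append(
            fill_region(counts, box, np.array([0, 0, lo]),
                        np.array([*box[:2], hi]), p["temperature"], rng)
        )
    setup = RunSetup(
        state=merge_states(slab, *fluids), lj=LJParams(), dt=0.005,
        gamma=p["gamma"], temperature=p["temperature"], seed=spec.seed,
    )
    ctrl = cannibalistic_pair(
        p["c0_s"], p["c0_u"], p["slab_lo"], p["slab_hi"],
        p["cr_gap"], p["cr_width"], p["fr_gap"], p["fr_width"], k=p["k"],
    )
    sink = SinkSourceSpec(
        mode="both", rate=p["sink_rate"], rate_source=p["source_rate"],
        capture=p["capture"], standoff=p["standoff"],
        temperature=p["temperature"],
    )
    setup.controller = ctrl
    setup.sink = sink
    return setup


# ---------------------------------------------------------------- spherical

SPHERICAL_DEFAULTS = dict(
    c0=0.10,
    box=14.0,
    gr_radius=2.0,    # nucleus growth region
    cr_lo=3.0,
    cr_hi=5.0,
    fr_center=5.8,
    fr_width=0.5,
    density=0.30,
    k=300.0,
    sink_rate=0.0,
    temperature=1.5,  # supercritical: keeps the solution single-phase
    gamma=1.0,
)


def make_spherical_scenario(c0=None, gr_radius=None, seed=0, **overrides) -> ScenarioSpec:
    """Concentric GR/TR/CR/FR shells about the box center; the reservoir is
    the box corners outside the outer shell."""
    p = dict(SPHERICAL_DEFAULTS)
    if c0 is not None:
        p["c0"] = float(c0)
    if gr_radius is not None:
        p["gr_radius"] = float(gr_radius)
    p.update(overrides)
    if not p["gr_radius"] < p["cr_lo"] < p["cr_hi"] < p["fr_center"]:
        raise ParameterError("shells must be ordered GR < TR < CR < FR")
    if p["fr_center"] + 2 * p["fr_width"] > 0.5 * p["box"]:
        raise ParameterError("outer shell exceeds the half box (minimum image)")
    return ScenarioSpec("spherical", p, int(seed))


def _build_spherical(spec: ScenarioSpec) -> RunSetup:
    p = spec.params
    rng = np.random.default_rng(spec.seed)
    box = np.full(3, p["box"])
    v = float(np.prod(box))
    n_solute = int(round(p["c0"] * v))
    n_solvent = int(round((p["density"] - p["c0"]) * v))
    state = fill_region(
        {"solute": n_solute, "solvent": n_solvent}, box, np.zeros(3), box,
        p["temperature"], rng,
    )
    center = 0.5 * box
    ctrl = spherical_controller(
        center, p["cr_lo"], p["cr_hi"], p["fr_center"], p["fr_width"],
        c0=p["c0"], k=p["k"], box=box,
    )
    sink = SinkSourceSpec(
        mode="sink", rate=p["sink_rate"], geometry="spherical",
        center=tuple(center), radius=p["gr_radius"],
        temperature=p["temperature"],
    ) if p["sink_rate"] > 0 else None
    return RunSetup(
        state=state, lj=LJParams(), dt=0.005, gamma=p["gamma"],
        temperature=p["temperature"], seed=spec.seed, controller=ctrl, sink=sink,
    )


# ---------------------------------------------------------------- synthetic

def make_synthetic_trajectory(kind: str, seed: int = 0, **kw) -> list[ParticleState]:
    """Static or scripted trajectories with analytically known observables.

    kinds: 'single_crossing' (one particle steps across a plane once),
    'uniform_gas' (seeded uniform fill, frozen in time), 'empty'.
    """
    rng = np.random.default_rng(seed)
    if kind == "empty":
        box = np.full(3, kw.get("box", 10.0))
        st = ParticleState(np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0, int), box)
        return [st]
    if kind == "single_crossing":
        box = np.full(3, kw.get("box", 10.0))
        plane = kw.get("plane", 5.0)
        nframes = kw.get("frames", 3)
        frames = []
        zs = [plane - 0.5] * (nframes - 1) + [plane + 0.5]
        for i, z in enumerate(zs):
            pos = np.array([[0.5 * box[0], 0.5 * box[1], z]])
            st = ParticleState(pos, np.zeros((1, 3)), np.zeros(1, int), box, step=i)
            frames.append(st)
        return frames
    if kind == "uniform_gas":
        box = np.full(3, kw.get("box", 10.0))
        n = kw.get("n", 500)
        nframes = kw.get("frames", 5)
        species = kw.get("species", "solute")
        from .engine import species_code

        pos = rng.uniform(0, 1, size=(n, 3)) * box
        code = species_code(species)
        return [
            ParticleState(pos.copy(), np.zeros((n, 3)),
                          np.full(n, code, int), box, step=i)
            for i in range(nframes)
        ]
    raise ParameterError(f"unknown synthetic trajectory kind {kind!r}")


_BUILDERS = {
    "growth": _build_growth,
    "membrane": _build_membrane,
    "cannibalistic": _build_cannibalistic,
    "spherical": _build_spherical,
}

SCENARIOS = {
    "growth": make_growth_scenario,
    "membrane": make_membrane_scenario,
    "cannibalistic": make_cannibalistic_scenario,
    "spherical": make_spherical_scenario,
}


def build_setup(spec: ScenarioSpec, steps: int = 0, **run_kwargs) -> RunSetup:
    """Materialize a scenario into a ready-to-run :class:`RunSetup`."""
    if spec.name not in _BUILDERS:
        raise ParameterError(f"unknown scenario {spec.name!r}")
    setup = _BUILDERS[spec.name](spec)
    setup.steps = steps
    for key, val in run_kwargs.items():
        if not hasattr(setup, key):
            raise ParameterError(f"unknown run option {key!r}")
        setattr(setup, key, val)
    return setup
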