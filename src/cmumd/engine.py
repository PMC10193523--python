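"""Minimal Lennard-Jones molecular-dynamics host for concentration control.

Reduced LJ units throughout (epsilon = sigma = m = k_B = 1).  The engine
provides a binary solute/solvent fluid, a BAOAB Langevin integrator that
degenerates to velocity Verlet at zero friction, periodic boundaries, frozen
crystal/membrane particles, and a stochastic sink/source that stands in for
crystallization: eligible solute adjacent to a frozen slab freezes (joins the
crystal) with a fixed per-step probability, and frozen particles can be
released back into solution at the opposite face.  The sink makes demand on
the concentration controller tunable and is not a model of crystallization
physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .errors import (
    GeometryError,
    NumericalBlowupError,
    PackingError,
    ParameterError,
    SimulationStop,
)

__all__ = [
    "SPECIES",
    "SOLUTE",
    "SOLVENT",
    "FROZEN",
    "WALL",
    "ParticleState",
    "LJParams",
    "SinkSourceSpec",
    "initialize_system",
    "fill_region",
    "lj_forces",
    "step_langevin",
    "sink_source_step",
    "build_membrane",
    "build_crystal_slab",
]

# diagnostic cap: any pair force beyond this signals overlapping particles
FORCE_CAP = 1e8

# species codes; FROZEN particles are crystal material (can be released),
# WALL particles are permanent scaffold (membrane)
SPECIES = ("solute", "solvent", "frozen", "wall")
SOLUTE, SOLVENT, FROZEN, WALL = 0, 1, 2, 3
_IMMOBILE = (FROZEN, WALL)


def species_code(name: str) -> int:
    try:
        return SPECIES.index(name)
    except ValueError:
        raise ParameterError(f"unknown species {name!r}; expected one of {SPECIES}")


@dataclass
class ParticleState:
    """Positions, velocities, species labels and box of the simulated system."""

    positions: np.ndarray  # (N, 3), wrapped into [0, box)
    velocities: np.ndarray  # (N, 3); zero for frozen/wall particles
    species: np.ndarray  # (N,) int codes into SPECIES
    box: np.ndarray  # (3,) edge lengths, fully periodic
    step: int = 0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.positions.shape != self.velocities.shape:
            raise ParameterError("positions and velocities shapes differ")
        self.velocities[~self.mobile] = 0.0
        self.wrap()

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def mobile(self) -> np.ndarray:
        return ~np.isin(self.species, _IMMOBILE)

    def count(self, name: str) -> int:
        return int(np.sum(self.species == species_code(name)))

    def wrap(self) -> None:
        np.mod(self.positions, self.box, out=self.positions)

    def copy(self) -> "ParticleState":
        return ParticleState(
            self.positions.copy(),
            self.velocities.copy(),
            self.species.copy(),
            self.box.copy(),
            self.step,
        )

    def kinetic_temperature(self) -> float:
        mob = self.mobile
        ndof = 3 * int(mob.sum())
        if ndof == 0:
            return 0.0
        return float(np.sum(self.velocities[mob] ** 2) / ndof)


@dataclass(frozen=True)
class LJParams:
    """Pair interaction table.  ``eps``/``sigma`` may be scalars (all pairs
    identical) or (4, 4) symmetric per-species tables.  ``shift_force`` brings
    the pair force continuously to zero at the cutoff (good energy
    conservation); ``False`` gives plain truncated-and-shifted LJ."""

    eps: float | np.ndarray = 1.0
    sigma: float | np.ndarray = 1.0
    cutoff: float = 2.5
    shift_force: bool = True

    def tables(self) -> tuple[np.ndarray, np.ndarray]:
        ns = len(SPECIES)
        eps = np.asarray(self.eps, dtype=np.float64)
        sig = np.asarray(self.sigma, dtype=np.float64)
        if eps.ndim == 0:
            eps = np.full((ns, ns), float(eps))
        if sig.ndim == 0:
            sig = np.full((ns, ns), float(sig))
        if eps.shape != (ns, ns) or sig.shape != (ns, ns):
            raise ParameterError(f"pair tables must be scalars or ({ns},{ns})")
        if not (np.allclose(eps, eps.T) and np.allclose(sig, sig.T)):
            raise ParameterError("pair tables must be symmetric")
        return eps, sig

    def validate_box(self, box: np.ndarray) -> None:
        if self.cutoff > 0.5 * float(np.min(box)):
            raise GeometryError(
                f"cutoff {self.cutoff} exceeds half the smallest box edge"
            )


def lj_forces(
    state: ParticleState, params: LJParams, method: str = "auto"
) -> tuple[np.ndarray, float]:
    """Pairwise LJ forces and potential energy under minimum image.

    ``method``: 'cell' (linked cells), 'naive' (O(N^2) reference), or 'auto'
    (cells whenever the box admits >= 3 cells per dimension).
    """
    params.validate_box(state.box)
    eps, sig = params.tables()
    ncells = np.floor(state.box / params.cutoff).astype(int)
    if method == "auto":
        method = "cell" if np.all(ncells >= 3) else "naive"
    if method == "cell" and np.any(ncells < 3):
        raise ParameterError("cell list requires >= 3 cells per dimension")
    kern = _kernels.lj_cell if method == "cell" else _kernels.lj_naive
    forces, pe = kern(
        state.positions, state.box, state.species, eps, sig,
        params.cutoff, params.shift_force,
    )
    fmax = float(np.abs(forces).max()) if forces.size else 0.0
    if not np.isfinite(fmax) or fmax > FORCE_CAP:
        raise NumericalBlowupError(
            f"LJ force {fmax:.3g} exceeds the cap {FORCE_CAP:.0e} "
            "(overlapping particles?)", step=state.step
        )
    return forces, float(pe)


def maxwell_boltzmann(n: int, temperature: float, rng: np.random.Generator):
    return rng.normal(0.0, np.sqrt(temperature), size=(n, 3))


def fill_region(
    counts: dict[str, int],
    box: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    temperature: float,
    rng: np.random.Generator,
    min_spacing: float = 0.95,
) -> ParticleState:
    """Place particles on a jittered simple-cubic lattice inside [lo, hi).

    Species labels are distributed at random over the occupied sites.  Raises
    :class:`~cmumd.errors.PackingError` if the region cannot host the request
    at ``min_spacing``.
    """
    box = np.asarray(box, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    n_total = int(sum(counts.values()))
    if n_total == 0:
        return ParticleState(
            np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0, dtype=int), box
        )
    extent = hi - lo
    if np.any(extent <= 0):
        raise GeometryError("empty fill region")
    # choose the largest lattice spacing that fits n_total sites
    nsite = np.maximum((extent / min_spacing).astype(int), 1)
    if int(np.prod(nsite)) < n_total:
        raise PackingError(
            f"cannot place {n_total} particles in region of volume "
            f"{np.prod(extent):.3g} at spacing {min_spacing}"
        )
    # shrink the grid toward the needed count to keep it roughly uniform
    while True:
        trial = np.maximum(nsite - 1, 1)
        if int(np.prod(trial)) >= n_total and np.any(trial < nsite):
            nsite = trial
        else:
            break
    spacing = extent / nsite
    gx, gy, gz = np.meshgrid(
        *[lo[d] + (np.arange(nsite[d]) + 0.5) * spacing[d] for d in range(3)],
        indexing="ij",
    )
    sites = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    chosen = rng.permutation(sites.shape[0])[:n_total]
    pos = sites[chosen]
    jitter_amp = np.minimum(spacing, min_spacing) * 0.15
    pos = pos + rng.uniform(-1, 1, size=pos.shape) * jitter_amp
    codes = np.concatenate(
        [np.full(c, species_code(name), dtype=int) for name, c in counts.items()]
    )
    rng.shuffle(codes)
    vel = maxwell_boltzmann(n_total, temperature, rng)
    mobile = ~np.isin(codes, _IMMOBILE)
    if mobile.any():
        vel[mobile] -= vel[mobile].mean(axis=0)  # zero net momentum
    return ParticleState(pos, vel, codes, box)


def initialize_system(
    n_solute: int,
    n_solvent: int,
    box,
    temperature: float = 0.85,
    seed: int = 0,
) -> ParticleState:
    """Homogeneous binary fluid filling the whole box; reproducible from seed."""
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    return fill_region(
        {"solute": n_solute, "solvent": n_solvent},
        box, np.zeros(3), box, temperature, rng,
    )


def merge_states(*states: ParticleState) -> ParticleState:
    """Concatenate particle sets sharing one box."""
    box = states[0].box
    for s in states[1:]:
        if not np.allclose(s.box, box):
            raise GeometryError("cannot merge states with different boxes")
    return ParticleState(
        np.concatenate([s.positions for s in states]),
        np.concatenate([s.velocities for s in states]),
        np.concatenate([s.species for s in states]),
        box.copy(),
    )


def step_langevin(
    state: ParticleState,
    total_force: np.ndarray,
    dt: float,
    gamma: float,
    temperature: float,
    rng: np.random.Generator,
    force_fn=None,
) -> tuple[ParticleState, np.ndarray]:
    """One BAOAB Langevin step (in place on a copy of the state).

    ``total_force`` is the force at the current positions; ``force_fn``
    recomputes the force at the new positions for the final half kick (if
    ``None``, positions-only update semantics are used and the returned force
    is the recomputed one is skipped).  With ``gamma = 0`` the map reduces
    exactly to velocity Verlet.  Frozen and wall particles never move.
    Returns (new_state, force_at_new_positions).
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    new = state.copy()
    mob = new.mobile
    v = new.velocities
    x = new.positions
    v[mob] += 0.5 * dt * total_force[mob]
    x[mob] += 0.5 * dt * v[mob]
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * temperature)
        noise = rng.normal(size=(int(mob.sum()), 3))
        v[mob] = c1 * v[mob] + c2 * noise
    x[mob] += 0.5 * dt * v[mob]
    new.wrap()
    if force_fn is not None:
        f_new = force_fn(new)
    else:
        f_new = total_force
    v[mob] += 0.5 * dt * f_new[mob]
    if not np.all(np.isfinite(x)):
        raise NumericalBlowupError("non-finite coordinates", step=state.step)
    new.step = state.step + 1
    return new, f_new


@dataclass(frozen=True)
class SinkSourceSpec:
    """Stochastic sink/source proxy for a growing/dissolving phase boundary.

    mode 'sink': solute within ``capture`` of a frozen-slab face (both faces)
    freezes with probability ``rate`` per step.  mode 'source': frozen
    particles within ``capture`` of a face are released as solute.  mode
    'both': the low-z face freezes and the high-z face releases (growth on
    one side, dissolution on the other).  In spherical geometry, eligibility
    is distance < ``radius`` from ``center``.  Explicit ``slab_lo``/``slab_hi``
    override the face-relative eligibility window.
    """

    mode: str = "sink"
    rate: float = 0.0
    rate_source: float | None = None  # release probability; defaults to rate
    capture: float = 1.5  # freeze window: reaches this far into the fluid
    standoff: float = 0.0  # freeze window keeps this gap from the face
    source_capture: float = 0.6  # release window depth into the crystal
    temperature: float = 0.85
    geometry: str = "planar"
    center: tuple[float, float, float] | None = None
    radius: float | None = None
    slab_lo: float | None = None
    slab_hi: float | None = None

    def __post_init__(self):
        if self.mode not in ("sink", "source", "both"):
            raise ParameterError(f"unknown sink/source mode {self.mode!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ParameterError("rate must be a probability in [0, 1]")
        if self.rate_source is not None and not 0.0 <= self.rate_source <= 1.0:
            raise ParameterError("rate_source must be a probability in [0, 1]")
        if self.geometry == "spherical" and (
            self.center is None or self.radius is None
        ):
            raise ParameterError("spherical sink needs center and radius")


def frozen_extent(
    state: ParticleState, bin_width: float = 0.5, frac: float = 0.5
) -> tuple[float, float]:
    """z-extent [lo, hi] of the compact frozen crystal slab (excludes wall).

    A z-bin counts as crystal once its frozen density reaches ``frac`` of
    the densest (core) bin; the faces are the outer edges of the outermost
    such bins.  Freshly frozen particles form an under-dense halo that does
    not advance the face until the layer fills, so stray freezes cannot
    drag the face (and with it the sink eligibility layer) into the fluid.
    """
    z = state.positions[state.species == FROZEN, 2]
    if z.size == 0:
        raise SimulationStop("no frozen material left: slab exhausted")
    lz = float(state.box[2])
    nbins = max(int(round(lz / bin_width)), 1)
    counts, edges = np.histogram(z, bins=nbins, range=(0.0, lz))
    dense = np.nonzero(counts >= frac * counts.max())[0]
    return float(edges[dense[0]]), float(edges[dense[-1] + 1])


def sink_source_step(
    state: ParticleState, spec: SinkSourceSpec, rng: np.random.Generator
) -> ParticleState:
    """Apply one sink/source event sweep; returns a new state.

    No-op when no particle is eligible or ``rate`` is zero.
    """
    if spec.rate == 0.0:
        return state
    new = state.copy()
    z = new.positions[:, 2]
    is_solute = new.species == SOLUTE
    is_frozen = new.species == FROZEN

    if spec.geometry == "spherical":
        d = new.positions - np.asarray(spec.center)
        d -= new.box * np.round(d / new.box)
        r = np.linalg.norm(d, axis=1)
        eligible_sink = is_solute & (r < spec.radius)
        eligible_src = is_frozen & (r < spec.radius)
    elif spec.slab_lo is not None and spec.slab_hi is not None:
        inside = (z >= spec.slab_lo) & (z <= spec.slab_hi)
        eligible_sink = is_solute & inside
        eligible_src = is_frozen & inside
    else:
        lo, hi = frozen_extent(new)
        if spec.mode == "both" and hi - lo < spec.capture:
            raise SimulationStop("slab thinner than capture layer: faces crossed")
        sink_lo = (z >= lo - spec.capture) & (z < lo - spec.standoff)
        sink_hi = (z > hi + spec.standoff) & (z <= hi + spec.capture)
        src_lo = (z >= lo) & (z < lo + spec.source_capture)
        src_hi = (z > hi - spec.source_capture) & (z <= hi)
        if spec.mode == "both":
            eligible_sink = is_solute & sink_lo
            eligible_src = is_frozen & src_hi
        else:
            eligible_sink = is_solute & (sink_lo | sink_hi)
            eligible_src = is_frozen & (src_lo | src_hi)

    if spec.mode in ("sink", "both"):
        hit = eligible_sink & (rng.random(new.n) < spec.rate)
        new.species[hit] = FROZEN
        new.velocities[hit] = 0.0
    if spec.mode in ("source", "both"):
        r_src = spec.rate if spec.rate_source is None else spec.rate_source
        hit = eligible_src & (rng.random(new.n) < r_src)
        k = int(hit.sum())
        if k:
            new.species[hit] = SOLUTE
            new.velocities[hit] = maxwell_boltzmann(k, spec.temperature, rng)
    return new


def _lattice_slab(box, z_lo, z_hi, spacing) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    nx = max(int(round(box[0] / spacing)), 1)
    ny = max(int(round(box[1] / spacing)), 1)
    nz = max(int(round((z_hi - z_lo) / spacing)), 1)
    sx, sy = box[0] / nx, box[1] / ny
    sz = (z_hi - z_lo) / nz
    gx, gy, gz = np.meshgrid(
        (np.arange(nx) + 0.5) * sx,
        (np.arange(ny) + 0.5) * sy,
        z_lo + (np.arange(nz) + 0.5) * sz,
        indexing="ij",
    )
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def build_crystal_slab(box, z_lo: float, z_hi: float, spacing: float = 1.1) -> ParticleState:
    """Frozen (releasable) crystal slab on a simple-cubic lattice."""
    pos = _lattice_slab(box, z_lo, z_hi, spacing)
    n = pos.shape[0]
    return ParticleState(
        pos, np.zeros((n, 3)), np.full(n, FROZEN, dtype=int), np.asarray(box, float)
    )


def build_membrane(
    box,
    z_lo: float,
    z_hi: float,
    pore_count: int = 0,
    pore_radius: float = 1.0,
    spacing: float = 1.1,
) -> tuple[ParticleState, float]:
    """Permanent wall slab with ``pore_count`` cylindrical channels along z.

    Pore centers are placed on a uniform grid over the x-y cross-section;
    overlapping or non-fitting pores raise GeometryError.  Returns the wall
    state and the open cross-section area pore_count * pi * r^2.
    """
    box = np.asarray(box, dtype=float)
    if pore_count < 0:
        raise ParameterError("pore_count must be >= 0")
    centers = np.zeros((0, 2))
    if pore_count > 0:
        ngrid = int(np.ceil(np.sqrt(pore_count)))
        cx = (np.arange(ngrid) + 0.5) * box[0] / ngrid
        cy = (np.arange(ngrid) + 0.5) * box[1] / ngrid
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        centers = np.column_stack([gx.ravel(), gy.ravel()])[:pore_count]
        min_sep = min(box[0], box[1]) / ngrid
        if 2 * pore_radius > min_sep:
            raise GeometryError(
                f"{pore_count} pores of radius {pore_radius} overlap in the "
                f"{box[0]} x {box[1]} cross-section"
            )
    pos = _lattice_slab(box, z_lo, z_hi, spacing)
    if pore_count > 0:
        d = pos[:, None, :2] - centers[None, :, :]
        d -= box[:2] * np.round(d / box[:2])
        keep = np.all(np.linalg.norm(d, axis=2) > pore_radius, axis=1)
        pos = pos[keep]
    n = pos.shape[0]
    state = ParticleState(
        pos, np.zeros((n, 3)), np.full(n, WALL, dtype=int), box
    )
    open_area = pore_count * np.pi * pore_radius**2
    return state, float(open_area)
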