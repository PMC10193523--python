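"""Concentration-restraint external forces (the CmuMD machinery).

The controller measures the instantaneous concentration of a target species
inside one or more control regions (CR) through a smooth indicator,

    c_inst = (1 / V_CR) * sum_j theta(x_j),

and applies to every controlled particle a harmonic-like external force

    F(x) = k * (c0 - c_inst) * G(x) * d_hat,

localized in the force region (FR) by the normalized bell G and oriented by
the unit direction d_hat from the FR toward the CR.  A deficit in the CR
(c_inst < c0) therefore pumps species from the reservoir across the FR into
the CR; an excess pushes them out.  Four geometry variants are provided:
planar symmetric (two mirrored CR/FR pairs sharing one target), asymmetric
(independent inlet/outlet targets across a membrane, with recirculation left
to the periodic boundaries), cannibalistic (two distinct targets flanking a
crystal slab, each anchored to its own adaptively tracked face), and
spherical (concentric shells around a nucleation center, forces along the
radius).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import ParticleState, species_code
from .errors import ConsistencyError, GeometryError, ParameterError
from .regions import (
    InterfacePosition,
    RegionSpec,
    bell_localizer,
    cr_indicator,
    update_regions,
)

__all__ = [
    "ControlLeg",
    "CmuController",
    "ControlRecord",
    "cr_concentration",
    "control_force",
    "symmetric_pair",
    "asymmetric_pair",
    "cannibalistic_pair",
    "spherical_controller",
    "spherical_control",
]

DEFAULT_SWITCH_FRACTION = 0.05  # switch width = CR width / 20


@dataclass(frozen=True)
class ControlLeg:
    """One (CR, FR, target) control unit."""

    region: RegionSpec
    c0: float
    k: float
    w: float | None = None  # switch width; default CR width / 20
    name: str = "cr"

    def __post_init__(self):
        if self.c0 < 0:
            raise ParameterError("target concentration c0 must be >= 0")
        if self.k < 0:
            raise ParameterError("force constant k must be >= 0")
        if self.w is not None and self.w <= 0:
            raise ParameterError("switch width must be > 0")

    @property
    def switch_width(self) -> float:
        return self.w if self.w is not None else DEFAULT_SWITCH_FRACTION * self.region.cr_width

    @property
    def direction(self) -> int:
        """+1 if the CR lies at larger coordinate than the FR, else -1."""
        if self.region.geometry == "spherical":
            return -1  # CR shell is always inside the FR shell
        return 1 if self.region.cr_mid > self.region.fr_center else -1


@dataclass
class CmuController:
    """Per-species concentration controller in one of four geometry variants."""

    variant: str
    legs: list[ControlLeg]
    species: str = "solute"
    adaptive: bool = False
    ema_window: int | None = None  # optional smoothing of c_inst (default off)

    def __post_init__(self):
        if self.variant not in ("symmetric", "asymmetric", "cannibalistic", "spherical"):
            raise ParameterError(f"unknown controller variant {self.variant!r}")
        if not self.legs:
            raise ParameterError("controller needs at least one control leg")
        for leg in self.legs:
            r = leg.region
            lo, hi = r.cr_lo - 0.5 * r.fr_width, r.cr_hi + 0.5 * r.fr_width
            if lo < r.fr_center < hi:
                raise GeometryError(
                    f"FR center {r.fr_center} of leg {leg.name!r} lies inside its CR"
                )
        self._ema: np.ndarray | None = None

    def concentrations(self, state: ParticleState) -> np.ndarray:
        """Instantaneous (optionally EMA-smoothed) c_inst for every leg."""
        c = np.array(
            [
                cr_concentration(state, leg.region, self.species, leg.switch_width)
                for leg in self.legs
            ]
        )
        if self.ema_window:
            if self._ema is None:
                self._ema = c.copy()
            else:
                a = 1.0 / self.ema_window
                self._ema = (1 - a) * self._ema + a * c
            return self._ema.copy()
        return c

    def forces(self, state: ParticleState) -> tuple[np.ndarray, np.ndarray]:
        c = self.concentrations(state)
        return control_force(state, self, c), c

    def reanchor(
        self, face_lo: float, face_hi: float, box_hi: float | None = None
    ) -> None:
        """Re-anchor anchored legs to freshly tracked interface faces: legs on
        side -1 follow the lower face, legs on side +1 the upper face."""
        for i, leg in enumerate(self.legs):
            if leg.region.anchored:
                face = face_lo if leg.region.side == -1 else face_hi
                self.legs[i] = replace(
                    leg, region=update_regions(face, leg.region, box_hi)
                )


def cr_concentration(
    state: ParticleState, region: RegionSpec, species: str, w: float
) -> float:
    """Smooth instantaneous concentration of ``species`` in the CR.

    Planar regions use the axial coordinate z and slab volume; spherical
    regions use the radial distance from ``region.center`` (minimum image)
    and the true shell volume.
    """
    if not species:
        raise ParameterError("species label must be non-empty")
    v_cr = region.cr_volume(state.box)
    if v_cr <= 0:
        raise ParameterError("CR volume must be positive")
    mask = state.species == species_code(species)
    if not mask.any():
        return 0.0
    coord = _control_coordinate(state, region, mask)
    theta = cr_indicator(coord, region, w)
    return float(np.sum(theta) / v_cr)


def _control_coordinate(state, region, mask) -> np.ndarray:
    if region.geometry == "planar":
        return state.positions[mask, 2]
    center = np.asarray(region.center, dtype=float)
    d = state.positions[mask] - center
    d -= state.box * np.round(d / state.box)
    return np.linalg.norm(d, axis=1)


def control_force(
    state: ParticleState, ctrl: CmuController, c_inst: np.ndarray
) -> np.ndarray:
    """(N, 3) external force array: k (c0 - c_inst) G localized in each FR.

    Uncontrolled species feel exactly zero force; forces act along the
    control axis z, or radially in the spherical variant (zero at the
    center, where the radial direction is undefined).
    """
    c_inst = np.asarray(c_inst, dtype=float)
    if c_inst.shape != (len(ctrl.legs),):
        raise ConsistencyError(
            f"c_inst has {c_inst.shape} entries for {len(ctrl.legs)} control legs"
        )
    forces = np.zeros_like(state.positions)
    mask = state.species == species_code(ctrl.species)
    if not mask.any():
        return forces
    idx = np.nonzero(mask)[0]
    for leg, c in zip(ctrl.legs, c_inst):
        r = leg.region
        amp = leg.k * (leg.c0 - c)
        if amp == 0.0:
            continue
        if r.geometry == "planar":
            g = bell_localizer(state.positions[idx, 2], r.fr_center, r.fr_width)
            forces[idx, 2] += amp * g * leg.direction
        else:
            center = np.asarray(r.center, dtype=float)
            d = state.positions[idx] - center
            d -= state.box * np.round(d / state.box)
            rr = np.linalg.norm(d, axis=1)
            g = bell_localizer(rr, r.fr_center, r.fr_width)
            safe = rr > 1e-12
            rhat = np.zeros_like(d)
            rhat[safe] = d[safe] / rr[safe, None]
            # direction toward the CR (inward) on deficit: -r_hat
            forces[idx] += (amp * g)[:, None] * rhat * leg.direction
    return forces


def _validate_fr_separation(legs: list[ControlLeg]) -> None:
    for i, a in enumerate(legs):
        for b in legs[i + 1 :]:
            if a.region.geometry != "planar" or b.region.geometry != "planar":
                continue
            gap = abs(a.region.fr_center - b.region.fr_center)
            if gap < 3.0 * (a.region.fr_width + b.region.fr_width):
                raise GeometryError(
                    f"force regions of legs {a.name!r} and {b.name!r} overlap "
                    f"(centers {gap:.3g} apart)"
                )


def face_leg(
    face: float,
    side: int,
    cr_gap: float,
    cr_width: float,
    fr_gap: float,
    fr_width: float,
    c0: float,
    k: float,
    w: float | None = None,
    name: str = "cr",
    anchored: bool = False,
) -> ControlLeg:
    """Control leg placed at fixed offsets from a phase-boundary face.

    ``cr_gap`` is the distance from the face to the inner CR edge (the
    transition region is the unforced layer in between), ``fr_gap`` the
    distance from the face to the FR center; ``side`` is +1 when the
    solution lies at coordinates above the face.
    """
    if cr_gap < 0 or cr_width <= 0:
        raise GeometryError("CR must have positive width outside the face")
    if fr_gap < cr_gap + cr_width:
        raise GeometryError("FR must lie outside the CR, away from the face")
    lo = face + side * cr_gap
    hi = face + side * (cr_gap + cr_width)
    region = RegionSpec(
        cr_lo=min(lo, hi),
        cr_hi=max(lo, hi),
        fr_center=face + side * fr_gap,
        fr_width=fr_width,
        tr_width=cr_gap,
        anchored=anchored,
        side=side,
        offset_cr_lo=cr_gap,
        offset_cr_hi=cr_gap + cr_width,
        offset_fr_center=fr_gap,
    )
    return ControlLeg(region=region, c0=c0, k=k, w=w, name=name)


def symmetric_pair(
    center: float,
    slab_half: float,
    cr_gap: float,
    cr_width: float,
    fr_gap: float,
    fr_width: float,
    c0: float,
    k: float,
    w: float | None = None,
    anchored: bool = False,
) -> CmuController:
    """Mirrored CR/FR pairs flanking a central slab, sharing one target c0.

    The two legs sit at fixed offsets from the slab faces ``center -/+
    slab_half`` and are exact reflections of each other through ``center``.
    A single-sided layout (``slab_half + cr_gap <= 0``) is rejected.
    """
    if slab_half < 0 or slab_half + cr_gap <= 0:
        raise GeometryError("symmetric scheme needs regions on both sides of the slab")
    legs = [
        face_leg(center - slab_half, -1, cr_gap, cr_width, fr_gap, fr_width,
                 c0, k, w, name="left", anchored=anchored),
        face_leg(center + slab_half, +1, cr_gap, cr_width, fr_gap, fr_width,
                 c0, k, w, name="right", anchored=anchored),
    ]
    _validate_fr_separation(legs)
    return CmuController(variant="symmetric", legs=legs, adaptive=anchored)


def asymmetric_pair(
    inlet: ControlLeg, outlet: ControlLeg, species: str = "solute"
) -> CmuController:
    """Independent inlet/outlet targets across a membrane (CGD-MD).

    Solute recirculates from outlet to inlet through the periodic boundary;
    no extra action is needed.  Equal targets are allowed (null gradient) but
    warned about, since they drive no net flux.
    """
    if inlet.c0 < outlet.c0:
        raise ParameterError(
            "inlet target must be >= outlet target for a forward gradient"
        )
    if inlet.c0 == outlet.c0:
        warnings.warn("equal inlet and outlet targets: zero driving force", stacklevel=2)
    legs = [replace(inlet, name="inlet"), replace(outlet, name="outlet")]
    _validate_fr_separation(legs)
    return CmuController(variant="asymmetric", legs=legs, species=species)


def cannibalistic_pair(
    c0_s: float,
    c0_u: float,
    face_lo: float,
    face_hi: float,
    cr_gap: float,
    cr_width: float,
    fr_gap: float,
    fr_width: float,
    k: float,
    w: float | None = None,
) -> CmuController:
    """Dual-target scheme: supersaturated CR at the low-z face (growth),
    undersaturated CR at the high-z face (dissolution), each anchored to its
    own interface z_I^S < z_I^U and re-anchored as the faces move."""
    if c0_s < c0_u:
        raise ParameterError(
            f"supersaturated target c0_s={c0_s} must exceed undersaturated c0_u={c0_u}"
        )
    if c0_s == c0_u:
        warnings.warn(
            "equal targets: cannibalistic scheme degenerates to the symmetric one",
            stacklevel=2,
        )
    if not face_lo < face_hi:
        raise GeometryError("slab faces must satisfy face_lo < face_hi")
    legs = [
        face_leg(face_lo, -1, cr_gap, cr_width, fr_gap, fr_width,
                 c0_s, k, w, name="S", anchored=True),
        face_leg(face_hi, +1, cr_gap, cr_width, fr_gap, fr_width,
                 c0_u, k, w, name="U", anchored=True),
    ]
    _validate_fr_separation(legs)
    return CmuController(variant="cannibalistic", legs=legs, adaptive=True)


def spherical_controller(
    center,
    cr_lo: float,
    cr_hi: float,
    fr_center: float,
    fr_width: float,
    c0: float,
    k: float,
    box,
    w: float | None = None,
) -> CmuController:
    """Single spherical CR shell around a nucleation center, FR outside it."""
    box = np.asarray(box, dtype=float)
    c = np.asarray(center, dtype=float)
    if np.any(c < 0) or np.any(c > box):
        raise GeometryError("spherical control center lies outside the box")
    region = RegionSpec(
        cr_lo=cr_lo, cr_hi=cr_hi, fr_center=fr_center, fr_width=fr_width,
        geometry="spherical", center=tuple(float(x) for x in c),
    )
    leg = ControlLeg(region=region, c0=c0, k=k, w=w, name="shell")
    return CmuController(variant="spherical", legs=[leg])


def spherical_control(state: ParticleState, ctrl: CmuController) -> np.ndarray:
    """Radial control forces for the spherical variant (convenience wrapper)."""
    if ctrl.variant != "spherical":
        raise ConsistencyError("spherical_control requires a spherical controller")
    f, _ = ctrl.forces(state)
    return f


class ControlRecord:
    """Diagnostic time series: per-CR instantaneous concentrations, applied
    force totals, and interface positions, appended monotonically in step."""

    COLUMNS_FIXED = ("step",)

    def __init__(self, leg_names: list[str], c0: list[float]):
        self.leg_names = list(leg_names)
        self.c0 = list(c0)
        self.rows: list[dict] = []

    def append(self, step, c_inst, force_total=0.0, faces=()):
        if self.rows and step <= self.rows[-1]["step"]:
            raise ConsistencyError("record steps must increase monotonically")
        if np.any(np.asarray(c_inst) < 0):
            raise ConsistencyError("negative instantaneous concentration")
        row = {"step": int(step), "force_total": float(force_total)}
        for name, c in zip(self.leg_names, c_inst):
            row[f"c_{name}"] = float(c)
        for i, f in enumerate(faces):
            row[f"iface_{i}"] = float(f)
        self.rows.append(row)

    def __len__(self):
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        for name, c0 in zip(self.leg_names, self.c0):
            df[f"c0_{name}"] = c0
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> pd.DataFrame:
        return pd.read_csv(path)
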