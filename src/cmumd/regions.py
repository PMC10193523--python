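"""Smooth region indicators, the bell-shaped force localizer, and adaptive
interface tracking.

The concentration controller partitions the simulation volume into a control
region (CR), a force region (FR), a transition region (TR) next to the phase
boundary, and the remaining molecule reservoir.  Region membership is never a
hard assignment: the CR indicator is a differentiable switching function and
the restraint force is localized by a normalized bell centred in the FR, so
that all control forces are smooth functions of the particle coordinates.

All lengths are in reduced Lennard-Jones units (sigma = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import GeometryError, InterfaceNotFoundError, ParameterError

__all__ = [
    "SwitchParams",
    "RegionSpec",
    "InterfacePosition",
    "InterfaceTracker",
    "fermi_switch",
    "cr_indicator",
    "bell_localizer",
    "locate_interface",
    "update_regions",
]


@dataclass(frozen=True)
class SwitchParams:
    """Smoothness parameters of the CR edge switching functions.

    ``width`` is the logistic width shared by both CR edges; edge positions
    are carried by the :class:`RegionSpec` the switch is applied to.
    """

    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ParameterError(f"switch width must be > 0, got {self.width}")


@dataclass(frozen=True)
class RegionSpec:
    """Geometry of one CR/FR pair, in planar (slab) or spherical (shell) form.

    Planar regions live on the control axis z with absolute coordinates;
    spherical regions are shells of radius r measured from ``center``.  An
    anchored region stores offsets from a phase-boundary interface and is
    repositioned with :func:`update_regions` as the interface moves; ``side``
    is +1 when the solution (and the region) lies at coordinates larger than
    the interface, -1 for the mirror case.
    """

    cr_lo: float
    cr_hi: float
    fr_center: float
    fr_width: float
    geometry: str = "planar"
    center: tuple[float, float, float] | None = None
    tr_width: float = 0.0
    anchored: bool = False
    side: int = +1
    offset_cr_lo: float = 0.0
    offset_cr_hi: float = 0.0
    offset_fr_center: float = 0.0

    def __post_init__(self):
        if self.geometry not in ("planar", "spherical"):
            raise ParameterError(f"unknown geometry {self.geometry!r}")
        if not self.cr_lo < self.cr_hi:
            raise GeometryError(
                f"CR bounds must satisfy cr_lo < cr_hi, got [{self.cr_lo}, {self.cr_hi}]"
            )
        if self.fr_width <= 0:
            raise ParameterError(f"fr_width must be > 0, got {self.fr_width}")
        if self.geometry == "spherical":
            if self.cr_lo < 0:
                raise GeometryError("spherical shell radii must be nonnegative")
            if self.fr_center < self.cr_hi:
                raise GeometryError("spherical FR must lie outside the CR shell")
        if self.side not in (-1, 1):
            raise ParameterError("side must be +1 or -1")

    @property
    def cr_width(self) -> float:
        return self.cr_hi - self.cr_lo

    @property
    def cr_mid(self) -> float:
        return 0.5 * (self.cr_lo + self.cr_hi)

    def cr_volume(self, box: np.ndarray) -> float:
        """CR volume: slab cross-section x width, or true shell volume."""
        if self.geometry == "planar":
            return float(box[0] * box[1] * self.cr_width)
        return float(4.0 / 3.0 * np.pi * (self.cr_hi**3 - self.cr_lo**3))


@dataclass(frozen=True)
class InterfacePosition:
    """Phase-boundary position(s) on the control axis at a given step.

    ``faces`` holds one coordinate for a single interface or two ascending
    coordinates (z_I of the lower and upper slab face) for a slab.
    """

    faces: tuple[float, ...]
    step: int = 0
    window: int = 1

    def __post_init__(self):
        if len(self.faces) == 2 and not self.faces[0] < self.faces[1]:
            raise GeometryError("slab faces must be in ascending coordinate order")

    @property
    def z(self) -> float:
        if len(self.faces) != 1:
            raise ParameterError("interface has two faces; index .faces explicitly")
        return self.faces[0]


def fermi_switch(x, x0: float, w: float, sign: int = +1):
    """Logistic (Fermi) switch: 1 far below ``x0``, 0 far above, 1/2 at ``x0``.

    ``sign=-1`` mirrors the orientation.  ``w`` sets the smoothing width.
    """
    if w <= 0:
        raise ParameterError(f"switch width must be > 0, got {w}")
    x = np.asarray(x, dtype=float)
    arg = np.clip(sign * (x - x0) / w, -500.0, 500.0)
    out = 1.0 / (1.0 + np.exp(arg))
    return out if out.ndim else float(out)


def cr_indicator(x, region: RegionSpec, w: float):
    """Smooth CR membership theta(x) in [0, 1].

    Product of a rising edge at ``cr_lo`` and a falling edge at ``cr_hi``;
    ~1 deep inside the CR, ~0 far outside, differentiable everywhere.
    """
    if w <= 0:
        raise ParameterError(f"switch width must be > 0, got {w}")
    if w >= region.cr_width:
        warnings.warn(
            f"switch width {w} exceeds CR width {region.cr_width}; "
            "the indicator will never approach 1",
            stacklevel=2,
        )
    lo = fermi_switch(x, region.cr_lo, w, sign=-1)
    hi = fermi_switch(x, region.cr_hi, w, sign=+1)
    return lo * hi


def bell_localizer(x, z_f: float, w_f: float):
    """Normalized bell G(x) that localizes the restraint force in the FR.

    Realized as the derivative of a Fermi function of width ``w_f``: a sech^2
    bell, symmetric about ``z_f``, with unit integral over the real line and
    peak height 1/(4 w_f).  With this normalization the force constant k
    carries the force scale.
    """
    if w_f <= 0:
        raise ParameterError(f"fr_width must be > 0, got {w_f}")
    x = np.asarray(x, dtype=float)
    u = np.clip((x - z_f) / (2.0 * w_f), -250.0, 250.0)
    out = 1.0 / (4.0 * w_f * np.cosh(u) ** 2)
    return out if out.ndim else float(out)


def _interp_crossing(z0, z1, c0, c1, thr):
    return z0 + (thr - c0) * (z1 - z0) / (c1 - c0)


def locate_interface(
    z,
    solvent_profile,
    bulk_level: float,
    fraction: float = 0.5,
    step: int = 0,
) -> InterfacePosition:
    """Find where the solvent density crosses ``fraction * bulk_level``.

    ``z`` are bin centers of a solvent concentration profile.  A dense phase
    (crystal slab, membrane) excludes solvent, so the profile dips there; the
    interface is read off at the threshold crossings, linearly interpolated
    between bins.  Profiles with a single crossing yield one face; profiles
    dipping in the middle yield the two faces bounding the dip, in ascending
    order.  A profile that never crosses raises
    :class:`~cmumd.errors.InterfaceNotFoundError`.
    """
    z = np.asarray(z, dtype=float)
    c = np.asarray(solvent_profile, dtype=float)
    if z.size < 2:
        raise ParameterError("profile needs at least 2 bins")
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"fraction must be in (0,1), got {fraction}")
    thr = fraction * bulk_level
    s = c - thr
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    # crossings where a bin sits exactly on the threshold
    exact = np.nonzero(s == 0)[0]
    crossings = [_interp_crossing(z[i], z[i + 1], c[i], c[i + 1], thr) for i in idx]
    crossings += [float(z[i]) for i in exact if 0 < i < z.size - 1]
    crossings.sort()
    if not crossings:
        raise InterfaceNotFoundError(
            "solvent profile never crosses the detection threshold"
        )
    if len(crossings) == 1:
        return InterfacePosition(faces=(crossings[0],), step=step)
    # two faces bounding the region of minimum solvent density
    imin = int(np.argmin(c))
    zmin = z[imin]
    left = [zc for zc in crossings if zc <= zmin]
    right = [zc for zc in crossings if zc > zmin]
    if not left or not right:
        # dip touches a box edge: fall back to outermost crossings
        return InterfacePosition(faces=(crossings[0], crossings[-1]), step=step)
    return InterfacePosition(faces=(left[-1], right[0]), step=step)


class InterfaceTracker:
    """Exponential-moving-average smoothing of the raw interface position.

    The raw 50%-crossing estimate fluctuates with the instantaneous solvent
    histogram; the tracker smooths each face over ``window`` diagnostic
    updates (EMA weight 1/window).
    """

    def __init__(self, window: int = 100):
        if window < 1:
            raise ParameterError("smoothing window must be >= 1")
        self.window = window
        self._faces: np.ndarray | None = None

    def update(self, raw: InterfacePosition) -> InterfacePosition:
        faces = np.asarray(raw.faces, dtype=float)
        if self._faces is None or self._faces.shape != faces.shape:
            self._faces = faces.copy()
        else:
            alpha = 1.0 / self.window
            self._faces = (1.0 - alpha) * self._faces + alpha * faces
        return InterfacePosition(
            faces=tuple(float(f) for f in self._faces),
            step=raw.step,
            window=self.window,
        )


def update_regions(
    iface: InterfacePosition | float,
    region: RegionSpec,
    box_hi: float | None = None,
) -> RegionSpec:
    """Re-anchor an anchored region to a new interface position.

    The CR bounds and FR center are placed at their configured offsets from
    the interface, measured along ``region.side``.  Pure function: the input
    spec is unchanged.  If ``box_hi`` is given, bounds leaving [0, box_hi]
    raise :class:`~cmumd.errors.GeometryError`.
    """
    if not region.anchored:
        raise ParameterError("update_regions requires an anchored RegionSpec")
    z_i = iface.z if isinstance(iface, InterfacePosition) else float(iface)
    s = region.side
    lo = z_i + s * region.offset_cr_lo
    hi = z_i + s * region.offset_cr_hi
    fr = z_i + s * region.offset_fr_center
    cr_lo, cr_hi = (lo, hi) if lo < hi else (hi, lo)
    if box_hi is not None:
        fr_edge_lo = fr - 3 * region.fr_width
        fr_edge_hi = fr + 3 * region.fr_width
        if min(cr_lo, fr_edge_lo) < 0 or max(cr_hi, fr_edge_hi) > box_hi:
            raise GeometryError(
                f"anchored region shifted outside the box [0, {box_hi}]"
            )
    return replace(region, cr_lo=cr_lo, cr_hi=cr_hi, fr_center=fr)
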