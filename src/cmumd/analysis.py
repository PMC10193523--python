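"""Observables: concentration profiles, plane-crossing flux, screening
factor, supersaturation bookkeeping, and control-quality diagnostics.

The supersaturation S = m / m_eq is the ratio of the actual to the
equilibrium solute content; under the ideal-solution approximation the
driving force per thermal energy unit is Delta mu / k_B T = ln S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .engine import SPECIES, ParticleState
from .errors import ParameterError

__all__ = [
    "ConcentrationProfile",
    "FluxResult",
    "SupersaturationResult",
    "density_profile",
    "flux_through_plane",
    "screening_factor",
    "supersaturation",
    "round_sig",
    "control_diagnostics",
]


@dataclass
class ConcentrationProfile:
    """Binned species concentrations along z (axial) or r (radial).

    Concentrations are number densities per true bin volume: slab volume
    Lx*Ly*dz for axial bins, shell volume 4/3 pi (r_hi^3 - r_lo^3) for
    radial bins.
    """

    bin_edges: np.ndarray
    concentrations: dict[str, np.ndarray]
    geometry: str = "axial"
    frames: int = 1

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        for name, c in self.concentrations.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (self.bin_edges.size - 1,):
                raise ParameterError(f"profile for {name!r} does not match bin count")
            if np.any(c < 0):
                raise ParameterError("concentrations must be nonnegative")
            self.concentrations[name] = c

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[species]

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"bin_lo": self.bin_edges[:-1], "bin_hi": self.bin_edges[1:]})
        for name, c in self.concentrations.items():
            df[f"c_{name}"] = c
        with open(path, "w") as fh:
            fh.write(f"# geometry={self.geometry} frames={self.frames}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "ConcentrationProfile":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
            df = pd.read_csv(fh)
        edges = np.append(df["bin_lo"].to_numpy(), df["bin_hi"].iloc[-1])
        conc = {
            col[2:]: df[col].to_numpy() for col in df.columns if col.startswith("c_")
        }
        return cls(edges, conc, geometry=meta["geometry"], frames=int(meta["frames"]))


def _frames_list(trajectory) -> list[ParticleState]:
    frames = list(trajectory)
    if not frames:
        raise ParameterError("empty frame range")
    return frames


def density_profile(
    trajectory,
    bin_width: float,
    species=("solute", "solvent"),
    axis: str = "z",
    center=None,
    r_max: float | None = None,
    frame_range: slice | None = None,
) -> ConcentrationProfile:
    """Time-averaged concentration profile along z, or radially about
    ``center`` when it is given."""
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    frames = _frames_list(
        trajectory[frame_range] if frame_range is not None else trajectory
    )
    box = frames[0].box
    radial = center is not None
    if radial:
        center = np.asarray(center, dtype=float)
        hi = r_max if r_max is not None else 0.5 * float(np.min(box))
    else:
        if axis != "z":
            raise ParameterError("axial profiles are along z")
        hi = float(box[2])
    nbins = max(int(np.round(hi / bin_width)), 1)
    edges = np.linspace(0.0, hi, nbins + 1)
    if radial:
        volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    else:
        volumes = box[0] * box[1] * np.diff(edges)
    counts = {name: np.zeros(nbins) for name in species}
    for st in frames:
        for name in species:
            mask = st.species == SPECIES.index(name)
            if radial:
                d = st.positions[mask] - center
                d -= box * np.round(d / box)
                coord = np.linalg.norm(d, axis=1)
            else:
                coord = st.positions[mask, 2]
            h, _ = np.histogram(coord, bins=edges)
            counts[name] += h
    conc = {name: counts[name] / (len(frames) * volumes) for name in species}
    return ConcentrationProfile(
        edges, conc, geometry="radial" if radial else "axial", frames=len(frames)
    )


@dataclass(frozen=True)
class FluxResult:
    """Net signed crossings per unit area per unit time through a z-plane.

    Sign convention: crossings along +z count positive.
    """

    j_z: float
    n_up: int
    n_down: int
    window_steps: int
    plane: float
    area: float
    dt: float

    @property
    def window_time(self) -> float:
        return self.window_steps * self.dt


def flux_through_plane(
    trajectory, z_plane: float, species: str = "solute", dt: float = 0.005
) -> FluxResult:
    """PBC-aware crossing count through the plane z = z_plane.

    Uses the minimum-image displacement between consecutive frames, so no
    particle may travel more than half the box between frames; a warning is
    emitted when displacements approach that limit (aliasing risk).
    """
    frames = _frames_list(trajectory)
    box = frames[0].box
    lz = float(box[2])
    area = float(box[0] * box[1])
    code = SPECIES.index(species)
    n_up = n_down = 0
    for a, b in zip(frames[:-1], frames[1:]):
        mask = (a.species == code) & (b.species == code)
        z0 = a.positions[mask, 2]
        dz = b.positions[mask, 2] - z0
        dz -= lz * np.round(dz / lz)
        if dz.size and np.max(np.abs(dz)) > 0.25 * lz:
            warnings.warn(
                "frame spacing too coarse: displacements exceed Lz/4, "
                "crossing counts may alias",
                stacklevel=2,
            )
        z1 = z0 + dz
        # the plane and its periodic images
        for zp in (z_plane - lz, z_plane, z_plane + lz):
            n_up += int(np.sum((z0 < zp) & (z1 >= zp)))
            n_down += int(np.sum((z0 >= zp) & (z1 < zp)))
    window = frames[-1].step - frames[0].step
    if window <= 0:
        window = len(frames) - 1  # fall back to frame count
    j = (n_up - n_down) / (area * window * dt) if window > 0 else 0.0
    return FluxResult(
        j_z=float(j), n_up=n_up, n_down=n_down, window_steps=int(window),
        plane=float(z_plane), area=area, dt=dt,
    )


def screening_factor(x, c_num, c_den, x_upper, min_denominator: float = 1e-12):
    """Ratio of running integrals f(x') = int_0^x' c_num dx / int_0^x' c_den dx.

    ``x`` are profile bin centers; integration is trapezoidal.  Where the
    denominator integral has not yet risen above ``min_denominator`` the
    ratio is undefined and returned as NaN (masked, never extrapolated).
    Plain number concentrations are used (no charge weighting).
    """
    x = np.asarray(x, dtype=float)
    c_num = np.asarray(c_num, dtype=float)
    c_den = np.asarray(c_den, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("need at least two profile points")
    num = cumulative_trapezoid(c_num, x, initial=0.0)
    den = cumulative_trapezoid(c_den, x, initial=0.0)
    x_upper = np.atleast_1d(np.asarray(x_upper, dtype=float))
    num_i = np.interp(x_upper, x, num)
    den_i = np.interp(x_upper, x, den)
    out = np.full_like(x_upper, np.nan)
    ok = den_i > min_denominator
    out[ok] = num_i[ok] / den_i[ok]
    return out


@dataclass(frozen=True)
class SupersaturationResult:
    """S = m / m_eq with the ideal driving force Delta mu / k_B T = ln S."""

    s: float
    dmu_kbt: float
    m: float
    m_eq: float
    ideal: bool = True

    @property
    def s_reported(self) -> float:
        """S rounded to two significant figures for reporting."""
        return round_sig(self.s, 2)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def supersaturation(m: float, m_eq: float) -> SupersaturationResult:
    """Supersaturation of a solution of molality ``m`` against solubility
    ``m_eq``; the ideal approximation labels ln S as the driving force."""
    if m <= 0 or m_eq <= 0:
        raise ParameterError("molalities must be positive")
    s = m / m_eq
    return SupersaturationResult(s=s, dmu_kbt=float(np.log(s)), m=m, m_eq=m_eq)


def control_diagnostics(
    record,
    c0: dict[str, float] | None = None,
    window: int = 1000,
    tolerance: float = 0.05,
) -> dict[str, dict]:
    """Control quality per CR: mean, SD, max drift, fraction of samples
    within relative ``tolerance`` of the target, and the longest contiguous
    controlled window of the centered running average.

    ``record`` is a ControlRecord or its DataFrame; targets default to the
    c0 columns stored in the record.
    """
    df = record.to_dataframe() if hasattr(record, "to_dataframe") else record
    if len(df) == 0:
        raise ParameterError("empty control record")
    legs = [c[2:] for c in df.columns if c.startswith("c_") and not c.startswith("c0_")]
    out = {}
    for name in legs:
        series = df[f"c_{name}"].to_numpy(dtype=float)
        target = (
            c0[name]
            if c0 is not None
            else float(df[f"c0_{name}"].iloc[0])
        )
        run = (
            pd.Series(series)
            .rolling(window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
        dev = np.abs(series - target)
        scale = target if target > 0 else 1.0
        within = np.abs(run - target) <= tolerance * scale
        # longest contiguous True span
        best = cur = 0
        for flag in within:
            cur = cur + 1 if flag else 0
            best = max(best, cur)
        steps = df["step"].to_numpy()
        cadence = int(steps[1] - steps[0]) if len(steps) > 1 else 1
        out[name] = {
            "target": target,
            "mean": float(series.mean()),
            "sd": float(series.std()),
            "running_mean": float(run.mean()),
            "max_drift": float(dev.max()),
            "fraction_within": float(np.mean(within)),
            "controlled_window_steps": int(best * cadence),
        }
    return out
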