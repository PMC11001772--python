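"""Standing-wave mode shapes of round and square patterning chambers.

Low-frequency vibration of a liquid-filled chamber excites Faraday standing
waves whose nodal lines (zero surface displacement) are the loci where
suspended cells accumulate.  For a round chamber the stationary surface
displacement of the (m, n) mode is

    zeta(r, theta) = J_m(alpha_mn * r / R) * cos(m * theta)

with J_m the Bessel function of the first kind, alpha_mn its n-th positive
zero, and R the radius of the simulated domain.  For a square chamber of
side lx = ly the honeycomb-like pattern arises from the superposition of two
degenerate modes,

    zeta(x, y) = cos(n pi x / lx) cos(m pi y / ly)
               - cos(m pi x / lx) cos(n pi y / ly).

This module evaluates these mode shapes on physical grids, extracts nodal
sets (the predicted cell-accumulation loci), samples intensity profiles
along symmetry lines, and converts a mode shape into a normalized
accumulation density with a prescribed ridge width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, special
from skimage import measure

from .exceptions import (
    BoundsError,
    ConfigError,
    DegenerateFieldError,
    DomainError,
)

__all__ = [
    "ModeSpec",
    "WaveField",
    "NodalSet",
    "bessel_zero",
    "round_mode_field",
    "square_mode_field",
    "extract_nodal_set",
    "symmetry_line_profile",
    "accumulation_map",
    "AccumulationMap",
]

#: Protocol metadata: the drive conditions that select the modes
#: experimentally.  The simulation is parameterized directly by (m, n).
DRIVE_FREQUENCY_HZ = 54.0
DRIVE_ACCELERATION_G = 1.2


@dataclass(frozen=True)
class ModeSpec:
    """Specification of a chamber vibration mode.

    Parameters
    ----------
    shape : {'round', 'square'}
        Chamber geometry.
    m, n : int
        Mode indices; ``m`` is the angular order (>= 0), ``n`` the radial /
        second index (>= 1).  Both are limited to <= 10.
    chamber_dim : float
        Round: radius R of the simulated domain, mm.  Square: side length
        (lx = ly), mm.
    grid_resolution : int
        Grid points per axis (>= 64).
    """

    shape: str
    m: int
    n: int
    chamber_dim: float
    grid_resolution: int = 512

    def __post_init__(self) -> None:
        if self.shape not in ("round", "square"):
            raise ConfigError(f"unknown chamber shape {self.shape!r}")
        if not (0 <= self.m <= 10):
            raise ConfigError(f"mode order m={self.m} outside [0, 10]")
        if not (1 <= self.n <= 10):
            raise ConfigError(f"mode index n={self.n} outside [1, 10]")
        if self.chamber_dim <= 0:
            raise ConfigError("chamber_dim must be positive")
        if self.grid_resolution < 64:
            raise ConfigError("grid_resolution must be >= 64")


@dataclass
class WaveField:
    """A mode shape sampled on a square physical grid.

    Attributes
    ----------
    zeta : ndarray
        Dimensionless surface displacement.  For round chambers points with
        r > R are NaN.
    pitch : float
        Physical grid step, mm per cell.
    frame : {'centered', 'corner'}
        Origin convention: round fields are centered on the chamber axis,
        square fields have the origin at the lower-left corner (the first
        row/column of the array).
    spec : ModeSpec or None
        The generating specification, when the field came from one of the
        analytic constructors.
    zeta_full : ndarray or None
        The unmasked analytic evaluation (used for contour tracing up to
        and slightly beyond the chamber boundary).
    """

    zeta: np.ndarray
    pitch: float
    frame: str = "centered"
    spec: ModeSpec | None = None
    zeta_full: np.ndarray | None = dc_field(default=None, repr=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.zeta, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ConfigError("zeta must be a square 2D grid")
        if self.pitch <= 0:
            raise ConfigError("pitch must be positive")
        self.zeta = z

    @property
    def zeta_max(self) -> float:
        return float(np.nanmax(np.abs(self.zeta)))

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical coordinates (x, y) of grid columns and rows, mm."""
        npts = self.zeta.shape[0]
        coords = np.arange(npts) * self.pitch
        if self.frame == "centered":
            coords = coords - coords[-1] / 2.0
        return coords, coords.copy()


@dataclass
class NodalSet:
    """Zero-displacement loci of a wave field.

    ``mask`` flags grid points with |zeta| below the tolerance, ``curves``
    are traced zero-level contours in physical mm, and ``radii`` lists the
    radii of concentric nodal circles for round m=0 modes (ascending, mm).
    """

    mask: np.ndarray
    curves: list[np.ndarray]
    radii: list[float] | None = None
    tol: float = 0.02


def bessel_zero(m: int, k: int) -> float:
    """Return alpha_{m,k}, the k-th positive zero of J_m.

    Raises
    ------
    DomainError
        If ``m < 0`` or ``k <= 0``.
    """
    if m < 0 or k <= 0:
        raise DomainError(f"bessel_zero requires m >= 0 and k >= 1, got {m=}, {k=}")
    return float(special.jn_zeros(m, k)[-1])


def _round_eval(spec: ModeSpec, r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    alpha = bessel_zero(spec.m, spec.n)
    return special.jv(spec.m, alpha * r / spec.chamber_dim) * np.cos(spec.m * theta)


def round_mode_field(spec: ModeSpec) -> WaveField:
    """Evaluate the round-chamber mode zeta = J_m(alpha_mn r/R) cos(m theta).

    The returned field is masked (NaN) outside r = R; the unmasked analytic
    evaluation is retained in ``zeta_full`` for contour extraction.
    """
    if spec.shape != "round":
        raise ConfigError("round_mode_field requires a round ModeSpec")
    R = spec.chamber_dim
    npts = spec.grid_resolution
    ax = np.linspace(-R, R, npts)
    pitch = ax[1] - ax[0]
    X, Y = np.meshgrid(ax, ax)
    r = np.hypot(X, Y)
    theta = np.arctan2(Y, X)
    zeta_full = _round_eval(spec, r, theta)
    zeta = zeta_full.copy()
    zeta[r > R] = np.nan
    return WaveField(zeta=zeta, pitch=pitch, frame="centered", spec=spec,
                     zeta_full=zeta_full)


def square_mode_field(spec: ModeSpec) -> WaveField:
    """Evaluate the two-mode superposition on the square [0, lx] x [0, ly].

    zeta(x, y) = cos(n pi x/lx) cos(m pi y/ly) - cos(m pi x/lx) cos(n pi y/ly);
    antisymmetric under x <-> y, so the main diagonal is always nodal.
    """
    if spec.shape != "square":
        raise ConfigError("square_mode_field requires a square ModeSpec")
    L = spec.chamber_dim
    npts = spec.grid_resolution
    ax = np.linspace(0.0, L, npts)
    pitch = ax[1] - ax[0]
    X, Y = np.meshgrid(ax, ax)
    m, n = spec.m, spec.n
    zeta = (np.cos(n * np.pi * X / L) * np.cos(m * np.pi * Y / L)
            - np.cos(m * np.pi * X / L) * np.cos(n * np.pi * Y / L))
    return WaveField(zeta=zeta, pitch=pitch, frame="corner", spec=spec,
                     zeta_full=zeta)


def _contour_to_mm(contour: np.ndarray, fld: WaveField) -> np.ndarray:
    """Convert a (row, col) contour from find_contours to physical (x, y) mm."""
    npts = fld.zeta.shape[0]
    xy = np.empty_like(contour)
    xy[:, 0] = contour[:, 1] * fld.pitch  # x from column
    xy[:, 1] = contour[:, 0] * fld.pitch  # y from row
    if fld.frame == "centered":
        half = (npts - 1) * fld.pitch / 2.0
        xy -= half
    return xy


def extract_nodal_set(fld: WaveField, tol: float = 0.02) -> NodalSet:
    """Extract the nodal set (|zeta| < tol * zeta_max) of a wave field.

    Curves are zero-level contours traced by marching squares with sub-cell
    linear interpolation.  For round m=0 modes the radii of concentric
    circular contours are reported (ascending, boundary circle r = R
    included when zeta(R) = 0).

    Raises
    ------
    DegenerateFieldError
        If the field is identically zero.
    ConfigError
        If ``tol`` is outside (0, 0.5).
    """
    if not (0.0 < tol < 0.5):
        raise ConfigError("tol must be in (0, 0.5)")
    zmax = fld.zeta_max
    if not np.isfinite(zmax) or zmax == 0.0:
        raise DegenerateFieldError("field has no amplitude; nodal set undefined")

    mask = np.abs(np.nan_to_num(fld.zeta, nan=np.inf)) < tol * zmax

    src = fld.zeta_full if fld.zeta_full is not None else np.nan_to_num(fld.zeta, nan=zmax)
    lo, hi = float(np.min(src)), float(np.max(src))
    contours = [] if not (lo < 0.0 < hi or lo == 0.0 or hi == 0.0) else \
        measure.find_contours(src, 0.0)

    is_round = fld.spec is not None and fld.spec.shape == "round"
    R = fld.spec.chamber_dim if fld.spec is not None else None

    curves: list[np.ndarray] = []
    circle_radii: list[float] = []
    for c in contours:
        xy = _contour_to_mm(c, fld)
        if is_round:
            rr = np.hypot(xy[:, 0], xy[:, 1])
            keep = rr <= R + fld.pitch
            if keep.sum() < 8:
                continue
            xy = xy[keep]
            rr = rr[keep]
        curves.append(xy)
        if is_round and fld.spec.m == 0 and len(xy) >= 16:
            closed = np.hypot(*(xy[0] - xy[-1])) < 3 * fld.pitch
            rm = float(rr.mean())
            if closed and rm > 0 and float(rr.std()) < max(0.03 * rm, fld.pitch):
                circle_radii.append(min(rm, R))

    radii = None
    if is_round and fld.spec.m == 0:
        circle_radii.sort()
        radii = []
        for r in circle_radii:
            if not radii or r - radii[-1] > 2 * fld.pitch:
                radii.append(r)
    return NodalSet(mask=mask, curves=curves, radii=radii, tol=tol)


def symmetry_line_profile(
    grid: WaveField | np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    samples: int = 256,
    pitch: float | None = None,
    frame: str = "centered",
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a straight-line profile through a field or image.

    ``start`` and ``end`` are (x, y) in physical units (mm for wave fields,
    or whatever unit ``pitch`` is expressed in for raw arrays).  Values are
    bilinearly interpolated at ``samples`` equispaced points.

    Returns
    -------
    (s, values)
        Arc-length coordinates from ``start`` and the interpolated values.

    Raises
    ------
    BoundsError
        If either endpoint lies outside the grid.
    """
    if isinstance(grid, WaveField):
        arr = grid.zeta
        pitch = grid.pitch
        frame = grid.frame
    else:
        arr = np.asarray(grid, dtype=float)
        if pitch is None:
            raise ConfigError("pitch is required when profiling a raw array")
    npts_r, npts_c = arr.shape
    half_x = (npts_c - 1) * pitch / 2.0
    half_y = (npts_r - 1) * pitch / 2.0

    def to_index(pt):
        x, y = pt
        if frame == "centered":
            col = (x + half_x) / pitch
            row = (y + half_y) / pitch
        else:
            col = x / pitch
            row = y / pitch
        if not (-0.5 <= col <= npts_c - 0.5 and -0.5 <= row <= npts_r - 0.5):
            raise BoundsError(f"point {pt} outside the grid")
        return row, col

    r0, c0 = to_index(start)
    r1, c1 = to_index(end)
    t = np.linspace(0.0, 1.0, samples)
    rows = r0 + (r1 - r0) * t
    cols = c0 + (c1 - c0) * t
    vals = ndimage.map_coordinates(np.nan_to_num(arr, nan=0.0),
                                   [rows, cols], order=1, mode="nearest")
    s = t * math.hypot(end[0] - start[0], end[1] - start[1])
    return s, vals


@dataclass
class AccumulationMap:
    """Normalized cell-accumulation density derived from a mode shape."""

    density: np.ndarray
    pitch: float
    frame: str
    ridge_width_mm: float


def accumulation_map(fld: WaveField, width: float) -> AccumulationMap:
    """Convert a mode shape into a nodal-ridge accumulation density.

    The density is ``exp(-(d / s)^2)`` where ``d = zeta / |grad zeta|`` is a
    first-order estimate of the signed distance to the nodal set and ``s``
    is set so the ridge's full width at half maximum equals ``width`` (mm).
    The result is normalized to integrate to 1 over the chamber.

    Raises
    ------
    ConfigError
        If ``width`` is not positive or exceeds the chamber dimension.
    """
    if width <= 0:
        raise ConfigError("ridge width must be positive")
    extent = fld.zeta.shape[0] * fld.pitch
    if width > extent:
        raise ConfigError("ridge width exceeds the chamber size")
    z = fld.zeta_full if fld.zeta_full is not None else np.nan_to_num(fld.zeta, nan=0.0)
    gy, gx = np.gradient(z, fld.pitch)
    gmag = np.hypot(gx, gy)
    gmag = np.maximum(gmag, 1e-9 * max(gmag.max(), 1e-30))
    d = z / gmag  # signed distance estimate, mm
    s = width / (2.0 * math.sqrt(math.log(2.0)))
    dens = np.exp(-((d / s) ** 2))
    dens[np.isnan(fld.zeta)] = 0.0  # outside the chamber
    total = dens.sum() * fld.pitch ** 2
    if total == 0:
        raise DegenerateFieldError("accumulation density vanished everywhere")
    dens /= total
    return AccumulationMap(density=dens, pitch=fld.pitch, frame=fld.frame,
                           ridge_width_mm=width)
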