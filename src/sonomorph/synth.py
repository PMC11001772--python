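"""Ground-truth-annotated synthetic data generators.

Three generators emulate the study inputs so that every downstream stage is
testable without any acquisition:

* patterned / random GFP+ cell-mask images — cells drawn as opaque discs,
  condensed onto the nodal ridges of a chamber mode (or placed uniformly for
  the stationary control), blurred with a Gaussian point-spread stand-in;
* maturing capillary ribbon networks with programmed per-day width
  distributions;
* two-group (patterned vs random, n=3 each) log-normal protein abundance
  tables with programmed up-/down-regulated subsets.

Every generator is a pure function of its spec (including the seed): the
same spec yields a bit-identical result.  Ground truth (pattern masks,
realized area fractions, ribbon centerlines and widths, regulation labels)
is attached to the output, never inferred downstream.

Cell discs are placed as a homogeneous binomial point process: the disc
count is fixed at round(lambda * area) with intensity lambda chosen so the
expected covered fraction of the Boolean model, 1 - exp(-lambda * a_disc),
matches the programmed GFP+ area fraction.  Fixing the count (rather than
drawing it Poisson) suppresses the dominant count-fluctuation term in the
realized-fraction variance while keeping the placement spatially uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from . import chamber
from .chamber import ModeSpec, WaveField
from .exceptions import ConfigError, GeneratorError
from .proteomics import AbundanceTable

__all__ = [
    "ImageSpec",
    "NetworkSpec",
    "ProteomeSpec",
    "SyntheticImage",
    "DAY_WIDTH_PROFILES",
    "generate_pattern_image",
    "generate_random_image",
    "generate_network_image",
    "generate_proteome",
]

#: Per-day ribbon width profiles (mean, SD) in µm for the maturing network
#: generator, selectable by ``NetworkSpec(day=...)``.  Widths are drawn from
#: a normal truncated at one pixel, so the realized mean exceeds the nominal
#: one when the SD is large; the truth sidecar records the realized draws.
DAY_WIDTH_PROFILES: dict[int, tuple[float, float]] = {
    1: (13.1, 24.7),
    3: (10.6, 18.9),
    5: (4.1, 9.5),
}


@dataclass(frozen=True)
class ImageSpec:
    """Specification of a synthetic patterned / random cell image.

    ``enhancement_pct`` programs the percent increase of the on-pattern GFP+
    area fraction over the off-pattern (background) fraction; the generator
    realizes both fractions within 2% relative for images >= 1024^2 px.
    """

    geometry: str  # 'rings' | 'honeycomb' | 'random'
    image_size: int = 2048
    pixel_pitch: float = 2.5  # µm / px
    cell_radius: float = 7.5  # µm
    line_width: float = 100.0  # µm
    background_fraction: float = 0.05
    enhancement_pct: float = 0.0
    noise_sd: float = 0.0  # additive Gaussian noise, fraction of dynamic range
    margin: float = 0.95  # chamber fills this fraction of the image half-extent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("rings", "honeycomb", "random"):
            raise ConfigError(f"unknown geometry {self.geometry!r}")
        if self.pixel_pitch <= 0:
            raise ConfigError("pixel_pitch must be positive")
        if self.image_size < 64:
            raise ConfigError("image_size must be >= 64")
        if self.cell_radius < self.pixel_pitch:
            raise ConfigError("cell_radius must be at least one pixel")
        if not (0.0 <= self.background_fraction < 0.9):
            raise ConfigError("background_fraction must be in [0, 0.9)")
        on = self.background_fraction * (1.0 + self.enhancement_pct / 100.0)
        if on >= 0.9:
            raise GeneratorError(
                f"programmed on-pattern fraction {on:.3f} >= 0.9 saturates the image")
        if not (0.0 <= self.noise_sd < 1.0):
            raise ConfigError("noise_sd must be in [0, 1)")
        if not (0.1 < self.margin <= 1.0):
            raise ConfigError("margin must be in (0.1, 1]")


@dataclass(frozen=True)
class NetworkSpec:
    """Specification of a synthetic capillary ribbon network image."""

    day: int | None = None  # 1, 3 or 5 selects a width profile
    ribbon_width_mean: float | None = None  # µm
    ribbon_width_sd: float | None = None  # µm
    ribbon_count: int = 25
    along_pattern: bool = False
    image_size: int = 768
    pixel_pitch: float = 1.0  # µm / px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.day is not None and self.day not in DAY_WIDTH_PROFILES:
            raise ConfigError(f"day must be one of {sorted(DAY_WIDTH_PROFILES)}")
        if self.day is None and self.ribbon_width_mean is None:
            raise ConfigError("either day or ribbon_width_mean must be given")
        if self.ribbon_width_mean is not None and self.ribbon_width_mean <= 0:
            raise ConfigError("ribbon_width_mean must be positive")
        if self.ribbon_count < 0:
            raise ConfigError("ribbon_count must be >= 0")

    def width_profile(self) -> tuple[float, float]:
        if self.ribbon_width_mean is not None:
            return self.ribbon_width_mean, self.ribbon_width_sd or 0.0
        return DAY_WIDTH_PROFILES[self.day]


@dataclass(frozen=True)
class ProteomeSpec:
    """Specification of a synthetic two-group protein abundance table.

    Per-protein log2 baselines are Normal(baseline_log2_mean, baseline_log2_sd);
    regulated proteins receive a group shift of +/-|Normal(log2_effect_mean,
    log2_effect_sd)| in the patterned group; per-sample residuals are
    Normal(0, residual_sd) on the log2 scale.  Abundances are 2**log2value,
    hence strictly positive.
    """

    n_proteins: int = 4000
    n_per_group: int = 3
    n_up: int = 643
    n_down: int = 261
    log2_effect_mean: float = 2.0
    log2_effect_sd: float = 0.3
    residual_sd: float = 0.25
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_proteins:
            raise ConfigError("n_up + n_down exceeds n_proteins")
        if min(self.n_up, self.n_down) < 0 or self.n_proteins <= 0:
            raise ConfigError("protein counts must be non-negative")
        if self.n_per_group < 2:
            raise ConfigError("need at least 2 samples per group")
        if self.residual_sd <= 0:
            raise ConfigError("residual_sd must be positive")


@dataclass
class SyntheticImage:
    """A generated intensity image plus its ground-truth annotations."""

    intensity: np.ndarray  # uint16
    pixel_pitch: float  # µm / px
    truth: dict[str, Any]
    spec: ImageSpec | NetworkSpec | None = None

    @property
    def cells_mask(self) -> np.ndarray:
        return self.truth["cells_mask"]


# ---------------------------------------------------------------------------
# field-on-image geometry
# ---------------------------------------------------------------------------

def _default_field(geometry: str) -> WaveField:
    if geometry == "rings":
        return chamber.round_mode_field(
            ModeSpec("round", m=0, n=4, chamber_dim=21.0, grid_resolution=512))
    return chamber.square_mode_field(
        ModeSpec("square", m=5, n=1, chamber_dim=15.0, grid_resolution=512))


def _field_on_image(fld: WaveField, spec: ImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Map a chamber mode onto the image grid.

    Returns ``(d_px, inside)``: a first-order signed distance (in pixels) to
    the nodal set, and the boolean chamber support on the image.
    The chamber is scaled to fill ``margin`` of the image half-extent.
    """
    size = spec.image_size
    half = (size - 1) / 2.0
    px = np.arange(size) - half
    X, Y = np.meshgrid(px, px)
    if fld.spec is not None and fld.spec.shape == "round":
        R = fld.spec.chamber_dim
        scale = R / (spec.margin * half)  # chamber mm per image px
        r = np.hypot(X, Y) * scale
        th = np.arctan2(Y, X)
        zeta = chamber._round_eval(fld.spec, r, th)
        inside = r <= R
        if fld.spec.m == 0:
            # rotationally symmetric: the nodal set is a family of circles
            # with analytically known radii, so the distance to it is exact
            # (the generic gradient linearization below shifts band centers
            # by a few µm at ring curvature)
            zeros = np.array([chamber.bessel_zero(0, k)
                              for k in range(1, fld.spec.n + 1)])
            radii_px = zeros / zeros[-1] * spec.margin * half
            r_px_grid = np.hypot(X, Y)
            d_px = np.full(r_px_grid.shape, np.inf)
            for r_k in radii_px:
                np.minimum(d_px, np.abs(r_px_grid - r_k), out=d_px)
            d_px[~inside] = np.inf
            return d_px, inside
    elif fld.spec is not None and fld.spec.shape == "square":
        L = fld.spec.chamber_dim
        scale = L / (2 * spec.margin * half)
        xs = (X + spec.margin * half) * scale
        ys = (Y + spec.margin * half) * scale
        inside = (xs >= 0) & (xs <= L) & (ys >= 0) & (ys <= L)
        m, n = fld.spec.m, fld.spec.n
        zeta = (np.cos(n * np.pi * xs / L) * np.cos(m * np.pi * ys / L)
                - np.cos(m * np.pi * xs / L) * np.cos(n * np.pi * ys / L))
    else:  # raw numeric field: interpolate onto the image grid
        src = np.nan_to_num(fld.zeta, nan=0.0)
        zoom = (size - 1) / (src.shape[0] - 1)
        zeta = ndimage.zoom(src, zoom, order=1, grid_mode=False)
        zeta = zeta[:size, :size]
        inside = np.ones_like(zeta, dtype=bool)
    gy, gx = np.gradient(zeta)  # per-pixel units
    gmag = np.hypot(gx, gy)
    gmag = np.maximum(gmag, 1e-9 * max(float(gmag.max()), 1e-30))
    d_px = zeta / gmag
    d_px[~inside] = np.inf
    return d_px, inside


def ring_radii_um(spec: ImageSpec, n: int = 4) -> np.ndarray:
    """Physical radii (µm, from image center) of the n concentric nodal
    rings as rendered by the rings geometry."""
    zeros = np.array([chamber.bessel_zero(0, k) for k in range(1, n + 1)])
    half_um = (spec.image_size - 1) / 2.0 * spec.pixel_pitch
    return zeros / zeros[-1] * spec.margin * half_um


# ---------------------------------------------------------------------------
# disc rasterization
# ---------------------------------------------------------------------------

def _disc_offsets(r_px: float) -> tuple[np.ndarray, np.ndarray]:
    c = int(math.floor(r_px))
    ii, jj = np.meshgrid(np.arange(-c, c + 1), np.arange(-c, c + 1), indexing="ij")
    sel = ii ** 2 + jj ** 2 <= r_px ** 2
    return ii[sel], jj[sel]


def _sample_in_region(rng: np.random.Generator, region: np.ndarray | None,
                      size: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """n iid uniform pixel positions, optionally restricted to a region mask."""
    if region is None:
        rows = rng.integers(0, size, n)
        cols = rng.integers(0, size, n)
        return rows, cols
    idx = np.flatnonzero(region.ravel())
    pick = rng.choice(idx, size=n, replace=True)
    return pick // size, pick % size


def _stamp_discs(mask: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                 off_i: np.ndarray, off_j: np.ndarray) -> None:
    size = mask.shape[0]
    for r, c in zip(rows, cols):
        ii = off_i + r
        jj = off_j + c
        ok = (ii >= 0) & (ii < size) & (jj >= 0) & (jj < size)
        mask[ii[ok], jj[ok]] = True


def _coverage_count(fraction: float, area_px: int, disc_area: float) -> int:
    """Disc count giving expected Boolean-model coverage ``fraction``."""
    if fraction <= 0:
        return 0
    lam = -math.log(1.0 - fraction) / disc_area
    return int(round(lam * area_px))


def _render_intensity(mask: np.ndarray, spec: ImageSpec,
                      rng: np.random.Generator) -> np.ndarray:
    sigma = (spec.cell_radius / spec.pixel_pitch) / 2.0
    img = ndimage.gaussian_filter(mask.astype(float), sigma)
    peak = img.max()
    if peak > 0:
        img = img / peak
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return (np.clip(img, 0.0, 1.0) * 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_pattern_image(spec: ImageSpec,
                           field: WaveField | None = None) -> SyntheticImage:
    """Generate a patterned cell image: background cells everywhere plus
    extra cells condensed on the nodal ridge band of width ``line_width``.

    The extra-cell intensity is placed on the band dilated by one cell
    radius so that coverage is uniform across the band (no edge deficit);
    the truth sidecar records the pattern band and realized fractions.
    """
    if spec.geometry not in ("rings", "honeycomb"):
        raise ConfigError("generate_pattern_image requires rings or honeycomb geometry")
    if field is None:
        field = _default_field(spec.geometry)
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size

    d_px, inside = _field_on_image(field, spec)
    half_w_px = (spec.line_width / spec.pixel_pitch) / 2.0
    r_cell_px = spec.cell_radius / spec.pixel_pitch
    band = np.abs(d_px) <= half_w_px
    band_dil = np.abs(d_px) <= half_w_px + r_cell_px

    off_i, off_j = _disc_offsets(r_cell_px)
    disc_area = float(len(off_i))
    f_bg = spec.background_fraction
    f_on = f_bg * (1.0 + spec.enhancement_pct / 100.0)

    mask = np.zeros((size, size), dtype=bool)
    n_bg = _coverage_count(f_bg, size * size, disc_area)
    rows, cols = _sample_in_region(rng, None, size, n_bg)
    _stamp_discs(mask, rows, cols, off_i, off_j)
    centers = [np.column_stack([rows, cols])]

    # extra intensity on the dilated band so the band itself sees uniform
    # coverage 1 - exp(-(lam_bg + lam_extra) * a)
    band_area = int(band_dil.sum())
    if band_area == 0:
        raise GeneratorError("pattern band is empty; check line_width and geometry")
    lam_extra = (-math.log(1.0 - f_on) + math.log(1.0 - f_bg)) / disc_area
    n_extra = int(round(lam_extra * band_area))
    rows, cols = _sample_in_region(rng, band_dil, size, n_extra)
    _stamp_discs(mask, rows, cols, off_i, off_j)
    centers.append(np.column_stack([rows, cols]))

    intensity = _render_intensity(mask, spec, rng)
    realized_on = float(mask[band].mean())
    # off-pattern fraction is measured away from the line: cells condensed at
    # the band edge protrude up to ~2 cell radii, so a guard zone of that
    # width around the band is excluded (the full complement is also kept)
    guard = np.abs(d_px) <= half_w_px + 2.0 * r_cell_px + 1.0
    realized_off = float(mask[~guard].mean())
    truth: dict[str, Any] = {
        "pattern_mask": band,
        "cells_mask": mask,
        "programmed_on_fraction": f_on,
        "programmed_off_fraction": f_bg,
        "realized_on_fraction": realized_on,
        "realized_off_fraction": realized_off,
        "realized_off_fraction_with_halo": float(mask[~band].mean()),
        "cell_centers": np.concatenate(centers, axis=0),
        "seed": spec.seed,
        "spec": spec,
    }
    if spec.geometry == "rings" and field.spec is not None:
        truth["ring_radii_um"] = ring_radii_um(spec, field.spec.n)
    return SyntheticImage(intensity=intensity, pixel_pitch=spec.pixel_pitch,
                          truth=truth, spec=spec)


def generate_random_image(spec: ImageSpec) -> SyntheticImage:
    """Generate the stationary (no sound) control: spatially uniform cell
    placement at ``background_fraction`` coverage; empty pattern truth."""
    if spec.geometry != "random":
        raise ConfigError("generate_random_image requires geometry='random'")
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    off_i, off_j = _disc_offsets(spec.cell_radius / spec.pixel_pitch)
    mask = np.zeros((size, size), dtype=bool)
    n = _coverage_count(spec.background_fraction, size * size, float(len(off_i)))
    rows, cols = _sample_in_region(rng, None, size, n)
    _stamp_discs(mask, rows, cols, off_i, off_j)
    intensity = _render_intensity(mask, spec, rng)
    truth = {
        "pattern_mask": np.zeros((size, size), dtype=bool),
        "cells_mask": mask,
        "cell_centers": np.column_stack([rows, cols]),
        "programmed_on_fraction": None,
        "programmed_off_fraction": spec.background_fraction,
        "realized_on_fraction": None,
        "realized_off_fraction": float(mask.mean()),
        "seed": spec.seed,
        "spec": spec,
    }
    return SyntheticImage(intensity=intensity, pixel_pitch=spec.pixel_pitch,
                          truth=truth, spec=spec)


def _random_walk_centerline(rng: np.random.Generator, size: int) -> np.ndarray:
    """A smooth random polyline across the image (pixel coordinates)."""
    pos = rng.uniform(0.1 * size, 0.9 * size, 2)
    ang = rng.uniform(0.0, 2 * np.pi)
    step = 4.0
    pts = [pos.copy()]
    # gentle curvature: radius of curvature ~ step/sd = 80 px, comfortably
    # larger than the widest ribbons so they do not fold onto themselves
    for _ in range(int(1.5 * size / step)):
        ang += rng.normal(0.0, 0.05)
        pos = pos + step * np.array([math.sin(ang), math.cos(ang)])
        if not (0 <= pos[0] < size and 0 <= pos[1] < size):
            break
        pts.append(pos.copy())
    return np.array(pts)


def _pattern_centerlines(fld: WaveField, spec: NetworkSpec) -> list[np.ndarray]:
    """Nodal curves of a chamber mode mapped to image pixel coordinates."""
    nodal = chamber.extract_nodal_set(fld)
    size = spec.image_size
    half = (size - 1) / 2.0
    curves = []
    for xy in nodal.curves:
        if fld.frame == "centered":
            ext = fld.zeta.shape[0] * fld.pitch / 2.0
            rc = np.column_stack([xy[:, 1] / ext * half + half,
                                  xy[:, 0] / ext * half + half])
        else:
            ext = fld.zeta.shape[0] * fld.pitch
            rc = np.column_stack([xy[:, 1] / ext * (size - 1),
                                  xy[:, 0] / ext * (size - 1)])
        rc = rc[(rc[:, 0] >= 0) & (rc[:, 0] < size)
                & (rc[:, 1] >= 0) & (rc[:, 1] < size)]
        if len(rc) >= 2:
            curves.append(rc)
    return curves


def generate_network_image(spec: NetworkSpec,
                           field: WaveField | None = None) -> SyntheticImage:
    """Generate a capillary-like ribbon network image.

    Ribbons are smooth polylines dilated to a per-ribbon width drawn from
    the (day-preset or explicit) normal distribution truncated at one pixel.
    With ``along_pattern`` the centerlines follow the nodal curves of the
    supplied chamber mode; otherwise placement is isotropic.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    mean, sd = spec.width_profile()
    min_w = spec.pixel_pitch  # 1 px truncation

    if spec.along_pattern:
        if field is None:
            field = _default_field("rings")
        pattern_lines = _pattern_centerlines(field, spec)
    else:
        pattern_lines = []

    def draw_width() -> float:
        if sd <= 0:
            return max(mean, min_w)
        while True:  # truncated normal, >= 1 px
            w = rng.normal(mean, sd)
            if w >= min_w:
                return float(w)

    mask = np.zeros((size, size), dtype=bool)
    ribbons: list[dict[str, Any]] = []
    for k in range(spec.ribbon_count):
        if spec.along_pattern and pattern_lines:
            base = pattern_lines[k % len(pattern_lines)]
            jitter = rng.normal(0.0, 1.0, base.shape)
            line = base + jitter
        else:
            line = _random_walk_centerline(rng, size)
        if len(line) < 2:
            continue
        w_um = draw_width()
        w_px = w_um / spec.pixel_pitch
        cl = np.zeros((size, size), dtype=bool)
        ipts = np.clip(np.round(line).astype(int), 0, size - 1)
        for a, b in zip(ipts[:-1], ipts[1:]):
            rr, cc = skdraw.line(a[0], a[1], b[0], b[1])
            cl[rr, cc] = True
        dist = ndimage.distance_transform_edt(~cl)
        mask |= dist <= w_px / 2.0
        ribbons.append({"centerline_px": line, "width_um": w_um})

    img = ndimage.gaussian_filter(mask.astype(float), 1.0)
    peak = img.max()
    if peak > 0:
        img /= peak
    intensity = (np.clip(img, 0, 1) * 65535).astype(np.uint16)
    truth = {
        "cells_mask": mask,
        "ribbons": ribbons,
        "realized_widths_um": np.array([r["width_um"] for r in ribbons]),
        "seed": spec.seed,
        "spec": spec,
    }
    return SyntheticImage(intensity=intensity, pixel_pitch=spec.pixel_pitch,
                          truth=truth, spec=spec)


def generate_proteome(spec: ProteomeSpec) -> tuple[AbundanceTable, pd.Series]:
    """Generate a two-group protein abundance table plus truth labels.

    Returns
    -------
    (table, truth)
        ``table`` is an :class:`~sonomorph.proteomics.AbundanceTable` with
        strictly positive abundances; ``truth`` labels each protein
        'up', 'down' or 'null' (regulation of patterned relative to random).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]

    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, n)
    effect = np.zeros(n)
    effect[: spec.n_up] = np.abs(
        rng.normal(spec.log2_effect_mean, spec.log2_effect_sd, spec.n_up))
    effect[spec.n_up: spec.n_up + spec.n_down] = -np.abs(
        rng.normal(spec.log2_effect_mean, spec.log2_effect_sd, spec.n_down))

    k = spec.n_per_group
    cols = [f"patterned_{i+1}" for i in range(k)] + [f"random_{i+1}" for i in range(k)]
    shift = np.concatenate([np.ones(k), np.zeros(k)])  # effect applies to patterned
    log2 = (baseline[:, None] + effect[:, None] * shift[None, :]
            + rng.normal(0.0, spec.residual_sd, (n, 2 * k)))
    data = pd.DataFrame(np.exp2(log2), index=pd.Index(ids, name="protein_id"),
                        columns=cols)
    groups = {c: ("patterned" if c.startswith("patterned") else "random")
              for c in cols}
    labels = np.array(["null"] * n, dtype=object)
    labels[: spec.n_up] = "up"
    labels[spec.n_up: spec.n_up + spec.n_down] = "down"
    truth = pd.Series(labels, index=data.index, name="truth")
    return AbundanceTable(data, groups), truth
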