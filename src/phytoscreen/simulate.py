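"""Seeded simulator of Phytostrip wells with exact per-pixel ground truth.

Side views emulate the root camera: bright, thin, curvilinear roots
(primary, laterals, root hairs) growing down through a 2 mm-thick gel
slab, photographed against a matt black background.  Overhead views
emulate the shoot camera: a green rosette on the white plinth.

A root system is grown as a discrete-step heading random walk (step =
1 px): at each step the heading is pulled toward vertical by the
``gravitropism`` weight and perturbed by a Gaussian of s.d.
``tortuosity`` degrees.  Laterals arise as a Poisson process along the
primary axis and elongate from the day their position was laid down;
root hairs are short, straight, near-perpendicular emergences from the
parent axis.

Rendering rasterises every stroke on a supersampled grid (butt-capped,
half-open on both axes, so an axis-aligned bar of length L and width w
covers exactly L*w pixel units).  The noise-free coverage is the
ground-truth probability map; the local tangent, folded to [0, 90]
degrees from horizontal, is the ground-truth orientation.  Blur and
noise are applied to the image only, never to the truth layers.

Image convention: origin top-left, row index increases downward (the
gel surface is row 0), angles are measured from the horizontal axis and
folded into [0, 90] because orientation is undirected.  All stochastic
operations take an explicit seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage.color import hsv2rgb

__all__ = [
    "WellGeometry",
    "GrowthParams",
    "Segment",
    "RootSystem",
    "OrientationMap",
    "RenderedWell",
    "PRESET_NAMES",
    "phenotype_preset",
    "simulate_root_system",
    "render_side_view",
    "render_rosette",
    "render_strip",
]


@dataclass(frozen=True)
class WellGeometry:
    """Pixel geometry of a single Phytostrip well.

    The physical well is 22 mm deep, so the default 440-pixel height puts
    the scale at 0.05 mm per pixel — coarser than the real macro optics
    (which resolve individual root hairs at roughly 0.02 mm/px) but fine
    enough that the thinnest rendered structures span several pixels.
    ``top_view_px`` is the side length of the square overhead crop of the
    same well.  The side view is always divided into exactly four
    horizontal quadrants for trait extraction.
    """

    height_px: int = 440
    width_px: int = 120
    mm_per_px: float | None = None
    top_view_px: int = 120
    quadrant_count: int = 4

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0 or self.top_view_px <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.quadrant_count != 4:
            raise ValueError("wells are divided into exactly four quadrants")
        if self.mm_per_px is None:
            object.__setattr__(self, "mm_per_px", 22.0 / self.height_px)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the root-growth random walk (lengths/rates in pixels).

    Defaults describe a healthy 7-day-old seedling at the default
    0.05 mm/px scale: a ~2.2 mm/day primary root, ~4 laterals per cm
    emerging at ~20 degrees from horizontal after a 2-day maturation
    delay, and 0.4 mm root hairs at ~6 per mm of parent axis.  Root hairs
    are drawn wider than their true ~10 um diameter so that, as in the
    real photographs, they remain visible structures at image scale.
    Two plants per well mirrors the standard sowing density of the screen.
    """

    days: float = 7.0
    primary_rate: float = 44.0
    tortuosity: float = 3.0
    gravitropism: float = 0.15
    lateral_density: float = 0.02
    lateral_angle: float = 20.0
    lateral_rate: float = 12.0
    lateral_delay_days: float = 2.0
    hair_density: float = 0.3
    hair_length: float = 8.0
    hair_angle_spread: float = 15.0
    primary_width: float = 4.0
    lateral_width: float = 2.5
    hair_width: float = 1.2
    n_plants: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = (
            "days", "primary_rate", "tortuosity", "lateral_density",
            "lateral_angle", "lateral_rate", "lateral_delay_days",
            "hair_density", "hair_length", "hair_angle_spread",
            "primary_width", "lateral_width", "hair_width",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.gravitropism <= 1.0:
            raise ValueError("gravitropism must lie in [0, 1]")
        if self.n_plants < 0:
            raise ValueError("n_plants must be >= 0")


#: Parameter overrides reproducing the qualitative phenotype classes seen in
#: chemical screens: lateral-root suppression, primary-growth inhibition,
#: root-hair elongation or loss, agravitropic/wavy growth, dense branching.
_PRESETS: dict[str, dict] = {
    "control": {},
    "no_laterals": {"lateral_density": 0.0},
    "short_primary": {"primary_rate": 16.0},
    "long_hairs": {"hair_length": 18.0, "hair_density": 0.4},
    "no_hairs": {"hair_density": 0.0},
    "agravitropic_wavy": {"gravitropism": 0.01, "tortuosity": 12.0},
    "dense_laterals": {"lateral_density": 0.06},
}

PRESET_NAMES = tuple(_PRESETS)


def phenotype_preset(name: str, **overrides) -> GrowthParams:
    """Growth parameters for a named phenotype class (see :data:`PRESET_NAMES`)."""
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return replace(GrowthParams(), **{**base, **overrides})


@dataclass
class Segment:
    """One rendered structure: a polyline of (row, col) points with a stroke width."""

    points: np.ndarray  # (N, 2) float, (row, col) pixel coordinates
    kind: str  # "primary" | "lateral" | "hair"
    width: float


@dataclass
class RootSystem:
    """Geometric ground truth of all root material in one well."""

    segments: list[Segment]
    geometry: WellGeometry

    def total_length(self, kind: str | None = None) -> float:
        tot = 0.0
        for seg in self.segments:
            if kind is not None and seg.kind != kind:
                continue
            d = np.diff(seg.points, axis=0)
            tot += float(np.sqrt((d ** 2).sum(axis=1)).sum())
        return tot


@dataclass
class OrientationMap:
    """Per-pixel angle from horizontal in [0, 90] with a validity mask."""

    angle_deg: np.ndarray
    valid: np.ndarray


@dataclass
class RenderedWell:
    """A rendered well image plus its noise-free ground-truth layers."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    truth_probability: np.ndarray | None = None
    truth_orientation: OrientationMap | None = None
    truth_shoot_mask: np.ndarray | None = None


def _heading_walk(
    rng: np.random.Generator,
    start: np.ndarray,
    heading0: float,
    n_steps: int,
    tortuosity: float,
    gravitropism: float,
    geometry: WellGeometry,
) -> np.ndarray:
    """Random-walk a polyline from ``start``.

    ``heading`` is the angle from the downward vertical (radians, positive
    toward increasing column).  Each 1-px step blends the heading toward
    vertical by ``gravitropism`` and adds Gaussian noise of s.d.
    ``tortuosity`` degrees.  The walk reflects off the side walls and
    truncates at the well bottom.
    """
    tort = math.radians(tortuosity)
    pts = [start.astype(float)]
    heading = heading0
    pos = start.astype(float)
    for _ in range(n_steps):
        heading = (1.0 - gravitropism) * heading
        if tort > 0:
            heading += rng.normal(0.0, tort)
        step = np.array([math.cos(heading), math.sin(heading)])
        new = pos + step
        if new[1] < 0.5 or new[1] > geometry.width_px - 1.5:
            heading = -heading  # reflect off the side wall
            step = np.array([math.cos(heading), math.sin(heading)])
            new = pos + step
            new[1] = np.clip(new[1], 0.5, geometry.width_px - 1.5)
        if new[0] > geometry.height_px - 1.0:
            break  # truncate at the well bottom
        if new[0] < 0.0:
            new[0] = 0.0
        pos = new
        pts.append(pos.copy())
    return np.array(pts)


def _polyline_tangents(points: np.ndarray) -> np.ndarray:
    d = np.diff(points, axis=0)
    n = np.sqrt((d ** 2).sum(axis=1, keepdims=True))
    n[n == 0] = 1.0
    return d / n


def _point_at_arclength(points: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent of a polyline at arclength ``s`` (clamped)."""
    d = np.diff(points, axis=0)
    seglen = np.sqrt((d ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seglen) - 1)
    frac = (s - cum[i]) / seglen[i] if seglen[i] > 0 else 0.0
    pt = points[i] + frac * d[i]
    tan = d[i] / seglen[i] if seglen[i] > 0 else np.array([1.0, 0.0])
    return pt, tan


def _grow_hairs(
    rng: np.random.Generator,
    parent: Segment,
    params: GrowthParams,
    geometry: WellGeometry,
    tip_exclusion: float = 5.0,
) -> list[Segment]:
    """Straight hairs emerging near-perpendicularly from a parent axis.

    The hair base sits on the parent's edge (half the parent width off
    axis) so hairs do not simply disappear under the parent stroke.  The
    elongation zone near the tip carries no hairs.
    """
    if params.hair_density <= 0 or params.hair_length <= 0:
        return []
    d = np.diff(parent.points, axis=0)
    length = float(np.sqrt((d ** 2).sum(axis=1)).sum())
    usable = max(0.0, length - tip_exclusion)
    n = rng.poisson(params.hair_density * usable)
    hairs: list[Segment] = []
    for _ in range(n):
        s = rng.uniform(0.0, usable)
        base, tan = _point_at_arclength(parent.points, s)
        normal = np.array([-tan[1], tan[0]])
        side = 1.0 if rng.random() < 0.5 else -1.0
        ang = math.radians(rng.normal(0.0, params.hair_angle_spread))
        direction = side * (math.cos(ang) * normal) + math.sin(ang) * tan
        direction /= np.linalg.norm(direction)
        length_px = params.hair_length * rng.uniform(0.7, 1.3)
        start = base + side * 0.5 * parent.width * normal
        start[0] = np.clip(start[0], 0.0, geometry.height_px - 1.0)
        start[1] = np.clip(start[1], 0.0, geometry.width_px - 1.0)
        end = start + length_px * direction
        end[0] = np.clip(end[0], 0.0, geometry.height_px - 1.0)
        end[1] = np.clip(end[1], 0.0, geometry.width_px - 1.0)
        hairs.append(Segment(np.array([start, end]), "hair", params.hair_width))
    return hairs


def simulate_root_system(
    params: GrowthParams,
    geometry: WellGeometry | None = None,
    seed: int | None = None,
) -> RootSystem:
    """Grow a root system; deterministic for a fixed ``seed``.

    ``seed`` overrides ``params.seed`` when given.  Primaries start on the
    gel surface (row 0) near the well centre; each of ``n_plants`` plants
    grows its own primary, laterals and hairs.
    """
    if geometry is None:
        geometry = WellGeometry()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    segments: list[Segment] = []
    n_primary_steps = int(round(params.primary_rate * params.days))
    centre = (geometry.width_px - 1) / 2.0
    offsets = np.linspace(-0.12, 0.12, max(params.n_plants, 1)) * geometry.width_px
    for plant in range(params.n_plants):
        start = np.array([0.0, centre + offsets[plant] + rng.normal(0.0, 1.5)])
        start[1] = np.clip(start[1], 1.0, geometry.width_px - 2.0)
        primary_pts = _heading_walk(
            rng, start, rng.normal(0.0, 0.05), n_primary_steps,
            params.tortuosity, params.gravitropism, geometry,
        )
        if len(primary_pts) < 2:
            continue
        primary = Segment(primary_pts, "primary", params.primary_width)
        segments.append(primary)

        # Laterals: Poisson along the realised primary axis; each lateral
        # emerges once the tip has passed its position and a maturation
        # delay has elapsed, then elongates at lateral_rate.
        d = np.diff(primary_pts, axis=0)
        plen = float(np.sqrt((d ** 2).sum(axis=1)).sum())
        laterals: list[Segment] = []
        if params.lateral_density > 0 and plen > 0:
            n_lat = rng.poisson(params.lateral_density * plen)
            for _ in range(n_lat):
                s = rng.uniform(0.0, plen)
                emergence_day = (
                    s / params.primary_rate if params.primary_rate > 0 else 0.0
                ) + params.lateral_delay_days
                age = params.days - emergence_day
                n_steps = int(round(params.lateral_rate * max(0.0, age)))
                if n_steps < 2:
                    continue
                base, _tan = _point_at_arclength(primary_pts, s)
                side = 1.0 if rng.random() < 0.5 else -1.0
                # heading from vertical for an emergence angle measured
                # from horizontal: |90 - lateral_angle| off vertical
                h0 = side * math.radians(90.0 - params.lateral_angle)
                h0 += math.radians(rng.normal(0.0, 8.0))
                lat_pts = _heading_walk(
                    rng, base, h0, n_steps,
                    params.tortuosity, 0.25 * params.gravitropism, geometry,
                )
                if len(lat_pts) >= 2:
                    laterals.append(Segment(lat_pts, "lateral", params.lateral_width))
        segments.extend(laterals)
        for parent in [primary, *laterals]:
            segments.extend(_grow_hairs(rng, parent, params, geometry))
    return RootSystem(segments, geometry)


def _rasterize(
    system: RootSystem, supersample: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free stroke coverage and folded tangent angle per pixel.

    Each polyline leg is a butt-capped stroke, half-open along both the
    axial ([0, L)) and perpendicular ([-w/2, w/2)) axes on the supersampled
    lattice, so strokes tile without double counting and an axis-aligned
    bar of length L and width w has coverage summing exactly to L*w.

    Strokes are rasterised into one layer per structure kind.  The
    coverage map is the union over kinds.  A pixel's truth angle is the
    coverage-weighted mean of the folded sample angles within it, which
    defines a continuous orientation field: where structures of
    different orientation genuinely overlap inside one pixel (a hair
    crossing its parent) no single angle is "the" truth, and the mean
    degrades gracefully instead of switching discontinuously on
    sub-resolution detail that no image-based estimator could resolve.
    Returns ``(coverage, angle_deg)``; angle is NaN where no root
    material is present.
    """
    geom = system.geometry
    S = supersample
    Hh, Wh = geom.height_px * S, geom.width_px * S
    kinds = ("primary", "lateral", "hair")
    cov = {k: np.zeros((Hh, Wh), dtype=bool) for k in kinds}
    ang = {k: np.full((Hh, Wh), np.nan) for k in kinds}

    def coord(idx: np.ndarray) -> np.ndarray:
        return (idx + 0.5) / S - 0.5

    for seg in system.segments:
        pts = seg.points
        half = seg.width / 2.0
        kcov, kang = cov[seg.kind], ang[seg.kind]
        for i in range(len(pts) - 1):
            p0, p1 = pts[i], pts[i + 1]
            d = p1 - p0
            L = math.hypot(d[0], d[1])
            if L == 0:
                continue
            u = d / L
            rmin = min(p0[0], p1[0]) - half
            rmax = max(p0[0], p1[0]) + half
            cmin = min(p0[1], p1[1]) - half
            cmax = max(p0[1], p1[1]) + half
            i0 = max(0, int(math.floor((rmin + 0.5) * S)))
            i1 = min(Hh, int(math.ceil((rmax + 0.5) * S)) + 1)
            j0 = max(0, int(math.floor((cmin + 0.5) * S)))
            j1 = min(Wh, int(math.ceil((cmax + 0.5) * S)) + 1)
            if i0 >= i1 or j0 >= j1:
                continue
            rr = coord(np.arange(i0, i1))[:, None] - p0[0]
            cc = coord(np.arange(j0, j1))[None, :] - p0[1]
            t = rr * u[0] + cc * u[1]
            perp = -rr * u[1] + cc * u[0]
            inside = (t >= 0.0) & (t < L) & (perp >= -half) & (perp < half)
            if not inside.any():
                continue
            kcov[i0:i1, j0:j1] |= inside
            a = math.degrees(math.atan2(abs(u[0]), abs(u[1])))
            block = kang[i0:i1, j0:j1]
            block[inside] = a

    union = np.zeros((Hh, Wh), dtype=bool)
    ang_all = np.full((Hh, Wh), np.nan)
    for k in kinds:  # finer kinds drawn later overwrite at shared samples
        union |= cov[k]
        ang_all = np.where(cov[k], ang[k], ang_all)
    coverage = union.reshape(geom.height_px, S, geom.width_px, S).mean(axis=(1, 3))
    blocks = ang_all.reshape(geom.height_px, S, geom.width_px, S)
    counts = np.isfinite(blocks).sum(axis=(1, 3))
    sums = np.nansum(blocks, axis=(1, 3))
    angle = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return coverage, angle


def render_side_view(
    system: RootSystem,
    geometry: WellGeometry | None = None,
    noise_sd: float = 0.02,
    blur_sigma: float = 0.6,
    background: float = 0.08,
    foreground: float = 0.90,
    supersample: int = 3,
    seed: int = 0,
) -> RenderedWell:
    """Render the side-camera view of a well with exact ground truth.

    The truth layers come from the noise-free rasterisation; blur and
    additive Gaussian noise touch the image only.  The blur uses reflect
    boundaries, so it redistributes intensity without losing mass.
    """
    if geometry is None:
        geometry = system.geometry
    elif geometry is not system.geometry:
        system = RootSystem(system.segments, geometry)
    coverage, angle = _rasterize(system, supersample)
    valid = coverage > 0.0
    gray = background + (foreground - background) * coverage
    if blur_sigma > 0:
        gray = ndi.gaussian_filter(gray, blur_sigma, mode="reflect")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gray = gray + rng.normal(0.0, noise_sd, gray.shape)
    gray = np.clip(gray, 0.0, 1.0)
    image = np.repeat(gray[:, :, None], 3, axis=2)
    return RenderedWell(
        image=image,
        truth_probability=coverage,
        truth_orientation=OrientationMap(angle_deg=angle, valid=valid),
    )


def render_rosette(
    n_leaves: int,
    leaf_size: float,
    hue: float,
    geometry: WellGeometry | None = None,
    noise_sd: float = 0.0,
    saturation: float = 0.8,
    value: float = 0.55,
    seed: int = 0,
) -> RenderedWell:
    """Render the overhead view: a rosette of elliptical leaves on white.

    Leaf ``k`` of ``n`` is an ellipse with semi-axes ``(leaf_size,
    0.45*leaf_size)`` rotated to angle ``2*pi*k/n`` and offset
    ``0.75*leaf_size`` from the image centre along that angle.  The truth
    mask is the union of the leaf ellipses; overlap is not double counted.
    ``hue`` is in degrees on the standard colour wheel (red 0, green 120).
    """
    if not 0.0 <= hue < 360.0:
        raise ValueError("hue must lie in [0, 360)")
    if geometry is None:
        geometry = WellGeometry()
    n = geometry.top_view_px
    mask = np.zeros((n, n), dtype=bool)
    centre = (n - 1) / 2.0
    for k in range(n_leaves):
        theta = 2.0 * math.pi * k / max(n_leaves, 1)
        cr = centre + 0.75 * leaf_size * math.sin(theta)
        cc = centre + 0.75 * leaf_size * math.cos(theta)
        rr, cc_idx = skdraw.ellipse(
            cr, cc, 0.45 * leaf_size, leaf_size, shape=mask.shape, rotation=theta
        )
        mask[rr, cc_idx] = True
    colour = hsv2rgb(np.array([[[hue / 360.0, saturation, value]]]))[0, 0]
    image = np.ones((n, n, 3))
    image[mask] = colour
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, image.shape)
    image = np.clip(image, 0.0, 1.0)
    return RenderedWell(image=image, truth_shoot_mask=mask)


def render_strip(
    wells: list[RenderedWell],
    margin: int = 6,
    background: float | tuple[float, float, float] = 0.08,
) -> tuple[np.ndarray, list[tuple[int, int, int, int]]]:
    """Composite per-well renders into one strip image, left to right.

    Returns the strip image and the crop boxes ``(row0, col0, row1, col1)``
    (half-open) that recover each well pixel-for-pixel.
    """
    if not wells:
        raise ValueError("need at least one well to composite")
    h = max(w.image.shape[0] for w in wells)
    widths = [w.image.shape[1] for w in wells]
    total_w = sum(widths) + margin * (len(wells) + 1)
    strip = np.empty((h + 2 * margin, total_w, 3))
    strip[:] = np.asarray(background, dtype=float)
    boxes: list[tuple[int, int, int, int]] = []
    col = margin
    for w in wells:
        hh, ww = w.image.shape[:2]
        strip[margin : margin + hh, col : col + ww] = w.image
        boxes.append((margin, col, margin + hh, col + ww))
        col += ww + margin
    return strip, boxes
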