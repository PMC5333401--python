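"""Probabilistic root-trait extraction from side-view well images.

Rather than a hard binary segmentation, every pixel is assigned a root
likelihood in [0, 1]; the well-level readouts are expectations under
that map.  The five headline traits are:

* ``root_mass`` — the sum of per-pixel likelihoods over the well, i.e.
  a likelihood estimate of the total number of root pixels;
* ``q[i][j]`` — the same expectation restricted to quadrant ``i`` (four
  equal-height horizontal bands, Q0 at the top) and orientation bin
  ``j`` (four 22.5-degree bins of the angle from horizontal), of which
  ``Q0-horizontal`` (= q[0][0], dominated by root hairs and laterals)
  and ``Q3-vertical`` (= q[3][3], dominated by the advancing primary
  root) are the named traits;
* ``leaf_area``/``leaf_hue`` live in :mod:`phytoscreen.shoots`.

Segmentation: the luminance image is background-subtracted against a
robust per-image estimate (median/MAD — roots are sparse against the
matt-black card), candidate root pixels must exceed the noise floor and
carry a multiscale curvilinear (Sato ridge) response, small speckles
are dropped, and the likelihood is the background-subtracted intensity
normalised by the estimated stroke brightness, clipped to [0, 1] and
restricted to a dilated support around the detected curvilinear
structures.  Because rendering blur redistributes intensity without
destroying it, the map's sum tracks the true stroke coverage.

Orientation: per-pixel dominant orientation from the structure tensor
at a configurable Gaussian scale, folded to [0, 90] degrees from
horizontal; a pixel's orientation is valid when the tensor coherence
and the root likelihood both clear their thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.filters import sato
from skimage.measure import label
from skimage.morphology import disk

from .plates import WellAddress

__all__ = [
    "SegmentationConfig",
    "OrientationMap",
    "QuadrantBands",
    "RootTraits",
    "crop_wells",
    "segment_roots",
    "estimate_orientation",
    "partition_quadrants",
    "compute_root_traits",
    "analyze_side_well",
    "ORIENTATION_BIN_EDGES",
]

from .simulate import OrientationMap  # shared orientation container

#: Half-open orientation bin edges in degrees; the last bin closes at 90.
ORIENTATION_BIN_EDGES = (0.0, 22.5, 45.0, 67.5, 90.0)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the probabilistic segmentation and orientation stages."""

    noise_k: float = 4.0  # core threshold in noise s.d. above background
    core_floor: float = 0.02  # minimum contrast for core pixels (unit scale)
    ridge_sigmas: tuple[float, ...] = (1.0, 2.0)
    ridge_rel_threshold: float = 0.05  # of the image's peak ridge response
    min_object_px: int = 4
    support_radius: int = 3  # dilation of the core into the blur skirt
    foreground_percentile: float = 99.0
    # orientation stage
    smoothing_scale: float = 1.4  # structure-tensor window scale (px)
    derivative_scale: float = 0.7  # Gaussian-derivative scale for gradients (px)
    mask_threshold: float = 0.3  # likelihood above which a pixel is structure
    wide_radius: float = 2.0  # half-width (px) separating backbone from hairs
    backbone_dilation: int = 2  # recover the backbone's full width
    claim_extension: float = 2.5  # px a hair's footprint extends over the backbone
    claim_halfwidth: float = 1.0  # half-width of that extended footprint
    min_component_px: int = 3
    min_elongation: float = 2.0  # eigenvalue ratio below which a blob has no axis
    max_straight_residual: float = 1.0  # rms off-axis spread (px) of a straight stroke
    local_pca_radius: float = 4.0  # neighbourhood for curved/tangled thin pixels
    prob_threshold: float = 0.02  # likelihood floor for a valid orientation


def _luminance(image: np.ndarray) -> np.ndarray:
    """Single [0, 1] luminance channel from an RGB(A) or greyscale image."""
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    elif img.dtype == np.uint16:
        img = img.astype(float) / 65535.0
    else:
        img = img.astype(float)
    if img.ndim == 3:
        img = rgb2gray(img[:, :, :3])
    return img


def crop_wells(
    strip_image: np.ndarray,
    crop_boxes: list[tuple[int, int, int, int]],
    strip_address: WellAddress | None = None,
) -> list[tuple[WellAddress | None, np.ndarray]]:
    """Crop a strip image into its wells, indexed 1..n left to right.

    ``crop_boxes`` are half-open ``(row0, col0, row1, col1)`` rectangles.
    Boxes extending outside the image raise; overlapping boxes are
    accepted with a warning (no geometric constraint is violated, but
    they usually indicate a mis-specified geometry file).
    """
    h, w = strip_image.shape[:2]
    boxes = [tuple(int(v) for v in b) for b in crop_boxes]
    for i, (r0, c0, r1, c1) in enumerate(boxes, start=1):
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(
                f"crop box {i} {(r0, c0, r1, c1)} outside image of shape {(h, w)}"
            )
    order = sorted(range(len(boxes)), key=lambda i: boxes[i][1])
    for a, b in zip(order, order[1:]):
        if boxes[b][1] < boxes[a][3]:
            warnings.warn(
                f"crop boxes {a + 1} and {b + 1} overlap", stacklevel=2
            )
            break
    out = []
    for idx, i in enumerate(order, start=1):
        r0, c0, r1, c1 = boxes[i]
        addr = strip_address.with_well(idx) if strip_address is not None else None
        out.append((addr, strip_image[r0:r1, c0:c1].copy()))
    return out


def _drop_small_components(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Remove connected components smaller than ``min_px`` pixels."""
    if min_px <= 1 or not mask.any():
        return mask
    labels, n = label(mask, connectivity=2, return_num=True)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def segment_roots(
    well_image: np.ndarray, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Per-pixel root likelihood in [0, 1] for a side-view well image.

    Near-zero on pure background; monotone in local contrast on root
    structures.  Returns an array of the image's spatial shape.
    """
    if config is None:
        config = SegmentationConfig()
    lum = _luminance(well_image)
    # Background level and noise from the lower tail only: roots are
    # strictly brighter than the matt-black card, and in a crowded well
    # they can cover enough area to contaminate the median.
    p10, p25 = np.percentile(lum, [10.0, 25.0])
    sigma = float(p25 - p10) / 0.608  # z(0.25) - z(0.10) for a Gaussian
    bg = float(p25) + 0.674 * sigma  # recentre to the background mode
    thr = bg + max(config.noise_k * sigma, config.core_floor)
    bright = lum > thr
    prob = np.zeros_like(lum)
    if not bright.any():
        return prob
    ridge = sato(lum, sigmas=config.ridge_sigmas, black_ridges=False)
    peak = float(ridge.max())
    core = bright & (ridge > config.ridge_rel_threshold * peak) if peak > 0 else bright
    core = _drop_small_components(core, config.min_object_px)
    if not core.any():
        return prob
    support = ndi.binary_dilation(core, structure=disk(config.support_radius))
    fg = float(np.percentile(lum[core], config.foreground_percentile))
    denom = max(fg - bg, 1e-6)
    prob = np.clip((lum - bg) / denom, 0.0, 1.0)
    prob[~support] = 0.0
    return prob


def _tensor_orientation(lum: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Per-pixel ridge orientation (degrees from horizontal, folded to [0, 90]).

    Structure tensor built from Gaussian-derivative gradients: a 2-tap
    difference gradient is anisotropic and biases oblique orientations
    toward the pixel axes by a couple of degrees, which matters when
    binning into 22.5-degree classes.  The ridge runs along the minor
    eigenvector; the major eigenvector angle comes from the half-angle
    formula, which stays stable where the off-diagonal term cancels.
    """
    sd, sw = config.derivative_scale, config.smoothing_scale
    gr = ndi.gaussian_filter(lum, sd, order=(1, 0), mode="nearest")
    gc = ndi.gaussian_filter(lum, sd, order=(0, 1), mode="nearest")
    arr = ndi.gaussian_filter(gr * gr, sw, mode="nearest")
    arc = ndi.gaussian_filter(gr * gc, sw, mode="nearest")
    acc = ndi.gaussian_filter(gc * gc, sw, mode="nearest")
    alpha = 0.5 * np.arctan2(2.0 * arc, arr - acc)
    return np.degrees(np.arctan2(np.abs(np.sin(alpha)), np.abs(np.cos(alpha))))


def estimate_orientation(
    probability_map: np.ndarray,
    well_image: np.ndarray,
    config: SegmentationConfig | None = None,
) -> OrientationMap:
    """Per-pixel root orientation, folded to [0, 90] degrees from horizontal.

    Roots are a mixture of two very different populations and a single
    local operator serves neither well, so the likelihood map is first
    decomposed by local width (distance transform of the thresholded
    map):

    * the *backbone* (primary root and laterals, wider than
      ``wide_radius``) takes smooth per-pixel structure-tensor angles;
    * each remaining thin connected component (root hairs, short thin
      fragments) is treated as one straight stroke — its axis from a
      likelihood-weighted PCA of its pixel coordinates — because a
      root hair only a few pixels long carries too little signal for
      per-pixel estimates.  The stroke's footprint is extended by
      ``claim_extension`` pixels along its axis over the backbone, so a
      hair's base keeps the hair's angle rather than the parent's.

    Pixels with likelihood but no angle of their own (blur skirts)
    inherit the angle of the nearest assigned structure.  Validity
    requires likelihood >= ``prob_threshold`` and a defined angle.
    """
    if config is None:
        config = SegmentationConfig()
    lum = _luminance(well_image)
    if lum.shape != probability_map.shape:
        raise ValueError(
            f"probability map {probability_map.shape} and image {lum.shape} differ"
        )
    prob = np.asarray(probability_map, dtype=float)
    h, w = prob.shape
    angle = np.full((h, w), np.nan)
    tensor = _tensor_orientation(lum, config)

    mask = prob > config.mask_threshold
    if mask.any():
        radius = ndi.distance_transform_edt(mask)
        backbone = (
            ndi.binary_dilation(
                radius >= config.wide_radius, structure=disk(config.backbone_dilation)
            )
            & mask
        )
        angle[backbone] = tensor[backbone]
        fine = mask & ~backbone
        labels, n = ndi.label(fine, structure=np.ones((3, 3), int))
        for i in range(1, n + 1):
            idx = np.where(labels == i)
            if len(idx[0]) < config.min_component_px:
                angle[idx] = tensor[idx]
                continue
            theta, axis, centroid, span, residual = _component_axis(
                idx, prob[idx], config
            )
            if theta is not None and residual <= config.max_straight_residual:
                # a straight stroke (root hair): one angle, footprint
                # extended over the parent's width
                angle[idx] = theta
                _claim_over_backbone(
                    angle, backbone, theta, axis, centroid, span, config
                )
            else:
                # curved tail or tangled mat: local PCA among thin-structure
                # pixels only, so the backbone cannot contaminate it; ends
                # touching the backbone claim into it with their own angle
                local = _local_pca_angles(idx, prob[idx], config)
                angle[idx] = local
                _claim_curved_ends(angle, backbone, idx, local, prob[idx], config)
        # blur skirts inherit the nearest assigned structure's angle
        has = ~np.isnan(angle)
        if has.any():
            ind = ndi.distance_transform_edt(
                ~has, return_distances=False, return_indices=True
            )
            angle = angle[ind[0], ind[1]]

    valid = (prob >= config.prob_threshold) & ~np.isnan(angle)
    return OrientationMap(angle_deg=angle, valid=valid)


def _component_axis(idx, weights, config: SegmentationConfig):
    """Dominant axis of a thin connected component by weighted PCA.

    Returns ``(theta_deg, axis_vector, centroid, (t_min, t_max))`` or
    ``(None, ...)`` when the component has no clear axis (near-isotropic
    blob, e.g. two crossing hairs).
    """
    pts = np.column_stack(idx).astype(float)
    wsum = weights.sum()
    mu = (pts * weights[:, None]).sum(axis=0) / wsum
    centred = pts - mu
    cov = (centred * weights[:, None]).T @ centred / wsum
    evals, evecs = np.linalg.eigh(cov)
    elongation = evals[-1] / max(evals[0], 1e-9)
    v = evecs[:, -1]
    if elongation < config.min_elongation:
        return None, None, None, None, None
    theta = float(np.degrees(np.arctan2(abs(v[0]), abs(v[1]))))
    t = centred @ v
    perp = centred @ evecs[:, 0]
    residual = float(np.sqrt((perp ** 2 * weights).sum() / wsum))
    return theta, v, mu, (float(t.min()), float(t.max())), residual


def _local_pca_angles(idx, weights, config: SegmentationConfig) -> np.ndarray:
    """Per-pixel angles for a curved or tangled thin component.

    Each pixel's angle is the dominant axis of the component pixels within
    ``local_pca_radius``, weighted by likelihood.  Restricting the
    neighbourhood to the thin-structure population keeps nearby wide
    roots out of the estimate.
    """
    from scipy.spatial import cKDTree

    pts = np.column_stack(idx).astype(float)
    tree = cKDTree(pts)
    neighbours = tree.query_ball_point(pts, r=config.local_pca_radius)
    out = np.empty(len(pts))
    for k, nb in enumerate(neighbours):
        sub = pts[nb]
        wts = weights[nb]
        mu = (sub * wts[:, None]).sum(axis=0) / wts.sum()
        centred = sub - mu
        cov = (centred * wts[:, None]).T @ centred / wts.sum()
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, -1]
        out[k] = np.degrees(np.arctan2(abs(v[0]), abs(v[1])))
    return out


def _claim_curved_ends(angle, backbone, idx, local_angles, weights, config):
    """Let a curved thin structure claim into the backbone at its ends.

    A lateral root's first few pixels overlap its parent's width; the
    end of the thin tail nearest the backbone extends into it along the
    end's own local direction, analogous to the straight-stroke claim.
    """
    pts = np.column_stack(idx).astype(float)
    if len(pts) < 4:
        return
    mu = pts.mean(axis=0)
    centred = pts - mu
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    t = centred @ vt[0]
    for pick in (np.argmin(t), np.argmax(t)):
        end = pts[pick]
        near = np.abs(t - t[pick]) <= 4.0
        if near.sum() < 2:
            continue
        inner = pts[near].mean(axis=0)
        direction = end - inner
        norm = np.hypot(*direction)
        if norm < 1e-6:
            continue
        direction = direction / norm
        theta = float(np.degrees(np.arctan2(abs(direction[0]), abs(direction[1]))))
        axis = direction
        span = (0.0, 0.0)
        _claim_over_backbone(
            angle, backbone, theta, axis, end, span, config
        )


def _claim_over_backbone(angle, backbone, theta, axis, centroid, span, config):
    """Extend a thin stroke's footprint along its axis over the backbone.

    A root hair emerges from the flank of its parent root, so part of it
    always overlaps the parent's width; without this step those base
    pixels would read the parent's orientation.
    """
    h, w = angle.shape
    t0 = span[0] - config.claim_extension
    t1 = span[1] + config.claim_extension
    hw = config.claim_halfwidth
    ends_r = (centroid[0] + t0 * axis[0], centroid[0] + t1 * axis[0])
    ends_c = (centroid[1] + t0 * axis[1], centroid[1] + t1 * axis[1])
    r0 = max(0, int(min(ends_r) - hw - 1))
    r1 = min(h, int(max(ends_r) + hw + 2))
    c0 = max(0, int(min(ends_c) - hw - 1))
    c1 = min(w, int(max(ends_c) + hw + 2))
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - centroid[0]
    cc = np.arange(c0, c1)[None, :] - centroid[1]
    t = rr * axis[0] + cc * axis[1]
    perp = -rr * axis[1] + cc * axis[0]
    inside = (t >= t0) & (t <= t1) & (np.abs(perp) <= hw)
    target = inside & backbone[r0:r1, c0:c1]
    sub = angle[r0:r1, c0:c1]
    sub[target] = theta


@dataclass(frozen=True)
class QuadrantBands:
    """Four half-open row intervals Q0 (top) .. Q3 (bottom)."""

    edges: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) != 5 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError(f"edges must be 5 strictly increasing rows, got {e}")

    @property
    def bands(self) -> list[tuple[int, int]]:
        return [(self.edges[i], self.edges[i + 1]) for i in range(4)]

    @property
    def heights(self) -> tuple[int, ...]:
        return tuple(b - a for a, b in self.bands)

    @property
    def n_rows(self) -> int:
        return self.edges[-1] - self.edges[0]


def partition_quadrants(n_rows: int) -> QuadrantBands:
    """Divide ``n_rows`` into four contiguous bands, remainder rows on top.

    Heights are floor/ceil of ``n_rows / 4``; when ``n_rows`` is not a
    multiple of 4 the extra rows go to the topmost bands so the partition
    is bit-reproducible.
    """
    if n_rows < 4:
        raise ValueError(f"need at least 4 rows to form quadrants, got {n_rows}")
    base, rem = divmod(n_rows, 4)
    heights = [base + 1 if i < rem else base for i in range(4)]
    edges = [0]
    for hgt in heights:
        edges.append(edges[-1] + hgt)
    return QuadrantBands(tuple(edges))


@dataclass
class RootTraits:
    """Quadrant-resolved probabilistic root traits of one well.

    ``q[i][j]`` is the expected root-pixel count in band ``i`` and
    orientation bin ``j``; pixels whose orientation is invalid contribute
    to ``root_mass`` (via ``invalid_mass``) but to no bin, and the
    identity ``q.sum() + invalid_mass == root_mass`` holds exactly by
    construction.
    """

    root_mass: float
    q: np.ndarray  # (4, 4) float
    invalid_mass: float

    @property
    def q0_horizontal(self) -> float:
        """Top-quadrant near-horizontal mass (root hairs and laterals)."""
        return float(self.q[0, 0])

    @property
    def q3_vertical(self) -> float:
        """Bottom-quadrant near-vertical mass (primary-root extension)."""
        return float(self.q[3, 3])

    def to_dict(self) -> dict[str, float]:
        out = {"root_mass": self.root_mass, "invalid_mass": self.invalid_mass}
        for i in range(4):
            for j in range(4):
                out[f"q{i}{j}"] = float(self.q[i, j])
        return out


def _orientation_bin(angle_deg: np.ndarray) -> np.ndarray:
    """Bin index 0-3 for angles in [0, 90]; half-open bins, last closed."""
    return np.minimum((np.nan_to_num(angle_deg) / 22.5).astype(int), 3)


def compute_root_traits(
    probability_map: np.ndarray,
    orientation: OrientationMap,
    bands: QuadrantBands,
) -> RootTraits:
    """Expected root-pixel counts per quadrant and orientation bin.

    ``root_mass`` is the total of the 16 band-by-bin partial sums plus the
    invalid-orientation mass, which equals the plain sum of the
    probability map up to floating-point regrouping.
    """
    prob = np.asarray(probability_map, dtype=float)
    if orientation.angle_deg.shape != prob.shape:
        raise ValueError("probability map and orientation map shapes differ")
    if bands.n_rows != prob.shape[0]:
        raise ValueError(
            f"bands cover {bands.n_rows} rows but map has {prob.shape[0]}"
        )
    bins = _orientation_bin(orientation.angle_deg)
    valid = orientation.valid
    q = np.zeros((4, 4))
    invalid_mass = 0.0
    for i, (r0, r1) in enumerate(bands.bands):
        p = prob[r0:r1]
        v = valid[r0:r1]
        b = bins[r0:r1]
        for j in range(4):
            q[i, j] = float(p[v & (b == j)].sum())
        invalid_mass += float(p[~v].sum())
    root_mass = float(q.sum()) + invalid_mass
    return RootTraits(root_mass=root_mass, q=q, invalid_mass=invalid_mass)


def analyze_side_well(
    well_image: np.ndarray, config: SegmentationConfig | None = None
) -> RootTraits:
    """Full per-well chain: segment, orient, partition, compute traits."""
    prob = segment_roots(well_image, config)
    orient = estimate_orientation(prob, well_image, config)
    bands = partition_quadrants(well_image.shape[0])
    return compute_root_traits(prob, orient, bands)


def traits_from_truth(rendered) -> RootTraits:
    """Reference traits computed directly from a render's truth layers.

    Serves as the independent oracle for the analysis chain: quadrant
    partition and orientation binning applied to the simulator's exact
    coverage and tangent-angle maps.
    """
    prob = rendered.truth_probability
    bands = partition_quadrants(prob.shape[0])
    return compute_root_traits(prob, rendered.truth_orientation, bands)


__all__.append("traits_from_truth")
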