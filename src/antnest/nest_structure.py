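"""Nest-morphology pipeline: registration, binarization, and structural
classification of excavated nests.

Photographs of a sand-filled 2D nest frame are registered onto a reference
view through a projective homography estimated from the frame's support
blocks, differenced against the pre-excavation image, and adaptively
thresholded into a binary excavation mask. The mask is skeletonized and cut
at junctions into branches; each branch gets a mean width (twice the mean
distance-transform value along its skeleton path) and an orientation -- the
angle of its principal axis from the horizontal, folded into [0, 90] degrees
so that 90 means aligned with gravity (straight down; image row index grows
downward). Branches are classified as chambers (wide and near-horizontal),
wide tunnels, or tunnels, and every mask pixel is assigned to its nearest
branch so that per-class areas partition the excavated area exactly.

A synthetic-mask generator rasterizes chambers (ellipses) and tunnels
(oriented thick segments) of known width/orientation with per-pixel ground
truth, to validate the segmentation end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, transform
from skimage.filters import threshold_local

TUNNEL = "tunnel"
WIDE_TUNNEL = "wide_tunnel"
CHAMBER = "chamber"
_PRIORITY = {TUNNEL: 1, WIDE_TUNNEL: 2, CHAMBER: 3}


@dataclass
class NestImage:
    """Color photograph of the nest with its physical pixel scale (cm/px)
    and optional control-point positions (row, col) of the support blocks."""

    pixels: np.ndarray  # (H, W, 3) float in [0, 1]
    pixel_scale: float
    control_points: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        self.pixels = np.asarray(self.pixels, float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) color image")
        if self.control_points is not None:
            cp = np.asarray(self.control_points, float)
            h, w = self.pixels.shape[:2]
            if np.any(cp < 0) or np.any(cp[:, 0] >= h) or np.any(cp[:, 1] >= w):
                raise ValueError("control points outside image bounds")
            self.control_points = cp


@dataclass(frozen=True)
class Homography:
    """3x3 projective matrix mapping source (row, col) to reference (row, col),
    normalized so the bottom-right entry is 1; ``rms`` is the reprojection
    root-mean-square error (px) on the fitting correspondences."""

    matrix: np.ndarray
    rms: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.matrix.T
        return out[:, :2] / out[:, 2:3]


@dataclass
class NestMask:
    """Binary excavation raster (True = excavated) with its pixel scale."""

    mask: np.ndarray
    pixel_scale: float

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        self.mask = np.asarray(self.mask, bool)

    @property
    def area_cm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_scale ** 2


@dataclass
class Branch:
    """One skeleton branch of the excavated structure."""

    branch_id: int
    path: np.ndarray  # (n, 2) ordered (row, col) skeleton pixels
    mean_width_cm: float
    orientation_deg: float
    area_cm2: float
    n_pixels: int
    cls: str | None = None


@dataclass(frozen=True)
class ClassifyConfig:
    """Width/orientation thresholds for structural classification (cm, deg).

    Widths bracket the ants' body length (0.8-1.7 cm): structures barely
    wider than an ant are tunnels, those above ~2 cm that run near-horizontal
    are chambers.
    """

    w_tunnel: float = 1.2
    w_chamber: float = 2.0
    chamber_max_orientation: float = 30.0


@dataclass(frozen=True)
class BinarizeConfig:
    block_size: int = 51     # adaptive-threshold window, px (odd)
    offset: float = 0.02     # added to the local mean before comparing
    min_area_cm2: float = 0.5


# ---------------------------------------------------------------------------
# Registration

def estimate_homography(src, dst) -> Homography:
    """Least-squares projective transform from >= 4 point correspondences.

    Points are (row, col); the solution is the coordinate-normalized DLT.
    Degenerate (e.g. collinear) configurations are rejected.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (n, 2) arrays")
    if len(src) < 4:
        raise ValueError("need at least 4 correspondences")
    # skimage transforms use (x, y) = (col, row)
    if hasattr(transform.ProjectiveTransform, "from_estimate"):
        tf = transform.ProjectiveTransform.from_estimate(src[:, ::-1], dst[:, ::-1])
        ok = bool(tf)
    else:  # older scikit-image
        tf = transform.ProjectiveTransform()
        ok = tf.estimate(src[:, ::-1], dst[:, ::-1])
    if not ok or not np.all(np.isfinite(tf.params)):
        raise ValueError("degenerate correspondences (collinear points?)")
    m_xy = tf.params
    if abs(m_xy[2, 2]) < 1e-12:
        raise ValueError("degenerate homography")
    # permute to (row, col) convention: swap axes 0<->1 in both input/output
    perm = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], float)
    m = perm @ m_xy @ perm
    m = m / m[2, 2]
    h = Homography(matrix=m)
    resid = h.apply(src) - dst
    return Homography(matrix=m, rms=float(np.sqrt(np.mean(resid ** 2) * 2)))


def register(image: NestImage, h: Homography) -> NestImage:
    """Warp ``image`` onto the reference frame (inverse-mapped bilinear)."""
    perm = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], float)
    tf = transform.ProjectiveTransform(matrix=perm @ h.matrix @ perm)
    warped = transform.warp(image.pixels, tf.inverse, order=1,
                            mode="constant", cval=0.0, preserve_range=True)
    return NestImage(warped, image.pixel_scale, None)


# ---------------------------------------------------------------------------
# Binarization and area

def binarize(current: NestImage, initial: NestImage,
             cfg: BinarizeConfig = BinarizeConfig()) -> NestMask:
    """Excavation mask from a registered image pair.

    Difference (current - initial, clipped at 0; excavated regions brighten
    against the backlight), intensity as the per-pixel max of the green and
    blue channels, adaptive local-mean threshold, then removal of specks
    smaller than ``min_area_cm2``.
    """
    if current.pixels.shape != initial.pixels.shape:
        raise ValueError("image pair must share one geometry")
    diff = np.clip(current.pixels - initial.pixels, 0.0, None)
    intensity = np.maximum(diff[..., 1], diff[..., 2])
    if intensity.max() == 0:
        return NestMask(np.zeros(intensity.shape, bool), current.pixel_scale)
    local = threshold_local(intensity, block_size=cfg.block_size,
                            method="mean", offset=-cfg.offset)
    mask = intensity > local
    min_px = max(1, int(round(cfg.min_area_cm2 / current.pixel_scale ** 2)))
    try:
        mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
    except TypeError:  # scikit-image < 0.26
        mask = morphology.remove_small_objects(mask, min_size=min_px)
    return NestMask(mask, current.pixel_scale)


def area_cm2(mask: NestMask) -> float:
    """Excavated area: white-pixel count times the squared pixel scale."""
    return mask.area_cm2


# ---------------------------------------------------------------------------
# Skeletonization and segmentation

def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def _order_path(coords: np.ndarray) -> np.ndarray:
    """Order skeleton pixels along the branch's principal axis."""
    if len(coords) < 3:
        return coords
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    return coords[np.argsort(proj)]


def branch_orientation(path: np.ndarray) -> float:
    """Angle of the path's principal axis from horizontal, in [0, 90] deg.

    0 = horizontal, 90 = aligned with gravity (down the image). Folding into
    [0, 90] makes the measure invariant to left-right mirroring.
    """
    path = np.asarray(path, float)
    if len(path) < 2:
        raise ValueError("orientation undefined for a single-pixel branch")
    centered = path - path.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    drow, dcol = vt[0]
    return float(np.degrees(np.arctan2(abs(drow), abs(dcol))))


def skeletonize_and_segment(mask: NestMask,
                            min_branch_cm: float = 1.0) -> list[Branch]:
    """Decompose the mask into skeleton branches.

    Morphological thinning to a 1-px skeleton; junction pixels (>= 3 skeleton
    neighbors) are removed to split branches; branches shorter than
    ``min_branch_cm`` are merged into the longest adjacent branch; every mask
    pixel is then assigned to the nearest branch, so per-branch areas
    partition the mask area exactly.
    """
    m = mask.mask
    if not m.any():
        return []
    scale = mask.pixel_scale
    skel = morphology.skeletonize(m)
    edt = ndimage.distance_transform_edt(m)
    counts = _neighbor_counts(skel)
    branch_px = skel & (counts < 3)
    labels = measure.label(branch_px, connectivity=2)
    if labels.max() == 0:
        # degenerate blob: the whole skeleton is one branch
        labels = measure.label(skel, connectivity=2)

    # merge sub-threshold fragments into their longest neighbor
    min_px = max(2, int(round(min_branch_cm / scale)))
    sizes = np.bincount(labels.ravel())
    order = np.argsort(sizes[1:])  # smallest fragments first
    for lab in (order + 1):
        if sizes[lab] == 0 or sizes[lab] >= min_px:
            continue
        region = labels == lab
        ring = ndimage.binary_dilation(region, np.ones((3, 3)), iterations=2)
        neigh = np.unique(labels[ring & (labels != lab) & (labels > 0)])
        if neigh.size:
            target = int(neigh[np.argmax(sizes[neigh])])
            labels[region] = target
            sizes[target] += sizes[lab]
            sizes[lab] = 0

    # assign junction pixels and then all mask pixels to the nearest branch
    have = labels > 0
    _, (ir, ic) = ndimage.distance_transform_edt(~have, return_indices=True)
    full = np.where(m, labels[ir, ic], 0)

    branches: list[Branch] = []
    for new_id, lab in enumerate(np.unique(labels[labels > 0]), start=1):
        coords = np.column_stack(np.nonzero(labels == lab))
        path = _order_path(coords)
        width = 2.0 * float(edt[coords[:, 0], coords[:, 1]].mean()) * scale
        if len(path) >= 2:
            orient = branch_orientation(path)
        else:
            orient = 0.0  # degenerate blob: treat as flat
        npix = int((full == lab).sum())
        branches.append(Branch(branch_id=new_id, path=path,
                               mean_width_cm=width, orientation_deg=orient,
                               area_cm2=npix * scale ** 2, n_pixels=npix))
    return branches


def classify(branches: list[Branch],
             cfg: ClassifyConfig = ClassifyConfig()) -> list[Branch]:
    """Label branches: chamber = wide and near-horizontal; wide tunnel =
    intermediate width; tunnel = the rest. Returns the same list, labeled."""
    for b in branches:
        if b.mean_width_cm >= cfg.w_chamber and \
                b.orientation_deg <= cfg.chamber_max_orientation:
            b.cls = CHAMBER
        elif cfg.w_tunnel < b.mean_width_cm < cfg.w_chamber:
            b.cls = WIDE_TUNNEL
        else:
            b.cls = TUNNEL
    return branches


@dataclass
class OrientationHistogram:
    """Area-weighted orientation distribution of one structural class over
    10-degree bins spanning [0, 90]."""

    cls: str
    bin_edges: np.ndarray
    fractions: np.ndarray
    total_area_cm2: float

    @property
    def empty(self) -> bool:
        return self.total_area_cm2 == 0

    def modal_bin(self) -> tuple[float, float]:
        i = int(np.argmax(self.fractions))
        return float(self.bin_edges[i]), float(self.bin_edges[i + 1])


def orientation_histogram(branches: list[Branch], cls: str,
                          weight: str = "area") -> OrientationHistogram:
    """Distribution of branch orientations for one class, weighted by branch
    area (default) or branch count."""
    edges = np.arange(0.0, 100.0, 10.0)
    sel = [b for b in branches if b.cls == cls]
    if not sel:
        return OrientationHistogram(cls, edges, np.zeros(9), 0.0)
    angles = np.array([b.orientation_deg for b in sel])
    w = np.array([b.area_cm2 for b in sel]) if weight == "area" else np.ones(len(sel))
    hist, _ = np.histogram(angles, bins=edges, weights=w)
    return OrientationHistogram(cls, edges, hist / hist.sum(),
                                float(sum(b.area_cm2 for b in sel)))


# ---------------------------------------------------------------------------
# Synthetic nest masks with ground truth

@dataclass(frozen=True)
class NestPrimitive:
    """One synthetic structure: a chamber (ellipse with axes length x width)
    or a tunnel / wide tunnel (thick segment), placed at ``center_cm``
    (row, col from the canvas top-left), oriented ``orientation_deg`` from
    horizontal."""

    cls: str
    center_cm: tuple[float, float]
    orientation_deg: float
    width_cm: float
    length_cm: float


@dataclass
class SynthNestSpec:
    primitives: list[NestPrimitive]
    canvas_cm: tuple[float, float] = (40.0, 30.0)  # (height, width)
    pixel_scale: float = 0.1

    def __post_init__(self) -> None:
        h, w = self.canvas_cm
        for p in self.primitives:
            r, c = p.center_cm
            if not (0 <= r <= h and 0 <= c <= w):
                raise ValueError(f"primitive center {p.center_cm} outside canvas")


@dataclass
class GroundTruth:
    class_map: np.ndarray       # 0 = background, else _PRIORITY codes
    orientation_map: np.ndarray  # degrees; NaN on background

    def cls_of(self, code: int) -> str:
        return {1: TUNNEL, 2: WIDE_TUNNEL, 3: CHAMBER}[code]


def synth_nest_mask(spec: SynthNestSpec, seed: int | None = None,
                    edge_noise: float = 0.0) -> tuple[NestMask, GroundTruth]:
    """Rasterize a synthetic nest with per-pixel ground truth.

    Chambers are ellipses (axes length x width), tunnels thick segments.
    Overlaps resolve by priority chamber > wide tunnel > tunnel. Optional
    ``edge_noise`` jitters the boundary by flipping pixels within 1 px of it
    with that probability.
    """
    scale = spec.pixel_scale
    h = int(round(spec.canvas_cm[0] / scale))
    w = int(round(spec.canvas_cm[1] / scale))
    rr, cc = np.mgrid[0:h, 0:w]
    class_map = np.zeros((h, w), np.int8)
    orient_map = np.full((h, w), np.nan)

    for prim in sorted(spec.primitives, key=lambda p: _PRIORITY[p.cls]):
        r0 = prim.center_cm[0] / scale
        c0 = prim.center_cm[1] / scale
        th = np.radians(prim.orientation_deg)
        # axis u along the structure (down-positive rows), v across
        dr, dc = np.sin(th), np.cos(th)
        u = (rr - r0) * dr + (cc - c0) * dc
        v = -(rr - r0) * dc + (cc - c0) * dr
        half_len = 0.5 * prim.length_cm / scale
        half_wid = 0.5 * prim.width_cm / scale
        if prim.cls == CHAMBER:
            inside = (u / half_len) ** 2 + (v / half_wid) ** 2 <= 1.0
        else:
            du = np.maximum(np.abs(u) - half_len, 0.0)
            inside = du ** 2 + v ** 2 <= half_wid ** 2
        code = _PRIORITY[prim.cls]
        take = inside & (class_map < code)
        class_map[take] = code
        orient_map[take] = prim.orientation_deg % 180
        # fold to [0, 90]
        orient_map[take] = np.minimum(orient_map[take], 180 - orient_map[take])

    mask = class_map > 0
    if edge_noise > 0:
        rng = np.random.default_rng(seed)
        boundary = mask ^ ndimage.binary_erosion(mask)
        boundary |= ndimage.binary_dilation(mask) ^ mask
        flip = boundary & (rng.random(mask.shape) < edge_noise)
        mask = mask ^ flip
        class_map = np.where(mask & (class_map == 0), 1, class_map)
        class_map = np.where(~mask, 0, class_map)
    return NestMask(mask, scale), GroundTruth(class_map, orient_map)


def segmentation_accuracy(branches: list[Branch], mask: NestMask,
                          truth: GroundTruth) -> dict[str, float]:
    """Pixel-class accuracy and per-branch orientation MAE vs ground truth."""
    scale = mask.pixel_scale
    pred = np.zeros(mask.mask.shape, np.int8)
    have = np.zeros(mask.mask.shape, bool)
    # rebuild the pixel assignment (nearest branch skeleton pixel)
    label_img = np.zeros(mask.mask.shape, int)
    for b in branches:
        label_img[b.path[:, 0], b.path[:, 1]] = b.branch_id
    _, (ir, ic) = ndimage.distance_transform_edt(label_img == 0, return_indices=True)
    nearest = label_img[ir, ic]
    code = {b.branch_id: _PRIORITY[b.cls] for b in branches}
    for b in branches:
        sel = mask.mask & (nearest == b.branch_id)
        pred[sel] = code[b.branch_id]
        have |= sel
    inside = mask.mask & (truth.class_map > 0)
    acc = float((pred[inside] == truth.class_map[inside]).mean()) if inside.any() else 1.0

    errs = []
    for b in branches:
        true_or = truth.orientation_map[b.path[:, 0], b.path[:, 1]]
        true_or = true_or[np.isfinite(true_or)]
        if true_or.size:
            t = float(np.median(true_or))
            errs.append(abs(b.orientation_deg - t))
    mae = float(np.mean(errs)) if errs else 0.0
    return {"pixel_accuracy": acc, "orientation_mae_deg": mae}


# ---------------------------------------------------------------------------
# IO

def write_mask_png(mask: NestMask, path, sidecar: bool = True) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (mask.mask.astype(np.uint8) * 255))
    if sidecar:
        with open(str(path) + ".json", "w") as fh:
            json.dump({"pixel_scale_cm_per_px": mask.pixel_scale}, fh)


def read_mask_png(path, pixel_scale: float | None = None) -> NestMask:
    import imageio.v3 as iio

    if pixel_scale is None:
        try:
            with open(str(path) + ".json") as fh:
                pixel_scale = float(json.load(fh)["pixel_scale_cm_per_px"])
        except FileNotFoundError as err:
            raise ValueError(f"no pixel scale given and no sidecar for {path}") from err
    arr = iio.imread(str(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return NestMask(arr > 127, pixel_scale)


def branches_to_frame(branches: list[Branch]):
    import pandas as pd

    return pd.DataFrame(
        {
            "branch_id": [b.branch_id for b in branches],
            "class": [b.cls for b in branches],
            "mean_width_cm": [b.mean_width_cm for b in branches],
            "orientation_deg": [b.orientation_deg for b in branches],
            "area_cm2": [b.area_cm2 for b in branches],
        }
    )
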