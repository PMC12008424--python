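"""Candidate anchor-point extraction ``P_e`` from grayscale images.

Three extractors cover the registration scenarios:

* :func:`detect_dark_keypoints` — sub-pixel centres of dark blobs (corner
  holes in scanning-probe images), optionally keeping only points whose
  smoothed intensity lies below the image mean.
* :func:`detect_square_corners` — Gaussian blur, Otsu binarisation and a
  minimum-area rectangle fit for bright/dark device outlines.
* :func:`classify_sites` — per-site intensity sampling to label projected
  sub-feature positions as present (adatom) or absent (defect).

Images are 2D float arrays; intensities are treated as arbitrary but
consistent units (the io module normalises file input to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import blob_dog, peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from shapely.geometry import MultiPoint

from .errors import DetectionFailureError, InvalidParameterError

__all__ = [
    "DetectionConfig",
    "SiteLabel",
    "SquareDetection",
    "detect_dark_keypoints",
    "detect_square_corners",
    "classify_sites",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Configuration of the keypoint / corner extractors.

    Attributes
    ----------
    blur_sigma : Gaussian smoothing width in pixels (default 1.0)
    intensity_filter : "below_mean", "above_mean" or "none" — retain only
        detections whose blurred intensity is on the stated side of the
        global mean
    min_separation : minimum distance between detections in pixels; of two
        conflicting detections the darker one is kept
    detector : "blob" (single-scale local extrema of the blurred image) or
        "sift_like" (multi-scale difference-of-Gaussian extrema)
    min_depth_frac : minimum blob depth as a fraction of the image's
        mean-to-minimum range, rejects noise extrema (default 0.25)
    min_area_frac : minimum foreground area fraction for the square detector
    """

    blur_sigma: float = 1.0
    intensity_filter: str = "below_mean"
    min_separation: float = 5.0
    detector: str = "blob"
    min_depth_frac: float = 0.25
    min_area_frac: float = 0.01
    refine_radius: int | None = None  # auto: ~0.45 * min_separation in [3, 8]

    def __post_init__(self):
        if self.blur_sigma < 0:
            raise InvalidParameterError("blur_sigma must be >= 0")
        if self.min_separation < 0:
            raise InvalidParameterError("min_separation must be >= 0")
        if self.intensity_filter not in ("below_mean", "above_mean", "none"):
            raise InvalidParameterError(
                f"unknown intensity_filter {self.intensity_filter!r}"
            )
        if self.detector not in ("blob", "sift_like"):
            raise InvalidParameterError(f"unknown detector {self.detector!r}")


@dataclass(frozen=True)
class SiteLabel:
    """Classification of one projected sub-feature site."""

    index: int
    label: str  # "present" | "absent"
    intensity: float


@dataclass(frozen=True)
class SquareDetection:
    """Corners of the fitted quadrilateral plus its centroid."""

    corners: np.ndarray  # (4, 2) canonical order
    centroid: np.ndarray  # (2,)


def _check_image(img) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise InvalidParameterError("image must be a nonempty 2D array")
    return a


def _subpixel_refine(sm: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Quadratic (parabolic) sub-pixel refinement of integer extrema of the
    *inverted* smoothed image; peaks are (row, col) minima of sm."""
    out = []
    rows, cols = sm.shape
    for r, c in peaks:
        dr = dc = 0.0
        if 0 < r < rows - 1:
            num = sm[r - 1, c] - sm[r + 1, c]
            den = sm[r - 1, c] - 2 * sm[r, c] + sm[r + 1, c]
            if den > 1e-15:
                dr = float(np.clip(0.5 * num / den, -1.0, 1.0))
        if 0 < c < cols - 1:
            num = sm[r, c - 1] - sm[r, c + 1]
            den = sm[r, c - 1] - 2 * sm[r, c] + sm[r, c + 1]
            if den > 1e-15:
                dc = float(np.clip(0.5 * num / den, -1.0, 1.0))
        out.append((c + dc, r + dr))
    return np.asarray(out, dtype=float).reshape(-1, 2)


def _weighted_centroid_refine(
    sm: np.ndarray, pts: np.ndarray, rad: int, iters: int = 5
) -> np.ndarray:
    """Iterative Gaussian-weighted depth centroid; removes the small
    systematic bias of the parabolic estimate for smooth symmetric wells.
    Points whose window would leave the image keep their parabolic value."""
    rows, cols = sm.shape
    sigma = rad / 2.5
    out = pts.copy()
    for i, (x0, y0) in enumerate(pts):
        x, y = x0, y0
        ok = True
        for _ in range(iters):
            r0, r1 = int(round(y)) - rad, int(round(y)) + rad + 1
            c0, c1 = int(round(x)) - rad, int(round(x)) + rad + 1
            if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
                ok = False
                break
            patch = sm[r0:r1, c0:c1]
            py, px = np.mgrid[r0:r1, c0:c1]
            depth = np.clip(patch.max() - patch, 0.0, None)
            w = depth * np.exp(-((px - x) ** 2 + (py - y) ** 2) / (2.0 * sigma**2))
            tot = w.sum()
            if tot <= 0:
                ok = False
                break
            x = float((w * px).sum() / tot)
            y = float((w * py).sum() / tot)
        if ok and np.hypot(x - x0, y - y0) <= 1.5:
            out[i] = (x, y)
    return out


def _enforce_separation(
    pts: np.ndarray, darkness: np.ndarray, min_sep: float
) -> np.ndarray:
    """Greedy non-maximum suppression: keep the darker of any pair closer
    than min_sep."""
    if len(pts) == 0 or min_sep <= 0:
        return np.arange(len(pts))
    order = np.argsort(-darkness)  # darkest (largest depth) first
    kept: list[int] = []
    for idx in order:
        ok = True
        for k in kept:
            if np.hypot(*(pts[idx] - pts[k])) < min_sep:
                ok = False
                break
        if ok:
            kept.append(idx)
    return np.sort(np.asarray(kept, dtype=int))


def detect_dark_keypoints(img, cfg: DetectionConfig = DetectionConfig()) -> np.ndarray:
    """Sub-pixel centres of dark blobs, as an (N, 2) array of (x, y).

    The image is Gaussian-smoothed with ``cfg.blur_sigma``; candidate centres
    are local minima (single-scale) or multi-scale difference-of-Gaussian
    extrema of the inverted image ("sift_like").  Candidates shallower than
    ``min_depth_frac`` of the mean-to-minimum range are rejected, the
    ``below_mean`` filter removes candidates at or above the global mean of
    the smoothed image, and ``min_separation`` is enforced by keeping the
    darker of any conflicting pair.  An empty result is valid.
    """
    a = _check_image(img)
    sm = ndimage.gaussian_filter(a, cfg.blur_sigma) if cfg.blur_sigma > 0 else a
    mean = float(sm.mean())
    depth_range = mean - float(sm.min())
    if depth_range <= 0:
        return np.empty((0, 2))

    if cfg.detector == "sift_like":
        blobs = blob_dog(
            sm.max() - sm,
            min_sigma=max(cfg.blur_sigma, 1.0),
            max_sigma=4.0 * max(cfg.blur_sigma, 1.0),
            threshold=0.05 * depth_range,
        )
        peaks = np.round(blobs[:, :2]).astype(int) if len(blobs) else np.empty((0, 2), int)
        peaks = np.unique(peaks, axis=0) if len(peaks) else peaks
    else:
        peaks = peak_local_max(
            sm.max() - sm, min_distance=1, exclude_border=False
        )

    if len(peaks) == 0:
        return np.empty((0, 2))

    vals = sm[peaks[:, 0], peaks[:, 1]]
    keep = (mean - vals) >= cfg.min_depth_frac * depth_range
    if cfg.intensity_filter == "below_mean":
        keep &= vals < mean
    elif cfg.intensity_filter == "above_mean":
        keep &= vals > mean
    peaks, vals = peaks[keep], vals[keep]
    if len(peaks) == 0:
        return np.empty((0, 2))

    pts = _subpixel_refine(sm, peaks)
    rad = cfg.refine_radius
    if rad is None:
        rad = int(np.clip(round(0.45 * cfg.min_separation), 3, 8))
    pts = _weighted_centroid_refine(sm, pts, rad)
    kept = _enforce_separation(pts, mean - vals, cfg.min_separation)
    return pts[kept]


def _canonical_corners(corners: np.ndarray) -> np.ndarray:
    """Counterclockwise order starting with the corner nearest the image
    origin (top-left)."""
    c = corners.mean(axis=0)
    ang = np.arctan2(corners[:, 1] - c[1], corners[:, 0] - c[0])
    order = np.argsort(ang)
    corners = corners[order]
    start = int(np.argmin(np.hypot(corners[:, 0], corners[:, 1])))
    return np.roll(corners, -start, axis=0)


def detect_square_corners(
    img, cfg: DetectionConfig = DetectionConfig()
) -> SquareDetection:
    """Detect the dominant quadrilateral region and return its 4 corners.

    Pipeline: Gaussian blur -> Otsu binarisation (foreground = the side
    occupying less than half the image) -> largest connected component ->
    minimum-area rotated rectangle of the component's convex hull.  The
    component centroid is returned alongside the corners.
    """
    a = _check_image(img)
    sm = ndimage.gaussian_filter(a, cfg.blur_sigma) if cfg.blur_sigma > 0 else a
    if np.ptp(sm) < 1e-12:
        raise DetectionFailureError("flat image: no structure to segment")
    # Otsu initialisation, then intermeans refinement: places the boundary at
    # the half-maximum of the blurred edge, i.e. on the true region outline
    t = float(threshold_otsu(sm))
    for _ in range(10):
        hi, lo = sm[sm > t], sm[sm <= t]
        if hi.size == 0 or lo.size == 0:
            break
        t_new = 0.5 * (float(hi.mean()) + float(lo.mean()))
        if abs(t_new - t) < 1e-9:
            break
        t = t_new
    fg = sm > t
    if fg.mean() > 0.5:
        fg = ~fg
    lab = cc_label(fg)
    if lab.max() == 0:
        raise DetectionFailureError("no foreground component found")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    comp = lab == int(np.argmax(sizes))
    if comp.sum() < cfg.min_area_frac * a.size:
        raise DetectionFailureError(
            f"largest component covers {comp.sum() / a.size:.4f} of the image, "
            f"below min_area_frac={cfg.min_area_frac}"
        )
    rr, cc = np.nonzero(comp)
    pix = MultiPoint(np.column_stack([cc, rr]).astype(float))
    # grow the pixel-centre hull by half a pixel so corners sit on the true
    # region boundary rather than on the outermost pixel centres
    hull = pix.convex_hull.buffer(0.5, join_style="mitre")
    rect = hull.minimum_rotated_rectangle
    corners = np.asarray(rect.exterior.coords)[:4]
    centroid = np.array([cc.mean(), rr.mean()])
    return SquareDetection(corners=_canonical_corners(corners), centroid=centroid)


def classify_sites(
    img,
    pts,
    window: int = 2,
    threshold: float | None = None,
) -> list[SiteLabel]:
    """Label each site as present/absent from local mean intensity.

    For every point, the mean intensity of the ``(2*window+1)^2`` patch
    centred on the rounded position is sampled.  A site is ``present`` when
    its sample is at or above the classification threshold.

    The default threshold adapts to the sample distribution.  When the
    sample spread exceeds a noise floor (eight robust image-noise standard
    deviations scaled by the patch averaging), the samples are bimodal and
    the threshold is the midpoint of their extremes.  Otherwise all sites
    share one label: ``present`` when the median sample is at or above the
    image median plus half the floor (so a constant image is
    deterministically all-``present``), ``absent`` when the sites sit at the
    background level.  An unbalanced population (a single defect among many
    adatoms, or vice versa) is classified correctly either way; a fixed
    ``threshold`` can always be supplied instead.
    """
    a = _check_image(img)
    p = np.asarray(pts, dtype=float).reshape(-1, 2)
    rows, cols = a.shape
    samples = []
    for i, (x, y) in enumerate(p):
        r, c = int(round(y)), int(round(x))
        if not (0 <= r < rows and 0 <= c < cols):
            raise InvalidParameterError(
                f"point {i} at ({x:.2f}, {y:.2f}) lies outside the image"
            )
        r0, r1 = max(0, r - window), min(rows, r + window + 1)
        c0, c1 = max(0, c - window), min(cols, c + window + 1)
        samples.append(float(a[r0:r1, c0:c1].mean()))
    samples = np.asarray(samples)
    if threshold is None:
        img_median = float(np.median(a))
        sigma = 1.4826 * float(np.median(np.abs(a - img_median)))
        floor = 8.0 * sigma / (2 * window + 1)
        spread = float(samples.max() - samples.min())
        if spread > floor and spread > 0:
            threshold = 0.5 * (samples.min() + samples.max())
        elif float(np.median(samples)) >= img_median + 0.5 * floor:
            threshold = -np.inf  # uniform bright population: all present
        else:
            threshold = np.inf  # uniform background population: all absent
    return [
        SiteLabel(index=i, label="present" if s >= threshold else "absent", intensity=s)
        for i, s in enumerate(samples)
    ]
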