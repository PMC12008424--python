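"""End-to-end registration workflows: register, rectify, sub-feature
localisation and unit-cell encoding, cross-frame cell matching, and
registered-image comparison (difference maps, line profiles).

The registration chain follows the two-stage design: extraction (optional)
-> vote filtering (lattice models) -> brute-force affine placement ->
nearest-neighbour pairing -> LMedS homography estimation -> reconstruction
``P_t = A^{-1} (x) H^{-1} (x) P_e`` and accuracy metrics against the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from . import transforms
from .anchor_models import AnchorModel, UnitCellTemplate, project_subfeatures
from .errors import (
    AnchorRegError,
    InsufficientDataError,
    InvalidParameterError,
    PlacementFailureError,
)
from .estimation import (
    EstimationResult,
    LmedsConfig,
    estimate_homography_lmeds,
    reconstruct_points,
)
from .extraction import (
    DetectionConfig,
    classify_sites,
    detect_dark_keypoints,
    detect_square_corners,
)
from .matching import PairSet, VoteConfig, place_model, vote_filter
from .transforms import AffineParams, TransformMatrix
from .validation import MetricConfig, mae as _mae, oks as _oks

logger = logging.getLogger("anchorreg")

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "CellFeature",
    "register",
    "rectify",
    "localize_and_encode",
    "match_frames",
    "difference_map",
    "line_profile",
]


@dataclass(frozen=True)
class RegistrationConfig:
    """Knobs of the end-to-end registration chain.

    ``affine`` fixes the prior-knowledge parameters (pixel scale from the
    model's inter-structure distance, rotation from the experimental setup);
    its translation is ignored and optimised by brute force.  ``gate`` is
    the pairing distance gate (default 0.35 of the placed unit length); on a
    first failure the placement is retried once with the gate widened x1.5.
    """

    affine: AffineParams = field(default_factory=AffineParams)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    use_vote: bool | None = None  # default: lattice models only
    vote_radius: float | None = None
    gate: float | None = None
    grid_steps: int = 50
    lmeds: LmedsConfig = field(default_factory=LmedsConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of one registration.

    ``P_t`` holds the paired extracted points reconstructed into model
    units, in pair order; ``mae``/``oks`` compare them against the paired
    model anchor points.  ``status`` is "ok", "degraded" (the pairing gate
    had to be relaxed) or "failed" (with ``reason``).
    """

    status: str
    affine: AffineParams | None = None
    A: TransformMatrix | None = None
    H: TransformMatrix | None = None
    pairs: PairSet | None = None
    estimation: EstimationResult | None = None
    P_e_used: np.ndarray | None = None
    P_t: np.ndarray | None = None
    mae: float | None = None
    oks: float | None = None
    reason: str | None = None
    model: AnchorModel | None = None

    def to_dict(self) -> dict:
        d = {"status": self.status, "mae": self.mae, "oks": self.oks}
        if self.reason:
            d["reason"] = self.reason
        if self.affine is not None:
            d["affine"] = self.affine.__dict__
        if self.H is not None:
            d["H"] = self.H.to_dict()
        if self.pairs is not None:
            d["pairs"] = self.pairs.to_dict()
        if self.P_t is not None:
            d["P_t"] = self.P_t.tolist()
        return d


def register(
    source,
    model: AnchorModel,
    cfg: RegistrationConfig = RegistrationConfig(),
) -> RegistrationResult:
    """Register an image or extracted point set against an anchor model.

    ``source`` is either a 2D grayscale image (dark keypoints are extracted
    with ``cfg.detection``) or an (N, 2) array of extracted points ``P_e``
    already in the image frame.
    """
    src = np.asarray(source, dtype=float)
    if src.ndim == 2 and src.shape[1] == 2:
        P_e = src
    elif src.ndim == 2:
        if model.is_lattice:
            P_e = detect_dark_keypoints(src, cfg.detection)
        else:
            # device-outline models: corners of the dominant quadrilateral
            P_e = detect_square_corners(src, cfg.detection).corners
    else:
        raise InvalidParameterError("source must be an image or an (N,2) point set")
    if len(P_e) == 0:
        return RegistrationResult(status="failed", reason="no extracted points")

    use_vote = model.is_lattice if cfg.use_vote is None else cfg.use_vote
    A_mat = transforms.compose_affine(cfg.affine.replace(x_0=0.0, y_0=0.0))
    scale = float(np.sqrt(abs(np.linalg.det(A_mat.m[:2, :2]))))
    L_img = model.unit_length * scale
    if use_vote:
        vcfg = VoteConfig(unit_length=L_img, radius=cfg.vote_radius)
        P_e = vote_filter(P_e, vcfg).kept
        if len(P_e) == 0:
            return RegistrationResult(
                status="failed", reason="vote filter removed every point"
            )

    gate = cfg.gate if cfg.gate is not None else 0.35 * L_img
    status = "ok"
    try:
        rough = place_model(
            model, cfg.affine, P_e, steps=cfg.grid_steps, gate=gate
        )
        if len(rough.pairs) < 4:
            raise InsufficientDataError("fewer than 4 pairs")
    except (PlacementFailureError, InsufficientDataError):
        logger.info("placement with gate %.3g failed; retrying with gate x1.5", gate)
        try:
            rough = place_model(
                model, cfg.affine, P_e, steps=cfg.grid_steps, gate=1.5 * gate
            )
        except PlacementFailureError as err:
            return RegistrationResult(status="failed", reason=str(err))
        status = "degraded"

    pairs = rough.pairs
    if len(pairs) < 4:
        return RegistrationResult(
            status="failed",
            reason=f"only {len(pairs)} pairs survived the relaxed gate",
        )
    A = transforms.compose_affine(rough.affine)
    src_pts = rough.placed_model[pairs.model_indices]
    dst_pts = P_e[pairs.extracted_indices]
    try:
        est = estimate_homography_lmeds(src_pts, dst_pts, cfg.lmeds)
    except AnchorRegError as err:
        return RegistrationResult(status="failed", reason=f"estimation failed: {err}")
    P_t = reconstruct_points(A, est.H, dst_pts)
    model_pts = model.points[pairs.model_indices]
    return RegistrationResult(
        status=status,
        affine=rough.affine,
        A=A,
        H=est.H,
        pairs=pairs,
        estimation=est,
        P_e_used=P_e,
        P_t=P_t,
        mae=_mae(P_t, model_pts),
        oks=_oks(P_t, model_pts, cfg.metric),
        model=model,
    )


def rectify(
    img,
    result: RegistrationResult,
    pixels_per_unit: float,
    margin: float = 0.0,
    out_shape: tuple[int, int] | None = None,
    fill: float = 0.0,
) -> np.ndarray:
    """Warp a registered image to its absolute-scale, undistorted geometry.

    The composite map sends image coordinates through ``(H A)^{-1}`` into
    model units, then scales by ``pixels_per_unit`` (shifting the model's
    bounding-box minimum to ``margin``), so anchor positions land on exact
    pixel coordinates spaced ``pixels_per_unit`` apart.
    """
    if result.status == "failed":
        raise InvalidParameterError("cannot rectify a failed registration")
    model = result.model
    mins = model.points.min(axis=0)
    K = np.array(
        [
            [pixels_per_unit, 0.0, margin - pixels_per_unit * mins[0]],
            [0.0, pixels_per_unit, margin - pixels_per_unit * mins[1]],
            [0.0, 0.0, 1.0],
        ]
    )
    HA = result.H.m @ result.A.m
    T = TransformMatrix(K @ np.linalg.inv(HA), kind="homography")
    if out_shape is None:
        span = np.ptp(model.points, axis=0)
        out_shape = (
            int(np.ceil(span[1] * pixels_per_unit + 2 * margin)) + 1,
            int(np.ceil(span[0] * pixels_per_unit + 2 * margin)) + 1,
        )
    return transforms.warp_image(img, T, out_shape=out_shape, fill=fill)


@dataclass(frozen=True)
class CellFeature:
    """Binary sub-feature encoding of one unit cell.

    ``vector`` has one element per template sub-feature in template order:
    1 = present (adatom), 0 = absent (defect).
    """

    cell_id: tuple[int, int]
    vector: tuple[int, ...]
    anchor_image_pos: np.ndarray

    def to_dict(self) -> dict:
        return {
            "cell_id": list(self.cell_id),
            "vector": list(self.vector),
            "anchor_image_pos": [float(v) for v in self.anchor_image_pos],
        }


def localize_and_encode(
    img,
    result: RegistrationResult,
    template: UnitCellTemplate,
    model: AnchorModel | None = None,
    window: int = 2,
    threshold: float | None = None,
) -> list[CellFeature]:
    """Project template sub-features into the image for every complete unit
    cell whose anchors were matched, classify each site from pixel values,
    and emit binary feature vectors in template order.

    Cells with any projected sub-feature outside the image are skipped (and
    logged), not extrapolated.
    """
    if result.status == "failed":
        raise InvalidParameterError("registration failed; nothing to localize")
    model = model if model is not None else result.model
    if not model.is_lattice:
        raise InvalidParameterError("unit-cell encoding requires a lattice model")
    a = np.asarray(img, dtype=float)
    rows, cols = a.shape
    L = model.unit_length
    b = model.lattice_basis
    nrows, ncols = model.lattice_shape
    idx = model.lattice_indices()
    matched = set(int(m) for m in result.pairs.model_indices)
    # anchor lattice index -> flat model index
    flat = {tuple(ij): k for k, ij in enumerate(idx)}
    anchor_cells_idx = np.round(
        template.cell_anchor_offsets @ np.linalg.inv(b)
    ).astype(int)

    admissible: list[tuple[tuple[int, int], np.ndarray, np.ndarray]] = []
    for i in range(nrows):
        for j in range(ncols):
            need = [(i + di, j + dj) for di, dj in anchor_cells_idx]
            if not all(t in flat for t in need):
                continue
            if not all(flat[t] in matched for t in need):
                logger.debug("cell (%d,%d): unmatched anchor, skipped", i, j)
                continue
            origin = L * (i * b[0] + j * b[1])
            pts = project_subfeatures(template, result.A, result.H, origin, L)
            if (
                pts[:, 0].min() < 0
                or pts[:, 1].min() < 0
                or pts[:, 0].max() > cols - 1
                or pts[:, 1].max() > rows - 1
            ):
                logger.debug("cell (%d,%d): sub-feature outside image, skipped", i, j)
                continue
            anchor_img = transforms.apply_transform(
                result.H, transforms.apply_transform(result.A, origin[None, :])
            )[0]
            admissible.append(((i, j), pts, anchor_img))
    if not admissible:
        return []
    # classify every site of every cell in one pass so the default threshold
    # (midpoint of robust percentiles) is global, not per cell
    all_pts = np.vstack([pts for _, pts, _ in admissible])
    labels = classify_sites(a, all_pts, window=window, threshold=threshold)
    out: list[CellFeature] = []
    k = 0
    for cell_id, pts, anchor_img in admissible:
        vec = tuple(
            1 if labels[k + s].label == "present" else 0 for s in range(len(pts))
        )
        k += len(pts)
        out.append(
            CellFeature(cell_id=cell_id, vector=vec, anchor_image_pos=anchor_img)
        )
    return out


def match_frames(
    cells_a: list[CellFeature], cells_b: list[CellFeature]
) -> tuple[list[tuple[tuple, tuple, int]], dict]:
    """Match unit cells across two frames by their binary feature vectors.

    Candidate matches are cells with identical vectors; ambiguity is resolved
    by choosing the single lattice translation (cell-index offset) consistent
    with the largest number of matches.  Returns the consistent matches as
    ``(cell_id_a, cell_id_b, hamming_score)`` triples (score 0 by
    construction) and a diagnostic dict.  If no translation is uniquely best
    (e.g. all vectors identical), the match list is empty and the diagnostic
    explains why.
    """
    if not cells_a or not cells_b:
        raise InvalidParameterError("both frames must contain encoded cells")
    if len({tuple(c.vector) for c in cells_a}) < 2 or len(
        {tuple(c.vector) for c in cells_b}
    ) < 2:
        # a single shared vector cannot pin down the lattice translation:
        # every offset is equally consistent up to boundary effects
        return [], {"reason": "ambiguous translation: no distinguishing cells"}
    votes: dict[tuple[int, int], list] = {}
    by_vec_b: dict[tuple, list[CellFeature]] = {}
    for cb in cells_b:
        by_vec_b.setdefault(tuple(cb.vector), []).append(cb)
    for ca in cells_a:
        for cb in by_vec_b.get(tuple(ca.vector), []):
            t = (cb.cell_id[0] - ca.cell_id[0], cb.cell_id[1] - ca.cell_id[1])
            votes.setdefault(t, []).append((ca.cell_id, cb.cell_id, 0))
    if not votes:
        return [], {"reason": "no cells share a feature vector"}
    counts = {t: len(v) for t, v in votes.items()}
    best_count = max(counts.values())
    winners = [t for t, c in counts.items() if c == best_count]
    if len(winners) > 1:
        return [], {
            "reason": "ambiguous translation: multiple offsets tie",
            "tied_translations": sorted(winners),
            "count": best_count,
        }
    t = winners[0]
    # one-to-one by construction only if cell ids unique per frame; dedupe
    matches = votes[t]
    return matches, {"translation": t, "count": best_count}


def difference_map(
    img_a,
    img_b,
    baseline: float | None = None,
    region: np.ndarray | None = None,
    histogram_match: bool = False,
) -> tuple[np.ndarray, float]:
    """Pixelwise difference of two registered images plus the fractional
    change of the dark-signal integral.

    The dark-signal integral is ``S = sum(max(0, baseline - I))`` over the
    analysis region, with the baseline defaulting to the Otsu threshold of
    the first image; the fractional change is ``(S_b - S_a) / S_a``.
    Intensities are differenced directly by default; ``histogram_match``
    matches the second image's histogram to the first before differencing
    (for cross-condition optical images).
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    if histogram_match:
        from skimage.exposure import match_histograms

        b = match_histograms(b, a)
    if baseline is None:
        baseline = float(threshold_otsu(a)) if np.ptp(a) > 0 else float(a.mean())
    mask = np.ones(a.shape, dtype=bool) if region is None else np.asarray(region, bool)
    S_a = float(np.sum(np.clip(baseline - a[mask], 0.0, None)))
    S_b = float(np.sum(np.clip(baseline - b[mask], 0.0, None)))
    if S_a == 0.0:
        frac = 0.0 if S_b == 0.0 else np.inf
    else:
        frac = (S_b - S_a) / S_a
    return b - a, float(frac)


def line_profile(img, p0, p1, width: int = 1) -> np.ndarray:
    """Bilinear intensity profile along the segment p0 -> p1.

    Samples at unit-pixel spacing (endpoints included), averaged across
    ``width`` integer perpendicular offsets centred on the line.
    """
    a = np.asarray(img, dtype=float)
    rows, cols = a.shape
    p0 = np.asarray(p0, dtype=float).reshape(2)
    p1 = np.asarray(p1, dtype=float).reshape(2)
    for name, p in (("p0", p0), ("p1", p1)):
        if not (0 <= p[0] <= cols - 1 and 0 <= p[1] <= rows - 1):
            raise InvalidParameterError(f"{name}={tuple(p)} lies outside the image")
    if width < 1:
        raise InvalidParameterError("width must be >= 1")
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(np.round(length)) + 1, 2)
    ts = np.linspace(0.0, 1.0, n)
    base = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    if length > 0:
        normal = np.array([-(p1 - p0)[1], (p1 - p0)[0]]) / length
    else:
        normal = np.array([0.0, 1.0])
    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    acc = np.zeros(n)
    for o in offsets:
        pts = base + o * normal[None, :]
        acc += ndimage.map_coordinates(
            a, [pts[:, 1], pts[:, 0]], order=1, mode="nearest", prefilter=False
        )
    return acc / width
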