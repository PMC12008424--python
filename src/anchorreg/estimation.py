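"""Fine matching stage: robust homography estimation by least median of
squares (LMedS) and absolute-scale point reconstruction.

The homography relates placed model points to extracted points,
``P_e = H (x) P_m'``.  With eight degrees of freedom, four correspondences
give the eight equations of the minimal problem.  LMedS repeatedly solves
random minimal subsets by the normalised direct linear transform (DLT) and
keeps the solution with the smallest median squared reprojection error over
all pairs — robust to up to ~50% incorrect pairings.  An optional refinement
re-solves the DLT in a least-squares sense over the inliers of the best
minimal solution.

Reconstruction maps extracted points back to model units:
``P_t = A^{-1} (x) H^{-1} (x) P_e``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import transforms
from .errors import DegeneracyError, InsufficientDataError, InvalidParameterError
from .transforms import TransformMatrix

__all__ = [
    "LmedsConfig",
    "EstimationResult",
    "estimate_homography_lmeds",
    "reconstruct_points",
]

_Z_TOL = 1e-12


@dataclass(frozen=True)
class LmedsConfig:
    """LMedS solver configuration.

    ``n_samples`` random minimal subsets are drawn (ignored when exactly four
    pairs are given — the interpolating homography is solved directly).  The
    robust scale is the standard LMedS estimate
    ``1.4826 * (1 + 5/(n-4)) * sqrt(median_sq_residual)``; pairs within
    ``inlier_k`` robust scales are inliers.
    """

    n_samples: int = 1000
    refine: bool = True
    inlier_k: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise InvalidParameterError("n_samples must be >= 1")
        if self.inlier_k <= 0:
            raise InvalidParameterError("inlier_k must be positive")


@dataclass(frozen=True)
class EstimationResult:
    H: TransformMatrix
    residuals: np.ndarray  # per-pair reprojection distance
    inlier_mask: np.ndarray  # bool per pair
    median_sq_residual: float

    def to_dict(self) -> dict:
        return {
            "H": self.H.to_dict(),
            "residuals": [float(r) for r in self.residuals],
            "inlier_mask": [bool(b) for b in self.inlier_mask],
            "median_sq_residual": float(self.median_sq_residual),
        }


def _hartley_normalization(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity T mapping the centroid to the origin and the RMS distance
    to sqrt(2); returns (T, T @ pts)."""
    c = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - c) ** 2, axis=1)))
    s = np.sqrt(2.0) / rms if rms > 1e-300 else 1.0
    T = np.array([[s, 0.0, -s * c[0]], [0.0, s, -s * c[1]], [0.0, 0.0, 1.0]])
    return T, (pts - c) * s


def _dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares DLT homography (n >= 4 pairs) with Hartley
    normalisation.  Returns the unnormalised 3x3 matrix."""
    Ts, srcn = _hartley_normalization(src)
    Td, dstn = _hartley_normalization(dst)
    n = len(src)
    A = np.zeros((2 * n, 9))
    x, y = srcn[:, 0], srcn[:, 1]
    u, v = dstn[:, 0], dstn[:, 1]
    A[0::2, 0] = x
    A[0::2, 1] = y
    A[0::2, 2] = 1.0
    A[0::2, 6] = -u * x
    A[0::2, 7] = -u * y
    A[0::2, 8] = -u
    A[1::2, 3] = x
    A[1::2, 4] = y
    A[1::2, 5] = 1.0
    A[1::2, 6] = -v * x
    A[1::2, 7] = -v * y
    A[1::2, 8] = -v
    _, sv, vt = np.linalg.svd(A)
    if sv[0] <= 0 or sv[-2] / sv[0] < 1e-10:
        raise DegeneracyError("degenerate configuration: DLT system rank < 8")
    Hn = vt[-1].reshape(3, 3)
    return np.linalg.inv(Td) @ Hn @ Ts


def _sq_residuals(H: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    homo = np.column_stack([src, np.ones(len(src))]) @ H.T
    z = homo[:, 2]
    out = np.full(len(src), np.inf)
    ok = np.abs(z) > _Z_TOL
    proj = homo[ok, :2] / z[ok, None]
    out[ok] = np.sum((proj - dst[ok]) ** 2, axis=1)
    return out


def _batched_minimal_solve(
    src: np.ndarray, dst: np.ndarray, subsets: np.ndarray
) -> np.ndarray:
    """Solve the 4-point DLT for every subset at once.

    Returns (S, 3, 3) homography candidates; degenerate subsets yield NaN
    matrices.  Normalisation uses the global Hartley transforms (sufficient
    for conditioning; the minimal solve is exact regardless).
    """
    Ts, srcn = _hartley_normalization(src)
    Td, dstn = _hartley_normalization(dst)
    S = len(subsets)
    s4 = srcn[subsets]  # (S, 4, 2)
    d4 = dstn[subsets]
    A = np.zeros((S, 8, 9))
    x, y = s4[..., 0], s4[..., 1]
    u, v = d4[..., 0], d4[..., 1]
    A[:, 0::2, 0] = x
    A[:, 0::2, 1] = y
    A[:, 0::2, 2] = 1.0
    A[:, 0::2, 6] = -u * x
    A[:, 0::2, 7] = -u * y
    A[:, 0::2, 8] = -u
    A[:, 1::2, 3] = x
    A[:, 1::2, 4] = y
    A[:, 1::2, 5] = 1.0
    A[:, 1::2, 6] = -v * x
    A[:, 1::2, 7] = -v * y
    A[:, 1::2, 8] = -v
    _, sv, vt = np.linalg.svd(A)
    Hn = vt[:, -1, :].reshape(S, 3, 3)
    bad = sv[:, 7] / np.maximum(sv[:, 0], 1e-300) < 1e-10
    Hn[bad] = np.nan
    Tdinv = np.linalg.inv(Td)
    return Tdinv[None] @ Hn @ Ts[None]


def robust_scale(median_sq_residual: float, n: int) -> float:
    """Standard LMedS robust standard-deviation estimate."""
    return 1.4826 * (1.0 + 5.0 / max(n - 4, 1)) * np.sqrt(median_sq_residual)


def estimate_homography_lmeds(
    src, dst, cfg: LmedsConfig = LmedsConfig()
) -> EstimationResult:
    """Estimate the homography mapping ``src`` (P_m') onto ``dst`` (P_e).

    With exactly four pairs the interpolating homography is solved directly.
    Otherwise ``cfg.n_samples`` random 4-subsets are solved and scored by the
    median squared reprojection error over *all* pairs; the minimiser wins.
    If ``cfg.refine``, a least-squares DLT over the inliers of the winner is
    solved and returned.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 2)
    dst = np.asarray(dst, dtype=float).reshape(-1, 2)
    if len(src) != len(dst):
        raise InvalidParameterError("src and dst must have equal length")
    n = len(src)
    if n < 4:
        raise InsufficientDataError(
            f"homography estimation needs >= 4 pairs, got {n}"
        )

    if n == 4:
        H = _dlt(src, dst)
        H = H / H[2, 2]
        res2 = _sq_residuals(H, src, dst)
        med = float(np.median(res2))
        return EstimationResult(
            H=TransformMatrix(H, kind="homography"),
            residuals=np.sqrt(res2),
            inlier_mask=np.ones(n, dtype=bool),
            median_sq_residual=med,
        )

    rng = np.random.default_rng(cfg.seed)
    # draw all minimal 4-subsets at once (argsort of uniforms = random perm)
    subsets = np.argsort(rng.random((cfg.n_samples, n)), axis=1)[:, :4]
    Hs = _batched_minimal_solve(src, dst, subsets)

    homo = np.column_stack([src, np.ones(n)])
    proj = np.einsum("sij,nj->sni", Hs, homo)  # (S, n, 3)
    z = proj[..., 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        xy = proj[..., :2] / z[..., None]
        res2_all = np.sum((xy - dst[None]) ** 2, axis=-1)
    res2_all[np.abs(z) <= _Z_TOL] = np.inf
    res2_all = np.nan_to_num(res2_all, nan=np.inf, posinf=np.inf)
    medians = np.median(res2_all, axis=1)
    best = int(np.argmin(medians))
    if not np.isfinite(medians[best]):
        raise DegeneracyError("all sampled minimal subsets were degenerate")
    H = Hs[best] / Hs[best][2, 2]
    med = float(medians[best])

    res2 = _sq_residuals(H, src, dst)
    sigma = robust_scale(med, n)
    inliers = np.sqrt(res2) <= cfg.inlier_k * max(sigma, 1e-12)

    if cfg.refine:
        # Bootstrap the inlier set for refinement.  The winning minimal
        # subset is interpolated exactly, so a scale taken straight from the
        # median underestimates pure detection noise, while any scale taken
        # from a subset can be corrupted by outliers.  Gross mispairings sit
        # orders of magnitude above the inlier residuals, so we split at the
        # largest multiplicative gap in the upper half of the sorted
        # residuals; with no convincing gap (pure noise) every pair is used.
        # the lower group keeps >= 6 points so a refit can never come close
        # to interpolating (12 equations against 8 degrees of freedom);
        # splits right at the minimised median order statistic would
        # otherwise fabricate a gap in pure noise
        order = np.argsort(res2)
        k_min = max(6, int(np.ceil(n / 2)))
        best_ratio, k_split = 1.0, n
        for k in range(k_min, n):
            lo = max(float(res2[order[k - 1]]), 1e-30)
            ratio = float(res2[order[k]]) / lo
            if ratio > best_ratio:
                best_ratio, k_split = ratio, k
        if best_ratio > 100.0:
            inliers = np.zeros(n, dtype=bool)
            inliers[order[:k_split]] = True
        else:
            inliers = np.ones(n, dtype=bool)
        # iterate inlier-weighted least squares to convergence; the refits
        # no longer interpolate, so the spec scale rule is now well posed
        for _ in range(10):
            if inliers.sum() < 4:
                break
            try:
                Hr = _dlt(src[inliers], dst[inliers])
            except DegeneracyError:
                break  # keep the current solution
            Hr = Hr / Hr[2, 2]
            res2_r = _sq_residuals(Hr, src, dst)
            H, res2 = Hr, res2_r
            med = float(np.median(res2))
            sigma = robust_scale(med, n)
            new_inliers = np.sqrt(res2) <= cfg.inlier_k * max(sigma, 1e-12)
            if np.array_equal(new_inliers, inliers):
                inliers = new_inliers
                break
            inliers = new_inliers

    return EstimationResult(
        H=TransformMatrix(H, kind="homography"),
        residuals=np.sqrt(res2),
        inlier_mask=inliers,
        median_sq_residual=med,
    )


def reconstruct_points(A, H, extracted) -> np.ndarray:
    """Map extracted points back to model units:
    ``P_t = A^{-1} (x) H^{-1} (x) P_e``."""
    Hinv = transforms.invert_transform(H)
    Ainv = transforms.invert_transform(A)
    return transforms.apply_transform(
        Ainv, transforms.apply_transform(Hinv, extracted)
    )
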