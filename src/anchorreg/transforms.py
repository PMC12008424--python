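"""Planar projective geometry: affine composition, homography application,
inversion and full-image perspective warping.

Conventions
-----------
* A point is ``(x, y)`` with ``x`` the column index and ``y`` the row index,
  origin at the top-left pixel centre, 0-based.
* Point sets are ``(N, 2)`` float arrays; order is meaningful (index =
  identity of a site).
* Transform matrices are 3x3 with the bottom-right element normalised to 1.
  An affine matrix additionally has ``m[2, 0] = m[2, 1] = 0``; a homography
  carries the two projective terms ``(g, h)`` in that row.

The affine matrix is composed as ``A = S(s_x, s_y) @ R(theta) @ Sh(a_x, a_y)
@ T(x_0, y_0)`` — scaling, rotation, shearing, translation multiplied in that
order.  Because translation is the right-most factor it acts in
pre-rotation (model) coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateProjectionError,
    InvalidParameterError,
    SingularTransformError,
)

_DET_TOL = 1e-12
_Z_TOL = 1e-12


@dataclass(frozen=True)
class AffineParams:
    """Parameters of a 2D affine transform.

    Attributes
    ----------
    s_x, s_y : scaling factors (dimensionless, must be positive)
    theta : rotation angle in radians
    a_x, a_y : shearing factors (dimensionless)
    x_0, y_0 : translation, in units of the *source* frame (applied before
        scaling/rotation/shearing — see module docstring)
    """

    s_x: float = 1.0
    s_y: float = 1.0
    theta: float = 0.0
    a_x: float = 0.0
    a_y: float = 0.0
    x_0: float = 0.0
    y_0: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.s_x, self.s_y, self.theta, self.a_x, self.a_y, self.x_0, self.y_0)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError("affine parameters must be finite")
        if self.s_x <= 0 or self.s_y <= 0:
            raise InvalidParameterError(
                f"scale factors must be positive, got s_x={self.s_x}, s_y={self.s_y}"
            )

    def replace(self, **kw) -> "AffineParams":
        d = self.__dict__ | kw
        return AffineParams(**d)


@dataclass(frozen=True)
class TransformMatrix:
    """A 3x3 projective matrix tagged as affine or homography.

    The matrix is normalised so ``m[2, 2] == 1`` and checked invertible at
    construction.
    """

    m: np.ndarray
    kind: str = "homography"

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (3, 3):
            raise InvalidParameterError(f"transform matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise InvalidParameterError("transform matrix must be finite")
        if abs(m[2, 2]) < _Z_TOL:
            raise SingularTransformError("cannot normalise: m[2,2] is ~0")
        m = m / m[2, 2]
        if abs(np.linalg.det(m)) <= _DET_TOL:
            raise SingularTransformError("transform matrix is singular")
        if self.kind not in ("affine", "homography"):
            raise InvalidParameterError(f"unknown transform kind {self.kind!r}")
        if self.kind == "affine" and (abs(m[2, 0]) > 0 or abs(m[2, 1]) > 0):
            raise InvalidParameterError(
                "affine matrix must have zero projective terms"
            )
        m.setflags(write=False)
        object.__setattr__(self, "m", m)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"kind": self.kind, "m": [float(v) for v in self.m.ravel()]}

    @classmethod
    def from_dict(cls, d: dict) -> "TransformMatrix":
        m = np.asarray(d["m"], dtype=float).reshape(3, 3)
        return cls(m=m, kind=d.get("kind", "homography"))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "TransformMatrix":
        return cls.from_dict(json.loads(s))


def identity(kind: str = "affine") -> TransformMatrix:
    return TransformMatrix(np.eye(3), kind=kind)


def as_matrix(T) -> np.ndarray:
    """Coerce a TransformMatrix or raw 3x3 array to an ndarray."""
    if isinstance(T, TransformMatrix):
        return T.m
    m = np.asarray(T, dtype=float)
    if m.shape != (3, 3):
        raise InvalidParameterError(f"expected 3x3 matrix, got shape {m.shape}")
    return m


def compose_affine(params: AffineParams) -> TransformMatrix:
    """Build the affine matrix ``A = S @ R @ Sh @ T`` from its parameters.

    The factor order means translation ``(x_0, y_0)`` is applied in
    pre-rotation coordinates: ``A p = S R Sh (p + t)`` up to shear coupling.
    """
    S = np.diag([params.s_x, params.s_y, 1.0])
    c, s = np.cos(params.theta), np.sin(params.theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    Sh = np.array([[1.0, params.a_x, 0.0], [params.a_y, 1.0, 0.0], [0.0, 0.0, 1.0]])
    T = np.array([[1.0, 0.0, params.x_0], [0.0, 1.0, params.y_0], [0.0, 0.0, 1.0]])
    return TransformMatrix(S @ R @ Sh @ T, kind="affine")


def chain(*Ts) -> TransformMatrix:
    """Matrix product of transforms, left to right: ``chain(A, B)`` applies
    B first then A (standard matrix composition A @ B)."""
    ms = [as_matrix(T) for T in Ts]
    m = ms[0]
    for other in ms[1:]:
        m = m @ other
    kinds = [T.kind if isinstance(T, TransformMatrix) else "homography" for T in Ts]
    kind = "affine" if all(k == "affine" for k in kinds) else "homography"
    if kind == "affine":
        # products of affines are affine; zero out numerical dust so the
        # stricter affine invariant holds exactly
        m = m.copy()
        m[2, 0] = m[2, 1] = 0.0
    return TransformMatrix(m, kind=kind)


def _as_points(pts) -> np.ndarray:
    p = np.asarray(pts, dtype=float)
    if p.ndim == 1 and p.shape[0] == 2:
        p = p[None, :]
    if p.ndim != 2 or p.shape[1] != 2:
        raise InvalidParameterError(f"point set must have shape (N, 2), got {p.shape}")
    return p


def apply_transform(T, pts) -> np.ndarray:
    """Apply a projective transform to a point set.

    Each point ``(x, y)`` is lifted to homogeneous coordinates, multiplied by
    the matrix, and de-homogenised: ``(x_t/z_t, y_t/z_t)``.  Order preserved.

    Raises
    ------
    DegenerateProjectionError
        if any point projects to infinity (``|z_t| < 1e-12``); the error
        carries the offending indices.
    """
    m = as_matrix(T)
    p = _as_points(pts)
    homo = np.column_stack([p, np.ones(len(p))])
    out = homo @ m.T
    z = out[:, 2]
    bad = np.flatnonzero(np.abs(z) < _Z_TOL)
    if bad.size:
        raise DegenerateProjectionError(
            f"points at infinity under transform (indices {bad.tolist()})", indices=bad
        )
    return out[:, :2] / z[:, None]


def invert_transform(T) -> TransformMatrix:
    """Inverse transform, renormalised so the bottom-right element is 1."""
    m = as_matrix(T)
    if abs(np.linalg.det(m)) <= _DET_TOL:
        raise SingularTransformError("cannot invert a singular transform")
    inv = np.linalg.inv(m)
    kind = T.kind if isinstance(T, TransformMatrix) else "homography"
    if kind == "affine":
        inv = inv.copy()
        inv[2, 0] = inv[2, 1] = 0.0
    return TransformMatrix(inv, kind=kind)


def warp_image(
    img: np.ndarray,
    T,
    out_shape: Sequence[int] | None = None,
    fill: float = 0.0,
) -> np.ndarray:
    """Perspective-warp a grayscale image by transform ``T``.

    The output pixel at ``(x, y)`` samples the input at
    ``apply_transform(T^{-1}, (x, y))`` with bilinear interpolation;
    out-of-bounds samples take ``fill``.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise InvalidParameterError("image must be a nonempty 2D array")
    if out_shape is None:
        out_shape = img.shape
    rows, cols = int(out_shape[0]), int(out_shape[1])
    if rows < 1 or cols < 1:
        raise InvalidParameterError(f"invalid output shape {out_shape}")
    inv = invert_transform(T).m
    yy, xx = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    homo = np.column_stack([pts, np.ones(len(pts))])
    src = homo @ inv.T
    z = src[:, 2]
    # pixels mapping to infinity sample the fill value instead of erroring
    safe = np.abs(z) >= _Z_TOL
    sx = np.full(len(pts), -1e9)
    sy = np.full(len(pts), -1e9)
    sx[safe] = src[safe, 0] / z[safe]
    sy[safe] = src[safe, 1] / z[safe]
    out = ndimage.map_coordinates(
        img, [sy, sx], order=1, mode="constant", cval=fill, prefilter=False
    )
    return out.reshape(rows, cols)
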