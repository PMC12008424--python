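"""Anchor-point models: periodic lattices, polygonal device outlines and
unit-cell templates with sub-feature coordinates.

An :class:`AnchorModel` holds the model point set ``P_m`` in unit-length
normalised model coordinates; pixel scale enters only through the affine
placement at registration time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import transforms
from .errors import InvalidParameterError

_SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class AnchorModel:
    """A predefined structural model.

    Attributes
    ----------
    name : model identifier
    points : (N, 2) anchor coordinates ``P_m`` in model units
    unit_length : inter-structure distance L (model units)
    lattice_basis : (2, 2) basis vectors as rows, or None for polygon models
    lattice_shape : (rows, cols) for lattice models, else None
    """

    name: str
    points: np.ndarray
    unit_length: float = 1.0
    lattice_basis: np.ndarray | None = None
    lattice_shape: tuple[int, int] | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
            raise InvalidParameterError("anchor points must be a nonempty (N,2) array")
        if self.unit_length <= 0:
            raise InvalidParameterError("unit_length must be positive")
        # pairwise distinctness
        d = pts[:, None, :] - pts[None, :, :]
        dist = np.hypot(d[..., 0], d[..., 1])
        np.fill_diagonal(dist, np.inf)
        if dist.min() < 1e-12:
            raise InvalidParameterError("anchor points must be pairwise distinct")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        if self.lattice_basis is not None:
            b = np.asarray(self.lattice_basis, dtype=float)
            b.setflags(write=False)
            object.__setattr__(self, "lattice_basis", b)

    @property
    def is_lattice(self) -> bool:
        return self.lattice_basis is not None

    def lattice_indices(self) -> np.ndarray:
        """(N, 2) integer (i, j) basis coefficients, row-major order."""
        if not self.is_lattice:
            raise InvalidParameterError("not a lattice model")
        rows, cols = self.lattice_shape
        ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([ii.ravel(), jj.ravel()])

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "unit_length": float(self.unit_length),
            "points": self.points.tolist(),
        }
        if self.is_lattice:
            d["lattice_basis"] = self.lattice_basis.tolist()
            d["lattice_shape"] = list(self.lattice_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnchorModel":
        basis = d.get("lattice_basis")
        shape = d.get("lattice_shape")
        return cls(
            name=d["name"],
            points=np.asarray(d["points"], dtype=float),
            unit_length=float(d.get("unit_length", 1.0)),
            lattice_basis=None if basis is None else np.asarray(basis, dtype=float),
            lattice_shape=None if shape is None else (int(shape[0]), int(shape[1])),
        )


@dataclass(frozen=True)
class UnitCellTemplate:
    """Sub-feature layout of one unit cell.

    ``cell_anchor_offsets`` are the cell's defining anchor points (e.g. the
    corner holes) and ``subfeature_offsets`` the ordered sub-feature
    coordinates (e.g. adatoms), both relative to the cell origin in
    unit-length normalised coordinates.  The sub-feature order is fixed: it
    defines the element order of the binary cell feature vector.
    """

    name: str
    cell_anchor_offsets: np.ndarray
    subfeature_offsets: np.ndarray

    def __post_init__(self):
        for attr in ("cell_anchor_offsets", "subfeature_offsets"):
            a = np.asarray(getattr(self, attr), dtype=float)
            if a.ndim != 2 or a.shape[1] != 2:
                raise InvalidParameterError(f"{attr} must be an (N,2) array")
            a.setflags(write=False)
            object.__setattr__(self, attr, a)

    @property
    def n_subfeatures(self) -> int:
        return len(self.subfeature_offsets)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cell_anchor_offsets": self.cell_anchor_offsets.tolist(),
            "subfeature_offsets": self.subfeature_offsets.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnitCellTemplate":
        return cls(
            name=d["name"],
            cell_anchor_offsets=np.asarray(d["cell_anchor_offsets"], dtype=float),
            subfeature_offsets=np.asarray(d["subfeature_offsets"], dtype=float),
        )


def make_lattice_model(
    rows: int,
    cols: int,
    unit_length: float = 1.0,
    basis=((1.0, 0.0), (0.0, 1.0)),
    name: str = "lattice",
) -> AnchorModel:
    """Periodic lattice of ``rows x cols`` anchor points.

    Point ``(i, j)`` sits at ``unit_length * (i*b1 + j*b2)``; points are
    emitted in row-major order (j fastest).
    """
    if rows < 1 or cols < 1:
        raise InvalidParameterError("rows and cols must be >= 1")
    if unit_length <= 0:
        raise InvalidParameterError("unit_length must be positive")
    b = np.asarray(basis, dtype=float)
    if b.shape != (2, 2) or abs(np.linalg.det(b)) < 1e-12:
        raise InvalidParameterError("basis must be two linearly independent 2D vectors")
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pts = unit_length * (ii.ravel()[:, None] * b[0] + jj.ravel()[:, None] * b[1])
    return AnchorModel(
        name=name,
        points=pts,
        unit_length=unit_length,
        lattice_basis=b,
        lattice_shape=(rows, cols),
    )


def _canonical_vertex_order(v: np.ndarray) -> np.ndarray:
    """Counterclockwise angular order about the centroid, starting from the
    vertex with smallest (y, then x)."""
    c = v.mean(axis=0)
    ang = np.arctan2(v[:, 1] - c[1], v[:, 0] - c[0])
    r = np.hypot(v[:, 0] - c[0], v[:, 1] - c[1])
    order = np.lexsort((r, ang))
    v = v[order]
    start = np.lexsort((v[:, 0], v[:, 1]))[0]
    return np.roll(v, -start, axis=0)


def make_polygon_model(vertices, name: str = "polygon") -> AnchorModel:
    """Polygonal device-outline model from its corner vertices.

    Vertices are canonicalised to counterclockwise order (in x-right/y-up
    sense on the stored coordinates) starting from the smallest ``(y, x)``
    vertex; ``unit_length`` is the shortest edge of the canonical cycle.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise InvalidParameterError("need at least 3 vertices of shape (N,2)")
    d = v[:, None, :] - v[None, :, :]
    dist = np.hypot(d[..., 0], d[..., 1])
    np.fill_diagonal(dist, np.inf)
    if dist.min() < 1e-12:
        raise InvalidParameterError("duplicate vertices")
    # collinearity: rank of centred vertices
    if np.linalg.matrix_rank(v - v.mean(axis=0), tol=1e-9) < 2:
        raise InvalidParameterError("vertices are collinear")
    v = _canonical_vertex_order(v)
    edges = np.roll(v, -1, axis=0) - v
    unit_length = float(np.hypot(edges[:, 0], edges[:, 1]).min())
    return AnchorModel(name=name, points=v, unit_length=unit_length)


def si7x7_template() -> UnitCellTemplate:
    """Unit-cell template for one triangular half cell of Si(111)-(7x7).

    The three corner holes form an equilateral triangle of side 1 (corner-hole
    distances normalised to 1): C1=(0,0), C2=(1,0), C3=(1/2, sqrt(3)/2).
    Six sub-features (adatoms) are numbered 1-3 for the corner adatoms,
    counterclockwise starting from the lowest-left corner hole, then 4-6 for
    the centre adatoms in the same angular order.  Adatom coordinates are
    geometric barycentric positions consistent with the dimer-adatom-stacking-
    fault arrangement at the resolution relevant for registration: corner
    adatom k at barycentric (5, 1, 1)/7 about corner k, centre adatom k at
    (1, 3, 3)/7.  Only the relative geometry matters for registration.
    """
    corners = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, _SQRT3 / 2.0]])
    corner_ad = []
    center_ad = []
    for k in range(3):
        c0, c1, c2 = corners[k], corners[(k + 1) % 3], corners[(k + 2) % 3]
        corner_ad.append((5.0 * c0 + c1 + c2) / 7.0)
        center_ad.append((c0 + 3.0 * c1 + 3.0 * c2) / 7.0)
    sub = np.vstack([corner_ad, center_ad])
    return UnitCellTemplate(
        name="si111-7x7-halfcell",
        cell_anchor_offsets=corners,
        subfeature_offsets=sub,
    )


def project_subfeatures(
    template: UnitCellTemplate,
    A,
    H,
    cell_origin,
    unit_length: float = 1.0,
) -> np.ndarray:
    """Map template sub-features of the cell at ``cell_origin`` into image
    coordinates: ``H (x) A (x) (cell_origin + unit_length * offsets)``.

    Order follows the template numbering; raises DegenerateProjectionError if
    any site projects to infinity.
    """
    origin = np.asarray(cell_origin, dtype=float).reshape(2)
    pts = origin[None, :] + unit_length * template.subfeature_offsets
    return transforms.apply_transform(H, transforms.apply_transform(A, pts))
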