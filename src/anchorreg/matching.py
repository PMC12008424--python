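"""Rough matching stage: vote-based filtering of periodic point clouds,
brute-force translation placement of the anchor model, and gated
nearest-neighbour pairing.

The vote algorithm scores every extracted point against its neighbours
within a candidate radius: +1 for each neighbour whose distance falls inside
the accepted band of inter-structure distances ``[tol_low*L, tol_high*L]``,
-1 otherwise.  Points with negative scores are excluded; isolated points
(no candidates) score 0 and are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import transforms
from .anchor_models import AnchorModel
from .errors import InvalidParameterError, PlacementFailureError
from .transforms import AffineParams

__all__ = [
    "VoteConfig",
    "VoteResult",
    "PairSet",
    "RoughMatchResult",
    "vote_filter",
    "pair_points",
    "place_model",
]


@dataclass(frozen=True)
class VoteConfig:
    """Vote-filter parameters.

    ``radius`` defaults to ``1.3 * unit_length``: it captures the four axial
    neighbours of a square lattice while excluding the diagonals.
    """

    unit_length: float
    radius: float | None = None
    tol_low: float = 0.9
    tol_high: float = 1.1

    def __post_init__(self):
        if self.unit_length <= 0:
            raise InvalidParameterError("unit_length must be positive")
        if not (0 < self.tol_low < 1 < self.tol_high):
            raise InvalidParameterError("need 0 < tol_low < 1 < tol_high")
        r = self.effective_radius
        if r < self.tol_high * self.unit_length:
            raise InvalidParameterError("radius must be >= tol_high * unit_length")

    @property
    def effective_radius(self) -> float:
        return 1.3 * self.unit_length if self.radius is None else self.radius


@dataclass(frozen=True)
class VoteResult:
    scores: np.ndarray  # int per input point
    kept: np.ndarray  # (K, 2)
    removed: np.ndarray  # (R, 2)
    kept_mask: np.ndarray  # bool per input point


@dataclass(frozen=True)
class PairSet:
    """Greedy one-to-one (model index, extracted index, distance) matches."""

    model_indices: np.ndarray
    extracted_indices: np.ndarray
    distances: np.ndarray
    gate: float
    n_model: int
    n_extracted: int

    def __len__(self) -> int:
        return len(self.model_indices)

    @property
    def unpaired_model(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_model), self.model_indices)

    @property
    def unpaired_extracted(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_extracted), self.extracted_indices)

    def to_dict(self) -> dict:
        return {
            "pairs": [
                [int(m), int(e), float(d)]
                for m, e, d in zip(
                    self.model_indices, self.extracted_indices, self.distances
                )
            ],
            "gate": float(self.gate),
            "n_model": int(self.n_model),
            "n_extracted": int(self.n_extracted),
        }


@dataclass(frozen=True)
class RoughMatchResult:
    affine: AffineParams  # with optimised x_0, y_0
    placed_model: np.ndarray  # P_m' = A (x) P_m
    pairs: PairSet
    objective: float

    def to_dict(self) -> dict:
        return {
            "affine": self.affine.__dict__,
            "pairs": self.pairs.to_dict(),
            "objective": float(self.objective),
        }


def vote_filter(pts, cfg: VoteConfig) -> VoteResult:
    """Score each point against neighbours within the candidate radius and
    drop points with negative scores."""
    p = np.asarray(pts, dtype=float).reshape(-1, 2)
    if len(p) == 0:
        raise InvalidParameterError("vote_filter needs at least one point")
    L = cfg.unit_length
    lo, hi = cfg.tol_low * L, cfg.tol_high * L
    tree = cKDTree(p)
    neighbours = tree.query_ball_point(p, cfg.effective_radius)
    scores = np.zeros(len(p), dtype=int)
    for i, cand in enumerate(neighbours):
        for j in cand:
            if j == i:
                continue
            d = np.hypot(*(p[j] - p[i]))
            scores[i] += 1 if lo <= d <= hi else -1
    mask = scores >= 0
    return VoteResult(scores=scores, kept=p[mask], removed=p[~mask], kept_mask=mask)


def pair_points(placed_model, extracted, gate: float) -> PairSet:
    """Pair each placed model point with its nearest extracted point.

    Greedy by ascending nearest-neighbour distance (tie-break: lowest model
    index); an extracted point already claimed by a nearer model point is
    unavailable, and distances above ``gate`` stay unpaired.
    """
    if gate <= 0:
        raise InvalidParameterError("gate must be positive")
    pm = np.asarray(placed_model, dtype=float).reshape(-1, 2)
    pe = np.asarray(extracted, dtype=float).reshape(-1, 2)
    if len(pm) == 0 or len(pe) == 0:
        return PairSet(
            model_indices=np.empty(0, int),
            extracted_indices=np.empty(0, int),
            distances=np.empty(0),
            gate=gate,
            n_model=len(pm),
            n_extracted=len(pe),
        )
    tree = cKDTree(pe)
    dists, nearest = tree.query(pm)
    order = np.lexsort((np.arange(len(pm)), dists))
    claimed: set[int] = set()
    mi, ei, dd = [], [], []
    for m in order:
        e = int(nearest[m])
        if dists[m] > gate or e in claimed:
            continue
        claimed.add(e)
        mi.append(int(m))
        ei.append(e)
        dd.append(float(dists[m]))
    return PairSet(
        model_indices=np.asarray(mi, int),
        extracted_indices=np.asarray(ei, int),
        distances=np.asarray(dd),
        gate=gate,
        n_model=len(pm),
        n_extracted=len(pe),
    )


def _linear_part(fixed: AffineParams) -> np.ndarray:
    """The scale/rotation/shear factor M with zero translation: A = M T."""
    return transforms.compose_affine(fixed.replace(x_0=0.0, y_0=0.0)).m


def placement_objective(placed, extracted) -> float:
    """Median nearest-neighbour distance from the placed model to P_e —
    robust to missing detections and spurious extracted points."""
    tree = cKDTree(np.asarray(extracted, float).reshape(-1, 2))
    d, _ = tree.query(np.asarray(placed, float).reshape(-1, 2))
    return float(np.median(d))


def translation_candidates(
    model: AnchorModel, fixed: AffineParams, extracted, steps: int = 50
) -> np.ndarray:
    """Brute-force translation grid in model-frame units.

    The grid is centred on the centroid-aligning translation.  For lattice
    models it spans one primitive cell (translation is identifiable only
    modulo the lattice) with step ``unit_length / steps``; for polygon models
    it spans the model's own extent.
    """
    if steps < 1:
        raise InvalidParameterError("translation grid needs >= 1 step")
    pe = np.asarray(extracted, float).reshape(-1, 2)
    M = _linear_part(fixed)
    Minv = np.linalg.inv(M)
    pe_model = transforms.apply_transform(Minv, pe)
    t0 = pe_model.mean(axis=0) - model.points.mean(axis=0)
    frac = np.linspace(-0.5, 0.5, steps, endpoint=False)
    if model.is_lattice:
        b = model.lattice_basis * model.unit_length
        offsets = (frac[:, None, None] * b[0] + frac[None, :, None] * b[1]).reshape(-1, 2)
    else:
        ext = np.ptp(model.points, axis=0)
        ext = np.maximum(ext, model.unit_length)
        offsets = np.stack(
            np.meshgrid(frac * ext[0], frac * ext[1], indexing="ij"), axis=-1
        ).reshape(-1, 2)
    return t0[None, :] + offsets


def place_model(
    model: AnchorModel,
    fixed: AffineParams,
    extracted,
    steps: int = 50,
    gate: float | None = None,
) -> RoughMatchResult:
    """Optimise the affine translation ``(x_0, y_0)`` by brute force.

    All other affine parameters come from prior knowledge (pixel scale from
    the structure-model distance, rotation from the experimental setup).  The
    translation minimising the placement objective is returned together with
    the placed model ``P_m'`` and the gated nearest-neighbour pairs.

    Raises :class:`PlacementFailureError` when no model point finds an
    extracted candidate within the gate at the best placement.
    """
    pe = np.asarray(extracted, dtype=float).reshape(-1, 2)
    if len(pe) == 0:
        raise InvalidParameterError("extracted point set is empty")
    cands = translation_candidates(model, fixed, pe, steps=steps)
    M = _linear_part(fixed)
    # placed(t) = M (P_m + t); evaluate all candidates in one KD query
    base = model.points
    placed_all = (base[None, :, :] + cands[:, None, :]) @ M[:2, :2].T + M[:2, 2]
    tree = cKDTree(pe)
    d, _ = tree.query(placed_all.reshape(-1, 2))
    objectives = np.median(d.reshape(len(cands), -1), axis=1)
    best = int(np.argmin(objectives))
    t_best = cands[best]
    affine = fixed.replace(x_0=float(t_best[0]), y_0=float(t_best[1]))
    placed = transforms.apply_transform(transforms.compose_affine(affine), base)
    if gate is None:
        scale = float(np.sqrt(abs(np.linalg.det(M[:2, :2]))))
        gate = 0.35 * model.unit_length * scale
    pairs = pair_points(placed, pe, gate=gate)
    if len(pairs) == 0:
        raise PlacementFailureError(
            f"no model point found an extracted candidate within gate={gate:.3g} "
            f"at the best placement (objective {objectives[best]:.3g})"
        )
    return RoughMatchResult(
        affine=affine,
        placed_model=placed,
        pairs=pairs,
        objective=float(objectives[best]),
    )
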