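"""Registration-accuracy metrics and the Monte-Carlo validation study.

The study quantifies how anchor-point detection error propagates through
homography estimation: a periodic lattice of anchor points (unit length 1)
is transformed by a random homography, Gaussian detection noise is added,
the homography is re-estimated from the noisy correspondences, and the
noise-free transformed points are reconstructed through the inverse
estimate.  Accuracy is summarised by the mean absolute error (MAE, mean
Euclidean distance in model units) and by Recall at an Object Keypoint
Similarity (OKS) threshold.

Reconstruction deliberately targets the *noise-free* underlying positions
(``P_t = H_est^{-1} (x) P_e_clean``): rectification warps the whole image,
not the noisy detections, and reconstructing the noisy points through a
4-point interpolating fit would be exactly error-free, which cannot reflect
registration accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import transforms
from .anchor_models import AnchorModel, UnitCellTemplate, make_lattice_model
from .errors import AnchorRegError, InvalidParameterError
from .estimation import LmedsConfig, estimate_homography_lmeds
from .transforms import AffineParams, TransformMatrix

__all__ = [
    "MetricConfig",
    "HomographyMagnitude",
    "SweepConfig",
    "SweepResult",
    "mae",
    "oks",
    "recall_at_oks",
    "random_homography",
    "run_noise_sweep",
    "render_fixture",
    "plot_recall_heatmap",
]


@dataclass(frozen=True)
class MetricConfig:
    """OKS metric parameters.

    The per-point similarity is ``exp(-d^2 / (2 s^2 kappa^2))`` with ``d``
    the Euclidean error, ``s = oks_scale`` the spatial scale (default: the
    unit length, 1) and ``kappa`` the per-point falloff constant; the OKS of
    a sample is the mean over points.  Recall is the fraction of samples
    with OKS above ``oks_threshold``.
    """

    oks_scale: float = 1.0
    oks_kappa: float = 0.5
    oks_threshold: float = 0.95

    def __post_init__(self):
        if self.oks_scale <= 0 or self.oks_kappa <= 0:
            raise InvalidParameterError("oks_scale and oks_kappa must be positive")
        if not (0 < self.oks_threshold <= 1):
            raise InvalidParameterError("oks_threshold must be in (0, 1]")


def _paired(P_t, P_m) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(P_t, float).reshape(-1, 2)
    b = np.asarray(P_m, float).reshape(-1, 2)
    if len(a) != len(b):
        raise InvalidParameterError(
            f"point sets must have equal length ({len(a)} vs {len(b)})"
        )
    return a, b


def mae(P_t, P_m) -> float:
    """Mean Euclidean distance between matched points, in model units."""
    a, b = _paired(P_t, P_m)
    return float(np.mean(np.hypot(*(a - b).T)))


def oks(P_t, P_m, cfg: MetricConfig = MetricConfig()) -> float:
    """Object Keypoint Similarity: mean per-point Gaussian similarity."""
    a, b = _paired(P_t, P_m)
    d2 = np.sum((a - b) ** 2, axis=1)
    return float(np.mean(np.exp(-d2 / (2.0 * cfg.oks_scale**2 * cfg.oks_kappa**2))))


def recall_at_oks(oks_values, threshold: float = 0.95) -> float:
    """Fraction of samples with OKS strictly above the threshold."""
    v = np.asarray(oks_values, dtype=float)
    if v.size == 0:
        raise InvalidParameterError("recall needs at least one OKS value")
    return float(np.mean(v > threshold))


@dataclass(frozen=True)
class HomographyMagnitude:
    """Perturbation scales for random homography draws (uniform half-widths
    about the identity): scale 1 +/- ``scale``, rotation +/- ``rotation`` rad,
    shear +/- ``shear``, translation +/- ``translation`` units, projective
    terms (g, h) +/- ``projective`` per unit."""

    scale: float = 0.1
    rotation: float = 0.1
    shear: float = 0.05
    translation: float = 0.5
    projective: float = 0.01

    def __post_init__(self):
        if any(
            v < 0
            for v in (self.scale, self.rotation, self.shear, self.translation, self.projective)
        ):
            raise InvalidParameterError("magnitudes must be >= 0")


def random_homography(
    rng: np.random.Generator,
    magnitude: HomographyMagnitude = HomographyMagnitude(),
    extent: float = 1.0,
    max_tries: int = 100,
) -> TransformMatrix:
    """Random perturbation of the identity homography.

    Affine parameters are drawn uniformly within the magnitude half-widths
    and composed; the projective terms (g, h) replace the zero entries of the
    bottom row.  Draws are rejected (and retried, up to ``max_tries``) unless
    the matrix is invertible with positive homogeneous ``z`` at the four
    corners of the ``[0, extent]^2`` lattice extent.
    """
    corners = np.array(
        [[0.0, 0.0], [extent, 0.0], [0.0, extent], [extent, extent]]
    )
    for _ in range(max_tries):
        m = magnitude
        params = AffineParams(
            s_x=1.0 + rng.uniform(-m.scale, m.scale),
            s_y=1.0 + rng.uniform(-m.scale, m.scale),
            theta=rng.uniform(-m.rotation, m.rotation),
            a_x=rng.uniform(-m.shear, m.shear),
            a_y=rng.uniform(-m.shear, m.shear),
            x_0=rng.uniform(-m.translation, m.translation),
            y_0=rng.uniform(-m.translation, m.translation),
        )
        H = transforms.compose_affine(params).m.copy()
        H[2, 0] = rng.uniform(-m.projective, m.projective)
        H[2, 1] = rng.uniform(-m.projective, m.projective)
        if abs(np.linalg.det(H)) <= 1e-12:
            continue
        z = np.column_stack([corners, np.ones(4)]) @ H[2]
        if np.all(z > 1e-6):
            return TransformMatrix(H, kind="homography")
    raise AnchorRegError(f"no admissible homography in {max_tries} draws")


@dataclass(frozen=True)
class SweepConfig:
    """Monte-Carlo sweep over detection-noise levels and anchor-point counts.

    ``point_counts`` must be perfect squares (square lattices of unit
    length 1).  ``n_samples`` random homographies are drawn per condition;
    the published study uses 10,000, the test suite uses smaller sizes with
    correspondingly widened tolerances.
    """

    noise_stds: tuple = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.1)
    point_counts: tuple = (4, 9, 16, 25, 36, 49)
    n_samples: int = 10000
    magnitude: HomographyMagnitude = field(default_factory=HomographyMagnitude)
    lmeds: LmedsConfig = field(default_factory=lambda: LmedsConfig(n_samples=200))
    seed: int = 0

    def __post_init__(self):
        if any(s < 0 for s in self.noise_stds):
            raise InvalidParameterError("noise stds must be >= 0")
        if self.n_samples < 1:
            raise InvalidParameterError("n_samples must be >= 1")
        for c in self.point_counts:
            side = int(round(np.sqrt(c)))
            if side * side != c or c < 4:
                raise InvalidParameterError(
                    f"point counts must be perfect squares >= 4, got {c}"
                )


@dataclass(frozen=True)
class SweepResult:
    """Tidy per-sample records plus per-condition summaries."""

    records: pd.DataFrame  # noise_std, point_count, sample, mae, oks, failed
    oks_threshold: float

    def summary(self) -> pd.DataFrame:
        g = self.records.groupby(["noise_std", "point_count"])
        out = g.agg(
            mae_mean=("mae", "mean"),
            mae_median=("mae", "median"),
            mae_q1=("mae", lambda s: s.quantile(0.25)),
            mae_q3=("mae", lambda s: s.quantile(0.75)),
            n_failed=("failed", "sum"),
        )
        thr = self.oks_threshold
        out["recall"] = g["oks"].apply(lambda s: float(np.mean(s > thr)))
        return out.reset_index()

    def recall(self, noise_std: float, point_count: int) -> float:
        r = self.records
        sel = r[(r.noise_std == noise_std) & (r.point_count == point_count)]
        return float(np.mean(sel.oks > self.oks_threshold))


def _sweep_condition(
    noise_std: float,
    point_count: int,
    n_samples: int,
    magnitude: HomographyMagnitude,
    lmeds: LmedsConfig,
    seed_seq: np.random.SeedSequence,
    metric: MetricConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    side = int(round(np.sqrt(point_count)))
    model = make_lattice_model(side, side, unit_length=1.0)
    P_m = model.points
    extent = float(side - 1) if side > 1 else 1.0
    rng = np.random.default_rng(seed_seq)
    maes = np.empty(n_samples)
    okss = np.empty(n_samples)
    failed = np.zeros(n_samples, dtype=bool)
    for i in range(n_samples):
        H_true = random_homography(rng, magnitude, extent=extent)
        P_e_clean = transforms.apply_transform(H_true, P_m)
        P_e_noisy = P_e_clean + rng.normal(0.0, noise_std, size=P_m.shape)
        try:
            est = estimate_homography_lmeds(
                P_m,
                P_e_noisy,
                replace(lmeds, seed=int(rng.integers(0, 2**31 - 1))),
            )
            P_t = transforms.apply_transform(
                transforms.invert_transform(est.H), P_e_clean
            )
            maes[i] = mae(P_t, P_m)
            okss[i] = oks(P_t, P_m, metric)
        except AnchorRegError:
            maes[i] = np.inf
            okss[i] = 0.0
            failed[i] = True
    return maes, okss, failed


def run_noise_sweep(
    cfg: SweepConfig, metric: MetricConfig = MetricConfig()
) -> SweepResult:
    """Run the full noise-std x point-count Monte-Carlo sweep.

    Per condition and sample: build the lattice, draw a random homography
    ``H_true``, transform the lattice, add i.i.d. Gaussian coordinate noise
    (image frame), estimate ``H_est`` from the noisy correspondences, and
    reconstruct ``P_t = H_est^{-1} (x) P_e_clean``.  MAE and OKS are recorded
    per sample; estimation failures count as MAE = +inf, OKS = 0 and are
    flagged.  Results are bitwise-reproducible for a fixed ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(len(cfg.noise_stds) * len(cfg.point_counts))
    frames = []
    k = 0
    for noise_std in cfg.noise_stds:
        for count in cfg.point_counts:
            maes, okss, failed = _sweep_condition(
                noise_std,
                count,
                cfg.n_samples,
                cfg.magnitude,
                cfg.lmeds,
                children[k],
                metric,
            )
            k += 1
            frames.append(
                pd.DataFrame(
                    {
                        "noise_std": noise_std,
                        "point_count": count,
                        "sample": np.arange(cfg.n_samples),
                        "mae": maes,
                        "oks": okss,
                        "failed": failed,
                    }
                )
            )
    return SweepResult(
        records=pd.concat(frames, ignore_index=True),
        oks_threshold=metric.oks_threshold,
    )


def _gaussian_splat(img: np.ndarray, pos: np.ndarray, amp: float, sigma: float):
    """Add ``amp * exp(-r^2 / 2 sigma^2)`` bumps at sub-pixel positions."""
    rows, cols = img.shape
    rad = int(np.ceil(4 * sigma))
    for x, y in pos:
        r0, r1 = int(np.floor(y)) - rad, int(np.ceil(y)) + rad + 1
        c0, c1 = int(np.floor(x)) - rad, int(np.ceil(x)) + rad + 1
        r0, r1 = max(r0, 0), min(r1, rows)
        c0, c1 = max(c0, 0), min(c1, cols)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amp * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2)
        )


@dataclass(frozen=True)
class FixtureGroundTruth:
    """What the synthetic renderer drew, for closing the loop in tests."""

    anchor_positions: np.ndarray  # (N, 2) image-frame anchor centres
    H_true: TransformMatrix
    subfeature_positions: dict  # (i, j) cell -> (n_sub, 2) image positions
    defects: tuple  # ((cell, subfeature_index), ...)


def render_fixture(
    model: AnchorModel,
    H_true,
    template: UnitCellTemplate | None = None,
    shape: tuple[int, int] = (256, 256),
    background: float = 0.6,
    well_depth: float = 0.4,
    well_sigma: float = 2.5,
    spot_amplitude: float = 0.3,
    spot_sigma: float = 1.8,
    snr: float | None = None,
    defects: tuple = (),
    seed: int = 0,
) -> tuple[np.ndarray, FixtureGroundTruth]:
    """Render a synthetic warped-lattice image with known ground truth.

    Dark Gaussian wells are drawn at the anchor positions mapped through
    ``H_true`` (which must already include the model-to-pixel scaling), and
    bright Gaussian spots at every present sub-feature of each complete unit
    cell of a lattice model.  ``defects`` lists ``((i, j), k)`` sub-features
    to omit.  Gaussian pixel noise of standard deviation ``well_depth / snr``
    is added when ``snr`` is given.  Same seed, same image.
    """
    rows, cols = int(shape[0]), int(shape[1])
    anchors_img = transforms.apply_transform(H_true, model.points)
    inside = (
        (anchors_img[:, 0] >= 0)
        & (anchors_img[:, 0] <= cols - 1)
        & (anchors_img[:, 1] >= 0)
        & (anchors_img[:, 1] <= rows - 1)
    )
    if not np.all(inside):
        raise InvalidParameterError(
            f"anchor points outside canvas: indices {np.flatnonzero(~inside).tolist()}"
        )
    img = np.full((rows, cols), background)
    _gaussian_splat(img, anchors_img, -well_depth, well_sigma)

    sub_positions: dict = {}
    defect_set = {(tuple(cell), int(k)) for cell, k in defects}
    if template is not None and model.is_lattice:
        L = model.unit_length
        b = model.lattice_basis
        nrows, ncols = model.lattice_shape
        for i in range(nrows - 1):
            for j in range(ncols - 1):
                origin = L * (i * b[0] + j * b[1])
                pts_model = origin[None, :] + L * template.subfeature_offsets
                pts_img = transforms.apply_transform(H_true, pts_model)
                if (
                    pts_img[:, 0].min() < 0
                    or pts_img[:, 1].min() < 0
                    or pts_img[:, 0].max() > cols - 1
                    or pts_img[:, 1].max() > rows - 1
                ):
                    continue
                sub_positions[(i, j)] = pts_img
                present = [
                    k
                    for k in range(len(pts_img))
                    if ((i, j), k) not in defect_set
                ]
                if present:
                    _gaussian_splat(
                        img, pts_img[present], spot_amplitude, spot_sigma
                    )
    if snr is not None:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, well_depth / snr, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    gt = FixtureGroundTruth(
        anchor_positions=anchors_img,
        H_true=H_true if isinstance(H_true, TransformMatrix) else TransformMatrix(np.asarray(H_true, float)),
        subfeature_positions=sub_positions,
        defects=tuple((tuple(c), int(k)) for c, k in defects),
    )
    return img, gt


def plot_recall_heatmap(summary: pd.DataFrame, path: str) -> None:
    """Save a Recall@OKS heatmap (noise std x point count) as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = summary.pivot(index="noise_std", columns="point_count", values="recall")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(pivot.values, origin="lower", aspect="auto", vmin=0, vmax=1)
    ax.set_xticks(range(len(pivot.columns)), [str(c) for c in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{v:g}" for v in pivot.index])
    ax.set_xlabel("anchor point count")
    ax.set_ylabel("noise std (model units)")
    fig.colorbar(im, ax=ax, label="Recall@OKS")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
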