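"""Similarity-transform registration from grader-picked fiducial pairs.

Graders mark corresponding retinal vessel bifurcations in the MP-SLO and
FAF images; the least-squares similarity transform (translation, rotation,
isotropic scale — no shear, no reflection) mapping source to target pixels
is recovered in closed form from the centered point sets (orthogonal
Procrustes with scale). At least three non-collinear pairs are required,
all pairs weighted equally; there is no outlier rejection, mirroring the
manual few-curated-points workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateConfigurationError, InsufficientDataError, InvalidInputError

#: Collinearity tolerance: smallest/largest singular value of the centered
#: source configuration.
COLLINEARITY_TOL = 1e-6


@dataclass
class FiducialPairSet:
    """Matched fiducial coordinates for one eye picked by one grader."""

    source_px: np.ndarray  # (n, 2) MP-SLO pixels
    target_px: np.ndarray  # (n, 2) FAF pixels
    grader_id: str = ""
    eye_id: str = ""
    pair_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.source_px = np.asarray(self.source_px, dtype=float)
        self.target_px = np.asarray(self.target_px, dtype=float)
        if self.source_px.shape != self.target_px.shape or self.source_px.ndim != 2 \
                or self.source_px.shape[1] != 2:
            raise InvalidInputError("source and target must be matching (n, 2) arrays")
        if not (np.all(np.isfinite(self.source_px)) and np.all(np.isfinite(self.target_px))):
            raise InvalidInputError("non-finite fiducial coordinates")
        if self.pair_ids is None:
            self.pair_ids = np.arange(len(self.source_px))

    def __len__(self) -> int:
        return len(self.source_px)


@dataclass(frozen=True)
class SimilarityTransform:
    """p' = scale · R(rotation) · p + translation, with scale > 0 and det R = +1."""

    scale: float
    rotation: float  # radians, counterclockwise in the (x right, y down) pixel frame
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise InvalidInputError("scale must be positive")

    @property
    def rotation_matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return np.array([[c, -s], [s, c]])

    @property
    def linear(self) -> np.ndarray:
        return self.scale * self.rotation_matrix

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) or (2,) coordinate array; order preserved."""
        xy = np.asarray(points, dtype=float)
        if xy.shape[-1] != 2:
            raise InvalidInputError(f"expected (..., 2) array, got shape {xy.shape}")
        return xy @ self.linear.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        inv_lin = self.rotation_matrix.T / self.scale
        t = -inv_lin @ np.asarray(self.translation)
        return SimilarityTransform(1.0 / self.scale, -self.rotation, (float(t[0]), float(t[1])))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, 0.0, (0.0, 0.0))


def apply_transform(t: SimilarityTransform, points: np.ndarray) -> np.ndarray:
    return t.apply(points)


def invert_transform(t: SimilarityTransform) -> SimilarityTransform:
    return t.inverse()


@dataclass
class FitDiagnostics:
    """Per-fit quality measures returned alongside the transform."""

    residuals: np.ndarray  # (n,) per-pair target-frame residual norms
    rmse: float
    n_pairs: int
    warnings: list[str] = field(default_factory=list)


def fit_similarity(pairs: FiducialPairSet) -> tuple[SimilarityTransform, FitDiagnostics]:
    """Closed-form least-squares similarity fit (reflection disallowed).

    Both point sets are centroid-centered; the rotation comes from the SVD
    of the cross-covariance with the reflection branch forced to a proper
    rotation (a warning diagnostic is set when the data would prefer a
    reflection), and the scale from the trace formula. Minimizes the sum
    of squared target-frame residuals over all similarity transforms.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 pairs.
    DegenerateConfigurationError
        Collinear or coincident source points.
    """
    n = len(pairs)
    if n < 3:
        raise InsufficientDataError(f"similarity fit needs ≥ 3 fiducial pairs, got {n}")

    src, dst = pairs.source_px, pairs.target_px
    mu_s, mu_t = src.mean(axis=0), dst.mean(axis=0)
    x, y = src - mu_s, dst - mu_t

    sv = np.linalg.svd(x, compute_uv=False)
    if sv[0] == 0 or sv[-1] < COLLINEARITY_TOL * sv[0]:
        raise DegenerateConfigurationError(
            "source fiducials are collinear or coincident; pick spread-out bifurcations"
        )

    cov = y.T @ x / n
    u, d, vt = np.linalg.svd(cov)
    warnings: list[str] = []
    sgn = np.ones(2)
    if np.linalg.det(u @ vt) < 0:
        # Data favor a mirror image; fundus-to-fundus registration cannot
        # mirror, so return the best proper rotation and flag it.
        sgn[-1] = -1.0
        warnings.append("pair configuration favors a reflection; proper rotation forced")
    rot = u @ np.diag(sgn) @ vt
    var_s = float((x ** 2).sum()) / n
    scale = float(np.dot(d, sgn)) / var_s
    if scale <= 0:
        raise DegenerateConfigurationError("non-positive fitted scale; check pair correspondence")
    t = mu_t - scale * rot @ mu_s

    rotation = float(np.arctan2(rot[1, 0], rot[0, 0]))
    transform = SimilarityTransform(scale, rotation, (float(t[0]), float(t[1])))

    res = np.linalg.norm(transform.apply(src) - dst, axis=1)
    diag = FitDiagnostics(residuals=res, rmse=float(np.sqrt(np.mean(res ** 2))),
                          n_pairs=n, warnings=warnings)
    return transform, diag
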