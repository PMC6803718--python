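"""Point-distribution model (PDM) over aponeurosis landmark configurations.

A shape is an ordered set of 2D landmarks along three boundaries
(superficial, middle, deep) of one image frame.  The PDM is a PCA of the
concatenated coordinate vectors: mean shape plus orthonormal modes of
variation with associated eigenvalues.  Shapes are modelled in raw image
coordinates (no Procrustes alignment): the transducer is fixed to the limb,
so absolute image position is informative.

Conventions: 0-based pixel indexing, x = column, y = row (depth, increasing
downward), origin at the top-left corner of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_BOUNDARIES = 3
DEFAULT_LANDMARKS_PER_BOUNDARY = 19


@dataclass(frozen=True)
class AponeurosisShape:
    """Ordered landmarks for the three aponeurosis boundaries of one frame.

    Parameters
    ----------
    landmarks : ndarray, shape (n_boundaries * n_per_boundary, 2)
        ``(x, y)`` pixel coordinates, boundaries stored superficial, middle,
        deep; within each boundary x is strictly increasing.
    frame_index : int
        Frame the labels belong to.
    n_per_boundary : int
        Landmarks per boundary (default 19, giving 57 points / 114 coords).
    """

    landmarks: np.ndarray
    frame_index: int = 0
    n_per_boundary: int = DEFAULT_LANDMARKS_PER_BOUNDARY

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks, dtype=float)
        if lm.ndim != 2 or lm.shape[1] != 2:
            raise ValueError(f"landmarks must be (n, 2), got {lm.shape}")
        expected = N_BOUNDARIES * self.n_per_boundary
        if lm.shape[0] != expected:
            raise ValueError(
                f"expected {expected} landmarks "
                f"({N_BOUNDARIES} boundaries x {self.n_per_boundary}), got {lm.shape[0]}"
            )
        for b in range(N_BOUNDARIES):
            xs = lm[b * self.n_per_boundary : (b + 1) * self.n_per_boundary, 0]
            if not np.all(np.diff(xs) > 0):
                raise ValueError(f"boundary {b}: x coordinates must be strictly increasing")
        object.__setattr__(self, "landmarks", lm)

    @property
    def n_landmarks(self) -> int:
        return self.landmarks.shape[0]

    def boundary(self, index: int) -> np.ndarray:
        """Landmarks of one boundary (0 = superficial, 1 = middle, 2 = deep)."""
        if not 0 <= index < N_BOUNDARIES:
            raise IndexError(f"boundary index {index} out of range")
        n = self.n_per_boundary
        return self.landmarks[index * n : (index + 1) * n]

    def to_vector(self) -> np.ndarray:
        """Concatenated coordinate vector (x0, y0, x1, y1, ...)."""
        return self.landmarks.reshape(-1).copy()

    @classmethod
    def from_vector(
        cls, vec: np.ndarray, frame_index: int = 0, n_per_boundary: int | None = None
    ) -> "AponeurosisShape":
        vec = np.asarray(vec, dtype=float)
        n_pb = n_per_boundary
        if n_pb is None:
            n_pb = vec.size // (2 * N_BOUNDARIES)
        return cls(vec.reshape(-1, 2), frame_index=frame_index, n_per_boundary=n_pb)

    def with_landmarks(self, landmarks: np.ndarray) -> "AponeurosisShape":
        return AponeurosisShape(
            landmarks, frame_index=self.frame_index, n_per_boundary=self.n_per_boundary
        )


@dataclass(frozen=True)
class PointDistributionModel:
    """PCA shape model: mean + retained eigenvectors/eigenvalues.

    ``modes`` has one column per retained mode; columns are orthonormal and
    ``mode_variances`` (pixel^2) is non-increasing.  The retained mode count
    is the minimal number whose cumulative eigenvalue fraction reaches
    ``variance_retained``.
    """

    mean_shape: np.ndarray
    modes: np.ndarray
    mode_variances: np.ndarray
    variance_retained: float
    n_training: int
    n_per_boundary: int = DEFAULT_LANDMARKS_PER_BOUNDARY
    all_variances: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def mode_sd(self) -> np.ndarray:
        """Per-mode standard deviation, sqrt of eigenvalues."""
        return np.sqrt(self.mode_variances)


@dataclass(frozen=True)
class ShapeParams:
    """Mode coefficients of a shape in the PDM subspace."""

    b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float).reshape(-1))


def build_pdm(
    training_shapes: list[AponeurosisShape] | tuple[AponeurosisShape, ...],
    variance_target: float = 0.985,
) -> PointDistributionModel:
    """Build a point-distribution model from labelled training shapes.

    The sample covariance (``n - 1`` denominator) of the concatenated shape
    vectors is eigendecomposed; the minimal number of leading modes whose
    cumulative eigenvalue fraction reaches ``variance_target`` is retained
    (default 0.985).

    Raises
    ------
    ValueError
        Fewer than 2 training shapes, or inconsistent landmark counts.
    """
    shapes = list(training_shapes)
    if len(shapes) < 2:
        raise ValueError(f"need at least 2 training shapes, got {len(shapes)}")
    if not 0 < variance_target <= 1:
        raise ValueError(f"variance_target must be in (0, 1], got {variance_target}")
    n_lm = shapes[0].n_landmarks
    n_pb = shapes[0].n_per_boundary
    if any(s.n_landmarks != n_lm for s in shapes):
        raise ValueError("all training shapes must have the same landmark count")

    X = np.stack([s.to_vector() for s in shapes])  # (n, d)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (len(shapes) - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    total = eigvals.sum()
    # Identical training shapes leave only floating-point dust in the
    # covariance; treat that as exactly degenerate.
    if total <= 1e-18 * max(1.0, float(mean @ mean)):
        # Degenerate: all training shapes identical.
        return PointDistributionModel(
            mean_shape=mean,
            modes=np.empty((mean.size, 0)),
            mode_variances=np.empty(0),
            variance_retained=0.0,
            n_training=len(shapes),
            n_per_boundary=n_pb,
            all_variances=eigvals,
        )

    cumfrac = np.cumsum(eigvals) / total
    n_keep = int(np.searchsorted(cumfrac, variance_target - 1e-12) + 1)
    n_keep = min(n_keep, eigvals.size)
    return PointDistributionModel(
        mean_shape=mean,
        modes=eigvecs[:, :n_keep].copy(),
        mode_variances=eigvals[:n_keep].copy(),
        variance_retained=float(cumfrac[n_keep - 1]),
        n_training=len(shapes),
        n_per_boundary=n_pb,
        all_variances=eigvals,
    )


def params_from_shape(shape: AponeurosisShape, pdm: PointDistributionModel) -> ShapeParams:
    """Project a shape into the PDM subspace: ``b = P^T (x - mean)``."""
    vec = shape.to_vector()
    if vec.size != pdm.mean_shape.size:
        raise ValueError(
            f"landmark-count mismatch: shape has {vec.size} coords, model expects "
            f"{pdm.mean_shape.size}"
        )
    return ShapeParams(pdm.modes.T @ (vec - pdm.mean_shape))


def shape_from_params(
    params: ShapeParams, pdm: PointDistributionModel, frame_index: int = 0
) -> AponeurosisShape:
    """Reconstruct a shape from mode coefficients: ``x = mean + P b``."""
    if params.b.size != pdm.n_modes:
        raise ValueError(f"expected {pdm.n_modes} coefficients, got {params.b.size}")
    vec = pdm.mean_shape + pdm.modes @ params.b
    return AponeurosisShape.from_vector(vec, frame_index=frame_index, n_per_boundary=pdm.n_per_boundary)


def clip_params(params: ShapeParams, pdm: PointDistributionModel, sd_limit: float = 3.0) -> ShapeParams:
    """Clip each coefficient to ``[-sd_limit * sqrt(lambda_i), +sd_limit * sqrt(lambda_i)]``."""
    if sd_limit <= 0:
        raise ValueError(f"sd_limit must be positive, got {sd_limit}")
    bound = sd_limit * pdm.mode_sd()
    return ShapeParams(np.clip(params.b, -bound, bound))


def project_to_plausible(
    shape: AponeurosisShape, pdm: PointDistributionModel, sd_limit: float = 3.0
) -> AponeurosisShape:
    """Nearest plausible shape: subspace projection with coefficients clipped.

    Coefficients beyond ``sd_limit`` standard deviations of their mode are
    clipped to the limit; the shape is rebuilt from the clipped coefficients.
    Idempotent, and never increases any ``|b_i|``.
    """
    if pdm.n_modes == 0:
        return AponeurosisShape.from_vector(
            pdm.mean_shape, frame_index=shape.frame_index, n_per_boundary=pdm.n_per_boundary
        )
    b = clip_params(params_from_shape(shape, pdm), pdm, sd_limit)
    return shape_from_params(b, pdm, frame_index=shape.frame_index)
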