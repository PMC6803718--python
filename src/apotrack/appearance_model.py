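"""Per-landmark Gaussian models of normalized intensity-gradient profiles.

At each landmark a 1D intensity profile is sampled along the local normal,
differentiated (central differences) and L1-normalized; the profiles over
the training set are summarized by a mean vector and a regularized
covariance matrix, one model per landmark per image-pyramid level.
Candidate landmark positions are scored by the Mahalanobis distance of
their profile from the model, which is proportional (up to constants) to
the negative log-likelihood under the Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

DEFAULT_PROFILE_HALF_LENGTH = 2  # samples either side of the landmark


@dataclass(frozen=True)
class ImagePyramid:
    """Coarse-to-fine image stack; level 0 is full resolution.

    Each level is Gaussian-smoothed (sigma 1 px) and decimated by 2 per
    axis, so level ``L`` has dimensions ``ceil(shape / 2**L)``.  Landmark
    coordinates map between levels by division/multiplication by ``2**L``.
    """

    levels: tuple[np.ndarray, ...]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def scale(self, level: int) -> float:
        return float(2**level)


def build_pyramid(image: np.ndarray, n_levels: int, sigma: float = 1.0) -> ImagePyramid:
    """Build a multiresolution pyramid by smooth-then-decimate.

    Raises
    ------
    ValueError
        ``n_levels < 1``, empty image, or image smaller than
        ``2**(n_levels - 1)`` px in either axis.
    """
    image = np.asarray(image, dtype=float)
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2D array")
    min_dim = 2 ** (n_levels - 1)
    if min(image.shape) < min_dim:
        raise ValueError(
            f"image {image.shape} too small for {n_levels} levels (needs >= {min_dim} px per axis)"
        )
    levels = [image]
    for _ in range(n_levels - 1):
        smoothed = ndimage.gaussian_filter(levels[-1], sigma=sigma, mode="nearest")
        levels.append(smoothed[::2, ::2])
    return ImagePyramid(levels=tuple(levels))


def sample_intensities(image: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinear intensity lookup at fractional ``(x, y)`` positions.

    Out-of-bounds positions clamp to the nearest edge pixel.  ``points`` may
    have any leading shape; the last axis is (x, y).
    """
    pts = np.asarray(points, dtype=float)
    # map_coordinates wants (row, col) = (y, x)
    coords = np.stack([pts[..., 1].ravel(), pts[..., 0].ravel()])
    vals = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    return vals.reshape(pts.shape[:-1])


def profile_points(point: np.ndarray, normal: np.ndarray, k: int) -> np.ndarray:
    """Unit-spaced sampling positions along the normal, ``2k + 3`` of them.

    The extra sample at each end feeds the central finite difference.
    """
    offsets = np.arange(-(k + 1), k + 2, dtype=float)
    return np.asarray(point, dtype=float) + offsets[:, None] * np.asarray(normal, dtype=float)


def _normalize_gradient(grad: np.ndarray) -> np.ndarray:
    """L1-normalize gradient vectors along the last axis (zero stays zero)."""
    denom = np.sum(np.abs(grad), axis=-1, keepdims=True)
    out = np.zeros_like(grad)
    np.divide(grad, denom, out=out, where=denom > 0)
    return out


def sample_profile(
    image: np.ndarray,
    point: np.ndarray,
    normal: np.ndarray,
    k: int = DEFAULT_PROFILE_HALF_LENGTH,
) -> np.ndarray:
    """Normalized intensity-gradient profile at a landmark.

    Intensities are sampled by bilinear interpolation at ``2k + 3``
    unit-spaced positions along the normal; central differences give
    ``2k + 1`` gradient values, which are divided by the sum of their
    absolute values (all-zero profile if that sum is zero).

    Raises
    ------
    ValueError
        Degenerate (zero-length) normal vector.
    """
    normal = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(normal)
    if norm == 0:
        raise ValueError("normal vector must be non-zero")
    normal = normal / norm
    pts = profile_points(point, normal, k)
    intensities = sample_intensities(image, pts)
    grad = (intensities[2:] - intensities[:-2]) / 2.0
    return _normalize_gradient(grad)


def sample_profiles_batch(
    image: np.ndarray, points: np.ndarray, normals: np.ndarray, k: int
) -> np.ndarray:
    """Vectorized :func:`sample_profile` for many (point, normal) pairs.

    ``points``/``normals`` are (..., 2); normals must already be unit
    length.  Returns profiles of shape ``(..., 2k + 1)``.
    """
    points = np.asarray(points, dtype=float)
    normals = np.asarray(normals, dtype=float)
    offsets = np.arange(-(k + 1), k + 2, dtype=float)
    pts = points[..., None, :] + offsets[:, None] * normals[..., None, :]
    intensities = sample_intensities(image, pts)
    grad = (intensities[..., 2:] - intensities[..., :-2]) / 2.0
    return _normalize_gradient(grad)


@dataclass(frozen=True)
class ProfileModelSet:
    """Gaussian profile models, one per (pyramid level, landmark).

    ``means`` has shape (n_levels, n_landmarks, 2k+1); ``covariances`` has
    shape (n_levels, n_landmarks, 2k+1, 2k+1) and is symmetric
    positive-definite after adding ``epsilon * I``.  ``inv_covariances``
    caches the inverses for fast Mahalanobis scoring.
    """

    means: np.ndarray
    covariances: np.ndarray
    inv_covariances: np.ndarray
    epsilon: np.ndarray
    k: int

    @property
    def n_levels(self) -> int:
        return self.means.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.means.shape[1]

    def model(self, level: int, landmark: int) -> tuple[np.ndarray, np.ndarray]:
        """(mean, covariance) for one landmark at one level."""
        return self.means[level, landmark], self.covariances[level, landmark]


def landmark_normals(landmarks: np.ndarray, n_per_boundary: int) -> np.ndarray:
    """Unit normals at each landmark, per boundary.

    The normal at landmark ``i`` is perpendicular to the segment joining its
    neighbours ``i - 1`` and ``i + 1`` on the same boundary; endpoints use
    their single neighbour.  Normals are oriented toward increasing depth
    (positive y) for determinism.
    """
    landmarks = np.asarray(landmarks, dtype=float)
    n_b = landmarks.shape[0] // n_per_boundary
    normals = np.empty_like(landmarks)
    for b in range(n_b):
        pts = landmarks[b * n_per_boundary : (b + 1) * n_per_boundary]
        tangent = np.empty_like(pts)
        tangent[1:-1] = pts[2:] - pts[:-2]
        tangent[0] = pts[1] - pts[0]
        tangent[-1] = pts[-1] - pts[-2]
        nrm = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)
        lengths = np.linalg.norm(nrm, axis=1, keepdims=True)
        lengths[lengths == 0] = 1.0
        nrm /= lengths
        flip = nrm[:, 1] < 0
        nrm[flip] *= -1
        normals[b * n_per_boundary : (b + 1) * n_per_boundary] = nrm
    return normals


def train_profile_models(
    pyramids: list[ImagePyramid],
    shapes: list,
    k: int = DEFAULT_PROFILE_HALF_LENGTH,
    n_levels: int | None = None,
    epsilon_scale: float = 1e-6,
) -> ProfileModelSet:
    """Fit per-landmark, per-level Gaussian profile models from labelled frames.

    For every training frame, profiles are sampled at the labelled landmark
    positions (scaled by ``2**level``) on each pyramid level; the per-model
    sample mean and covariance (``n - 1`` denominator) are computed, and the
    covariance is regularized by ``epsilon * I`` with
    ``epsilon = epsilon_scale * mean(diag)`` (floored at ``epsilon_scale``
    for degenerate all-zero covariances).

    Raises
    ------
    ValueError
        Fewer than 2 training frames or mismatched pyramid depths.
    """
    if len(pyramids) < 2:
        raise ValueError(f"need at least 2 training frames, got {len(pyramids)}")
    if len(pyramids) != len(shapes):
        raise ValueError("one labelled shape per training pyramid required")
    if n_levels is None:
        n_levels = pyramids[0].n_levels
    if any(p.n_levels < n_levels for p in pyramids):
        raise ValueError(f"all pyramids must have at least {n_levels} levels")

    n_frames = len(pyramids)
    n_landmarks = shapes[0].n_landmarks
    p_len = 2 * k + 1
    profiles = np.empty((n_levels, n_frames, n_landmarks, p_len))
    for f, (pyr, shape) in enumerate(zip(pyramids, shapes)):
        normals = landmark_normals(shape.landmarks, shape.n_per_boundary)
        for lev in range(n_levels):
            pts = shape.landmarks / pyr.scale(lev)
            profiles[lev, f] = sample_profiles_batch(pyr.levels[lev], pts, normals, k)

    means = profiles.mean(axis=1)  # (levels, landmarks, p_len)
    centered = profiles - means[:, None]
    cov = np.einsum("lfni,lfnj->lnij", centered, centered) / (n_frames - 1)
    diag_mean = np.einsum("lnii->ln", cov) / p_len
    eps = epsilon_scale * np.maximum(diag_mean, 1.0)
    cov = cov + eps[..., None, None] * np.eye(p_len)
    inv = np.linalg.inv(cov)
    return ProfileModelSet(means=means, covariances=cov, inv_covariances=inv, epsilon=eps, k=k)


def mahalanobis(profile: np.ndarray, mean: np.ndarray, covariance: np.ndarray) -> float:
    """Squared Mahalanobis distance ``(g - m)^T S^-1 (g - m)``.

    Raises
    ------
    numpy.linalg.LinAlgError
        Singular covariance (should not occur after regularization); never
        silently pseudo-inverted.
    """
    profile = np.asarray(profile, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if profile.shape != mean.shape:
        raise ValueError(f"dimension mismatch: {profile.shape} vs {mean.shape}")
    diff = profile - mean
    sol = np.linalg.solve(covariance, diff)
    return float(diff @ sol)


def mahalanobis_batch(profiles: np.ndarray, mean: np.ndarray, inv_covariance: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distances for a stack of profiles (last axis = profile)."""
    diff = np.asarray(profiles, dtype=float) - mean
    return np.einsum("...i,ij,...j->...", diff, inv_covariance, diff)
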