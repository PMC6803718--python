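"""Coarse-to-fine active-shape-model search and sequence tracking.

Each landmark is moved along its local normal to the integer-offset
candidate minimizing the Mahalanobis distance of its normalized
intensity-gradient profile from the trained Gaussian model; after every
sweep the shape is pulled back to the plausible region of the
point-distribution model (coefficients within +/-3 SD).  The search runs
from the coarsest pyramid level to the finest; frame 0 of a sequence is
initialized by racing two searches started from the two training-trial mean
shapes, later frames start from the previous frame's fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from apotrack.appearance_model import (
    ImagePyramid,
    ProfileModelSet,
    landmark_normals,
    mahalanobis_batch,
    sample_profiles_batch,
)
from apotrack.shape_model import (
    AponeurosisShape,
    PointDistributionModel,
    project_to_plausible,
)


@dataclass(frozen=True)
class SearchConfig:
    """Tuning knobs for the landmark search.

    ``search_range`` is in pixels of the level being searched, so coarse
    levels cover proportionally larger full-resolution displacements.
    """

    search_range: int = 5
    max_iterations: int = 10
    convergence_fraction: float = 0.9
    n_levels_track: int = 4
    n_levels_init: int = 5
    sd_limit: float = 3.0

    def __post_init__(self) -> None:
        if self.search_range < 1 or self.max_iterations < 1:
            raise ValueError("search_range and max_iterations must be >= 1")
        if not 0 < self.convergence_fraction <= 1:
            raise ValueError("convergence_fraction must be in (0, 1]")
        if self.n_levels_track < 1 or self.n_levels_init < self.n_levels_track:
            raise ValueError("need n_levels_init >= n_levels_track >= 1")
        if self.sd_limit <= 0:
            raise ValueError("sd_limit must be positive")


@dataclass(frozen=True)
class FrameSegmentation:
    """Fit result for one frame."""

    shape: AponeurosisShape
    total_mahalanobis: float  # sum of per-landmark d^2 at the finest level
    n_iterations: int
    converged: bool
    accumulated_mahalanobis: float = 0.0  # summed over all landmarks and levels
    flags: tuple[str, ...] = field(default=())


def _candidate_scores(
    image: np.ndarray,
    points: np.ndarray,
    normals: np.ndarray,
    models: ProfileModelSet,
    level: int,
    search_range: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mahalanobis d^2 of every integer-offset candidate for every landmark.

    Returns ``(scores, offsets)`` with scores shaped
    ``(n_landmarks, 2 * search_range + 1)``; out-of-bounds candidates get
    ``+inf``.
    """
    offsets = np.arange(-search_range, search_range + 1, dtype=float)
    cand = points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    profiles = sample_profiles_batch(image, cand, np.broadcast_to(normals[:, None, :], cand.shape), models.k)
    n_lm = points.shape[0]
    scores = np.empty((n_lm, offsets.size))
    for i in range(n_lm):
        scores[i] = mahalanobis_batch(
            profiles[i], models.means[level, i], models.inv_covariances[level, i]
        )
    h, w = image.shape
    oob = (
        (cand[..., 0] < 0)
        | (cand[..., 0] > w - 1)
        | (cand[..., 1] < 0)
        | (cand[..., 1] > h - 1)
    )
    scores[oob] = np.inf
    return scores, offsets


def _select_offsets(scores: np.ndarray, offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Argmin per landmark with ties broken toward smaller |offset|, then negative.

    Landmarks whose candidates are all out of bounds keep offset 0 and are
    flagged.
    """
    order = np.lexsort((offsets, np.abs(offsets)))  # preference order for ties
    ranked = scores[:, order]
    best = np.argmin(ranked, axis=1)  # first occurrence wins = preferred tie-break
    chosen = offsets[order][best]
    all_oob = ~np.isfinite(scores).any(axis=1)
    chosen[all_oob] = 0.0
    return chosen, all_oob


def search_landmark(
    image: np.ndarray,
    point: np.ndarray,
    normal: np.ndarray,
    model_mean: np.ndarray,
    model_inv_cov: np.ndarray,
    search_range: int = 5,
    k: int | None = None,
) -> tuple[np.ndarray, float, bool]:
    """Move one landmark to the best candidate along its normal.

    Candidates are the ``2 * search_range + 1`` integer offsets; the one
    minimizing the profile Mahalanobis d^2 wins, ties broken toward smaller
    ``|offset|`` then toward the negative offset.  Returns
    ``(new_point, d2, out_of_bounds_flag)``; with every candidate out of
    bounds the landmark is left unmoved and flagged.
    """
    if k is None:
        k = (model_mean.shape[-1] - 1) // 2
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    point = np.asarray(point, dtype=float)
    offsets = np.arange(-search_range, search_range + 1, dtype=float)
    cand = point[None, :] + offsets[:, None] * normal[None, :]
    profiles = sample_profiles_batch(
        image, cand, np.broadcast_to(normal, cand.shape), k
    )
    scores = mahalanobis_batch(profiles, model_mean, model_inv_cov)
    h, w = image.shape
    oob = (
        (cand[:, 0] < 0) | (cand[:, 0] > w - 1) | (cand[:, 1] < 0) | (cand[:, 1] > h - 1)
    )
    scores = np.where(oob, np.inf, scores)
    if not np.isfinite(scores).any():
        return point.copy(), np.inf, True
    order = np.lexsort((offsets, np.abs(offsets)))
    best = order[np.argmin(scores[order])]
    return cand[best].copy(), float(scores[best]), False


def fit_frame(
    pyramid: ImagePyramid,
    init_shape: AponeurosisShape,
    models: ProfileModelSet,
    pdm: PointDistributionModel,
    config: SearchConfig | None = None,
    n_levels: int | None = None,
) -> FrameSegmentation:
    """Fit one frame by coarse-to-fine constrained landmark search.

    At each level (coarsest first) the search iterates {move every landmark
    to its best candidate, project the shape to the plausible region} until
    the convergence fraction of landmarks moves less than one level-pixel,
    or ``max_iterations`` is reached.  Never raises on a poor fit — quality
    is reported in the returned record.
    """
    if config is None:
        config = SearchConfig()
    if n_levels is None:
        n_levels = config.n_levels_track
    n_levels = min(n_levels, pyramid.n_levels, models.n_levels)

    shape = init_shape
    flags: list[str] = []
    total_iters = 0
    accumulated = 0.0
    final_d2 = 0.0
    converged_finest = False
    for level in range(n_levels - 1, -1, -1):
        image = pyramid.levels[level]
        scale = pyramid.scale(level)
        converged = False
        for _ in range(config.max_iterations):
            total_iters += 1
            normals = landmark_normals(shape.landmarks, shape.n_per_boundary)
            pts_level = shape.landmarks / scale
            scores, offsets = _candidate_scores(
                image, pts_level, normals, models, level, config.search_range
            )
            chosen, oob = _select_offsets(scores, offsets)
            if oob.any():
                flags.append(f"level{level}:out_of_bounds:{int(oob.sum())}")
            best_d2 = scores[np.arange(scores.shape[0]), np.searchsorted(offsets, chosen)]
            best_d2 = np.where(np.isfinite(best_d2), best_d2, 0.0)
            accumulated += float(best_d2.sum())
            final_d2 = float(best_d2.sum())
            moved = shape.landmarks + (chosen[:, None] * scale) * normals
            try:
                proposal = shape.with_landmarks(moved)
            except ValueError:
                # x-ordering broken by large lateral moves: keep previous shape,
                # constrain and continue.
                flags.append(f"level{level}:invalid_proposal")
                proposal = shape
            shape = project_to_plausible(proposal, pdm, config.sd_limit)
            if np.mean(np.abs(chosen) < 1.0) >= config.convergence_fraction:
                converged = True
                break
        if level == 0:
            converged_finest = converged
    return FrameSegmentation(
        shape=shape,
        total_mahalanobis=final_d2,
        n_iterations=total_iters,
        converged=converged_finest,
        accumulated_mahalanobis=accumulated,
        flags=tuple(flags),
    )


def initialize_first_frame(
    pyramid: ImagePyramid,
    pdm: PointDistributionModel,
    trial_mean_shapes: tuple[AponeurosisShape, AponeurosisShape],
    models: ProfileModelSet,
    config: SearchConfig | None = None,
) -> FrameSegmentation:
    """First-frame initialization: race two searches, keep the better one.

    One search starts from each training trial's mean shape, using the
    deeper initialization pyramid (``n_levels_init``); the result with the
    lowest Mahalanobis distance accumulated over all landmarks and all
    resolution levels is selected (ties go to the first candidate).
    """
    if config is None:
        config = SearchConfig()
    if len(trial_mean_shapes) != 2:
        raise ValueError(f"exactly two candidate mean shapes required, got {len(trial_mean_shapes)}")
    results = [
        fit_frame(pyramid, start, models, pdm, config, n_levels=config.n_levels_init)
        for start in trial_mean_shapes
    ]
    best = min(range(2), key=lambda i: results[i].accumulated_mahalanobis)
    return results[best]


def track_sequence(
    frames: np.ndarray,
    pdm: PointDistributionModel,
    models: ProfileModelSet,
    trial_mean_shapes: tuple[AponeurosisShape, AponeurosisShape],
    config: SearchConfig | None = None,
) -> list[FrameSegmentation]:
    """Segment every frame of a sequence.

    Frame 0 goes through :func:`initialize_first_frame`; each later frame is
    fitted starting from the previous frame's shape (identity motion prior)
    on the tracking pyramid depth.  Unconverged frames are flagged, never
    fatal.
    """
    from apotrack.appearance_model import build_pyramid

    if config is None:
        config = SearchConfig()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("frames must be a non-empty (n_frames, H, W) stack")

    results: list[FrameSegmentation] = []
    pyr0 = build_pyramid(frames[0], config.n_levels_init)
    results.append(initialize_first_frame(pyr0, pdm, trial_mean_shapes, models, config))
    for f in range(1, frames.shape[0]):
        pyr = build_pyramid(frames[f], config.n_levels_track)
        prev = results[-1].shape
        prev = AponeurosisShape(
            prev.landmarks, frame_index=f, n_per_boundary=prev.n_per_boundary
        )
        results.append(fit_frame(pyr, prev, models, pdm, config))
    return results
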