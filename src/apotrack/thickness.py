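"""Muscle thickness from aponeurosis fits, stride segmentation, normalization.

Thickness is the vertical (depth-axis) distance between the superficial and
deep boundary of a muscle, evaluated at 20 equally spaced sites across the
common x-span of the fitted boundaries and converted to mm with the pixel
pitch; the mean of the sites is carried alongside.  Strides are segmented
from the vertical ground-reaction force (threshold crossing with debounce),
each stride is linearly resampled to 200 nodes (0-100% stride cycle), and
the quiet-standing baseline is subtracted to give thickness change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from apotrack.shape_model import AponeurosisShape
from apotrack.synthdata import GrfTrace

DEFAULT_N_SITES = 20
DEFAULT_N_NODES = 200

#: muscle -> (superficial boundary index, deep boundary index) for the two
#: transducer views: the gastrocnemius lies between the superficial and
#: middle aponeurosis, soleus between middle and deep.
DEFAULT_BOUNDARY_MAP: dict[str, tuple[int, int]] = {
    "MG": (0, 1),
    "LG": (0, 1),
    "SO": (1, 2),
}


@dataclass(frozen=True)
class ThicknessSeries:
    """Per-frame thickness at the evaluation sites for one muscle."""

    muscle: str
    site_thickness: np.ndarray  # (n_frames, n_sites), mm
    mean_thickness: np.ndarray  # (n_frames,), mm
    site_x: np.ndarray  # (n_sites,), pixels
    pixel_pitch: float  # mm / pixel
    frame_times: np.ndarray  # (n_frames,), seconds
    crossing_flags: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        st = np.asarray(self.site_thickness, dtype=float)
        mt = np.asarray(self.mean_thickness, dtype=float)
        if not np.allclose(mt, st.mean(axis=1), atol=1e-10):
            raise ValueError("mean_thickness must equal the mean of the site values")
        if self.crossing_flags is None:
            object.__setattr__(self, "crossing_flags", st < 0)


@dataclass(frozen=True)
class StrideWindow:
    """Half-open stride interval [start, end) in seconds."""

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def interpolate_boundary(landmarks: np.ndarray, query_x: np.ndarray) -> np.ndarray:
    """Monotone piecewise-cubic (PCHIP) depth of a boundary at query columns.

    Passes exactly through the landmarks; reproduces straight lines.

    Raises
    ------
    ValueError
        Any query outside the landmark x-range (no extrapolation).
    """
    landmarks = np.asarray(landmarks, dtype=float)
    query_x = np.asarray(query_x, dtype=float)
    xs, ys = landmarks[:, 0], landmarks[:, 1]
    lo, hi = xs[0], xs[-1]
    if np.any(query_x < lo - 1e-9) or np.any(query_x > hi + 1e-9):
        raise ValueError(
            f"query x outside landmark span [{lo}, {hi}]; extrapolation not supported"
        )
    return PchipInterpolator(xs, ys)(np.clip(query_x, lo, hi))


def compute_thickness(
    shape: AponeurosisShape,
    muscle: str,
    boundary_map: dict[str, tuple[int, int]] | None = None,
    n_sites: int = DEFAULT_N_SITES,
    pixel_pitch: float = 1.0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Per-site and mean thickness (mm) of one muscle from one frame's fit.

    The ``n_sites`` evaluation x-positions are equally spaced over the
    common x-span of the muscle's two boundaries; thickness is the deep
    minus superficial interpolated depth at each site, times ``pixel_pitch``.
    Negative values (crossing boundaries) are retained but flagged.

    Returns ``(site_thickness_mm, mean_mm, site_x_px)``.
    """
    if boundary_map is None:
        boundary_map = DEFAULT_BOUNDARY_MAP
    if muscle not in boundary_map:
        raise KeyError(f"unknown muscle {muscle!r}; expected one of {sorted(boundary_map)}")
    sup_id, deep_id = boundary_map[muscle]
    sup = shape.boundary(sup_id)
    deep = shape.boundary(deep_id)
    x_lo = max(sup[0, 0], deep[0, 0])
    x_hi = min(sup[-1, 0], deep[-1, 0])
    if x_hi <= x_lo:
        raise ValueError("boundaries share no x-span")
    site_x = np.linspace(x_lo, x_hi, n_sites)
    thick_px = interpolate_boundary(deep, site_x) - interpolate_boundary(sup, site_x)
    thick_mm = thick_px * pixel_pitch
    return thick_mm, float(thick_mm.mean()), site_x


def thickness_series(
    shapes: list[AponeurosisShape],
    muscle: str,
    pixel_pitch: float,
    frame_times: np.ndarray | None = None,
    boundary_map: dict[str, tuple[int, int]] | None = None,
    n_sites: int = DEFAULT_N_SITES,
) -> ThicknessSeries:
    """Apply :func:`compute_thickness` to every frame of a tracked sequence."""
    if frame_times is None:
        frame_times = np.arange(len(shapes), dtype=float)
    rows = []
    site_x = None
    for shape in shapes:
        t_mm, _, sx = compute_thickness(shape, muscle, boundary_map, n_sites, pixel_pitch)
        rows.append(t_mm)
        site_x = sx
    st = np.stack(rows)
    return ThicknessSeries(
        muscle=muscle,
        site_thickness=st,
        mean_thickness=st.mean(axis=1),
        site_x=site_x,
        pixel_pitch=pixel_pitch,
        frame_times=np.asarray(frame_times, dtype=float),
    )


def detect_strides(
    grf: GrfTrace,
    force_threshold: float = 20.0,
    n_strides: int = 4,
    debounce_s: float = 0.05,
) -> list[StrideWindow]:
    """Segment strides from a vertical GRF trace.

    A foot strike is an upward crossing of the threshold preceded by at
    least ``debounce_s`` continuously below it; a stride is the half-open
    interval between consecutive strikes.  The first ``n_strides``
    consecutive strides are returned.

    Raises
    ------
    ValueError
        Fewer than ``n_strides + 1`` foot strikes found.
    """
    force = np.asarray(grf.vertical_force, dtype=float)
    t = np.asarray(grf.time, dtype=float)
    below = force < force_threshold
    min_gap = max(int(round(debounce_s * grf.sampling_rate)), 1)

    strikes = []
    run_below = 0
    prev_below = True
    for i in range(force.size):
        if below[i]:
            run_below += 1
            prev_below = True
        else:
            if prev_below and run_below >= min_gap:
                strikes.append(t[i])
            run_below = 0
            prev_below = False
    if len(strikes) < n_strides + 1:
        raise ValueError(
            f"insufficient strikes: found {len(strikes)}, need {n_strides + 1} "
            f"(threshold {force_threshold} N)"
        )
    return [
        StrideWindow(start=strikes[i], end=strikes[i + 1]) for i in range(n_strides)
    ]


def normalize_stride(
    values: np.ndarray,
    times: np.ndarray,
    window: StrideWindow,
    n_nodes: int = DEFAULT_N_NODES,
) -> np.ndarray:
    """Resample a frame time series onto ``n_nodes`` equally spaced stride nodes.

    Node 0 sits at the strike, node ``n_nodes - 1`` at
    ``end - duration / n_nodes`` (half-open interval).  ``values`` may be
    1D (one series) or 2D (n_frames, n_sites); linear interpolation per
    column.

    Raises
    ------
    ValueError
        Fewer than 2 frames inside the stride window.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    in_win = (times >= window.start) & (times < window.end)
    # Retain one bracketing frame each side so interpolation covers the window.
    idx = np.flatnonzero(in_win)
    if idx.size < 2:
        raise ValueError("stride window contains fewer than 2 frames")
    lo = max(idx[0] - 1, 0)
    hi = min(idx[-1] + 2, times.size)
    t_sel, v_sel = times[lo:hi], values[lo:hi]
    node_t = window.start + (window.duration / n_nodes) * np.arange(n_nodes)
    out = np.empty((n_nodes, values.shape[1]))
    for j in range(values.shape[1]):
        out[:, j] = np.interp(node_t, t_sel, v_sel[:, j])
    return out[:, 0] if squeeze else out


def standing_baseline(series: ThicknessSeries) -> np.ndarray:
    """Per-site standing thickness: mean over the standing trial's frames (mm)."""
    return series.site_thickness.mean(axis=0)


def subtract_baseline(normalized: np.ndarray, standing_thickness: np.ndarray) -> np.ndarray:
    """Thickness change: trial minus standing, per site per node.

    ``normalized`` is (n_nodes, n_sites); ``standing_thickness`` is
    (n_sites,).

    Raises
    ------
    ValueError
        Site-count mismatch.
    """
    normalized = np.asarray(normalized, dtype=float)
    standing = np.asarray(standing_thickness, dtype=float)
    if normalized.shape[-1] != standing.shape[0]:
        raise ValueError(
            f"site-count mismatch: trial has {normalized.shape[-1]}, standing has {standing.shape[0]}"
        )
    return normalized - standing


def stride_normalized_change(
    series: ThicknessSeries,
    grf: GrfTrace,
    standing: np.ndarray,
    n_strides: int = 4,
    n_nodes: int = DEFAULT_N_NODES,
    force_threshold: float = 20.0,
) -> np.ndarray:
    """Full per-trial pipeline: strides -> 200-node resampling -> baseline change.

    Returns an array of shape ``(n_strides, n_nodes, n_sites + 1)``; the
    last column is the mean-site series (mean of per-site changes).
    """
    windows = detect_strides(grf, force_threshold=force_threshold, n_strides=n_strides)
    out = np.empty((n_strides, n_nodes, series.site_thickness.shape[1] + 1))
    for s, win in enumerate(windows):
        norm = normalize_stride(series.site_thickness, series.frame_times, win, n_nodes)
        change = subtract_baseline(norm, standing)
        out[s, :, :-1] = change
        out[s, :, -1] = change.mean(axis=1)
    return out
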