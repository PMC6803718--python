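"""Synthetic phantoms with known ground truth for every downstream stage.

Three generator families:

* phantom ultrasound sequences — three bright, gently curved, time-varying
  bands (the aponeurosis boundaries) over a speckle-like background, with
  analytically known per-frame landmark positions;
* stride-periodic vertical ground-reaction-force traces with stance
  (half-sine bump) and flight (zero-force) phases and known event times;
* smooth 1D Gaussian random fields of controlled FWHM, optionally with
  injected region/condition effects, for statistics validation.

The depth axis is the image row index, increasing downward; all modules
share this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from apotrack.shape_model import AponeurosisShape

DEFAULT_LANDMARK_SPACING = 32  # px between landmark x-positions
DEFAULT_PIXEL_PITCH = 2.75 / 32  # mm per pixel


@dataclass(frozen=True)
class BoundaryCurve:
    """Parametric depth curve ``y(x, t)`` for one aponeurosis boundary.

    ``y(x, t) = poly(x) + curve_amplitude * sin(2 pi x / curve_period + curve_phase)
    + motion_amplitude * sin(2 pi t / motion_period + motion_phase)``

    with ``poly`` a polynomial in x (coefficients low order first) and ``t``
    the frame index.  Setting amplitudes to zero gives static polynomial
    boundaries; a constant term alone gives a flat band.
    """

    poly: tuple[float, ...] = (0.0,)
    curve_amplitude: float = 0.0
    curve_period: float = 256.0
    curve_phase: float = 0.0
    motion_amplitude: float = 0.0
    motion_period: float = 25.0
    motion_phase: float = 0.0

    def depth(self, x: np.ndarray, frame: float) -> np.ndarray:
        """Evaluate the boundary depth (row coordinate) at columns ``x``."""
        x = np.asarray(x, dtype=float)
        y = np.polynomial.polynomial.polyval(x, np.asarray(self.poly, dtype=float))
        if self.curve_amplitude:
            y = y + self.curve_amplitude * np.sin(
                2 * np.pi * x / self.curve_period + self.curve_phase
            )
        if self.motion_amplitude:
            y = y + self.motion_amplitude * np.sin(
                2 * np.pi * frame / self.motion_period + self.motion_phase
            )
        return y


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, appearance and noise parameters for a phantom sequence."""

    image_height: int = 352
    image_width: int = 608
    n_frames: int = 10
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    boundaries: tuple[BoundaryCurve, BoundaryCurve, BoundaryCurve] = (
        BoundaryCurve(poly=(60.0,)),
        BoundaryCurve(poly=(160.0,)),
        BoundaryCurve(poly=(260.0,)),
    )
    band_brightness: float = 0.8
    band_half_width: float = 3.0  # Gaussian ridge sigma-like half width, px
    background_brightness: float = 0.15
    speckle_snr: float = 0.0  # 0 disables multiplicative speckle
    additive_noise_sd: float = 0.0
    landmark_spacing: int = DEFAULT_LANDMARK_SPACING
    n_landmarks_per_boundary: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if len(self.boundaries) != 3:
            raise ValueError("exactly three boundary curves required")

    def landmark_x(self) -> np.ndarray:
        """The landmark x-positions: ``n`` columns separated by the spacing, centred."""
        n = self.n_landmarks_per_boundary
        span = (n - 1) * self.landmark_spacing
        if span >= self.image_width:
            raise ValueError(
                f"landmark span {span} px exceeds image width {self.image_width}"
            )
        x0 = (self.image_width - 1 - span) / 2.0
        return x0 + self.landmark_spacing * np.arange(n, dtype=float)


@dataclass(frozen=True)
class PhantomSequence:
    """Rendered frames plus the analytic truth landmarks they were drawn from."""

    frames: np.ndarray  # (n_frames, H, W), float in [0, 1]
    truth_shapes: tuple[AponeurosisShape, ...]
    config: PhantomConfig

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def truth_thickness_px(self, boundary_pair: tuple[int, int], x: np.ndarray, frame: int) -> np.ndarray:
        """Analytic vertical distance between two boundaries at columns ``x``."""
        sup, deep = boundary_pair
        cfg = self.config
        return cfg.boundaries[deep].depth(x, frame) - cfg.boundaries[sup].depth(x, frame)


def _validate_no_crossing(config: PhantomConfig) -> None:
    x = np.arange(config.image_width, dtype=float)
    for frame in range(config.n_frames):
        depths = [b.depth(x, frame) for b in config.boundaries]
        if np.any(depths[0] >= depths[1]) or np.any(depths[1] >= depths[2]):
            raise ValueError(
                f"boundary curves cross or touch at frame {frame}: boundaries must be "
                "ordered superficial < middle < deep at every x"
            )


def generate_phantom_sequence(config: PhantomConfig) -> PhantomSequence:
    """Render a phantom sequence with bright ridges along the true curves.

    Each boundary is drawn as a Gaussian-profiled ridge centred on its curve;
    multiplicative gamma speckle (mean 1, ``sd = 1 / speckle_snr``) and
    additive Gaussian noise are applied afterwards.  Deterministic given the
    config seed.

    Raises
    ------
    ValueError
        Boundary curves crossing anywhere in any frame.
    """
    _validate_no_crossing(config)
    rng = np.random.default_rng(config.seed)
    H, W = config.image_height, config.image_width
    rows = np.arange(H, dtype=float)[:, None]
    cols = np.arange(W, dtype=float)

    lx = config.landmark_x()
    frames = np.empty((config.n_frames, H, W))
    truth = []
    for f in range(config.n_frames):
        img = np.full((H, W), config.background_brightness)
        for b in config.boundaries:
            depth = b.depth(cols, f)[None, :]
            ridge = np.exp(-0.5 * ((rows - depth) / config.band_half_width) ** 2)
            img = np.maximum(img, config.band_brightness * ridge)
        if config.speckle_snr > 0:
            shape = config.speckle_snr**2
            img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)
        if config.additive_noise_sd > 0:
            img = img + rng.normal(0.0, config.additive_noise_sd, size=img.shape)
        frames[f] = np.clip(img, 0.0, 1.0)

        pts = []
        for b in config.boundaries:
            ys = b.depth(lx, f)
            pts.append(np.stack([lx, ys], axis=1))
        landmarks = np.concatenate(pts)
        if np.any(landmarks[:, 1] < 0) or np.any(landmarks[:, 1] > H - 1):
            raise ValueError(f"truth landmarks outside image bounds at frame {f}")
        truth.append(
            AponeurosisShape(
                landmarks, frame_index=f, n_per_boundary=config.n_landmarks_per_boundary
            )
        )
    return PhantomSequence(frames=frames, truth_shapes=tuple(truth), config=config)


@dataclass(frozen=True)
class GrfTrace:
    """Vertical ground-reaction-force trace with known foot-strike times."""

    time: np.ndarray  # seconds
    vertical_force: np.ndarray  # newtons, >= 0
    sampling_rate: float  # Hz
    true_event_times: np.ndarray  # stance-onset instants, strictly increasing


def generate_grf(
    stride_period: float,
    duty_factor: float,
    n_strides: int,
    sampling_rate: float = 2000.0,
    noise_sd: float = 0.0,
    peak_force: float = 1500.0,
    seed: int = 0,
) -> GrfTrace:
    """Synthesize a stride-periodic vertical GRF trace.

    Each stance phase is a positive half-sine bump of the given peak; swing
    phases are zero force (plus optional Gaussian noise, rectified at zero).
    ``true_event_times`` holds exactly the ``n_strides`` stride-onset
    instants; the rendered force trace additionally contains the closing
    foot strike after the last stride, so that ``n_strides`` complete
    stride intervals can be delimited downstream.

    Raises
    ------
    ValueError
        Non-positive period, duty factor outside (0, 1), or ``n_strides < 1``.
    """
    if stride_period <= 0:
        raise ValueError(f"stride_period must be positive, got {stride_period}")
    if not 0 < duty_factor < 1:
        raise ValueError(f"duty_factor must be in (0, 1), got {duty_factor}")
    if n_strides < 1:
        raise ValueError(f"n_strides must be >= 1, got {n_strides}")

    rng = np.random.default_rng(seed)
    lead = 0.25 * stride_period  # quiet lead-in before the first strike
    total = lead + (n_strides + 1) * stride_period
    n_samples = int(np.ceil(total * sampling_rate)) + 1
    t = np.arange(n_samples) / sampling_rate
    force = np.zeros(n_samples)
    stance_dur = duty_factor * stride_period
    all_onsets = lead + stride_period * np.arange(n_strides + 1)
    event_times = all_onsets[:n_strides]
    for onset in all_onsets:
        in_stance = (t >= onset) & (t < onset + stance_dur)
        phase = (t[in_stance] - onset) / stance_dur
        force[in_stance] += peak_force * np.sin(np.pi * phase)
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=n_samples)
    force = np.clip(force, 0.0, None)
    return GrfTrace(
        time=t,
        vertical_force=force,
        sampling_rate=sampling_rate,
        true_event_times=event_times,
    )


def generate_smooth_null_fields(
    n_fields: int,
    n_nodes: int,
    fwhm: float,
    sd: float = 1.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero-mean smooth Gaussian 1D fields with unit pointwise variance * sd.

    White Gaussian noise is circularly convolved with a Gaussian kernel of
    the requested FWHM and rescaled so the pointwise variance is exactly
    ``sd**2`` in expectation (division by the kernel's L2 norm).

    Raises
    ------
    ValueError
        ``fwhm <= 0`` or ``n_nodes < 2``.
    """
    if fwhm <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if sd == 0:
        return np.zeros((n_fields, n_nodes))
    sigma = fwhm / np.sqrt(8.0 * np.log(2.0))
    # Pad so circular wrap-around correlations do not alias into the field.
    pad = int(np.ceil(4 * sigma))
    n_total = n_nodes + 2 * pad
    half = n_total // 2
    lags = np.arange(n_total) - half
    kernel = np.exp(-0.5 * (lags / sigma) ** 2)
    kernel /= np.linalg.norm(kernel)
    white = rng.standard_normal((n_fields, n_total))
    smooth = np.fft.irfft(
        np.fft.rfft(white, axis=1) * np.fft.rfft(np.fft.ifftshift(kernel)), n=n_total, axis=1
    )
    return sd * smooth[:, pad : pad + n_nodes]


@dataclass(frozen=True)
class EffectFieldSet:
    """Fully labelled factorial field data with known injected effects."""

    observations: np.ndarray  # (n_obs, n_nodes)
    subject: np.ndarray  # (n_obs,) int labels
    region: np.ndarray
    condition: np.ndarray
    stride: np.ndarray
    region_offsets: np.ndarray  # (n_regions, n_nodes)
    condition_offsets: np.ndarray  # (n_conditions, n_nodes)
    subject_intercepts: np.ndarray  # (n_subjects,)


def generate_effect_fields(
    region_offsets: np.ndarray,
    condition_offsets: np.ndarray,
    n_subjects: int,
    n_strides: int = 1,
    noise_fwhm: float = 20.0,
    noise_sd: float = 1.0,
    subject_sd: float = 0.5,
    seed: int = 0,
) -> EffectFieldSet:
    """Simulate a full factorial region x condition x stride x subject design.

    Each observation = subject intercept + region curve + condition curve +
    smooth noise (FWHM ``noise_fwhm``, pointwise sd ``noise_sd``).  With
    ``noise_sd = 0`` the pointwise cell means exactly equal the injected sums.

    Raises
    ------
    ValueError
        Region and condition offset curves on different node grids.
    """
    region_offsets = np.atleast_2d(np.asarray(region_offsets, dtype=float))
    condition_offsets = np.atleast_2d(np.asarray(condition_offsets, dtype=float))
    if region_offsets.shape[1] != condition_offsets.shape[1]:
        raise ValueError(
            "region and condition offset curves must share the same node grid: "
            f"{region_offsets.shape[1]} vs {condition_offsets.shape[1]} nodes"
        )
    n_nodes = region_offsets.shape[1]
    n_regions = region_offsets.shape[0]
    n_conditions = condition_offsets.shape[0]
    rng = np.random.default_rng(seed)
    intercepts = rng.normal(0.0, subject_sd, size=n_subjects)

    n_obs = n_subjects * n_regions * n_conditions * n_strides
    if noise_sd > 0:
        noise = generate_smooth_null_fields(n_obs, n_nodes, noise_fwhm, sd=noise_sd, rng=rng)
    else:
        noise = np.zeros((n_obs, n_nodes))

    subj_l = np.empty(n_obs, dtype=int)
    reg_l = np.empty(n_obs, dtype=int)
    cond_l = np.empty(n_obs, dtype=int)
    str_l = np.empty(n_obs, dtype=int)
    obs = np.empty((n_obs, n_nodes))
    i = 0
    for s in range(n_subjects):
        for r in range(n_regions):
            for c in range(n_conditions):
                for st in range(n_strides):
                    obs[i] = intercepts[s] + region_offsets[r] + condition_offsets[c] + noise[i]
                    subj_l[i], reg_l[i], cond_l[i], str_l[i] = s, r, c, st
                    i += 1
    return EffectFieldSet(
        observations=obs,
        subject=subj_l,
        region=reg_l,
        condition=cond_l,
        stride=str_l,
        region_offsets=region_offsets,
        condition_offsets=condition_offsets,
        subject_intercepts=intercepts,
    )


def make_training_config(config: PhantomConfig, motion_phase_shift: float = np.pi / 2, seed_offset: int = 1000) -> PhantomConfig:
    """Variant config emulating a second labelled trial (phase-shifted motion)."""
    boundaries = tuple(
        replace(b, motion_phase=b.motion_phase + motion_phase_shift) for b in config.boundaries
    )
    return replace(config, boundaries=boundaries, seed=config.seed + seed_offset)
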