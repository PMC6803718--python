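"""File formats, run configuration and the end-to-end pipeline orchestration.

Formats
-------
* image sequences: multi-frame TIFF (or a directory of ordered PNGs) with a
  JSON sidecar carrying pixel pitch, config and truth landmarks;
* labels: JSON mapping frame index -> (3 x n x 2) coordinate array;
* trained model: a single JSON archive holding the PDM and profile models;
* GRF: two-column CSV ``time_s,force_N``;
* thickness: long-format CSV ``trial,muscle,stride,site,node,thickness_mm,change_mm``;
* SPM results: JSON with the statistic field, df, FWHM, threshold, clusters.

Every output file carries the hash of the run configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from apotrack import synthdata
from apotrack.appearance_model import ProfileModelSet, build_pyramid, train_profile_models
from apotrack.asm_search import SearchConfig, track_sequence
from apotrack.shape_model import AponeurosisShape, PointDistributionModel, build_pdm
from apotrack.synthdata import BoundaryCurve, GrfTrace, PhantomConfig
from apotrack import thickness as thick

SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Declarative defaults for a full simulate-train-track-thickness-spm run."""

    seed: int = 0
    image_height: int = 256
    image_width: int = 320
    n_frames: int = 64
    frame_rate_hz: float = 20.0
    pixel_pitch: float = synthdata.DEFAULT_PIXEL_PITCH
    landmark_spacing: int = 16
    n_landmarks_per_boundary: int = 19
    speckle_snr: float = 10.0
    motion_amplitude_px: float = 5.0
    training_stride: int = 2
    variance_target: float = 0.985
    profile_half_length: int = 2
    n_levels_track: int = 4
    n_levels_init: int = 5
    search_range: int = 5
    max_iterations: int = 10
    sd_limit: float = 3.0
    stride_period_s: float = 0.6
    duty_factor: float = 0.62
    n_strides: int = 4
    n_nodes: int = 200
    n_sites: int = 20
    force_threshold_n: float = 20.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        positive = (
            "image_height image_width n_frames frame_rate_hz pixel_pitch "
            "landmark_spacing n_landmarks_per_boundary training_stride "
            "variance_target profile_half_length n_levels_track n_levels_init "
            "search_range max_iterations sd_limit stride_period_s duty_factor "
            "n_strides n_nodes n_sites alpha"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.duty_factor < 1:
            raise ValueError("duty_factor must be in (0, 1)")
        if self.n_levels_init < self.n_levels_track:
            raise ValueError("n_levels_init must be >= n_levels_track")

    def frames_needed(self) -> int:
        """Frames required to cover the requested strides at the frame rate."""
        return int(np.ceil(self.n_strides * self.stride_period_s * self.frame_rate_hz)) + 2

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build from a plain mapping; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, for output provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML (or JSON) document."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data or {})


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------

def write_image_sequence(path: str | Path, frames: np.ndarray, pixel_pitch: float, extra: dict | None = None) -> None:
    """Write a float [0, 1] stack as 16-bit multi-frame TIFF plus JSON sidecar."""
    path = Path(path)
    frames = np.asarray(frames, dtype=float)
    data = np.round(np.clip(frames, 0, 1) * 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {"schema_version": SCHEMA_VERSION, "pixel_pitch_mm": pixel_pitch}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_image_sequence(path: str | Path, pixel_pitch: float | None = None) -> tuple[np.ndarray, dict]:
    """Read a multi-frame TIFF or a directory of ordered PNGs.

    Frames come back as grayscale float in [0, 1] (integer inputs divided by
    their dtype maximum, so 8- and 16-bit encodings of the same physical
    content agree).  Pixel pitch is taken from the JSON sidecar unless
    overridden.

    Raises
    ------
    FileNotFoundError / ValueError
        Missing or unreadable input; empty PNG directory.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("*.png"))
        if not files:
            raise ValueError(f"no PNG frames found in directory {path}")
        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    if frames.ndim == 4:  # RGB -> luminance by channel mean
        frames = frames.mean(axis=-1)
    if np.issubdtype(frames.dtype, np.integer):
        frames = frames.astype(float) / np.iinfo(frames.dtype).max
    else:
        frames = frames.astype(float)

    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if pixel_pitch is not None:
        meta["pixel_pitch_mm"] = pixel_pitch
    meta.setdefault("n_frames", int(frames.shape[0]))
    return frames, meta


# --------------------------------------------------------------------------
# labels and model archive
# --------------------------------------------------------------------------

def write_labels(path: str | Path, shapes: list[AponeurosisShape]) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "frames": {
            str(s.frame_index): s.landmarks.reshape(3, s.n_per_boundary, 2).tolist()
            for s in shapes
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_labels(path: str | Path) -> list[AponeurosisShape]:
    payload = json.loads(Path(path).read_text())
    shapes = []
    for key in sorted(payload["frames"], key=int):
        arr = np.asarray(payload["frames"][key], dtype=float)
        shapes.append(
            AponeurosisShape(
                arr.reshape(-1, 2), frame_index=int(key), n_per_boundary=arr.shape[1]
            )
        )
    return shapes


def write_model(path: str | Path, pdm: PointDistributionModel, profiles: ProfileModelSet, meta: dict | None = None) -> None:
    """Serialize the PDM + profile models into one JSON archive."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "pdm": {
            "mean_shape": pdm.mean_shape.tolist(),
            "modes": pdm.modes.tolist(),
            "mode_variances": pdm.mode_variances.tolist(),
            "variance_retained": pdm.variance_retained,
            "n_training": pdm.n_training,
            "n_per_boundary": pdm.n_per_boundary,
        },
        "profiles": {
            "means": profiles.means.tolist(),
            "covariances": profiles.covariances.tolist(),
            "epsilon": profiles.epsilon.tolist(),
            "k": profiles.k,
        },
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path: str | Path) -> tuple[PointDistributionModel, ProfileModelSet, dict]:
    payload = json.loads(Path(path).read_text())
    p = payload["pdm"]
    pdm = PointDistributionModel(
        mean_shape=np.asarray(p["mean_shape"]),
        modes=np.asarray(p["modes"]).reshape(len(p["mean_shape"]), -1),
        mode_variances=np.asarray(p["mode_variances"]),
        variance_retained=p["variance_retained"],
        n_training=p["n_training"],
        n_per_boundary=p["n_per_boundary"],
    )
    pr = payload["profiles"]
    cov = np.asarray(pr["covariances"])
    profiles = ProfileModelSet(
        means=np.asarray(pr["means"]),
        covariances=cov,
        inv_covariances=np.linalg.inv(cov),
        epsilon=np.asarray(pr["epsilon"]),
        k=int(pr["k"]),
    )
    return pdm, profiles, payload.get("meta", {})


# --------------------------------------------------------------------------
# GRF / thickness / SPM tables
# --------------------------------------------------------------------------

def write_grf(path: str | Path, grf: GrfTrace) -> None:
    pd.DataFrame({"time_s": grf.time, "force_N": grf.vertical_force}).to_csv(path, index=False)


def read_grf(path: str | Path, sampling_rate: float | None = None) -> GrfTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    if sampling_rate is None:
        sampling_rate = 1.0 / np.median(np.diff(t))
    return GrfTrace(
        time=t,
        vertical_force=df["force_N"].to_numpy(float),
        sampling_rate=float(sampling_rate),
        true_event_times=np.empty(0),
    )


def thickness_long_table(
    changes: np.ndarray,
    muscle: str,
    trial: str,
    thickness_abs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format table from a (n_strides, n_nodes, n_sites + 1) change array.

    Site labels are ``1..n_sites`` plus ``"mean"``.
    """
    n_strides, n_nodes, n_cols = changes.shape
    site_labels = [str(i + 1) for i in range(n_cols - 1)] + ["mean"]
    records = {
        "trial": np.repeat(trial, n_strides * n_nodes * n_cols),
        "muscle": np.repeat(muscle, n_strides * n_nodes * n_cols),
        "stride": np.repeat(np.arange(1, n_strides + 1), n_nodes * n_cols),
        "node": np.tile(np.repeat(np.arange(n_nodes), n_cols), n_strides),
        "site": np.tile(site_labels, n_strides * n_nodes),
        "change_mm": changes.reshape(-1),
    }
    if thickness_abs is not None:
        records["thickness_mm"] = thickness_abs.reshape(-1)
    return pd.DataFrame(records)


def write_spm_result(path: str | Path, result, config_hash: str = "") -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config_hash,
        "stat_kind": result.stat_kind,
        "stat": np.asarray(result.stat).tolist(),
        "df": list(result.df),
        "fwhm": result.fwhm,
        "critical_threshold": result.critical_threshold,
        "alpha": result.alpha,
        "clusters": [list(c) for c in result.clusters],
        "flags": list(result.flags),
    }
    Path(path).write_text(json.dumps(payload))


def read_spm_result(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# --------------------------------------------------------------------------
# pipeline orchestration
# --------------------------------------------------------------------------

def _phantom_config(cfg: RunConfig, motion: float, seed: int, n_frames: int | None = None) -> PhantomConfig:
    h = cfg.image_height
    period_frames = cfg.stride_period_s * cfg.frame_rate_hz
    rows = (0.2 * h, 0.5 * h, 0.8 * h)
    phases = (0.0, 0.7, 1.3)
    boundaries = tuple(
        BoundaryCurve(
            poly=(row, 0.01 * (i - 1)),
            curve_amplitude=2.0,
            curve_period=cfg.image_width * 0.9,
            curve_phase=phases[i],
            motion_amplitude=motion * (0.4 + 0.3 * i),
            motion_period=period_frames,
            motion_phase=phases[i],
        )
        for i, row in enumerate(rows)
    )
    return PhantomConfig(
        image_height=cfg.image_height,
        image_width=cfg.image_width,
        n_frames=cfg.n_frames if n_frames is None else n_frames,
        pixel_pitch=cfg.pixel_pitch,
        boundaries=boundaries,
        speckle_snr=cfg.speckle_snr,
        landmark_spacing=cfg.landmark_spacing,
        n_landmarks_per_boundary=cfg.n_landmarks_per_boundary,
        seed=seed,
    )


def train_from_sequences(
    sequences: list[synthdata.PhantomSequence],
    cfg: RunConfig,
) -> tuple[PointDistributionModel, ProfileModelSet, tuple[AponeurosisShape, AponeurosisShape]]:
    """Emulate hand labelling: subsample truth frames, build PDM + profile models."""
    all_shapes: list[AponeurosisShape] = []
    pyramids = []
    trial_means = []
    for seq in sequences:
        shapes = list(seq.truth_shapes[:: cfg.training_stride])
        all_shapes.extend(shapes)
        pyramids.extend(
            build_pyramid(seq.frames[s.frame_index], cfg.n_levels_init) for s in shapes
        )
        mean_vec = np.mean([s.to_vector() for s in shapes], axis=0)
        trial_means.append(AponeurosisShape.from_vector(mean_vec, n_per_boundary=shapes[0].n_per_boundary))
    pdm = build_pdm(all_shapes, cfg.variance_target)
    profiles = train_profile_models(
        pyramids, all_shapes, k=cfg.profile_half_length, n_levels=cfg.n_levels_init
    )
    return pdm, profiles, (trial_means[0], trial_means[1])


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute simulate -> train -> track -> thickness -> spm on phantom data.

    Deterministic given ``config.seed`` (a single root seed derives every
    stage seed).  Returns a summary dict; all artifacts are written under
    ``outdir`` tagged with the config hash.

    Raises
    ------
    ValueError
        Invalid configuration (checked before any computation).
    """
    from apotrack import spm as spm_mod

    if config.n_frames < config.frames_needed():
        raise ValueError(
            f"n_frames={config.n_frames} cannot cover {config.n_strides} strides of "
            f"{config.stride_period_s} s at {config.frame_rate_hz} Hz "
            f"(need >= {config.frames_needed()})"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.digest()
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=8)

    # --- simulate ---------------------------------------------------------
    trial_a = synthdata.generate_phantom_sequence(
        _phantom_config(config, config.motion_amplitude_px, int(seeds[0]))
    )
    trial_b_cfg = synthdata.make_training_config(
        _phantom_config(config, config.motion_amplitude_px, int(seeds[1]))
    )
    trial_b = synthdata.generate_phantom_sequence(trial_b_cfg)
    main_seq = synthdata.generate_phantom_sequence(
        _phantom_config(config, config.motion_amplitude_px, int(seeds[2]))
    )
    standing_seq = synthdata.generate_phantom_sequence(
        _phantom_config(config, 0.0, int(seeds[3]), n_frames=max(2, config.n_frames // 8))
    )
    grf = synthdata.generate_grf(
        stride_period=config.stride_period_s,
        duty_factor=config.duty_factor,
        n_strides=config.n_strides,
        seed=int(seeds[4]),
    )
    write_image_sequence(
        outdir / "phantom.tiff",
        main_seq.frames,
        config.pixel_pitch,
        extra={"config_hash": chash},
    )
    write_grf(outdir / "grf.csv", grf)

    # --- train ------------------------------------------------------------
    pdm, profiles, trial_means = train_from_sequences([trial_a, trial_b], config)
    write_model(outdir / "model.json", pdm, profiles, meta={"config_hash": chash})

    # --- track ------------------------------------------------------------
    search_cfg = SearchConfig(
        search_range=config.search_range,
        max_iterations=config.max_iterations,
        n_levels_track=config.n_levels_track,
        n_levels_init=config.n_levels_init,
        sd_limit=config.sd_limit,
    )
    fits = track_sequence(main_seq.frames, pdm, profiles, trial_means, search_cfg)
    standing_fits = track_sequence(standing_seq.frames, pdm, profiles, trial_means, search_cfg)
    fits_payload = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": chash,
        "frames": [
            {
                "landmarks": f.shape.landmarks.tolist(),
                "total_mahalanobis": f.total_mahalanobis,
                "n_iterations": f.n_iterations,
                "converged": f.converged,
                "flags": list(f.flags),
            }
            for f in fits
        ],
    }
    (outdir / "fits.json").write_text(json.dumps(fits_payload))

    # --- thickness --------------------------------------------------------
    # Frame timestamps start at the first detected strike so the tracked
    # window covers the requested strides.
    windows = thick.detect_strides(grf, config.force_threshold_n, config.n_strides)
    frame_times = windows[0].start + np.arange(config.n_frames) / config.frame_rate_hz
    tables = []
    stride_stacks = {}
    for muscle in ("LG", "SO"):
        series = thick.thickness_series(
            [f.shape for f in fits], muscle, config.pixel_pitch, frame_times,
            n_sites=config.n_sites,
        )
        standing_series = thick.thickness_series(
            [f.shape for f in standing_fits], muscle, config.pixel_pitch,
            n_sites=config.n_sites,
        )
        standing = thick.standing_baseline(standing_series)
        changes = thick.stride_normalized_change(
            series, grf, standing,
            n_strides=config.n_strides, n_nodes=config.n_nodes,
            force_threshold=config.force_threshold_n,
        )
        stride_stacks[muscle] = changes
        tables.append(thickness_long_table(changes, muscle, trial="phantom"))
    table = pd.concat(tables, ignore_index=True)
    table.insert(0, "config_hash", chash)
    table.to_csv(outdir / "thickness.csv", index=False)

    # --- spm --------------------------------------------------------------
    # Demo-scale inference: region (site) effect with strides as the
    # blocking units of the single phantom "participant".
    changes = stride_stacks["SO"]  # (strides, nodes, sites + 1)
    n_strides, n_nodes, n_cols = changes.shape
    n_sites = n_cols - 1
    obs = changes[:, :, :n_sites].transpose(0, 2, 1).reshape(-1, n_nodes)
    design = spm_mod.FieldDesign(
        observations=obs,
        subject=np.repeat(np.arange(n_strides), n_sites),
        region=np.tile(np.arange(n_sites), n_strides),
        condition=np.zeros(n_strides * n_sites, dtype=int),
        stride=np.zeros(n_strides * n_sites, dtype=int),
    )
    spm_result = spm_mod.spm_anova(design, effect="region", alpha=config.alpha)
    write_spm_result(outdir / "spm.json", spm_result, config_hash=chash)

    rms_err = _phantom_rms_error(main_seq, fits)
    summary = {
        "config_hash": chash,
        "n_frames": int(main_seq.n_frames),
        "n_converged": int(sum(f.converged for f in fits)),
        "landmark_rms_error_px": rms_err,
        "spm_clusters": [list(c) for c in spm_result.clusters],
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _phantom_rms_error(seq: synthdata.PhantomSequence, fits) -> float:
    errs = [
        fit.shape.landmarks - truth.landmarks
        for fit, truth in zip(fits, seq.truth_shapes)
    ]
    return float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))
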