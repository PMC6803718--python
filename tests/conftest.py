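import numpy as np
import pytest

from apotrack.io import RunConfig, _phantom_config, train_from_sequences
from apotrack import synthdata as sd
from apotrack.asm_search import SearchConfig, track_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_shapes(rng, n_shapes, n_per_boundary=19, jitter=3.0):
    """Valid random training shapes: jittered depths, fixed x grid."""
    from apotrack.shape_model import AponeurosisShape

    x = 10.0 + 32.0 * np.arange(n_per_boundary)
    shapes = []
    for i in range(n_shapes):
        pts = []
        for b, base in enumerate((60.0, 160.0, 260.0)):
            y = base + rng.normal(0, jitter, size=n_per_boundary)
            pts.append(np.stack([x, y], axis=1))
        shapes.append(
            AponeurosisShape(np.concatenate(pts), frame_index=i, n_per_boundary=n_per_boundary)
        )
    return shapes


@pytest.fixture(scope="session")
def tracked_phantom_factory():
    """Simulate + train + track a small phantom once per (seed, snr, frames)."""
    cache = {}

    def factory(seed=3, speckle_snr=0.0, n_frames=50):
        key = (seed, speckle_snr, n_frames)
        if key not in cache:
            cfg = RunConfig(seed=seed, n_frames=n_frames, speckle_snr=speckle_snr)
            trial_a = sd.generate_phantom_sequence(
                _phantom_config(cfg, cfg.motion_amplitude_px, seed + 11)
            )
            trial_b = sd.generate_phantom_sequence(
                sd.make_training_config(_phantom_config(cfg, cfg.motion_amplitude_px, seed + 12))
            )
            main = sd.generate_phantom_sequence(
                _phantom_config(cfg, cfg.motion_amplitude_px, seed + 13)
            )
            pdm, profiles, means = train_from_sequences([trial_a, trial_b], cfg)
            fits = track_sequence(main.frames, pdm, profiles, means, SearchConfig())
            cache[key] = dict(
                cfg=cfg, main=main, pdm=pdm, profiles=profiles, means=means, fits=fits
            )
        return cache[key]

    return factory
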