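import numpy as np
import pytest

from apotrack import appearance_model as am
from apotrack import asm_search as asm
from apotrack import shape_model as sm
from apotrack import synthdata as sd
from apotrack.io import RunConfig, _phantom_config, train_from_sequences
from tests.test_synthdata import flat_config


def brute_force_search(image, point, normal, mean, cov, search_range):
    """Independent enumeration oracle with the documented tie-breaks."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    h, w = image.shape
    best = None
    for off in range(-search_range, search_range + 1):
        cand = np.asarray(point, float) + off * normal
        if not (0 <= cand[0] <= w - 1 and 0 <= cand[1] <= h - 1):
            continue
        prof = am.sample_profile(image, cand, normal, k=(mean.size - 1) // 2)
        d2 = am.mahalanobis(prof, mean, cov)
        key = (d2, abs(off), off)
        if best is None or key < best[0]:
            best = (key, cand, d2)
    if best is None:
        return np.asarray(point, float), np.inf, True
    return best[1], best[2], False


def random_spd(rng, n=5):
    a = rng.normal(size=(n, n))
    return a @ a.T + 0.3 * np.eye(n)


class TestSearchLandmark:
    def test_current_minimizer_unmoved(self):
        """Constant image: every candidate ties at d2 of the zero profile; the
        zero-offset tie-break keeps the landmark in place."""
        img = np.full((32, 32), 0.5)
        mean = np.zeros(5)
        cov = np.eye(5)
        pt, d2, oob = asm.search_landmark(img, (16.0, 16.0), (0.0, 1.0), mean, np.linalg.inv(cov))
        np.testing.assert_allclose(pt, (16.0, 16.0))
        assert not oob

    def test_step_edge_recovered_from_offset(self):
        img = np.zeros((64, 64))
        img[32:, :] = 1.0
        edge_pt = np.array([30.0, 31.5])
        normal = np.array([0.0, 1.0])
        prof_on_edge = am.sample_profile(img, edge_pt, normal)
        cov = np.linalg.inv(0.01 * np.eye(5))
        pt, d2, _ = asm.search_landmark(img, edge_pt + [0, 3.0], normal, prof_on_edge, cov)
        np.testing.assert_allclose(pt, edge_pt, atol=1e-9)
        assert d2 == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            img = rng.random((24, 24))
            pt = rng.uniform(4, 20, size=2)
            normal = rng.normal(size=2)
            while np.linalg.norm(normal) < 1e-6:
                normal = rng.normal(size=2)
            mean = rng.normal(size=5)
            cov = random_spd(rng)
            got_pt, got_d2, got_oob = asm.search_landmark(
                img, pt, normal, mean, np.linalg.inv(cov), search_range=5
            )
            exp_pt, exp_d2, exp_oob = brute_force_search(img, pt, normal, mean, cov, 5)
            np.testing.assert_allclose(got_pt, exp_pt, atol=1e-9)
            assert got_d2 == pytest.approx(exp_d2, rel=1e-8)
            assert got_oob == exp_oob

    def test_all_candidates_out_of_bounds_flagged(self, rng):
        img = rng.random((40, 40))
        pt = np.array([-50.0, -50.0])
        got_pt, d2, oob = asm.search_landmark(img, pt, (0.0, 1.0), np.zeros(5), np.eye(5))
        assert oob
        np.testing.assert_array_equal(got_pt, pt)


class TestSearchConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            asm.SearchConfig(search_range=0)
        with pytest.raises(ValueError):
            asm.SearchConfig(n_levels_init=2, n_levels_track=4)
        with pytest.raises(ValueError):
            asm.SearchConfig(sd_limit=-1.0)


@pytest.fixture(scope="module")
def trained_noiseless():
    cfg = RunConfig(seed=21, n_frames=24, speckle_snr=0.0)
    trial_a = sd.generate_phantom_sequence(_phantom_config(cfg, cfg.motion_amplitude_px, 31))
    trial_b = sd.generate_phantom_sequence(
        sd.make_training_config(_phantom_config(cfg, cfg.motion_amplitude_px, 32))
    )
    main = sd.generate_phantom_sequence(_phantom_config(cfg, cfg.motion_amplitude_px, 33))
    pdm, profiles, means = train_from_sequences([trial_a, trial_b], cfg)
    return cfg, main, pdm, profiles, means


class TestFitFrame:
    def test_truth_init_is_near_fixed_point(self, trained_noiseless):
        cfg, main, pdm, profiles, means = trained_noiseless
        pyr = am.build_pyramid(main.frames[0], 4)
        fit = asm.fit_frame(pyr, main.truth_shapes[0], profiles, pdm)
        assert fit.converged
        rms = np.sqrt(np.mean((fit.shape.landmarks - main.truth_shapes[0].landmarks) ** 2))
        assert rms < 0.5

    def test_depth_shift_basin_of_attraction(self, trained_noiseless):
        cfg, main, pdm, profiles, means = trained_noiseless
        pyr = am.build_pyramid(main.frames[0], 4)
        shifted = main.truth_shapes[0].with_landmarks(
            main.truth_shapes[0].landmarks + [0.0, 8.0]
        )
        fit = asm.fit_frame(pyr, shifted, profiles, pdm)
        rms = np.sqrt(np.mean((fit.shape.landmarks - main.truth_shapes[0].landmarks) ** 2))
        assert rms < 1.5

    def test_tiny_sd_limit_returns_mean_shape(self, trained_noiseless):
        cfg, main, pdm, profiles, means = trained_noiseless
        pyr = am.build_pyramid(main.frames[0], 4)
        config = asm.SearchConfig(sd_limit=1e-9)
        fit = asm.fit_frame(pyr, main.truth_shapes[0], profiles, pdm, config)
        np.testing.assert_allclose(
            fit.shape.to_vector(), pdm.mean_shape, atol=1e-6
        )

    def test_result_within_plausible_region(self, trained_noiseless):
        cfg, main, pdm, profiles, means = trained_noiseless
        pyr = am.build_pyramid(main.frames[1], 4)
        fit = asm.fit_frame(pyr, means[0], profiles, pdm)
        b = sm.params_from_shape(fit.shape, pdm).b
        bounds = 3.0 * pdm.mode_sd()
        assert np.all(np.abs(b) <= bounds + 1e-6)
        assert fit.total_mahalanobis >= 0


class TestInitializeFirstFrame:
    def test_identical_starts_returns_first(self, trained_noiseless):
        cfg, main, pdm, profiles, means = trained_noiseless
        pyr = am.build_pyramid(main.frames[0], 5)
        fit = asm.initialize_first_frame(pyr, pdm, (means[0], means[0]), profiles)
        ref = asm.fit_frame(pyr, means[0], profiles, pdm, n_levels=5)
        np.testing.assert_allclose(fit.shape.landmarks, ref.shape.landmarks)

    def test_truth_start_beats_displaced_start(self, trained_noiseless):
        cfg, main, pdm, profiles, means = trained_noiseless
        pyr = am.build_pyramid(main.frames[0], 5)
        truth = main.truth_shapes[0]
        displaced = truth.with_landmarks(truth.landmarks + [0.0, 30.0])
        fit = asm.initialize_first_frame(pyr, pdm, (truth, displaced), profiles)
        truth_fit = asm.fit_frame(pyr, truth, profiles, pdm, n_levels=5)
        np.testing.assert_allclose(fit.shape.landmarks, truth_fit.shape.landmarks)

    def test_selection_is_argmin_of_accumulated_scores(self, trained_noiseless):
        cfg, main, pdm, profiles, means = trained_noiseless
        pyr = am.build_pyramid(main.frames[0], 5)
        results = [
            asm.fit_frame(pyr, start, profiles, pdm, n_levels=5) for start in means
        ]
        chosen = asm.initialize_first_frame(pyr, pdm, means, profiles)
        best = min(results, key=lambda r: r.accumulated_mahalanobis)
        assert chosen.accumulated_mahalanobis == pytest.approx(best.accumulated_mahalanobis)

    def test_requires_exactly_two_starts(self, trained_noiseless):
        cfg, main, pdm, profiles, means = trained_noiseless
        pyr = am.build_pyramid(main.frames[0], 5)
        with pytest.raises(ValueError, match="two"):
            asm.initialize_first_frame(pyr, pdm, (means[0],), profiles)


class TestTrackSequence:
    def test_single_frame_equals_initialization(self, trained_noiseless):
        cfg, main, pdm, profiles, means = trained_noiseless
        fits = asm.track_sequence(main.frames[:1], pdm, profiles, means)
        pyr = am.build_pyramid(main.frames[0], 5)
        ref = asm.initialize_first_frame(pyr, pdm, means, profiles)
        assert len(fits) == 1
        np.testing.assert_allclose(fits[0].shape.landmarks, ref.shape.landmarks)

    def test_phantom_ground_truth_recovery(self, tracked_phantom_factory):
        data = tracked_phantom_factory(seed=3, speckle_snr=0.0, n_frames=50)
        errs = [
            np.sqrt(np.mean((f.shape.landmarks - t.landmarks) ** 2))
            for f, t in zip(data["fits"], data["main"].truth_shapes)
        ]
        assert np.mean(np.asarray(errs) < 1.5) >= 0.95

    def test_static_phantom_stationary_after_first_frame(self):
        cfg = RunConfig(seed=8, n_frames=6, speckle_snr=0.0, motion_amplitude_px=5.0)
        trial_a = sd.generate_phantom_sequence(_phantom_config(cfg, 5.0, 41))
        trial_b = sd.generate_phantom_sequence(
            sd.make_training_config(_phantom_config(cfg, 5.0, 42))
        )
        static = sd.generate_phantom_sequence(_phantom_config(cfg, 0.0, 43))
        pdm, profiles, means = train_from_sequences([trial_a, trial_b], cfg)
        fits = asm.track_sequence(static.frames, pdm, profiles, means)
        for prev, cur in zip(fits[1:-1], fits[2:]):
            rms = np.sqrt(np.mean((cur.shape.landmarks - prev.shape.landmarks) ** 2))
            assert rms < 0.5

    def test_every_tracked_shape_plausible(self, tracked_phantom_factory):
        data = tracked_phantom_factory(seed=3, speckle_snr=10.0, n_frames=50)
        pdm = data["pdm"]
        bounds = 3.0 * pdm.mode_sd()
        for fit in data["fits"]:
            b = sm.params_from_shape(fit.shape, pdm).b
            assert np.all(np.abs(b) <= bounds + 1e-6)

    def test_empty_sequence_rejected(self, trained_noiseless):
        cfg, main, pdm, profiles, means = trained_noiseless
        with pytest.raises(ValueError, match="non-empty"):
            asm.track_sequence(np.empty((0, 64, 64)), pdm, profiles, means)
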