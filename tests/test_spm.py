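import numpy as np
import pytest
from scipy import stats

from apotrack import spm
from apotrack import synthdata as sd


def make_design(values, n_nodes=1):
    """FieldDesign from a (subjects, regions, conditions) array, constant fields."""
    ns, na, nb = values.shape
    obs = np.repeat(values.reshape(-1)[:, None], n_nodes, axis=1)
    return spm.FieldDesign(
        observations=obs,
        subject=np.repeat(np.arange(ns), na * nb),
        region=np.tile(np.repeat(np.arange(na), nb), ns),
        condition=np.tile(np.arange(nb), ns * na),
        stride=np.zeros(ns * na * nb, dtype=int),
    )


class TestFieldDesign:
    def test_unbalanced_rejected(self, rng):
        obs = rng.random((5, 10))
        with pytest.raises(ValueError, match="unbalanced"):
            spm.FieldDesign(
                observations=obs,
                subject=np.array([0, 0, 1, 1, 1]),
                region=np.zeros(5, dtype=int),
                condition=np.array([0, 1, 0, 1, 1]),
                stride=np.zeros(5, dtype=int),
            )

    def test_cell_means_average_strides(self, rng):
        obs = np.vstack([np.full((1, 4), 1.0), np.full((1, 4), 3.0),
                         np.full((1, 4), 5.0), np.full((1, 4), 7.0)])
        design = spm.FieldDesign(
            observations=obs,
            subject=np.array([0, 0, 1, 1]),
            region=np.zeros(4, dtype=int),
            condition=np.zeros(4, dtype=int),
            stride=np.array([0, 1, 0, 1]),
        )
        cells = design.cell_means()
        np.testing.assert_allclose(cells[:, 0, 0, 0], [2.0, 6.0])


class TestPointwiseRmAnova:
    def test_constant_factor_gives_zero_f(self, rng):
        vals = rng.normal(size=(5, 1, 3)) * np.ones((5, 4, 3))  # no region variation
        f, df = spm.pointwise_rm_anova(make_design(vals, 8), "region")
        np.testing.assert_array_equal(f, 0.0)

    def test_matches_pingouin_0d_oracle(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        vals = rng.normal(size=(6, 3, 2))
        design = make_design(vals, n_nodes=4)
        rows = [
            dict(subject=s, region=a, condition=b, y=vals[s, a, b])
            for s in range(6) for a in range(3) for b in range(2)
        ]
        aov = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["region", "condition"],
            subject="subject", detailed=True,
        ).set_index("Source")
        for effect, source in (
            ("region", "region"), ("condition", "condition"), ("interaction", "region * condition")
        ):
            f, df = spm.pointwise_rm_anova(design, effect)
            expected = float(aov.loc[source, "F"])
            np.testing.assert_allclose(f, expected, rtol=1e-6)
            assert df == (int(aov.loc[source, "ddof1"]), int(aov.loc[source, "ddof2"]))

    def test_noiseless_effect_gives_huge_f_at_affected_nodes(self):
        n_nodes = 50
        reg = np.zeros((3, n_nodes))
        reg[0, 10:20] = 2.0
        data = sd.generate_effect_fields(
            reg, np.zeros((2, n_nodes)), n_subjects=4, noise_sd=0.0, subject_sd=1.0, seed=0
        )
        design = spm.FieldDesign(
            data.observations, data.subject, data.region, data.condition, data.stride
        )
        f, _ = spm.pointwise_rm_anova(design, "region")
        assert np.all(f[10:20] > 1e6)
        np.testing.assert_array_equal(f[:10], 0.0)
        np.testing.assert_array_equal(f[20:], 0.0)

    def test_stride_replicates_mode_runs(self, rng):
        vals = rng.normal(size=(4, 3, 2))
        design = make_design(vals, 2)
        f_cm, _ = spm.pointwise_rm_anova(design, "region", "cell_means")
        f_sr, _ = spm.pointwise_rm_anova(design, "region", "stride_replicates")
        np.testing.assert_allclose(f_cm, f_sr)  # one stride: identical

    def test_preconditions(self, rng):
        design = make_design(rng.normal(size=(1, 3, 2)), 2)
        with pytest.raises(ValueError, match="2 subjects"):
            spm.pointwise_rm_anova(design, "region")
        with pytest.raises(ValueError, match="effect"):
            spm.pointwise_rm_anova(make_design(rng.normal(size=(3, 2, 2)), 2), "speed")


class TestPairedT:
    def test_identical_sets_zero(self, rng):
        a = rng.random((6, 20))
        t, df, flags = spm.pointwise_paired_t(a, a.copy())
        np.testing.assert_array_equal(t, 0.0)
        assert df == 5

    def test_constant_difference_flagged_infinite(self):
        a = np.zeros((5, 10))
        b = a - 2.0
        t, df, flags = spm.pointwise_paired_t(a, b)
        assert np.all(np.isposinf(t))
        assert flags and "zero_variance" in flags[0]

    def test_matches_closed_form_oracle(self, rng):
        a = rng.normal(size=(9, 1))
        b = rng.normal(size=(9, 1))
        t, df, _ = spm.pointwise_paired_t(a, b)
        d = (a - b)[:, 0]
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(9))
        assert t[0] == pytest.approx(expected, abs=1e-10)
        sp_t, _ = stats.ttest_rel(a[:, 0], b[:, 0])
        assert t[0] == pytest.approx(sp_t, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            spm.pointwise_paired_t(np.zeros((1, 5)), np.zeros((1, 5)))


class TestEstimateFwhm:
    def test_generator_truth_recovered(self):
        r = sd.generate_smooth_null_fields(1000, 200, 20.0, seed=2)
        assert abs(spm.estimate_fwhm(r) - 20.0) / 20.0 < 0.10

    def test_white_noise_limit(self, rng):
        w = rng.standard_normal((1000, 200))
        assert 1.06 < spm.estimate_fwhm(w) < 1.25

    def test_constant_along_nodes_infinite(self, rng):
        r = np.tile(rng.normal(size=(10, 1)), (1, 50))
        assert spm.estimate_fwhm(r) == np.inf

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            spm.estimate_fwhm(np.zeros((5, 50)))


class TestRftThreshold:
    def test_0d_limit_matches_quantiles(self):
        for kind, df, q in (
            ("t", (1, 8), stats.t.isf(0.05, 8)),
            ("F", (3, 24), stats.f.isf(0.05, 3, 24)),
        ):
            u = spm.rft_critical_threshold(kind, df, 200, np.inf, 0.05)
            assert u == pytest.approx(q, abs=1e-4)

    def test_threshold_increases_as_fwhm_decreases(self):
        us = [
            spm.rft_critical_threshold("F", (2, 16), 200, w, 0.05)
            for w in (50.0, 25.0, 12.0, 6.0)
        ]
        assert all(b > a for a, b in zip(us, us[1:]))

    def test_gaussian_field_monte_carlo_calibration(self):
        rng = np.random.default_rng(77)
        fields = sd.generate_smooth_null_fields(10_000, 200, 10.0, rng=rng)
        u = spm.rft_critical_threshold("t", (1, 1e6), 200, 10.0, 0.05)
        rate = np.mean(fields.max(axis=1) > u)
        assert 0.03 <= rate <= 0.07

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            spm.rft_critical_threshold("t", (1, 8), 200, -1.0, 0.05)
        with pytest.raises(ValueError):
            spm.rft_critical_threshold("t", (1, 8), 200, 10.0, 1.5)
        with pytest.raises(ValueError):
            spm._ec1_density("z", 1.0, (1, 8))


class TestClusters:
    def test_below_threshold_empty(self):
        assert spm.suprathreshold_clusters(np.zeros(200), 1.0) == ()

    def test_single_run_interval(self):
        f = np.zeros(200)
        f[64:123] = 5.0
        assert spm.suprathreshold_clusters(f, 1.0) == ((32.0, 61.5),)

    def test_involution(self, rng):
        f = rng.normal(size=200)
        assert spm.suprathreshold_clusters(f, 0.5) == spm.suprathreshold_clusters(-(-f), 0.5)

    def test_run_to_field_end(self):
        f = np.zeros(200)
        f[190:] = 3.0
        assert spm.suprathreshold_clusters(f, 1.0) == ((95.0, 100.0),)

    def test_infinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            spm.suprathreshold_clusters(np.zeros(10), np.inf)


class TestPosthocFamily:
    def test_bonferroni_arithmetic(self, rng):
        sets = {k: rng.normal(size=(8, 100)) + sd.generate_smooth_null_fields(8, 100, 15, rng=rng)
                for k in "abcde"}
        comps = [("a", "b"), ("a", "c"), ("a", "d"), ("a", "e")]
        results = spm.posthoc_paired_t_family(sets, comps, alpha_family=0.05)
        assert all(r.alpha == pytest.approx(0.0125) for r in results.values())

    def test_self_comparison_no_clusters(self, rng):
        a = rng.normal(size=(6, 50))
        results = spm.posthoc_paired_t_family({"x": a}, [("x", "x")])
        res = results[("x", "x")]
        np.testing.assert_array_equal(res.stat, 0.0)
        assert res.clusters == ()

    def test_corrected_threshold_exceeds_single_test(self, rng):
        a = sd.generate_smooth_null_fields(8, 100, 15.0, seed=1)
        b = sd.generate_smooth_null_fields(8, 100, 15.0, seed=2)
        single = spm.spm_paired_t(a, b, alpha=0.05)
        family = spm.posthoc_paired_t_family({"a": a, "b": b}, [("a", "b")] * 1, 0.05 / 4)
        corrected = family[("a", "b")]
        assert corrected.critical_threshold > single.critical_threshold

    def test_empty_comparisons_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            spm.posthoc_paired_t_family({}, [])


class TestSpmPipeline:
    def test_anova_pipeline_detects_injected_effect(self):
        n_nodes = 200
        reg = np.zeros((3, n_nodes))
        reg[0, 60:121] = 2.0
        data = sd.generate_effect_fields(
            reg, np.zeros((2, n_nodes)), n_subjects=8, noise_fwhm=20.0, noise_sd=1.0, seed=4
        )
        design = spm.FieldDesign(
            data.observations, data.subject, data.region, data.condition, data.stride
        )
        res = spm.spm_anova(design, "region")
        assert any(a < 60.0 and b > 30.0 for a, b in res.clusters)

    def test_null_data_usually_not_significant(self):
        hits = 0
        rng = np.random.default_rng(11)
        for _ in range(20):
            fields = sd.generate_smooth_null_fields(12, 200, 20.0, rng=rng)
            design = spm.FieldDesign(
                observations=fields,
                subject=np.repeat(np.arange(6), 2),
                region=np.zeros(12, dtype=int),
                condition=np.tile(np.arange(2), 6),
                stride=np.zeros(12, dtype=int),
            )
            res = spm.spm_anova(design, "condition")
            hits += res.significant
        assert hits <= 4
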