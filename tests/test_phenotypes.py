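"""Phenotype families: geometry, morphology, GLCM texture, kinetics."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from dceradiomics import phantom as ph
from dceradiomics import phenotypes as phe
from dceradiomics.core import DceSeries, TumorMask


class TestSizeFeatures:
    def test_single_voxel_formulae(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        f = phe.size_features(mask, (2.0, 1.0, 1.0))
        assert f["volume_mm3"] == pytest.approx(2.0)
        assert f["effective_diameter_mm"] == pytest.approx((12 / math.pi) ** (1 / 3))

    def test_digital_sphere_geometry(self, sphere_truth_05mm, sphere_spec_05mm):
        f = phe.size_features(sphere_truth_05mm.mask, sphere_spec_05mm.spacing_mm)
        assert f["effective_diameter_mm"] == pytest.approx(20.0, rel=0.02)
        assert f["max_linear_size_mm"] == pytest.approx(20.0, rel=0.02)
        assert f["surface_area_mm2"] == pytest.approx(4 * math.pi * 100, rel=0.05)

    def test_max_linear_size_matches_brute_force(self, rng):
        spacing = (2.0, 1.0, 0.8)
        for _ in range(5):
            mask = np.zeros((8, 8, 8), bool)
            idx = rng.choice(512, size=40, replace=False)
            mask.flat[idx] = True
            pts = np.argwhere(mask) * np.asarray(spacing)
            expected = pdist(pts).max()
            got = phe.size_features(mask, spacing)["max_linear_size_mm"]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_hull_path_agrees_with_brute_force(self, rng):
        # >600 points exercises the convex-hull path; compare to full pdist
        pts = rng.normal(size=(1500, 3)) * [2.0, 1.0, 0.8]
        assert phe._max_pairwise_distance(pts) == pytest.approx(
            pdist(pts).max(), abs=1e-9
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            phe.size_features(np.zeros((3, 3, 3), bool), (1, 1, 1))


class TestShapeFeatures:
    def test_sphere_irregularity_near_zero(self, sphere_truth_05mm, sphere_spec_05mm):
        f = phe.shape_features(sphere_truth_05mm.mask, sphere_spec_05mm.spacing_mm)
        assert f["irregularity"] <= 0.05
        assert f["sphericity"] >= 0.95
        assert f["sphericity"] + f["irregularity"] == pytest.approx(1.0)

    def test_irregularity_monotone_in_perturbation(self):
        values = []
        for amp in (0.0, 0.4):
            spec = ph.PhantomSpec(irregularity_amp=amp, texture_amp=0.0, rng_seed=9)
            truth = ph.make_tumor_mask(spec)
            values.append(
                phe.shape_features(truth.mask, spec.spacing_mm)["irregularity"]
            )
        assert values[1] > values[0]


class TestMorphology:
    @pytest.fixture()
    def bright_sphere(self):
        z, y, x = np.ogrid[-12:13, -12:13, -12:13]
        mask = (z**2 + y**2 + x**2) <= 8**2
        vol = np.where(mask, 100.0, 0.0)
        grid = np.zeros((25, 25, 25), bool) | mask
        return vol, grid

    def test_sharp_sphere_radial_cosines_near_one(self, bright_sphere):
        vol, mask = bright_sphere
        f = phe.morphology_features(vol, mask, (1.0, 1.0, 1.0))
        # gradients point radially: low variance of the cosine distribution
        assert f["variance_radial_gradient_hist"] < 0.05
        assert f["margin_sharpness"] > 0

    def test_blur_reduces_margin_sharpness(self, bright_sphere):
        from scipy.ndimage import gaussian_filter

        vol, mask = bright_sphere
        sharp = phe.morphology_features(vol, mask, (1.0, 1.0, 1.0))
        blurred = phe.morphology_features(
            gaussian_filter(vol, 3.0), mask, (1.0, 1.0, 1.0)
        )
        assert blurred["margin_sharpness"] < sharp["margin_sharpness"]

    def test_spiculation_raises_radial_gradient_variance(self):
        out = {}
        for amp in (0.0, 0.5):
            spec = ph.PhantomSpec(
                irregularity_amp=amp, texture_amp=0.0, noise_sigma=0.0, rng_seed=21
            )
            truth = ph.make_tumor_mask(spec)
            series = ph.make_dce_series(truth, spec)
            out[amp] = phe.morphology_features(
                series.intensities[1], truth.mask, spec.spacing_mm
            )["variance_radial_gradient_hist"]
        assert out[0.5] > out[0.0]


class TestGlcm:
    def test_constant_region_degenerate(self):
        mask = np.ones((4, 4, 4), bool)
        f = phe.glcm_texture_features(np.full((4, 4, 4), 7.0), mask)
        assert f["entropy"] == 0.0
        assert f["contrast"] == 0.0
        assert f["energy"] == 1.0

    def test_two_voxel_hand_enumeration(self):
        # two voxels with distinct levels, one offset: GLCM = [[0,.5],[.5,0]]
        vol = np.zeros((1, 1, 2))
        vol[0, 0, 1] = 1.0
        mask = np.ones((1, 1, 2), bool)
        p = phe.glcm_matrix(vol, mask, n_gray_levels=2, offsets=[(0, 0, 1)])
        assert np.allclose(p, [[0.0, 0.5], [0.5, 0.0]])
        assert phe.haralick_features(p)["entropy"] == pytest.approx(1.0)

    def test_matrix_normalised_and_feature_ranges(self, rng):
        vol = rng.random((6, 6, 6)) * 50
        mask = rng.random((6, 6, 6)) > 0.3
        p = phe.glcm_matrix(vol, mask)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(p, p.T)
        f = phe.haralick_features(p)
        assert f["entropy"] >= 0
        assert 0 < f["energy"] <= 1

    def test_entropy_monotone_in_texture_amp(self):
        entropies = []
        for amp in (0.0, 0.4, 0.8):
            spec = ph.PhantomSpec(texture_amp=amp, noise_sigma=0.0, rng_seed=13)
            truth = ph.make_tumor_mask(spec)
            series = ph.make_dce_series(truth, spec)
            entropies.append(
                phe.glcm_texture_features(series.intensities[1], truth.mask)["entropy"]
            )
        assert entropies[0] < entropies[1] < entropies[2]


class TestKinetics:
    def test_most_enhancing_curve_homogeneous_matches_closed_form(self):
        spec = ph.PhantomSpec(texture_amp=0.0, noise_sigma=0.0, rng_seed=4)
        truth = ph.make_tumor_mask(spec)
        series = ph.make_dce_series(truth, spec)
        curve = phe.most_enhancing_curve(series, truth.mask)
        a, alpha, beta = spec.kinetic_params
        expected = ph.kinetic_curve(curve.times_min, a, alpha, beta)
        assert np.allclose(curve.values, expected, atol=1e-10)

    def test_top_decile_matches_brute_force(self, rng):
        data = np.ones((4, 6, 6, 6)) * 100.0
        bump = rng.random((6, 6, 6)) * 80
        for t in range(1, 4):
            data[t] += bump
        series = DceSeries(data, (1, 1, 1), [0, 1, 2, 3])
        mask = np.ones((6, 6, 6), bool)
        curve = phe.most_enhancing_curve(series, mask, top_fraction=0.1, min_voxels=10)
        enh = bump / 100.0
        order = np.argsort(enh.ravel())[::-1][:22]  # ceil(0.1*216)=22
        expected = enh.ravel()[order].mean()
        assert curve.values[0] == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self, default_phantom):
        _, truth, series = default_phantom
        c1 = phe.most_enhancing_curve(series, truth.mask)
        scaled = DceSeries(series.intensities * 10, series.spacing_mm, series.times_min)
        c2 = phe.most_enhancing_curve(scaled, truth.mask)
        assert np.allclose(c1.values, c2.values, atol=1e-12)

    def test_worked_example(self):
        curve = phe.EnhancementCurve([0.5, 1.0, 0.8], [1.0, 2.0, 4.0])
        f = phe.kinetic_features(curve)
        assert f["max_enhancement"] == 1.0
        assert f["time_to_peak_min"] == 2.0
        assert f["uptake_rate"] == pytest.approx(0.5)
        assert f["washout_rate"] == pytest.approx(0.1)

    def test_monotone_curve_washout_zero(self):
        f = phe.kinetic_features(phe.EnhancementCurve([0.2, 0.5, 0.9], [1, 2, 4]))
        assert f["washout_rate"] == 0.0

    def test_dense_sampling_recovers_analytic_peak(self):
        alpha, beta = 2.5, 0.15
        t = np.linspace(0.01, 12, 1200)
        curve = phe.EnhancementCurve(ph.kinetic_curve(t, 1.0, alpha, beta), t)
        f = phe.kinetic_features(curve)
        assert abs(f["time_to_peak_min"] - ph.analytic_peak_time(alpha, beta)) <= (
            t[1] - t[0]
        )

    def test_scaling_properties(self):
        base = phe.EnhancementCurve([0.5, 1.0, 0.8], [1.0, 2.0, 4.0])
        scaled = phe.EnhancementCurve(np.asarray(base.values) * 3, base.times_min)
        f0, f3 = phe.kinetic_features(base), phe.kinetic_features(scaled)
        assert f3["max_enhancement"] == pytest.approx(3 * f0["max_enhancement"])
        assert f3["uptake_rate"] == pytest.approx(3 * f0["uptake_rate"])
        assert f3["time_to_peak_min"] == f0["time_to_peak_min"]
        assert f3["curve_shape_index"] == pytest.approx(f0["curve_shape_index"])
        assert f3["signal_enhancement_ratio"] == pytest.approx(
            f0["signal_enhancement_ratio"]
        )


class TestVarianceKinetics:
    def test_homogeneous_phantom_all_zero(self):
        spec = ph.PhantomSpec(texture_amp=0.0, noise_sigma=0.0, rng_seed=4)
        truth = ph.make_tumor_mask(spec)
        series = ph.make_dce_series(truth, spec)
        f = phe.variance_kinetics(series, truth.mask)
        assert all(abs(v) < 1e-20 for v in f.values())

    def test_heterogeneous_peak_aligns_with_enhancement_peak(self):
        # A_v all proportional => V(t) ∝ E(t)^2, peaks at the same sample
        spec = ph.PhantomSpec(texture_amp=0.5, noise_sigma=0.0, rng_seed=4)
        truth = ph.make_tumor_mask(spec)
        series = ph.make_dce_series(truth, spec)
        f = phe.variance_kinetics(series, truth.mask)
        curve = phe.most_enhancing_curve(series, truth.mask)
        kf = phe.kinetic_features(curve)
        assert f["max_variance_enhancement"] > 0
        assert f["time_to_peak_variance_min"] == kf["time_to_peak_min"]

    def test_variance_curve_matches_brute_force(self, default_phantom):
        _, truth, series = default_phantom
        f = phe.variance_kinetics(series, truth.mask)
        enh, _ = series.relative_enhancement()
        v = np.array([enh[t][truth.mask.mask].var() for t in range(enh.shape[0])])
        assert f["max_variance_enhancement"] == pytest.approx(v.max(), abs=1e-12)

    def test_single_voxel_mask_warns_and_zeroes(self, caplog):
        data = np.ones((4, 3, 3, 3)) * 100
        data[1:, 1, 1, 1] = 150
        series = DceSeries(data, (1, 1, 1), [0, 1, 2, 3])
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with caplog.at_level("WARNING"):
            f = phe.variance_kinetics(series, mask)
        assert all(v == 0.0 for v in f.values())
        assert "single-voxel" in caplog.text


class TestExtractAll:
    def test_registry_contract(self, default_phantom):
        _, truth, series = default_phantom
        vec = phe.extract_all(series, truth.mask)
        assert len(vec.values) >= 33
        assert tuple(vec.values) == phe.feature_names()
        cats = {vec.category(n) for n in vec.values}
        assert cats == {
            "size", "shape", "morphology", "texture", "kinetics", "variance_kinetics",
        }
        assert all(np.isfinite(v) for v in vec.values.values())

    def test_deterministic(self, default_phantom):
        _, truth, series = default_phantom
        v1 = phe.extract_all(series, truth.mask)
        v2 = phe.extract_all(series, truth.mask)
        assert v1.values == v2.values

    def test_geometry_intensity_invariance(self, default_phantom):
        _, truth, series = default_phantom
        scaled = DceSeries(series.intensities * 7, series.spacing_mm, series.times_min)
        v1 = phe.extract_all(series, truth.mask)
        v2 = phe.extract_all(scaled, truth.mask)
        for name in ("volume_mm3", "effective_diameter_mm", "surface_area_mm2",
                     "sphericity", "irregularity", "max_linear_size_mm"):
            assert v1.values[name] == v2.values[name]
        # kinetic features are built on relative enhancement: also invariant
        assert v1.values["max_enhancement"] == pytest.approx(
            v2.values["max_enhancement"], abs=1e-12
        )

    def test_internal_consistency_diameter_volume(self, default_phantom):
        _, truth, series = default_phantom
        v = phe.extract_all(series, truth.mask).values
        assert v["effective_diameter_mm"] ** 3 * math.pi / 6 == pytest.approx(
            v["volume_mm3"], rel=1e-9
        )
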