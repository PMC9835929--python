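import numpy as np
import pytest
import scipy.integrate

from microphase.core import LengthDistribution, Profile, Volume
from microphase.structure import (
    aster_center,
    axial_profile,
    fit_length_distribution,
    lognormal_stats,
    predict_aster_profile,
    predict_bilayer_profile,
    profile_agreement,
    radial_average,
    tip_anchor_kernel,
)
from microphase.synthetic import fixed_length, make_aster_volume, make_bilayer_volume


class TestLognormalStats:
    def test_measured_length_law_mean_and_mode(self, length_law):
        """The M=1.4, S=0.6 polydispersity has mean 4.9 um, mode 2.8 um."""
        stats = lognormal_stats(length_law)
        assert round(stats["mean"], 1) == 4.9
        assert round(stats["mode"], 1) == 2.8

    def test_degenerate_limit(self):
        d = LengthDistribution(0.0, 1e-6)
        assert lognormal_stats(d)["mean"] == pytest.approx(1.0, abs=1e-9)
        assert lognormal_stats(d)["mode"] == pytest.approx(1.0, abs=1e-9)


class TestFitLengthDistribution:
    def test_recovers_parameters_from_large_sample(self, length_law, rng):
        lengths = length_law.sample(10_000, rng)
        fit = fit_length_distribution(lengths)
        assert fit.log_mu == pytest.approx(1.4, abs=0.02)
        assert fit.log_sigma == pytest.approx(0.6, abs=0.02)

    def test_fitted_pdf_normalized(self, length_law, rng):
        fit = fit_length_distribution(length_law.sample(500, rng))
        total, _ = scipy.integrate.quad(fit.pdf, 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_rejects_nonpositive_and_degenerate(self):
        with pytest.raises(ValueError, match="positive"):
            fit_length_distribution([1.0] * 9 + [-2.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_length_distribution([3.0] * 20)


class TestTipAnchorKernel:
    def test_degenerate_length_is_step(self):
        x = np.linspace(0, 10, 101)
        k = tip_anchor_kernel(fixed_length(5.0), x)
        assert np.all(k[x < 4.99] > 0.999)
        assert np.all(k[x > 5.01] < 1e-3)

    def test_starts_at_one_and_decreases(self, length_law):
        x = np.linspace(0, 30, 200)
        k = tip_anchor_kernel(length_law, x)
        assert k[0] == pytest.approx(1.0)
        assert np.all(np.diff(k) <= 1e-12)
        assert k[-1] < 1e-3

    def test_matches_pdf_quadrature(self, length_law):
        """K(x) equals 1 - integral of the pdf up to x (quadrature oracle)."""
        for x in (1.0, 3.0, 7.0, 15.0):
            cdf, _ = scipy.integrate.quad(length_law.pdf, 0, x)
            assert tip_anchor_kernel(length_law, np.array([x]))[0] == (
                pytest.approx(1 - cdf, abs=1e-8))


class TestPredictions:
    def test_delta_core_reproduces_kernel(self):
        """A point anchor with fixed length L gives a rectangle on [0, L]."""
        coord = np.arange(0.05, 12, 0.1)
        g = np.zeros_like(coord)
        g[0] = 1.0
        pred = predict_aster_profile(
            Profile(coordinate=coord, intensity=g, kind="radial"),
            fixed_length(8.0))
        assert np.all(pred.intensity[coord < 7.9] > 0.999)
        assert np.all(pred.intensity[coord > 8.2] < 1e-6)

    def test_delta_sheet_gives_symmetric_rectangle(self):
        coord = np.arange(-10, 10, 0.1)
        g = np.zeros_like(coord)
        g[np.argmin(np.abs(coord))] = 1.0
        pred = predict_bilayer_profile(
            Profile(coordinate=coord, intensity=g, kind="normal"),
            fixed_length(5.0))
        inside = np.abs(coord) < 4.9
        outside = np.abs(coord) > 5.2
        assert np.all(pred.intensity[inside] > 0.999)
        assert np.all(pred.intensity[outside] < 1e-6)

    def test_symmetric_sheet_predicts_symmetric_profile(self, length_law):
        coord = np.arange(-10, 10.01, 0.1)
        g = np.exp(-(coord**2) / 0.5)
        pred = predict_bilayer_profile(
            Profile(coordinate=coord, intensity=g, kind="normal"), length_law)
        np.testing.assert_allclose(pred.intensity, pred.intensity[::-1],
                                   atol=1e-9)

    def test_wider_core_widens_prediction(self, length_law):
        coord = np.arange(0.05, 20, 0.1)
        preds = []
        for sigma in (0.5, 2.0):
            g = coord**2 * np.exp(-(coord**2) / (2 * sigma**2))
            prof = Profile(coordinate=coord, intensity=g, kind="radial")
            preds.append(predict_aster_profile(prof, length_law))
        # wider anchor cloud -> more mass at large radii after peak norm.
        tail = coord > 8
        assert preds[1].intensity[tail].sum() > preds[0].intensity[tail].sum()

    def test_matches_rasterized_aster(self, aster, length_law):
        """Forward model vs rasterization oracle (shell-profile pairing)."""
        mt, k4, _ = aster
        centre = aster_center(k4)
        kin = radial_average(k4, center=centre, weight="shell", r_max=18)
        meas = radial_average(mt, center=centre, weight="shell", r_max=18)
        pred = predict_aster_profile(kin, length_law)
        assert profile_agreement(meas.normalized(), pred)["nrmse"] < 0.1

    def test_matches_rasterized_bilayer(self, length_law):
        mt, k4, gt = make_bilayer_volume(
            sheet_axis=0, areal_density=2.0, length_law=length_law,
            shape=(96, 48, 48), voxel_size=0.5, psf_sigma=0.2, seed=3)
        pos = gt.params["sheet_position"]
        kin = axial_profile(k4, axis=0, origin=pos)
        meas = axial_profile(mt, axis=0, origin=pos)
        pred = predict_bilayer_profile(kin, length_law)
        assert profile_agreement(meas.normalized(), pred)["nrmse"] < 0.1


class TestRadialAverage:
    def test_matches_brute_force_binning(self, rng):
        """Annulus means agree with a per-pixel loop on a 64x64 toy image."""
        img = rng.random((64, 64))
        vol = Volume(img, (1.0, 1.0))
        centre = np.array([32.0, 32.0])
        prof = radial_average(vol, center=centre, bin_width=2.0)
        # brute force
        sums, counts = {}, {}
        for i in range(64):
            for j in range(64):
                r = np.hypot(i + 0.5 - 32, j + 0.5 - 32)
                b = int(r // 2.0)
                sums[b] = sums.get(b, 0.0) + img[i, j]
                counts[b] = counts.get(b, 0) + 1
        for k, (c, v) in enumerate(zip(prof.coordinate, prof.intensity)):
            b = int(c // 2.0)
            assert v == pytest.approx(sums[b] / counts[b], rel=1e-9)

    def test_uniform_image_gives_flat_profile(self):
        vol = Volume(np.full((48, 48), 3.0), (0.5, 0.5))
        prof = radial_average(vol, bin_width=1.0)
        np.testing.assert_allclose(prof.intensity, 3.0, rtol=1e-12)

    def test_radially_symmetric_function_recovered(self):
        y, x = np.meshgrid(np.arange(64) + 0.5, np.arange(64) + 0.5,
                           indexing="ij")
        r = np.hypot(y - 32, x - 32)
        vol = Volume(np.exp(-r / 10), (1.0, 1.0))
        prof = radial_average(vol, center=np.array([32.0, 32.0]),
                              bin_width=1.0, r_max=25)
        expected = np.exp(-prof.coordinate / 10)
        assert np.max(np.abs(prof.intensity - expected) / expected) < 0.05

    def test_center_outside_grid_rejected(self):
        vol = Volume(np.ones((16, 16)), 1.0)
        with pytest.raises(ValueError, match="outside"):
            radial_average(vol, center=np.array([100.0, 2.0]))


class TestAxialProfile:
    def test_uniform_slab_is_top_hat_with_zero_stderr(self):
        data = np.zeros((32, 16, 16))
        data[10:20] = 2.0
        vol = Volume(data, 1.0)
        prof = axial_profile(vol, axis=0)
        assert np.all(prof.intensity[10:20] == 2.0)
        assert np.all(prof.intensity[:10] == 0.0)
        np.testing.assert_allclose(prof.stderr, 0.0, atol=1e-12)

    def test_matches_direct_plane_loop(self, rng):
        data = rng.random((12, 8, 8))
        vol = Volume(data, (2.0, 1.0, 1.0))
        prof = axial_profile(vol, axis=0)
        for k in range(12):
            assert prof.intensity[k] == pytest.approx(data[k].mean())
        np.testing.assert_allclose(prof.coordinate, (np.arange(12) + 0.5) * 2.0)


class TestProfileAgreement:
    def test_identical_profiles(self):
        p = Profile(coordinate=[0, 1, 2], intensity=[1.0, 2.0, 1.0])
        res = profile_agreement(p, p)
        assert res["nrmse"] == pytest.approx(0.0, abs=1e-12)
        assert res["r2"] == pytest.approx(1.0)

    def test_zero_prediction_has_nonpositive_r2(self):
        m = Profile(coordinate=[0, 1, 2], intensity=[1.0, 3.0, 1.0])
        p = Profile(coordinate=[0, 1, 2], intensity=[0.0, 0.0, 0.0])
        assert profile_agreement(m, p)["r2"] <= 0

    def test_three_bin_manual_arithmetic(self):
        """measured (2, 4, 2), predicted (1, 4, 3):
        rmse = sqrt((1+0+1)/3), nrmse = rmse/4; r2 = 1 - 2/(8/3)."""
        m = Profile(coordinate=[0, 1, 2], intensity=[2.0, 4.0, 2.0])
        p = Profile(coordinate=[0, 1, 2], intensity=[1.0, 4.0, 3.0])
        res = profile_agreement(m, p)
        assert res["nrmse"] == pytest.approx(np.sqrt(2.0 / 3.0) / 4.0)
        assert res["r2"] == pytest.approx(1.0 - 2.0 / (8.0 / 3.0))

    def test_disjoint_supports_rejected(self):
        a = Profile(coordinate=[0, 1], intensity=[1.0, 1.0])
        b = Profile(coordinate=[5, 6], intensity=[1.0, 1.0])
        with pytest.raises(ValueError, match="disjoint"):
            profile_agreement(a, b)
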