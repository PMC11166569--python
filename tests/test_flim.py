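import numpy as np
import pytest
from scipy.special import erfc

from tensiopipe import flim as fl
from tensiopipe import synthdata as sd
from tensiopipe.synthdata.flimscene import site_mask


def exp_conv_gauss(t, tau, sigma, t0):
    """Analytic exponential-decay x Gaussian-IRF density (independent oracle)."""
    t = np.asarray(t, dtype=float)
    if sigma == 0:
        out = np.where(t >= t0, np.exp(-(t - t0) / tau) / tau, 0.0)
        return out
    arg = (sigma**2 / tau - (t - t0)) / (sigma * np.sqrt(2.0))
    return (
        0.5 / tau * np.exp(sigma**2 / (2 * tau**2) - (t - t0) / tau) * erfc(arg)
    )


def make_exact_single_exp(tau=4.0, t0=1.0, window=40.0, n_bins=400, n_photons=1e6):
    edges = np.linspace(0, window, n_bins + 1)
    t = 0.5 * (edges[:-1] + edges[1:])
    pdf = exp_conv_gauss(t, tau, 0.0, t0)
    counts = n_photons * pdf / pdf.sum()
    irf = np.zeros(n_bins)
    irf[np.searchsorted(edges, t0) - 1] = 1.0
    return fl.TCSPCHistogram(t, counts, irf)


class TestReconvolution:
    def test_noiseless_single_exponential_exact(self):
        h = make_exact_single_exp(tau=4.0)
        fit = fl.fit_reconvolution(h, single_exponential=True)
        assert abs(fit.tau_long - 4.0) < 0.01

    def test_photon_threshold_masks_instead_of_raising(self):
        h = make_exact_single_exp(n_photons=999)
        fit = fl.fit_reconvolution(h)
        assert not fit.valid
        assert np.isnan(fit.tau_long)
        # the published minimum photon rule
        from tensiopipe.constants import MIN_PHOTONS_PER_PIXEL

        assert MIN_PHOTONS_PER_PIXEL == 1000

    def test_biexponential_recovery_within_3se(self):
        cfg = sd.TCSPCGenConfig(
            tau_long=5.0, tau_short=2.0, frac_long=0.6, irf_fwhm=0.2,
            n_photons=100_000, window_ns=50.0, n_bins=512, seed=12,
        )
        h = sd.generate_tcspc_histogram(cfg)
        fit = fl.fit_reconvolution(h)
        assert abs(fit.tau_long - 5.0) <= 3 * fit.se["tau_long"]
        assert abs(fit.tau_short - 2.0) <= 3 * fit.se["tau_short"]

    def test_against_grid_search_mle_oracle(self):
        cfg = sd.TCSPCGenConfig(
            tau_long=5.0, tau_short=2.0, frac_long=0.6, irf_fwhm=0.2,
            n_photons=200_000, window_ns=50.0, n_bins=512, seed=19,
        )
        h = sd.generate_tcspc_histogram(cfg)
        # oracle: multinomial NLL on the analytic (erfc) model, grid over
        # tau_long with the other parameters at generator truth
        grid = np.arange(4.0, 6.0, 0.02)
        nlls = []
        for tl in grid:
            pdf = 0.6 * exp_conv_gauss(h.time_ns, tl, cfg.irf_sd, cfg.t0_ns)
            pdf = pdf + 0.4 * exp_conv_gauss(h.time_ns, 2.0, cfg.irf_sd, cfg.t0_ns)
            p = pdf / pdf.sum()
            nlls.append(-np.sum(h.counts * np.log(p + 1e-300)))
        oracle_tau = grid[int(np.argmin(nlls))]
        fit = fl.fit_reconvolution(h)
        assert abs(fit.tau_long - oracle_tau) <= 3 * fit.se["tau_long"] + 0.02

    def test_unbiased_at_1e4_photons(self):
        errs, ses = [], []
        for seed in range(20):
            cfg = sd.TCSPCGenConfig(
                tau_long=5.0, tau_short=2.0, frac_long=0.6, irf_fwhm=0.2,
                n_photons=10_000, window_ns=50.0, n_bins=256, seed=100 + seed,
            )
            fit = fl.fit_reconvolution(sd.generate_tcspc_histogram(cfg))
            errs.append(fit.tau_long - 5.0)
            ses.append(fit.se["tau_long"])
        # mean error consistent with zero at Monte-Carlo resolution
        assert abs(np.mean(errs)) < 3 * np.mean(ses) / np.sqrt(len(errs)) + 0.02

    def test_exposure_rescaling_invariance(self):
        cfg = sd.TCSPCGenConfig(
            tau_long=5.0, tau_short=2.0, frac_long=0.6, irf_fwhm=0.2,
            n_photons=50_000, window_ns=50.0, n_bins=256, seed=7,
        )
        h = sd.generate_tcspc_histogram(cfg)
        h4 = fl.TCSPCHistogram(h.time_ns, h.counts * 4, h.irf_counts)
        f1 = fl.fit_reconvolution(h, compute_se=False)
        f4 = fl.fit_reconvolution(h4, compute_se=False)
        assert abs(f4.tau_long - f1.tau_long) < 0.05
        assert f4.amp_long / f1.amp_long == pytest.approx(4.0, rel=0.1)

    def test_degenerate_collapses_to_single_exponential(self):
        h = make_exact_single_exp(tau=4.0, n_photons=50_000)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fl.fit_reconvolution(h)
        assert fit.tau_long == pytest.approx(fit.tau_short)
        assert abs(fit.tau_long - 4.0) < 0.05


@pytest.fixture(scope="module")
def uniform_image():
    cfg = sd.FlimSceneConfig(
        shape=(10, 10), pixel_size_um=0.15, tau_base=4.0, tau_short=1.5,
        tau_site_delta=0.0, site_center=(5, 5), site_radius_um=0.5,
        site_width_um=0.2, photons_per_pixel=2000, n_bins=128,
        window_ns=25.0, seed=3,
    )
    stack, t, irf, _ = sd.generate_flim_scene(cfg)
    img = fl.fit_lifetime_image(
        stack, t, irf, pixel_size_um=0.15, photon_threshold=1000
    )
    return cfg, img


class TestLifetimeImage:

    def test_uniform_scene_sd_within_cramer_rao_factor2(self, uniform_image):
        cfg, img = uniform_image
        emp_sd = float(np.nanstd(img.tau_long[img.mask]))
        # numeric Cramer-Rao bound from the analytic model at the truth,
        # nuisance amplitudes profiled via the full Fisher matrix
        edges = np.linspace(0, cfg.window_ns, cfg.n_bins + 1)
        t = 0.5 * (edges[:-1] + edges[1:])
        dt = t[1] - t[0]
        n_ph = cfg.photons_per_pixel

        def model(theta):
            tl, al, ash = theta
            return n_ph * dt * (
                al * exp_conv_gauss(t, tl, cfg.irf_fwhm / 2.355, 1.0)
                + ash * exp_conv_gauss(t, cfg.tau_short, cfg.irf_fwhm / 2.355, 1.0)
            )

        theta0 = np.array([cfg.tau_base, cfg.frac_long, 1 - cfg.frac_long])
        m0 = model(theta0)
        J = np.empty((len(t), 3))
        for k in range(3):
            dth = np.zeros(3)
            dth[k] = 1e-5
            J[:, k] = (model(theta0 + dth) - model(theta0 - dth)) / 2e-5
        fisher = J.T @ (J / np.clip(m0, 1e-12, None)[:, None])
        crb_sd = float(np.sqrt(np.linalg.inv(fisher)[0, 0]))
        assert crb_sd / 2 < emp_sd < crb_sd * 2

    def test_masked_pixels_below_threshold(self, uniform_image):
        _, img = uniform_image
        assert img.mask.all()  # every pixel got 2000 photons
        assert np.isfinite(img.tau_long[img.mask]).all()

    def test_annulus_delta_recovered(self):
        cfg = sd.FlimSceneConfig(
            shape=(12, 12), pixel_size_um=0.15, tau_base=4.0, tau_short=1.5,
            tau_site_delta=0.3, site_center=(6, 6), site_radius_um=0.6,
            site_width_um=0.3, photons_per_pixel=3000, n_bins=128, seed=5,
        )
        stack, t, irf, _ = sd.generate_flim_scene(cfg)
        img = fl.fit_lifetime_image(stack, t, irf, pixel_size_um=0.15)
        m = site_mask(cfg)
        d_site = np.nanmean(img.tau_long[m & img.mask])
        d_bg = np.nanmean(img.tau_long[~m & img.mask])
        n_site = int((m & img.mask).sum())
        se = float(np.nanmean(img.tau_se)) * np.sqrt(1.0 / n_site + 1.0 / (~m).sum())
        assert abs((d_site - d_bg) - 0.3) <= 3 * se + 0.05

    def test_low_photon_scene_rejected(self):
        stack = np.ones((3, 3, 64), dtype=int)  # 64 photons per pixel
        t = np.linspace(0.05, 6.4, 64)
        irf = np.zeros(64)
        irf[2] = 1.0
        with pytest.raises(ValueError):
            fl.fit_lifetime_image(stack, t, irf, photon_threshold=1000)


class TestTensionCalibration:
    def test_exact_line(self):
        tau = np.array([4.0, 4.4, 4.8, 5.2, 5.6])
        cal = fl.calibrate_tension(tau, 1.325 * tau - 2.0)
        assert cal.factor == pytest.approx(1.325)
        assert cal.r_squared == pytest.approx(1.0)

    def test_unit_relabeling_identity(self):
        # mN/m and nN/um are the same unit, so relabeling cannot change c
        tau = np.array([4.0, 4.5, 5.0, 5.5])
        ten_mn_per_m = 1.325 * tau
        ten_nn_per_um = ten_mn_per_m * 1.0
        assert (
            fl.calibrate_tension(tau, ten_mn_per_m).factor
            == fl.calibrate_tension(tau, ten_nn_per_um).factor
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fl.calibrate_tension([4.0, 5.0], [1.0, 2.0])

    def test_noisy_recovery_within_3se(self):
        rng = np.random.default_rng(8)
        tau = np.array([4.2, 4.5, 4.8, 5.1, 5.4])
        ten = 1.325 * tau - 2.0 + rng.normal(0, 0.15, 5)
        cal = fl.calibrate_tension(tau, ten)
        assert abs(cal.factor - 1.325) <= 3 * cal.factor_sd

    def test_lifetime_to_tension(self):
        cal = fl.TensionCalibration(1.325, 0.0, 0.0, 1.0)
        assert fl.lifetime_to_tension(0.0, cal) == 0.0
        assert fl.lifetime_to_tension(0.1, cal) == pytest.approx(0.1325)
        assert fl.lifetime_to_tension(0.2, cal) == pytest.approx(
            2 * fl.lifetime_to_tension(0.1, cal)
        )


class TestStimulusTension:
    def test_exact_slopes(self):
        F = np.array([2.0, 10.0, 25.0, 50.0])
        alpha, _, r2 = fl.fit_stimulus_tension(F, 0.0065 * F)
        assert alpha == pytest.approx(0.0065)
        assert r2 == pytest.approx(1.0)
        p = np.array([0.0, 25.0, 50.0, 100.0])
        alpha_p, _, _ = fl.fit_stimulus_tension(p, 0.0024 * p + 0.1)
        assert alpha_p == pytest.approx(0.0024)

    def test_zero_slope_within_se(self):
        rng = np.random.default_rng(2)
        x = np.arange(5.0)
        alpha, se, _ = fl.fit_stimulus_tension(x, rng.normal(0, 0.01, 5))
        assert abs(alpha) <= 3 * se


class TestIntegrateTensionChange:
    def make_image(self, tau, px=0.1):
        shape = tau.shape
        return fl.LifetimeImage(
            photons=np.full(shape, 2000),
            tau_long=tau.astype(float),
            tau_se=np.full(shape, 0.01),
            mask=np.ones(shape, dtype=bool),
            pixel_size_um=px,
        )

    def test_identical_images_give_zero(self):
        tau = np.full((8, 8), 4.0)
        cal = fl.TensionCalibration(1.325, 0.0, 0.0, 1.0)
        total, mask = fl.integrate_tension_change(
            self.make_image(tau), self.make_image(tau), cal
        )
        assert total == 0.0
        assert not mask.any()

    def test_direct_arithmetic(self):
        before = np.full((10, 10), 4.0)
        after = before.copy()
        after[:5, :5] += 0.2  # 25 pixels
        cal = fl.TensionCalibration(1.325, 0.0, 0.0, 1.0)
        total, mask = fl.integrate_tension_change(
            self.make_image(before), self.make_image(after), cal, noise_sd=0.05
        )
        assert mask.sum() == 25
        assert total == pytest.approx(25 * 1.325 * 0.2 * 0.01)

    def test_additive_over_disjoint_regions(self):
        before = np.full((10, 10), 4.0)
        a = before.copy()
        a[:3, :3] += 0.3
        b = before.copy()
        b[6:, 6:] += 0.2
        both = before + (a - before) + (b - before)
        cal = fl.TensionCalibration(1.0, 0.0, 0.0, 1.0)
        kw = dict(noise_sd=0.05)
        t_a, _ = fl.integrate_tension_change(
            self.make_image(before), self.make_image(a), cal, **kw
        )
        t_b, _ = fl.integrate_tension_change(
            self.make_image(before), self.make_image(b), cal, **kw
        )
        t_ab, _ = fl.integrate_tension_change(
            self.make_image(before), self.make_image(both), cal, **kw
        )
        assert t_ab == pytest.approx(t_a + t_b)

    def test_misaligned_shapes_rejected(self):
        cal = fl.TensionCalibration(1.0, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="misaligned"):
            fl.integrate_tension_change(
                self.make_image(np.full((8, 8), 4.0)),
                self.make_image(np.full((9, 9), 4.0)),
                cal,
            )


class TestKymograph:
    ROIS = {"site": np.arange(10, 16), "membrane": np.arange(30, 40)}

    def test_constant_kymograph_no_change(self):
        rng = np.random.default_rng(0)
        tau = 4.0 + rng.normal(0, 0.02, (60, 48))
        inten = np.ones((60, 48))
        res = fl.analyze_kymograph(tau, inten, self.ROIS, 2.0, 0.08)
        assert not any(res.changed.values())

    def test_bleb_like_membrane_step_detected(self):
        from tensiopipe.synthdata.flimscene import generate_flim_kymograph

        cfg = sd.FlimSceneConfig(shape=(1, 48), seed=2)
        tau, inten = generate_flim_kymograph(
            cfg, n_lines=60, contact_line=25,
            site_pixels=slice(10, 16), membrane_pixels=slice(30, 40),
            delta_site=0.25, delta_membrane=0.2,
        )
        res = fl.analyze_kymograph(tau, inten, self.ROIS, 25 * 0.02, 0.02)
        assert res.changed["membrane"]
        assert abs(res.change_line["membrane"] - 25) <= 1

    def test_intact_cell_membrane_verdict_negative(self):
        cfg = sd.FlimSceneConfig(shape=(1, 48), seed=4)
        from tensiopipe.synthdata.flimscene import generate_flim_kymograph

        tau, inten = generate_flim_kymograph(
            cfg, n_lines=60, contact_line=25,
            site_pixels=slice(10, 16), membrane_pixels=slice(30, 40),
            delta_site=0.25, delta_membrane=0.0,
        )
        res = fl.analyze_kymograph(tau, inten, self.ROIS, 25 * 0.08, 0.08)
        assert res.changed["site"]
        assert not res.changed["membrane"]

    def test_contact_outside_record_rejected(self):
        tau = np.full((30, 48), 4.0)
        with pytest.raises(ValueError, match="contact"):
            fl.analyze_kymograph(tau, tau, self.ROIS, 10.0, 0.08)


class TestStimulusPipeline:
    def test_alpha_recovery_through_image_fitting(self):
        # scenes built from the indentation coefficient as ground truth,
        # run through per-pixel fitting and the stimulus-tension line fit
        c_factor = 1.325
        alpha_F = 0.0065
        cal = fl.TensionCalibration(c_factor, 0.0, 0.0, 1.0)
        forces = [2.0, 15.0, 30.0, 50.0]
        d_taus = []
        base_cfg = dict(
            shape=(9, 9), pixel_size_um=0.15, tau_base=4.0, tau_short=1.5,
            site_center=(4, 4), site_radius_um=0.45, site_width_um=0.3,
            photons_per_pixel=4000, n_bins=128,
        )
        for i, F in enumerate(forces):
            cfg = sd.FlimSceneConfig(
                tau_site_delta=alpha_F / c_factor, seed=40 + i, **base_cfg
            )
            stack, t, irf, _ = sd.generate_flim_scene(cfg, stimulus_scale=F)
            img = fl.fit_lifetime_image(stack, t, irf, pixel_size_um=0.15)
            m = site_mask(cfg)
            d_taus.append(
                np.nanmean(img.tau_long[m & img.mask])
                - np.nanmean(img.tau_long[~m & img.mask])
            )
        dT = fl.lifetime_to_tension(np.asarray(d_taus), cal)
        alpha_fit, se, _ = fl.fit_stimulus_tension(forces, dT)
        assert abs(alpha_fit - alpha_F) <= 3 * se
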