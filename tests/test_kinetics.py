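"""Kinetic model: convolution oracles, fitting, error estimates, SNR."""

import numpy as np
import pytest

import perfusekit as pk
from perfusekit.datatypes import AIFCurve
from perfusekit.kinetics import _ConvolutionGrid


def _constant_aif(c0=2.0, t_end=20.0, n=201):
    t = np.linspace(0.0, t_end, n)
    return AIFCurve(times=t, values=np.full(n, c0)), t


class TestForwardModel:
    def test_zero_amplitude_gives_zero_tac(self, aif, acq_times):
        tac = pk.forward_model(aif, 0.0, 0.5, acq_times)
        assert np.all(tac == 0.0)

    @pytest.mark.parametrize("lam", [0.2, 0.5, 1.0])
    def test_constant_aif_matches_closed_form(self, lam):
        # step input: TAC(t) = A c0 (1 - exp(-lam t)) / lam
        aif, t = _constant_aif()
        A, c0 = 0.1, 2.0
        tac = pk.forward_model(aif, A, lam, t, grid_step=0.1)
        ref = A * c0 * (1 - np.exp(-lam * t)) / lam
        rel = np.abs(tac[1:] - ref[1:]) / ref[1:]
        assert rel.max() < 0.005

    def test_impulse_aif_gives_exponential(self):
        # unit-area impulse at an interior grid point: the convolution
        # identity gives the pure exponential residue after the impulse
        dt = 0.02
        t = np.arange(0.0, 10.0 + dt / 2, dt)
        k = 50  # impulse at t = 1.0
        vals = np.zeros_like(t)
        vals[k] = 1.0 / dt
        aif = AIFCurve(times=t, values=vals)
        A, lam = 0.3, 0.7
        tac = pk.forward_model(aif, A, lam, t, grid_step=dt)
        after = t > t[k]
        ref = A * np.exp(-lam * (t[after] - t[k]))
        assert np.abs(tac[after] - ref).max() < 0.005 * ref.max()
        assert np.all(tac[t < t[k]] == 0.0)

    def test_linear_in_amplitude_and_aif(self, aif, acq_times):
        base = pk.forward_model(aif, 0.1, 0.5, acq_times)
        assert np.allclose(pk.forward_model(aif, 0.3, 0.5, acq_times), 3 * base)
        aif3 = AIFCurve(times=aif.times, values=3 * aif.values)
        assert np.allclose(pk.forward_model(aif3, 0.1, 0.5, acq_times), 3 * base)

    def test_nonincreasing_times_rejected(self, aif):
        with pytest.raises(ValueError):
            pk.forward_model(aif, 0.1, 0.5, np.array([0.0, 1.0, 1.0]))


class TestFitVoxel:
    def test_noiseless_self_consistency(self, aif, acq_times):
        tac = pk.forward_model(aif, 0.1, 0.5, acq_times, grid_step=0.025)
        fit = pk.fit_voxel(tac, aif, acq_times)
        assert fit.converged
        assert fit.A == pytest.approx(0.1, rel=1e-4)
        assert fit.lam == pytest.approx(0.5, rel=1e-4)

    def test_matches_exhaustive_grid_search(self, aif, acq_times):
        # brute-force oracle: exhaustive sweep of 200 washout rates over
        # the bounds with the amplitude profiled in closed form (the SSE
        # is quadratic in A), plus a 200 x 200 full-grid dominance check
        tac = pk.forward_model(aif, 0.08, 0.45, acq_times, grid_step=0.025)
        opts = pk.FitOptions()
        grid = _ConvolutionGrid(aif, acq_times, 0.025)
        A_grid = np.linspace(*opts.bounds_A, 200)
        lam_grid = np.linspace(*opts.bounds_lam, 200)
        best = (np.inf, None, None)
        full_grid_best = np.inf
        for lam in lam_grid:
            m, _ = grid.model(lam, with_grad=False)
            A_star = float(np.clip((m @ tac) / (m @ m), *opts.bounds_A))
            sse = float(((A_star * m - tac) ** 2).sum())
            if sse < best[0]:
                best = (sse, A_star, lam)
            sse_grid = ((A_grid[:, None] * m[None, :] - tac) ** 2).sum(axis=1)
            full_grid_best = min(full_grid_best, float(sse_grid.min()))
        fit = pk.fit_voxel(tac, aif, acq_times, opts)
        assert abs(fit.lam - best[2]) <= np.diff(lam_grid)[0]
        # amplitude agrees with the closed-form profile at the fitted rate
        m_hat, _ = grid.model(fit.lam, with_grad=False)
        A_profile = float((m_hat @ tac) / (m_hat @ m_hat))
        assert fit.A == pytest.approx(A_profile, rel=1e-3)
        # the continuous optimiser is at least as good as either search
        assert fit.objective_value <= best[0] + 1e-12
        assert fit.objective_value <= full_grid_best + 1e-12

    def test_flat_tac_flagged_low_signal(self, aif, acq_times):
        fit = pk.fit_voxel(np.zeros_like(acq_times), aif, acq_times)
        assert fit.converged
        assert "low-signal" in fit.flags
        assert fit.A == pk.FitOptions().bounds_A[0]

    def test_scatter_attains_cramer_rao_bound(self, aif, acq_times):
        """At the spectral noise calibration the least-squares fitter is an
        efficient estimator: the empirical lambda scatter matches the
        Cramer-Rao bound computed from the model Jacobian."""
        A, lam = 0.2 / 2.2, 1 / 2.2
        sigma = 8.0 / 112.02
        grid = _ConvolutionGrid(aif, acq_times, 0.025)
        m, dm = grid.model(lam)
        J = np.column_stack([m, A * dm])
        crlb_sd = np.sqrt((sigma ** 2 * np.linalg.inv(J.T @ J))[1, 1])
        tac0 = A * m
        rng = np.random.default_rng(42)
        lams = np.array([
            pk.fit_voxel(tac0 + rng.normal(0, sigma, tac0.shape), aif,
                         acq_times).lam
            for _ in range(300)
        ])
        assert lams.std() / crlb_sd == pytest.approx(1.0, abs=0.2)
        within = np.abs(lams - lam) <= 2.5 * crlb_sd
        assert within.mean() >= 0.95
        assert abs(lams.mean() - lam) < crlb_sd  # no gross bias

    def test_too_few_points_rejected(self, aif):
        with pytest.raises(ValueError):
            pk.fit_voxel([1.0, 2.0, 3.0], aif, np.array([0.0, 1.0, 2.0]))


class TestFitErrors:
    def test_identity_hessian(self):
        f = lambda x: 0.5 * float(x @ x)  # Hessian = I
        err = pk.fit_errors(f, [0.0, 0.0], f_tol=1.0)
        assert err == pytest.approx((1.0, 1.0), rel=1e-4)

    @pytest.mark.parametrize("a,b", [(2.0, 3.0), (0.5, 10.0)])
    def test_quadratic_analytic_oracle(self, a, b):
        opt = np.array([0.3, 0.7])
        f = lambda x: a * (x[0] - opt[0]) ** 2 + b * (x[1] - opt[1]) ** 2
        f_tol = 1e-8
        err = pk.fit_errors(f, opt, f_tol)
        assert err[0] == pytest.approx(np.sqrt(f_tol / (2 * a)), rel=1e-4)
        assert err[1] == pytest.approx(np.sqrt(f_tol / (2 * b)), rel=1e-4)

    def test_quadrupling_ftol_doubles_errors(self):
        f = lambda x: 2.0 * (x[0] - 1) ** 2 + 5.0 * (x[1] - 2) ** 2
        e1 = pk.fit_errors(f, [1.0, 2.0], 1e-8)
        e4 = pk.fit_errors(f, [1.0, 2.0], 4e-8)
        assert e4[0] == pytest.approx(2 * e1[0], rel=1e-6)
        assert e4[1] == pytest.approx(2 * e1[1], rel=1e-6)

    def test_indefinite_hessian_gives_nan(self):
        f = lambda x: float(x[0] ** 2 - x[1] ** 2)  # saddle
        with pytest.warns(RuntimeWarning):
            err = pk.fit_errors(f, [0.0, 0.0], 1e-8)
        assert np.all(np.isnan(err))

    def test_error_scatter_decreases_with_noise(self, aif, acq_times):
        """Median parameter errors shrink monotonically as noise drops
        (HU-scale signal, as in a conventional acquisition)."""
        hu_aif = AIFCurve(times=aif.times, values=31.25 * aif.values)
        tac0 = pk.forward_model(hu_aif, 0.1, 0.5, acq_times, grid_step=0.025)
        rng = np.random.default_rng(3)
        medians = []
        for sigma in (30.0, 10.0, 3.0):
            errs = [
                pk.fit_voxel(tac0 + rng.normal(0, sigma, tac0.shape), hu_aif,
                             acq_times).err_lam
                for _ in range(60)
            ]
            medians.append(np.nanmedian(errs))
        assert medians[0] > medians[1] > medians[2]


class TestTacSnr:
    def test_snr_tracks_peak_over_sigma(self, aif, acq_times):
        tac0 = pk.forward_model(aif, 0.1, 0.5, acq_times, grid_step=0.025)
        sigma = tac0.max() / 20
        rng = np.random.default_rng(8)
        snrs = []
        for _ in range(100):
            tac = tac0 + rng.normal(0, sigma, tac0.shape)
            fit = pk.fit_voxel(tac, aif, acq_times)
            snrs.append(pk.tac_snr(fit, tac, aif, acq_times))
        assert np.median(snrs) == pytest.approx(tac0.max() / sigma, rel=0.15)

    def test_halving_noise_doubles_median_snr(self, aif, acq_times):
        tac0 = pk.forward_model(aif, 0.1, 0.5, acq_times, grid_step=0.025)
        rng = np.random.default_rng(12)

        def median_snr(sigma, n=100):
            out = []
            for _ in range(n):
                tac = tac0 + rng.normal(0, sigma, tac0.shape)
                fit = pk.fit_voxel(tac, aif, acq_times)
                out.append(pk.tac_snr(fit, tac, aif, acq_times))
            return np.median(out)

        s = tac0.max() / 10
        assert median_snr(s / 2) == pytest.approx(2 * median_snr(s), rel=0.15)

    def test_zero_residual_sd_flagged_infinite(self, aif, acq_times):
        tac = pk.forward_model(aif, 0.1, 0.5, acq_times, grid_step=0.025)
        fit = pk.fit_voxel(tac, aif, acq_times)
        # residuals are ~0 to machine precision but not exactly; force it
        exact = pk.forward_model(aif, fit.A, fit.lam, acq_times)
        with pytest.warns(RuntimeWarning):
            snr = pk.tac_snr(fit, exact, aif, acq_times)
        assert np.isinf(snr)


class TestFitVolume:
    def test_mask_selects_fitted_voxels(self, noiseless_sim):
        sim = noiseless_sim
        mask = np.zeros(sim.series.spatial_shape, dtype=bool)
        mask[0, 2, 4] = mask[0, 12, 5] = True
        aif = pk.measure_aif(sim.series, sim.labels)
        maps = pk.fit_volume(sim.series, aif, mask=mask)
        assert np.isfinite(maps["A"][mask]).all()
        assert np.isnan(maps["A"][~mask]).all()

    def test_identical_tacs_identical_fits(self, noiseless_sim):
        sim = noiseless_sim
        mask = np.zeros(sim.series.spatial_shape, dtype=bool)
        mask[0, 3, 5] = mask[0, 3, 6] = True  # same band -> same TAC
        aif = pk.measure_aif(sim.series, sim.labels)
        maps = pk.fit_volume(sim.series, aif, mask=mask)
        vals = maps["lam"][mask]
        assert vals[0] == vals[1]

    def test_noiseless_roundtrip_recovers_truth(self, noiseless_sim):
        sim = noiseless_sim
        aif = pk.measure_aif(sim.series, sim.labels)
        mask = sim.labels.tissue_mask
        maps = pk.fit_volume(sim.series, aif, mask=mask)
        for key in ("A", "lam"):
            rel = np.abs(maps[key][mask] - sim.truth[key][mask]) / sim.truth[key][mask]
            assert rel.max() < 1e-4

    def test_empty_mask_warns(self, noiseless_sim):
        sim = noiseless_sim
        aif = pk.measure_aif(sim.series, sim.labels)
        with pytest.warns(RuntimeWarning):
            maps = pk.fit_volume(
                sim.series, aif,
                mask=np.zeros(sim.series.spatial_shape, dtype=bool),
            )
        assert np.isnan(maps["A"]).all()

    def test_spectral_errors_smaller_than_conventional(self, small_phantom):
        """The high-SNR iodine-density modality yields strictly smaller
        median fit-parameter errors than conventional HU."""
        med = {}
        for modality in ("iodine_density", "conventional_hu"):
            sim = pk.simulate_series(small_phantom, modality, seed=21)
            aif = pk.measure_aif(sim.series, sim.labels)
            opts = pk.FitOptions(
                subtract_baseline=(modality == "conventional_hu"))
            maps = pk.fit_volume(sim.series, aif, mask=sim.labels.tissue_mask,
                                 opts=opts)
            med[modality] = (np.nanmedian(maps["err_A"]),
                             np.nanmedian(maps["err_lam"]))
        assert med["iodine_density"][0] < med["conventional_hu"][0]
        assert med["iodine_density"][1] < med["conventional_hu"][1]


class TestEstimatorAPI:
    def test_sklearn_params_roundtrip(self, aif, acq_times):
        from sklearn.base import clone

        est = pk.OneCompartmentModel(aif=aif, times=acq_times, f_tol=1e-9)
        est2 = clone(est)
        assert est2.get_params()["f_tol"] == 1e-9
        est2.set_params(lam0=0.7)
        assert est2.lam0 == 0.7

    def test_fit_predict_reproduces_noiseless_curves(self, aif, acq_times):
        X = np.stack([
            pk.forward_model(aif, 0.1, 0.5, acq_times, grid_step=0.025),
            pk.forward_model(aif, 0.07, 0.37, acq_times, grid_step=0.025),
        ])
        est = pk.OneCompartmentModel(aif=aif, times=acq_times).fit(X)
        assert est.A_ == pytest.approx([0.1, 0.07], rel=1e-3)
        pred = est.predict()
        assert np.allclose(pred, X, rtol=1e-3, atol=1e-6)
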