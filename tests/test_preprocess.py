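"""HRF/design construction, scaling, nuisance regression, AR fitting
and prewhitening."""

import numpy as np
import pytest
from scipy.signal import lfilter

from sbglm import (
    ARModel,
    BoldRun,
    average_ar_across_runs,
    build_design,
    fit_ar_yule_walker,
    fit_classical,
    make_hrf,
    make_mesh,
    nuisance_regress,
    prewhiten,
    scale_bold,
    smooth_on_mesh,
)
from sbglm.preprocess import ar_process_autocov, build_whitening_operator


class TestMakeHrf:
    def test_zero_at_origin(self):
        h = make_hrf(0.5)
        assert h[0] == 0.0

    def test_peak_between_4_and_7_seconds(self):
        dt = 0.01
        h = make_hrf(dt)
        assert 4.0 <= np.argmax(h) * dt <= 7.0

    def test_halving_tr_doubles_samples(self):
        assert make_hrf(0.5, total_length_s=32).size == 2 * make_hrf(1.0, 32).size - 1

    def test_invalid_tr(self):
        with pytest.raises(ValueError):
            make_hrf(0.0)


class TestBuildDesign:
    def test_convolution_oracle(self):
        """Single 12 s block at onset 10 s: the finalised column equals a
        direct-summation convolution on the same oversampled grid."""
        tr, T, ov = 0.72, 100, 16
        design = build_design({"a": [10.0]}, {"a": [12.0]}, T, tr, oversampling=ov)
        dt = tr / ov
        n_fine = T * ov
        box = np.zeros(n_fine)
        i0, i1 = round(10.0 / dt), round(22.0 / dt)
        box[i0:i1] = 1.0
        h = make_hrf(tr, oversampling=ov)
        conv = np.zeros(n_fine)
        for t in range(n_fine):  # direct summation
            lo = max(0, t - h.size + 1)
            conv[t] = sum(box[s] * h[t - s] for s in range(lo, t + 1))
        col = conv[::ov]
        col = col / col.max()
        col = col - col.mean()
        np.testing.assert_allclose(design.task_matrix[:, 0], col, atol=1e-10)

    def test_max_scaling_before_centering(self):
        tr, T, ov = 0.72, 120, 16
        design = build_design(
            {"a": [5.0], "b": [40.0]}, {"a": [12.0], "b": [12.0]}, T, tr, oversampling=ov
        )
        # independent reconstruction via numpy convolution
        dt = tr / ov
        h = make_hrf(tr, oversampling=ov)
        for k, (onset, name) in enumerate([(5.0, "a"), (40.0, "b")]):
            box = np.zeros(T * ov)
            box[round(onset / dt) : round((onset + 12.0) / dt)] = 1.0
            x = np.convolve(box, h)[: T * ov][::ov]
            x = x / x.max()
            assert x.max() == pytest.approx(1.0)  # max-scaled before centring
            np.testing.assert_allclose(
                design.task_matrix[:, k], x - x.mean(), atol=1e-10
            )

    def test_empty_onsets_gives_zero_column(self):
        design = build_design({"a": [], "b": [10.0]}, {"a": [], "b": [12.0]}, 80, 0.72)
        assert np.all(design.task_matrix[:, 0] == 0)

    def test_onset_beyond_run_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            build_design({"a": [100.0]}, {"a": [12.0]}, 50, 0.72)

    def test_derivatives_in_nuisance(self):
        design = build_design({"a": [10.0]}, {"a": [12.0]}, 100, 0.72)
        assert design.nuisance_matrix.shape == (100, 1)
        assert design.nuisance_matrix[0, 0] == 0.0


class TestScaleBold:
    def test_constant_series_becomes_zero(self):
        run = BoldRun(np.full((10, 3), 500.0), 1.0)
        assert np.all(scale_bold(run).data == 0)

    def test_two_point_series(self):
        run = BoldRun(np.array([[90.0], [110.0]]), 1.0)
        np.testing.assert_allclose(scale_bold(run).data, [[-10.0], [10.0]])

    def test_output_centred(self, rng):
        run = BoldRun(1000 + 10 * rng.standard_normal((50, 7)), 1.0)
        out = scale_bold(run)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_nonpositive_mean_rejected_with_vertex(self):
        data = np.ones((10, 3))
        data[:, 2] = -1.0
        with pytest.raises(ValueError, match="vertex 2"):
            scale_bold(BoldRun(data, 1.0))


class TestNuisanceRegress:
    def test_projection_oracle(self, rng):
        T, P, K = 50, 4, 2
        y = rng.standard_normal((T, 3))
        X = rng.standard_normal((T, K))
        Z = rng.standard_normal((T, P))
        y_r, X_r = nuisance_regress(y, X, Z)
        H = Z @ np.linalg.solve(Z.T @ Z, Z.T)
        np.testing.assert_allclose(y_r, y - H @ y, atol=1e-8)
        np.testing.assert_allclose(X_r, X - H @ X, atol=1e-8)
        assert np.abs(Z.T @ y_r).max() < 1e-8
        assert np.abs(Z.T @ X_r).max() < 1e-8

    def test_pure_trend_removed(self):
        t = np.linspace(0, 1, 40)
        y_r, _ = nuisance_regress(3 * t, np.ones((40, 1)), t[:, None])
        assert np.abs(y_r).max() < 1e-10

    def test_task_column_in_nuisance_zeroed(self, rng):
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        _, X_r = nuisance_regress(y, X, X[:, :1])
        assert np.abs(X_r[:, 0]).max() < 1e-10

    def test_rank_deficient_nuisance_warns(self, rng):
        Z = rng.standard_normal((30, 2))
        Z = np.column_stack([Z, Z[:, 0]])
        with pytest.warns(UserWarning, match="rank deficient"):
            nuisance_regress(rng.standard_normal(30), rng.standard_normal((30, 1)), Z)


class TestYuleWalker:
    def test_white_noise_coefficients_near_zero(self, rng):
        phi, s2 = fit_ar_yule_walker(rng.standard_normal(5000), 6)
        assert np.abs(phi).max() < 0.05

    def test_ar1_recovery(self, rng):
        x = lfilter([1.0], [1.0, -0.5], rng.standard_normal(10_000))
        phi, _ = fit_ar_yule_walker(x, 6)
        assert 0.45 <= phi[0] <= 0.55
        assert np.abs(phi[1:]).max() < 0.06

    def test_dense_toeplitz_oracle(self, rng):
        x = lfilter([1.0], [1.0, -0.4, 0.2], rng.standard_normal(800))
        p = 4
        phi, s2 = fit_ar_yule_walker(x, p)
        xc = x - x.mean()
        g = np.array([xc[: x.size - k] @ xc[k:] for k in range(p + 1)]) / x.size
        Gam = np.array([[g[abs(i - j)] for j in range(p)] for i in range(p)])
        phi_o = np.linalg.solve(Gam, g[1:])
        np.testing.assert_allclose(phi, phi_o, atol=1e-10)
        assert s2 == pytest.approx(g[0] - phi_o @ g[1:], abs=1e-10)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.regression.linear_model import yule_walker

        x = lfilter([1.0], [1.0, -0.6, 0.15], rng.standard_normal(2000))
        phi, s2 = fit_ar_yule_walker(x, 3)
        rho, sigma = yule_walker(x, order=3, method="mle", demean=True)
        np.testing.assert_allclose(phi, rho, atol=1e-8)
        assert np.sqrt(s2) == pytest.approx(sigma, abs=1e-8)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_ar_yule_walker(np.ones(50), 6)


class TestAverageAr:
    def test_mean_of_two_runs(self):
        m1 = ARModel([[0.2, 0.0]], [1.0])
        m2 = ARModel([[0.4, 0.0]], [3.0])
        avg = average_ar_across_runs([m1, m2])
        assert avg.coefs[0, 0] == pytest.approx(0.3)
        assert avg.innovation_variance[0] == pytest.approx(2.0)

    def test_order_invariance_and_identity(self):
        models = [ARModel([[0.1 * i, 0.05]], [1.0 + i]) for i in range(3)]
        a = average_ar_across_runs(models)
        b = average_ar_across_runs(models[::-1])
        np.testing.assert_allclose(a.coefs, b.coefs)
        same = average_ar_across_runs([models[0], models[0]])
        np.testing.assert_allclose(same.coefs, models[0].coefs)

    def test_mismatched_vertex_sets_rejected(self):
        with pytest.raises(ValueError):
            average_ar_across_runs(
                [ARModel([[0.1]], [1.0]), ARModel([[0.1], [0.2]], [1.0, 1.0])]
            )


class TestSmoothOnMesh:
    def test_constant_field_unchanged(self):
        mesh = make_mesh("grid", 8)
        out = smooth_on_mesh(np.full(64, 3.5), mesh, fwhm_mm=2.0)
        np.testing.assert_allclose(out, 3.5)

    def test_zero_fwhm_is_identity(self, rng):
        mesh = make_mesh("grid", 6)
        x = rng.standard_normal(36)
        np.testing.assert_array_equal(smooth_on_mesh(x, mesh, 0.0), x)

    def test_impulse_profile_matches_gaussian(self):
        """A unit impulse on a fine planar grid smooths to an isotropic
        Gaussian profile of sigma = fwhm/2.3548 within 15% at d <= 2 sigma."""
        g = 21
        mesh = make_mesh("grid", g, grid_spacing_mm=0.25)
        fwhm = 2.0
        sigma = fwhm / np.sqrt(8 * np.log(2))
        x = np.zeros(g * g)
        centre = (g // 2) * g + g // 2
        x[centre] = 1.0
        out = smooth_on_mesh(x, mesh, fwhm)
        xy = mesh.vertices[:, :2]
        d = np.linalg.norm(xy - xy[centre], axis=1)
        # axis-aligned directions, where graph-geodesic = Euclidean
        # distance (off-axis paths are distorted by the triangulation)
        on_axis = (xy[:, 0] == xy[centre, 0]) | (xy[:, 1] == xy[centre, 1])
        sel = on_axis & (d > 0) & (d <= 2 * sigma)
        assert sel.sum() >= 8
        expected = out[centre] * np.exp(-d[sel] ** 2 / (2 * sigma**2))
        np.testing.assert_allclose(out[sel], expected, rtol=0.15)


class TestPrewhiten:
    def test_pure_rescaling_with_zero_coefficients(self, rng):
        T, N = 40, 3
        y = rng.standard_normal((T, N))
        X = rng.standard_normal((T, 2))
        ar = ARModel(np.zeros((N, 6)), np.full(N, 4.0))
        out = prewhiten(y, X, ar)
        np.testing.assert_allclose(out.bold, y / 2.0, atol=1e-12)
        np.testing.assert_allclose(out.design[0], X / 2.0, atol=1e-12)

    def test_whitening_operator_banded_lower_triangular(self):
        phi = np.array([0.4, 0.2])
        W = build_whitening_operator(phi, 1.3, 30).toarray()
        assert np.abs(np.triu(W, 1)).max() == 0
        assert np.abs(np.tril(W, -3)).max() == 0  # bandwidth p = 2

    def test_exact_whitening_of_ar_covariance(self):
        phi = np.array([0.5, -0.2, 0.1])
        s2 = 0.8
        T = 25
        g = ar_process_autocov(phi, s2, T - 1)
        Sigma = np.array([[g[abs(i - j)] for j in range(T)] for i in range(T)])
        W = build_whitening_operator(phi, s2, T).toarray()
        np.testing.assert_allclose(W @ Sigma @ W.T, np.eye(T), atol=1e-8)

    def test_whitens_simulated_ar2(self, rng):
        T, N = 2000, 4
        phi = np.array([0.5, -0.3])
        noise = lfilter([1.0], np.concatenate([[1.0], -phi]), rng.standard_normal((T, N)), axis=0)
        ar = ARModel(np.tile(phi, (N, 1)), np.ones(N))
        out = prewhiten(noise, np.zeros((T, 1)), ar)
        for lag in range(1, 7):
            rs = [
                np.corrcoef(out.bold[:-lag, v], out.bold[lag:, v])[0, 1]
                for v in range(N)
            ]
            # mean over vertices within 2 SE; individual values within 3.5 SE
            assert abs(np.mean(rs)) < 2.0 / np.sqrt(T)
            assert np.abs(rs).max() < 3.5 / np.sqrt(T)

    def test_noncausal_rejected(self):
        ar = ARModel([[1.5]], [1.0])
        with pytest.raises(ValueError, match="non-causal"):
            prewhiten(np.zeros((20, 1)), np.zeros((20, 1)), ar)


class TestPipelineInvariants:
    def test_noiseless_estimand_preserved(self, rng):
        """Nuisance regression then prewhitening leaves the OLS estimand
        unchanged: on noiseless data the downstream beta-hat is exact."""
        from sbglm import SimulationSpec, simulate_study
        from sbglm.pipeline import prepare_visit

        spec = SimulationSpec(
            mesh_kind="grid",
            mesh_size=6,
            n_tasks=2,
            n_runs=1,
            n_subjects=1,
            n_visits=1,
            n_timepoints=120,
            noise_sd=0.0,
            subject_sd=0.0,
            visit_sd=0.0,
            seed=5,
        )
        study = simulate_study(spec)
        sess = prepare_visit(study.runs[0][0], study.design, study.mesh, ar_order=0)[0]
        fit = fit_classical(sess)
        truth = study.truth.visit_fields[0, 0][:, study.mesh.data_indices].T
        np.testing.assert_allclose(fit.beta, truth, atol=1e-6)

    def test_full_pipeline_whitens_ar6_noise(self):
        """Scale -> nuisance regression -> AR(6) fit with cross-run
        averaging and smoothing -> prewhiten leaves classical residuals
        with mean |lag-1| autocorrelation < 0.05 at T = 500."""
        from sbglm import SimulationSpec, simulate_study
        from sbglm.pipeline import prepare_visit

        spec = SimulationSpec(
            mesh_kind="grid",
            mesh_size=8,
            n_tasks=1,
            n_runs=2,
            n_subjects=1,
            n_visits=1,
            n_timepoints=500,
            field_sd=1.0,
            subject_sd=0.0,
            visit_sd=0.0,
            noise_sd=1.0,
            seed=3,
        )
        study = simulate_study(spec)
        sessions = prepare_visit(study.runs[0][0], study.design, study.mesh)
        sess = sessions[0]
        fit = fit_classical(sess)
        resid = sess.bold - np.einsum("vtk,vk->tv", sess.design, fit.beta)
        lag1 = np.array(
            [np.corrcoef(resid[:-1, v], resid[1:, v])[0, 1] for v in range(resid.shape[1])]
        )
        assert np.mean(np.abs(lag1)) < 0.05
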