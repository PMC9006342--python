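"""Spatial Bayesian GLM: marginal posterior, fitting, derived fields."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from sbglm import (
    LinearCombination,
    MaternHyperparams,
    PriorSpec,
    SessionData,
    TriangularMesh,
    build_fem_matrices,
    build_precision,
    derive_field,
    fit_bayes_glm,
    fit_classical,
    log_marginal_posterior,
    make_mesh,
    simulate_study,
    SimulationSpec,
)
from sbglm.pipeline import prepare_visit


def dense_marginal_oracle(y, X, ops, kappa, tau, sigma2, prior):
    """log p(y|theta) + log pi(theta) by explicit covariance assembly:
    stack y vertex-major and build Sigma = s2 I + Xbig Q^{-1} Xbig'."""
    T, N = y.shape
    K = X.shape[1]
    n = ops.n_mesh
    data_idx = ops.Psi.indices
    Qinv = np.linalg.inv(build_precision(ops, MaternHyperparams(kappa, tau)).toarray())
    # Xbig maps the K stacked mesh fields to the stacked data vector
    Xbig = np.zeros((T * N, K * n))
    for v in range(N):
        for k in range(K):
            Xbig[v * T : (v + 1) * T, k * n + data_idx[v]] = X[:, k]
    Qinv_full = np.kron(np.eye(K), Qinv)
    Sigma = sigma2 * np.eye(T * N) + Xbig @ Qinv_full @ Xbig.T
    ll = multivariate_normal.logpdf(y.T.ravel(), mean=np.zeros(T * N), cov=Sigma)
    return (
        ll + prior.log_prior(np.full(K, kappa), np.full(K, tau), sigma2),
        Xbig,
        Qinv_full,
    )


@pytest.fixture(scope="module")
def toy_problem():
    rng = np.random.default_rng(7)
    mesh = make_mesh("grid", 3)  # 9 vertices
    ops = build_fem_matrices(mesh)
    T, K = 20, 1
    X = rng.standard_normal((T, K))
    beta = rng.standard_normal(mesh.n_vertices)
    y = np.outer(X[:, 0], beta[mesh.data_indices]) + 0.5 * rng.standard_normal(
        (T, mesh.n_data)
    )
    return mesh, ops, SessionData(y, X, ["t0"])


class TestLogMarginalPosterior:
    def test_matches_dense_marginalisation_oracle(self, toy_problem):
        mesh, ops, sess = toy_problem
        prior = PriorSpec()
        theta = np.array([0.8, 0.7, 0.25])
        val = log_marginal_posterior(theta, [sess], ops, prior)
        oracle, _, _ = dense_marginal_oracle(
            sess.bold, sess.design, ops, 0.8, 0.7, 0.25, prior
        )
        assert val == pytest.approx(oracle, abs=1e-6)

    def test_relabeling_invariance(self, toy_problem):
        mesh, ops, sess = toy_problem
        rng = np.random.default_rng(1)
        perm = rng.permutation(mesh.n_vertices)
        inv = np.argsort(perm)
        mesh_p = TriangularMesh(mesh.vertices[perm], inv[mesh.faces])
        ops_p = build_fem_matrices(mesh_p)
        # data columns follow Psi's row order = sorted mesh index order
        col_of_vertex = np.argsort(ops_p.Psi.indices)  # not needed: remap directly
        y_p = sess.bold[:, np.argsort(inv[mesh.data_indices])]
        sess_p = SessionData(y_p, sess.design, sess.task_names)
        theta = np.array([0.8, 0.7, 0.25])
        v1 = log_marginal_posterior(theta, [sess], ops)
        v2 = log_marginal_posterior(theta, [sess_p], ops_p)
        assert v2 == pytest.approx(v1, abs=1e-8)

    def test_prior_constant_shift(self, toy_problem):
        mesh, ops, sess = toy_problem
        theta = np.array([0.8, 0.7, 0.25])
        p1 = PriorSpec()
        p2 = PriorSpec(noise_precision_rate=1e-3)
        shift = p2.log_prior(np.array([0.8]), np.array([0.7]), 0.25) - p1.log_prior(
            np.array([0.8]), np.array([0.7]), 0.25
        )
        v1 = log_marginal_posterior(theta, [sess], ops, p1)
        v2 = log_marginal_posterior(theta, [sess], ops, p2)
        assert v2 - v1 == pytest.approx(shift, abs=1e-10)

    def test_nonpositive_theta_rejected(self, toy_problem):
        _, ops, sess = toy_problem
        with pytest.raises(ValueError):
            log_marginal_posterior(np.array([-1.0, 1.0, 1.0]), [sess], ops)


class TestFitBayesGlm:
    def test_posterior_matches_dense_conditional_oracle(self, toy_problem):
        mesh, ops, sess = toy_problem
        theta = np.array([0.8, 0.7, 0.25])
        post = fit_bayes_glm(sess, ops, fixed_theta=theta)
        _, Xbig, Qinv_full = dense_marginal_oracle(
            sess.bold, sess.design, ops, 0.8, 0.7, 0.25, PriorSpec()
        )
        P_dense = np.linalg.inv(Qinv_full) + Xbig.T @ Xbig / 0.25
        mu_dense = np.linalg.solve(P_dense, Xbig.T @ sess.bold.T.ravel() / 0.25)
        np.testing.assert_allclose(post.mean, mu_dense, atol=1e-6)
        np.testing.assert_allclose(post.precision.toarray(), P_dense, atol=1e-6)

    def test_identical_runs_give_identical_fields(self, toy_problem):
        mesh, ops, sess = toy_problem
        post = fit_bayes_glm([sess, sess], ops, fixed_theta=[0.8, 0.7, 0.25])
        np.testing.assert_allclose(
            post.mean_fields[0], post.mean_fields[1], atol=1e-10
        )

    def test_vanishing_noise_recovers_least_squares(self):
        rng = np.random.default_rng(2)
        mesh = make_mesh("grid", 4)
        ops = build_fem_matrices(mesh)
        T = 50
        X = rng.standard_normal((T, 1))
        beta = rng.standard_normal(mesh.n_vertices)
        y = np.outer(X[:, 0], beta[mesh.data_indices])
        sess = SessionData(y, X, ["a"])
        post = fit_bayes_glm(sess, ops, fixed_theta=[0.5, 1.0, 1e-8])
        ls = y.T @ X[:, 0] / (X[:, 0] @ X[:, 0])
        np.testing.assert_allclose(post.beta_data(0, 0), ls, atol=1e-4)

    def test_single_run_is_multi_run_with_j1(self, toy_problem):
        mesh, ops, sess = toy_problem
        p1 = fit_bayes_glm(sess, ops, fixed_theta=[0.8, 0.7, 0.25])
        p2 = fit_bayes_glm([sess], ops, fixed_theta=[0.8, 0.7, 0.25])
        np.testing.assert_allclose(p1.mean, p2.mean, atol=1e-12)


@pytest.fixture(scope="module")
def fitted(toy_problem):
    mesh, ops, sess = toy_problem
    return mesh, fit_bayes_glm([sess, sess], ops, fixed_theta=[0.8, 0.7, 0.25])


class TestDeriveField:

    def test_selection_weight_returns_block(self, fitted):
        mesh, post = fitted
        df = derive_field(post, LinearCombination.single(2, 1, 0, 0))
        np.testing.assert_allclose(df.mean, post.beta_data(0, 0), atol=1e-12)

    def test_cross_run_average_halves_variance(self, fitted):
        mesh, post = fitted
        single = derive_field(post, LinearCombination.single(2, 1, 0, 0))
        avg = derive_field(post, LinearCombination.run_average(2, 1, 0))
        np.testing.assert_allclose(
            avg.marginal_variance, single.marginal_variance / 2, rtol=1e-10
        )

    def test_mean_linearity(self, fitted):
        mesh, post = fitted
        a = derive_field(post, LinearCombination([[1.0], [0.0]]))
        b = derive_field(post, LinearCombination([[0.0], [1.0]]))
        c = derive_field(post, LinearCombination([[0.5], [0.5]]))
        np.testing.assert_allclose(c.mean, 0.5 * a.mean + 0.5 * b.mean, atol=1e-12)

    def test_sample_moments_match(self, fitted, rng):
        mesh, post = fitted
        df = derive_field(post, LinearCombination.run_average(2, 1, 0))
        s = df.sample(rng, 4000)
        assert np.abs(s.mean(axis=0) - df.mean).max() < 4 * np.sqrt(
            df.marginal_variance.max() / 4000
        )
        se = df.marginal_variance * np.sqrt(2.0 / 4000)
        assert np.all(np.abs(s.var(axis=0) - df.marginal_variance) < 5 * se)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LinearCombination([[0.0, 0.0]])


class TestRecoveryProperties:
    def test_bayes_smoother_and_multirun_more_efficient(self):
        """Posterior mean fields are smoother along mesh edges than the
        classical estimates, and the cross-run average beats the
        single-run posterior on RMSE (small replicated simulation)."""
        wins_smooth = 0
        multi_rmse, single_rmse = [], []
        reps = 6
        for rep in range(reps):
            spec = SimulationSpec(
                mesh_kind="icosphere",
                mesh_size=1,
                radius_mm=30.0,
                n_tasks=1,
                n_runs=2,
                n_subjects=1,
                n_visits=1,
                n_timepoints=120,
                kappa=0.3,
                field_sd=1.0,
                subject_sd=0.0,
                visit_sd=0.0,
                noise_sd=1.5,
                seed=100 + rep,
            )
            study = simulate_study(spec)
            sessions = prepare_visit(study.runs[0][0], study.design, study.mesh,
                                     ar_order=0)
            truth = study.truth.visit_fields[0, 0][0]
            di = study.mesh.data_indices
            post = fit_bayes_glm(sessions, study.ops, n_starts=1)
            avg = derive_field(post, LinearCombination.run_average(2, 1, 0)).mean
            post1 = fit_bayes_glm(sessions[0], study.ops, n_starts=1)
            one = derive_field(post1, LinearCombination.single(1, 1, 0, 0)).mean
            y_cat = np.vstack([s.bold for s in sessions])
            X_cat = np.concatenate([s.design for s in sessions], axis=-2)
            cfit = fit_classical(SessionData(y_cat, X_cat, ["a"]))
            multi_rmse.append(np.sqrt(np.mean((avg - truth[di]) ** 2)))
            single_rmse.append(np.sqrt(np.mean((one - truth[di]) ** 2)))
            # mean squared first difference along mesh edges
            edges = np.unique(
                np.sort(
                    np.concatenate(
                        [study.mesh.faces[:, [0, 1]], study.mesh.faces[:, [1, 2]],
                         study.mesh.faces[:, [2, 0]]]
                    ),
                    axis=1,
                ),
                axis=0,
            )
            bay_mesh = np.zeros(study.mesh.n_vertices)
            bay_mesh[di] = avg
            cla_mesh = np.zeros(study.mesh.n_vertices)
            cla_mesh[di] = cfit.beta[:, 0]
            rough = lambda f: np.mean(  # noqa: E731
                (f[edges[:, 0]] - f[edges[:, 1]]) ** 2
            )
            if rough(bay_mesh) <= rough(cla_mesh):
                wins_smooth += 1
        assert wins_smooth == reps  # smoother in every replicate here
        assert np.mean(multi_rmse) <= np.mean(single_rmse)
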