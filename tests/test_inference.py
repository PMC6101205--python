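"""Asymptotic covariance machinery: W, G, the oblique projection,
restricted avar, Wald tables, bootstrap and AIC rank selection."""

import numpy as np
import pytest

from rrglm import (
    Gaussian,
    ModelSpec,
    Multinomial,
    ParamVector,
    fit_full,
    fit_reduced,
    loglik,
)
from rrglm.inference import (
    aic_rank_path,
    asymptotic_covariance,
    avar_reduced,
    bootstrap_cov,
    build_G,
    coordinate_labels,
    estimate_W,
    projection,
    wald_table,
    AsymCov,
)
from rrglm.simulate import simulate_dataset, workforce_like_scenario

from conftest import random_reduced_instance


def build_G_hchart(C0, B0, spec):
    """Full-column-rank gradient of the corner chart (C = [I_d; A]).

    Drops the columns of the vec(C) block that correspond to the frozen
    identity rows, leaving an injective parametrization whose span equals
    span(G); requires C0 in corner form.
    """
    d = C0.shape[1]
    G = build_G(C0, B0, spec)
    k1 = spec.k1
    keep = [True] * G.shape[1]
    for l in range(d):
        for a in range(d):  # identity rows of C are not free parameters
            keep[k1 + l * k1 + a] = False
    return G[:, np.asarray(keep)]


def random_spd(rng, m, scale=1.0):
    A = rng.standard_normal((m, m))
    return scale * (A @ A.T + m * np.eye(m))


# ---------------------------------------------------------------------------
# W
# ---------------------------------------------------------------------------

class TestEstimateW:
    def test_kronecker_closed_form_multinomial_null(self):
        # with beta = 0 the information factorizes: W = (E xx')^{-1} (x) H0^{-1}
        rng = np.random.default_rng(0)
        fam = Multinomial(3)
        spec = ModelSpec(fam, p=2)
        params = ParamVector(np.zeros(2), np.zeros((2, 2)), np.zeros((2, 0)),
                             np.zeros(0))
        X = rng.standard_normal((300, 2))
        W = estimate_W(X, params, spec)
        Xt = np.column_stack([np.ones(300), X])
        M2 = Xt.T @ Xt / 300
        H0 = fam.hess_psi(np.zeros(2))
        np.testing.assert_allclose(
            W, np.kron(np.linalg.inv(M2), np.linalg.inv(H0)), atol=1e-8
        )

    def test_gaussian_known_variance_closed_form(self):
        rng = np.random.default_rng(1)
        fam = Gaussian(3, sigma2=2.0)
        spec = ModelSpec(fam, p=2)
        params = ParamVector(rng.standard_normal(3),
                             rng.standard_normal((3, 2)),
                             np.zeros((3, 0)), np.zeros(0))
        X = rng.standard_normal((200, 2))
        W = estimate_W(X, params, spec)
        Xt = np.column_stack([np.ones(200), X])
        M2 = Xt.T @ Xt / 200
        np.testing.assert_allclose(
            W, np.kron(np.linalg.inv(M2), np.eye(3) / 2.0), atol=1e-8
        )

    def test_matches_numeric_hessian_of_loglik(self):
        rng = np.random.default_rng(2)
        spec, params = random_reduced_instance(rng, k1=2, r=2, d=1, p_extra=1)
        spec_full = spec.with_rank(None)
        X = rng.standard_normal((400, spec.p))
        from rrglm.design import eta_matrix

        y = spec.family.sample_conditional(eta_matrix(params, X, spec), rng)
        fit = fit_full(X, y, spec_full)
        xi = fit.params.pack()
        m = xi.size
        h = 1e-5
        hess = np.empty((m, m))
        for i in range(m):
            for j in range(m):
                pts = []
                for si, sj in [(1, 1), (1, -1), (-1, 1), (-1, -1)]:
                    z = xi.copy()
                    z[i] += si * h
                    z[j] += sj * h
                    pts.append(
                        loglik(ParamVector.unpack(z, spec_full), X, y, spec_full)
                    )
                hess[i, j] = (pts[0] - pts[1] - pts[2] + pts[3]) / (4 * h * h)
        W = estimate_W(X, fit.params, spec_full)
        np.testing.assert_allclose(W, np.linalg.inv(-hess), rtol=5e-3,
                                   atol=1e-4)

    def test_singular_information_names_direction(self):
        fam = Multinomial(3)
        spec = ModelSpec(fam, p=1)
        params = ParamVector(np.zeros(2), np.zeros((2, 1)), np.zeros((2, 0)),
                             np.zeros(0))
        X = np.zeros((50, 1))  # constant predictor duplicates the intercept
        with pytest.raises(ValueError, match="null direction"):
            estimate_W(X, params, spec)


# ---------------------------------------------------------------------------
# G and the projection
# ---------------------------------------------------------------------------

class TestGradientMatrix:
    def test_workforce_shape(self):
        spec = ModelSpec(Multinomial(4), p=14, constrained=tuple(range(12)),
                         d=1)
        C0 = np.array([[1.0], [1.4], [2.0]])
        B0 = np.ones((1, 12))
        assert build_G(C0, B0, spec).shape == (45, 24)

    def test_differential_of_factorization_map(self):
        # G (0, vec dC, vec dB, 0, 0) = vec(dC B + C dB), exactly
        rng = np.random.default_rng(3)
        spec, params = random_reduced_instance(rng)
        k1, r, d, p = spec.k1, spec.r, spec.d, spec.p
        G = build_G(params.C, params.B, spec)
        dC = rng.standard_normal((k1, d))
        dB = rng.standard_normal((d, r))
        dtheta = np.concatenate([
            np.zeros(k1), dC.ravel(order="F"), dB.ravel(order="F"),
            np.zeros(k1 * (p - r) + spec.k2),
        ])
        got = (G @ dtheta)[k1:k1 + k1 * r]
        expect = (dC @ params.B + params.C @ dB).ravel(order="F")
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_full_rank_factor_spans_beta1_rows(self):
        spec = ModelSpec(Multinomial(4), p=4, constrained=(0, 1, 2, 3), d=3)
        B0 = np.random.default_rng(4).standard_normal((3, 4))
        G = build_G(np.eye(3), B0, spec)
        rows = slice(3, 3 + 12)
        P = projection(G, np.eye(G.shape[0]))
        np.testing.assert_allclose(P[rows, rows], np.eye(12), atol=1e-10)

    def test_rank_deficient_product_rejected(self):
        spec = ModelSpec(Multinomial(4), p=4, constrained=(0, 1, 2, 3), d=2)
        with pytest.raises(ValueError, match="rank"):
            build_G(np.zeros((3, 2)), np.zeros((2, 4)), spec)


class TestProjection:
    def test_invertible_G_gives_identity(self):
        rng = np.random.default_rng(5)
        G = rng.standard_normal((6, 6))
        Sigma = random_spd(rng, 6)
        np.testing.assert_allclose(projection(G, Sigma), np.eye(6),
                                   atol=1e-9)

    def test_orthonormal_columns_euclidean(self):
        rng = np.random.default_rng(6)
        Q, _ = np.linalg.qr(rng.standard_normal((8, 3)))
        np.testing.assert_allclose(projection(Q, np.eye(8)), Q @ Q.T,
                                   atol=1e-10)

    def test_idempotent_and_self_adjoint(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            spec, params = random_reduced_instance(rng)
            G = build_G(params.C, params.B, spec)
            Sigma = random_spd(rng, G.shape[0])
            P = projection(G, Sigma)
            np.testing.assert_allclose(P @ P, P, atol=1e-9)
            np.testing.assert_allclose(Sigma @ P, P.T @ Sigma, atol=1e-9)

    def test_span_equivalence_with_h_chart(self):
        # the projection depends on G only through span(G): the rank-
        # deficient factorization gradient and the injective corner-chart
        # gradient give the same projection and the same avar
        rng = np.random.default_rng(8)
        from rrglm import factorize_corner

        for _ in range(10):
            spec, params = random_reduced_instance(rng)
            C0, B0, _ = factorize_corner(params.beta1, spec.d)
            G = build_G(C0, B0, spec)
            Gh = build_G_hchart(C0, B0, spec)
            assert np.linalg.matrix_rank(Gh) == Gh.shape[1]
            Sigma = random_spd(rng, G.shape[0])
            P1 = projection(G, Sigma)
            # ordinary inverse is valid on the full-column-rank chart
            P2 = Gh @ np.linalg.inv(Gh.T @ Sigma @ Gh) @ Gh.T @ Sigma
            np.testing.assert_allclose(P1, P2, atol=1e-9)
            W = random_spd(rng, G.shape[0])
            a1 = avar_reduced(W, G).avar
            Winv = np.linalg.inv(W)
            a2 = Gh @ np.linalg.inv(Gh.T @ Winv @ Gh) @ Gh.T
            np.testing.assert_allclose(a1, a2, atol=1e-8)

    def test_sigma_must_be_spd(self):
        G = np.eye(3)
        with pytest.raises(ValueError, match="positive definite"):
            projection(G, -np.eye(3))


# ---------------------------------------------------------------------------
# avar
# ---------------------------------------------------------------------------

class TestAvar:
    def test_vacuous_restriction_returns_W(self):
        rng = np.random.default_rng(9)
        spec, params = random_reduced_instance(rng, k1=3, r=4, d=3)
        G = build_G(params.C, params.B, spec)
        W = random_spd(rng, G.shape[0])
        cov = avar_reduced(W, G)
        np.testing.assert_allclose(cov.avar, W, rtol=1e-8, atol=1e-8)

    def test_invariant_to_factor_choice(self):
        rng = np.random.default_rng(10)
        spec, params = random_reduced_instance(rng, k1=3, r=5, d=2)
        W = random_spd(rng, spec.n_params)
        base = avar_reduced(W, build_G(params.C, params.B, spec)).avar
        for _ in range(5):
            M = rng.standard_normal((spec.d, spec.d)) + 2 * np.eye(spec.d)
            G2 = build_G(params.C @ M, np.linalg.inv(M) @ params.B, spec)
            np.testing.assert_allclose(avar_reduced(W, G2).avar, base,
                                       atol=1e-8)

    def test_efficiency_gain_psd(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            spec, params = random_reduced_instance(rng)
            X = rng.standard_normal((300, spec.p))
            W = estimate_W(X, params, spec)
            cov = avar_reduced(W, build_G(params.C, params.B, spec))
            assert np.linalg.eigvalsh(W - cov.avar).min() >= -1e-8

    def test_avar_equals_projection_times_W(self):
        rng = np.random.default_rng(12)
        spec, params = random_reduced_instance(rng)
        G = build_G(params.C, params.B, spec)
        W = random_spd(rng, G.shape[0])
        cov = avar_reduced(W, G)
        np.testing.assert_allclose(
            cov.avar, projection(G, np.linalg.inv(W)) @ W, atol=1e-8
        )

    def test_conformability_error(self):
        with pytest.raises(ValueError, match="rows"):
            avar_reduced(np.eye(4), np.ones((3, 2)))


# ---------------------------------------------------------------------------
# Wald table
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_fit():
    scen = workforce_like_scenario(1500, seed=77)
    X, y = simulate_dataset(scen)
    fit = fit_reduced(X.to_numpy(), y, scen.spec)
    cov = asymptotic_covariance(fit, X.to_numpy())
    return scen, fit, cov


class TestWaldTable:
    def test_layout_matches_study_structure(self, small_fit):
        scen, fit, cov = small_fit
        tab = wald_table(fit, cov)
        assert len(tab) == 45
        assert set(tab["block"]) == {"eta_bar1", "beta1", "beta2"}
        assert (tab["block"] == "beta1").sum() == 36
        # one row per predictor x contrast; 15 predictors incl intercept
        assert tab["predictor"].nunique() == 15
        assert tab["contrast"].nunique() == 3
        assert set(tab["contrast"]) == {
            "log(p1/p4)", "log(p2/p4)", "log(p3/p4)"
        }

    def test_ci_covers_estimate_and_matches_level(self, small_fit):
        scen, fit, cov = small_fit
        tab = wald_table(fit, cov, level=0.95)
        assert np.all(tab["ci_low"] <= tab["estimate"])
        assert np.all(tab["estimate"] <= tab["ci_high"])
        half = (tab["ci_high"] - tab["ci_low"]) / 2
        np.testing.assert_allclose(half, 1.959963984540054 * tab["se"],
                                   atol=1e-10)

    def test_zero_variance_coordinate_degenerate_ci(self, small_fit):
        scen, fit, cov = small_fit
        frozen = AsymCov(W=cov.W, avar=np.zeros_like(cov.avar), n=cov.n)
        tab = wald_table(fit, frozen)
        assert np.all(tab["se"] == 0)
        np.testing.assert_array_equal(tab["ci_low"], tab["estimate"])
        np.testing.assert_array_equal(tab["ci_high"], tab["estimate"])

    def test_refuses_nonconverged_fit(self, small_fit):
        scen, fit, cov = small_fit
        import dataclasses

        bad = dataclasses.replace(fit, converged=False,
                                  message="iteration limit")
        with pytest.raises(ValueError, match="non-converged"):
            wald_table(bad, cov)

    def test_null_coordinate_type_I_error(self, workforce_battery):
        # the 'worry' loading is exactly zero in the generator: its Wald
        # test at 5% must reject at close to the nominal rate
        scen, xis, ses, n_failed = workforce_battery
        labels = coordinate_labels(scen.spec)
        idx = labels.index[
            (labels["predictor"] == "worry")
            & (labels["contrast"] == "log(p1/p4)")
        ][0]
        z = np.abs(xis[:, idx] / ses[:, idx])
        rate = np.mean(z > 1.959963984540054)
        assert 0.035 <= rate <= 0.065


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def gaussian_instance():
    rng = np.random.default_rng(13)
    n, p, q, d = 1000, 4, 3, 1
    X = rng.standard_normal((n, p))
    B = np.outer([1.0, 0.7, -0.5], [0.8, 0.5, 0.3, -0.4])
    Y = X @ B.T + rng.standard_normal((n, q))
    spec = ModelSpec(Gaussian(q, sigma2=1.0), p=p, d=d)
    return X, Y, spec


class TestBootstrap:
    def test_agrees_with_analytic_avar(self, gaussian_instance):
        X, Y, spec = gaussian_instance
        bcov = bootstrap_cov(X, Y, spec, n_boot=400, seed=5)
        fit = fit_reduced(X, Y, spec)
        acov = asymptotic_covariance(fit, X)
        rel = np.linalg.norm(bcov - acov.avar) / np.linalg.norm(acov.avar)
        assert rel < 0.25

    def test_deterministic_given_seed(self, gaussian_instance):
        X, Y, spec = gaussian_instance
        a = bootstrap_cov(X, Y, spec, n_boot=25, seed=42)
        b = bootstrap_cov(X, Y, spec, n_boot=25, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_zero_replicates_rejected(self, gaussian_instance):
        X, Y, spec = gaussian_instance
        with pytest.raises(ValueError, match="positive"):
            bootstrap_cov(X, Y, spec, n_boot=0, seed=1)


# ---------------------------------------------------------------------------
# AIC rank selection
# ---------------------------------------------------------------------------

class TestAicRankPath:
    def test_single_rank_single_row(self):
        scen = workforce_like_scenario(800, seed=19)
        X, y = simulate_dataset(scen)
        tab = aic_rank_path(X.to_numpy(), y, scen.spec, ranks=[1])
        assert len(tab) == 1 and tab["selected"].iloc[0]

    def test_loglik_nondecreasing_in_rank(self):
        scen = workforce_like_scenario(1200, seed=23)
        X, y = simulate_dataset(scen)
        tab = aic_rank_path(X.to_numpy(), y, scen.spec, ranks=[1, 2, 3])
        ll = tab.sort_values("rank")["loglik"].to_numpy()
        assert np.all(np.diff(ll) >= -1e-6)
        # effective counts: raw minus d^2, reaching the full 45 at d = 3
        np.testing.assert_array_equal(
            tab.sort_values("rank")["n_params"], [23, 35, 45]
        )

    def test_invalid_rank_rejected(self):
        scen = workforce_like_scenario(500, seed=2)
        X, y = simulate_dataset(scen)
        with pytest.raises(ValueError, match="outside"):
            aic_rank_path(X.to_numpy(), y, scen.spec, ranks=[5])
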