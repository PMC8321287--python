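"""Mean-field dynamics: sigmoids, polynomial interaction, fixed points, energy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srfield import lifting, srheat
from srfield import neurofield as nf


finite_reals = st.floats(-50.0, 50.0, allow_nan=False)


class TestSigmoids:
    def test_sigma_known_values(self):
        assert nf.sigma(0.5, 5.0) == 0.0
        assert nf.sigma(0.0, 20.0) == 1.0
        assert nf.sigma(1.0, 20.0) == -1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(r=finite_reals, alpha=st.floats(1.001, 40.0))
    def test_sigma_bounded_and_decreasing_flag(self, r, alpha):
        v = nf.sigma(r, alpha)
        assert -1.0 <= v <= 1.0
        assert nf.sigma(r + 0.1, alpha) <= v + 1e-12

    def test_sigma_hat_is_shifted_negated_sigma(self):
        r = np.linspace(-3, 3, 1201)
        for alpha in (2.0, 8.0, 20.0):
            assert np.abs(nf.sigma_hat(r, alpha) + nf.sigma(r + 0.5, alpha)).max() <= 1e-14

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(r=finite_reals, alpha=st.floats(1.001, 40.0))
    def test_sigma_hat_odd(self, r, alpha):
        assert nf.sigma_hat(-r, alpha) == pytest.approx(-nf.sigma_hat(r, alpha), abs=1e-12)

    def test_primitive_even_nonnegative_derivative(self):
        alpha = 6.0
        r = np.linspace(-2, 2, 4001)
        prim = nf.sigma_hat_primitive(r, alpha)
        assert np.all(prim >= 0.0)
        assert np.abs(prim - prim[::-1]).max() <= 1e-14
        h = r[1] - r[0]
        deriv = (prim[2:] - prim[:-2]) / (2 * h)
        away = np.abs(np.abs(r[1:-1]) - 1.0 / alpha) > 2 * h
        assert np.abs(deriv - nf.sigma_hat(r[1:-1], alpha)).max(where=away, initial=0) <= 1e-6


class TestLocalMean:
    def test_constant_is_fixed(self):
        a = np.full((16, 16, 4), 0.4)
        assert np.abs(nf.local_mean(a, 3.0) - a).max() <= 1e-12

    def test_per_slice_sum_preserved(self, rng):
        a = rng.random((16, 16, 4))
        u = nf.local_mean(a, 2.5)
        assert np.abs(u.sum(axis=(0, 1)) - a.sum(axis=(0, 1))).max() <= 1e-10 * a.sum()

    def test_large_sigma_limit_is_spatial_mean(self, rng):
        a = rng.random((16, 16, 3))
        u = nf.local_mean(a, 20.0)
        means = a.mean(axis=(0, 1))
        assert np.abs(u - means[None, None, :]).max() <= 1e-6

    def test_invalid_sigma(self, rng):
        with pytest.raises(ValueError):
            nf.local_mean(rng.random((8, 8, 2)), 0.0)


class TestPolynomialFit:
    def test_linear_regime_recovers_slope(self):
        poly = nf.fit_sigma_hat_poly(0.8, 5, 1.0)
        assert poly.coeffs[1] == pytest.approx(0.8, abs=1e-10)
        others = np.delete(poly.coeffs, 1)
        assert np.abs(others).max() <= 1e-10

    def test_even_coefficients_vanish(self):
        poly = nf.fit_sigma_hat_poly(8.0, 7, 1.0)
        assert np.abs(poly.coeffs[::2]).max() <= 1e-10

    def test_error_decreases_with_degree(self):
        r = np.linspace(-1, 1, 10_000)
        target = nf.sigma_hat(r, 8.0)
        errs = {}
        for n in (3, 7):
            poly = nf.fit_sigma_hat_poly(8.0, n, 1.0)
            errs[n] = np.abs(poly(r) - target).max()
        assert errs[7] < errs[3]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            nf.fit_sigma_hat_poly(8.0, 0, 1.0)
        with pytest.raises(ValueError):
            nf.fit_sigma_hat_poly(8.0, 3, 0.0)


class TestInteractionCoeffs:
    def test_degree_one_expansion(self, rng):
        a = rng.random((4, 4, 2))
        coeffs = nf.interaction_coeffs(a, np.array([0.0, 1.0]))
        assert np.allclose(coeffs[0], a)
        assert np.allclose(coeffs[1], -1.0)

    def test_zero_activation_gives_alternating_coeffs(self):
        c = np.array([0.3, -1.2, 0.5, 2.0])
        coeffs = nf.interaction_coeffs(np.zeros((3, 3, 2)), c)
        for i in range(4):
            assert np.allclose(coeffs[i], (-1.0) ** i * c[i])

    def test_binomial_identity_against_double_loop(self, rng):
        a = rng.random((4, 4, 2))
        c = rng.standard_normal(4)
        coeffs = nf.interaction_coeffs(a, c)
        for b in rng.standard_normal(20):
            lhs = sum(coeffs[i] * b ** i for i in range(4))
            rhs = sum(c[j] * (a - b) ** j for j in range(4))
            assert np.abs(lhs - rhs).max() <= 1e-12


def make_state(rng, n=8, k=4, lo=0.4, hi=0.6, sigma_mu=1.5):
    a0 = rng.random((n, n, k)) * (hi - lo) + lo
    return nf.EvolutionState(A=a0.copy(), A0=a0, U=nf.local_mean(a0, sigma_mu))


class TestWilsonCowanStep:
    def test_zero_state_update_value(self):
        z = np.zeros((8, 8, 4))
        state = nf.EvolutionState(A=z.copy(), A0=z.copy(), U=z.copy())
        cfg = nf.ModelConfig(model="wc", lam=0.0, alpha=20.0, dt=0.1, tau=0.2,
                             dtau=0.01, sigma_mu=1.0, M=1.0)
        nf.wc_step(state, cfg)
        # sigma(0) = 1 and the heat flow preserves constants: update = dt/(2M)
        assert np.abs(state.A - cfg.dt / 2.0).max() <= 1e-10

    def test_fidelity_dominated_fixed_point(self, rng):
        n, k = 16, 4
        bank = lifting.build_cake_bank(n, k)
        img = rng.random((n, n))
        cfg = nf.ModelConfig(model="wc", lam=1e3, alpha=20.0, sigma_mu=2.0,
                             dt=0.9 / 1001.0, tau=0.1, dtau=0.01,
                             max_iters=400, tol=1e-10)
        res = nf.evolve(img, cfg, bank)
        rel = np.linalg.norm(res.output - img) / np.linalg.norm(img)
        assert rel <= 0.02

    def test_converges_within_stability_bound(self, rng):
        n, k = 16, 4
        bank = lifting.build_cake_bank(n, k)
        img = rng.random((n, n))
        cfg = nf.ModelConfig(model="wc", lam=1.0, alpha=20.0, sigma_mu=2.0,
                             dt=0.25, tau=0.1, dtau=0.005, max_iters=10_000, tol=1e-8)
        res = nf.evolve(img, cfg, bank)
        assert res.state.residuals[-1] < 1e-8
        assert res.state.p < 10_000

    def test_constant_input_stays_spatially_constant(self):
        bank = lifting.build_cake_bank(16, 4)
        cfg = nf.ModelConfig(model="wc", lam=0.5, alpha=20.0, sigma_mu=2.0,
                             dt=0.3, tau=0.2, dtau=0.01, max_iters=50, tol=1e-12)
        res = nf.evolve(np.full((16, 16), 0.6), cfg, bank)
        assert np.ptp(res.output) <= 1e-8

    def test_iterates_stay_bounded(self, rng):
        state = make_state(rng, lo=0.0, hi=1.0)
        cfg = nf.ModelConfig(model="wc", lam=1.0, alpha=20.0, sigma_mu=1.5,
                             dt=0.25, tau=0.1, dtau=0.01)
        op = nf.build_interaction_operator(cfg, 8, 4)
        bound = max(np.abs(state.A0).max(),
                    (cfg.lam * np.abs(state.A0).max() + np.abs(state.U).max() + 0.6)
                    / (1 + cfg.lam)) + 1e-9
        for _ in range(2000):
            nf.wc_step(state, cfg, op)
        assert np.abs(state.A).max() <= bound


class TestLHEStep:
    def test_constant_image_is_exact_fixed_point(self):
        n, k = 16, 4
        bank = lifting.build_cake_bank(n, k)
        cfg = nf.ModelConfig(model="lhe", lam=1.0, alpha=8.0, sigma_mu=2.0,
                             dt=0.15, tau=0.5, dtau=0.01, max_iters=5, tol=0.0)
        res = nf.evolve(np.full((n, n), 0.6), cfg, bank)
        assert np.abs(res.activation - res.state.A0).max() <= 1e-10

    def test_polynomial_path_equals_dense_double_sum(self, rng):
        n, k, tau, beta = 6, 3, 0.05, 0.4
        a = rng.random((n, n, k)) * 0.3 + 0.3
        poly = nf.fit_sigma_hat_poly(8.0, 3, 1.0)
        kernel = srheat.dense_heat_kernel(n, k, tau, beta)
        dense_op = lambda x: srheat.dense_heat_oracle(x, tau, beta)
        fast = nf._lhe_interaction(a, poly, dense_op)
        flat = a.transpose(2, 0, 1).reshape(-1)
        contrast = flat[:, None] - flat[None, :]
        sigma_poly = np.polynomial.polynomial.polyval(contrast, poly.coeffs)
        dense = (kernel * sigma_poly).sum(axis=1).reshape(k, n, n).transpose(1, 2, 0)
        assert np.abs(fast - dense).max() <= 1e-10

    def test_energy_descent_with_dense_kernel(self, rng):
        n, k, tau, beta = 8, 4, 0.1, 0.4
        state = make_state(rng, n, k)
        cfg = nf.ModelConfig(model="lhe", lam=1.0, alpha=8.0, sigma_mu=1.5,
                             dt=0.01, tau=tau, dtau=0.005, beta=beta, poly_degree=7)
        kernel = srheat.dense_heat_kernel(n, k, tau, beta)
        op = srheat.HeatFlow(n, k, tau, 0.005, beta).apply
        poly = nf.default_contrast_poly(cfg, state)
        poly_primitive = lambda r: np.polynomial.polynomial.polyval(
            r, nf._poly_primitive(poly.coeffs))
        e_poly = [nf.lhe_energy(state.A, state.A0, state.U, cfg, kernel,
                                primitive=poly_primitive)]
        e_true = [nf.lhe_energy(state.A, state.A0, state.U, cfg, kernel)]
        for _ in range(50):
            nf.lhe_step(state, cfg, op, poly)
            e_poly.append(nf.lhe_energy(state.A, state.A0, state.U, cfg, kernel,
                                        primitive=poly_primitive))
            e_true.append(nf.lhe_energy(state.A, state.A0, state.U, cfg, kernel))
        assert np.diff(e_poly).max() <= 1e-8   # exact Lyapunov of the iterated map
        assert np.diff(e_true).max() <= 1e-8   # survives the polynomial approximation here

    def test_energy_estimate_matches_dense_kernel(self, rng):
        n, k, tau, beta = 6, 3, 0.05, 0.4
        state = make_state(rng, n, k)
        cfg = nf.ModelConfig(model="lhe", lam=1.0, alpha=8.0, sigma_mu=1.5,
                             dt=0.05, tau=tau, dtau=0.005, beta=beta)
        poly = nf.default_contrast_poly(cfg, state)
        kernel = srheat.dense_heat_kernel(n, k, tau, beta)
        dense_op = lambda x: srheat.dense_heat_oracle(x, tau, beta)
        poly_primitive = lambda r: np.polynomial.polynomial.polyval(
            r, nf._poly_primitive(poly.coeffs))
        dense_val = nf.lhe_energy(state.A, state.A0, state.U, cfg, kernel,
                                  primitive=poly_primitive)
        est = nf.lhe_energy_estimate(state, cfg, dense_op, poly)
        assert est == pytest.approx(dense_val, rel=1e-10)

    def test_residuals_decrease_after_burn_in(self):
        from srfield import stimuli

        spec = stimuli.StimulusSpec(size=64, bar_width=10, grating_spacing=7.7,
                                    line_thickness=1.5, variant="grating")
        img = stimuli.make_stimulus(spec)
        bank = lifting.build_cake_bank(64, 8)
        cfg = nf.ModelConfig(model="lhe", lam=2.0, alpha=8.0, sigma_mu=0.5,
                             dt=0.15, tau=5.0, dtau=0.01, max_iters=120, tol=1e-8)
        res = nf.evolve(img, cfg, bank)
        tail = np.array(res.state.residuals[5:])
        assert np.all(np.diff(tail) <= 1e-12)


class TestGaussianBaseline:
    def test_constant_unchanged_and_mass_preserved(self, rng):
        a = rng.random((16, 16, 4))
        out = nf.gaussian_interaction(a, 3.0)
        assert abs(out.sum() - a.sum()) / abs(a.sum()) <= 1e-10
        const = np.full((16, 16, 4), 0.5)
        assert np.abs(nf.gaussian_interaction(const, 3.0) - const).max() <= 1e-12

    def test_spatial_isotropy(self):
        n, K = 32, 4
        a = np.zeros((n, n, K))
        a[n // 2, n // 2, 1] = 1.0
        out = nf.gaussian_interaction(a, 2.0)
        yy, xx = np.mgrid[0:n, 0:n] - n // 2
        w = out.sum(axis=-1)
        mx = (w * xx ** 2).sum() / w.sum()
        my = (w * yy ** 2).sum() / w.sum()
        assert abs(mx - my) <= 1e-8


class TestEvolvePipeline:
    def test_fidelity_limit_recovers_input(self, rng):
        n, k = 16, 4
        bank = lifting.build_cake_bank(n, k)
        img = rng.random((n, n))
        for model in ("wc", "lhe"):
            cfg = nf.ModelConfig(model=model, lam=1e3, alpha=8.0, sigma_mu=2.0,
                                 dt=0.9 / 1001.0, tau=0.0, dtau=0.01,
                                 max_iters=400, tol=1e-10)
            res = nf.evolve(img, cfg, bank)
            rel = np.linalg.norm(res.output - img) / np.linalg.norm(img)
            assert rel <= 0.02

    def test_divergent_step_aborts(self, rng):
        bank = lifting.build_cake_bank(8, 4)
        with pytest.warns(UserWarning, match="stability bound"):
            cfg = nf.ModelConfig(model="wc", lam=1.0, alpha=20.0, sigma_mu=1.0,
                                 dt=2.0, tau=0.1, dtau=0.01, max_iters=5000, tol=0.0)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(RuntimeError, match="divergence"):
                nf.evolve(rng.random((8, 8)), cfg, bank)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            nf.ModelConfig(model="other")
        with pytest.raises(ValueError):
            nf.ModelConfig(kernel="gaussian3d")  # needs sigma_omega
        with pytest.warns(UserWarning, match="stability bound"):
            nf.ModelConfig(lam=1.0, dt=0.9)
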