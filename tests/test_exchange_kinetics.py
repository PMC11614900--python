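"""Exchange-kinetics model and fitting tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sabrex.exchange_kinetics import (
    ExchangeSystem, KineticsDataset, biexp_eval, fit_biexp_global, fit_model,
    kd_from_eigenvalue, rate_matrix, simulate_model,
)


def make_system(k_d=8.0, R=0.07, ratio=1 / 12.24, **kw):
    return ExchangeSystem(k_d=k_d, c_complex=ratio, c_free=1.0,
                          R_e=R, R_f=R, **kw)


TAU = np.concatenate([[0.0], np.geomspace(0.05, 20.0, 17)])


class TestBiexpEval:
    @pytest.mark.parametrize("R,k,A,B,C", [(0.07, 4.63, 1.0, -0.5, 0.1),
                                           (0.0, 1.0, 2.0, 3.0, -1.0)])
    def test_t0_is_sum_of_amplitudes(self, R, k, A, B, C):
        assert biexp_eval(R, k, A, B, C, 0.0) == pytest.approx(A + B + C)

    def test_zero_amplitudes_give_constant(self):
        t = np.linspace(0, 10, 7)
        assert np.allclose(biexp_eval(0.3, 2.0, 0.0, 0.0, 1.7, t), 1.7)


class TestRateMatrix:
    def test_simplified_conserves_magnetization_without_relaxation(self):
        L = rate_matrix("simplified", make_system(R=0.0))
        assert np.allclose(L.sum(axis=0), 0.0, atol=1e-12)

    def test_full_conserves_magnetization_without_relaxation(self):
        sys_ = ExchangeSystem(k_d=5.0, c_complex=0.1, c_free=1.0)
        L = rate_matrix("full", sys_)
        assert np.allclose(L.sum(axis=0), 0.0, atol=1e-12)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            rate_matrix("bogus", make_system())

    @given(k_d=st.floats(0.1, 50.0), r=st.floats(1e-3, 10.0),
           R=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_eigenvalue_identity(self, k_d, r, R):
        """Simplified-model eigenvalues are -R and -(R + k_d (0.5 + r))."""
        sys_ = ExchangeSystem(k_d=k_d, c_complex=r, c_free=1.0, R_e=R, R_f=R)
        ev = np.sort(np.linalg.eigvals(rate_matrix("simplified", sys_)).real)
        expected = np.sort([-R, -(R + k_d * (0.5 + r))])
        assert np.allclose(ev, expected, rtol=1e-9, atol=1e-9)


class TestSimulateModel:
    def test_no_exchange_decouples_pools(self):
        sys_ = ExchangeSystem(k_d=0.0, c_complex=0.1, c_free=1.0,
                              R_e=0.5, R_f=0.2)
        M_e, M_f = simulate_model("simplified", sys_, 1.0, TAU)
        assert np.allclose(M_e, np.exp(-0.5 * TAU), atol=1e-12)
        assert np.allclose(M_f, 0.0, atol=1e-12)

    @pytest.mark.parametrize("model", ["simplified", "full"])
    def test_total_magnetization_conserved_without_relaxation(self, model):
        sys_ = ExchangeSystem(k_d=4.0, c_complex=0.2, c_free=1.0)
        t = np.linspace(0, 100, 41)
        L = rate_matrix(model, sys_)
        y0 = np.zeros(L.shape[0])
        y0[0] = 1.0
        from scipy.linalg import expm
        totals = [expm(L * ti).dot(y0).sum() for ti in t]
        assert np.allclose(totals, 1.0, atol=1e-9)

    def test_free_curve_has_interior_maximum(self):
        M_e, M_f = simulate_model("simplified", make_system(), 1.0, TAU)
        imax = int(np.argmax(M_f))
        assert 0 < imax < len(TAU) - 1
        assert M_f[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_fine_step_euler_integration(self):
        sys_ = make_system(k_d=3.0, R=0.2, ratio=0.3)
        t_grid = np.array([0.0, 0.5, 1.0, 2.0])
        M_e, M_f = simulate_model("simplified", sys_, 1.0, t_grid)
        L = rate_matrix("simplified", sys_)
        y = np.array([1.0, 0.0])
        dt = 1e-5
        out = [y.copy()]
        checkpoints = iter(t_grid[1:])
        nxt = next(checkpoints)
        t = 0.0
        while True:
            y = y + dt * (L @ y)
            t += dt
            if t >= nxt - dt / 2:
                out.append(y.copy())
                try:
                    nxt = next(checkpoints)
                except StopIteration:
                    break
        out = np.array(out)
        assert np.allclose(out[:, 0], M_e, atol=1e-4)
        assert np.allclose(out[:, 1], M_f, atol=1e-4)

    def test_full_converges_to_simplified_for_fast_reassociation(self):
        base = dict(k_d=6.0, c_complex=0.1, c_free=1.0, R_e=0.1, R_f=0.1)
        Ms_e, Ms_f = simulate_model("simplified", ExchangeSystem(**base),
                                    1.0, TAU)
        Mf_e, Mf_f = simulate_model(
            "full", ExchangeSystem(**base, k_assoc=6.0e4), 1.0, TAU)
        assert np.allclose(Mf_e, Ms_e, atol=2e-4)
        assert np.allclose(Mf_f, Ms_f, atol=2e-4)


class TestKdFromEigenvalue:
    def test_worked_example_bound_free_ratio(self):
        """k = 4.63 s^-1 with 12.24 free ligands per complex gives ~8.0."""
        kd, _ = kd_from_eigenvalue(4.63, 1 / 12.24)
        assert kd == pytest.approx(8.0, abs=0.05)

    def test_ratio_half_returns_k(self):
        assert kd_from_eigenvalue(3.3, 0.5)[0] == pytest.approx(3.3)

    def test_zero_eigenvalue_gives_zero_rate(self):
        assert kd_from_eigenvalue(0.0, 0.2)[0] == 0.0

    def test_error_propagation(self):
        kd, s = kd_from_eigenvalue(4.63, 1 / 12.24, sigma_k=0.07)
        assert s == pytest.approx(0.07 / (0.5 + 1 / 12.24), rel=1e-9)


class TestGlobalBiexpFit:
    def test_noiseless_exact_recovery(self):
        R, k = 0.07, 4.63
        M_e = biexp_eval(R, k, 0.2, 0.8, 0.0, TAU)
        M_f = biexp_eval(R, k, 0.9, -0.9, 0.0, TAU)
        fit = fit_biexp_global(KineticsDataset(TAU, M_e, M_f),
                               fit_offset=False)
        assert fit.R == pytest.approx(R, rel=1e-6)
        assert fit.k == pytest.approx(k, rel=1e-6)
        assert not fit.degenerate

    def test_noisy_recovery_within_three_sigma(self):
        rng = np.random.default_rng(7)
        R, k = 0.07, 4.63
        M_e = biexp_eval(R, k, 0.2, 0.8, 0.0, TAU)
        M_f = biexp_eval(R, k, 0.9, -0.9, 0.0, TAU)
        sig = 0.01
        data = KineticsDataset(
            TAU, M_e + rng.normal(0, sig, TAU.shape),
            M_f + rng.normal(0, sig, TAU.shape),
            np.full(TAU.shape, sig), np.full(TAU.shape, sig))
        fit = fit_biexp_global(data, fit_offset=False)
        assert abs(fit.k - k) < 3 * fit.sigma_k
        assert abs(fit.R - R) < 3 * fit.sigma_R

    def test_matrix_model_fast_rate_equals_fast_eigenvalue(self):
        """Fitted (R, k) are the two eigenvalue magnitudes of the two-pool
        rate matrix, so the fitted gap k - R equals the eigenvalue gap."""
        sys_ = make_system(k_d=8.0, R=0.07, ratio=1 / 12.24)
        M_e, M_f = simulate_model("simplified", sys_, 1.0, TAU)
        fit = fit_biexp_global(KineticsDataset(TAU, M_e, M_f),
                               fit_offset=False)
        ev = np.sort(-np.linalg.eigvals(rate_matrix("simplified",
                                                    sys_)).real)
        assert fit.R == pytest.approx(ev[0], rel=1e-5, abs=1e-8)
        assert fit.k == pytest.approx(ev[1], rel=1e-5)
        assert fit.eigenvalue_gap == pytest.approx(
            8.0 * (0.5 + 1 / 12.24), rel=1e-4)

    def test_too_few_points_rejected(self):
        t = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            fit_biexp_global(KineticsDataset(t, t * 0, t * 0))


class TestFitModel:
    def test_noiseless_simplified_exact_recovery(self):
        sys_ = make_system(k_d=8.0, R=0.07)
        M_e, M_f = simulate_model("simplified", sys_, 1.0, TAU)
        data = KineticsDataset(TAU, M_e, M_f, ratio=sys_.ratio)
        fit = fit_model(data, "simplified")
        assert fit.k_d == pytest.approx(8.0, rel=1e-6)
        assert fit.R == pytest.approx(0.07, rel=1e-5)

    def test_noisy_recovery_within_three_sigma(self):
        rng = np.random.default_rng(11)
        sys_ = make_system(k_d=8.0, R=0.07)
        M_e, M_f = simulate_model("simplified", sys_, 1.0, TAU)
        sig = 0.02
        data = KineticsDataset(
            TAU, M_e + rng.normal(0, sig, TAU.shape),
            M_f + rng.normal(0, sig, TAU.shape),
            np.full(TAU.shape, sig), np.full(TAU.shape, sig),
            ratio=sys_.ratio)
        fit = fit_model(data, "simplified")
        assert abs(fit.k_d - 8.0) < 3 * fit.sigma_kd

    def test_full_model_on_simplified_data_agrees(self):
        sys_ = make_system(k_d=8.0, R=0.07)
        M_e, M_f = simulate_model("simplified", sys_, 1.0, TAU)
        data = KineticsDataset(TAU, M_e, M_f, ratio=sys_.ratio)
        fit = fit_model(data, "full")
        assert fit.k_d == pytest.approx(8.0, rel=0.05)

    def test_eigen_analysis_and_model_fit_agree_on_two_pool_data(self):
        sys_ = make_system(k_d=8.0, R=0.07)
        M_e, M_f = simulate_model("simplified", sys_, 1.0, TAU)
        data = KineticsDataset(TAU, M_e, M_f, ratio=sys_.ratio)
        mfit = fit_model(data, "simplified")
        bfit = fit_biexp_global(data, fit_offset=False)
        kd_eig, _ = kd_from_eigenvalue(bfit.eigenvalue_gap, sys_.ratio)
        assert mfit.k_d == pytest.approx(kd_eig, rel=1e-3)

    def test_roundtrip_eigenvalue_recovers_generating_kd(self):
        """gen -> biexp fit -> Eq.-style conversion returns k_d (noiseless).

        The fitted fast constant is R + k_d (0.5 + r); subtracting the
        fitted slow constant isolates the exchange eigenvalue exactly.
        """
        for kd_true, r in [(1.0, 0.05), (8.0, 1 / 12.24), (25.0, 0.5)]:
            sys_ = make_system(k_d=kd_true, R=0.07, ratio=r)
            M_e, M_f = simulate_model("simplified", sys_, 1.0, TAU)
            fit = fit_biexp_global(KineticsDataset(TAU, M_e, M_f),
                                   fit_offset=False)
            kd, _ = kd_from_eigenvalue(fit.eigenvalue_gap, r)
            assert kd == pytest.approx(kd_true, rel=1e-3)


class TestDatasetValidation:
    def test_non_monotone_tau_rejected(self):
        with pytest.raises(ValueError, match="non-monotone"):
            KineticsDataset(np.array([0.0, 2.0, 1.0]), np.zeros(3),
                            np.zeros(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            KineticsDataset(np.array([0.0, 1.0]), np.zeros(3), np.zeros(2))

    def test_normalization_scales_both_curves(self):
        d = KineticsDataset(np.array([0.0, 1.0]), np.array([2.0, 1.0]),
                            np.array([0.5, 0.25]))
        norm, scale = d.normalized()
        assert scale == 2.0
        assert norm.M_e.max() == pytest.approx(1.0)
        assert norm.M_f[0] == pytest.approx(0.25)
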