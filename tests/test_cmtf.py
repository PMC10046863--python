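"""Tests of the coupled decomposition: forward models, objective,
gradients, optimization, normalization, and ensembles."""

import numpy as np
import pytest

import cmtfusion as cf
from cmtfusion.cmtf import CMTF, CMTFModel, CMTFWeights, OptimizationError


def _random_model(dims, R, K, Q, seed):
    rng = np.random.default_rng(seed)
    Is, If, Ic, Iv = dims
    return CMTFModel(
        S=rng.standard_normal((Is, R)), F=rng.standard_normal((If, R)),
        C=rng.standard_normal((Ic, R)), V=rng.standard_normal((Iv, R)),
        B=rng.standard_normal((Iv, K)), N=rng.standard_normal((Is, Q)),
        P=rng.standard_normal((Iv, Q)),
    )


class TestFMRIForward:
    def test_impulse_hrf_reduces_to_matrix_product(self):
        m = _random_model((30, 5, 4, 8), 2, 1, 0, seed=1)
        basis = cf.build_hrf_basis(K=1, TR=2.0)
        basis.basis = np.zeros_like(basis.basis)
        basis.basis[0, 0] = 1.0
        m.B[:] = 1.0
        np.testing.assert_allclose(cf.fmri_forward(m, basis), m.S @ m.V.T,
                                   atol=1e-12)

    def test_zero_sources_leave_uncoupled_term(self, basis_k2):
        m = _random_model((30, 5, 4, 8), 2, 2, 2, seed=2)
        m.S[:] = 0.0
        np.testing.assert_allclose(cf.fmri_forward(m, basis_k2), m.N @ m.P.T,
                                   atol=1e-12)

    def test_matches_quadruple_loop_oracle(self, basis_k2):
        m = _random_model((25, 5, 4, 7), 2, 2, 1, seed=3)
        Yhat = cf.fmri_forward(m, basis_k2)
        h = basis_k2.basis
        Is, Iv = 25, 7
        brute = np.zeros((Is, Iv))
        for t in range(Is):
            for v in range(Iv):
                for r in range(2):
                    for k in range(2):
                        conv = sum(h[k, tau] * m.S[t - tau, r]
                                   for tau in range(min(t + 1, h.shape[1])))
                        brute[t, v] += conv * m.B[v, k] * m.V[v, r]
                brute[t, v] += sum(m.N[t, q] * m.P[v, q] for q in range(1))
        assert np.linalg.norm(Yhat - brute) <= 1e-10 * np.linalg.norm(brute)


class TestAmplitudes:
    def test_unit_norm_columns(self):
        m = _random_model((20, 6, 5, 9), 3, 2, 0, seed=4)
        for M in (m.S, m.F, m.C):
            M /= np.linalg.norm(M, axis=0, keepdims=True)
        lam_x, _ = cf.amplitudes(m)
        np.testing.assert_allclose(lam_x, 1.0, atol=1e-12)

    def test_zero_hrf_coefficients(self):
        m = _random_model((20, 6, 5, 9), 3, 2, 0, seed=5)
        m.B[:] = 0.0
        _, lam_y = cf.amplitudes(m)
        np.testing.assert_array_equal(lam_y, 0.0)

    def test_matches_direct_formula(self):
        m = _random_model((20, 6, 5, 9), 3, 2, 1, seed=6)
        lam_x, lam_y = cf.amplitudes(m)
        for r in range(3):
            expected = (np.linalg.norm(m.S[:, r]) * np.linalg.norm(m.F[:, r])
                        * np.linalg.norm(m.C[:, r]))
            assert lam_x[r] == pytest.approx(expected, rel=1e-12)
            expected_y = sum(
                np.linalg.norm(m.B[:, k] * m.V[:, r]) for k in range(2)
            )
            assert lam_y[r] == pytest.approx(expected_y, rel=1e-12)


class TestObjective:
    def test_zero_at_ground_truth(self, small_truth, basis_k2):
        gt = small_truth
        X = cf.assemble_eeg_tensor(gt, snr_db=np.inf)
        Y = cf.assemble_fmri_matrix(gt, basis_k2, snr_db=np.inf)
        m = CMTFModel(S=gt.S, F=gt.F, C=gt.C, V=gt.V, B=gt.B, N=gt.N, P=gt.P)
        w = CMTFWeights(gamma_x=0.0, gamma_y=0.0)
        assert cf.cmtf_objective(m, X, Y, basis_k2, w) == pytest.approx(0.0, abs=1e-18)

    def test_zero_model_gives_data_energy(self, basis_k2, rng):
        X = rng.standard_normal((20, 5, 4))
        Y = rng.standard_normal((20, 7))
        m = _random_model((20, 5, 4, 7), 2, 2, 1, seed=7)
        for name in ("S", "F", "C", "V", "B", "N", "P"):
            getattr(m, name)[:] = 0.0
        w = CMTFWeights(beta_x=1.0, beta_y=1.0, gamma_x=0.0, gamma_y=0.0)
        expected = np.sum(X**2) + np.sum(Y**2)
        assert cf.cmtf_objective(m, X, Y, basis_k2, w) == pytest.approx(expected)

    def test_matches_elementwise_oracle(self, basis_k2, rng):
        X = rng.standard_normal((20, 5, 4))
        Y = rng.standard_normal((20, 7))
        m = _random_model((20, 5, 4, 7), 2, 2, 1, seed=8)
        w = CMTFWeights(beta_x=0.3, beta_y=0.7, gamma_x=0.05, gamma_y=0.02,
                        scale_free=False)
        J = cf.cmtf_objective(m, X, Y, basis_k2, w)
        Xhat = np.einsum("tr,fr,cr->tfc", m.S, m.F, m.C)
        Yhat = cf.fmri_forward(m, basis_k2)
        lam_x, lam_y = cf.amplitudes(m)
        oracle = (0.3 * np.sum((X - Xhat) ** 2) + 0.7 * np.sum((Y - Yhat) ** 2)
                  + 0.05 * lam_x.sum() + 0.02 * lam_y.sum())
        assert J == pytest.approx(oracle, rel=1e-10)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, small_coupled,
                                                          basis_k2):
        """Directional finite differences per coordinate block agree with
        the analytic gradient to <= 1e-5 relative."""
        X, Y = small_coupled
        prob = CMTF(X, Y, basis_k2, rank=2, q=1)
        init = cf.random_init(X.shape, 2, seed=21)
        m0 = prob._init_model(init)
        theta = prob._pack(m0.S, m0.F, m0.C, m0.V, m0.B, m0.N, m0.P)
        _, g = prob._objective_grad(theta)
        rng = np.random.default_rng(0)
        pos = 0
        for shape in prob._shapes:
            n = int(np.prod(shape))
            if n == 0:
                continue
            d = np.zeros_like(theta)
            d[pos : pos + n] = rng.standard_normal(n)
            d /= np.linalg.norm(d)
            h = 1e-4
            fd = (prob._objective_grad(theta + h * d)[0]
                  - prob._objective_grad(theta - h * d)[0]) / (2 * h)
            fd2 = (prob._objective_grad(theta + h / 2 * d)[0]
                   - prob._objective_grad(theta - h / 2 * d)[0]) / h
            fd = (4 * fd2 - fd) / 3  # Richardson extrapolation
            an = float(g @ d)
            # floor covers finite-difference round-off on blocks whose
            # gradient is numerically zero (N, P start at an exact optimum)
            assert abs(fd - an) <= 1e-5 * max(abs(fd), abs(an), 1e-4)
            pos += n

    def test_gradient_vanishes_at_truth_in_coupled_cp_limit(self, small_stim):
        """With gamma = 0, Q = 0, K = 1 and an impulse HRF the optimum of J
        coincides with a coupled CP problem; at the noiseless truth the
        gradient is (numerically) zero."""
        gt = cf.generate_ground_truth(R=2, K=1, Q=0, dims=(70, 10, 8, 15),
                                      stimulus=small_stim, seed=31)
        gt.B[:] = 1.0
        basis = cf.build_hrf_basis(K=1, TR=2.0)
        basis.basis = np.zeros_like(basis.basis)
        basis.basis[0, 0] = 1.0
        X = cf.assemble_eeg_tensor(gt, snr_db=np.inf)
        Y = cf.assemble_fmri_matrix(gt, basis, snr_db=np.inf)
        prob = CMTF(X, Y, basis, rank=2, q=0,
                    weights=CMTFWeights(gamma_x=0.0, gamma_y=0.0))
        theta = prob._pack(gt.S, gt.F, gt.C, gt.V, gt.B, gt.N, gt.P)
        J, g = prob._objective_grad(theta)
        assert J == pytest.approx(0.0, abs=1e-16)
        assert np.linalg.norm(g) <= 1e-6


class TestFit:
    def test_parameter_recovery_small(self, small_truth, small_coupled,
                                      basis_k2):
        X, Y = small_coupled
        gt = small_truth
        best = None
        for s in range(5):
            cp, _ = cf.cpd_fit(X, 2, seed=s, max_iter=200)
            res = CMTF(X, Y, basis_k2, 2, q=1).fit(init=cp, max_iter=500)
            if best is None or res.objective < best.objective:
                best = res
        fms = cf.factor_match_score(
            cf.CPDFactors(gt.S, gt.F, gt.C), best.model.eeg_factors()
        )
        assert fms >= 0.95

    def test_zero_iterations_returns_initialized_model(self, small_coupled,
                                                       basis_k2):
        X, Y = small_coupled
        prob = CMTF(X, Y, basis_k2, 2, q=1)
        res = prob.fit(init=cf.random_init(X.shape, 2, seed=0), max_iter=0)
        assert not res.diagnostics.converged
        assert res.diagnostics.n_iter == 0

    def test_cost_trace_monotone(self, small_coupled, basis_k2):
        X, Y = small_coupled
        res = CMTF(X, Y, basis_k2, 2, q=1).fit(
            init=cf.random_init(X.shape, 2, seed=5), max_iter=150
        )
        trace = np.array(res.diagnostics.cost_trace)
        assert np.all(np.diff(trace) <= 1e-8 * np.maximum(trace[:-1], 1e-12))

    def test_coupling_is_shared(self, small_coupled, basis_k2):
        """Perturbing S changes both reconstructions: the temporal factor
        is one shared object."""
        X, Y = small_coupled
        res = CMTF(X, Y, basis_k2, 2, q=1).fit(
            init=cf.random_init(X.shape, 2, seed=6), max_iter=50
        )
        m = res.model
        X0, Y0 = res.reconstruct_eeg(), res.predict_fmri()
        m.S[3, 0] += 0.1
        X1 = np.einsum("tr,fr,cr->tfc", m.S, m.F, m.C)
        Y1 = cf.fmri_forward(m, basis_k2)
        assert np.linalg.norm(X1 - X0) > 0
        assert np.linalg.norm(Y1 - Y0) > 0

    def test_l1_penalty_shrinks_amplitudes(self, small_coupled, basis_k2):
        """Fitted ||lambda_x||_1 does not increase as gamma_x grows."""
        X, Y = small_coupled
        init = None
        norms = []
        for gx in (0.0, 0.05, 0.5):
            cp, _ = cf.cpd_fit(X, 2, seed=2, max_iter=200)
            res = CMTF(X, Y, basis_k2, 2, q=1,
                       weights=CMTFWeights(gamma_x=gx, gamma_y=0.01)).fit(
                init=cp, max_iter=400)
            lam_x, _ = res.amplitudes()
            norms.append(lam_x.sum())
        assert norms[0] + 1e-9 >= norms[1] >= norms[2] - 1e-9

    def test_nonfinite_inputs_rejected(self, basis_k2):
        X = np.zeros((10, 4, 3))
        Y = np.zeros((10, 5))
        Y[0, 0] = np.inf
        with pytest.raises(ValueError):
            CMTF(X, Y, basis_k2, 1)

    def test_time_mismatch_rejected(self, basis_k2):
        with pytest.raises(ValueError):
            CMTF(np.zeros((10, 4, 3)), np.zeros((11, 5)), basis_k2, 1)


class TestNormalize:
    def test_unit_norms_and_idempotence(self, small_coupled, basis_k2):
        X, Y = small_coupled
        res = CMTF(X, Y, basis_k2, 2, q=1).fit(
            init=cf.random_init(X.shape, 2, seed=7), max_iter=100
        )
        m = cf.normalize_model(res.model)
        for M in (m.F, m.C, m.V):
            np.testing.assert_allclose(np.linalg.norm(M, axis=0), 1.0,
                                       atol=1e-12)
        m2 = cf.normalize_model(m)
        np.testing.assert_allclose(m2.S, m.S, atol=1e-12)
        np.testing.assert_allclose(m2.v_scale, m.v_scale, atol=1e-12)

    def test_reconstructions_preserved(self, small_coupled, basis_k2):
        X, Y = small_coupled
        res = CMTF(X, Y, basis_k2, 2, q=1).fit(
            init=cf.random_init(X.shape, 2, seed=8), max_iter=100
        )
        m, n = res.model, cf.normalize_model(res.model)
        Xa = np.einsum("tr,fr,cr->tfc", m.S, m.F, m.C)
        Xb = np.einsum("tr,fr,cr->tfc", n.S, n.F, n.C)
        assert np.linalg.norm(Xa - Xb) <= 1e-10 * np.linalg.norm(Xa)
        Ya = cf.fmri_forward(m, basis_k2)
        Yb = cf.fmri_forward(n, basis_k2)
        assert np.linalg.norm(Ya - Yb) <= 1e-10 * np.linalg.norm(Ya)

    def test_prescaled_model_normalizes_to_same_form(self, small_coupled,
                                                     basis_k2):
        X, Y = small_coupled
        res = CMTF(X, Y, basis_k2, 2, q=1).fit(
            init=cf.random_init(X.shape, 2, seed=9), max_iter=50
        )
        m = res.model
        scaled = m.copy()
        scaled.F[:, 0] *= 3.0
        scaled.S[:, 0] /= 3.0
        a, b = cf.normalize_model(m), cf.normalize_model(scaled)
        np.testing.assert_allclose(a.F, b.F, atol=1e-10)
        np.testing.assert_allclose(a.S, b.S, atol=1e-10)


class TestEnsemble:
    def test_reproducible_and_distinct_runs(self, small_coupled, basis_k2):
        X, Y = small_coupled
        kw = dict(n_runs=2, seed=3, cpd_max_iter=50, max_iter=50)
        a = cf.run_ensemble(X, Y, basis_k2, 2, Q=1, **kw)
        b = cf.run_ensemble(X, Y, basis_k2, 2, Q=1, **kw)
        assert len(a) == len(b) == 2
        np.testing.assert_array_equal(a[0].model.S, b[0].model.S)
        assert not np.array_equal(a[0].model.S, a[1].model.S)

    def test_single_run(self, small_coupled, basis_k2):
        X, Y = small_coupled
        out = cf.run_ensemble(X, Y, basis_k2, 1, Q=0, n_runs=1, seed=0,
                              cpd_max_iter=30, max_iter=30)
        assert len(out) == 1

    def test_most_runs_reach_comparable_fit(self, small_coupled, basis_k2):
        """On an easy problem nearly all runs land near the best fit."""
        X, Y = small_coupled
        out = cf.run_ensemble(X, Y, basis_k2, 2, Q=1, n_runs=10, seed=17,
                              cpd_max_iter=150, max_iter=300)
        errs = np.array([r.diagnostics.rel_error_x for r in out])
        assert (errs <= 2 * errs.min()).sum() >= 9
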