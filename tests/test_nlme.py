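"""NLME engine: recovery, Laplace accuracy, empirical-Bayes individualisation."""

import warnings

import numpy as np
import pytest

from tiapbms import CohortDesign, DecayConstants, NLMECurveModel, generate_cohort, get_function
from tiapbms.cohort import TimeActivityCohort
from tiapbms.nlme import _LaplaceKernel, cv_from_se2


def gauss_hermite_neg2ll(cohort, x_f, om2, sig2, n_nodes=64):
    """Brute-force 1-D Gauss-Hermite marginal -2lnL (random effect on A1 of f2a)."""
    fn = get_function("f2a")
    decay = DecayConstants()
    nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for pid in cohort.patient_ids:
        sub = cohort.patient(pid)
        t = sub["time_min"].to_numpy()
        logy = np.log(sub["activity"].to_numpy())
        like = 0.0
        for z, w in zip(nodes, wts):
            eta = np.sqrt(2.0 * om2) * z
            lnf = np.log(fn.evaluate(
                {"A1": np.exp(x_f[0] + eta), "lambda1": np.exp(x_f[1])}, t, decay))
            ll = -0.5 * np.sum((logy - lnf) ** 2) / sig2 \
                - 0.5 * len(t) * np.log(2 * np.pi * sig2)
            like += w * np.exp(ll) / np.sqrt(np.pi)
        total += -2.0 * np.log(like)
    return total


class TestCV:
    def test_zero_se(self):
        assert cv_from_se2(0.0) == 0.0

    def test_gate_boundary(self):
        # sqrt(exp(se^2) - 1) = 0.5  <=>  se^2 = ln(1.25)
        assert cv_from_se2(np.log(1.25)) == pytest.approx(0.5, rel=1e-12)

    def test_infinite_se(self):
        assert cv_from_se2(np.inf) == np.inf


class TestLaplaceAccuracy:
    def test_matches_gauss_hermite_on_linear_toy(self, tiny_cohort):
        """Log-linear random effect: Laplace equals quadrature to <= 1e-3."""
        kern = _LaplaceKernel(get_function("f2a"), DecayConstants(), tiny_cohort, ["A1"])
        x_f = np.log([0.045, 2.8e-4])
        om2, sig2 = 0.01, 0.0225
        lap, _ = kern.neg2ll(x_f, np.array([om2]), sig2)
        gh = gauss_hermite_neg2ll(tiny_cohort, x_f, om2, sig2)
        assert abs(lap - gh) <= 1e-3

    def test_matches_exact_linear_gaussian_marginal(self, tiny_cohort):
        kern = _LaplaceKernel(get_function("f2a"), DecayConstants(), tiny_cohort, ["A1"])
        x_f = np.log([0.045, 2.8e-4])
        om2, sig2 = 0.09, 0.02
        lap, _ = kern.neg2ll(x_f, np.array([om2]), sig2)
        decay = DecayConstants()
        total = 0.0
        for pid in tiny_cohort.patient_ids:
            sub = tiny_cohort.patient(pid)
            t = sub["time_min"].to_numpy()
            logy = np.log(sub["activity"].to_numpy())
            mean = x_f[0] - (np.exp(x_f[1]) + decay.lambda_phys) * t
            S = sig2 * np.eye(len(t)) + om2
            r = logy - mean
            total += np.log(np.linalg.det(2 * np.pi * S)) + r @ np.linalg.solve(S, r)
        assert lap == pytest.approx(total, abs=1e-9)


class TestFit:
    def test_noise_free_recovery(self, noisefree_f2a_sim):
        """Exact generating parameters recovered when all variability is off."""
        m = NLMECurveModel(function="f2a", n_starts=1).fit(noisefree_f2a_sim.cohort)
        assert m.converged_
        assert m.fixed_effects_["A1"] == pytest.approx(0.04, rel=1e-3)
        assert m.fixed_effects_["lambda1"] == pytest.approx(3e-4, rel=1e-3)
        # empirical-Bayes individual parameters collapse onto the truth
        for pid in noisefree_f2a_sim.cohort.patient_ids:
            ind = m.individual_params(pid)
            assert ind["A1"] == pytest.approx(0.04, rel=1e-3)

    def test_k_counting_default_random_effects(self, default_sim):
        m = NLMECurveModel(function="f3a", n_starts=1).fit(default_sim.cohort)
        assert m.K_ == 7  # 3 fixed + 3 variances + 1 residual

    def test_single_patient_warns(self):
        sim = generate_cohort(CohortDesign(n_patients=1, n_extra_patients=0), seed=0)
        with pytest.warns(UserWarning, match="fewer than 2 patients"):
            m = NLMECurveModel(function="f2a", n_starts=1).fit(sim.cohort)
        assert not m.omega2_identifiable_

    def test_unknown_patient_raises(self, default_sim):
        m = NLMECurveModel(function="f2a", n_starts=1).fit(default_sim.cohort)
        with pytest.raises(KeyError):
            m.individual_params("does-not-exist")

    def test_unknown_random_effect_rejected(self, default_sim):
        with pytest.raises(ValueError, match="random effect"):
            NLMECurveModel(function="f2a", random_effects=["A9"]).fit(default_sim.cohort)

    def test_relabelling_invariance(self, default_sim):
        """Patient labels and row order must not change the fit."""
        m1 = NLMECurveModel(function="f2a", n_starts=1).fit(default_sim.cohort)
        frame = default_sim.cohort.frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        frame = frame.assign(patient_id="Z" + frame["patient_id"].str[1:])
        shuffled = TimeActivityCohort._validated(frame)
        m2 = NLMECurveModel(function="f2a", n_starts=1).fit(shuffled)
        assert m1.neg2loglik_ == pytest.approx(m2.neg2loglik_, abs=1e-6)
        for p in m1.fixed_effects_:
            assert m1.fixed_effects_[p] == pytest.approx(m2.fixed_effects_[p], rel=1e-5)

    def test_nesting_random_effects_lowers_objective(self, default_sim):
        """A richer random-effect structure cannot fit worse (same data)."""
        sub = NLMECurveModel(function="f2a", random_effects=["A1"],
                             n_starts=2).fit(default_sim.cohort)
        full = NLMECurveModel(function="f2a", random_effects=["A1", "lambda1"],
                              n_starts=2).fit(default_sim.cohort)
        assert full.neg2loglik_ <= sub.neg2loglik_ + 1e-3

    def test_pooled_limit_equals_log_nls(self, default_sim):
        """No random effects + fixed sigma reduces to pooled log-scale NLS."""
        from scipy.optimize import least_squares

        m = NLMECurveModel(function="f2a", random_effects=[],
                           fix_sigma_res=0.2, n_starts=2).fit(default_sim.cohort)
        t = default_sim.cohort.frame["time_min"].to_numpy()
        logy = np.log(default_sim.cohort.frame["activity"].to_numpy())
        fn = get_function("f2a")
        decay = DecayConstants()

        def resid(x):
            f = fn.evaluate({"A1": np.exp(x[0]), "lambda1": np.exp(x[1])}, t, decay)
            return logy - np.log(f)

        sol = least_squares(resid, np.log([0.03, 2e-4]), method="lm")
        assert m.fixed_effects_["A1"] == pytest.approx(np.exp(sol.x[0]), rel=1e-4)
        assert m.fixed_effects_["lambda1"] == pytest.approx(np.exp(sol.x[1]), rel=1e-4)

    def test_predict_population_and_individual(self, default_sim):
        m = NLMECurveModel(function="f2a", n_starts=1).fit(default_sim.cohort)
        t = np.array([100.0, 1000.0])
        pop = m.predict(t)
        assert pop.shape == (2,) and np.all(pop > 0)
        pid = default_sim.cohort.patient_ids[0]
        ind = m.predict(t, groups=[pid, pid])
        fnval = get_function("f2a").evaluate(m.individual_params(pid), t, m.decay_)
        np.testing.assert_allclose(ind, fnval)

    def test_unfittable_function_flagged_not_converged(self, default_sim):
        """A curve pinned to zero at t=0 cannot describe these data."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = NLMECurveModel(function="f5b", n_starts=1).fit(default_sim.cohort)
        assert not m.converged_
        assert m.neg2loglik_ == np.inf
        assert m.cv_max_ == np.inf
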