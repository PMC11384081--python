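"""Non-linear mixed-effects fitting of sum-of-exponential curves.

Population model
----------------
For patient *i* with observations :math:`y_{ij}` at times :math:`t_{ij}`:

.. math::

    \\ln y_{ij} = \\ln f(t_{ij}; P_i) + \\varepsilon_{ij},
    \\qquad \\varepsilon_{ij} \\sim N(0, \\sigma_{res}^2)

(the "exponential" or multiplicative residual-error model), with individual
parameters tied to population typical values (fixed effects, TVP) through
log-normal inter-individual variability

.. math::

    P_{ik} = TVP_k \\exp(\\eta_{ik}), \\qquad \\eta_{ik} \\sim N(0, \\omega_k^2)

with a diagonal random-effect covariance.  Fraction-type parameters
(``alpha``) instead receive the Gaussian deviation additively on the logit
scale so the [0, 1] constraint is respected.

The marginal likelihood (random effects integrated out) is approximated by
the Laplace method at the per-patient empirical-Bayes mode; the reported
objective is the minimised :math:`-2\\ln P`.  The inner mode search is a
damped Newton iteration with analytic gradients, vectorised across
patients; the Laplace log-determinant uses a finite-difference Hessian of
that analytic gradient.  The outer search over (log TVP, log omega^2,
log sigma) is a Nelder-Mead simplex with a data-driven pooled-fit start
plus seeded log-normal multi-start jitter.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from ._numdiff import fd_hessian
from .cohort import TimeActivityCohort, as_cohort
from .functions import DecayConstants, SOEFunction, get_function

__all__ = ["NLMECurveModel", "fit_nlme", "cv_from_se2"]

_LOG_TINY = np.log(np.finfo(float).tiny)


def _transform_forward(values, kinds):
    """Natural scale -> unconstrained scale (log, or logit for fractions)."""
    out = np.empty(len(values))
    for i, (v, k) in enumerate(zip(values, kinds)):
        out[i] = logit(v) if k == "alpha" else np.log(v)
    return out


def _transform_inverse(z, kinds):
    out = np.empty_like(z)
    for i, k in enumerate(kinds):
        out[..., i] = expit(z[..., i]) if k == "alpha" else np.exp(z[..., i])
    return out


def cv_from_se2(se2):
    """CV of a log-normally distributed quantity: sqrt(exp(se^2) - 1)."""
    se2 = np.asarray(se2, dtype=float)
    with np.errstate(over="ignore"):
        out = np.sqrt(np.expm1(se2))
    return np.where(np.isfinite(se2), out, np.inf) if out.ndim else (
        float(out) if np.isfinite(se2) else np.inf
    )


class _LaplaceKernel:
    """Vectorised per-patient inner problem for one candidate function."""

    def __init__(self, fn: SOEFunction, decay: DecayConstants, cohort: TimeActivityCohort,
                 re_params: list[str]):
        self.fn = fn
        self.decay = decay
        self.t, self.logy, self.mask, self.ids = cohort.padded_arrays()
        self.n_i = self.mask.sum(axis=1)
        self.P = len(self.ids)
        self.re_idx = np.asarray([fn.params.index(p) for p in re_params], dtype=int)
        self.q = len(self.re_idx)
        self.kinds = fn.kinds
        K = fn.n_shape_params
        # coefficient and rate maps are (at most) linear + bilinear in the
        # shape parameters: c = B theta + 0.5 theta' Cpp theta, mu = R theta
        # + lambda_phys, with constant B, Cpp, R
        self._B = fn.coef_jacobian(np.zeros(K))      # (M, K)
        self._Cpp = fn.coef_hessian_const()          # (M, K, K)
        self._R = fn.rate_jacobian(np.zeros(K))      # (M, K)
        self._bilinear = bool(np.any(self._Cpp))
        self._alpha_cols = np.asarray([k == "alpha" for k in fn.kinds])

    # -- model pieces -------------------------------------------------------

    def _theta(self, x_f, eta):
        """Individual natural-scale parameters, shape (P, K)."""
        z = np.repeat(x_f[None, :], self.P, axis=0)
        if self.q:
            z[:, self.re_idx] += eta
        if self._alpha_cols.any():
            return _transform_inverse(z, self.kinds)
        return np.exp(z)

    def _eval(self, x_f, eta, om2, sig2, order=0):
        """Joint per-patient negative log density, derivatives wrt eta.

        order 0: value only; order 1: + gradient and Gauss-Newton Hessian;
        order 2: + exact Hessian.  Shapes: (P,), (P, q), (P, q, q).
        """
        t, re, q = self.t, self.re_idx, self.q
        tiny = np.finfo(float).tiny
        theta = self._theta(x_f, eta)
        if self._bilinear:
            dc_var = np.einsum("mkl,pl->pmk", self._Cpp, theta)
            c = theta @ self._B.T + 0.5 * np.einsum("pmk,pk->pm", dc_var, theta)
        else:
            c = theta @ self._B.T
        mu = theta @ self._R.T + self.decay.lambda_phys
        E = np.exp(-mu[:, None, :] * t[:, :, None])
        f = np.einsum("pm,pjm->pj", c, E)
        fc = np.clip(f, tiny, None)
        r = (self.logy - np.log(fc)) * self.mask
        val = 0.5 * np.einsum("pj,pj->p", r, r) / sig2 \
            + 0.5 * self.n_i * np.log(2 * np.pi * sig2)
        if q:
            val = val + 0.5 * np.sum(eta * eta / om2, axis=1) \
                + 0.5 * np.sum(np.log(2 * np.pi * om2))
        if order == 0:
            return val, None, None

        dc = self._B[None, :, :] + dc_var if self._bilinear else \
            np.broadcast_to(self._B, (self.P,) + self._B.shape)
        dmu = self._R
        df = np.einsum("pjm,pmk->pjk", E, dc)
        df -= np.einsum("pj,pjm,mk->pjk", t, E * c[:, None, :], dmu)
        if self._alpha_cols.any():
            gp = np.where(self._alpha_cols, theta * (1.0 - theta), theta)
            gpp = np.where(self._alpha_cols,
                           theta * (1.0 - theta) * (1.0 - 2.0 * theta), theta)
        else:
            gp = gpp = theta
        L = df[:, :, re] * gp[:, None, re] / fc[:, :, None]
        Lm = L * self.mask[:, :, None]
        grad = -np.einsum("pj,pjq->pq", r, Lm) / sig2 + eta / om2
        idx = np.arange(q)
        H_gn = np.einsum("pjq,pjr->pqr", Lm, Lm) / sig2
        H_gn[:, idx, idx] += 1.0 / om2
        if order == 1:
            return val, grad, H_gn

        d2f = np.einsum("pjm,mkl->pjkl", E, self._Cpp)
        cross = np.einsum("pj,pjm,pmk,ml->pjkl", t, E, dc, dmu)
        d2f -= cross + np.swapaxes(cross, -1, -2)
        d2f += np.einsum("pj,pjm,mk,ml->pjkl", t * t, E * c[:, None, :], dmu, dmu)
        A = d2f[:, :, re[:, None], re[None, :]]
        A = A * gp[:, None, re, None] * gp[:, None, None, re]
        A[:, :, idx, idx] += df[:, :, re] * gpp[:, None, re]
        d2lnf = A / fc[:, :, None, None] - L[:, :, :, None] * L[:, :, None, :]
        H = np.einsum("pjq,pjr->pqr", Lm, Lm)
        H -= np.einsum("pj,pjqr->pqr", r, d2lnf)
        H /= sig2
        H[:, idx, idx] += 1.0 / om2
        return val, grad, (H, H_gn)

    # -- inner objective ----------------------------------------------------

    def h(self, x_f, eta, om2, sig2):
        """Joint negative log density per patient, shape (P,)."""
        return self._eval(x_f, eta, om2, sig2, order=0)[0]

    def h_grad(self, x_f, eta, om2, sig2):
        """(h, grad_h, gauss_newton_H) batched across patients."""
        return self._eval(x_f, eta, om2, sig2, order=1)

    def solve_modes(self, x_f, eta0, om2, sig2, tol=1e-8, max_iter=100):
        """Damped exact-Newton search for the empirical-Bayes modes.

        Batched across patients; falls back to the (always positive
        definite) Gauss-Newton Hessian where the exact one is not a
        descent metric.
        """
        eta = eta0.copy()
        val, grad, (H, H_gn) = self._eval(x_f, eta, om2, sig2, order=2)
        ok = False
        for _ in range(max_iter):
            if np.max(np.abs(grad)) < tol:
                ok = True
                break
            try:
                delta = np.linalg.solve(H, -grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                delta = np.linalg.solve(H_gn, -grad[..., None])[..., 0]
            descent = np.einsum("pq,pq->p", delta, grad) < 0
            if not np.all(descent):
                delta_gn = np.linalg.solve(H_gn, -grad[..., None])[..., 0]
                delta[~descent] = delta_gn[~descent]
            step = np.ones(self.P)
            for _ in range(25):
                cand = eta + step[:, None] * delta
                val_new = self.h(x_f, cand, om2, sig2)
                worse = val_new > val + 1e-12
                if not np.any(worse):
                    break
                step[worse] *= 0.5
            moved = val_new <= val + 1e-12
            eta[moved] = eta[moved] + step[moved, None] * delta[moved]
            val, grad, (H, H_gn) = self._eval(x_f, eta, om2, sig2, order=2)
        else:
            ok = np.max(np.abs(grad)) < tol
        return eta, val, H_gn, ok

    def neg2ll(self, x_f, om2, sig2, warm_eta=None):
        """Laplace-approximated -2 ln marginal likelihood (sum over patients).

        ``warm_eta`` seeds the inner Newton search (the converged mode is
        start-independent up to inner multimodality); a non-converged inner
        search yields +inf rather than an unreliable log-determinant.

        The determinant uses the Gauss-Newton (Fisher-type) curvature
        G'G/sigma^2 + Omega^-1 rather than the exact Hessian: it is bounded
        below by Omega^-1, which removes the spurious likelihood collapse
        that the exact-curvature Laplace suffers when a patient has as many
        random effects as observations (the determinant can then be driven
        to zero along an interpolation direction).  The two coincide
        whenever the model is linear in the random effects on the log
        scale.
        """
        if self.q == 0:
            val = self.h(x_f, np.zeros((self.P, 0)), om2, sig2)
            return float(2.0 * np.sum(val)), np.zeros((self.P, 0))
        eta0 = np.zeros((self.P, self.q)) if warm_eta is None else warm_eta
        eta, val, H, ok = self.solve_modes(x_f, eta0, om2, sig2)
        if not ok:
            return np.inf, eta
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            return np.inf, eta
        out = 2.0 * np.sum(val) - self.P * self.q * np.log(2 * np.pi) + np.sum(logdet)
        return float(out), eta


def _pooled_start(fn: SOEFunction, decay: DecayConstants, cohort: TimeActivityCohort):
    """Data-driven initial fixed effects from a pooled log-scale curve fit."""
    t = cohort.frame["time_min"].to_numpy()
    y = cohort.frame["activity"].to_numpy()
    logy = np.log(y)
    early = y[t <= np.quantile(t, 0.34)]
    a0 = float(np.median(early)) if len(early) else float(np.median(y))
    # crude terminal biological slope from first/last pooled medians
    t_lo, t_hi = np.quantile(t, [0.2, 0.8])
    y_lo = np.median(y[t <= t_lo]) if np.any(t <= t_lo) else a0
    y_hi = np.median(y[t >= t_hi]) if np.any(t >= t_hi) else a0 * 0.1
    span = max(t_hi - t_lo, 1.0)
    slope = max(np.log(max(y_lo, 1e-12) / max(y_hi, 1e-12)) / span, 1e-6)
    slope = max(slope - decay.lambda_phys, 1e-6)

    n_A = sum(1 for k in fn.kinds if k == "A")
    n_lam = sum(1 for k in fn.kinds if k == "lam")
    a_split = {1: [1.0], 2: [0.8, 0.2], 3: [0.7, 0.2, 0.1]}[n_A]
    lam_ladder = [slope * 5.0, slope, slope / 10.0][:n_lam]
    init = []
    ia = il = 0
    for kind in fn.kinds:
        if kind == "A":
            init.append(max(a0, 1e-9) * a_split[ia])
            ia += 1
        elif kind == "lam":
            init.append(max(lam_ladder[il], 1e-8))
            il += 1
        else:  # alpha
            init.append(0.7)
    x0 = _transform_forward(np.asarray(init), fn.kinds)

    def resid(x):
        theta = _transform_inverse(x[None, :], fn.kinds)[0]
        f = fn.evaluate(fn.param_dict(theta), t, decay)
        ok = f > 0
        r = np.where(ok, logy - np.log(np.clip(f, 1e-300, None)), 50.0 + np.abs(f))
        return r

    try:
        sol = optimize.least_squares(resid, x0, method="lm", max_nfev=400)
        if np.all(np.isfinite(sol.x)):
            x0 = sol.x
    except Exception:
        pass
    return x0


class NLMECurveModel(BaseEstimator):
    """Population (NLME) fit of one sum-of-exponentials function.

    Parameters
    ----------
    function : str, default "f3a"
        Name of the candidate function (see :mod:`tiapbms.functions`).
    random_effects : "all" or list of str
        Shape parameters carrying a random effect (default: all of them).
    half_life_days : float
        Physical half-life of the radionuclide in days.
    init_fixed : dict or None
        Natural-scale starting values for the fixed effects; ``None`` uses a
        pooled-fit data-driven start.
    init_omega2, init_sigma_res : float
        Starting random-effect variance (log-scale) and residual SD.
    fix_omega2, fix_sigma_res : float or None
        Fix variance components instead of estimating them (each fixed
        component is excluded from the parameter count K).
    n_starts : int
        Multi-start budget; start 0 is the plain initialisation, further
        starts jitter every coordinate with N(0, jitter_sd^2) on the
        unconstrained scale.
    tol : float
        Relative objective convergence tolerance of the outer search.
    random_state : int
        Seed for the multi-start jitter.

    Attributes
    ----------
    fixed_effects_ : dict
        Typical values (TVP) on the natural scale.
    omega2_ : dict
        Random-effect variances per parameter.
    sigma_res_ : float
        Residual SD of the log observations.
    neg2loglik_ : float
        Minimised Laplace -2 ln P.
    K_ : int
        Total estimated parameter count (fixed + variances + residual).
    cv_ : dict, cv_max_ : float
        Coefficient of variation sqrt(exp(se^2)-1) of each fixed effect from
        the log-scale standard error, and their maximum (goodness gate
        statistic).
    eta_ : DataFrame
        Per-patient empirical-Bayes random-effect modes.
    individual_params_ : DataFrame
        Per-patient natural-scale parameters TVP*exp(eta).
    converged_ : bool
    """

    def __init__(self, function="f3a", random_effects="all", half_life_days=6.6443,
                 init_fixed=None, init_omega2=0.1, init_sigma_res=0.2,
                 fix_omega2=None, fix_sigma_res=None, n_starts=3, jitter_sd=0.5,
                 tol=1e-4, max_iter=2000, random_state=0):
        self.function = function
        self.random_effects = random_effects
        self.half_life_days = half_life_days
        self.init_fixed = init_fixed
        self.init_omega2 = init_omega2
        self.init_sigma_res = init_sigma_res
        self.fix_omega2 = fix_omega2
        self.fix_sigma_res = fix_sigma_res
        self.n_starts = n_starts
        self.jitter_sd = jitter_sd
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None, groups=None):
        cohort = as_cohort(X, y, groups)
        fn = get_function(self.function)
        decay = DecayConstants(self.half_life_days)
        re_params = list(fn.params) if self.random_effects == "all" else list(self.random_effects)
        unknown = [p for p in re_params if p not in fn.params]
        if unknown:
            raise ValueError(f"random effect(s) {unknown} not parameters of {fn.name}")
        if cohort.n_patients < 2:
            warnings.warn(
                "fitting a population model to fewer than 2 patients; "
                "random-effect variances are not identifiable",
                UserWarning,
            )
        kern = _LaplaceKernel(fn, decay, cohort, re_params)
        q = kern.q
        est_om = self.fix_omega2 is None and q > 0
        est_sig = self.fix_sigma_res is None
        n_f = fn.n_shape_params

        def unpack(x):
            x_f = x[:n_f]
            pos = n_f
            if est_om:
                om2 = np.exp(x[pos:pos + q])
                pos += q
            elif q:
                om2 = np.full(q, float(self.fix_omega2))
            else:
                om2 = np.zeros(0)
            sig = np.exp(x[pos]) if est_sig else float(self.fix_sigma_res)
            return x_f, om2, sig ** 2

        state = {"eta": np.zeros((kern.P, q))}

        def objective(x):
            if not np.all(np.isfinite(x)) or np.any(np.abs(x) > 60):
                return np.inf
            x_f, om2, sig2 = unpack(x)
            with np.errstate(all="ignore"):
                val, eta = kern.neg2ll(x_f, om2, sig2, state["eta"])
            if np.isfinite(val):
                state["eta"] = eta
            return val

        # starting point
        if self.init_fixed is not None:
            base_f = _transform_forward(
                np.asarray([self.init_fixed[p] for p in fn.params]), fn.kinds
            )
        else:
            base_f = _pooled_start(fn, decay, cohort)
        pieces = [base_f]
        if est_om:
            pieces.append(np.full(q, np.log(self.init_omega2)))
        if est_sig:
            pieces.append([np.log(self.init_sigma_res)])
        x_base = np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in pieces])

        rng = np.random.default_rng(self.random_state)
        best = None
        for start in range(max(1, int(self.n_starts))):
            x0 = x_base if start == 0 else x_base + rng.normal(0.0, self.jitter_sd, x_base.size)
            state["eta"] = np.zeros((kern.P, q))
            if not np.isfinite(objective(x0)):
                continue
            # quasi-Newton descent, then a derivative-free polish: the
            # surface has a narrow variance/residual ravine where FD
            # gradients stall early
            with np.errstate(invalid="ignore", over="ignore"), \
                    warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = optimize.minimize(
                    objective, x0, method="L-BFGS-B",
                    options=dict(maxiter=self.max_iter, ftol=1e-11, gtol=1e-6,
                                 eps=1e-6),
                )
                if not np.isfinite(res.fun):
                    continue
                res2 = optimize.minimize(
                    objective, res.x, method="Powell",
                    options=dict(maxiter=300, ftol=1e-8, xtol=1e-5),
                )
            if np.isfinite(res2.fun) and res2.fun <= res.fun:
                cand = (res2.fun, bool(res2.success or res.success), res2.x.copy())
            else:
                cand = (res.fun, bool(res.success), res.x.copy())
            if best is None or cand[0] < best[0] - 1e-9:
                best = cand

        self.cohort_ = cohort
        self.fn_ = fn
        self.decay_ = decay
        self.random_effects_ = re_params
        self.N_ = cohort.n_obs
        self.n_patients_ = cohort.n_patients
        self.K_ = n_f + (q if est_om else 0) + (1 if est_sig else 0)
        if best is None:
            # no start reached a finite objective: flagged failure, never a
            # silent success (some candidates, e.g. curves pinned to zero at
            # t=0, cannot represent these data at all)
            warnings.warn(f"{fn.name}: no start produced a finite Laplace "
                          "objective; fit flagged as not converged", UserWarning)
            self.converged_ = False
            self.neg2loglik_ = np.inf
            self.fixed_effects_ = {}
            self.fixed_effects_log_ = {}
            self.se_log_ = {p: np.inf for p in fn.params}
            self.omega2_ = {}
            self.sigma_res_ = np.nan
            self.cv_ = {p: np.inf for p in fn.params}
            self.cv_max_ = np.inf
            self.eta_ = pd.DataFrame(index=kern.ids, columns=re_params, dtype=float)
            self.individual_params_ = pd.DataFrame(index=kern.ids,
                                                   columns=list(fn.params),
                                                   dtype=float)
            self.omega2_identifiable_ = False
            return self

        fun_best, success, x_best = best
        x_f, om2, sig2 = unpack(x_best)
        with np.errstate(all="ignore"):
            _, eta_hat = kern.neg2ll(x_f, om2, sig2, state["eta"])

        # standard errors from the outer FD Hessian
        se_x = np.full(x_best.size, np.inf)
        with np.errstate(all="ignore"):
            try:
                H = fd_hessian(lambda x: objective(x), x_best, step=1e-3)
                cov = 2.0 * np.linalg.inv(H)
                d = np.diag(cov)
                se_x = np.where(d > 0, np.sqrt(np.abs(d)), np.inf)
                if np.any(d <= 0):
                    se_x[d <= 0] = np.inf
            except np.linalg.LinAlgError:
                pass

        tvp = _transform_inverse(x_f[None, :], fn.kinds)[0]
        theta_ind = kern._theta(x_f, eta_hat)

        self.cohort_ = cohort
        self.fn_ = fn
        self.decay_ = decay
        self.random_effects_ = re_params
        self.fixed_effects_ = dict(zip(fn.params, tvp.tolist()))
        self.fixed_effects_log_ = dict(zip(fn.params, x_f.tolist()))
        self.se_log_ = dict(zip(fn.params, se_x[:n_f].tolist()))
        self.omega2_ = dict(zip(re_params, om2.tolist()))
        self.sigma_res_ = float(np.sqrt(sig2))
        self.neg2loglik_ = float(fun_best)
        self.K_ = int(x_best.size)
        self.N_ = cohort.n_obs
        self.n_patients_ = cohort.n_patients
        self.converged_ = bool(success)
        cvs = {p: float(cv_from_se2(se ** 2)) if np.isfinite(se) else np.inf
               for p, se in self.se_log_.items()}
        self.cv_ = cvs
        self.cv_max_ = max(cvs.values())
        self.eta_ = pd.DataFrame(eta_hat, index=kern.ids, columns=re_params)
        self.individual_params_ = pd.DataFrame(theta_ind, index=kern.ids,
                                               columns=list(fn.params))
        if cohort.n_patients < 2:
            self.omega2_identifiable_ = False
        else:
            self.omega2_identifiable_ = True
        return self

    # -- post-fit accessors -------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "neg2loglik_"):
            raise RuntimeError("model is not fitted")

    def individual_params(self, patient_id) -> dict[str, float]:
        """Empirical-Bayes natural-scale parameters for one patient."""
        self._check_fitted()
        pid = str(patient_id)
        if pid not in self.individual_params_.index:
            raise KeyError(f"unknown patient id {patient_id!r}")
        return self.individual_params_.loc[pid].to_dict()

    def predict(self, X, groups=None):
        """Predicted activity fraction at times ``X`` (minutes).

        With ``groups`` the per-patient empirical-Bayes curves are used;
        without, the population-typical curve.
        """
        self._check_fitted()
        t = np.asarray(X, dtype=float).ravel()
        if groups is None:
            return self.fn_.evaluate(self.fixed_effects_, t, self.decay_)
        groups = np.asarray(groups).astype(str)
        out = np.empty(t.size)
        for pid in np.unique(groups):
            sel = groups == pid
            out[sel] = self.fn_.evaluate(self.individual_params(pid), t[sel], self.decay_)
        return out

    def tia(self, patient_id=None, t_end=100_000.0):
        """Closed-form TIA (minutes); per patient, or a Series for all.

        ``patient_id=None`` returns the per-patient table; pass a patient id
        for a single value; ``"population"`` for the typical-value curve.
        """
        self._check_fitted()
        if patient_id == "population":
            return self.fn_.tia(self.fixed_effects_, self.decay_, t_end)
        if patient_id is not None:
            return self.fn_.tia(self.individual_params(patient_id), self.decay_, t_end)
        return pd.Series(
            {pid: self.fn_.tia(self.individual_params(pid), self.decay_, t_end)
             for pid in self.individual_params_.index},
            name=f"tia_{self.fn_.name}",
        )


def fit_nlme(cohort, function="f3a", **kwargs) -> NLMECurveModel:
    """Functional wrapper: fit one SOE function to a cohort by NLME."""
    return NLMECurveModel(function=function, **kwargs).fit(cohort)
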