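"""Frequency-based (Saltelli) parameter sampling for TIA uncertainty.

IBMS/SP-PBMS TIA standard deviations come from pushing a deterministic
frequency-based design through log-normal parameter marginals:

    X(s) = 1/2 + (1/pi) * arcsin(sin(omega*s + phi))

sampled on an even grid of ``n_evals`` points over s in (-pi/2, pi/2)
produces a triangle-wave filling of [0, 1]; per-parameter random phases
phi_i (seeded) decorrelate the columns.  The [0, 1] values are mapped to
parameter draws through the log-normal quantile function whose log-scale
moments are matched to the requested natural-scale mean and SD:

    mu_log     = 2 ln m - 0.5 ln(m^2 + s^2)
    sigma_log  = sqrt( ln(m^2 + s^2) - 2 ln m )

The TIA is evaluated per draw; the sample mean and SD are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .functions import DecayConstants, get_function

__all__ = [
    "LogNormalMoments",
    "normal_to_lognormal",
    "FrequencySampler",
    "frequency_sample",
    "tia_uncertainty",
]


@dataclass(frozen=True)
class LogNormalMoments:
    """Log-scale mean and SD of a log-normal distribution."""

    mu_log: float
    sigma_log: float

    def quantile(self, u):
        """Inverse CDF at u in [0, 1] (degenerate when sigma_log == 0)."""
        if self.sigma_log == 0:
            return np.full_like(np.asarray(u, dtype=float), np.exp(self.mu_log))
        return stats.lognorm.ppf(u, s=self.sigma_log, scale=np.exp(self.mu_log))


def normal_to_lognormal(mean_normal: float, sd_normal: float) -> LogNormalMoments:
    """Match log-normal log-scale moments to a natural-scale mean and SD."""
    m, s = float(mean_normal), float(sd_normal)
    if m <= 0:
        raise ValueError("mean_normal must be positive")
    if s < 0:
        raise ValueError("sd_normal must be >= 0")
    mu = 2.0 * np.log(m) - 0.5 * np.log(m * m + s * s)
    var = np.log(m * m + s * s) - 2.0 * np.log(m)
    return LogNormalMoments(mu_log=float(mu), sigma_log=float(np.sqrt(max(var, 0.0))))


@dataclass(frozen=True)
class FrequencySampler:
    """Deterministic triangle-wave sampler over [0, 1]."""

    omega: int = 1028
    n_evals: int = 8193
    seed: int = 0

    def sample(self, n_params: int) -> np.ndarray:
        """(n_evals, n_params) matrix of values in [0, 1]."""
        if n_params < 1:
            raise ValueError("n_params must be >= 1")
        # midpoint grid spanning the open interval (-pi/2, pi/2)
        s = (np.arange(self.n_evals) + 0.5) / self.n_evals * np.pi - np.pi / 2.0
        phi = np.random.default_rng(self.seed).uniform(0.0, 2.0 * np.pi, n_params)
        return 0.5 + np.arcsin(np.sin(self.omega * s[:, None] + phi[None, :])) / np.pi


def frequency_sample(n_params: int, omega: int = 1028, n_evals: int = 8193,
                     seed: int = 0) -> np.ndarray:
    """Functional wrapper for :class:`FrequencySampler`."""
    return FrequencySampler(omega=omega, n_evals=n_evals, seed=seed).sample(n_params)


def _param_sd_from_cov(result) -> dict:
    """Free-parameter SDs from a WLS fit covariance (diagonal)."""
    if result.cov is None:
        return {p: np.nan for p in result.free_params}
    d = np.diag(result.cov)
    return {
        p: (np.sqrt(v) if v >= 0 else np.nan)
        for p, v in zip(result.free_params, d)
    }


def tia_uncertainty(fit, sampler: FrequencySampler | None = None,
                    t_end: float = 100_000.0) -> pd.DataFrame:
    """Per-patient TIA mean and SD for an IBMS or SP-PBMS fit.

    ``fit`` is a fitted :class:`~tiapbms.baselines.IndividualCurveFit` or
    :class:`~tiapbms.baselines.SharedParamCurveFit`.  Each free parameter
    with a positive mean and a finite positive SD (from the fit covariance)
    is sampled through its log-normal quantile; parameters without a usable
    SD (or non-positive mean) are held fixed with a warning.  Returns a
    frame with columns ``tia`` (point estimate), ``tia_mean`` and ``tia_sd``.
    """
    sampler = sampler or FrequencySampler()
    fn = fit.fn_
    decay: DecayConstants = fit.decay_
    rows = {}
    for pid, res in fit.results_.items():
        sds = _param_sd_from_cov(res)
        sampled = []
        for p in res.free_params:
            mean = res.params[p]
            sd = sds.get(p, np.nan)
            if mean <= 0 or not np.isfinite(sd) or sd <= 0:
                if not (np.isfinite(sd) and sd == 0):
                    warnings.warn(
                        f"{pid}: parameter {p} held fixed in the uncertainty "
                        f"sampling (mean={mean:g}, sd={sd})",
                        UserWarning,
                    )
                continue
            sampled.append((p, normal_to_lognormal(mean, sd)))
        point = fn.tia(res.params, decay, t_end)
        if not sampled:
            rows[pid] = dict(tia=point, tia_mean=point, tia_sd=0.0)
            continue
        U = sampler.sample(len(sampled))
        theta = np.tile(
            fn.param_array(res.params), (sampler.n_evals, 1)
        )
        for j, (p, mom) in enumerate(sampled):
            theta[:, fn.params.index(p)] = mom.quantile(U[:, j])
        tias = fn.tia(theta, decay, t_end)
        rows[pid] = dict(tia=point, tia_mean=float(np.mean(tias)),
                         tia_sd=float(np.std(tias, ddof=1)))
    out = pd.DataFrame(rows).T
    out.index.name = "patient_id"
    return out
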