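"""AICc model selection, Akaike weights, model averaging and the Jackknife.

The workflow: fit every candidate sum-of-exponentials function to the whole
cohort with the NLME engine, gate on goodness of fit (converged fit and
maximum fixed-effect CV below 0.5), score the gate-passing functions with
the small-sample corrected Akaike criterion

    AICc = -2 ln P + 2K + 2K(K+1)/(N-K-1),

convert AICc differences to Akaike weights w_i = exp(-d_i/2)/sum exp(-d_j/2)
(the probability that function i is the best of the gated set), and form
the model-averaged TIA per patient as the weight-sum of the per-function
empirical-Bayes TIAs.  A leave-one-patient-out Jackknife repeats the whole
pipeline to measure selection stability.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import as_cohort
from .functions import get_function
from .nlme import NLMECurveModel

__all__ = [
    "aicc",
    "aicc_penalty",
    "akaike_weights",
    "bic",
    "goodness_gate",
    "model_average_tia",
    "ModelSelection",
    "jackknife",
]


def aicc_penalty(K: int, N: int) -> float:
    """Small-sample AICc penalty term 2K + 2K(K+1)/(N-K-1)."""
    if N - K - 1 <= 0:
        raise ValueError(
            f"AICc undefined for K={K}, N={N} (need N - K - 1 > 0); "
            "exclude this candidate upstream"
        )
    return 2.0 * K + 2.0 * K * (K + 1.0) / (N - K - 1.0)


def aicc(neg2lnP: float, K: int, N: int) -> float:
    """Corrected Akaike Information Criterion."""
    return float(neg2lnP) + aicc_penalty(K, N)


def bic(neg2lnP: float, K: int, N: int) -> float:
    """Bayesian Information Criterion, -2 ln P + K ln N."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return float(neg2lnP) + K * np.log(N)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights from AICc values (log-sum-exp; robust to large deltas)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AICc value")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite AICc; exclude those functions before weighting")
    half_delta = 0.5 * (a - a.min())
    logw = -half_delta
    logw -= np.log(np.sum(np.exp(logw - logw.max()))) + logw.max()
    return np.exp(logw)


def goodness_gate(fits: dict, cv_threshold: float = 0.5) -> pd.DataFrame:
    """Gate fitted models on convergence and maximum fixed-effect CV.

    ``fits`` maps function name -> fitted :class:`NLMECurveModel`.  Returns a
    frame with pass/fail and the recorded reason.
    """
    rows = []
    for name, fit in fits.items():
        if not fit.converged_:
            rows.append((name, False, "did not converge"))
        elif not np.isfinite(fit.cv_max_):
            rows.append((name, False, "CV infinite (singular information)"))
        elif fit.cv_max_ >= cv_threshold:
            rows.append((name, False, f"max CV {fit.cv_max_:.2f} >= {cv_threshold}"))
        else:
            rows.append((name, True, ""))
    return pd.DataFrame(rows, columns=["function", "passed_gate", "reason"]).set_index("function")


def model_average_tia(weights: dict, tias: dict) -> pd.Series:
    """Model-averaged TIA per patient, sum_i w_i * TIA_i.

    ``weights`` maps function name -> Akaike weight (must sum to 1);
    ``tias`` maps function name -> per-patient TIA Series over an identical
    patient set.
    """
    if set(weights) != set(tias):
        raise ValueError(
            f"function sets differ: weights {sorted(weights)} vs TIAs {sorted(tias)}"
        )
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {total!r}")
    names = list(weights)
    table = pd.concat([pd.Series(tias[n]) for n in names], axis=1, keys=names)
    if table.isna().any().any():
        raise ValueError("patient sets differ between functions")
    out = table.mul(pd.Series(weights), axis=1).sum(axis=1)
    out.name = "tia_ma"
    return out


class ModelSelection(BaseEstimator):
    """Population-based model selection over a set of SOE candidates.

    Fits each candidate with :class:`~tiapbms.nlme.NLMECurveModel`, applies
    the CV goodness gate and computes AICc Akaike weights over the passing
    set.  Functions failing the gate receive weight exactly 0 with a
    recorded reason.

    Attributes
    ----------
    table_ : DataFrame
        One row per candidate: K, N, -2lnP, AICc, delta, Akaike weight,
        max CV, gate flag and reason.
    fits_ : dict
        Fitted NLMECurveModel per candidate.
    weights_ : dict
        Akaike weights of the gate-passing functions (sum to 1).
    best_function_ : str
        Highest-weight function (ties broken by smaller K, then name).
    """

    def __init__(self, functions=("f2a", "f3a", "f3b", "f3c", "f4a", "f4b",
                                  "f5a", "f5b", "f5c", "f6a", "f6b"),
                 cv_threshold=0.5, half_life_days=6.6443, n_starts=3,
                 tol=1e-4, random_state=0):
        self.functions = functions
        self.cv_threshold = cv_threshold
        self.half_life_days = half_life_days
        self.n_starts = n_starts
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None, groups=None):
        cohort = as_cohort(X, y, groups)
        names = list(self.functions)
        fits: dict[str, NLMECurveModel] = {}
        failures: dict[str, str] = {}
        for name in names:
            K = 2 * get_function(name).n_shape_params + 1
            if cohort.n_obs - K - 1 <= 0:
                failures[name] = f"K={K} too large for N={cohort.n_obs} (AICc undefined)"
                continue
            model = NLMECurveModel(
                function=name, half_life_days=self.half_life_days,
                n_starts=self.n_starts, tol=self.tol,
                random_state=self.random_state,
            )
            try:
                fits[name] = model.fit(cohort)
            except RuntimeError as exc:
                failures[name] = str(exc)

        gate = goodness_gate(fits, self.cv_threshold)
        passing = [n for n in fits if gate.loc[n, "passed_gate"]]
        if not passing:
            raise RuntimeError(
                "no candidate function passed the goodness-of-fit gate; "
                "reasons: " + "; ".join(
                    [f"{n}: {gate.loc[n, 'reason']}" for n in fits]
                    + [f"{n}: {r}" for n, r in failures.items()]
                )
            )
        aicc_pass = {n: aicc(fits[n].neg2loglik_, fits[n].K_, fits[n].N_) for n in passing}
        w = akaike_weights([aicc_pass[n] for n in passing])
        weights = dict(zip(passing, w.tolist()))

        rows = []
        amin = min(aicc_pass.values())
        for name in names:
            if name in fits:
                f = fits[name]
                a = aicc(f.neg2loglik_, f.K_, f.N_)
                rows.append(dict(
                    function=name, K=f.K_, N=f.N_, neg2lnP=f.neg2loglik_,
                    AICc=a, delta=a - amin if name in weights else np.nan,
                    weight=weights.get(name, 0.0), cv_max=f.cv_max_,
                    passed_gate=name in weights,
                    reason=gate.loc[name, "reason"],
                ))
            else:
                rows.append(dict(
                    function=name, K=np.nan, N=cohort.n_obs, neg2lnP=np.nan,
                    AICc=np.nan, delta=np.nan, weight=0.0, cv_max=np.nan,
                    passed_gate=False, reason=failures[name],
                ))
        self.table_ = pd.DataFrame(rows).set_index("function")
        self.fits_ = fits
        self.weights_ = weights
        self.cohort_ = cohort
        # best: highest weight, ties by smaller K then name
        self.best_function_ = min(
            weights, key=lambda n: (-weights[n], fits[n].K_, n)
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "table_"):
            raise RuntimeError("selection is not fitted")

    def model_average_tia(self, t_end=100_000.0) -> pd.Series:
        """Per-patient model-averaged TIA over the gate-passing functions."""
        self._check_fitted()
        tias = {n: self.fits_[n].tia(t_end=t_end) for n in self.weights_}
        return model_average_tia(self.weights_, tias)

    def tia_table(self, t_end=100_000.0) -> pd.DataFrame:
        """Per-patient TIA of every gate-passing function plus the MA column."""
        self._check_fitted()
        tias = {n: self.fits_[n].tia(t_end=t_end) for n in self.weights_}
        out = pd.DataFrame(tias)
        out["MA"] = model_average_tia(self.weights_, tias)
        return out


def jackknife(X, y=None, groups=None, functions=("f3a", "f3c", "f4a"),
              cv_threshold=0.5, n_starts=3, random_state=0,
              **nlme_kwargs) -> dict:
    """Leave-one-patient-out stability of the Akaike-weight selection.

    Repeats the fit + gate + weight pipeline once per left-out patient and
    summarises each function's weight across replicates (mean, SD, median,
    min, max) together with the count of replicates it ranked first.
    Replicates whose selection fails entirely are recorded and excluded with
    a warning, never silently.
    """
    cohort = as_cohort(X, y, groups)
    if cohort.n_patients < 3:
        raise ValueError("jackknife needs at least 3 patients")
    replicates = {}
    failed = {}
    for pid in cohort.patient_ids:
        sub = cohort.drop_patient(pid)
        sel = ModelSelection(functions=functions, cv_threshold=cv_threshold,
                             n_starts=n_starts, random_state=random_state,
                             **nlme_kwargs)
        try:
            sel.fit(sub)
        except RuntimeError as exc:
            failed[pid] = str(exc)
            warnings.warn(f"jackknife replicate without {pid} failed: {exc}",
                          UserWarning)
            continue
        replicates[pid] = {n: sel.table_.loc[n, "weight"] for n in functions}

    wtab = pd.DataFrame(replicates).T  # replicates x functions
    wtab.index.name = "left_out"
    first = wtab.idxmax(axis=1)
    summary = pd.DataFrame({
        "mean": wtab.mean(axis=0),
        "sd": wtab.std(axis=0, ddof=1),
        "median": wtab.median(axis=0),
        "min": wtab.min(axis=0),
        "max": wtab.max(axis=0),
        "n_first": first.value_counts().reindex(wtab.columns, fill_value=0),
    })
    summary.index.name = "function"
    return {"weights": wtab, "summary": summary, "failed": failed}
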