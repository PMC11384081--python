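"""Sum-of-exponentials (SOE) fit functions for radiopharmaceutical kinetics.

The candidate set contains eleven parameterisations of mono-, bi- and
tri-exponential curves.  Every exponential term decays with a total rate
``mu = lambda_bio + lambda_phys`` where ``lambda_phys`` is the physical decay
constant of the radionuclide (177Lu by default) and ``lambda_bio`` is a
biological clearance rate; some terms carry a bare ``exp(-lambda_phys*t)``
(no biological clearance).  The digit in a function's name equals its number
of adjustable shape parameters, e.g. ``f3a(t) = A1*exp(-(l1+lp)*t) +
A2*exp(-lp*t)`` has the three shape parameters A1, A2, l1.

Each function is represented termwise: ``f(t) = sum_m c_m(p) * exp(-mu_m(p)*t)``
with analytic coefficient/rate Jacobians, which gives closed-form
time-integrated activities (TIA) and cheap derivatives for the fitting
engines.  Activities are dimensionless fractions of injected activity and
the canonical internal time unit is minutes, so a TIA is in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DecayConstants",
    "SOEFunction",
    "FUNCTIONS",
    "get_function",
    "function_names",
    "evaluate",
    "tia",
    "validate_params",
]

MINUTES_PER_DAY = 1440.0
#: default 177Lu physical half-life in days
DEFAULT_HALF_LIFE_DAYS = 6.6443


@dataclass(frozen=True)
class DecayConstants:
    """Physical decay of the radionuclide.

    Parameters
    ----------
    half_life_days:
        Physical half-life in days (default: 177Lu, 6.6443 d).
    """

    half_life_days: float = DEFAULT_HALF_LIFE_DAYS

    def __post_init__(self) -> None:
        if not self.half_life_days > 0:
            raise ValueError("half_life_days must be positive")

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant in 1/min."""
        return float(np.log(2.0) / (self.half_life_days * MINUTES_PER_DAY))


# ---------------------------------------------------------------------------
# termwise representation
#
# A coefficient spec is one of
#   ("p",    name)        -> +p
#   ("neg",  name)        -> -p
#   ("prod", a, alpha)    -> a * alpha
#   ("prod1m", a, alpha)  -> a * (1 - alpha)
#   ("negsum", a, b)      -> -(a + b)
# A rate spec is ("bio", name) -> lambda_name + lambda_phys, or
# ("phys",) -> lambda_phys.
# ---------------------------------------------------------------------------

_PARAM_KIND = {"A": "prefactor", "lam": "decay rate", "alpha": "fraction"}


@dataclass(frozen=True)
class SOEFunction:
    """One candidate sum-of-exponentials function."""

    name: str
    params: tuple[str, ...]
    kinds: tuple[str, ...]  # per-parameter: "A" | "lam" | "alpha"
    terms: tuple[tuple[tuple, tuple], ...]  # ((coef_spec, rate_spec), ...)
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {p: i for i, p in enumerate(self.params)})

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_shape_params(self) -> int:
        return len(self.params)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def param_array(self, params) -> np.ndarray:
        """Coerce a dict or sequence of shape parameters to an ordered array."""
        if isinstance(params, dict):
            missing = [p for p in self.params if p not in params]
            if missing:
                raise ValueError(f"{self.name}: missing parameter(s) {missing}")
            return np.asarray([params[p] for p in self.params], dtype=float)
        arr = np.asarray(params, dtype=float)
        if arr.shape[-1] != len(self.params):
            raise ValueError(
                f"{self.name} expects {len(self.params)} parameters "
                f"{self.params}, got shape {arr.shape}"
            )
        return arr

    def param_dict(self, arr) -> dict[str, float]:
        arr = np.asarray(arr, dtype=float)
        return {p: float(arr[..., i]) for i, p in enumerate(self.params)}

    # -- validation ---------------------------------------------------------

    def validate(self, params) -> list[str]:
        """Return a list of constraint violations (empty iff valid).

        Constraints: every pre-factor A_j >= 0, every biological decay
        constant lambda_j >= 0 and fractions alpha in [0, 1].
        """
        arr = self.param_array(params)
        violations = []
        for i, (pname, kind) in enumerate(zip(self.params, self.kinds)):
            v = arr[..., i]
            if not np.all(np.isfinite(v)):
                violations.append(f"{pname}: non-finite value")
                continue
            if kind in ("A", "lam") and np.any(v < 0):
                violations.append(
                    f"{pname}: {_PARAM_KIND[kind]} must be >= 0, got {np.min(v):g}"
                )
            elif kind == "alpha" and (np.any(v < 0) or np.any(v > 1)):
                violations.append(f"{pname}: fraction must be in [0, 1]")
        return violations

    def _check(self, params) -> np.ndarray:
        arr = self.param_array(params)
        violations = self.validate(arr)
        if violations:
            raise ValueError(f"{self.name}: invalid parameters: {'; '.join(violations)}")
        return arr

    # -- termwise pieces ----------------------------------------------------

    def coefficients(self, params) -> np.ndarray:
        """Signed term coefficients c_m, shape ``params.shape[:-1] + (M,)``."""
        arr = self.param_array(params)
        out = []
        for coef, _ in self.terms:
            out.append(self._coef_value(coef, arr))
        return np.stack(out, axis=-1)

    def rates(self, params, decay: DecayConstants) -> np.ndarray:
        """Total decay rate mu_m of every term (1/min)."""
        arr = self.param_array(params)
        lp = decay.lambda_phys
        out = []
        for _, rate in self.terms:
            if rate[0] == "phys":
                out.append(np.broadcast_to(lp, arr.shape[:-1]).astype(float))
            else:
                out.append(arr[..., self._index[rate[1]]] + lp)
        return np.stack(out, axis=-1)

    def _coef_value(self, coef, arr) -> np.ndarray:
        kind = coef[0]
        if kind == "p":
            return +arr[..., self._index[coef[1]]]
        if kind == "neg":
            return -arr[..., self._index[coef[1]]]
        if kind == "prod":
            return arr[..., self._index[coef[1]]] * arr[..., self._index[coef[2]]]
        if kind == "prod1m":
            return arr[..., self._index[coef[1]]] * (1.0 - arr[..., self._index[coef[2]]])
        if kind == "negsum":
            return -(arr[..., self._index[coef[1]]] + arr[..., self._index[coef[2]]])
        raise ValueError(f"unknown coefficient spec {coef!r}")

    def coef_jacobian(self, params) -> np.ndarray:
        """d c_m / d p_k, shape ``(..., M, K)``."""
        arr = self.param_array(params)
        batch = arr.shape[:-1]
        jac = np.zeros(batch + (self.n_terms, self.n_shape_params))
        for m, (coef, _) in enumerate(self.terms):
            kind = coef[0]
            if kind == "p":
                jac[..., m, self._index[coef[1]]] = 1.0
            elif kind == "neg":
                jac[..., m, self._index[coef[1]]] = -1.0
            elif kind == "prod":
                ia, iq = self._index[coef[1]], self._index[coef[2]]
                jac[..., m, ia] = arr[..., iq]
                jac[..., m, iq] = arr[..., ia]
            elif kind == "prod1m":
                ia, iq = self._index[coef[1]], self._index[coef[2]]
                jac[..., m, ia] = 1.0 - arr[..., iq]
                jac[..., m, iq] = -arr[..., ia]
            elif kind == "negsum":
                jac[..., m, self._index[coef[1]]] = -1.0
                jac[..., m, self._index[coef[2]]] = -1.0
        return jac

    def coef_hessian_const(self) -> np.ndarray:
        """d^2 c_m / dp_k dp_l, shape (M, K, K).

        Coefficient maps are at most bilinear in the parameters, so this is
        a parameter-independent constant tensor.
        """
        H = np.zeros((self.n_terms, self.n_shape_params, self.n_shape_params))
        for m, (coef, _) in enumerate(self.terms):
            if coef[0] in ("prod", "prod1m"):
                ia, iq = self._index[coef[1]], self._index[coef[2]]
                v = 1.0 if coef[0] == "prod" else -1.0
                H[m, ia, iq] = H[m, iq, ia] = v
        return H

    def rate_jacobian(self, params) -> np.ndarray:
        """d mu_m / d p_k, shape ``(..., M, K)`` (0/1 entries)."""
        arr = self.param_array(params)
        batch = arr.shape[:-1]
        jac = np.zeros(batch + (self.n_terms, self.n_shape_params))
        for m, (_, rate) in enumerate(self.terms):
            if rate[0] == "bio":
                jac[..., m, self._index[rate[1]]] = 1.0
        return jac

    # -- evaluation and integration -----------------------------------------

    def evaluate(self, params, t, decay: DecayConstants | None = None) -> np.ndarray:
        """Evaluate f(t) for t >= 0 (minutes); returns activity fraction."""
        decay = decay or DecayConstants()
        arr = self._check(params)
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        c = self.coefficients(arr)  # (..., M)
        mu = self.rates(arr, decay)  # (..., M)
        # broadcast params against t: result shape = broadcast(batch, t.shape)
        e = np.exp(-mu[..., None, :] * t[..., None])
        val = np.sum(c[..., None, :] * e, axis=-1)
        return val.reshape(np.broadcast_shapes(arr.shape[:-1], t.shape))

    def tia(self, params, decay: DecayConstants | None = None,
            t_end: float | None = 100_000.0) -> float | np.ndarray:
        """Closed-form time-integrated activity over [0, t_end] minutes.

        ``t_end=None`` (or ``inf``) integrates to infinity using A/mu per
        term.  A term with mu == 0 contributes ``c * t_end`` (the
        finite-horizon limit of ``c*(1-exp(-mu*T))/mu``).
        """
        decay = decay or DecayConstants()
        arr = self._check(params)
        c = self.coefficients(arr)
        mu = self.rates(arr, decay)
        if t_end is None or np.isinf(t_end):
            if np.any(mu <= 0):
                raise ValueError("infinite-horizon TIA requires all mu > 0")
            out = np.sum(c / mu, axis=-1)
        else:
            if not t_end > 0:
                raise ValueError("t_end must be positive")
            with np.errstate(divide="ignore", invalid="ignore"):
                integ = np.where(
                    mu > 0,
                    -np.expm1(-mu * t_end) / np.where(mu > 0, mu, 1.0),
                    t_end,
                )
            out = np.sum(c * integ, axis=-1)
        return float(out) if np.ndim(out) == 0 else out


def _fn(name: str, params: Sequence[tuple[str, str]], terms) -> SOEFunction:
    names = tuple(p for p, _ in params)
    kinds = tuple(k for _, k in params)
    return SOEFunction(name=name, params=names, kinds=kinds, terms=tuple(terms))


_A, _L, _AL = "A", "lam", "alpha"

FUNCTIONS: dict[str, SOEFunction] = {
    f.name: f
    for f in [
        _fn("f2a", [("A1", _A), ("lambda1", _L)],
            [(("p", "A1"), ("bio", "lambda1"))]),
        _fn("f3a", [("A1", _A), ("A2", _A), ("lambda1", _L)],
            [(("p", "A1"), ("bio", "lambda1")),
             (("p", "A2"), ("phys",))]),
        _fn("f3b", [("A1", _A), ("alpha", _AL), ("lambda1", _L)],
            [(("prod", "A1", "alpha"), ("bio", "lambda1")),
             (("prod1m", "A1", "alpha"), ("phys",))]),
        _fn("f3c", [("A1", _A), ("alpha", _AL), ("lambda1", _L)],
            [(("prod1m", "A1", "alpha"), ("bio", "lambda1")),
             (("prod", "A1", "alpha"), ("phys",))]),
        _fn("f4a", [("A1", _A), ("A2", _A), ("lambda1", _L), ("lambda2", _L)],
            [(("p", "A1"), ("bio", "lambda1")),
             (("p", "A2"), ("bio", "lambda2"))]),
        _fn("f4b", [("A1", _A), ("alpha", _AL), ("lambda1", _L), ("lambda2", _L)],
            [(("prod", "A1", "alpha"), ("bio", "lambda1")),
             (("prod1m", "A1", "alpha"), ("bio", "lambda2"))]),
        _fn("f5a", [("A1", _A), ("A2", _A), ("A3", _A), ("lambda1", _L), ("lambda2", _L)],
            [(("p", "A1"), ("bio", "lambda1")),
             (("p", "A2"), ("bio", "lambda2")),
             (("neg", "A3"), ("phys",))]),
        _fn("f5b", [("A1", _A), ("A2", _A), ("lambda1", _L), ("lambda2", _L), ("lambda3", _L)],
            [(("p", "A1"), ("bio", "lambda1")),
             (("p", "A2"), ("bio", "lambda2")),
             (("negsum", "A2", "A1"), ("bio", "lambda3"))]),
        _fn("f5c", [("A1", _A), ("A2", _A), ("A3", _A), ("lambda1", _L), ("lambda2", _L)],
            [(("p", "A1"), ("bio", "lambda1")),
             (("p", "A2"), ("bio", "lambda2")),
             (("p", "A3"), ("phys",))]),
        _fn("f6a", [("A1", _A), ("A2", _A), ("A3", _A),
                    ("lambda1", _L), ("lambda2", _L), ("lambda3", _L)],
            [(("p", "A1"), ("bio", "lambda1")),
             (("p", "A2"), ("bio", "lambda2")),
             (("neg", "A3"), ("bio", "lambda3"))]),
        _fn("f6b", [("A1", _A), ("A2", _A), ("A3", _A),
                    ("lambda1", _L), ("lambda2", _L), ("lambda3", _L)],
            [(("p", "A1"), ("bio", "lambda1")),
             (("p", "A2"), ("bio", "lambda2")),
             (("p", "A3"), ("bio", "lambda3"))]),
    ]
}


def function_names() -> list[str]:
    return list(FUNCTIONS)


def get_function(name: str) -> SOEFunction:
    try:
        return FUNCTIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown SOE function {name!r}; available: {', '.join(FUNCTIONS)}"
        ) from None


def resolve_functions(spec) -> list[SOEFunction]:
    """Resolve 'all', a comma-separated string, or a list of names."""
    if spec is None or spec == "all":
        return list(FUNCTIONS.values())
    if isinstance(spec, str):
        spec = [s.strip() for s in spec.split(",") if s.strip()]
    return [get_function(s) if isinstance(s, str) else s for s in spec]


# thin functional wrappers ---------------------------------------------------

def evaluate(name: str, params, t, decay: DecayConstants | None = None):
    """Evaluate SOE function ``name`` at times ``t`` (minutes)."""
    return get_function(name).evaluate(params, t, decay)


def tia(name: str, params, decay: DecayConstants | None = None,
        t_end: float | None = 100_000.0):
    """Closed-form TIA of SOE function ``name`` over [0, t_end] minutes."""
    return get_function(name).tia(params, decay, t_end)


def validate_params(name: str, params) -> list[str]:
    """List of constraint violations for ``params`` (empty list iff valid)."""
    return get_function(name).validate(params)
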