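"""Synthetic study-design cohorts with known ground truth.

Emulates a sparse post-therapy imaging schedule: 13 patients scanned at
roughly 1.1 h, 20.7 h and 163.8 h post injection, one patient with one
extra point near 66.1 h and three patients with two extra points near
45.9 h and 68.7 h, for 46 observations in total.  Individual kinetic
parameters follow the log-normal population model (logit-normal for
fraction parameters) and observations carry multiplicative log-normal
residual noise — the same structure the NLME engine assumes.

Default truth is ``f3a`` with physiologically plausible kidney-like
magnitudes (A1 ~ 4% of injected activity clearing with a biological
half-life of roughly a day on top of physical decay, plus a small slowly
clearing fraction A2).  These defaults are fixture choices of this package,
not published parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import TimeActivityCohort
from .functions import DecayConstants, get_function
from .nlme import _transform_forward, _transform_inverse

__all__ = ["CohortDesign", "SimulatedCohort", "generate_cohort", "truth_tia"]

#: default truth fixed effects (natural scale, rates per minute)
DEFAULT_TRUTH_TVP = {"A1": 0.04, "A2": 0.005, "lambda1": 0.02 / 60.0}


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design and generating truth for a synthetic cohort."""

    n_patients: int = 13
    #: nominal scan times, hours post injection: (mean, SD)
    base_schedule_h: tuple = ((1.1, 0.7), (20.7, 2.3), (163.8, 2.0))
    #: one patient receives a single extra point (hours, SD)
    extra_single_h: tuple = (66.1, 0.0)
    #: this many patients receive two extra points each
    n_extra_patients: int = 3
    extra_pair_h: tuple = ((45.9, 1.6), (68.7, 1.7))
    truth_function: str = "f3a"
    truth_tvp: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH_TVP))
    omega: float = 0.3        # inter-individual log-scale SD, every parameter
    sigma_res: float = 0.15   # residual SD of log observations
    half_life_days: float = 6.6443


@dataclass(frozen=True)
class SimulatedCohort:
    """A generated cohort plus everything needed for recovery checks."""

    cohort: TimeActivityCohort
    design: CohortDesign
    individual_params: pd.DataFrame  # natural scale, patients x parameters
    seed: int

    def truth_tia(self, t_end: float | None = 100_000.0) -> pd.Series:
        """Closed-form reference TIA at the true per-patient parameters."""
        fn = get_function(self.design.truth_function)
        decay = DecayConstants(self.design.half_life_days)
        return pd.Series(
            {pid: fn.tia(row.to_dict(), decay, t_end)
             for pid, row in self.individual_params.iterrows()},
            name="tia_truth",
        )


def _draw_time(rng, mean_h, sd_h):
    if sd_h == 0:
        return mean_h * 60.0
    for _ in range(100):
        v = rng.normal(mean_h, sd_h)
        if v > 0:
            return v * 60.0
    raise ValueError(
        f"could not draw a positive time from N({mean_h}, {sd_h}^2) in 100 tries"
    )


def generate_cohort(design: CohortDesign | None = None, seed: int = 0) -> SimulatedCohort:
    """Generate a study-design cohort; deterministic given (design, seed)."""
    design = design or CohortDesign()
    rng = np.random.default_rng(seed)
    fn = get_function(design.truth_function)
    decay = DecayConstants(design.half_life_days)
    tvp = np.asarray([design.truth_tvp[p] for p in fn.params], dtype=float)
    z_pop = _transform_forward(tvp, fn.kinds)

    ids = [f"P{i + 1:02d}" for i in range(design.n_patients)]
    # patient 1 gets the single extra point; the next n_extra_patients get pairs
    extras: dict[str, list] = {pid: [] for pid in ids}
    if design.extra_single_h is not None and design.n_patients >= 1:
        extras[ids[0]].append(design.extra_single_h)
    for k in range(min(design.n_extra_patients, max(design.n_patients - 1, 0))):
        extras[ids[1 + k]].extend(design.extra_pair_h)

    rows = []
    params = {}
    for pid in ids:
        eta = rng.normal(0.0, design.omega, fn.n_shape_params)
        theta = _transform_inverse((z_pop + eta)[None, :], fn.kinds)[0]
        params[pid] = theta
        sched = list(design.base_schedule_h) + extras[pid]
        times = sorted(_draw_time(rng, m, s) for m, s in sched)
        f = fn.evaluate(fn.param_dict(theta), np.asarray(times), decay)
        eps = rng.normal(0.0, design.sigma_res, len(times))
        y = f * np.exp(eps)
        for t, v in zip(times, y):
            rows.append((pid, t, v))

    frame = pd.DataFrame(rows, columns=["patient_id", "time", "activity"])
    cohort = TimeActivityCohort.from_frame(frame, "min")
    ip = pd.DataFrame(params, index=list(fn.params)).T
    return SimulatedCohort(cohort=cohort, design=design, individual_params=ip, seed=seed)


def truth_tia(sim: SimulatedCohort, t_end: float | None = 100_000.0) -> pd.Series:
    """Functional wrapper for :meth:`SimulatedCohort.truth_tia`."""
    return sim.truth_tia(t_end)
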