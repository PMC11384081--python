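"""Time-activity cohort container.

A cohort is a long table of (patient_id, time, activity) observations:
time in minutes post injection, activity as a positive fraction of the
injected activity.  Activities must be strictly positive because the fitting
engines work on log observations (multiplicative error model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TimeActivityCohort", "TIME_UNIT_MINUTES"]

TIME_UNIT_MINUTES = {"min": 1.0, "h": 60.0, "d": 1440.0}


@dataclass(frozen=True)
class TimeActivityCohort:
    """Per-patient (time, activity) observations, times in minutes."""

    frame: pd.DataFrame  # columns: patient_id, time_min, activity

    @staticmethod
    def from_frame(df: pd.DataFrame, time_unit: str = "min") -> "TimeActivityCohort":
        required = {"patient_id", "time", "activity"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort table missing column(s): {sorted(missing)}")
        try:
            factor = TIME_UNIT_MINUTES[time_unit]
        except KeyError:
            raise ValueError(f"time unit must be one of {list(TIME_UNIT_MINUTES)}") from None
        out = pd.DataFrame(
            {
                "patient_id": df["patient_id"].astype(str),
                "time_min": pd.to_numeric(df["time"]) * factor,
                "activity": pd.to_numeric(df["activity"]),
            }
        )
        return TimeActivityCohort._validated(out)

    @staticmethod
    def from_arrays(times_min, activities, patient_ids) -> "TimeActivityCohort":
        out = pd.DataFrame(
            {
                "patient_id": np.asarray(patient_ids).astype(str),
                "time_min": np.asarray(times_min, dtype=float),
                "activity": np.asarray(activities, dtype=float),
            }
        )
        return TimeActivityCohort._validated(out)

    @staticmethod
    def _validated(df: pd.DataFrame) -> "TimeActivityCohort":
        if len(df) == 0:
            raise ValueError("cohort is empty")
        bad = df.index[~np.isfinite(df["time_min"]) | (df["time_min"] < 0)]
        if len(bad):
            raise ValueError(f"non-finite or negative times at rows {list(bad)}")
        bad = df.index[~np.isfinite(df["activity"]) | (df["activity"] <= 0)]
        if len(bad):
            raise ValueError(
                "activities must be positive (log-residual model); "
                f"offending rows: {list(bad)}"
            )
        dup = df.duplicated(subset=["patient_id", "time_min"], keep=False)
        if dup.any():
            offenders = df.loc[dup, ["patient_id", "time_min"]].drop_duplicates()
            raise ValueError(
                "duplicate (patient, time) pairs: "
                + "; ".join(f"{r.patient_id}@{r.time_min:g}min" for r in offenders.itertuples())
            )
        df = df.sort_values(["patient_id", "time_min"], kind="stable").reset_index(drop=True)
        return TimeActivityCohort(df)

    # -- accessors ----------------------------------------------------------

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["patient_id"]))

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def patient(self, patient_id: str) -> pd.DataFrame:
        sub = self.frame[self.frame["patient_id"] == str(patient_id)]
        if len(sub) == 0:
            raise KeyError(f"unknown patient id {patient_id!r}")
        return sub

    def drop_patient(self, patient_id: str) -> "TimeActivityCohort":
        sub = self.frame[self.frame["patient_id"] != str(patient_id)]
        if len(sub) == len(self.frame):
            raise KeyError(f"unknown patient id {patient_id!r}")
        return TimeActivityCohort(sub.reset_index(drop=True))

    def padded_arrays(self):
        """Pad observations to a (n_patients, max_obs) rectangle.

        Returns ``(t, logy, mask, ids)`` where mask is 1.0 for real
        observations and 0.0 for padding; padded times/logy are benign
        values so vectorised kernels stay finite.
        """
        ids = self.patient_ids
        groups = [self.patient(pid) for pid in ids]
        jmax = max(len(g) for g in groups)
        t = np.zeros((len(ids), jmax))
        logy = np.zeros((len(ids), jmax))
        mask = np.zeros((len(ids), jmax))
        for i, g in enumerate(groups):
            n = len(g)
            t[i, :n] = g["time_min"].to_numpy()
            logy[i, :n] = np.log(g["activity"].to_numpy())
            mask[i, :n] = 1.0
        return t, logy, mask, ids

    def to_xy(self):
        """Return (X, y, groups) arrays in sklearn convention."""
        return (
            self.frame["time_min"].to_numpy(),
            self.frame["activity"].to_numpy(),
            self.frame["patient_id"].to_numpy(),
        )


def as_cohort(X, y=None, groups=None) -> TimeActivityCohort:
    """Coerce estimator inputs to a :class:`TimeActivityCohort`.

    ``X`` may already be a cohort, a long DataFrame with columns
    (patient_id, time, activity) in minutes, or an array of times in
    minutes with ``y`` activities and ``groups`` patient labels.
    """
    if isinstance(X, TimeActivityCohort):
        return X
    if isinstance(X, pd.DataFrame):
        if {"patient_id", "time", "activity"} <= set(X.columns):
            return TimeActivityCohort.from_frame(X, "min")
        raise ValueError("DataFrame input needs columns patient_id, time, activity")
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if y is None:
        raise ValueError("y (activities) is required with array input")
    if groups is None:
        groups = np.zeros(len(X), dtype=int)  # single-patient convenience
    return TimeActivityCohort.from_arrays(X, y, groups)
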