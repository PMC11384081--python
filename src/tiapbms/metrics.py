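"""Accuracy metrics: relative deviations and RMSE against a reference TIA.

Each method's per-patient TIA is compared with the model-averaged (MA)
reference: RD_j = (TIA_j - TIA_MA)/TIA_MA in percent, and
RMSE_j = sqrt(SD(RD_j)^2 + mean(RD_j)^2) over patients.  The SD uses the
sample (n-1) denominator by default; with the population (n) denominator
the RMSE identity RMSE = sqrt(mean(RD^2)) holds exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["relative_deviation", "rmse", "tia_report"]


def relative_deviation(tia_method, tia_reference) -> pd.Series:
    """Per-patient relative deviation in percent.

    Both inputs are per-patient Series (or aligned arrays); the reference
    must be strictly positive.
    """
    a = pd.Series(tia_method, dtype=float)
    b = pd.Series(tia_reference, dtype=float)
    if set(a.index) != set(b.index):
        raise ValueError("patient sets of method and reference differ")
    b = b.reindex(a.index)
    if np.any(b <= 0):
        raise ValueError("reference TIA must be positive")
    out = (a - b) / b * 100.0
    out.name = "rd_percent"
    return out


def rmse(rds, ddof: int = 1) -> float:
    """RMSE of relative deviations: sqrt(SD(RD)^2 + mean(RD)^2).

    ``ddof=1`` (sample SD) is the default; ``ddof=0`` makes the result
    identical to sqrt(mean(RD^2)).
    """
    r = np.asarray(rds, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 relative deviations")
    return float(np.sqrt(np.std(r, ddof=ddof) ** 2 + np.mean(r) ** 2))


def tia_report(tias: dict, reference: str = "MA", ddof: int = 1) -> dict:
    """Table-2-shaped comparison of per-method TIAs against a reference.

    ``tias`` maps method name -> per-patient TIA Series (one entry must be
    the reference).  Returns ``{"tia": ..., "rd": ..., "summary": ...}``
    DataFrames; the summary carries mean (SD), median [min, max] and RMSE of
    the RDs per method.  Metadata records the SD denominator used.
    """
    if reference not in tias:
        raise ValueError(f"reference method {reference!r} not in {sorted(tias)}")
    tia_tab = pd.DataFrame({m: pd.Series(v, dtype=float) for m, v in tias.items()})
    if tia_tab.isna().any().any():
        raise ValueError("patient sets differ between methods")
    ref = tia_tab[reference]
    rd_tab = pd.DataFrame({m: relative_deviation(tia_tab[m], ref) for m in tia_tab})
    rows = []
    for m in rd_tab:
        r = rd_tab[m]
        rows.append(dict(
            method=m,
            mean_rd=r.mean(),
            sd_rd=r.std(ddof=ddof),
            median_rd=r.median(),
            min_rd=r.min(),
            max_rd=r.max(),
            rmse=rmse(r, ddof=ddof) if m != reference else 0.0,
        ))
    summary = pd.DataFrame(rows).set_index("method")
    summary.attrs["sd_denominator"] = "n-1" if ddof == 1 else "n"
    return {"tia": tia_tab, "rd": rd_tab, "summary": summary}
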