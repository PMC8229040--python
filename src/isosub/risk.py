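"""Outcome preparation: z-scores, BMI, mean blood pressure, and the
clustered cardiometabolic risk score (CCRS).

The CCRS summarises overall cardiometabolic risk as the mean of sample
z-scores of HbA1c, triglycerides, mean arterial-cuff blood pressure
((systolic + diastolic)/2), inverted HDL cholesterol and — in the
adiposity-inclusive variant — waist circumference.  Higher scores mean
higher risk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CCRS_COMPONENTS = ("hba1c", "triglycerides", "mean_bp", "hdl", "waist")


def standardize(values, name: str = "outcome") -> pd.Series:
    """Sample z-score: (value - mean) / SD with the n-1 denominator.

    Missing values are excluded from the mean/SD and propagate as missing
    in the output.  A constant vector has no scale and raises.
    """
    s = pd.Series(values, dtype=float)
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"cannot standardise '{name}': no variation in observed values")
    return (s - s.mean()) / sd


def compute_bmi(mass_kg, height_m):
    """Body mass index, mass (kg) / height (m) squared."""
    mass_kg = np.asarray(mass_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(height_m <= 0.5):
        raise ValueError("height must exceed 0.5 m")
    return mass_kg / height_m**2


def mean_bp(sbp_mmhg, dbp_mmhg):
    """Mean of systolic and diastolic blood pressure (mmHg)."""
    return (np.asarray(sbp_mmhg, dtype=float) + np.asarray(dbp_mmhg, dtype=float)) / 2.0


def compute_ccrs(
    panel: pd.DataFrame,
    include_waist: bool = True,
    complete_case: bool = False,
) -> pd.Series:
    """Clustered cardiometabolic risk score for each row of ``panel``.

    ``panel`` must carry columns ``hba1c``, ``triglycerides``, ``hdl`` and
    either ``mean_bp`` or both ``sbp_mmhg``/``dbp_mmhg``; ``waist`` is
    required when ``include_waist``.  Components are z-scored over the rows
    supplied, HDL is inverted (higher HDL is protective), and the score is
    the rowwise mean of available components (all components for
    ``complete_case=True``).
    """
    if len(panel) < 2:
        raise ValueError("CCRS standardisation needs at least 2 rows")
    work = panel.copy()
    if "mean_bp" not in work.columns:
        work["mean_bp"] = mean_bp(work["sbp_mmhg"], work["dbp_mmhg"])
    components = CCRS_COMPONENTS if include_waist else CCRS_COMPONENTS[:-1]
    z = pd.DataFrame(index=work.index)
    for c in components:
        if c not in work.columns:
            raise ValueError(f"CCRS requires column '{c}'")
        zc = standardize(work[c], name=c)
        z[c] = -zc if c == "hdl" else zc
    if complete_case:
        return z.mean(axis=1).where(z.notna().all(axis=1))
    return z.mean(axis=1)  # available-case: skipna mean; all-missing -> NaN


def add_risk_scores(df: pd.DataFrame, complete_case: bool = False) -> pd.DataFrame:
    """Augment a participant table with z-scored components and both CCRS variants.

    Adds ``z_<component>`` columns (HDL inverted as ``z_hdl_inverted``),
    ``ccrs`` (with waist) and ``ccrs_no_adiposity``.
    """
    out = df.copy()
    if "mean_bp" not in out.columns and {"sbp_mmhg", "dbp_mmhg"} <= set(out.columns):
        out["mean_bp"] = mean_bp(out["sbp_mmhg"], out["dbp_mmhg"])
    for c in CCRS_COMPONENTS:
        if c in out.columns:
            zc = standardize(out[c], name=c)
            if c == "hdl":
                out["z_hdl_inverted"] = -zc
            else:
                out[f"z_{c}"] = zc
    out["ccrs"] = compute_ccrs(out, include_waist=True, complete_case=complete_case)
    out["ccrs_no_adiposity"] = compute_ccrs(out, include_waist=False, complete_case=complete_case)
    return out
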