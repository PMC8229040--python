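"""Valid wear-day screening and participant-level averaging.

Thigh-worn activity monitors yield one record per monitored day.  A day
is analytically usable only if the device was worn long enough, the
wearer actually moved, and no single posture implausibly dominates the
record (a signature of mis-worn or mis-processed devices).  Participants
contribute to analysis only if enough of their days survive screening;
their behaviour profile is the arithmetic mean over valid days.

Screening thresholds (defaults):

* wear time >= 600 min (10 h of valid waking wear),
* >= 500 step events (one event is a two-step stride, i.e. 1000 steps),
* no single behaviour occupying more than 95% of wear time,
* >= 4 valid days to be included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import BehaviourComposition

MIN_WEAR_MIN = 600.0
MIN_STEP_EVENTS = 500
MAX_BEHAVIOUR_FRACTION = 0.95
MIN_VALID_DAYS = 4

#: Reason codes attached to failed days.
REASON_SHORT_WEAR = "wear<600min"
REASON_LOW_STEPS = "steps<500events"
REASON_MONOBEHAVIOUR = "monobehaviour>95%"

DAY_COLUMNS = [
    "participant_id",
    "date",
    "wear_min",
    "sit_min",
    "stand_min",
    "step_min",
    "step_events",
]


@dataclass(frozen=True)
class DayVerdict:
    valid: bool
    reasons: tuple[str, ...]


def is_valid_day(
    wear_min: float,
    sit_min: float,
    stand_min: float,
    step_min: float,
    step_events: float,
    *,
    min_wear_min: float = MIN_WEAR_MIN,
    min_step_events: float = MIN_STEP_EVENTS,
    max_behaviour_fraction: float = MAX_BEHAVIOUR_FRACTION,
    denominator: str = "wear",
) -> DayVerdict:
    """Screen a single monitored day, returning a verdict with reason codes.

    ``denominator`` selects what the dominance rule divides by: total wear
    time (``"wear"``, default) or the sum of the three behaviours
    (``"behaviours"``).
    """
    for v in (wear_min, sit_min, stand_min, step_min, step_events):
        if v < 0:
            raise ValueError("day fields must be non-negative")
    reasons: list[str] = []
    if wear_min < min_wear_min:
        reasons.append(REASON_SHORT_WEAR)
    if step_events < min_step_events:
        reasons.append(REASON_LOW_STEPS)
    denom = wear_min if denominator == "wear" else sit_min + stand_min + step_min
    if denom <= 0:
        # a zero-wear day already fails the wear rule; dominance is moot
        if REASON_SHORT_WEAR not in reasons:
            reasons.append(REASON_SHORT_WEAR)
    elif max(sit_min, stand_min, step_min) / denom > max_behaviour_fraction:
        reasons.append(REASON_MONOBEHAVIOUR)
    return DayVerdict(valid=not reasons, reasons=tuple(reasons))


def validate_days(days: pd.DataFrame, **criteria) -> pd.DataFrame:
    """Apply :func:`is_valid_day` to every row, adding ``valid`` and ``reasons``."""
    missing = [c for c in DAY_COLUMNS if c not in days.columns and c != "date"]
    if missing:
        raise ValueError(f"day table is missing columns: {missing}")
    out = days.copy()
    verdicts = [
        is_valid_day(
            r.wear_min, r.sit_min, r.stand_min, r.step_min, r.step_events, **criteria
        )
        for r in days.itertuples()
    ]
    out["valid"] = [v.valid for v in verdicts]
    out["reasons"] = [";".join(v.reasons) for v in verdicts]
    return out


def participant_average(
    days: pd.DataFrame,
    min_valid_days: int = MIN_VALID_DAYS,
    **criteria,
) -> dict:
    """Average one participant's valid days into a single behaviour record.

    Returns a dict with ``included`` flag, number of valid days, and (when
    included) the averaged behaviour minutes and wear.  Participants with
    fewer than ``min_valid_days`` valid days are flagged excluded rather
    than raising.
    """
    if len(days) and days["participant_id"].nunique() > 1:
        raise ValueError("participant_average expects days from a single participant")
    pid = days["participant_id"].iloc[0] if len(days) else None
    if len(days) == 0:
        return {"participant_id": pid, "included": False, "n_valid_days": 0}
    checked = validate_days(days, **criteria)
    valid = checked[checked["valid"]]
    if len(valid) < min_valid_days:
        return {
            "participant_id": pid,
            "included": False,
            "n_valid_days": int(len(valid)),
        }
    return {
        "participant_id": pid,
        "included": True,
        "n_valid_days": int(len(valid)),
        "sit_min": float(valid["sit_min"].mean()),
        "stand_min": float(valid["stand_min"].mean()),
        "step_min": float(valid["step_min"].mean()),
        "wear_min": float(valid["wear_min"].mean()),
    }


def summarise_participants(
    days: pd.DataFrame, min_valid_days: int = MIN_VALID_DAYS, **criteria
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen a multi-participant day table.

    Returns ``(participants, exclusions)``: included participants with their
    averaged composition, and an exclusion log with valid-day counts and the
    reason codes seen across their failed days.
    """
    checked = validate_days(days, **criteria)
    included_rows, excluded_rows = [], []
    for pid, grp in checked.groupby("participant_id", sort=True):
        valid = grp[grp["valid"]]
        if len(valid) >= min_valid_days:
            included_rows.append(
                {
                    "participant_id": pid,
                    "n_valid_days": len(valid),
                    "sit_min": valid["sit_min"].mean(),
                    "stand_min": valid["stand_min"].mean(),
                    "step_min": valid["step_min"].mean(),
                    "wear_min": valid["wear_min"].mean(),
                }
            )
        else:
            seen = sorted({r for rs in grp["reasons"] if rs for r in rs.split(";")})
            excluded_rows.append(
                {
                    "participant_id": pid,
                    "n_valid_days": len(valid),
                    "n_days": len(grp),
                    "failure_reasons": ";".join(seen),
                }
            )
    participants = pd.DataFrame(
        included_rows,
        columns=["participant_id", "n_valid_days", "sit_min", "stand_min", "step_min", "wear_min"],
    )
    exclusions = pd.DataFrame(
        excluded_rows, columns=["participant_id", "n_valid_days", "n_days", "failure_reasons"]
    )
    return participants, exclusions


def read_day_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"day CSV {path} is missing columns: {missing}")
    return df


def composition_from_row(row) -> BehaviourComposition:
    """Build a :class:`BehaviourComposition` from a participant table row."""
    parts = (float(row["sit_min"]), float(row["stand_min"]), float(row["step_min"]))
    return BehaviourComposition(*parts, total_min=sum(parts))
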