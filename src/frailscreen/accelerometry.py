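"""Accelerometer wear-time validation and activity-energy summaries.

A day counts as valid only when the device was worn for strictly more than
600 minutes; a participant is eligible for analysis with at least 3 valid
days. The participant-level exposure is the mean daily activity energy
expenditure (kcal per kg body weight per day, AEE) over valid days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VALID_WEAR_MINUTES",
    "MIN_VALID_DAYS",
    "AccelSummary",
    "flag_valid_days",
    "summarize",
    "summarize_all",
]

#: A valid day requires wear time strictly greater than this many minutes.
VALID_WEAR_MINUTES = 600.0
#: Minimum number of valid days for analysis eligibility.
MIN_VALID_DAYS = 3
_MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class AccelSummary:
    participant_id: str
    n_valid_days: int
    mean_aee: float  # NaN when no valid day
    eligible: bool


def _check_wear(wear: np.ndarray) -> None:
    bad = ~((wear >= 0) & (wear <= _MINUTES_PER_DAY))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"wear_minutes out of [0, 1440] at row {row}: {wear[row]!r}"
        )


def flag_valid_days(days: pd.DataFrame) -> np.ndarray:
    """Boolean validity flag per daily record (wear strictly > 600 min)."""
    wear = np.asarray(days["wear_minutes"], dtype=float)
    _check_wear(wear)
    return wear > VALID_WEAR_MINUTES


def summarize(days: pd.DataFrame, participant_id: str | None = None) -> AccelSummary:
    """Summarise one participant's daily records.

    Mean AEE is taken over valid days only; invalid days never contribute.
    An empty record set yields n_valid_days = 0, eligible = False.
    """
    if participant_id is None:
        ids = days["participant_id"].unique() if len(days) else []
        if len(ids) > 1:
            raise ValueError(f"records span multiple participants: {list(ids)}")
        participant_id = str(ids[0]) if len(ids) else ""
    if len(days) == 0:
        return AccelSummary(participant_id, 0, float("nan"), False)
    valid = flag_valid_days(days)
    n_valid = int(valid.sum())
    aee = np.asarray(days["aee"], dtype=float)
    if not np.isfinite(aee[valid]).all():
        raise ValueError("non-finite aee on a valid day")
    mean_aee = float(aee[valid].mean()) if n_valid else float("nan")
    return AccelSummary(participant_id, n_valid, mean_aee, n_valid >= MIN_VALID_DAYS)


def summarize_all(days: pd.DataFrame) -> pd.DataFrame:
    """Per-participant summary table (participant_id, n_valid_days, mean_aee, eligible)."""
    _check_wear(np.asarray(days["wear_minutes"], dtype=float))
    rows = []
    for pid, grp in days.groupby("participant_id", sort=True):
        s = summarize(grp, participant_id=str(pid))
        rows.append((s.participant_id, s.n_valid_days, s.mean_aee, s.eligible))
    return pd.DataFrame(
        rows, columns=["participant_id", "n_valid_days", "mean_aee", "eligible"]
    )
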