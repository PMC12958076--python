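"""Eligibility screening, SMS scheduling/withholding, and endpoint logic.

The primary endpoint is on-time vaccination: receipt within the closed
window from 14 days before the due date to 28 days after. Occasions
vaccinated more than 14 days early are excluded from analysis (no reminder
could have been issued); an occasion with no receipt record and complete
follow-up counts as not on time. A parent's index occasion is their first
SMS-eligible occasion after randomisation — exactly one per parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .arms import Arm
from .config import ONTIME_WINDOW

EARLY_CUTOFF = ONTIME_WINDOW[0]  # -14
LATE_CUTOFF = ONTIME_WINDOW[1]  # 28
MIN_DOSE_INTERVAL_DAYS = 28  # minimum window between eligible vaccine doses

STATUS_EXCLUDED_EARLY = "excluded_early"
STATUS_ONTIME = "ontime"
STATUS_NOT_ONTIME = "not_ontime"


@dataclass(frozen=True)
class EligibilityRecord:
    occasion_id: int
    eligible: bool
    reasons: tuple = ()

    def __post_init__(self):
        if self.eligible != (len(self.reasons) == 0):
            raise ValueError("eligible flag inconsistent with reasons")


@dataclass(frozen=True)
class SmsEvent:
    occasion_id: int
    planned_day: int
    sent: bool
    withheld_reason: Optional[str] = None

    def __post_init__(self):
        if self.sent and self.withheld_reason is not None:
            raise ValueError("a sent SMS cannot carry a withheld reason")


@dataclass(frozen=True)
class EndpointRecord:
    occasion_id: int
    status: str
    followup_complete: bool
    receipt_offset: Optional[int] = None


def screen_eligibility(
    occasion_id: int,
    *,
    opted_out: bool = False,
    has_phone: bool = True,
    has_name_and_dob: bool = True,
    receipt_offset: Optional[int] = None,
    days_since_prior_dose: Optional[int] = None,
) -> EligibilityRecord:
    """Deterministic eligibility screen for one occasion.

    Reasons mirror the trial's exclusions: parents opted out of SMS, missing
    phone number, missing name or date of birth, vaccination more than 14
    days before due, or the 4-week minimum interval since the prior eligible
    dose not met.
    """
    reasons: List[str] = []
    if opted_out:
        reasons.append("opted_out")
    if not has_phone:
        reasons.append("missing_phone")
    if not has_name_and_dob:
        reasons.append("missing_name_or_dob")
    if receipt_offset is not None and receipt_offset < EARLY_CUTOFF:
        reasons.append("early_vaccinated")
    if days_since_prior_dose is not None and days_since_prior_dose < MIN_DOSE_INTERVAL_DAYS:
        reasons.append("min_interval_unmet")
    return EligibilityRecord(occasion_id, eligible=not reasons, reasons=tuple(reasons))


def schedule_sms(
    arm: Arm,
    occasion_id: int,
    due_date: int,
    receipt_date: Optional[int] = None,
    days_since_prior_dose: Optional[int] = None,
    suppressed_days: Optional[set] = None,
) -> SmsEvent:
    """Plan (or withhold) the reminder for an SMS-arm occasion.

    The message is planned at due_date + the arm's timing offset and
    withheld if the vaccine was already recorded before the planned day or
    the 4-week minimum interval between eligible doses was unmet.
    ``suppressed_days`` optionally marks calendar days on which no SMS can
    go out (clinic server outages); a message planned for such a day is
    withheld, not rescheduled. Control-arm occasions never produce an
    event (contract error).
    """
    if arm.is_control:
        raise ValueError("control arm occasions produce no SMS event")
    planned = due_date + arm.timing
    if receipt_date is not None and receipt_date < planned:
        return SmsEvent(occasion_id, planned, sent=False, withheld_reason="already_vaccinated")
    if days_since_prior_dose is not None and days_since_prior_dose < MIN_DOSE_INTERVAL_DAYS:
        return SmsEvent(occasion_id, planned, sent=False, withheld_reason="min_interval_unmet")
    if suppressed_days is not None and planned in suppressed_days:
        return SmsEvent(occasion_id, planned, sent=False, withheld_reason="outage")
    return SmsEvent(occasion_id, planned, sent=True)


def ascertain_endpoint(
    occasion_id: int,
    due_date: int,
    receipt_offset: Optional[int],
    as_of_day: int,
) -> EndpointRecord:
    """Classify one occasion at calendar day ``as_of_day``.

    On-time iff receipt is within [-14, 28] days of due; receipt more than
    14 days early is excluded from analysis; absent receipt with the 28-day
    follow-up complete is not on time.
    """
    if as_of_day < due_date + EARLY_CUTOFF:
        raise ValueError("endpoint ascertained before the on-time window opens")
    complete = as_of_day >= due_date + LATE_CUTOFF
    if receipt_offset is not None and receipt_offset < EARLY_CUTOFF:
        return EndpointRecord(occasion_id, STATUS_EXCLUDED_EARLY, complete, receipt_offset)
    if receipt_offset is not None and EARLY_CUTOFF <= receipt_offset <= LATE_CUTOFF:
        return EndpointRecord(occasion_id, STATUS_ONTIME, complete, receipt_offset)
    return EndpointRecord(occasion_id, STATUS_NOT_ONTIME, complete, receipt_offset)


# ---------------------------------------------------------------------------
# vectorised helpers over the occasion-level DataFrame
# ---------------------------------------------------------------------------

def classify_endpoints(occasions: pd.DataFrame) -> pd.Series:
    """Endpoint status per occasion row (receipt_day is the signed offset)."""
    r = occasions["receipt_day"].astype("Float64").to_numpy(dtype=float, na_value=np.nan)
    status = np.full(len(occasions), STATUS_NOT_ONTIME, dtype=object)
    with np.errstate(invalid="ignore"):
        status[(r >= EARLY_CUTOFF) & (r <= LATE_CUTOFF)] = STATUS_ONTIME
        status[r < EARLY_CUTOFF] = STATUS_EXCLUDED_EARLY
    return pd.Series(status, index=occasions.index, name="endpoint_status")


def sms_eligible_mask(occasions: pd.DataFrame) -> pd.Series:
    """SMS eligibility per occasion: not vaccinated more than 14 days early."""
    return classify_endpoints(occasions) != STATUS_EXCLUDED_EARLY


def mark_index_occasions(occasions: pd.DataFrame) -> pd.DataFrame:
    """Set ``is_index`` on each parent's first SMS-eligible occasion.

    Ties in due date break by earliest child_id then occasion_id, making the
    index occasion invariant to input row order. Exactly one index per
    parent with any eligible occasion; zero otherwise.
    """
    occ = occasions.copy()
    occ["is_index"] = False
    eligible = occ[sms_eligible_mask(occ)]
    if len(eligible):
        ordered = eligible.sort_values(["due_date", "child_id", "occasion_id"], kind="mergesort")
        first = ordered.groupby("parent_id", sort=False).head(1)
        occ.loc[first.index, "is_index"] = True
    return occ


def completed_followup_mask(occasions: pd.DataFrame, as_of_day: int) -> pd.Series:
    """Occasions whose 28-day follow-up window has closed by ``as_of_day``."""
    return occasions["due_date"] + LATE_CUTOFF <= as_of_day
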