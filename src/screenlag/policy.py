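"""Virtual biennial screening schedule and detection-delay quantification.

Attended visits are binned into annual screening *cycles* using fixed
14-month breaks anchored at each person's baseline: cycle c covers elapsed
time in ((c−1)·14, c·14] months, tolerant of late annual attendance.  Under a
biennial policy only even cycles (2, 4, 6, …) are attended, so an STDR or PDR
event first detected at a visit falling in an odd cycle would have been
diagnosed at least one year later — a *delayed* event.  Delay counts are
reported overall and per stratum as events per 100,000 eligible persons with
exact binomial (Clopper-Pearson) intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .registry import DAYS_PER_MONTH
from .survival import PER_100K_PERSONS, RateEstimate

__all__ = [
    "CyclePolicy",
    "PolicyResult",
    "cycle_of",
    "assign_cycle",
    "simulate_biennial",
    "delayed_rate_per_100k",
    "stratify_policy",
]


@dataclass(frozen=True)
class CyclePolicy:
    """Cycle binning and attendance pattern of the virtual schedule.

    ``cycle_break_months`` must exceed 12 so that late annual attendance still
    lands in its intended cycle.  ``attended_parity='even'`` is the biennial
    schedule (cycles 2, 4, 6, … attended); ``'all'`` keeps every cycle
    attended (the annual status quo, a degeneracy check).  ``assignment``
    offers ordinal visit numbering as a sensitivity alternative to the
    time-based bins.
    """

    cycle_break_months: float = 14.0
    attended_parity: str = "even"
    assignment: str = "time"

    def __post_init__(self) -> None:
        if self.cycle_break_months <= 12:
            raise ValueError("cycle_break_months must exceed 12")
        if self.attended_parity not in ("even", "all"):
            raise ValueError("attended_parity must be 'even' or 'all'")
        if self.assignment not in ("time", "ordinal"):
            raise ValueError("assignment must be 'time' or 'ordinal'")

    @property
    def cycle_break_days(self) -> float:
        return self.cycle_break_months * DAYS_PER_MONTH


def cycle_of(elapsed_days: float, policy: CyclePolicy | None = None) -> int:
    """Cycle index (≥1) for a visit at ``elapsed_days`` after baseline.

    The smallest c ≥ 1 with elapsed ≤ c × cycle_break (boundary inclusive).
    """
    policy = policy or CyclePolicy()
    if elapsed_days < 0:
        raise ValueError("visit precedes baseline")
    return max(1, math.ceil(elapsed_days / policy.cycle_break_days))


def assign_cycle(visit_date, baseline_date, policy: CyclePolicy | None = None) -> int:
    """Cycle index of a calendar visit relative to a baseline date."""
    delta = (pd.Timestamp(visit_date) - pd.Timestamp(baseline_date)) / pd.Timedelta(days=1)
    return cycle_of(float(delta), policy)


@dataclass
class PolicyResult:
    """Per-event delay determination plus aggregate counts."""

    per_person: pd.DataFrame
    total_stdr: int
    delayed_stdr: int
    total_pdr: int
    delayed_pdr: int


def simulate_biennial(
    cohort: pd.DataFrame,
    episodes: pd.DataFrame | None = None,
    policy: CyclePolicy | None = None,
) -> PolicyResult:
    """Delay determination for every STDR event in the cohort.

    An event is *delayed* when its detection visit falls in a cycle skipped
    under the policy (odd cycles for the biennial parity).  The episode table,
    when supplied, is used to locate the first attended visit at the next
    even cycle — the date the event would actually have surfaced under
    biennial screening (often absent: people are referred out after
    detection, so no later visit exists; such events still count as delayed).
    PDR events are the ``is_pdr`` subset and inherit the same determination.
    """
    policy = policy or CyclePolicy()
    ev = cohort[cohort["exit_reason"] == "stdr_event"]

    if policy.assignment == "ordinal":
        if episodes is None:
            raise ValueError("ordinal assignment requires the episode table")
        cycles = _ordinal_cycles(ev, episodes)
    else:
        elapsed = (
            pd.to_datetime(ev["exit_date"]) - pd.to_datetime(ev["baseline_date"])
        ) / pd.Timedelta(days=1)
        if (elapsed < 0).any():
            bad = ev.loc[elapsed < 0, "person_id"].iloc[0]
            raise ValueError(f"event episode precedes baseline for person {bad!r}")
        cycles = np.maximum(1, np.ceil(elapsed.to_numpy() / policy.cycle_break_days)).astype(int)

    if policy.attended_parity == "even":
        delayed = cycles % 2 == 1
    else:
        delayed = np.zeros(len(ev), dtype=bool)
    detected_cycle = np.where(delayed, cycles + 1, cycles)

    detect_date = np.full(len(ev), np.datetime64("NaT"), dtype="datetime64[ns]")
    if episodes is not None and len(ev):
        ep = episodes[episodes["person_id"].isin(ev["person_id"])]
        by_person = {p: g["date"].to_numpy() for p, g in ep.groupby("person_id")}
        base = pd.to_datetime(ev["baseline_date"]).to_numpy()
        for i, (pid, b, dc, dly) in enumerate(
            zip(ev["person_id"].to_numpy(), base, detected_cycle, delayed)
        ):
            if not dly:
                detect_date[i] = pd.to_datetime(ev["exit_date"].to_numpy()[i])
                continue
            dates = by_person.get(pid, np.empty(0, dtype="datetime64[ns]"))
            lo = b + np.timedelta64(int(round((dc - 1) * policy.cycle_break_days)), "D")
            hi = b + np.timedelta64(int(round(dc * policy.cycle_break_days)), "D")
            later = dates[(dates > lo) & (dates <= hi)]
            if later.size:
                detect_date[i] = later[0]

    per_person = pd.DataFrame(
        {
            "person_id": ev["person_id"].to_numpy(),
            "event_cycle": cycles,
            "detected_cycle": detected_cycle,
            "delayed": delayed,
            "event_type": np.where(ev["is_pdr"].to_numpy(dtype=bool), "PDR", "STDR"),
            "biennial_detect_date": detect_date,
        }
    )
    is_pdr = ev["is_pdr"].to_numpy(dtype=bool)
    return PolicyResult(
        per_person=per_person,
        total_stdr=int(len(ev)),
        delayed_stdr=int(delayed.sum()),
        total_pdr=int(is_pdr.sum()),
        delayed_pdr=int((delayed & is_pdr).sum()),
    )


def _ordinal_cycles(ev: pd.DataFrame, episodes: pd.DataFrame) -> np.ndarray:
    """Cycle = ordinal number of attended post-baseline visits up to the event."""
    ep = episodes[episodes["person_id"].isin(ev["person_id"])]
    by_person = {p: g["date"].to_numpy() for p, g in ep.groupby("person_id")}
    out = np.empty(len(ev), dtype=int)
    for i, (pid, b, x) in enumerate(
        zip(ev["person_id"], pd.to_datetime(ev["baseline_date"]), pd.to_datetime(ev["exit_date"]))
    ):
        dates = by_person.get(pid)
        if dates is None:
            raise ValueError(f"no episodes for person {pid!r}")
        k = int(((dates > np.datetime64(b)) & (dates <= np.datetime64(x))).sum())
        if k == 0:
            raise ValueError(f"event episode not assignable to a cycle for person {pid!r}")
        out[i] = k
    return out


def delayed_rate_per_100k(
    delayed: int, eligible: int, ci_method: str = "clopper-pearson", alpha: float = 0.05
) -> RateEstimate:
    """Delayed events per 100,000 eligible persons with exact binomial CI."""
    if eligible <= 0:
        raise ValueError("eligible must be positive")
    if not 0 <= delayed <= eligible:
        raise ValueError("need 0 <= delayed <= eligible")
    p = delayed / eligible
    if ci_method == "clopper-pearson":
        lo = 0.0 if delayed == 0 else stats.beta.ppf(alpha / 2, delayed, eligible - delayed + 1)
        hi = 1.0 if delayed == eligible else stats.beta.ppf(1 - alpha / 2, delayed + 1, eligible - delayed)
    elif ci_method == "wilson":
        z = stats.norm.ppf(1 - alpha / 2)
        denom = 1 + z * z / eligible
        centre = (p + z * z / (2 * eligible)) / denom
        half = z * math.sqrt(p * (1 - p) / eligible + z * z / (4 * eligible * eligible)) / denom
        lo, hi = max(centre - half, 0.0), min(centre + half, 1.0)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    s = PER_100K_PERSONS
    return RateEstimate(int(delayed), float(eligible), s, s * p, s * lo, s * hi, ci_method)


def stratify_policy(
    result: PolicyResult,
    cohort: pd.DataFrame,
    by: str = "ethnicity",
    ci_method: str = "clopper-pearson",
) -> pd.DataFrame:
    """Per-stratum delayed STDR/PDR counts and rates per 100,000 persons.

    The stratum denominators are cohort sizes; stratum delayed counts sum to
    the overall delayed counts.  Missing stratum values form an explicit
    ``"unknown"`` stratum.
    """
    strata = cohort[["person_id", by]].copy()
    strata[by] = strata[by].astype(object).where(strata[by].notna(), "unknown")
    pp = result.per_person.merge(strata, on="person_id", how="left")

    rows = []
    for level, grp in strata.groupby(by, observed=True):
        eligible = len(grp)
        sub = pp[pp[by] == level]
        d_stdr = int(sub["delayed"].sum())
        d_pdr = int((sub["delayed"] & (sub["event_type"] == "PDR")).sum())
        r_pdr = delayed_rate_per_100k(d_pdr, eligible, ci_method)
        r_stdr = delayed_rate_per_100k(d_stdr, eligible, ci_method)
        rows.append(
            (level, eligible, d_pdr, r_pdr.point, r_pdr.ci_low, r_pdr.ci_high,
             d_stdr, r_stdr.point, r_stdr.ci_low, r_stdr.ci_high)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "stratum", "eligible",
            "delayed_pdr", "delayed_pdr_per_100k", "pdr_ci_low", "pdr_ci_high",
            "delayed_stdr", "delayed_stdr_per_100k", "stdr_ci_low", "stdr_ci_high",
        ],
    )
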