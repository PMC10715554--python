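"""Low-risk cohort construction: the staged eligibility cascade.

Entry into the low-risk cohort requires two consecutive attended screening
episodes graded R0M0 in both eyes roughly a year apart; the second episode of
the earliest such pair is the person's baseline.  Anyone showing STDR or
stable treated PDR (R3S) at or before that baseline is excluded.  Follow-up
after baseline ends at the first episode that is not a clean R0M0: an STDR
presentation is the event; non-referable retinopathy (R1) or an ungradable
episode right-censors the person at that date; otherwise the person is
administratively censored at the last attended episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import DAYS_PER_YEAR, summarise_episodes

__all__ = [
    "EligibilityRules",
    "CascadeReport",
    "find_baseline",
    "classify_followup",
    "build_cohort",
    "COHORT_COLUMNS",
]

EXIT_REASONS = ("stdr_event", "r1_censor", "u_censor", "admin_censor")

COHORT_COLUMNS = [
    "person_id",
    "baseline_date",
    "sex",
    "age_group",
    "age_at_first_episode",
    "ethnicity",
    "diabetes_type",
    "duration_years",
    "imd_quintile",
    "exit_date",
    "exit_reason",
    "is_pdr",
    "followup_years",
]


@dataclass(frozen=True)
class EligibilityRules:
    """Operational definition of 'two consecutive annual R0M0 screens'.

    ``min_pair_gap``/``max_pair_gap`` bound the gap (years) between the two
    qualifying episodes; the permissible window is configurable because
    screening practice tolerates late annual attendance.
    ``censor_at_first_dr=False`` switches to the alternative reading in which
    non-referable R1 episodes do not censor and a later STDR still counts.
    """

    min_pair_gap: float = 0.5
    max_pair_gap: float = 1.5
    require_complete_demographics: bool = True
    censor_at_first_dr: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_pair_gap < self.max_pair_gap:
            raise ValueError("need 0 < min_pair_gap < max_pair_gap")


@dataclass
class CascadeReport:
    """Ordered (exclusion step label, persons remaining) counts."""

    steps: list = field(default_factory=list)

    def add(self, label: str, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1][1]:
            raise ValueError("cascade counts must be non-increasing")
        self.steps.append((label, int(remaining)))

    def to_dict(self) -> dict:
        return {label: n for label, n in self.steps}


def _person_flags(episodes: pd.DataFrame):
    """(dates in days, clean flag, disqualifying STDR/R3S flag, summary df)."""
    summ = summarise_episodes(episodes)
    days = summ["date"].to_numpy(dtype="datetime64[D]").astype(np.int64)
    if len(days) > 1 and (np.diff(days) <= 0).any():
        raise ValueError("episodes must be strictly increasing in date")
    clean = summ["clean"].to_numpy()
    disqualify = summ["stdr"].to_numpy()
    return days, clean, disqualify, summ


def _baseline_index(days, clean, disqualify, rules: EligibilityRules):
    """(baseline index | None, failure reason) on pre-extracted arrays."""
    if len(days) < 2:
        return None, "no_pair"
    gaps = np.diff(days) / DAYS_PER_YEAR
    cand = clean[1:] & clean[:-1] & (gaps >= rules.min_pair_gap) & (gaps <= rules.max_pair_gap)
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        return None, "no_pair"
    b = int(idx[0]) + 1
    if disqualify[: b + 1].any():
        return None, "prior_stdr"
    return b, None


def find_baseline(episodes: pd.DataFrame, rules: EligibilityRules | None = None):
    """Positional index of the baseline episode for one person, or ``None``.

    The baseline is the second episode of the earliest pair of successive
    attended episodes that are both person-level R0M0 with a gap inside the
    configured window.  Returns ``None`` if no qualifying pair exists or if
    any episode at or before the candidate baseline shows STDR or R3S.
    Episodes must be date-sorted (ties are an error).
    """
    rules = rules or EligibilityRules()
    days, clean, disq, _ = _person_flags(episodes)
    b, _reason = _baseline_index(days, clean, disq, rules)
    return b


def _classify(days, summ_after, rules: EligibilityRules):
    """Classify post-baseline episodes given their summary flag arrays.

    ``summ_after`` is a dict of numpy arrays (clean, stdr, pdr, ungradable)
    for episodes strictly after baseline, date order.  Returns
    (exit offset index | None, exit_reason, is_pdr); ``None`` index means
    zero follow-up.
    """
    clean = summ_after["clean"]
    if len(clean) == 0:
        return None, "admin_censor", False
    if rules.censor_at_first_dr:
        nc = np.flatnonzero(~clean)
        if nc.size:
            j = int(nc[0])
            if summ_after["stdr"][j]:
                return j, "stdr_event", bool(summ_after["pdr"][j])
            if summ_after["ungradable"][j]:
                return j, "u_censor", False
            return j, "r1_censor", False
    else:
        # alternative reading: R1 does not censor; exit at first STDR or U
        stop = summ_after["stdr"] | summ_after["ungradable"]
        nc = np.flatnonzero(stop)
        if nc.size:
            j = int(nc[0])
            if summ_after["stdr"][j]:
                return j, "stdr_event", bool(summ_after["pdr"][j])
            return j, "u_censor", False
    return len(clean) - 1, "admin_censor", False


def classify_followup(episodes_after_baseline: pd.DataFrame, rules: EligibilityRules | None = None):
    """(exit_date, exit_reason, is_pdr) from the post-baseline episodes.

    Scans episodes in date order and exits at the first non-R0M0 episode:
    STDR → event; ungradable → censor; any other retinopathy → censor.  With
    no post-baseline episode the person is administratively censored with
    zero follow-up (exit_date ``None``; caller substitutes the baseline date).
    """
    rules = rules or EligibilityRules()
    summ = summarise_episodes(episodes_after_baseline)
    arrays = {k: summ[k].to_numpy() for k in ("clean", "stdr", "pdr", "ungradable")}
    j, reason, is_pdr = _classify(None, arrays, rules)
    if j is None:
        return None, reason, is_pdr
    return summ["date"].iloc[j], reason, is_pdr


def build_cohort(
    episodes: pd.DataFrame,
    profiles: pd.DataFrame,
    rules: EligibilityRules | None = None,
):
    """Apply the full exclusion cascade and emit one record per cohort member.

    Steps, in order: persons identified → attended at least once → complete
    demographics (if required) → qualifying R0M0 pair → no STDR/R3S at or
    before baseline.  Returns ``(cohort, CascadeReport)`` where ``cohort`` has
    one row per eligible person with baseline covariates, exit date/reason and
    follow-up years ((exit − baseline)/365.25).
    """
    rules = rules or EligibilityRules()
    report = CascadeReport()
    report.add("identified", len(profiles))

    ep = episodes.sort_values(["person_id", "date"], kind="mergesort")
    attenders = set(ep["person_id"].unique())
    prof = profiles[profiles["person_id"].isin(attenders)]
    report.add("attended at least once", len(prof))

    if rules.require_complete_demographics:
        needed = ["sex", "age_at_first_episode", "ethnicity", "diabetes_type", "duration_years"]
        complete = prof[needed].notna().all(axis=1)
        prof = prof[complete]
    report.add("complete demographics", len(prof))

    summ = summarise_episodes(ep)
    keep_ids = set(prof["person_id"])
    summ = summ[summ["person_id"].isin(keep_ids)]

    pid = summ["person_id"].to_numpy()
    days = summ["date"].to_numpy(dtype="datetime64[D]").astype(np.int64)
    clean = summ["clean"].to_numpy()
    stdr = summ["stdr"].to_numpy()
    pdr = summ["pdr"].to_numpy()
    ungr = summ["ungradable"].to_numpy()
    dates = summ["date"].to_numpy()

    boundaries = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1], True])
    records = []
    n_with_pair = 0
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        d = days[s:e]
        if len(d) > 1 and (np.diff(d) <= 0).any():
            raise ValueError(f"duplicate or unsorted episode dates for person {pid[s]!r}")
        b, reason = _baseline_index(d, clean[s:e], stdr[s:e], rules)
        if b is None:
            if reason == "prior_stdr":
                n_with_pair += 1
            continue
        n_with_pair += 1
        after = {
            "clean": clean[s + b + 1 : e],
            "stdr": stdr[s + b + 1 : e],
            "pdr": pdr[s + b + 1 : e],
            "ungradable": ungr[s + b + 1 : e],
        }
        j, exit_reason, is_pdr = _classify(None, after, rules)
        if j is None:
            exit_date = dates[s + b]
        else:
            exit_date = dates[s + b + 1 + j]
        baseline_date = dates[s + b]
        followup = (exit_date - baseline_date) / np.timedelta64(1, "D") / DAYS_PER_YEAR
        records.append((pid[s], baseline_date, exit_date, exit_reason, is_pdr, followup))

    # "has a qualifying pair" counts persons who achieved a clean annual pair
    # regardless of prior STDR; the prior-STDR exclusion is the final step.
    report.add("qualifying R0M0 pair", n_with_pair)
    report.add("no prior STDR/R3S", len(records))

    if records:
        core = pd.DataFrame(
            records,
            columns=["person_id", "baseline_date", "exit_date", "exit_reason", "is_pdr", "followup_years"],
        )
    else:
        core = pd.DataFrame(
            {
                "person_id": pd.Series(dtype=object),
                "baseline_date": pd.Series(dtype="datetime64[ns]"),
                "exit_date": pd.Series(dtype="datetime64[ns]"),
                "exit_reason": pd.Series(dtype=object),
                "is_pdr": pd.Series(dtype=bool),
                "followup_years": pd.Series(dtype=float),
            }
        )
    cohort = core.merge(profiles, on="person_id", how="left")
    cohort = cohort[COHORT_COLUMNS]
    return cohort.reset_index(drop=True), report
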