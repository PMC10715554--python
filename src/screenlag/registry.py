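"""Screening-registry data model: UK NSC retinopathy grades, episodes, demographics.

The registry holds one row per *attended* screening episode with per-eye
retinopathy (R) and maculopathy (M) grades on the UK National Screening
Committee scale:

* R0 — no retinopathy, R1 — mild non-proliferative, R2 — moderate-to-severe
  non-proliferative, R3 — proliferative (PDR), R3S — stable treated PDR,
  U — ungradable;
* M0 — no referable maculopathy, M1 — referable maculopathy, U — ungradable.

Sight-threatening diabetic retinopathy (STDR) is any R2, R3 or M1 in either
eye; PDR (R3) is the most serious subset.  Person-level summaries use the
worst eye.  An episode with a U component in either eye is treated as
ungradable as a whole: the analysis excludes or censors at such episodes, so
the disease flags are left False by convention even if the fellow eye shows
disease.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "R_TOKENS",
    "M_TOKENS",
    "SEX_LEVELS",
    "AGE_BANDS",
    "ETHNICITY_LEVELS",
    "DIABETES_LEVELS",
    "DAYS_PER_YEAR",
    "DAYS_PER_MONTH",
    "RegistryError",
    "EyeGrade",
    "PersonGradeSummary",
    "summarise_person_grade",
    "summarise_episodes",
    "age_band",
    "derive_imd_quintile",
    "read_registry",
    "write_registry",
]

R_TOKENS = ("R0", "R1", "R2", "R3", "R3S", "U")
M_TOKENS = ("M0", "M1", "U")
#: R grades that make an episode sight-threatening.  R3S (stable treated PDR)
#: is included so that any history of proliferative disease disqualifies a
#: person from the low-risk cohort at baseline.
STDR_R_TOKENS = frozenset({"R2", "R3", "R3S"})

SEX_LEVELS = ("female", "male")
AGE_BANDS = ("<45", "45-<55", "55-<65", ">=65")
ETHNICITY_LEVELS = (
    "white",
    "south_asian",
    "black",
    "any_other_asian",
    "other",
    "mixed",
    "chinese",
    "unknown",
)
DIABETES_LEVELS = ("type2", "type1", "other", "unknown")

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0

EPISODE_COLUMNS = ["person_id", "date", "r_left", "m_left", "r_right", "m_right"]
DEMOGRAPHIC_COLUMNS = [
    "person_id",
    "sex",
    "age_at_first_episode",
    "ethnicity",
    "diabetes_type",
    "duration_years",
    "imd_quintile",
]


class RegistryError(ValueError):
    """Malformed registry content (bad token, duplicate episode, bad date...)."""


@dataclass(frozen=True)
class EyeGrade:
    """Retinopathy/maculopathy grade pair for one eye."""

    r: str
    m: str

    def __post_init__(self) -> None:
        if self.r not in R_TOKENS:
            raise RegistryError(f"invalid R grade token {self.r!r}")
        if self.m not in M_TOKENS:
            raise RegistryError(f"invalid M grade token {self.m!r}")

    @property
    def ungradable(self) -> bool:
        return self.r == "U" or self.m == "U"


@dataclass(frozen=True)
class PersonGradeSummary:
    """Worst-eye, person-level view of one screening episode.

    Invariants: ``pdr ⇒ stdr ⇒ any_dr``; if ``ungradable`` the disease flags
    are False by convention (the episode is excluded/censored downstream).
    """

    any_dr: bool
    stdr: bool
    pdr: bool
    ungradable: bool

    @property
    def clean(self) -> bool:
        """True for a fully gradable R0M0-both-eyes episode."""
        return not (self.any_dr or self.ungradable)


def summarise_person_grade(left: EyeGrade, right: EyeGrade) -> PersonGradeSummary:
    """Collapse two eye grades to the person-level flags used by the analysis.

    STDR is any R2/R3 (or R3S history) or M1 in either eye; PDR is any R3.
    A U component in either eye marks the whole episode ungradable.
    Symmetric in (left, right).
    """
    if left.ungradable or right.ungradable:
        return PersonGradeSummary(False, False, False, True)
    rs = {left.r, right.r}
    ms = {left.m, right.m}
    pdr = "R3" in rs
    stdr = bool(rs & STDR_R_TOKENS) or "M1" in ms
    any_dr = stdr or rs != {"R0"} or ms != {"M0"}
    return PersonGradeSummary(any_dr, stdr, pdr, False)


def summarise_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`summarise_person_grade` over an episode table.

    Returns a copy of ``episodes`` with boolean columns ``any_dr``, ``stdr``,
    ``pdr``, ``ungradable`` and ``clean``.
    """
    rl = episodes["r_left"].to_numpy(dtype=object)
    rr = episodes["r_right"].to_numpy(dtype=object)
    ml = episodes["m_left"].to_numpy(dtype=object)
    mr = episodes["m_right"].to_numpy(dtype=object)

    ungr = (rl == "U") | (rr == "U") | (ml == "U") | (mr == "U")
    stdr_r = np.isin(rl, list(STDR_R_TOKENS)) | np.isin(rr, list(STDR_R_TOKENS))
    pdr = (rl == "R3") | (rr == "R3")
    m1 = (ml == "M1") | (mr == "M1")
    stdr = (stdr_r | m1) & ~ungr
    pdr = pdr & ~ungr
    any_dr = (stdr | (rl != "R0") | (rr != "R0") | m1) & ~ungr

    out = episodes.copy()
    out["any_dr"] = any_dr
    out["stdr"] = stdr
    out["pdr"] = pdr
    out["ungradable"] = ungr
    out["clean"] = ~(any_dr | ungr)
    return out


def age_band(age_years: float) -> str:
    """Age category used throughout the analysis (<45, 45-<55, 55-<65, >=65)."""
    if age_years < 45:
        return "<45"
    if age_years < 55:
        return "45-<55"
    if age_years < 65:
        return "55-<65"
    return ">=65"


def derive_imd_quintile(imd_score, reference_cutpoints) -> object:
    """Map a deprivation score to a quintile 1-5 given 4 ascending cutpoints.

    The caller supplies national reference cutpoints oriented so the quintile
    index increases with the score (quintile 1 = most deprived under the
    registry's convention).  Tie rule: a score equal to a cutpoint moves into
    the higher quintile.  A missing score yields ``None`` (never silently 0).
    """
    cut = list(reference_cutpoints)
    if len(cut) != 4 or any(b <= a for a, b in zip(cut, cut[1:])):
        raise ValueError("reference_cutpoints must be 4 strictly ascending values")
    if imd_score is None or (isinstance(imd_score, float) and np.isnan(imd_score)):
        return None
    return 1 + sum(imd_score >= c for c in cut)


def _fail(path, row: int, field: str, msg: str) -> None:
    raise RegistryError(f"{path}: row {row}, field {field!r}: {msg}")


def read_registry(episodes_path, demographics_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the episodes and demographics CSV files.

    Episode rows are validated for grade tokens and ISO-8601 dates; duplicate
    (person_id, date) pairs are an error because episodes for a person must be
    strictly orderable in time.  Demographic category tokens are validated
    against the ONS-derived level sets; genuinely absent values (empty cells)
    are kept as missing and flagged to the cohort builder, which decides
    exclusion.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    ep = pd.read_csv(episodes_path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in EPISODE_COLUMNS if c not in ep.columns]
    if missing_cols:
        raise RegistryError(f"{episodes_path}: missing columns {missing_cols}")

    for field, tokens in [
        ("r_left", R_TOKENS),
        ("r_right", R_TOKENS),
        ("m_left", M_TOKENS),
        ("m_right", M_TOKENS),
    ]:
        bad = ~ep[field].isin(tokens)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            _fail(episodes_path, i + 1, field, f"invalid grade token {ep[field].iloc[i]!r}")
    if (ep["person_id"] == "").any():
        i = int(np.flatnonzero((ep["person_id"] == "").to_numpy())[0])
        _fail(episodes_path, i + 1, "person_id", "empty person id")
    dates = pd.to_datetime(ep["date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        i = int(np.flatnonzero(dates.isna().to_numpy())[0])
        _fail(episodes_path, i + 1, "date", f"invalid ISO-8601 date {ep['date'].iloc[i]!r}")
    ep = ep.assign(date=dates)
    dup = ep.duplicated(subset=["person_id", "date"], keep=False)
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        _fail(
            episodes_path,
            i + 1,
            "date",
            f"duplicate episode for person {ep['person_id'].iloc[i]!r} "
            f"on {ep['date'].iloc[i].date()}",
        )
    ep = ep.sort_values(["person_id", "date"], kind="mergesort").reset_index(drop=True)

    dem = pd.read_csv(demographics_path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in DEMOGRAPHIC_COLUMNS if c not in dem.columns]
    if missing_cols:
        raise RegistryError(f"{demographics_path}: missing columns {missing_cols}")
    dupd = dem.duplicated(subset=["person_id"], keep=False)
    if dupd.any():
        i = int(np.flatnonzero(dupd.to_numpy())[0])
        _fail(demographics_path, i + 1, "person_id", "duplicate person")

    for field, tokens in [
        ("sex", SEX_LEVELS),
        ("ethnicity", ETHNICITY_LEVELS),
        ("diabetes_type", DIABETES_LEVELS),
    ]:
        bad = ~(dem[field].isin(tokens) | (dem[field] == ""))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            _fail(demographics_path, i + 1, field, f"invalid token {dem[field].iloc[i]!r}")

    def _numeric(field, lo=None, hi=None, integer=False):
        raw = dem[field].replace("", np.nan)
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            _fail(demographics_path, i + 1, field, f"not numeric: {dem[field].iloc[i]!r}")
        ok = vals.dropna()
        if lo is not None and (ok < lo).any():
            i = int(np.flatnonzero((vals < lo).fillna(False).to_numpy())[0])
            _fail(demographics_path, i + 1, field, f"value {vals.iloc[i]} below {lo}")
        if hi is not None and (ok > hi).any():
            i = int(np.flatnonzero((vals > hi).fillna(False).to_numpy())[0])
            _fail(demographics_path, i + 1, field, f"value {vals.iloc[i]} above {hi}")
        if integer and ((ok % 1) != 0).any():
            i = int(np.flatnonzero(((vals % 1) != 0).fillna(False).to_numpy())[0])
            _fail(demographics_path, i + 1, field, "not an integer")
        return vals

    age = _numeric("age_at_first_episode", lo=0, hi=120)
    dur = _numeric("duration_years", lo=0)
    imd = _numeric("imd_quintile", lo=1, hi=5, integer=True)
    imd_score = _numeric("imd_score") if "imd_score" in dem.columns else None

    out = pd.DataFrame(
        {
            "person_id": dem["person_id"],
            "sex": dem["sex"].replace("", np.nan),
            "age_at_first_episode": age,
            "ethnicity": dem["ethnicity"].replace("", np.nan),
            "diabetes_type": dem["diabetes_type"].replace("", np.nan),
            "duration_years": dur,
            "imd_quintile": imd.astype("Int64"),
        }
    )
    if imd_score is not None:
        out["imd_score"] = imd_score
    out["age_group"] = out["age_at_first_episode"].map(
        lambda a: age_band(a) if pd.notna(a) else np.nan
    )
    return ep, out


def _format_float(x) -> str:
    if pd.isna(x):
        return ""
    return repr(float(x))


def write_registry(episodes: pd.DataFrame, demographics: pd.DataFrame, episodes_path, demographics_path) -> None:
    """Write episode/demographics tables in the canonical CSV dialect.

    UTF-8, comma-separated, header row, ISO-8601 dates; floats via ``repr`` so
    that read → write round-trips are byte-identical.
    """
    ep = episodes.copy()
    ep["date"] = pd.to_datetime(ep["date"]).dt.strftime("%Y-%m-%d")
    ep[EPISODE_COLUMNS].to_csv(episodes_path, index=False, encoding="utf-8")

    dem = demographics.copy()
    for col in ("age_at_first_episode", "duration_years"):
        dem[col] = dem[col].map(_format_float)
    dem["imd_quintile"] = dem["imd_quintile"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    for col in ("sex", "ethnicity", "diabetes_type"):
        dem[col] = dem[col].fillna("")
    cols = list(DEMOGRAPHIC_COLUMNS)
    if "imd_score" in dem.columns:
        dem["imd_score"] = dem["imd_score"].map(_format_float)
        cols.insert(cols.index("imd_quintile"), "imd_score")
    dem[cols].to_csv(demographics_path, index=False, encoding="utf-8")


def _registry_paths(directory) -> tuple[Path, Path]:
    d = Path(directory)
    return d / "episodes.csv", d / "demographics.csv"
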