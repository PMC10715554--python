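"""Synthetic screening-registry generator.

Real diabetic eye screening data are held inside NHS networks and are not
shareable, so every downstream stage of this package is exercised on synthetic
registries that reproduce the statistical structure the analysis assumes:

* a multi-ethnic population of people living with diabetes, with the
  sociodemographic mixture of a large urban English screening programme;
* independent exponential latent clocks for progression to non-referable
  retinopathy (R1M0) and to sight-threatening retinopathy (STDR), the STDR
  hazard following a proportional-hazards structure over age group, sex,
  ethnicity, diabetes type, diabetes duration and deprivation quintile;
* roughly annual attended visits (log-normal gaps, median 1.0 y, IQR 0.2 y),
  staggered entry over a 10-year programme window, a never-attending fraction,
  and a small rate of ungradable episodes.

Disease is *detected* only at attended visits; the latent onset time is not
observable downstream, mirroring real screening.  A person whose STDR becomes
visible at a visit is referred to hospital eye services and drops out of the
screening schedule.  Grade trajectories are monotone (no regression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .registry import DAYS_PER_YEAR, age_band

__all__ = [
    "SimulationConfig",
    "LatentHistory",
    "ConfigError",
    "sample_population",
    "simulate_latent_history",
    "simulate_visit_schedule",
    "generate_registry",
    "mean_relative_risk",
    "calibrate_lambda0",
    "linear_predictor",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# Continuous-age sampling ranges for each analysis age band.
_AGE_RANGES = {"<45": (20.0, 45.0), "45-<55": (45.0, 55.0), "55-<65": (55.0, 65.0), ">=65": (65.0, 90.0)}


def _default_mixtures() -> dict:
    # Baseline sociodemographic mixture of the emulated screening cohort
    # (proportions normalised to sum to one).
    raw = {
        "sex": {"female": 0.48, "male": 0.52},
        "age_group": {"<45": 0.20, "45-<55": 0.24, "55-<65": 0.25, ">=65": 0.31},
        "ethnicity": {
            "white": 0.37,
            "south_asian": 0.36,
            "black": 0.16,
            "any_other_asian": 0.058,
            "other": 0.028,
            "mixed": 0.012,
            "chinese": 0.007,
            "unknown": 0.008,
        },
        "diabetes_type": {"type2": 0.95, "type1": 0.026, "other": 0.002, "unknown": 0.018},
        "imd_quintile": {1: 0.11, 2: 0.32, 3: 0.29, 4: 0.19, 5: 0.099},
    }
    return {
        dim: {k: v / sum(m.values()) for k, v in m.items()} for dim, m in raw.items()
    }


def _default_log_hr() -> dict:
    # Mutually adjusted hazard ratios for STDR used as simulation truth.
    hr = {
        "age_group": {"45-<55": 0.70, "55-<65": 0.54, ">=65": 0.70},
        "sex": {"male": 0.96},
        "ethnicity": {
            "south_asian": 1.54,
            "black": 2.21,
            "any_other_asian": 1.39,
            "other": 1.86,
            "mixed": 2.07,
            "chinese": 0.63,
            "unknown": 1.91,
        },
        "diabetes_type": {"type1": 1.41, "other": 1.83, "unknown": 1.35},
        "imd_quintile": {2: 1.16, 3: 1.06, 4: 1.08, 5: 1.12},
    }
    out = {dim: {k: math.log(v) for k, v in d.items()} for dim, d in hr.items()}
    out["duration_per_5y"] = math.log(1.26)
    return out


@dataclass
class SimulationConfig:
    """All tunable parameters of the synthetic registry.

    ``lambda0_stdr`` is the STDR hazard (per person-year) of the reference
    covariate profile (female, <45, white, type 2, duration 0, IMD 1).  When
    left ``None`` it is calibrated analytically so the *marginal* STDR hazard
    over the demographic mixture equals ``overall_rate_target`` (default
    0.51 events per 100 person-years).
    """

    n_persons: int = 50_000
    seed: int = 0
    demographic_mixture: dict = field(default_factory=_default_mixtures)
    duration_mean: float = 4.0
    duration_sd: float = 5.3
    lambda0_stdr: Optional[float] = None
    overall_rate_target: float = 0.0051
    log_hr: dict = field(default_factory=_default_log_hr)
    lambda_r1: float = 0.05
    p_pdr_given_stdr: float = 103.0 / 1788.0
    visit_gap_median: float = 1.0
    visit_gap_iqr: tuple = (0.9, 1.1)
    max_followup_years: float = 8.0
    never_attend_prob: float = 0.108
    u_grade_prob: float = 0.001
    study_start: date = date(2012, 1, 3)
    study_end: date = date(2021, 12, 31)
    p_missing_demographics: float = 0.005

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ConfigError("n_persons must be >= 0")
        for p_name in ("never_attend_prob", "u_grade_prob", "p_pdr_given_stdr", "p_missing_demographics"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{p_name}={p} outside [0, 1]")
        for dim, mix in self.demographic_mixture.items():
            if any(p < 0 for p in mix.values()):
                raise ConfigError(f"negative probability in mixture {dim!r}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"mixture {dim!r} does not sum to 1")
        if self.lambda0_stdr is not None and self.lambda0_stdr < 0:
            raise ConfigError("lambda0_stdr must be >= 0")
        if self.lambda_r1 < 0:
            raise ConfigError("lambda_r1 must be >= 0")
        if self.overall_rate_target <= 0 and self.lambda0_stdr is None:
            raise ConfigError("overall_rate_target must be positive when calibrating")
        q1, q3 = self.visit_gap_iqr
        if not (0 <= q1 <= self.visit_gap_median <= q3):
            raise ConfigError("visit_gap_iqr must bracket visit_gap_median")
        if self.max_followup_years <= 0:
            raise ConfigError("max_followup_years must be positive")
        if self.study_end <= self.study_start:
            raise ConfigError("study_end must be after study_start")
        if self.duration_sd < 0 or self.duration_mean < 0:
            raise ConfigError("duration parameters must be non-negative")

    def resolved_lambda0(self) -> float:
        """Baseline hazard, calibrating to ``overall_rate_target`` if unset."""
        if self.lambda0_stdr is not None:
            return self.lambda0_stdr
        return calibrate_lambda0(self, self.overall_rate_target)


@dataclass(frozen=True)
class LatentHistory:
    """Latent progression times for one person (years from programme entry)."""

    person_id: str
    t_stdr: float
    t_r1: float
    is_pdr: bool


def _truncnorm_mgf(t: float, mean: float, sd: float) -> float:
    """E[exp(t X)] for X ~ Normal(mean, sd^2) truncated to [0, inf)."""
    if sd == 0:
        return math.exp(t * max(mean, 0.0))
    a = mean / sd
    return math.exp(mean * t + 0.5 * sd * sd * t * t) * stats.norm.cdf(a + sd * t) / stats.norm.cdf(a)


def mean_relative_risk(config: SimulationConfig) -> float:
    """Analytic E[exp(X'beta)] over the configured demographic mixture.

    Covariate dimensions are sampled independently, so the expectation
    factorises into per-dimension means times the moment generating function
    of the truncated-normal diabetes duration evaluated at beta_duration/5.
    """
    out = 1.0
    for dim, mix in config.demographic_mixture.items():
        betas = config.log_hr.get(dim, {})
        out *= sum(p * math.exp(betas.get(level, 0.0)) for level, p in mix.items())
    b_dur = config.log_hr.get("duration_per_5y", 0.0) / 5.0
    out *= _truncnorm_mgf(b_dur, config.duration_mean, config.duration_sd)
    return out


def calibrate_lambda0(config: SimulationConfig, target_rate: Optional[float] = None) -> float:
    """Baseline hazard such that the marginal STDR hazard equals the target."""
    if target_rate is None:
        target_rate = config.overall_rate_target
    return target_rate / mean_relative_risk(config)


def linear_predictor(profiles: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Cox linear predictor X'beta for each profile row (reference = 0)."""
    lp = np.zeros(len(profiles))
    for dim in ("sex", "age_group", "ethnicity", "diabetes_type", "imd_quintile"):
        betas = config.log_hr.get(dim, {})
        if betas:
            lp += profiles[dim].map(lambda v: betas.get(v, 0.0)).to_numpy(dtype=float)
    b_dur = config.log_hr.get("duration_per_5y", 0.0)
    lp += (profiles["duration_years"].to_numpy(dtype=float) / 5.0) * b_dur
    return lp


def _sample_categorical(mix: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    levels = list(mix.keys())
    probs = np.array([mix[k] for k in levels], dtype=float)
    idx = rng.choice(len(levels), size=n, p=probs / probs.sum())
    return np.array(levels, dtype=object)[idx]


def sample_population(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n_persons`` covariate profiles from the configured mixtures.

    Continuous age is drawn uniformly within the sampled age band (the band is
    the analysis unit); diabetes duration is normal truncated at zero.  A small
    configurable fraction has ethnicity unrecorded (missing, distinct from the
    self-reported 'unknown' category).
    """
    config.validate()
    n = config.n_persons
    mix = config.demographic_mixture
    profiles = pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n)],
            "sex": _sample_categorical(mix["sex"], n, rng),
            "age_group": _sample_categorical(mix["age_group"], n, rng),
            "ethnicity": _sample_categorical(mix["ethnicity"], n, rng),
            "diabetes_type": _sample_categorical(mix["diabetes_type"], n, rng),
            "imd_quintile": pd.array(
                _sample_categorical(mix["imd_quintile"], n, rng).astype(int), dtype="Int64"
            ),
        }
    )
    lo = np.array([_AGE_RANGES[g][0] for g in profiles["age_group"]]) if n else np.empty(0)
    hi = np.array([_AGE_RANGES[g][1] for g in profiles["age_group"]]) if n else np.empty(0)
    age = np.round(lo + rng.random(n) * (hi - lo), 1)
    # rounding must not push an age across its band boundary
    profiles["age_at_first_episode"] = np.clip(age, lo, hi - 0.1) if n else age
    # truncated-normal duration via inverse CDF on a uniform restricted to the
    # admissible quantile range (exact, no rejection loop)
    if config.duration_sd > 0:
        p0 = stats.norm.cdf(-config.duration_mean / config.duration_sd)
        u = p0 + rng.random(n) * (1 - p0)
        dur = config.duration_mean + config.duration_sd * stats.norm.ppf(u)
        dur = np.maximum(dur, 0.0)
    else:
        dur = np.full(n, config.duration_mean)
    profiles["duration_years"] = np.round(dur, 1)
    if config.p_missing_demographics > 0 and n:
        miss = rng.random(n) < config.p_missing_demographics
        profiles.loc[miss, "ethnicity"] = np.nan
    return profiles


def _latent_times(profiles: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator):
    """Vectorised latent clocks (years from entry) for every profile."""
    n = len(profiles)
    lam0 = config.resolved_lambda0()
    filled = profiles.copy()
    # unrecorded ethnicity still progresses like the population reference mix;
    # use the 'unknown' category's hazard for simplicity
    filled["ethnicity"] = filled["ethnicity"].fillna("unknown")
    rates = lam0 * np.exp(linear_predictor(filled, config))
    u = rng.random(n)
    with np.errstate(divide="ignore"):
        t_stdr = np.where(rates > 0, -np.log1p(-u) / np.where(rates > 0, rates, 1.0), np.inf)
    u2 = rng.random(n)
    if config.lambda_r1 > 0:
        t_r1 = -np.log1p(-u2) / config.lambda_r1
    else:
        t_r1 = np.full(n, np.inf)
    is_pdr = rng.random(n) < config.p_pdr_given_stdr
    return t_stdr, t_r1, is_pdr


def simulate_latent_history(profile, config: SimulationConfig, rng: np.random.Generator) -> LatentHistory:
    """Latent progression history for a single person profile.

    ``profile`` is a mapping (or Series) with the PersonProfile covariates.
    """
    row = pd.DataFrame([dict(profile)])
    t_stdr, t_r1, is_pdr = _latent_times(row, config, rng)
    return LatentHistory(
        person_id=str(row["person_id"].iloc[0]) if "person_id" in row else "",
        t_stdr=float(t_stdr[0]),
        t_r1=float(t_r1[0]),
        is_pdr=bool(is_pdr[0]) if np.isfinite(t_stdr[0]) else False,
    )


def _lognormal_params(median: float, iqr: tuple) -> tuple[float, float]:
    """(mu, sigma) with exact median and exact interquartile *width*.

    Three constraints (median and both quartiles) cannot all be met by a
    two-parameter log-normal; the median and the IQR width q3-q1 are matched
    exactly, placing the quartiles symmetrically around the median on the log
    scale.
    """
    q1, q3 = iqr
    mu = math.log(median)
    width = q3 - q1
    if width <= 0:
        return mu, 0.0
    z75 = stats.norm.ppf(0.75)
    sigma = math.asinh(width / (2.0 * median)) / z75
    return mu, sigma


def simulate_visit_schedule(
    config: SimulationConfig, rng: np.random.Generator, horizon: Optional[float] = None
) -> np.ndarray:
    """Visit times (years from entry) for one person.

    The first visit is at entry (t=0); successive gaps are i.i.d. log-normal.
    With probability ``never_attend_prob`` the schedule is empty.  Truncated at
    ``horizon`` (default ``max_followup_years``).
    """
    if horizon is None:
        horizon = config.max_followup_years
    if rng.random() < config.never_attend_prob:
        return np.empty(0)
    mu, sigma = _lognormal_params(config.visit_gap_median, config.visit_gap_iqr)
    times = [0.0]
    while True:
        gap = float(np.exp(mu + sigma * rng.standard_normal()))
        t = times[-1] + gap
        if t > horizon:
            break
        times.append(t)
    return np.asarray(times)


def _visit_matrix(n: int, horizons: np.ndarray, config: SimulationConfig, rng: np.random.Generator):
    """Visit times (n x K matrix, NaN-padded) for all persons at once."""
    mu, sigma = _lognormal_params(config.visit_gap_median, config.visit_gap_iqr)
    max_h = float(horizons.max(initial=0.0))
    cols = [np.zeros(n)]  # visit at entry
    total = np.zeros(n)
    while True:
        alive = total <= max_h
        if not alive.any():
            break
        gaps = np.exp(mu + sigma * rng.standard_normal(n))
        total = total + gaps
        if (total > horizons).all():
            break
        cols.append(total.copy())
        if len(cols) > 200:  # safety: horizons are <= ~10 years, gaps ~1 year
            break
    times = np.column_stack(cols)
    times[times > horizons[:, None]] = np.nan
    return times


def generate_registry(config: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Generate a complete synthetic registry (episodes, profiles).

    Deterministic given ``config.seed`` (when ``rng`` is not supplied).  Grade
    at a visit is decided by the latent state at the visit time: R0M0 before
    any onset, R1M0 after the R1 clock, an STDR presentation (R3 if the PDR
    flag is set, else R2 or M1 with equal probability) after the STDR clock.
    Each episode is independently ungradable (all components U) with
    ``u_grade_prob``; a person is referred out — no further visits — after the
    first *gradable* STDR presentation.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    profiles = sample_population(config, rng)
    n = len(profiles)
    t_stdr, t_r1, is_pdr = _latent_times(profiles, config, rng)

    window_days = (config.study_end - config.study_start).days
    entry_days = rng.integers(0, window_days + 1, size=n)
    attend = rng.random(n) >= config.never_attend_prob
    horizons = np.minimum(config.max_followup_years, (window_days - entry_days) / DAYS_PER_YEAR)
    horizons = np.where(attend, horizons, -1.0)

    times = _visit_matrix(n, horizons, config, rng)  # years from entry
    valid = ~np.isnan(times)

    # latent grade state per visit: 0=R0M0, 1=R1M0, 2=STDR presentation
    state = np.zeros_like(times, dtype=np.int8)
    state[(times >= t_r1[:, None])] = 1
    state[(times >= t_stdr[:, None])] = 2
    u_mask = (rng.random(times.shape) < config.u_grade_prob) & valid

    # referral: drop visits after the first gradable STDR presentation
    presented = (state == 2) & ~u_mask & valid
    any_presented = presented.any(axis=1)
    first_idx = np.where(any_presented, presented.argmax(axis=1), times.shape[1])
    keep = valid & (np.arange(times.shape[1])[None, :] <= first_idx[:, None])

    rows_person, rows_visit = np.nonzero(keep)
    t_flat = times[rows_person, rows_visit]
    state_flat = state[rows_person, rows_visit]
    u_flat = u_mask[rows_person, rows_visit]

    n_ep = len(rows_person)
    r_left = np.full(n_ep, "R0", dtype=object)
    r_right = np.full(n_ep, "R0", dtype=object)
    m_left = np.full(n_ep, "M0", dtype=object)
    m_right = np.full(n_ep, "M0", dtype=object)

    eye_is_left = rng.random(n_ep) < 0.5  # which eye carries the worst grade
    r2_not_m1 = rng.random(n_ep) < 0.5

    r1_rows = (state_flat == 1) & ~u_flat
    r_left[r1_rows & eye_is_left] = "R1"
    r_right[r1_rows & ~eye_is_left] = "R1"

    stdr_rows = (state_flat == 2) & ~u_flat
    pdr_flat = is_pdr[rows_person]
    pdr_rows = stdr_rows & pdr_flat
    r2_rows = stdr_rows & ~pdr_flat & r2_not_m1
    m1_rows = stdr_rows & ~pdr_flat & ~r2_not_m1
    r_left[pdr_rows & eye_is_left] = "R3"
    r_right[pdr_rows & ~eye_is_left] = "R3"
    r_left[r2_rows & eye_is_left] = "R2"
    r_right[r2_rows & ~eye_is_left] = "R2"
    m_left[m1_rows & eye_is_left] = "M1"
    m_right[m1_rows & ~eye_is_left] = "M1"

    for arr in (r_left, r_right, m_left, m_right):
        arr[u_flat] = "U"

    day_offsets = entry_days[rows_person] + np.round(t_flat * DAYS_PER_YEAR).astype(np.int64)
    dates = pd.Timestamp(config.study_start) + pd.to_timedelta(day_offsets, unit="D")

    episodes = pd.DataFrame(
        {
            "person_id": profiles["person_id"].to_numpy()[rows_person],
            "date": dates,
            "r_left": r_left,
            "m_left": m_left,
            "r_right": r_right,
            "m_right": m_right,
        }
    )
    episodes = episodes.sort_values(["person_id", "date"], kind="mergesort").reset_index(drop=True)

    out_profiles = profiles.copy()
    out_profiles["age_group"] = out_profiles["age_at_first_episode"].map(age_band)
    return episodes, out_profiles
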