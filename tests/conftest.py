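import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_episodes(rows):
    """Episode table from (person_id, date, grades) rows.

    ``grades`` is either a person-level shorthand like ``"R0M0"`` (both eyes
    identical) or a 4-tuple (r_left, m_left, r_right, m_right).
    """
    recs = []
    for pid, d, g in rows:
        if isinstance(g, str):
            r, m = g[: len(g) - 2], g[-2:]
            g = (r, m, r, m)
        recs.append(
            {
                "person_id": pid,
                "date": pd.Timestamp(d),
                "r_left": g[0],
                "m_left": g[1],
                "r_right": g[2],
                "m_right": g[3],
            }
        )
    cols = ["person_id", "date", "r_left", "m_left", "r_right", "m_right"]
    if not recs:
        return pd.DataFrame({c: pd.Series(dtype="datetime64[ns]" if c == "date" else object) for c in cols})
    return pd.DataFrame(recs)[cols]


def make_profiles(pids, **overrides):
    """Demographics table with reference-profile defaults."""
    n = len(pids)
    base = {
        "person_id": pd.Series(list(pids), dtype=object),
        "sex": ["female"] * n,
        "age_at_first_episode": [40.0] * n,
        "age_group": ["<45"] * n,
        "ethnicity": ["white"] * n,
        "diabetes_type": ["type2"] * n,
        "duration_years": [4.0] * n,
        "imd_quintile": pd.array([1] * n, dtype="Int64"),
    }
    for k, v in overrides.items():
        seq = isinstance(v, (list, pd.Series, np.ndarray, pd.api.extensions.ExtensionArray))
        base[k] = v if seq else [v] * n
    return pd.DataFrame(base)


def make_cohort(rows, **profile_overrides):
    """Cohort table from (person_id, followup_years, exit_reason[, is_pdr]) rows."""
    pids = [r[0] for r in rows]
    prof = make_profiles(pids, **profile_overrides)
    base = pd.Timestamp("2015-01-01")
    cohort = prof.copy()
    cohort["baseline_date"] = base
    cohort["followup_years"] = [float(r[1]) for r in rows]
    cohort["exit_reason"] = [r[2] for r in rows]
    cohort["is_pdr"] = [bool(r[3]) if len(r) > 3 else False for r in rows]
    cohort["exit_date"] = [
        base + pd.Timedelta(days=round(float(r[1]) * 365.25)) for r in rows
    ]
    return cohort


@pytest.fixture(scope="session")
def recovery_runs():
    """Twenty replicate pipelines at n=50,000 under the default conditions.

    Each replicate: simulate registry → eligibility cascade → person-time and
    ethnicity-stratified rates → mutually adjusted Cox fit.  Shared across the
    parameter-recovery assertions because the simulation is by far the most
    expensive step.
    """
    import screenlag as sl

    runs = []
    for seed in range(1, 21):
        cfg = sl.SimulationConfig(n_persons=50_000, seed=seed)
        episodes, profiles = sl.generate_registry(cfg)
        cohort, cascade = sl.build_cohort(episodes, profiles)
        total = sl.person_years(cohort)
        overall = sl.incidence_rate(
            int(total["events"][0]), float(total["person_years"][0])
        ).point
        eth = sl.person_years(cohort, by="ethnicity").set_index("ethnicity")
        black_rate = 100.0 * eth.loc["black", "events"] / eth.loc["black", "person_years"]
        table = sl.cox_fit(cohort).table
        row = table[(table["term"] == "ethnicity") & (table["level"] == "black")].iloc[0]
        runs.append(
            {
                "seed": seed,
                "overall_rate": overall,
                "black_rate": float(black_rate),
                "black_hr": float(row["hr"]),
                "black_hr_ci": (float(row["ci_low"]), float(row["ci_high"])),
                "cascade": cascade.steps,
                "cohort_size": len(cohort),
            }
        )
    return runs
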