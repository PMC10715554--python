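"""Person-time, incidence CIs, Kaplan-Meier and Cox against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import brentq

from screenlag import (
    cox_fit,
    cumulative_incidence_by_year,
    incidence_rate,
    km_curve,
    person_years,
    proportionality_check,
    rates_by,
)

from conftest import make_cohort


# ---------------------------------------------------------------- person-time
class TestPersonYears:
    def test_arithmetic(self):
        cohort = make_cohort([("A", 3.0, "stdr_event"), ("B", 1.5, "admin_censor")])
        tab = person_years(cohort)
        assert tab["events"][0] == 1 and tab["person_years"][0] == pytest.approx(4.5)

    def test_partition_conservation(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"P{i}", float(rng.uniform(0, 8)), "stdr_event" if rng.random() < 0.3 else "admin_censor")
            for i in range(200)
        ]
        sexes = list(rng.choice(["female", "male"], size=200))
        cohort = make_cohort(rows, sex=sexes)
        total = person_years(cohort)
        by_sex = person_years(cohort, by="sex")
        assert by_sex["events"].sum() == total["events"][0]
        assert by_sex["person_years"].sum() == pytest.approx(total["person_years"][0])

    def test_pdr_subset(self):
        cohort = make_cohort(
            [("A", 2.0, "stdr_event", True), ("B", 2.0, "stdr_event", False)]
        )
        assert person_years(cohort, outcome="pdr")["events"][0] == 1


# ------------------------------------------------------------ incidence rates
def poisson_ci_by_cdf_inversion(k, alpha=0.05):
    """Independent oracle: invert the Poisson CDF numerically."""
    lo = 0.0 if k == 0 else brentq(lambda lam: stats.poisson.sf(k - 1, lam) - alpha / 2, 1e-9, 10 * k + 50)
    hi = brentq(lambda lam: stats.poisson.cdf(k, lam) - alpha / 2, 1e-9, 10 * k + 100)
    return lo, hi


class TestIncidenceRate:
    def test_zero_events_closed_form(self):
        r = incidence_rate(0, 100.0, scale=100.0)
        assert r.point == 0 and r.ci_low == 0
        assert r.ci_high == pytest.approx(-np.log(0.025), abs=1e-4)  # 3.6889 per 100 py

    def test_published_scale_arithmetic(self):
        r = incidence_rate(1788, 350_588.0, scale=100.0)
        assert r.point == pytest.approx(0.510, abs=0.0005)

    @pytest.mark.parametrize("k", [1, 5, 10, 100])
    def test_exact_ci_matches_cdf_inversion(self, k):
        r = incidence_rate(k, 1000.0, scale=1.0)
        lo, hi = poisson_ci_by_cdf_inversion(k)
        assert r.ci_low * 1000 == pytest.approx(lo, abs=1e-4)
        assert r.ci_high * 1000 == pytest.approx(hi, abs=1e-4)

    def test_coverage_simulation(self):
        # exact Poisson CIs are conservative: empirical coverage >= 95%
        rng = np.random.default_rng(2)
        lam = 5.0
        ks = rng.poisson(lam, size=2000)
        covered = 0
        for k in ks:
            r = incidence_rate(int(k), 1.0, scale=1.0)
            covered += r.ci_low <= lam <= r.ci_high
        assert covered / 2000 >= 0.95

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            incidence_rate(-1, 10.0)
        with pytest.raises(ValueError):
            incidence_rate(1, 0.0)

    def test_alternative_ci_methods_bracket_point(self):
        for method in ("normal", "lognormal"):
            r = incidence_rate(20, 400.0, ci_method=method)
            assert r.ci_low <= r.point <= r.ci_high
            assert r.method == method


# ------------------------------------------------------------- Kaplan--Meier
def km_brute_force(times, events, t):
    """Product over risk sets: S(t) = prod_{t_i <= t, event} (1 - d_i/n_i)."""
    s = 1.0
    for ti in sorted(set(times[events])):
        if ti > t:
            break
        n_at_risk = sum(x >= ti for x in times)
        d = sum((x == ti) and e for x, e in zip(times, events))
        s *= 1 - d / n_at_risk
    return s


def _km_eval(curve, t):
    tt = curve["time"].to_numpy()
    ss = curve["survival"].to_numpy()
    idx = np.searchsorted(tt, t, side="right") - 1
    return ss[idx] if idx >= 0 else 1.0


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        cohort = make_cohort([(f"P{i}", t, "stdr_event") for i, t in enumerate(times)])
        curve = km_curve(cohort)["overall"]
        for t in times:
            assert _km_eval(curve, t) == pytest.approx(np.mean([x > t for x in times]))

    def test_all_censored_is_one(self):
        cohort = make_cohort([(f"P{i}", t, "admin_censor") for i, t in enumerate([1, 2, 3])])
        curve = km_curve(cohort)["overall"]
        assert (curve["survival"] == 1.0).all()

    def test_interleaved_censoring_against_oracle(self):
        fixture = [(1.0, 1), (1.5, 0), (2.0, 1), (2.0, 1), (2.5, 0), (3.0, 1), (3.5, 0), (4.0, 1)]
        cohort = make_cohort(
            [(f"P{i}", t, "stdr_event" if e else "admin_censor") for i, (t, e) in enumerate(fixture)]
        )
        curve = km_curve(cohort)["overall"]
        times = np.array([t for t, _ in fixture])
        events = np.array([bool(e) for _, e in fixture])
        for t in [0.5, 1.0, 2.0, 2.9, 3.0, 4.0]:
            assert _km_eval(curve, t) == pytest.approx(km_brute_force(times, events, t))

    @given(
        st.lists(
            st.tuples(st.floats(0.1, 8.0), st.booleans()),
            min_size=1,
            max_size=20,
        )
    )
    def test_random_fixtures_against_oracle(self, fixture):
        cohort = make_cohort(
            [(f"P{i}", round(t, 2), "stdr_event" if e else "admin_censor")
             for i, (t, e) in enumerate(fixture)]
        )
        curve = km_curve(cohort)["overall"]
        times = cohort["followup_years"].to_numpy()
        events = (cohort["exit_reason"] == "stdr_event").to_numpy()
        for t in [0.5, 1.0, 2.5, 4.0, 8.0]:
            assert _km_eval(curve, t) == pytest.approx(km_brute_force(times, events, t))


class TestCumulativeIncidence:
    def test_no_events_all_zero(self):
        cohort = make_cohort([("A", 5.0, "admin_censor"), ("B", 3.0, "r1_censor")])
        tab = cumulative_incidence_by_year(cohort)
        assert (tab["cumulative_incidence"] == 0).all()

    def test_single_person_step(self):
        cohort = make_cohort([("A", 2.3, "stdr_event")])
        tab = cumulative_incidence_by_year(cohort).set_index("year")
        assert tab.loc[2, "cumulative_incidence"] == 0.0
        assert tab.loc[3, "cumulative_incidence"] == 1.0

    def test_six_person_fixture_hand_computed(self):
        fixture = [(1.5, 1), (2.5, 0), (3.5, 1), (4.0, 1), (5.0, 0), (6.0, 0)]
        cohort = make_cohort(
            [(f"P{i}", t, "stdr_event" if e else "admin_censor") for i, (t, e) in enumerate(fixture)]
        )
        tab = cumulative_incidence_by_year(cohort).set_index("year")["cumulative_incidence"]
        # hand product-limit (right-continuous: the t=4.0 event is in S(4)):
        # S(2)=S(3)=5/6; S(4)=5/6 * 3/4 * 2/3 = 5/12
        assert tab.loc[1] == pytest.approx(0.0)
        assert tab.loc[2] == pytest.approx(1 - 5 / 6)
        assert tab.loc[3] == pytest.approx(1 - 5 / 6)
        for y in (4, 5, 6, 7, 8):
            assert tab.loc[y] == pytest.approx(1 - 5 / 6 * 3 / 4 * 2 / 3)
        assert (tab.diff().dropna() >= -1e-12).all()


# ---------------------------------------------------------------------- Cox
def _binary_ethnicity_cohort(rows):
    eth = [r[3] for r in rows]
    return make_cohort([r[:3] for r in rows], ethnicity=eth)


class TestCoxFit:
    def test_tied_pair_closed_form_unit_hr(self):
        # two tied events with opposite covariates: Efron (and Breslow) score
        # is zero exactly at beta = 0
        cohort = _binary_ethnicity_cohort(
            [("A", 1.0, "stdr_event", "black"), ("B", 1.0, "stdr_event", "white")]
        )
        row = _black_row(cox_fit(cohort).table)
        assert row["hr"] == pytest.approx(1.0, abs=1e-6)

    def test_four_person_closed_form(self):
        # score equation solves to exp(beta) = sqrt(2)
        cohort = _binary_ethnicity_cohort(
            [
                ("A", 1.0, "stdr_event", "black"),
                ("B", 2.0, "stdr_event", "white"),
                ("C", 3.0, "admin_censor", "white"),
                ("D", 3.0, "admin_censor", "black"),
            ]
        )
        row = _black_row(cox_fit(cohort).table)
        # rel tolerance reflects the fitter's Newton convergence threshold
        assert row["hr"] == pytest.approx(np.sqrt(2), rel=2e-3)

    def test_null_binary_covariate_recovery(self):
        rng = np.random.default_rng(3)
        n = 400
        t = rng.exponential(2.0, n)
        cens = rng.uniform(0, 4, n)
        obs = np.minimum(t, cens)
        rows = [
            (f"P{i}", float(obs[i]), "stdr_event" if t[i] <= cens[i] else "admin_censor",
             "black" if i % 2 else "white")
            for i in range(n)
        ]
        table = cox_fit(_binary_ethnicity_cohort(rows)).table
        row = _black_row(table)
        assert row["ci_low"] <= 1.0 <= row["ci_high"]
        se = (np.log(row["ci_high"]) - np.log(row["ci_low"])) / (2 * 1.96)
        assert abs(np.log(row["hr"])) < 3 * se

    def test_absent_level_reported_not_silently_dropped(self):
        rows = [
            ("A", 1.0, "stdr_event", "black"),
            ("B", 2.0, "stdr_event", "white"),
            ("C", 3.0, "admin_censor", "white"),
            ("D", 3.0, "admin_censor", "black"),
        ]
        table = cox_fit(_binary_ethnicity_cohort(rows)).table
        chinese = table[(table["term"] == "ethnicity") & (table["level"] == "chinese")]
        assert len(chinese) == 1 and np.isnan(chinese["hr"].iloc[0])

    def test_requires_events(self):
        cohort = make_cohort([("A", 1.0, "admin_censor")])
        with pytest.raises(ValueError, match="event"):
            cox_fit(cohort)

    def test_continuous_age_variant(self):
        rng = np.random.default_rng(4)
        n = 300
        rows = [
            (f"P{i}", float(rng.uniform(0.5, 5)), "stdr_event" if rng.random() < 0.4 else "admin_censor")
            for i in range(n)
        ]
        ages = list(rng.uniform(20, 90, n))
        cohort = make_cohort(rows, age_at_first_episode=ages)
        from screenlag import age_band

        cohort["age_group"] = cohort["age_at_first_episode"].map(age_band)
        table = cox_fit(cohort, age="continuous").table
        assert "age" in set(table["term"])
        assert "age_group" not in set(table["term"])


def _black_row(table):
    return table[(table["term"] == "ethnicity") & (table["level"] == "black")].iloc[0]


class TestProportionality:
    def test_null_data_not_systematically_rejected(self):
        rng = np.random.default_rng(5)
        n = 2000
        eth = rng.choice(["white", "black"], n)
        lam = np.where(eth == "black", 0.4, 0.2)
        t = rng.exponential(1 / lam)
        cens = rng.uniform(0, 6, n)
        obs = np.minimum(t, cens)
        rows = [
            (f"P{i}", float(obs[i]), "stdr_event" if t[i] <= cens[i] else "admin_censor")
            for i in range(n)
        ]
        cohort = make_cohort(rows, ethnicity=list(eth))
        check = proportionality_check(cox_fit(cohort))
        row = check[check["term"] == "ethnicity[black]"].iloc[0]
        assert row["note"] == "" and row["p"] > 0.001

    def test_constructed_violation_detected(self):
        # hazard effect reverses at t=2: scaled Schoenfeld residuals trend
        rng = np.random.default_rng(6)
        n = 3000
        eth = np.array(["black", "white"])[rng.integers(0, 2, n)]
        t = np.empty(n)
        for i in range(n):
            lam1, lam2 = (1.0, 0.05) if eth[i] == "black" else (0.25, 0.25)
            draw = rng.exponential(1 / lam1)
            t[i] = draw if draw < 2 else 2 + rng.exponential(1 / lam2)
        cens = np.full(n, 6.0)
        obs = np.minimum(t, cens)
        rows = [
            (f"P{i}", float(obs[i]), "stdr_event" if t[i] <= cens[i] else "admin_censor")
            for i in range(n)
        ]
        cohort = make_cohort(rows, ethnicity=list(eth))
        check = proportionality_check(cox_fit(cohort))
        row = check[check["term"] == "ethnicity[black]"].iloc[0]
        assert row["p"] < 0.01

    def test_degenerate_residuals_reported_undefined(self):
        cohort = _binary_ethnicity_cohort(
            [
                ("A", 1.0, "stdr_event", "black"),
                ("B", 2.0, "stdr_event", "white"),
                ("C", 3.0, "admin_censor", "white"),
                ("D", 3.0, "admin_censor", "black"),
            ]
        )
        check = proportionality_check(cox_fit(cohort))
        assert (check["note"] == "undefined").all()  # only two events


def test_rates_by_strata_table():
    rng = np.random.default_rng(7)
    rows = [
        (f"P{i}", float(rng.uniform(0.5, 6)), "stdr_event" if rng.random() < 0.2 else "admin_censor")
        for i in range(300)
    ]
    eth = list(rng.choice(["white", "black", "south_asian"], 300))
    cohort = make_cohort(rows, ethnicity=eth)
    tab = rates_by(cohort, by="ethnicity")
    assert set(tab["ethnicity"]) == set(eth)
    assert (tab["ci_low"] <= tab["rate"]).all() and (tab["rate"] <= tab["ci_high"]).all()
    overall = person_years(cohort)
    assert tab["events"].sum() == overall["events"][0]
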