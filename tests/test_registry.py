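"""Registry primitives: eligibility, predictor extraction, 3mCDP derivation,
switch-table construction and CSV round-trips, checked on hand-built records."""

from __future__ import annotations

import datetime as dt

import pytest

from dmtrank import (
    BuildConfig,
    EDSSAssessment,
    PatientRecord,
    RegistryError,
    TherapyEpisode,
    build_switch_table,
    check_eligibility,
    derive_3mcdp,
    extract_predictors,
    read_registry_csv,
    write_registry_csv,
)
from dmtrank.util import DAYS_PER_MONTH

D = dt.date


def _patient(
    episodes=None,
    relapses=None,
    edss=None,
    diagnosis=D(2010, 1, 1),
    sex="female",
    birth_year=1980,
):
    return PatientRecord(
        patient_id="T001",
        sex=sex,
        birth_year=birth_year,
        diagnosis_date=diagnosis,
        episodes=episodes or [TherapyEpisode("interferon_beta", D(2011, 1, 1), None)],
        relapses=relapses or [],
        edss=edss or [EDSSAssessment(D(2011, 6, 1), 2.0)],
    )


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

class TestEligibility:
    def test_accepts_standard_patient(self):
        el = check_eligibility(_patient(), D(2012, 1, 1))
        assert el.accepted and el.reason is None

    def test_rejects_recent_diagnosis(self):
        el = check_eligibility(_patient(diagnosis=D(2011, 10, 1)), D(2012, 1, 1))
        assert not el.accepted
        assert "6 months" in el.reason

    def test_boundary_exactly_6_months_accepted(self):
        diagnosis = D(2011, 7, 1)
        index = diagnosis + dt.timedelta(days=round(6 * DAYS_PER_MONTH))
        assert check_eligibility(_patient(diagnosis=diagnosis), index).accepted

    def test_rejects_edss_above_6(self):
        p = _patient(edss=[EDSSAssessment(D(2011, 6, 1), 6.5)])
        el = check_eligibility(p, D(2012, 1, 1))
        assert not el.accepted and "EDSS" in el.reason

    def test_edss_exactly_6_accepted(self):
        p = _patient(edss=[EDSSAssessment(D(2011, 6, 1), 6.0)])
        assert check_eligibility(p, D(2012, 1, 1)).accepted

    def test_rejects_without_edss_history(self):
        p = _patient(edss=[EDSSAssessment(D(2013, 1, 1), 2.0)])
        el = check_eligibility(p, D(2012, 1, 1))
        assert not el.accepted and "EDSS" in el.reason


# ---------------------------------------------------------------------------
# predictor extraction
# ---------------------------------------------------------------------------

class TestExtractPredictors:
    def test_twelve_month_window_is_half_open(self):
        index = D(2012, 1, 1)
        window = dt.timedelta(days=round(12 * DAYS_PER_MONTH))
        inside = index - window + dt.timedelta(days=1)
        boundary = index - window  # exactly 12 months ago: excluded
        p = _patient(relapses=[boundary, inside, index])
        pv = extract_predictors(p, index)
        assert pv.relapses_last_12m == 2

    def test_time_since_last_relapse_capped(self):
        p = _patient(relapses=[D(2011, 2, 1)])
        pv = extract_predictors(p, D(2030, 1, 1), tslr_cap_months=120.0)
        assert pv.time_since_last_relapse == 120.0
        # no relapse on record -> cap as well
        pv2 = extract_predictors(_patient(), D(2012, 1, 1))
        assert pv2.time_since_last_relapse == 120.0

    def test_previous_dmts_count_distinct_substances(self):
        eps = [
            TherapyEpisode("interferon_beta", D(2011, 1, 1), D(2012, 1, 1)),
            TherapyEpisode("glatiramer_acetate", D(2012, 1, 1), D(2013, 1, 1)),
            TherapyEpisode("interferon_beta", D(2013, 1, 1), D(2014, 1, 1)),
            TherapyEpisode("fingolimod", D(2014, 1, 1), None, is_second_line=True),
        ]
        p = _patient(episodes=eps, edss=[EDSSAssessment(D(2011, 2, 1), 2.0)])
        pv = extract_predictors(p, D(2015, 1, 1))
        assert pv.current_dmt == "fingolimod"
        # interferon twice + glatiramer = 2 distinct previous substances
        assert pv.n_previous_dmts == 2
        assert pv.any_previous_second_line is False

    def test_age_and_edss_reference(self):
        p = _patient(
            birth_year=1975,
            edss=[EDSSAssessment(D(2011, 6, 1), 2.0), EDSSAssessment(D(2012, 6, 1), 3.5)],
        )
        pv = extract_predictors(p, D(2012, 7, 1))
        assert pv.age == 2012 - 1975
        assert pv.edss == 3.5  # latest at or before index

    def test_requires_current_episode(self):
        p = _patient(episodes=[TherapyEpisode("interferon_beta", D(2013, 1, 1), None)])
        with pytest.raises(RegistryError):
            extract_predictors(p, D(2012, 1, 1))


# ---------------------------------------------------------------------------
# 3-month confirmed disability progression
# ---------------------------------------------------------------------------

class TestDerive3mCDP:
    def _edss(self, scores):
        return [EDSSAssessment(d, s) for d, s in scores]

    def test_confirmed_step_is_event(self):
        p = _patient(edss=self._edss([
            (D(2011, 6, 1), 2.0),
            (D(2012, 6, 1), 3.0),   # provoking +1.0
            (D(2012, 9, 15), 3.0),  # first assessment >= 90 d later confirms
        ]))
        res = derive_3mcdp(p, D(2012, 1, 1), horizon_months=24.0)
        assert res.event and res.event_date == D(2012, 6, 1) and not res.censored

    def test_unconfirmed_blip_is_no_event(self):
        p = _patient(edss=self._edss([
            (D(2011, 6, 1), 2.0),
            (D(2012, 6, 1), 3.0),
            (D(2012, 9, 15), 2.0),  # back to baseline at confirmation
            (D(2013, 6, 1), 3.0),   # later high score without confirmation visit
        ]))
        res = derive_3mcdp(p, D(2012, 1, 1), horizon_months=24.0)
        assert not res.event and not res.censored

    def test_first_assessment_after_90_days_decides(self):
        # an 80-day visit still at threshold does NOT confirm; the first
        # visit >= 90 days later is below threshold -> no event
        p = _patient(edss=self._edss([
            (D(2011, 6, 1), 2.0),
            (D(2012, 6, 1), 3.0),
            (D(2012, 8, 20), 3.0),   # 80 days: not a confirmation visit
            (D(2012, 9, 1), 3.5),    # 92 days after provoking: confirms
        ]))
        res = derive_3mcdp(p, D(2012, 1, 1), horizon_months=24.0)
        assert res.event

    def test_step_is_half_point_above_55(self):
        p = _patient(edss=self._edss([
            (D(2011, 6, 1), 6.0),
            (D(2012, 6, 1), 6.5),
            (D(2012, 9, 15), 6.5),
        ]))
        res = derive_3mcdp(p, D(2012, 1, 1), horizon_months=24.0)
        assert res.event

    def test_provoking_outside_horizon_ignored(self):
        p = _patient(edss=self._edss([
            (D(2011, 6, 1), 2.0),
            (D(2014, 6, 1), 3.0),
            (D(2014, 9, 15), 3.0),
        ]))
        assert not derive_3mcdp(p, D(2012, 1, 1), horizon_months=24.0).event
        assert derive_3mcdp(p, D(2012, 1, 1), horizon_months=36.0).event

    def test_no_follow_up_is_censored(self):
        p = _patient(edss=self._edss([(D(2011, 6, 1), 2.0)]))
        res = derive_3mcdp(p, D(2012, 1, 1), horizon_months=24.0)
        assert res.censored and not res.event

    def test_monotone_in_horizon(self):
        p = _patient(edss=self._edss([
            (D(2011, 6, 1), 2.0),
            (D(2013, 6, 1), 3.0),
            (D(2013, 9, 15), 3.0),
        ]))
        horizons = [12.0, 18.0, 24.0, 36.0, 48.0]
        events = [derive_3mcdp(p, D(2012, 1, 1), h).event for h in horizons]
        assert events == sorted(events)  # False..False,True..True


# ---------------------------------------------------------------------------
# switch table and record validation
# ---------------------------------------------------------------------------

class TestSwitchTable:
    def test_second_episode_is_a_switch_row(self, catalogue):
        eps = [
            TherapyEpisode("interferon_beta", D(2011, 1, 1), D(2013, 1, 1)),
            TherapyEpisode("fingolimod", D(2013, 1, 1), D(2015, 1, 1), is_second_line=True),
        ]
        p = _patient(episodes=eps, edss=[EDSSAssessment(D(2011, 2, 1), 2.0)])
        rows = build_switch_table([p], BuildConfig(catalogue=catalogue))
        assert len(rows) == 1
        row = rows[0]
        assert row.assigned_dmt == "fingolimod"
        assert row.predictors.current_dmt == "interferon_beta"
        assert row.index_date == D(2013, 1, 1)
        assert row.exposure_months == pytest.approx(
            (D(2015, 1, 1) - D(2013, 1, 1)).days / DAYS_PER_MONTH
        )

    def test_first_episode_is_not_a_switch(self, catalogue):
        p = _patient()
        assert build_switch_table([p], BuildConfig(catalogue=catalogue)) == []

    def test_ineligible_switch_skipped(self, catalogue):
        eps = [
            TherapyEpisode("interferon_beta", D(2011, 1, 1), D(2013, 1, 1)),
            TherapyEpisode("fingolimod", D(2013, 1, 1), None),
        ]
        p = _patient(episodes=eps, edss=[EDSSAssessment(D(2011, 2, 1), 6.5)])
        assert build_switch_table([p], BuildConfig(catalogue=catalogue)) == []

    def test_overlapping_episodes_rejected(self):
        with pytest.raises(RegistryError):
            _patient(episodes=[
                TherapyEpisode("interferon_beta", D(2011, 1, 1), D(2013, 1, 1)),
                TherapyEpisode("fingolimod", D(2012, 6, 1), None),
            ])

    def test_exposure_capped(self, catalogue):
        eps = [
            TherapyEpisode("interferon_beta", D(2011, 1, 1), D(2013, 1, 1)),
            TherapyEpisode("fingolimod", D(2013, 1, 1), None),  # ongoing, long
        ]
        p = _patient(
            episodes=eps,
            edss=[EDSSAssessment(D(2011, 2, 1), 2.0), EDSSAssessment(D(2020, 1, 1), 2.0)],
        )
        rows = build_switch_table([p], BuildConfig(catalogue=catalogue, max_exposure_months=60.0))
        assert rows[0].exposure_months == 60.0


class TestCSVRoundTrip:
    def test_roundtrip_preserves_cohort(self, small_cohort, catalogue, tmp_path):
        write_registry_csv(small_cohort, tmp_path / "reg")
        back = read_registry_csv(tmp_path / "reg", catalogue)
        assert len(back) == len(small_cohort)
        by_id = {p.patient_id: p for p in back}
        for p in small_cohort:
            q = by_id[p.patient_id]
            assert q.sex == p.sex and q.birth_year == p.birth_year
            assert q.diagnosis_date == p.diagnosis_date
            assert q.relapses == p.relapses
            assert q.edss == p.edss
            assert q.episodes == p.episodes

    def test_missing_column_fails_with_filename(self, small_cohort, tmp_path):
        write_registry_csv(small_cohort, tmp_path / "reg")
        f = tmp_path / "reg" / "patients.csv"
        lines = f.read_text().splitlines()
        header = lines[0].split(",")
        drop = header.index("birth_year")
        rewritten = [
            ",".join(v for i, v in enumerate(line.split(",")) if i != drop)
            for line in lines
        ]
        f.write_text("\n".join(rewritten))
        with pytest.raises(RegistryError, match="patients.csv"):
            read_registry_csv(tmp_path / "reg")

    def test_bad_date_reports_line_number(self, small_cohort, tmp_path):
        write_registry_csv(small_cohort, tmp_path / "reg")
        f = tmp_path / "reg" / "relapses.csv"
        lines = f.read_text().splitlines()
        parts = lines[1].split(",")
        parts[-1] = "not-a-date"
        lines[1] = ",".join(parts)
        f.write_text("\n".join(lines))
        with pytest.raises(RegistryError, match="line 2"):
            read_registry_csv(tmp_path / "reg")
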