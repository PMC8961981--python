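"""Registry domain model: patients, therapy episodes, relapses, EDSS.

This module defines the longitudinal patient record as captured by an MS
registry, screens patients for model eligibility at a therapy-switch index
date, extracts the ten-predictor vector the outcome models use, derives the
3-month confirmed disability progression (3mCDP) endpoint from raw EDSS
series, and reads/writes the package's four-file CSV dialect.

Conventions
-----------
* All durations are real-valued months of 30.4375 days.
* Therapy episodes are half-open intervals ``[start, end)``.
* The "current" therapy at an index date is the therapy being discontinued,
  i.e. the latest episode that started strictly before the index date.
* The relapse look-back window is half-open: ``(index - 12 months, index]``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .catalogue import DMTCatalogue, default_catalogue
from .util import DAYS_PER_MONTH, months_between

log = logging.getLogger(__name__)

#: Minimum time between RRMS diagnosis and first use of the predictor, months.
MIN_MONTHS_SINCE_DIAGNOSIS = 6.0
#: The models are not applicable above this EDSS (the scale is strongly
#: non-linear beyond it).
MAX_ELIGIBLE_EDSS = 6.0
#: Default cap for "time since last relapse" when no relapse is on record.
DEFAULT_TSLR_CAP_MONTHS = 120.0
#: Confirmation delay for confirmed disability progression, days.
CDP_CONFIRMATION_DAYS = 90


class RegistryError(ValueError):
    """Structured input/consistency error in registry data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_VALID_EDSS = {i / 2 for i in range(0, 21)}


@dataclass(frozen=True, order=True)
class EDSSAssessment:
    date: dt.date
    score: float

    def __post_init__(self):
        if self.score not in _VALID_EDSS:
            raise RegistryError(
                f"EDSS score must be a multiple of 0.5 in [0, 10], got {self.score}"
            )


@dataclass(frozen=True)
class TherapyEpisode:
    dmt_id: str
    start_date: dt.date
    end_date: Optional[dt.date]  # None = ongoing
    is_second_line: bool = False

    def __post_init__(self):
        if self.end_date is not None and not self.start_date < self.end_date:
            raise RegistryError(
                f"episode start {self.start_date} must precede end {self.end_date}"
            )


@dataclass
class PatientRecord:
    patient_id: str
    sex: str  # "female" | "male"
    birth_year: int
    diagnosis_date: dt.date
    episodes: list[TherapyEpisode] = field(default_factory=list)
    relapses: list[dt.date] = field(default_factory=list)
    edss: list[EDSSAssessment] = field(default_factory=list)

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise RegistryError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.diagnosis_date is None:
            raise RegistryError("diagnosis_date is required")
        self.episodes = sorted(self.episodes, key=lambda e: e.start_date)
        for a, b in zip(self.episodes, self.episodes[1:]):
            if a.end_date is None or a.end_date > b.start_date:
                raise RegistryError(
                    f"patient {self.patient_id}: overlapping episodes "
                    f"({a.dmt_id} / {b.dmt_id})"
                )
        self.relapses = sorted(self.relapses)
        self.edss = sorted(self.edss, key=lambda a: a.date)


@dataclass(frozen=True)
class PredictorVector:
    """The ten model predictors evaluated at a therapy-switch index date."""

    age: float  # years
    sex: str  # "female" | "male"
    edss: float  # latest total score at or before index
    current_dmt: str  # therapy being discontinued
    current_dmt_duration: float  # months on that therapy
    n_previous_dmts: int  # distinct substances before the current one
    any_previous_second_line: bool
    time_since_diagnosis: float  # months
    relapses_last_12m: int
    time_since_last_relapse: float  # months, capped

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SwitchRecord:
    """One modelling row: predictors at a DMT switch plus observed outcomes."""

    patient_id: str
    index_date: dt.date
    predictors: PredictorVector
    assigned_dmt: str  # the therapy started at index_date
    exposure_months: float
    relapse_count: int
    cdp_event: bool
    cdp_censored: bool = False

    def __post_init__(self):
        if self.exposure_months <= 0:
            raise RegistryError("exposure_months must be positive")
        if self.relapse_count < 0:
            raise RegistryError("relapse_count must be non-negative")


@dataclass(frozen=True)
class Eligibility:
    accepted: bool
    reason: Optional[str] = None


@dataclass(frozen=True)
class CDPResult:
    event: bool
    event_date: Optional[dt.date]
    censored: bool


# ---------------------------------------------------------------------------
# screening and extraction
# ---------------------------------------------------------------------------

def latest_edss_at(p: PatientRecord, index_date: dt.date) -> Optional[EDSSAssessment]:
    """Most recent assessment at or before ``index_date`` (None if absent)."""
    best = None
    for a in p.edss:
        if a.date <= index_date:
            best = a
        else:
            break
    return best


def check_eligibility(p: PatientRecord, index_date: dt.date) -> Eligibility:
    """Screen a patient for model applicability at an index date.

    Accepted iff at least 6 months have passed since RRMS diagnosis, an EDSS
    assessment exists at or before the index date, and that assessment is
    <= 6.0. Boundary values (exactly 6 months, EDSS exactly 6.0) are accepted.
    """
    if p.diagnosis_date is None:  # defensive; __post_init__ enforces it
        raise RegistryError("missing diagnosis_date")
    if months_between(index_date, p.diagnosis_date) < MIN_MONTHS_SINCE_DIAGNOSIS:
        return Eligibility(False, "< 6 months since diagnosis")
    ref = latest_edss_at(p, index_date)
    if ref is None:
        return Eligibility(False, "no EDSS assessment before index date")
    if ref.score > MAX_ELIGIBLE_EDSS:
        return Eligibility(False, "EDSS > 6")
    return Eligibility(True)


def _current_episode(p: PatientRecord, index_date: dt.date) -> TherapyEpisode:
    """The therapy being (or about to be) discontinued at ``index_date``:
    the latest episode with start strictly before the index."""
    current = None
    for e in p.episodes:
        if e.start_date < index_date:
            current = e
        else:
            break
    if current is None:
        raise RegistryError(
            f"patient {p.patient_id}: no current DMT at index {index_date}"
        )
    return current


def extract_predictors(
    p: PatientRecord,
    index_date: dt.date,
    catalogue: DMTCatalogue | None = None,
    tslr_cap_months: float = DEFAULT_TSLR_CAP_MONTHS,
) -> PredictorVector:
    """Evaluate the ten model predictors at a switch index date.

    Pure function of the record and the date: relapses are counted over the
    half-open window ``(index - 12 months, index]``; time since last relapse
    is measured to the most recent relapse at or before the index and capped
    at ``tslr_cap_months`` (also used when no relapse is on record).
    """
    current = _current_episode(p, index_date)
    cur_end = min(current.end_date or index_date, index_date)
    previous = [e for e in p.episodes if e.start_date < current.start_date]

    ref = latest_edss_at(p, index_date)
    if ref is None:
        raise RegistryError(f"patient {p.patient_id}: no EDSS before {index_date}")

    window_start = index_date - dt.timedelta(days=round(12 * DAYS_PER_MONTH))
    n12 = sum(1 for r in p.relapses if window_start < r <= index_date)

    past = [r for r in p.relapses if r <= index_date]
    tslr = months_between(index_date, past[-1]) if past else tslr_cap_months

    return PredictorVector(
        age=float(index_date.year - p.birth_year),
        sex=p.sex,
        edss=ref.score,
        current_dmt=current.dmt_id,
        current_dmt_duration=months_between(cur_end, current.start_date),
        n_previous_dmts=len({e.dmt_id for e in previous}),
        any_previous_second_line=any(e.is_second_line for e in previous),
        time_since_diagnosis=months_between(index_date, p.diagnosis_date),
        relapses_last_12m=n12,
        time_since_last_relapse=min(tslr, tslr_cap_months),
    )


def derive_3mcdp(
    p: PatientRecord, index_date: dt.date, horizon_months: float
) -> CDPResult:
    """Derive 3-month confirmed disability progression within a horizon.

    Reference EDSS is the latest assessment at or before the index date. A
    progression is an assessment after the index with an increase of >= 1.0
    point when the reference is <= 5.5, or >= 0.5 point when the reference is
    > 5.5 (the standard trial step rule; this registry convention is an
    assumption documented in the methods note). The provoking assessment must
    fall within the horizon; it counts as an event only if the *first*
    assessment at least 90 days later still meets the increase (the
    confirmation visit may fall beyond the horizon).

    Events are monotone in the horizon: an event at horizon h is an event at
    every longer horizon.
    """
    ref = latest_edss_at(p, index_date)
    if ref is None:
        raise RegistryError(f"patient {p.patient_id}: no EDSS before {index_date}")
    step = 1.0 if ref.score <= 5.5 else 0.5
    threshold = ref.score + step
    horizon_end = index_date + dt.timedelta(days=round(horizon_months * DAYS_PER_MONTH))

    follow_up = [a for a in p.edss if a.date > index_date]
    if not follow_up:
        return CDPResult(False, None, censored=True)

    for i, a in enumerate(follow_up):
        if a.date > horizon_end:
            break
        if a.score < threshold:
            continue
        confirm = next(
            (
                b
                for b in follow_up[i + 1 :]
                if (b.date - a.date).days >= CDP_CONFIRMATION_DAYS
            ),
            None,
        )
        if confirm is not None and confirm.score >= threshold:
            return CDPResult(True, a.date, censored=False)
    return CDPResult(False, None, censored=False)


# ---------------------------------------------------------------------------
# switch-table construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BuildConfig:
    catalogue: DMTCatalogue = field(default_factory=default_catalogue)
    max_exposure_months: float = 60.0
    tslr_cap_months: float = DEFAULT_TSLR_CAP_MONTHS


def build_switch_table(
    cohort: Sequence[PatientRecord], config: BuildConfig | None = None
) -> list[SwitchRecord]:
    """Assemble the modelling table: one row per eligible DMT switch.

    Every episode after a patient's first defines a candidate switch at its
    start date. Rows failing eligibility are logged and skipped; a single bad
    record never aborts the build. Deterministic given input and config.
    """
    config = config or BuildConfig()
    rows: list[SwitchRecord] = []
    for p in cohort:
        try:
            rows.extend(_patient_rows(p, config))
        except RegistryError as err:
            log.warning("skipping patient %s: %s", p.patient_id, err)
    return rows


def _patient_rows(p: PatientRecord, config: BuildConfig) -> list[SwitchRecord]:
    rows = []
    last_seen = max(
        [a.date for a in p.edss] + [r for r in p.relapses] + [dt.date.min],
    )
    for episode in p.episodes[1:]:
        index = episode.start_date
        verdict = check_eligibility(p, index)
        if not verdict.accepted:
            log.info("patient %s @ %s ineligible: %s", p.patient_id, index, verdict.reason)
            continue
        end = episode.end_date or last_seen
        exposure = min(months_between(end, index), config.max_exposure_months)
        if exposure <= 0:
            continue
        pv = extract_predictors(p, index, config.catalogue, config.tslr_cap_months)
        window_end = index + dt.timedelta(days=round(exposure * DAYS_PER_MONTH))
        count = sum(1 for r in p.relapses if index < r <= window_end)
        cdp = derive_3mcdp(p, index, exposure)
        rows.append(
            SwitchRecord(
                patient_id=p.patient_id,
                index_date=index,
                predictors=pv,
                assigned_dmt=episode.dmt_id,
                exposure_months=exposure,
                relapse_count=count,
                cdp_event=cdp.event,
                cdp_censored=cdp.censored,
            )
        )
    return rows


def switch_table_to_frame(rows: Sequence[SwitchRecord]) -> pd.DataFrame:
    """Flatten SwitchRecords into a DataFrame (one predictor per column)."""
    recs = []
    for r in rows:
        d = r.predictors.as_dict()
        d.update(
            patient_id=r.patient_id,
            index_date=r.index_date,
            assigned_dmt=r.assigned_dmt,
            exposure_months=r.exposure_months,
            relapse_count=r.relapse_count,
            cdp_event=r.cdp_event,
            cdp_censored=r.cdp_censored,
        )
        recs.append(d)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------
#
# Four UTF-8 CSV files keyed by patient_id, ISO-8601 dates:
#   patients.csv: patient_id,sex,birth_year,diagnosis_date
#   episodes.csv: patient_id,dmt_id,start_date,end_date  (end empty = ongoing)
#   relapses.csv: patient_id,relapse_date
#   edss.csv:     patient_id,date,score

_PATIENT_COLS = ["patient_id", "sex", "birth_year", "diagnosis_date"]
_EPISODE_COLS = ["patient_id", "dmt_id", "start_date", "end_date"]
_RELAPSE_COLS = ["patient_id", "relapse_date"]
_EDSS_COLS = ["patient_id", "date", "score"]


def _parse_date(value: str, file: str, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError:
        raise RegistryError(f"{file}, line {line}: invalid date {value!r}") from None


def _read_table(path: Path, cols: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise RegistryError(f"missing registry file {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise RegistryError(f"{path.name}: missing mandatory columns {missing}")
    return df


def read_registry_csv(
    directory: str | Path, catalogue: DMTCatalogue | None = None
) -> list[PatientRecord]:
    """Read a cohort from the four-file CSV dialect.

    Malformed rows raise :class:`RegistryError` with file and line number;
    missing mandatory columns hard-fail.
    """
    directory = Path(directory)
    catalogue = catalogue or default_catalogue()

    patients = _read_table(directory / "patients.csv", _PATIENT_COLS)
    episodes = _read_table(directory / "episodes.csv", _EPISODE_COLS)
    relapses = _read_table(directory / "relapses.csv", _RELAPSE_COLS)
    edss = _read_table(directory / "edss.csv", _EDSS_COLS)

    by_id: dict[str, PatientRecord] = {}
    for i, row in patients.iterrows():
        line = i + 2  # header is line 1
        try:
            by_id[row.patient_id] = PatientRecord(
                patient_id=row.patient_id,
                sex=row.sex,
                birth_year=int(row.birth_year),
                diagnosis_date=_parse_date(row.diagnosis_date, "patients.csv", line),
            )
        except (ValueError, RegistryError) as err:
            raise RegistryError(f"patients.csv, line {line}: {err}") from None

    def _patient(pid: str, file: str, line: int) -> PatientRecord:
        if pid not in by_id:
            raise RegistryError(f"{file}, line {line}: unknown patient_id {pid!r}")
        return by_id[pid]

    for i, row in episodes.iterrows():
        line = i + 2
        end = row.end_date or None
        _patient(row.patient_id, "episodes.csv", line).episodes.append(
            TherapyEpisode(
                dmt_id=row.dmt_id,
                start_date=_parse_date(row.start_date, "episodes.csv", line),
                end_date=_parse_date(end, "episodes.csv", line) if end else None,
                is_second_line=(
                    catalogue.is_second_line(row.dmt_id)
                    if row.dmt_id in catalogue
                    else False
                ),
            )
        )
    for i, row in relapses.iterrows():
        line = i + 2
        _patient(row.patient_id, "relapses.csv", line).relapses.append(
            _parse_date(row.relapse_date, "relapses.csv", line)
        )
    for i, row in edss.iterrows():
        line = i + 2
        try:
            score = float(row.score)
            assessment = EDSSAssessment(_parse_date(row.date, "edss.csv", line), score)
        except (ValueError, RegistryError) as err:
            raise RegistryError(f"edss.csv, line {line}: {err}") from None
        _patient(row.patient_id, "edss.csv", line).edss.append(assessment)

    cohort = []
    for p in by_id.values():
        # re-validate ordering invariants after assembly
        cohort.append(
            PatientRecord(
                p.patient_id, p.sex, p.birth_year, p.diagnosis_date,
                p.episodes, p.relapses, p.edss,
            )
        )
    return cohort


def write_registry_csv(cohort: Sequence[PatientRecord], directory: str | Path) -> None:
    """Write a cohort in the four-file CSV dialect (lossless round-trip)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "birth_year": p.birth_year,
                "diagnosis_date": p.diagnosis_date.isoformat(),
            }
            for p in cohort
        ],
        columns=_PATIENT_COLS,
    ).to_csv(directory / "patients.csv", index=False)

    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "dmt_id": e.dmt_id,
                "start_date": e.start_date.isoformat(),
                "end_date": e.end_date.isoformat() if e.end_date else "",
            }
            for p in cohort
            for e in p.episodes
        ],
        columns=_EPISODE_COLS,
    ).to_csv(directory / "episodes.csv", index=False)

    pd.DataFrame(
        [
            {"patient_id": p.patient_id, "relapse_date": r.isoformat()}
            for p in cohort
            for r in p.relapses
        ],
        columns=_RELAPSE_COLS,
    ).to_csv(directory / "relapses.csv", index=False)

    pd.DataFrame(
        [
            {"patient_id": p.patient_id, "date": a.date.isoformat(), "score": a.score}
            for p in cohort
            for a in p.edss
        ],
        columns=_EDSS_COLS,
    ).to_csv(directory / "edss.csv", index=False)
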