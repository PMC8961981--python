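"""Synthetic registry cohorts with known ground truth.

The generator emulates the structure of a longitudinal treatment registry
for relapsing-remitting MS: per-patient therapy episodes with switch index
dates, relapse events whose post-switch counts follow a negative-binomial
regression with a log-exposure offset, EDSS trajectories embedding 3-month
confirmed disability progression events drawn from a complementary-log-log
model, and therapy assignment that is *confounded* with disease activity
(sicker patients preferentially receive high-efficacy therapy).

Ground truth is expressed on the natural covariate scale, centred at
reference covariate values, so that the intercepts are interpretable as log
event rates per month for a typical switching patient. Everything downstream
(model fitting, ranking, propensity-weighted evaluation) can therefore be
tested against known parameters without any real data.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .catalogue import DMTCatalogue, default_catalogue
from .registry import (
    DEFAULT_TSLR_CAP_MONTHS,
    EDSSAssessment,
    PatientRecord,
    PredictorVector,
    SwitchRecord,
    TherapyEpisode,
    extract_predictors,
)
from .util import DAYS_PER_MONTH

#: Covariate reference values at which the generator's intercepts apply.
REFERENCE_VALUES = {
    "age": 38.0,  # years
    "edss": 2.5,
    "current_dmt_duration": 18.0,  # months
    "n_previous_dmts": 1.0,
    "time_since_diagnosis": 60.0,  # months
    "relapses_last_12m": 1.0,
    "time_since_last_relapse": 12.0,  # months
}

_EFFECT_KEYS = (
    "age",
    "sex_male",
    "edss",
    "current_dmt_duration",
    "n_previous_dmts",
    "any_previous_second_line",
    "time_since_diagnosis",
    "relapses_last_12m",
    "time_since_last_relapse",
)


@dataclass(frozen=True)
class OutcomeTruth:
    """True coefficients for one outcome (natural scale).

    ``intercept`` is the log event rate per month at the reference covariate
    values under the reference therapy effect 0. ``effects`` act per natural
    unit of each predictor; ``discontinued`` is the effect of which therapy
    is being stopped; ``treatment`` is the effect of the newly assigned DMT.
    """

    intercept: float
    effects: dict[str, float]
    discontinued: dict[str, float]
    treatment: dict[str, float]

    def linear_predictor(self, pv: PredictorVector, assigned_dmt: str) -> float:
        eta = self.intercept
        x = pv.as_dict()
        for key, beta in self.effects.items():
            if key == "sex_male":
                eta += beta * (1.0 if pv.sex == "male" else 0.0)
            elif key == "any_previous_second_line":
                eta += beta * float(pv.any_previous_second_line)
            else:
                eta += beta * (x[key] - REFERENCE_VALUES[key])
        eta += self.discontinued.get(pv.current_dmt, 0.0)
        eta += self.treatment[assigned_dmt]
        return eta


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of the synthetic registry's data-generating process."""

    n_patients: int = 2000
    catalogue: DMTCatalogue = field(default_factory=default_catalogue)
    relapse: "OutcomeTruth" = None  # filled by default_generator_spec
    cdp: "OutcomeTruth" = None
    dispersion: float = 1.5  # NB overdispersion r; var = mu + mu^2/r
    #: per-DMT assignment-utility coefficients (multinomial logit over the
    #: catalogue); keys: intercept, relapses_last_12m, edss
    assignment: dict[str, dict[str, float]] = None
    #: scales the covariate-dependent part of the assignment utilities;
    #: 0 = randomized (unconfounded) therapy choice
    confounding_scale: float = 1.0
    exposure_log_mean: float = math.log(24.0)  # months
    exposure_log_sd: float = 0.45
    exposure_min: float = 6.0
    exposure_max: float = 60.0
    episode_count_probs: tuple[float, ...] = (0.50, 0.35, 0.15)  # P(2), P(3), P(4)
    blip_prob: float = 0.06  # isolated transient -0.5 EDSS dips
    tslr_cap_months: float = DEFAULT_TSLR_CAP_MONTHS
    seed: int = 0

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for truth in (self.relapse, self.cdp):
            if truth is not None:
                missing = set(truth.treatment) ^ set(self.catalogue.ids)
                if missing:
                    raise ValueError(f"treatment effects do not match catalogue: {missing}")

    def replace(self, **kw) -> "GeneratorSpec":
        return dataclasses.replace(self, **kw)


def default_generator_spec(**overrides) -> GeneratorSpec:
    """Study conditions used throughout the package's simulations.

    Baseline annualized relapse rate ~0.4 under the reference therapy, ~10%
    two-year risk of confirmed progression, moderate NB overdispersion, and
    treatment effects spanning the realistic range between platform and
    high-efficacy DMTs. Assignment is confounded: recent relapse activity and
    higher EDSS push patients toward high-efficacy therapy.
    """
    relapse = OutcomeTruth(
        intercept=math.log(0.033),  # ~0.40 relapses / year
        effects={
            "age": -0.020,
            "sex_male": 0.10,
            "edss": 0.08,
            "current_dmt_duration": -0.005,
            "n_previous_dmts": 0.08,
            "any_previous_second_line": 0.15,
            "time_since_diagnosis": -0.002,
            "relapses_last_12m": 0.25,
            "time_since_last_relapse": -0.004,
        },
        discontinued={
            "interferon_beta": 0.00,
            "glatiramer_acetate": 0.05,
            "dimethyl_fumarate": -0.05,
            "teriflunomide": 0.00,
            "fingolimod": -0.08,
            "natalizumab": -0.12,
        },
        treatment={
            "interferon_beta": 0.00,
            "glatiramer_acetate": 0.05,
            "dimethyl_fumarate": -0.15,
            "teriflunomide": -0.05,
            "fingolimod": -0.35,
            "natalizumab": -0.55,
        },
    )
    cdp = OutcomeTruth(
        intercept=math.log(0.0044),  # ~10% 2-year 3mCDP risk
        effects={
            "age": 0.010,
            "sex_male": 0.05,
            "edss": 0.12,
            "current_dmt_duration": -0.002,
            "n_previous_dmts": 0.05,
            "any_previous_second_line": 0.10,
            "time_since_diagnosis": 0.001,
            "relapses_last_12m": 0.10,
            "time_since_last_relapse": -0.002,
        },
        discontinued={
            "interferon_beta": 0.00,
            "glatiramer_acetate": 0.03,
            "dimethyl_fumarate": -0.03,
            "teriflunomide": 0.00,
            "fingolimod": -0.05,
            "natalizumab": -0.08,
        },
        treatment={
            "interferon_beta": 0.00,
            "glatiramer_acetate": 0.05,
            "dimethyl_fumarate": -0.10,
            "teriflunomide": -0.02,
            "fingolimod": -0.20,
            "natalizumab": -0.30,
        },
    )
    assignment = {
        "interferon_beta": {"intercept": 0.0, "relapses_last_12m": -0.30, "edss": -0.10},
        "glatiramer_acetate": {"intercept": 0.1, "relapses_last_12m": -0.20, "edss": -0.10},
        "dimethyl_fumarate": {"intercept": 0.3, "relapses_last_12m": 0.00, "edss": 0.00},
        "teriflunomide": {"intercept": 0.0, "relapses_last_12m": -0.10, "edss": 0.00},
        "fingolimod": {"intercept": -0.3, "relapses_last_12m": 0.45, "edss": 0.25},
        "natalizumab": {"intercept": -0.8, "relapses_last_12m": 0.70, "edss": 0.40},
    }
    spec = GeneratorSpec(relapse=relapse, cdp=cdp, assignment=assignment)
    return spec.replace(**overrides) if overrides else spec


def null_treatment_spec(**overrides) -> GeneratorSpec:
    """Variant with identical treatment effects for every DMT (both outcomes):
    the induced therapy ranking is uninformative. Assignment confounding is
    kept, so adherence labels remain covariate-dependent."""
    base = default_generator_spec()
    zero = {d: 0.0 for d in base.catalogue.ids}
    spec = base.replace(
        relapse=dataclasses.replace(base.relapse, treatment=dict(zero)),
        cdp=dataclasses.replace(base.cdp, treatment=dict(zero)),
    )
    return spec.replace(**overrides) if overrides else spec


def informative_ranking_spec(**overrides) -> GeneratorSpec:
    """Variant with widely separated treatment effects for both outcomes and
    a raised progression rate, so the induced therapy ranking is strongly
    informative and scenario analyses have working power at moderate cohort
    sizes. Assignment confounding is kept."""
    base = default_generator_spec()
    relapse = dataclasses.replace(
        base.relapse,
        treatment={
            "interferon_beta": 0.45,
            "glatiramer_acetate": 0.55,
            "dimethyl_fumarate": -0.15,
            "teriflunomide": 0.00,
            "fingolimod": -0.65,
            "natalizumab": -0.85,
        },
    )
    cdp = dataclasses.replace(
        base.cdp,
        intercept=math.log(0.0145),
        treatment={
            "interferon_beta": 0.55,
            "glatiramer_acetate": 0.65,
            "dimethyl_fumarate": -0.10,
            "teriflunomide": 0.00,
            "fingolimod": -0.70,
            "natalizumab": -1.00,
        },
    )
    spec = base.replace(relapse=relapse, cdp=cdp)
    return spec.replace(**overrides) if overrides else spec


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_EDSS_GRID = np.arange(0.0, 6.51, 0.5)


def _draw_baseline_edss(rng) -> float:
    w = np.exp(-0.45 * np.arange(len(_EDSS_GRID)))
    w /= w.sum()
    return float(rng.choice(_EDSS_GRID, p=w))


def _assignment_probs(spec: GeneratorSpec, pv: PredictorVector) -> np.ndarray:
    u = []
    for d in spec.catalogue.ids:
        a = spec.assignment[d]
        u.append(
            a.get("intercept", 0.0)
            + spec.confounding_scale
            * (
                a.get("relapses_last_12m", 0.0) * (pv.relapses_last_12m - 1.0)
                + a.get("edss", 0.0) * (pv.edss - 2.5)
            )
        )
    u = np.asarray(u)
    p = np.exp(u - u.max())
    return p / p.sum()


def _draw_exposure_months(spec: GeneratorSpec, rng) -> float:
    x = rng.lognormal(spec.exposure_log_mean, spec.exposure_log_sd)
    return float(np.clip(x, spec.exposure_min, spec.exposure_max))


def _nb_count(rng, mu: float, r: float) -> int:
    return int(rng.negative_binomial(r, r / (r + mu)))


def generate_patient(spec: GeneratorSpec, patient_id: str, rng) -> PatientRecord:
    """Simulate one patient's full registry history.

    Outcomes for each post-switch episode are drawn from the true outcome
    models *given the predictor vector the extractor would compute at that
    switch*, so fitting the outcome models on the assembled switch table
    recovers the generator truth. Relapse dates are placed uniformly within
    the episode (order statistics of a mixed-Poisson process conditioned on
    its count); EDSS trajectories are piecewise-constant walks on the
    0.5-grid with isolated transient dips and, for progression events, an
    injected step confirmed by a dedicated assessment 98 days later.
    """
    sex = "male" if rng.random() < 0.32 else "female"
    n_ep = int(rng.choice([2, 3, 4], p=spec.episode_count_probs))
    anchor = dt.date(2012, 1, 1) + dt.timedelta(days=int(rng.integers(0, 2200)))

    ep_len_days = [
        round(_draw_exposure_months(spec, rng) * DAYS_PER_MONTH) for _ in range(n_ep)
    ]
    ep_starts = [anchor]
    for L in ep_len_days[:-1]:
        ep_starts.append(ep_starts[-1] + dt.timedelta(days=L))
    first_switch = ep_starts[1]

    if rng.random() < 0.95:
        delta_m = 6.0 + rng.gamma(2.0, 30.0)
    else:
        delta_m = rng.uniform(0.0, 6.0)  # too recently diagnosed -> screened out
    diagnosis = first_switch - dt.timedelta(days=round(delta_m * DAYS_PER_MONTH))

    age = float(np.clip(rng.normal(38.0, 10.0), 18.0, 65.0))
    birth_year = first_switch.year - int(round(age))

    baseline = _draw_baseline_edss(rng)
    first_line = [d.id for d in spec.catalogue if d.line == 1]
    episodes = [
        TherapyEpisode(
            dmt_id=str(rng.choice(first_line)),
            start_date=ep_starts[0],
            end_date=ep_starts[1],
            is_second_line=False,
        )
    ]

    relapses: list[dt.date] = []
    hist_window_days = 365 + (first_switch - anchor).days
    n_hist = rng.poisson(0.035 * hist_window_days / DAYS_PER_MONTH)
    for _ in range(n_hist):
        off = int(rng.integers(1, hist_window_days))
        day = first_switch - dt.timedelta(days=off)
        if day != anchor:
            relapses.append(day)

    edss: list[EDSSAssessment] = [EDSSAssessment(ep_starts[0], baseline)]
    b_cur = baseline

    for k in range(1, n_ep):
        index = ep_starts[k]
        days = ep_len_days[k]
        end = index + dt.timedelta(days=days)
        exposure_m = days / DAYS_PER_MONTH
        edss.append(EDSSAssessment(index, b_cur))

        partial = PatientRecord(
            patient_id, sex, birth_year, diagnosis,
            list(episodes), list(relapses), list(edss),
        )
        pv = extract_predictors(partial, index, spec.catalogue, spec.tslr_cap_months)

        assigned = str(
            rng.choice(spec.catalogue.ids, p=_assignment_probs(spec, pv))
        )
        episodes.append(
            TherapyEpisode(
                dmt_id=assigned,
                start_date=index,
                end_date=end,
                is_second_line=spec.catalogue.is_second_line(assigned),
            )
        )

        # relapse outcome
        mu = exposure_m * math.exp(spec.relapse.linear_predictor(pv, assigned))
        count = _nb_count(rng, mu, spec.dispersion)
        if count and days > 4:
            offs = rng.integers(2, days - 1, size=count)
            relapses.extend(index + dt.timedelta(days=int(o)) for o in offs)

        # disability outcome
        p_ev = 1.0 - math.exp(
            -exposure_m * math.exp(spec.cdp.linear_predictor(pv, assigned))
        )
        event = rng.random() < p_ev
        step = 1.0 if b_cur <= 5.5 else 0.5
        if event:
            t_e = int(days * (0.15 + 0.70 * rng.random()))
            new_level = min(b_cur + step, 9.5)
            edss.append(EDSSAssessment(index + dt.timedelta(days=t_e), new_level))
            edss.append(
                EDSSAssessment(index + dt.timedelta(days=t_e + 98), new_level)
            )
            # routine visits resume after confirmation
            t = t_e + 98 + 91
            while t < days:
                edss.append(EDSSAssessment(index + dt.timedelta(days=t), new_level))
                t += 91
            b_cur = new_level
        else:
            t = 91
            last_blip = True  # no dip at the first interior visit
            while t < days:
                score = b_cur
                if not last_blip and b_cur >= 0.5 and rng.random() < spec.blip_prob:
                    score = b_cur - 0.5
                    last_blip = True
                else:
                    last_blip = False
                edss.append(EDSSAssessment(index + dt.timedelta(days=t), score))
                t += 91

    final_end = ep_starts[-1] + dt.timedelta(days=ep_len_days[-1])
    edss.append(EDSSAssessment(final_end + dt.timedelta(days=100), b_cur))

    # drop duplicate assessment dates (late confirmations can coincide with a
    # later routine visit; scores agree by construction)
    seen: dict[dt.date, EDSSAssessment] = {}
    for a in sorted(edss, key=lambda a: a.date):
        seen.setdefault(a.date, a)

    return PatientRecord(
        patient_id=patient_id,
        sex=sex,
        birth_year=birth_year,
        diagnosis_date=diagnosis,
        episodes=episodes,
        relapses=sorted(relapses),
        edss=list(seen.values()),
    )


def generate_cohort(spec: GeneratorSpec, seed: Optional[int] = None) -> list[PatientRecord]:
    """Generate ``spec.n_patients`` independent patients.

    Each patient draws from an independent child stream of the master seed,
    so cohorts of different sizes under the same seed agree patient-by-
    patient (the accrual property used by :func:`generate_growth_series`).
    """
    master = spec.seed if seed is None else seed
    children = np.random.SeedSequence(int(master)).spawn(spec.n_patients)
    return [
        generate_patient(spec, f"P{i:06d}", np.random.default_rng(child))
        for i, child in enumerate(children)
    ]


def generate_growth_series(
    spec: GeneratorSpec,
    n_cuts: int,
    growth_per_cut: float = 0.013,
    seed: Optional[int] = None,
) -> list[list[PatientRecord]]:
    """Nested cohorts emulating registry accrual.

    Cut ``k`` has ``round(n0 * (1 + g)^k)`` patients and is a superset of cut
    ``k-1`` (patients are only ever added). The default growth rate of 1.3%
    per cut mirrors quarterly accrual of a mature national registry.
    """
    if growth_per_cut <= 0:
        raise ValueError("growth_per_cut must be > 0")
    if n_cuts < 1:
        raise ValueError("n_cuts must be >= 1")
    sizes = [int(round(spec.n_patients * (1.0 + growth_per_cut) ** k)) for k in range(n_cuts)]
    full = generate_cohort(spec.replace(n_patients=sizes[-1]), seed=seed)
    return [full[:n] for n in sizes]


# ---------------------------------------------------------------------------
# direct switch-table sampling (method-calibration studies)
# ---------------------------------------------------------------------------

def sample_switch_records(
    spec: GeneratorSpec, n_rows: int, seed: int
) -> list[SwitchRecord]:
    """Sample modelling rows directly from the outcome models.

    Bypasses patient-history assembly: covariates come from simple marginal
    distributions, therapy assignment and outcomes from the same true models
    as :func:`generate_cohort`. One row per synthetic patient. Used for
    calibration studies (type-I error, weighting bias) where only the
    table-level method is exercised and many replicates are needed.
    """
    rng = np.random.default_rng(seed)
    cat = spec.catalogue.ids
    rows = []
    index = dt.date(2015, 1, 1)
    for i in range(n_rows):
        pv = PredictorVector(
            age=float(np.clip(rng.normal(38, 10), 18, 65)),
            sex="male" if rng.random() < 0.32 else "female",
            edss=_draw_baseline_edss(rng),
            current_dmt=str(rng.choice(cat)),
            current_dmt_duration=float(np.clip(rng.lognormal(math.log(18), 0.6), 1, 120)),
            n_previous_dmts=int(rng.poisson(0.8)),
            any_previous_second_line=bool(rng.random() < 0.15),
            time_since_diagnosis=float(6 + rng.gamma(2.0, 30.0)),
            relapses_last_12m=int(rng.poisson(0.9)),
            time_since_last_relapse=float(
                min(rng.exponential(15.0), spec.tslr_cap_months)
            ),
        )
        assigned = str(rng.choice(cat, p=_assignment_probs(spec, pv)))
        exposure = _draw_exposure_months(spec, rng)
        mu = exposure * math.exp(spec.relapse.linear_predictor(pv, assigned))
        count = _nb_count(rng, mu, spec.dispersion)
        p_ev = 1.0 - math.exp(
            -exposure * math.exp(spec.cdp.linear_predictor(pv, assigned))
        )
        rows.append(
            SwitchRecord(
                patient_id=f"S{i:06d}",
                index_date=index,
                predictors=pv,
                assigned_dmt=assigned,
                exposure_months=exposure,
                relapse_count=count,
                cdp_event=bool(rng.random() < p_ev),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# mapping generator truth onto a fitted model's coefficient scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryTarget:
    name: str
    truth: float
    draws: np.ndarray  # posterior draws of the matching quantity


def recovery_targets(fit, truth: OutcomeTruth) -> list[RecoveryTarget]:
    """Express generator truth on the fitted model's (standardized) scale.

    Continuous predictors are standardized at fit time, so the true
    standardized coefficient is the natural-scale effect times the frozen
    training SD. Categorical effects and therapy effects are compared as
    contrasts against the fit's reference level (the absolute level is only
    softly identified against the intercept under partial pooling).
    """
    targets: list[RecoveryTarget] = []
    meta = fit.design
    for j, name in enumerate(meta.columns):
        draws = fit.draws["beta"][:, j]
        if name in meta.standardization:  # continuous column
            mean, sd = meta.standardization[name]
            targets.append(RecoveryTarget(name, truth.effects[name] * sd, draws))
        elif name == "sex_male":
            targets.append(RecoveryTarget(name, truth.effects["sex_male"], draws))
        elif name == "any_previous_second_line":
            targets.append(
                RecoveryTarget(name, truth.effects["any_previous_second_line"], draws)
            )
        elif name.startswith("current_dmt["):
            level = name[len("current_dmt[") : -1]
            t = truth.discontinued[level] - truth.discontinued[meta.current_dmt_ref]
            targets.append(RecoveryTarget(name, t, draws))
    ref = meta.dmt_levels[0]
    ref_ix = 0
    for j, level in enumerate(meta.dmt_levels):
        if j == ref_ix:
            continue
        targets.append(
            RecoveryTarget(
                f"treatment[{level}-{ref}]",
                truth.treatment[level] - truth.treatment[ref],
                fit.draws["alpha"][:, j] - fit.draws["alpha"][:, ref_ix],
            )
        )
    return targets
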