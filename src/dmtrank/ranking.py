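"""Therapy ranking and decision-support reports.

Turns per-DMT event-free probabilities into a ranked table per endpoint,
with preference-based exclusions ("shading"): excluded therapies keep their
computed probability but carry no rank, so the impact of a preference on the
achievable outcome spectrum stays visible. Probabilities are also rendered
as natural frequencies ("73 of 100 patients like you"), the presentation
format best understood in shared physician-patient decision making.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .catalogue import DMTCatalogue
from .models import (
    MAX_HORIZON_MONTHS,
    MIN_HORIZON_MONTHS,
    ModelError,
    PosteriorFit,
    explain_prediction,
    prob_event_free,
)
from .registry import PredictorVector
from .util import round_floats

OUTCOME_LABELS = {"relapse": "relapse-free", "cdp": "3mCDP-free"}


@dataclass(frozen=True)
class PredictionResult:
    dmt_id: str
    outcome: str  # "relapse-free" | "3mCDP-free"
    horizon_months: float
    probability: float
    ci90: tuple[float, float]
    rank: Optional[int]  # None when excluded by preference
    excluded_by_preference: bool = False
    exclusion_reason: Optional[str] = None

    @property
    def natural_frequency(self) -> str:
        n = int(self.probability * 100 + 0.5)  # round half-up per 100
        return f"{n} of 100"


@dataclass(frozen=True)
class RankingTable:
    horizon_months: float
    by_outcome: dict[str, list[PredictionResult]]  # ordered, ranked first

    def ranked(self, outcome: str) -> list[PredictionResult]:
        return [r for r in self.by_outcome[outcome] if r.rank is not None]

    def top(self, outcome: str, n: int = 1) -> list[str]:
        return [r.dmt_id for r in self.ranked(outcome)[:n]]

    def bottom(self, outcome: str, n: int = 1) -> list[str]:
        return [r.dmt_id for r in self.ranked(outcome)[-n:]]


def rank_therapies(
    relapse_fit: PosteriorFit,
    cdp_fit: PosteriorFit,
    x: PredictorVector,
    horizon_months: float,
    preferences: Mapping[str, str] | Sequence[str] | None = None,
    enforce_horizon_range: bool = True,
) -> RankingTable:
    """Rank every catalogue DMT by event-free probability, per endpoint.

    ``preferences`` maps excluded DMT ids to a reason (or is a plain list of
    ids). Ordering is by decreasing posterior-mean probability; exact ties
    break by narrower 90% interval, then catalogue order. Excluding a DMT
    never changes any other DMT's probability.
    """
    if relapse_fit.spec.catalogue != cdp_fit.spec.catalogue:
        raise ModelError("relapse and CDP fits must share the DMT catalogue")
    catalogue: DMTCatalogue = relapse_fit.spec.catalogue
    if enforce_horizon_range and not (
        MIN_HORIZON_MONTHS <= horizon_months <= MAX_HORIZON_MONTHS
    ):
        raise ModelError(
            f"prediction period must be between {MIN_HORIZON_MONTHS:.0f} and "
            f"{MAX_HORIZON_MONTHS:.0f} months, got {horizon_months}"
        )
    if isinstance(preferences, Mapping):
        excluded = dict(preferences)
    else:
        excluded = {d: "excluded by preference" for d in (preferences or [])}

    by_outcome: dict[str, list[PredictionResult]] = {}
    for fit in (relapse_fit, cdp_fit):
        label = OUTCOME_LABELS[fit.outcome]
        cat_order = {d: i for i, d in enumerate(catalogue.ids)}
        preds = []
        for dmt in catalogue.ids:
            p = prob_event_free(fit, x, dmt, horizon_months)
            preds.append(p)
        # decreasing probability; ties -> narrower ci90, then catalogue order
        preds.sort(
            key=lambda p: (
                -p.probability,
                p.ci90[1] - p.ci90[0],
                cat_order[p.dmt_id],
            )
        )
        results, rank = [], 0
        for p in preds:
            if p.dmt_id in excluded:
                results.append(
                    PredictionResult(
                        p.dmt_id, label, horizon_months, p.probability, p.ci90,
                        rank=None, excluded_by_preference=True,
                        exclusion_reason=excluded[p.dmt_id],
                    )
                )
            else:
                rank += 1
                results.append(
                    PredictionResult(
                        p.dmt_id, label, horizon_months, p.probability, p.ci90,
                        rank=rank,
                    )
                )
        by_outcome[label] = results
    return RankingTable(horizon_months=float(horizon_months), by_outcome=by_outcome)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def render_report(
    table: RankingTable,
    x: PredictorVector,
    relapse_fit: PosteriorFit,
    cdp_fit: PosteriorFit,
) -> tuple[dict, str]:
    """Structured decision-support report: (JSON-ready dict, plain text).

    Contains natural frequencies, 90% credible intervals, the prediction
    horizon, and the per-predictor contribution panel for the top-ranked DMT
    of each endpoint. Byte-stable for fixed inputs (floats rounded to 4
    decimals, keys sorted in the JSON rendering).
    """
    doc: dict = {
        "horizon_months": table.horizon_months,
        "patient": x.as_dict(),
        "outcomes": {},
    }
    lines = [f"Therapy ranking over {table.horizon_months:.0f} months", ""]
    for label, results in table.by_outcome.items():
        fit = relapse_fit if label == OUTCOME_LABELS["relapse"] else cdp_fit
        entries = []
        lines.append(f"Probability of staying {label}:")
        for r in results:
            entries.append(
                {
                    "dmt_id": r.dmt_id,
                    "rank": r.rank,
                    "probability": r.probability,
                    "ci90": list(r.ci90),
                    "natural_frequency": r.natural_frequency,
                    "excluded_by_preference": r.excluded_by_preference,
                    "exclusion_reason": r.exclusion_reason,
                }
            )
            mark = "  (excluded)" if r.excluded_by_preference else ""
            rank = "-" if r.rank is None else str(r.rank)
            lines.append(
                f"  {rank:>2}. {r.dmt_id:<22} {r.natural_frequency:>10}"
                f"   [{r.ci90[0]:.2f}, {r.ci90[1]:.2f}]{mark}"
            )
        top = next((r for r in results if r.rank == 1), None)
        panel = None
        if top is not None:
            ex = explain_prediction(fit, x, top.dmt_id)
            panel = {
                "dmt_id": top.dmt_id,
                "intercept": ex.intercept,
                "therapy_effect": ex.therapy_effect,
                "contributions": [
                    {
                        "predictor": c.predictor,
                        "value": c.value,
                        "contribution": c.contribution,
                        "percentile": c.percentile,
                    }
                    for c in ex.contributions
                ],
            }
        doc["outcomes"][label] = {"ranking": entries, "explanation": panel}
        lines.append("")
    return round_floats(doc), "\n".join(lines)


def report_json(doc: dict) -> str:
    return json.dumps(doc, sort_keys=True, indent=2)
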