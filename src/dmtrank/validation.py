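"""Goodness-of-fit, discrimination, and robustness monitoring.

Implements the model-quality machinery used to watch the predictive models
as a registry accrues data: mean squared error and negative log-likelihood,
the concordance index (in- and out-of-sample, patient-level splits),
empirical 90% coefficient intervals across random-initialization refits, and
the growth monitor that tracks both against the first data cut as reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .models import ModelSpec, PosteriorFit, design_row, fit as fit_model
from .registry import BuildConfig, PatientRecord, SwitchRecord, build_switch_table
from .util import fork_seeds


# ---------------------------------------------------------------------------
# concordance index
# ---------------------------------------------------------------------------

def c_index(
    predictions: Sequence[float],
    observed: Sequence[float],
    exposure: Optional[Sequence[float]] = None,
) -> Optional[float]:
    """Concordance index in [0, 1]; 1 indicates perfect predictions.

    Over all pairs whose observed outcomes differ, the fraction where the
    predicted ordering matches the observed ordering; prediction ties score
    0.5. For count outcomes pass ``exposure`` to compare exposure-normalized
    observed rates (predictions should then be rates or any monotone score).
    Returns None when no usable pair exists (all outcomes identical).
    """
    pred = np.asarray(predictions, float)
    obs = np.asarray(observed, float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predictions and observed must be 1-D of equal length")
    if pred.size < 2:
        raise ValueError("need at least 2 observations")
    if exposure is not None:
        obs = obs / np.asarray(exposure, float)

    n = pred.size
    num = 0.0
    den = 0
    chunk = 512
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        do = obs[i0:i1, None] - obs[None, :]
        dp = pred[i0:i1, None] - pred[None, :]
        # count each unordered pair once: j > i
        mask = np.zeros_like(do, bool)
        idx = np.arange(i0, i1)
        mask[np.arange(i1 - i0)[:, None], np.arange(n)[None, :]] = (
            np.arange(n)[None, :] > idx[:, None]
        )
        usable = mask & (do != 0)
        den += int(usable.sum())
        agree = np.sign(dp) == np.sign(do)
        ties = dp == 0
        num += float(agree[usable & ~ties].sum()) + 0.5 * float(ties[usable].sum())
    if den == 0:
        return None
    return num / den


# ---------------------------------------------------------------------------
# predicted outcomes for a table
# ---------------------------------------------------------------------------

def _table_matrices(fit: PosteriorFit, table: Sequence[SwitchRecord], max_draws: int):
    X = np.stack([design_row(fit.design, r.predictors) for r in table])
    exposure = np.array([r.exposure_months for r in table])
    S = fit.n_draws
    take = np.linspace(0, S - 1, min(max_draws, S)).astype(int)
    b0 = fit.draws["b0"][take]
    beta = fit.draws["beta"][take]
    alphas = {}
    pooled = 0
    for d in {r.assigned_dmt for r in table}:
        a, flag = fit.alpha_draws(d)
        alphas[d] = a[take]
        pooled += int(flag)
    A = np.stack([alphas[r.assigned_dmt] for r in table])  # (n, S')
    eta = X @ beta.T + b0[None, :] + A  # (n, S')
    return eta, exposure, take, pooled


def predicted_outcomes(
    fit: PosteriorFit, table: Sequence[SwitchRecord], max_draws: int = 300
) -> np.ndarray:
    """Posterior-mean predicted outcome per row: expected relapse count over
    the row's exposure (relapse model) or event probability (CDP model)."""
    eta, exposure, take, _ = _table_matrices(fit, table, max_draws)
    if fit.outcome == "relapse":
        mu = np.exp(eta + np.log(exposure)[:, None])
        return mu.mean(1)
    if fit.cdp_link == "logit_exposure":
        from scipy.special import expit

        g = fit.draws["gamma"][take]
        return expit(eta + g[None, :] * np.log(exposure)[:, None]).mean(1)
    lam = np.exp(eta + np.log(exposure)[:, None])
    return (1.0 - np.exp(-lam)).mean(1)


@dataclass(frozen=True)
class Metrics:
    c_index: Optional[float]
    mse: float
    nll: float


def goodness_of_fit(
    fit: PosteriorFit, table: Sequence[SwitchRecord], max_draws: int = 300
) -> Metrics:
    """MSE, NLL and C-index of a fit on a (test or training) table.

    MSE is in outcome units: squared relapse-count error for the relapse
    model, squared event-indicator error for the CDP model. NLL is the mean
    negative log posterior-predictive mass of the observed outcomes.
    """
    eta, exposure, take, _ = _table_matrices(fit, table, max_draws)
    if fit.outcome == "relapse":
        y = np.array([r.relapse_count for r in table], float)
        mu = np.exp(eta + np.log(exposure)[:, None])  # (n, S)
        pred = mu.mean(1)
        r = fit.draws["r"][take][None, :]
        pmf = stats.nbinom.pmf(y[:, None], r, r / (r + mu))
        nll = float(-np.log(np.clip(pmf.mean(1), 1e-300, None)).mean())
        mse = float(((y - pred) ** 2).mean())
        ci = c_index(pred / exposure, y, exposure=exposure)
    else:
        y = np.array([int(r.cdp_event) for r in table], float)
        if fit.cdp_link == "logit_exposure":
            from scipy.special import expit

            g = fit.draws["gamma"][take]
            pev = expit(eta + g[None, :] * np.log(exposure)[:, None])
        else:
            pev = 1.0 - np.exp(-np.exp(eta + np.log(exposure)[:, None]))
        p = pev.mean(1)
        mse = float(((y - p) ** 2).mean())
        p_clip = np.clip(p, 1e-12, 1 - 1e-12)
        nll = float(-(y * np.log(p_clip) + (1 - y) * np.log1p(-p_clip)).mean())
        ci = c_index(p, y)
    return Metrics(c_index=ci, mse=mse, nll=nll)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    outcome: str
    in_sample: Metrics
    out_of_sample: Metrics
    n_train: int
    n_test: int
    k_folds: int
    seed: int
    n_pooled_predictions: int = 0


def cross_validate(
    table: Sequence[SwitchRecord],
    spec: ModelSpec,
    k_folds: int = 5,
    seed: int = 0,
    max_draws: int = 300,
) -> ValidationReport:
    """Patient-level k-fold cross-validation.

    Folds split by patient (never by row) so out-of-sample metrics measure
    generalization to unseen patients. A fold whose test rows contain a DMT
    absent from its training rows receives predictions from the pooling
    distribution; the count of such rows is reported. In-sample metrics come
    from the fit on the full table. Reproducible given the seed.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    patients = sorted({r.patient_id for r in table})
    rng = np.random.default_rng(fork_seeds(seed, 1, label="cv-split")[0])
    order = rng.permutation(len(patients))
    fold_of = {patients[i]: int(order[i]) % k_folds for i in range(len(patients))}

    full = fit_model(table, spec, seed=fork_seeds(seed, 1, label="cv-full")[0])
    in_m = goodness_of_fit(full, table, max_draws)

    fold_metrics, weights, pooled = [], [], 0
    fold_seeds = fork_seeds(seed, k_folds, label="cv-folds")
    for k in range(k_folds):
        test = [r for r in table if fold_of[r.patient_id] == k]
        train = [r for r in table if fold_of[r.patient_id] != k]
        if not test or not train:
            continue
        f = fit_model(train, spec, seed=fold_seeds[k])
        _, _, _, n_pooled = _table_matrices(f, test, 1)
        pooled += n_pooled
        fold_metrics.append(goodness_of_fit(f, test, max_draws))
        weights.append(len(test))

    w = np.array(weights, float)
    w /= w.sum()

    def avg(vals):
        vals = [v for v in vals]
        if any(v is None for v in vals):
            vals = [v if v is not None else 0.5 for v in vals]
        return float(np.dot(w, vals))

    out_m = Metrics(
        c_index=avg([m.c_index for m in fold_metrics]),
        mse=avg([m.mse for m in fold_metrics]),
        nll=avg([m.nll for m in fold_metrics]),
    )
    return ValidationReport(
        outcome=spec.outcome,
        in_sample=in_m,
        out_of_sample=out_m,
        n_train=len(table),
        n_test=len(table),
        k_folds=k_folds,
        seed=seed,
        n_pooled_predictions=pooled,
    )


# ---------------------------------------------------------------------------
# empirical coefficient intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoefficientIntervals:
    """90% empirical intervals of coefficient point estimates across refits
    that differ only in their random initialization (not a bootstrap: the
    data are never resampled). Small spans mean the training data, not the
    initialization, determines the coefficients."""

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    estimates: np.ndarray  # (n_refits_kept, n_coefficients)
    n_refits: int
    n_excluded: int

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def median_span(self) -> float:
        return float(np.median(self.span))


def _coefficient_vector(f: PosteriorFit) -> tuple[list[str], np.ndarray]:
    names = ["intercept"] + list(f.design.columns)
    est = [f.draws["b0"].mean()] + list(f.draws["beta"].mean(0))
    for i, d in enumerate(f.design.dmt_levels):
        names.append(f"alpha[{d}]")
        est.append(f.draws["alpha"][:, i].mean())
    if "r" in f.draws:
        names.append("log_r")
        est.append(np.log(f.draws["r"]).mean())
    return names, np.asarray(est)


def empirical_coefficient_intervals(
    table: Sequence[SwitchRecord],
    spec: ModelSpec,
    n_refits: int = 20,
    seed: int = 0,
    refit_seeds: Optional[Sequence[int]] = None,
) -> CoefficientIntervals:
    """Refit the model ``n_refits`` times from random initializations and
    summarize each coefficient's point estimates by its 5th-95th percentile
    interval. Non-convergent refits are excluded and counted; more than 20%
    exclusions fails the run."""
    if n_refits < 20:
        raise ValueError("n_refits must be >= 20 for stable 90% intervals")
    if refit_seeds is None:
        refit_seeds = fork_seeds(seed, n_refits, label="refits")
    names, rows, excluded = None, [], 0
    for s in refit_seeds:
        f = fit_model(table, spec, seed=int(s))
        if not f.converged:
            excluded += 1
            continue
        names, est = _coefficient_vector(f)
        rows.append(est)
    if excluded > 0.2 * n_refits:
        raise RuntimeError(
            f"{excluded}/{n_refits} refits failed convergence; "
            "the empirical intervals are unreliable"
        )
    est = np.stack(rows)
    lo, hi = np.percentile(est, [5, 95], axis=0)
    return CoefficientIntervals(
        names=names, lower=lo, upper=hi, estimates=est,
        n_refits=n_refits, n_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# growth monitoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthCut:
    cut: int
    n_patients: int
    n_rows: int
    c_index_in: Optional[float]
    c_index_out: Optional[float]
    delta_in: float
    delta_out: float
    median_span: float
    spans: dict[str, float]


@dataclass(frozen=True)
class GrowthReport:
    outcome: str
    cuts: list[GrowthCut]

    @property
    def median_spans(self) -> list[float]:
        return [c.median_span for c in self.cuts]


def monitor_growth(
    series: Sequence[Sequence[PatientRecord]],
    spec: ModelSpec,
    eval_cohort: Sequence[PatientRecord],
    build_config: Optional[BuildConfig] = None,
    n_refits: int = 20,
    seed: int = 0,
    refit_spec: Optional[ModelSpec] = None,
) -> GrowthReport:
    """Track model quality across accruing data cuts, first cut as reference.

    For each cut: fit the model, measure the C-index in-sample and on a fixed
    held-out evaluation cohort (out-of-sample), and compute empirical
    coefficient intervals. Deltas are reported against the first cut. The
    refit seed stream and the performance-fit seed are shared across cuts
    (paired design), so cut-to-cut changes reflect data growth rather than
    Monte-Carlo noise.
    """
    if len(series) < 3:
        raise ValueError("need >= 3 data cuts to monitor a trend")
    build_config = build_config or BuildConfig(catalogue=spec.catalogue)
    eval_table = build_switch_table(eval_cohort, build_config)
    if refit_spec is None:
        # interval refits only feed point estimates, so they use shorter
        # chains with a looser R-hat gate that still catches divergence;
        # the shared seed stream keeps the chain noise paired across cuts
        refit_spec = spec.replace(
            sampler=spec.sampler.reduced(),
            rhat_threshold=max(spec.rhat_threshold, 1.3),
        )
    refit_seeds = fork_seeds(seed, n_refits, label="refits")
    perf_seed = fork_seeds(seed, 1, label="perf")[0]

    cuts: list[GrowthCut] = []
    ref_in = ref_out = None
    for k, cohort in enumerate(series):
        table = build_switch_table(cohort, build_config)
        f = fit_model(table, spec, seed=perf_seed)
        m_in = goodness_of_fit(f, table)
        m_out = goodness_of_fit(f, eval_table)
        ci = empirical_coefficient_intervals(
            table, refit_spec, n_refits=n_refits, refit_seeds=refit_seeds
        )
        if k == 0:
            ref_in, ref_out = m_in.c_index, m_out.c_index
        cuts.append(
            GrowthCut(
                cut=k,
                n_patients=len(cohort),
                n_rows=len(table),
                c_index_in=m_in.c_index,
                c_index_out=m_out.c_index,
                delta_in=(m_in.c_index or 0) - (ref_in or 0),
                delta_out=(m_out.c_index or 0) - (ref_out or 0),
                median_span=ci.median_span,
                spans=dict(zip(ci.names, ci.span.tolist())),
            )
        )
    return GrowthReport(outcome=spec.outcome, cuts=cuts)
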