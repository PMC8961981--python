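"""Hierarchical Bayesian outcome models for post-switch RRMS outcomes.

Two generalized linear models, one per endpoint:

* **Relapse model** — the relapse count ``y_i`` observed over an exposure of
  ``t_i`` months follows a negative binomial with mean
  ``mu_i = exp(x_i' beta + alpha_{d(i)} + log t_i)`` and dispersion ``r``
  (variance ``mu + mu^2 / r``). The probability of staying relapse-free over
  a horizon ``h`` is the posterior zero-count probability
  ``(r / (r + mu(h)))^r``.
* **3mCDP model** — the binary confirmed-progression indicator follows a
  Bernoulli with complementary-log-log link and log-exposure offset,
  ``P(event) = 1 - exp(-t * exp(x' beta' + alpha'_d))``, a discrete
  proportional-hazards formulation that makes varying observation time
  principled for a binary endpoint. A plain-logit variant with log-exposure
  as a covariate is available via ``ModelSpec.cdp_link``.

Therapy effects ``alpha_d`` are partially pooled across the DMT catalogue
(non-centred parameterization, boundary-avoiding pooling scale); newly introduced
therapies with sparse data can be given informative priors via
``ModelSpec.dmt_prior_overrides``.

Posteriors are sampled with an ensemble sampler (emcee, affine-invariant
stretch moves) initialized from a ball around a maximum-likelihood GLM
estimate; split-chain R-hat over walkers is stored as the convergence
diagnostic.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .catalogue import CatalogueError, DMTCatalogue, default_catalogue
from .registry import PredictorVector, SwitchRecord
from .util import fork_seeds

_CONTINUOUS = (
    "age",
    "edss",
    "current_dmt_duration",
    "n_previous_dmts",
    "time_since_diagnosis",
    "relapses_last_12m",
    "time_since_last_relapse",
)
_BINARY = ("sex_male", "any_previous_second_line")

MIN_HORIZON_MONTHS = 24.0
MAX_HORIZON_MONTHS = 72.0


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerSettings:
    walkers: Optional[int] = None  # default: max(32, 2*ndim + 2), even
    steps: int = 1600  # post-warmup steps (before thinning)
    burn: int = 1000
    thin: int = 4
    seed: int = 0
    init_jitter: float = 1.0  # init ball radius in GLM standard-error units

    def reduced(self, factor: float = 0.4) -> "SamplerSettings":
        """Shorter chains for many-refit procedures where only posterior
        means enter; pair with a looser R-hat gate."""
        return dataclasses.replace(
            self,
            steps=max(200, int(self.steps * factor)),
            burn=max(200, int(self.burn * factor)),
        )


@dataclass(frozen=True)
class ModelSpec:
    outcome: str  # "relapse" | "cdp"
    catalogue: DMTCatalogue = field(default_factory=default_catalogue)
    cdp_link: str = "cloglog"  # "cloglog" | "logit_exposure"
    beta_prior_scale: float = 2.5
    intercept_prior_scale: float = 5.0
    tau_prior_scale: float = 1.0  # Gamma(2, 1/scale) prior on the pooling SD
    log_dispersion_prior: tuple[float, float] = (0.0, 1.5)
    #: informative priors for sparse/new DMTs: dmt_id -> (location, scale)
    dmt_prior_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    rhat_threshold: float = 1.15

    def __post_init__(self):
        if self.outcome not in ("relapse", "cdp"):
            raise ModelError(f"outcome must be 'relapse' or 'cdp', got {self.outcome!r}")
        if self.cdp_link not in ("cloglog", "logit_exposure"):
            raise ModelError(f"unknown cdp_link {self.cdp_link!r}")

    def replace(self, **kw) -> "ModelSpec":
        return dataclasses.replace(self, **kw)

    def scale_priors(self, factor: float) -> "ModelSpec":
        """All prior scales multiplied by ``factor`` (robustness checks)."""
        loc, sc = self.log_dispersion_prior
        return self.replace(
            beta_prior_scale=self.beta_prior_scale * factor,
            intercept_prior_scale=self.intercept_prior_scale * factor,
            tau_prior_scale=self.tau_prior_scale * factor,
            log_dispersion_prior=(loc, sc * factor),
        )


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMeta:
    columns: list[str]
    standardization: dict[str, tuple[float, float]]  # col -> (mean, sd)
    current_dmt_ref: str
    current_dmt_levels: list[str]  # non-reference levels, design order
    dmt_levels: list[str]  # assigned-therapy levels with hierarchical effects
    quantiles: dict[str, list[float]]  # training percentile grid (0..100)
    binary_prevalence: dict[str, float]

    def to_json(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "DesignMeta":
        d = dict(d)
        d["standardization"] = {k: tuple(v) for k, v in d["standardization"].items()}
        return cls(**d)


def _raw_features(pv: PredictorVector) -> dict[str, float]:
    x = pv.as_dict()
    x["sex_male"] = 1.0 if pv.sex == "male" else 0.0
    x["any_previous_second_line"] = float(pv.any_previous_second_line)
    return x


def build_design(
    table: Sequence[SwitchRecord], catalogue: DMTCatalogue
) -> tuple[np.ndarray, np.ndarray, DesignMeta]:
    """Build the standardized design matrix and assigned-DMT index.

    Continuous predictors are standardized by training mean/SD; the
    discontinued therapy enters as one-hot columns against the most frequent
    level; sex and prior-second-line are 0/1 indicators. Returns
    ``(X, dmt_index, meta)``.
    """
    if not table:
        raise ModelError("empty training table")
    raw = {k: np.array([_raw_features(r.predictors)[k] for r in table], float)
           for k in _CONTINUOUS + _BINARY}
    cur = [r.predictors.current_dmt for r in table]
    assigned = [r.assigned_dmt for r in table]

    for d in set(cur) | set(assigned):
        if d not in catalogue:
            raise CatalogueError(f"unknown DMT {d!r}; catalogue has {catalogue.ids}")

    dmt_levels = [d for d in catalogue.ids if d in set(assigned)]
    if len(dmt_levels) < 2:
        raise ModelError(
            f"need >= 2 assigned-DMT levels for a hierarchical fit, got {dmt_levels}"
        )
    level_ix = {d: i for i, d in enumerate(dmt_levels)}
    d_idx = np.array([level_ix[d] for d in assigned])

    counts = {d: cur.count(d) for d in set(cur)}
    ref = max(sorted(counts), key=counts.get)
    cur_levels = [d for d in catalogue.ids if d in counts and d != ref]

    cols, data, standardization = [], [], {}
    for k in _CONTINUOUS:
        sd = float(raw[k].std())
        mean = float(raw[k].mean())
        if sd < 1e-12:
            raise ModelError(f"degenerate design: column {k!r} is constant")
        cols.append(k)
        data.append((raw[k] - mean) / sd)
        standardization[k] = (mean, sd)
    for k in _BINARY:
        cols.append(k)
        data.append(raw[k])
    for d in cur_levels:
        cols.append(f"current_dmt[{d}]")
        data.append(np.array([1.0 if c == d else 0.0 for c in cur]))

    X = np.column_stack(data)
    _check_collinearity(X, cols)

    grid = list(range(101))
    quantiles = {k: np.percentile(raw[k], grid).tolist() for k in _CONTINUOUS}
    prevalence = {k: float(raw[k].mean()) for k in _BINARY}

    meta = DesignMeta(
        columns=cols,
        standardization=standardization,
        current_dmt_ref=ref,
        current_dmt_levels=cur_levels,
        dmt_levels=dmt_levels,
        quantiles=quantiles,
        binary_prevalence=prevalence,
    )
    return X, d_idx, meta


def _check_collinearity(X: np.ndarray, cols: list[str]) -> None:
    # QR with column pivoting flags (near-)dependent columns by name
    _, s, vt = np.linalg.svd(X - X.mean(0), full_matrices=False)
    bad = s < 1e-8 * s[0]
    if bad.any():
        involved = set()
        for row in vt[bad]:
            involved.update(np.array(cols)[np.abs(row) > 0.3].tolist())
        raise ModelError(f"degenerate design: collinear columns {sorted(involved)}")


def design_row(meta: DesignMeta, pv: PredictorVector) -> np.ndarray:
    x = _raw_features(pv)
    out = np.empty(len(meta.columns))
    for j, c in enumerate(meta.columns):
        if c in meta.standardization:
            m, s = meta.standardization[c]
            out[j] = (x[c] - m) / s
        elif c in _BINARY:
            out[j] = x[c]
        else:  # current_dmt dummy
            level = c[len("current_dmt[") : -1]
            out[j] = 1.0 if pv.current_dmt == level else 0.0
    return out


# ---------------------------------------------------------------------------
# log posterior
# ---------------------------------------------------------------------------

class _Posterior:
    """Vectorized log posterior over an ensemble of parameter vectors.

    Parameter layout: ``[b0, beta(p), a_raw(k), log_tau, (gamma), (log_r)]``
    where ``gamma`` only exists for the logit-exposure CDP link and ``log_r``
    only for the relapse model. Therapy effects are non-centred
    (``alpha_d = tau * a_raw_d``), which keeps the geometry sampler-friendly
    when the data only weakly identify the pooling scale; DMTs with
    informative-prior overrides use ``loc_d + scale_d * a_raw_d`` with a
    fixed scale instead.
    """

    def __init__(self, X, d_idx, y, exposure, spec: ModelSpec, meta: DesignMeta):
        self.X = X
        self.d_idx = d_idx
        self.y = y.astype(float)
        self.log_t = np.log(exposure)
        self.spec = spec
        self.k = len(meta.dmt_levels)
        self.p = X.shape[1]
        self.kind = spec.outcome
        self.link = spec.cdp_link
        self.has_gamma = self.kind == "cdp" and self.link == "logit_exposure"
        self.has_r = self.kind == "relapse"
        self.ndim = 1 + self.p + self.k + 1 + int(self.has_gamma) + int(self.has_r)

        loc = np.zeros(self.k)
        scale_override = np.full(self.k, np.nan)
        for i, d in enumerate(meta.dmt_levels):
            if d in spec.dmt_prior_overrides:
                loc[i], scale_override[i] = spec.dmt_prior_overrides[d]
        self.alpha_loc = loc
        self.alpha_scale_override = scale_override
        self.pooled = np.isnan(scale_override)

        if self.kind == "relapse":
            ymax = int(self.y.max())
            # m_j = #{i : y_i > j}; sum_i log Gamma(y_i+r)/Gamma(r) = sum_j m_j log(r+j)
            self.count_tail = np.array(
                [np.sum(self.y > j) for j in range(ymax)], float
            )
            self.count_js = np.arange(ymax, dtype=float)
            self.lgamma_y1 = float(special.gammaln(self.y + 1).sum())

    def unpack(self, theta: np.ndarray):
        theta = np.atleast_2d(theta)
        i = 0
        b0 = theta[:, i]; i += 1
        beta = theta[:, i : i + self.p]; i += self.p
        a_raw = theta[:, i : i + self.k]; i += self.k
        log_tau = theta[:, i]; i += 1
        gamma = theta[:, i] if self.has_gamma else None
        if self.has_gamma:
            i += 1
        log_r = theta[:, i] if self.has_r else None
        return b0, beta, a_raw, log_tau, gamma, log_r

    def alpha(self, a_raw: np.ndarray, log_tau: np.ndarray) -> np.ndarray:
        tau = np.exp(log_tau)[:, None]
        scale = np.where(self.pooled, tau, self.alpha_scale_override)
        return self.alpha_loc[None, :] + scale * a_raw

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        squeeze = theta.ndim == 1
        b0, beta, a_raw, log_tau, gamma, log_r = self.unpack(theta)
        alpha = self.alpha(a_raw, log_tau)

        eta = self.X @ beta.T + b0[None, :] + alpha.T[self.d_idx, :]  # (n, W)
        lp = self._log_prior(b0, beta, a_raw, log_tau, gamma, log_r)

        if self.kind == "relapse":
            r = np.exp(np.clip(log_r, -10, 10))
            # clip eta once and reuse it: clipping only inside exp() would
            # break the y*eta - y*log(r+mu) cancellation and make the
            # likelihood unbounded for runaway linear predictors
            eta = np.clip(eta + self.log_t[:, None], -30, 30)
            mu = np.exp(eta)
            log_rmu = np.log(r[None, :] + mu)
            ll = (
                self.y @ eta
                - (self.y[:, None] * log_rmu).sum(0)
                - r * log_rmu.sum(0)
                + self.y.size * r * np.log(r)
                - self.lgamma_y1
            )
            if self.count_tail.size:
                ll += np.log(r[:, None] + self.count_js[None, :]) @ self.count_tail
        else:
            if self.has_gamma:
                eta = eta + gamma[None, :] * self.log_t[:, None]
                pev = special.expit(np.clip(eta, -30, 30))
                pev = np.clip(pev, 1e-12, 1 - 1e-12)
                ll = self.y @ np.log(pev) + (1 - self.y) @ np.log1p(-pev)
            else:
                lam = np.exp(np.clip(eta + self.log_t[:, None], -30, 30))
                lam = np.maximum(lam, 1e-12)
                log_pev = np.log(-np.expm1(-lam))
                ll = self.y @ log_pev - (1 - self.y) @ lam

        out = lp + ll
        out[~np.isfinite(out)] = -1e300
        return out[0] if squeeze else out

    def _log_prior(self, b0, beta, a_raw, log_tau, gamma, log_r) -> np.ndarray:
        s = self.spec
        lp = -0.5 * (b0 / s.intercept_prior_scale) ** 2
        lp = lp - 0.5 * ((beta / s.beta_prior_scale) ** 2).sum(1)
        lp = lp - 0.5 * (a_raw**2).sum(1)
        tau = np.exp(log_tau)
        # boundary-avoiding Gamma(2, 1/scale) on tau (density -> 0 at tau = 0,
        # so the pooling scale cannot collapse and over-shrink the per-DMT
        # contrasts when only a handful of therapies inform it), plus the
        # log-Jacobian of the log transform
        lp = lp + 2.0 * log_tau - tau / s.tau_prior_scale
        if gamma is not None:
            lp = lp - 0.5 * (gamma / 2.0) ** 2
        if log_r is not None:
            loc, sc = s.log_dispersion_prior
            lp = lp - 0.5 * ((log_r - loc) / sc) ** 2
        return lp


# ---------------------------------------------------------------------------
# posterior fit container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorFit:
    outcome: str
    cdp_link: str
    design: DesignMeta
    draws: dict[str, np.ndarray]  # b0 (S,), beta (S,p), alpha (S,k), tau, r?, gamma?
    max_rhat: float
    converged: bool
    acceptance_fraction: float
    n_train: int
    fingerprint: str
    spec: ModelSpec

    @property
    def n_draws(self) -> int:
        return self.draws["b0"].shape[0]

    # -- serialization ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "outcome": self.outcome,
            "cdp_link": self.cdp_link,
            "design": self.design.to_json(),
            "max_rhat": self.max_rhat,
            "converged": self.converged,
            "acceptance_fraction": self.acceptance_fraction,
            "n_train": self.n_train,
            "fingerprint": self.fingerprint,
            "catalogue": [
                {"id": e.id, "name": e.name, "line": e.line}
                for e in self.spec.catalogue
            ],
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))
        np.savez_compressed(directory / "draws.npz", **self.draws)

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorFit":
        from .catalogue import DMTCatalogue, DMTEntry

        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        draws = dict(np.load(directory / "draws.npz"))
        cat = DMTCatalogue(
            [DMTEntry(d["id"], d["name"], d["line"]) for d in meta["catalogue"]]
        )
        return cls(
            outcome=meta["outcome"],
            cdp_link=meta["cdp_link"],
            design=DesignMeta.from_json(meta["design"]),
            draws=draws,
            max_rhat=meta["max_rhat"],
            converged=meta["converged"],
            acceptance_fraction=meta["acceptance_fraction"],
            n_train=meta["n_train"],
            fingerprint=meta["fingerprint"],
            spec=ModelSpec(outcome=meta["outcome"], catalogue=cat,
                           cdp_link=meta["cdp_link"]),
        )

    # -- therapy-effect access ---------------------------------------------
    def alpha_draws(self, dmt_id: str) -> tuple[np.ndarray, bool]:
        """Posterior draws of the therapy effect; ``pooled_fallback`` is True
        when the DMT was absent from training and the draws come from the
        pooling distribution."""
        if dmt_id not in self.spec.catalogue:
            raise CatalogueError(
                f"unknown DMT {dmt_id!r}; catalogue has {self.spec.catalogue.ids}"
            )
        levels = self.design.dmt_levels
        if dmt_id in levels:
            return self.draws["alpha"][:, levels.index(dmt_id)], False
        seed = int.from_bytes(
            (self.fingerprint + dmt_id).encode()[:4].ljust(4, b"\0"), "big"
        ) % (2**31 - 1)
        z = np.random.default_rng(seed).standard_normal(self.n_draws)
        return self.draws["tau"] * z, True


def _fingerprint(y, exposure) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(np.asarray(y, float).tobytes())
    h.update(np.round(np.asarray(exposure, float), 6).tobytes())
    return h.hexdigest()[:12]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit(
    table: Sequence[SwitchRecord], spec: ModelSpec, seed: Optional[int] = None
) -> PosteriorFit:
    """Fit one outcome model and return posterior draws.

    ``seed`` (default ``spec.sampler.seed``) drives both the random walker
    initialization and the chain; refitting with a different seed realises
    the "randomly sampled initialization" used for empirical coefficient
    intervals. Non-convergent fits (split R-hat above the configured
    threshold) are returned but flagged via ``converged=False``.
    """
    import emcee

    X, d_idx, meta = build_design(table, spec.catalogue)
    y = np.array(
        [r.relapse_count if spec.outcome == "relapse" else int(r.cdp_event) for r in table],
        float,
    )
    exposure = np.array([r.exposure_months for r in table], float)
    if np.any(exposure <= 0):
        raise ModelError("all rows must have positive exposure")

    post = _Posterior(X, d_idx, y, exposure, spec, meta)
    seed = spec.sampler.seed if seed is None else seed
    init_seed, chain_seed = fork_seeds(seed, 2, label="fit")

    theta_map, scales = _map_estimate(post, y, exposure)

    st = spec.sampler
    nwalkers = st.walkers or max(32, 2 * post.ndim + 2)
    nwalkers += nwalkers % 2
    rng = np.random.default_rng(init_seed)
    init = theta_map[None, :] + st.init_jitter * scales[None, :] * rng.standard_normal(
        (nwalkers, post.ndim)
    )
    lp0 = post(init)
    bad = ~np.isfinite(lp0) | (lp0 < post(theta_map) - 1e6)
    while bad.any():
        init[bad] = 0.5 * (init[bad] + theta_map[None, :])
        bad = ~np.isfinite(post(init))

    # Affine-invariant stretch moves. A differential-evolution move mixture
    # was tried first but equilibrated ~15-20% too narrow on these GLM-like
    # posteriors (ensemble spread feeds back into the DE proposal scale);
    # stretch moves reproduce the Laplace/MLE posterior widths exactly.
    moves = [(emcee.moves.StretchMove(), 1.0)]
    sampler = emcee.EnsembleSampler(
        nwalkers, post.ndim, post, vectorize=True, moves=moves
    )
    sampler._random = np.random.RandomState(chain_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sampler.run_mcmc(init, st.burn + st.steps, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=st.burn, thin=st.thin)  # (T, W, D)

    max_rhat = _split_rhat(chain)
    flat = chain.reshape(-1, post.ndim)
    b0, beta, a_raw, log_tau, gamma, log_r = post.unpack(flat)
    draws = {
        "b0": b0,
        "beta": beta,
        "alpha": post.alpha(a_raw, log_tau),
        "tau": np.exp(log_tau),
    }
    if log_r is not None:
        draws["r"] = np.exp(log_r)
    if gamma is not None:
        draws["gamma"] = gamma

    return PosteriorFit(
        outcome=spec.outcome,
        cdp_link=spec.cdp_link,
        design=meta,
        draws=draws,
        max_rhat=float(max_rhat),
        converged=bool(max_rhat <= spec.rhat_threshold),
        acceptance_fraction=float(sampler.acceptance_fraction.mean()),
        n_train=len(table),
        fingerprint=_fingerprint(y, exposure),
        spec=spec,
    )


def _map_estimate(post: _Posterior, y, exposure) -> tuple[np.ndarray, np.ndarray]:
    """Starting point and per-parameter scales for the walker initialization.

    A maximum-likelihood GLM (per-DMT intercepts, no global intercept, so the
    fit is identified without the pooling prior) provides the center and its
    standard errors the scales; a BFGS pass on the log posterior is the
    fallback when the GLM does not converge.
    """
    try:
        return _glm_estimate(post, y, exposure)
    except Exception:
        x0 = np.zeros(post.ndim)
        rate = max(y.sum(), 0.5) / exposure.sum()
        if post.kind == "relapse":
            x0[0] = np.log(rate)
            x0[-1] = 0.4  # log r
        else:
            x0[0] = np.log(max(-np.log1p(-min(y.mean(), 0.95)) / exposure.mean(), 1e-6))
        x0[1 + post.p + post.k] = np.log(0.3)  # log tau
        neg = lambda t: -post(t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(neg, x0, method="BFGS",
                                    options={"maxiter": 200, "gtol": 1e-4})
        hinv = np.asarray(res.hess_inv)
        scales = np.sqrt(np.clip(np.diag(hinv), 1e-6, 1.0))
        return res.x, scales


def _glm_estimate(post: _Posterior, y, exposure) -> tuple[np.ndarray, np.ndarray]:
    import statsmodels.api as sm

    n, k = post.X.shape[0], post.k
    D = np.zeros((n, k))
    D[np.arange(n), post.d_idx] = 1.0
    XX = np.column_stack([D, post.X])
    offset = post.log_t.copy()
    if post.kind == "relapse":
        family = sm.families.Poisson()
    elif post.has_gamma:
        family = sm.families.Binomial()
        XX = np.column_stack([XX, post.log_t])
        offset = None
    else:
        family = sm.families.Binomial(link=sm.genmod.families.links.CLogLog())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, XX, family=family, offset=offset).fit(maxiter=100)
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise RuntimeError("GLM initialization failed")

    c = res.params[:k]  # per-DMT intercepts
    beta = res.params[k : k + post.p]
    b0 = float(c.mean())
    alpha = c - b0
    # initial pooling scale from the spread of the ML therapy effects; the
    # non-centred raw effects are alpha / tau0
    tau0 = float(np.clip(np.std(alpha), 0.1, 1.0))

    theta = np.zeros(post.ndim)
    scales = np.full(post.ndim, 0.1)
    theta[0] = b0
    scales[0] = float(np.sqrt((res.bse[:k] ** 2).mean()))
    theta[1 : 1 + post.p] = beta
    scales[1 : 1 + post.p] = res.bse[k : k + post.p]
    raw = alpha.copy()
    raw[post.pooled] = alpha[post.pooled] / tau0
    ov = ~post.pooled
    if ov.any():
        raw[ov] = (alpha[ov] - post.alpha_loc[ov]) / post.alpha_scale_override[ov]
    theta[1 + post.p : 1 + post.p + k] = raw
    scales[1 + post.p : 1 + post.p + k] = np.clip(res.bse[:k] / tau0, None, 1.0)
    theta[1 + post.p + k] = np.log(tau0)
    scales[1 + post.p + k] = 0.4
    i = 1 + post.p + k + 1
    if post.has_gamma:
        theta[i] = res.params[-1]
        scales[i] = res.bse[-1]
        i += 1
    if post.has_r:
        # Pearson-moment dispersion from the Poisson fit: alpha_nb = 1/r
        mu = res.fittedvalues
        a_nb = float(np.sum(((y - mu) ** 2 - y) / mu) / mu.sum())
        theta[i] = -np.log(np.clip(a_nb, 0.05, 10.0))
        scales[i] = 0.15
    return theta, np.clip(scales, 1e-3, 1.0)


def _split_rhat(chain: np.ndarray) -> float:
    """Split R-hat over the two halves of the sampling period.

    ``chain`` is (steps, walkers, dim). Each half is flattened across
    walkers, so the statistic compares the ensemble's estimates from the
    first and second half of the run: unfinished burn-in, drift, or stuck
    subsets of walkers inflate it. Individual walkers in an affine-invariant
    ensemble wander slowly by design and are not treated as independent
    chains.
    """
    import arviz as az

    half = chain.shape[0] // 2
    a = chain[:half].reshape(-1, chain.shape[2])
    b = chain[chain.shape[0] - half :].reshape(-1, chain.shape[2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(np.stack([a, b]))
        return float(az.rhat(ds).x.max())


# ---------------------------------------------------------------------------
# event-free probabilities
# ---------------------------------------------------------------------------

def nb_zero_prob(mu, r):
    """P(count = 0) for a negative binomial with mean ``mu``, dispersion ``r``.

    ``(r / (r + mu))^r``; tends to ``exp(-mu)`` (Poisson) as ``r`` grows and
    to 1 as ``mu -> 0``.
    """
    mu = np.asarray(mu, float)
    r = np.asarray(r, float)
    return np.exp(r * (np.log(r) - np.log(r + mu)))


@dataclass(frozen=True)
class EventFreePrediction:
    dmt_id: str
    outcome: str
    horizon_months: float
    probability: float
    ci90: tuple[float, float]
    pooled_fallback: bool = False


def _eta_draws(fit: PosteriorFit, x: np.ndarray, dmt_id: str):
    alpha, pooled = fit.alpha_draws(dmt_id)
    eta = fit.draws["b0"] + fit.draws["beta"] @ x + alpha
    return eta, pooled


def event_free_draws(
    fit: PosteriorFit, x: np.ndarray, dmt_id: str, horizon_months: float
) -> tuple[np.ndarray, bool]:
    """Per-draw event-free probability for one patient row (design scale)."""
    if horizon_months < 0:
        raise ModelError("horizon must be >= 0")
    eta, pooled = _eta_draws(fit, x, dmt_id)
    if horizon_months == 0:
        return np.ones_like(eta), pooled
    if fit.outcome == "relapse":
        mu = np.exp(eta + np.log(horizon_months))
        p = nb_zero_prob(mu, fit.draws["r"])
    elif fit.cdp_link == "logit_exposure":
        p = 1.0 - special.expit(eta + fit.draws["gamma"] * np.log(horizon_months))
    else:
        p = np.exp(-np.exp(eta + np.log(horizon_months)))
    return p, pooled


def prob_event_free(
    fit: PosteriorFit, x: PredictorVector, dmt_id: str, horizon_months: float
) -> EventFreePrediction:
    """Posterior event-free probability with a 90% credible interval.

    The point estimate is the posterior mean of the per-draw probability;
    the interval spans its 5th-95th percentiles.
    """
    row = design_row(fit.design, x)
    p, pooled = event_free_draws(fit, row, dmt_id, horizon_months)
    lo, hi = np.percentile(p, [5, 95])
    return EventFreePrediction(
        dmt_id=dmt_id,
        outcome=fit.outcome,
        horizon_months=float(horizon_months),
        probability=float(p.mean()),
        ci90=(float(lo), float(hi)),
        pooled_fallback=pooled,
    )


# ---------------------------------------------------------------------------
# per-predictor contribution breakdown
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contribution:
    predictor: str
    value: float  # covariate value on its natural scale (or 0/1)
    contribution: float  # posterior-mean coefficient x deviation from reference
    percentile: Optional[float]  # position within the training distribution


@dataclass(frozen=True)
class Explanation:
    contributions: list[Contribution]
    therapy_effect: float
    intercept: float

    @property
    def total(self) -> float:
        """Linear predictor minus intercept (excluding the offset)."""
        return sum(c.contribution for c in self.contributions) + self.therapy_effect


def explain_prediction(
    fit: PosteriorFit, x: PredictorVector, dmt_id: str
) -> Explanation:
    """Additive decomposition of the linear predictor into per-predictor terms.

    Each term is the posterior-mean coefficient times the covariate's
    deviation from its reference (training mean for continuous predictors,
    reference category otherwise), so the terms sum to the linear predictor
    minus the intercept. Percentiles locate the patient within the training
    distribution.
    """
    row = design_row(fit.design, x)
    beta_mean = fit.draws["beta"].mean(0)
    raw = _raw_features(x)
    out = []
    for j, col in enumerate(fit.design.columns):
        contrib = float(beta_mean[j] * row[j])
        if col in fit.design.standardization:
            q = np.asarray(fit.design.quantiles[col])
            pct = float(np.interp(raw[col], q, np.arange(101), left=0, right=100))
            out.append(Contribution(col, float(raw[col]), contrib, pct))
        elif col in _BINARY:
            out.append(Contribution(col, float(raw[col]), contrib,
                                    100.0 * fit.design.binary_prevalence[col]))
        else:
            out.append(Contribution(col, row[j], contrib, None))
    alpha, _ = fit.alpha_draws(dmt_id)
    return Explanation(
        contributions=out,
        therapy_effect=float(alpha.mean()),
        intercept=float(fit.draws["b0"].mean()),
    )
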