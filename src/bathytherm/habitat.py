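"""Quadratic logistic bathythermal habitat model.

The presence model is a Bernoulli GLM on the logit scale,

    logit(p) = b0 + b1*SST + b2*SST^2 + b3*Depth + b4*Depth^2,

fitted by maximum likelihood with Newton/IRLS iterations (step-halved so
the log-likelihood never decreases). Covariates are standardised internally
for numerical conditioning and estimates are reported back in natural units
(degrees C, metres). Model selection follows forward stepwise search on AIC
subject to also increasing the percent deviance explained, respecting the
quadratic hierarchy (a squared term may only enter alongside its linear
term). Diagnostics use Dunn-Smyth randomized quantile residuals, which are
standard normal under a correctly specified model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "HabitatFit",
    "TERM_ORDER",
    "fit_logistic",
    "deviance_explained",
    "forward_stepwise",
    "predict_probability",
    "quantile_residuals",
]

TERM_ORDER = ("sst", "sst2", "depth", "depth2")
_HIERARCHY = {"sst2": "sst", "depth2": "depth"}


@dataclass
class HabitatFit:
    """A fitted Bernoulli GLM on (a subset of) the quadratic terms.

    ``beta``/``cov`` are in natural covariate units, ordered (intercept,
    *terms). ``pct_deviance_explained`` is relative to the intercept-only
    model on the same rows.
    """

    terms: tuple[str, ...]
    beta: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    aic: float
    null_deviance: float
    residual_deviance: float
    pct_deviance_explained: float
    converged: bool
    n_obs: int
    n_iter: int

    def coef(self, name: str) -> float:
        names = ("intercept",) + self.terms
        return float(self.beta[names.index(name)])

    @property
    def beta_full(self) -> np.ndarray:
        """(b0..b4) with zeros for terms not in the model."""
        out = np.zeros(5)
        out[0] = self.beta[0]
        for j, t in enumerate(self.terms, start=1):
            out[1 + TERM_ORDER.index(t)] = self.beta[j]
        return out

    @property
    def peak_sst(self) -> float:
        b = self.beta_full
        if b[2] >= 0:
            return float("nan")
        return -b[1] / (2.0 * b[2])

    @property
    def peak_depth(self) -> float:
        b = self.beta_full
        if b[4] >= 0:
            return float("nan")
        return -b[3] / (2.0 * b[4])

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def to_dict(self) -> dict:
        names = ("intercept",) + self.terms
        return {
            "terms": list(self.terms),
            "beta": {n: float(b) for n, b in zip(names, self.beta)},
            "se": {n: float(s) for n, s in zip(names, self.standard_errors())},
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "null_deviance": self.null_deviance,
            "residual_deviance": self.residual_deviance,
            "pct_deviance_explained": self.pct_deviance_explained,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def _design_matrix(table: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    sst = table["sst_c"].to_numpy(dtype=float)
    depth = table["depth_m"].to_numpy(dtype=float)
    cols = {"sst": sst, "sst2": sst**2, "depth": depth, "depth2": depth**2}
    x = np.column_stack([np.ones(len(table))] + [cols[t] for t in terms])
    return x


def _check_hierarchy(terms) -> tuple[str, ...]:
    terms = tuple(terms)
    unknown = set(terms) - set(TERM_ORDER)
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}")
    for t in terms:
        parent = _HIERARCHY.get(t)
        if parent is not None and parent not in terms:
            raise ValueError(f"hierarchy violation: {t} requires {parent}")
    return tuple(t for t in TERM_ORDER if t in terms)


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    table: pd.DataFrame,
    terms=TERM_ORDER,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> HabitatFit:
    """Maximum-likelihood fit of the Bernoulli GLM on the requested terms.

    Newton/IRLS on internally standardised covariates with step-halving;
    convergence requires the score norm (standardised scale) below ``tol``
    and a positive-definite negative Hessian. Perfect separation manifests
    as divergence and is flagged via ``converged=False``.
    """
    terms = _check_hierarchy(terms)
    y = table["y"].to_numpy(dtype=float)
    n = len(y)
    if n == 0 or y.sum() == 0 or y.sum() == n:
        raise ValueError("need at least one presence and one absence")
    x_nat = _design_matrix(table, terms)
    p_dim = x_nat.shape[1]

    # standardise non-intercept columns
    mu = x_nat[:, 1:].mean(axis=0) if p_dim > 1 else np.empty(0)
    sd = x_nat[:, 1:].std(axis=0) if p_dim > 1 else np.empty(0)
    sd = np.where(sd > 0, sd, 1.0)
    x = x_nat.copy()
    if p_dim > 1:
        x[:, 1:] = (x_nat[:, 1:] - mu) / sd

    beta = np.zeros(p_dim)
    beta[0] = np.log(y.mean() / (1.0 - y.mean()))
    ll = _bernoulli_loglik(y, x @ beta)
    converged = False
    it = 0
    info = np.eye(p_dim)
    for it in range(1, max_iter + 1):
        eta = x @ beta
        p = expit(eta)
        score = x.T @ (y - p)
        w = p * (1.0 - p)
        info = x.T @ (x * w[:, None])
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving: never let the log-likelihood decrease
        lam = 1.0
        for _ in range(60):
            cand = beta + lam * step
            ll_new = _bernoulli_loglik(y, x @ cand)
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        ll = _bernoulli_loglik(y, x @ beta)
    else:
        it = max_iter
    eta = x @ beta
    p = expit(eta)
    score = x.T @ (y - p)
    if np.max(np.abs(score)) < tol:
        converged = True
    # require a positive-definite negative Hessian
    try:
        np.linalg.cholesky(info + 1e-300 * np.eye(p_dim))
    except np.linalg.LinAlgError:
        converged = False
    if not converged:
        warnings.warn("logistic fit did not converge (possible separation)")

    # back-transform to natural units: beta_nat = A beta_std
    a = np.eye(p_dim)
    if p_dim > 1:
        a[0, 1:] = -mu / sd
        for j in range(1, p_dim):
            a[j, j] = 1.0 / sd[j - 1]
    beta_nat = a @ beta
    try:
        cov_std = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_std = np.full((p_dim, p_dim), np.nan)
    cov_nat = a @ cov_std @ a.T
    cov_nat = 0.5 * (cov_nat + cov_nat.T)

    ll = _bernoulli_loglik(y, eta)
    resdev = -2.0 * ll
    pbar = y.mean()
    nulldev = -2.0 * n * (pbar * np.log(pbar) + (1.0 - pbar) * np.log(1.0 - pbar))
    pct = 100.0 * (1.0 - resdev / nulldev) if nulldev > 0 else float("nan")
    return HabitatFit(
        terms=terms,
        beta=beta_nat,
        cov=cov_nat,
        log_likelihood=ll,
        aic=-2.0 * ll + 2.0 * p_dim,
        null_deviance=nulldev,
        residual_deviance=resdev,
        pct_deviance_explained=pct,
        converged=converged,
        n_obs=n,
        n_iter=it,
    )


def deviance_explained(fit: HabitatFit, null_fit: HabitatFit) -> float:
    """Percent deviance explained of ``fit`` relative to ``null_fit``:
    100 * (1 - residual/null)."""
    if null_fit.residual_deviance <= 0:
        raise ValueError("null deviance is zero")
    return 100.0 * (1.0 - fit.residual_deviance / null_fit.residual_deviance)


def forward_stepwise(table: pd.DataFrame, candidate_terms=TERM_ORDER, tol: float = 1e-6):
    """Forward stepwise selection on AIC + percent deviance explained.

    Starting from the intercept-only model, at each step every
    hierarchy-admissible candidate is fitted; candidates qualify if they
    both lower the AIC and raise the deviance explained, and the
    lowest-AIC qualifier enters. Returns (selected fit, trace).
    """
    candidates = [t for t in TERM_ORDER if t in set(candidate_terms)]
    current: tuple[str, ...] = ()
    best = fit_logistic(table, current, tol=tol)
    trace = [
        {"step": 0, "added": None, "terms": (), "aic": best.aic,
         "pct_deviance_explained": best.pct_deviance_explained}
    ]
    step = 0
    while True:
        step += 1
        admissible = [
            t
            for t in candidates
            if t not in current and (_HIERARCHY.get(t) is None or _HIERARCHY[t] in current)
        ]
        tried = []
        qualifying = []
        for t in admissible:
            fit_t = fit_logistic(table, current + (t,), tol=tol)
            tried.append((t, fit_t))
            if fit_t.aic < best.aic and fit_t.pct_deviance_explained > best.pct_deviance_explained:
                qualifying.append((t, fit_t))
        if not qualifying:
            break
        t_add, fit_add = min(qualifying, key=lambda tf: tf[1].aic)
        current = fit_add.terms
        best = fit_add
        trace.append(
            {
                "step": step,
                "added": t_add,
                "terms": current,
                "aic": best.aic,
                "pct_deviance_explained": best.pct_deviance_explained,
                "candidates": {t: f.aic for t, f in tried},
            }
        )
    return best, trace


def predict_probability(fit: HabitatFit, sst, depth) -> np.ndarray:
    """Inverse-logit of the fitted linear predictor, vectorised over fields.

    NaN covariates (masked cells) propagate to NaN probabilities.
    """
    sst = np.asarray(sst, dtype=float)
    depth = np.asarray(depth, dtype=float)
    b = fit.beta_full
    eta = b[0] + b[1] * sst + b[2] * sst**2 + b[3] * depth + b[4] * depth**2
    return expit(eta)


def quantile_residuals(fit: HabitatFit, table: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """Dunn-Smyth randomized quantile residuals for the Bernoulli fit.

    For y = 0 the residual quantile is uniform on (0, 1-p); for y = 1 on
    (1-p, 1); the normal quantile of that draw is standard normal when the
    model is correctly specified.
    """
    if not fit.converged:
        warnings.warn("computing residuals for a non-converged fit")
    y = table["y"].to_numpy(dtype=float)
    p = predict_probability(fit, table["sst_c"].to_numpy(), table["depth_m"].to_numpy())
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=len(y))
    q = np.where(y == 0, u * (1.0 - p), (1.0 - p) + u * p)
    q = np.clip(q, 1e-12, 1.0 - 1e-12)
    return norm.ppf(q)
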