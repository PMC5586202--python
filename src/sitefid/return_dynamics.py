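"""Survival analysis of site returns: the self-attracting-walk signature.

Every visit of an ant to a site is followed either by a first return to
that site (an observed event) or by the end of observation (censored).
If movement were Markovian, the waiting time until return would not depend
on how long the ant dwelt at the site during the previous visit.  A Cox
proportional-hazards model with the return time as response and the dwell
time as predictor tests this: a hazard ratio above 1 per minute of dwell
means long stays are followed by fast returns -- the statistical signature
of a self-attracting walk, in which previously visited sites become more
attractive with each visit.  Caste, community membership and the brood
content of the site at the visit are included as additional predictors.

Fitting is done by an in-package Newton-Raphson partial-likelihood engine
(Efron or Breslow ties) with observed-information or cluster-robust
sandwich variances; the engine also supports the mixed-effects variant --
a log-normal shared frailty (per-ant or per-colony random intercept on the
log-hazard) -- by penalized partial likelihood with a Laplace-approximate
marginal likelihood for the frailty variance.  Plain fits are cross-checked
against statsmodels' proportional-hazards implementation in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .core_data import BROOD_STAGES, BroodCensus, GridSpec, brood_site_table
from .overlap_networks import CommunityPartition
from .site_fidelity import VisitRecord

__all__ = [
    "CoxFit",
    "build_visit_history",
    "fit_cox",
    "model_selection",
    "cox_partial_loglik",
    "cox_score_residuals",
]

BROOD_PREDICTORS = tuple(f"n_{stage}" for stage in BROOD_STAGES)
DEFAULT_PREDICTORS = ("dwell", "caste", "community") + BROOD_PREDICTORS


# ---------------------------------------------------------------------------
# Visit-history table
# ---------------------------------------------------------------------------


def build_visit_history(
    colony_visits: Mapping[str, Mapping[str, Sequence[VisitRecord]]],
    castes: Mapping[tuple[str, str], str],
    partitions: Mapping[str, CommunityPartition] | None = None,
    censuses: Mapping[str, BroodCensus] | None = None,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """One row per site visit, with censored return-time response.

    ``colony_visits`` maps colony -> ant -> visit records; ``castes`` maps
    (colony, ant) -> caste.  When ``partitions`` is given, colonies whose
    network could not be partitioned into >=2 communities are excluded (their
    ants cannot be labelled nurse/other) and each record carries community =
    1 for nurse, 0 otherwise.  When ``censuses`` and ``grid`` are given,
    per-stage brood counts at the visit's start tick are attached
    (latest-preceding census).
    """
    rows = []
    for colony, ants in colony_visits.items():
        part = None
        if partitions is not None:
            part = partitions.get(colony)
            if part is None or not part.partitioned:
                warnings.warn(
                    f"colony {colony}: no usable community partition; excluded",
                    stacklevel=2,
                )
                continue
        brood = None
        if censuses is not None and colony in censuses:
            if grid is None:
                raise ValueError("grid required for brood covariates")
            table = brood_site_table(censuses[colony], grid)
            cticks = np.sort(table["census_tick"].unique())
            brood = {
                (int(r["census_tick"]), int(r["site"])): tuple(
                    int(r[s]) for s in BROOD_STAGES
                )
                for _, r in table.iterrows()
            }
        for ant, visits in ants.items():
            caste = castes[(colony, ant)]
            community = None
            if part is not None:
                community = 1 if part.label_of(ant) == "nurse" else 0
            for v in visits:
                if v.censored:
                    time, event = v.censor_time, 0
                else:
                    time, event = v.return_time, 1
                row = {
                    "colony": colony,
                    "ant": ant,
                    "site": v.site,
                    "visit_k": v.k,
                    "time": float(time),
                    "event": event,
                    "dwell": float(v.dwell),
                    "caste": 1 if caste == "queen" else 0,
                }
                if community is not None:
                    row["community"] = community
                if brood is not None:
                    chosen = cticks[cticks <= v.start_tick]
                    use = int(chosen[-1]) if len(chosen) else int(cticks[0])
                    counts = brood.get((use, v.site), (0,) * len(BROOD_STAGES))
                    for name, c in zip(BROOD_PREDICTORS, counts):
                        row[name] = c
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Partial likelihood engine (used for the frailty mode and by the oracles)
# ---------------------------------------------------------------------------


def _prepare(X, time, event):
    order = np.argsort(-np.asarray(time, dtype=float), kind="stable")
    return (
        np.asarray(X, dtype=float)[order],
        np.asarray(time, dtype=float)[order],
        np.asarray(event, dtype=int)[order],
    )


def cox_partial_loglik(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    beta: np.ndarray,
    ties: str = "efron",
    derivatives: bool = False,
):
    """Cox log partial likelihood (Breslow or Efron ties), optionally with
    gradient and Hessian.  Rows need not be sorted."""
    X, time, event = _prepare(X, time, event)
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # affine shift cancels in every term; guards overflow
    w = np.exp(eta)
    wx = w[:, None] * X
    cw = np.cumsum(w)
    cwx = np.cumsum(wx, axis=0)
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)
    cwxx = np.cumsum(wxx, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j) if event[k]]
        d = len(d_idx)
        if d:
            # risk set = everything with time >= time[i] = rows [0, j)
            s0 = cw[j - 1]
            s1 = cwx[j - 1]
            s2 = cwxx[j - 1]
            ll += float(eta[d_idx].sum())
            if derivatives:
                grad += X[d_idx].sum(axis=0)
            if ties == "breslow":
                ll -= d * np.log(s0)
                if derivatives:
                    xb = s1 / s0
                    grad -= d * xb
                    hess -= d * (s2 / s0 - np.outer(xb, xb))
            elif ties == "efron":
                s0d = w[d_idx].sum()
                s1d = wx[d_idx].sum(axis=0)
                s2d = wxx[d_idx].sum(axis=0)
                for l in range(d):
                    f = l / d
                    a0 = s0 - f * s0d
                    ll -= np.log(a0)
                    if derivatives:
                        a1 = s1 - f * s1d
                        xb = a1 / a0
                        grad -= xb
                        hess -= (s2 - f * s2d) / a0 - np.outer(xb, xb)
            else:
                raise ValueError(f"unknown ties method {ties!r}")
        i = j
    if derivatives:
        return ll, grad, hess
    return ll


def cox_score_residuals(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    beta: np.ndarray,
    ties: str = "efron",
) -> np.ndarray:
    """Per-record score residuals (n x p), in the input row order.

    These are the building blocks of the cluster-robust sandwich variance;
    censored records earlier than the first event correctly contribute
    zero.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)

    # event-time groups in ascending order
    order = np.argsort(time, kind="stable")
    ts = time[order]
    event_times = np.unique(ts[event[order] == 1])
    U = np.zeros((n, p))
    # cumulative full-weight hazard-increment sums over event groups
    cum0 = np.zeros(len(event_times) + 1)
    cum1 = np.zeros((len(event_times) + 1, p))
    group_info = []
    for g, t in enumerate(event_times):
        at_risk = time >= t
        d_idx = np.flatnonzero((time == t) & (event == 1))
        d = len(d_idx)
        s0 = w[at_risk].sum()
        s1 = (w[at_risk, None] * X[at_risk]).sum(axis=0)
        if ties == "breslow" or d == 1:
            a0 = np.full(d, s0)
            xbar = np.tile(s1 / s0, (d, 1))
        elif ties == "efron":
            s0d = w[d_idx].sum()
            s1d = (w[d_idx, None] * X[d_idx]).sum(axis=0)
            f = np.arange(d) / d
            a0 = s0 - f * s0d
            xbar = (s1[None, :] - f[:, None] * s1d[None, :]) / a0[:, None]
        else:
            raise ValueError(f"unknown ties method {ties!r}")
        cum0[g + 1] = cum0[g] + (1.0 / a0).sum()
        cum1[g + 1] = cum1[g] + (xbar / a0[:, None]).sum(axis=0)
        group_info.append((t, d_idx, a0, xbar))

    # accumulated hazard part: every record is at risk for event times <= t_i
    upto = np.searchsorted(event_times, time, side="right")
    U -= w[:, None] * (X * cum0[upto][:, None] - cum1[upto])

    for t, d_idx, a0, xbar in group_info:
        d = len(d_idx)
        # death term
        U[d_idx] += X[d_idx] - xbar.mean(axis=0)[None, :]
        if ties == "efron" and d > 1:
            # tied deaths carry reduced weight (1 - l/d) in their own group
            f = (np.arange(d) / d)[:, None]
            corr0 = (f / a0[:, None]).sum()
            corr1 = (f * xbar / a0[:, None]).sum(axis=0)
            U[d_idx] += w[d_idx, None] * (X[d_idx] * corr0 - corr1[None, :])
    return U


def _newton_cox(
    X,
    time,
    event,
    ties: str = "efron",
    ridge: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
):
    """Newton-Raphson maximization of the (optionally ridge-penalized)
    partial likelihood.  ``ridge`` holds per-coefficient penalties lambda_j
    (penalty = -sum lambda_j beta_j^2 / 2).  Returns (beta, penalized ll,
    penalized Hessian, converged)."""
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    lam = np.zeros(p) if ridge is None else np.asarray(ridge, dtype=float)

    def objective(b):
        ll, g, h = cox_partial_loglik(X, time, event, b, ties, derivatives=True)
        ll -= 0.5 * float(lam @ (b * b))
        g = g - lam * b
        h = h - np.diag(lam)
        return ll, g, h

    ll, g, h = objective(beta)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-h, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-h, g, rcond=None)[0]
        # step halving
        for _ in range(30):
            new = beta + step
            ll_new, g_new, h_new = objective(new)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            beta, ll, g, h = new, ll_new, g_new, h_new
            converged = True
            break
        beta, ll, g, h = new, ll_new, g_new, h_new
    return beta, ll, h, converged


# ---------------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Result of a proportional-hazards fit.

    ``table`` has one row per predictor with the coefficient beta, hazard
    ratio HR = exp(beta), the standard error on both scales (``se`` is the
    SE of beta; ``se_hr`` = HR * se, the delta-method SE of the HR), the
    Wald z and its two-sided p.  ``loglik`` is the log partial likelihood
    at the optimum (for frailty fits, the Laplace-approximate integrated
    log likelihood), and ``aic`` = 2k - 2 loglik with k the number of fixed
    effects (plus one for the frailty variance).
    """

    table: pd.DataFrame
    ties: str
    variance: str
    loglik: float
    aic: float
    n: int
    n_events: int
    converged: bool
    frailty_group: str | None = None
    frailty_variance: float | None = None
    dropped: list[str] = field(default_factory=list)

    def hazard_ratio(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "hr"])

    def confint_hr(self, predictor: str, level: float = 0.95):
        zcrit = norm.ppf(0.5 + level / 2)
        b = float(self.table.loc[predictor, "coef"])
        se = float(self.table.loc[predictor, "se"])
        return float(np.exp(b - zcrit * se)), float(np.exp(b + zcrit * se))


def _drop_constant(records: pd.DataFrame, predictors: Sequence[str]):
    keep, dropped = [], []
    for name in predictors:
        if name not in records.columns:
            raise ValueError(f"predictor {name!r} missing from records")
        if records[name].nunique() > 1:
            keep.append(name)
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(
            f"dropping constant (non-identifiable) predictors: {dropped}",
            stacklevel=3,
        )
    if not keep:
        raise ValueError("all predictors constant: model not identifiable")
    return keep, dropped


def fit_cox(
    records: pd.DataFrame,
    predictors: Sequence[str] = ("dwell",),
    ties: str = "efron",
    variance: str = "robust",
    cluster: str = "ant",
    frailty_group: str = "ant",
    frailty_theta: float | None = None,
) -> CoxFit:
    """Fit the return-hazard model on a visit-history table.

    variance:
      - ``"model"``: observed-information SEs.
      - ``"robust"``: sandwich SEs clustered on ``cluster`` (default: ant;
        ants are uniquely identified within colonies in these data).
      - ``"frailty"``: log-normal shared frailty on ``frailty_group``
        ("ant" or "colony"), fitted by penalized partial likelihood with
        the frailty variance chosen by Laplace-approximate marginal
        likelihood.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    if records["event"].sum() < 1:
        raise ValueError("no events in records")
    predictors, dropped = _drop_constant(records, predictors)
    X = records[list(predictors)].to_numpy(dtype=float)
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    n, p = X.shape
    n_events = int(event.sum())

    if variance in ("model", "robust"):
        beta, ll, hess, converged = _newton_cox(X, time, event, ties=ties)
        info = -hess
        cov_model = np.linalg.inv(info)
        if variance == "robust":
            groups = records[cluster].astype(str)
            if cluster == "ant" and "colony" in records.columns:
                groups = records["colony"].astype(str) + "/" + groups
            U = cox_score_residuals(X, time, event, beta, ties=ties)
            g = pd.DataFrame(U).groupby(groups.to_numpy()).sum().to_numpy()
            meat = g.T @ g
            cov = cov_model @ meat @ cov_model
        else:
            cov = cov_model
        se = np.sqrt(np.diag(cov))
        aic = 2 * p - 2 * ll
        frailty_var = None
    elif variance == "frailty":
        beta, se, ll, frailty_var, converged = _fit_frailty(
            X,
            time,
            event,
            records[frailty_group].astype(str).to_numpy(),
            ties,
            theta=frailty_theta,
        )
        aic = 2 * (p + 1) - 2 * ll
    else:
        raise ValueError(f"unknown variance treatment {variance!r}")

    if not np.all(np.isfinite(beta)):
        raise RuntimeError("Cox fit did not converge (non-finite coefficients)")
    z = beta / se
    pvals = 2 * norm.sf(np.abs(z))
    hr = np.exp(beta)
    table = pd.DataFrame(
        {
            "coef": beta,
            "hr": hr,
            "se": se,
            "se_hr": hr * se,
            "z": z,
            "p": pvals,
        },
        index=pd.Index(predictors, name="predictor"),
    )
    return CoxFit(
        table=table,
        ties=ties,
        variance=variance,
        loglik=ll,
        aic=aic,
        n=n,
        n_events=n_events,
        converged=converged,
        frailty_group=frailty_group if variance == "frailty" else None,
        frailty_variance=frailty_var,
        dropped=dropped,
    )


def _fit_frailty(X, time, event, groups, ties, theta=None):
    """Log-normal shared frailty by penalized partial likelihood.

    Group-level log-frailties b_g ~ N(0, theta) enter the linear predictor
    as penalized coefficients on group indicators; for fixed theta the
    penalized likelihood is maximized by Newton-Raphson, and theta is chosen
    to maximize the Laplace-approximate integrated likelihood
    l(theta) = lp(beta, b) - b'b/(2 theta) - 1/2 log det(theta K_bb + I),
    with K_bb the partial-likelihood information block of b.  Passing
    ``theta`` fixes the frailty variance instead of estimating it.
    """
    labels, gidx = np.unique(groups, return_inverse=True)
    q = len(labels)
    n, p = X.shape
    Z = np.zeros((n, q))
    Z[np.arange(n), gidx] = 1.0
    XZ = np.hstack([X, Z])

    state = {"beta": None}

    def neg_marginal(log_theta):
        theta = float(np.exp(log_theta))
        ridge = np.concatenate([np.zeros(p), np.full(q, 1.0 / theta)])
        coef, pll, hess_pen, _ = _newton_cox(
            XZ, time, event, ties=ties, ridge=ridge, beta0=state["beta"]
        )
        state["beta"] = coef
        b = coef[p:]
        # unpenalized information block of b
        k_bb = -(hess_pen[p:, p:] - np.diag(np.full(q, -1.0 / theta)))
        lp = pll + 0.5 * float(b @ b) / theta  # strip penalty back off
        sign, logdet = np.linalg.slogdet(theta * k_bb + np.eye(q))
        lm = lp - 0.5 * float(b @ b) / theta - 0.5 * logdet
        state["last"] = (coef, hess_pen, lm, theta)
        return -lm

    if theta is not None:
        neg_marginal(np.log(theta))
        success = True
    else:
        opt = minimize_scalar(
            neg_marginal, bounds=(np.log(1e-4), np.log(25.0)), method="bounded",
            options={"xatol": 1e-3},
        )
        neg_marginal(opt.x)  # ensure state matches the optimum
        success = bool(opt.success)
    coef, hess_pen, lm, theta = state["last"]
    cov = np.linalg.inv(-hess_pen)
    se = np.sqrt(np.diag(cov)[:p])
    return coef[:p], se, lm, theta, success


def model_selection(
    records: pd.DataFrame,
    predictors: Sequence[str] = ("dwell",),
    candidates: Sequence[dict] | None = None,
    ties: str = "efron",
) -> tuple[CoxFit, pd.DataFrame]:
    """Fit candidate variance structures and pick the minimum-AIC model.

    Candidates default to the plain fixed-effects model, a per-colony
    frailty and a per-ant frailty.  Ties in AIC resolve to the earlier
    candidate (stable order).  Returns (chosen fit, AIC table).
    """
    if candidates is None:
        candidates = [
            {"variance": "model"},
            {"variance": "frailty", "frailty_group": "colony"},
            {"variance": "frailty", "frailty_group": "ant"},
        ]
    fits = []
    rows = []
    for spec in candidates:
        fit = fit_cox(records, predictors, ties=ties, **spec)
        fits.append(fit)
        rows.append(
            {
                "variance": fit.variance,
                "frailty_group": fit.frailty_group,
                "loglik": fit.loglik,
                "aic": fit.aic,
            }
        )
    table = pd.DataFrame(rows)
    best = int(np.argmin([f.aic for f in fits]))
    return fits[best], table
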