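"""Univariate association models for the matched and survival contrasts.

``fit_conditional_logistic`` maximizes the exact 1:1 matched-pair
conditional likelihood, which reduces to an intercept-free logistic model
on within-pair covariate differences with outcome fixed at 1; both
likelihood routes are computed and cross-checked on every fit.

``fit_cox`` is a Newton-Raphson proportional-hazards fit with Efron (or
Breslow) tie handling and observed-information standard errors; it also
returns the partial log-likelihood so nested models can be compared by
likelihood-ratio tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sncsig.diffexpr import bh_adjust

log = logging.getLogger(__name__)

ADJUSTMENT_COVARIATES = [
    "age", "bmi", "apoe4", "education",
    "smoking_former", "smoking_current",
    "med_antidep_anxio", "med_antihtn", "med_statin", "med_other_lipid",
    "mmse",
]


@dataclass
class ModelFit:
    """Raw solver output shared by the logistic and Cox fitters."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    flagged: bool = False
    flag_reason: str = ""
    n_iter: int = 0
    cov: np.ndarray | None = None
    names: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        z = self.beta / self.se
        p = 2.0 * stats.norm.sf(np.abs(z))
        lo = self.beta - 1.959963984540054 * self.se
        hi = self.beta + 1.959963984540054 * self.se
        return pd.DataFrame(
            {
                "term": self.names or [f"x{i}" for i in range(len(self.beta))],
                "estimate": self.beta,
                "se": self.se,
                "exp_estimate": np.exp(self.beta),
                "ci95_low": np.exp(lo),
                "ci95_high": np.exp(hi),
                "p": p,
            }
        )


def design_matrix(pheno: pd.DataFrame, include_sex: bool = True) -> pd.DataFrame:
    """Adjustment-covariate design (smoking as former/current dummies)."""
    d = pd.DataFrame(index=pheno.index)
    if include_sex:
        d["sex"] = pheno["sex"].astype(float)
    d["age"] = pheno["age"].astype(float)
    d["bmi"] = pheno["bmi"].astype(float)
    d["apoe4"] = pheno["apoe4"].astype(float)
    d["education"] = pheno["education"].astype(float)
    d["smoking_former"] = (pheno["smoking"] == "former").astype(float)
    d["smoking_current"] = (pheno["smoking"] == "current").astype(float)
    for m in ("med_antidep_anxio", "med_antihtn", "med_statin", "med_other_lipid"):
        d[m] = pheno[m].astype(float)
    d["mmse"] = pheno["mmse"].astype(float)
    return d


def pair_differences(
    X: np.ndarray, pair_ids: np.ndarray, case_indicator: np.ndarray
) -> np.ndarray:
    """Case-minus-control covariate differences, one row per pair."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(pair_ids):
        X = X.T
    pair_ids = np.asarray(pair_ids)
    case = np.asarray(case_indicator).astype(int)
    rows = []
    for pid in pd.unique(pair_ids):
        idx = np.flatnonzero(pair_ids == pid)
        if len(idx) != 2 or sorted(case[idx]) != [0, 1]:
            raise ValueError(f"pair {pid!r} is not a discordant 1:1 pair")
        i_case = idx[case[idx] == 1][0]
        i_ctrl = idx[case[idx] == 0][0]
        rows.append(X[i_case] - X[i_ctrl])
    return np.asarray(rows)


def _clogit_loglik_direct(beta, X, pair_ids, case_indicator) -> float:
    """Conditional likelihood computed from the pair definition (oracle route)."""
    eta = X @ beta
    ll = 0.0
    case = np.asarray(case_indicator).astype(int)
    pair_ids = np.asarray(pair_ids)
    for pid in pd.unique(pair_ids):
        idx = np.flatnonzero(pair_ids == pid)
        e = eta[idx]
        ll += e[case[idx] == 1][0] - np.logaddexp(e[0], e[1])
    return float(ll)


def clogit_loglik(beta: np.ndarray, D: np.ndarray) -> float:
    """Pair-difference route: sum of -log(1 + exp(-D beta))."""
    return float(-np.logaddexp(0.0, -(D @ beta)).sum())


def fit_conditional_logistic(
    X: np.ndarray,
    pair_ids: np.ndarray,
    case_indicator: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    verify_equivalence: bool = True,
) -> ModelFit:
    """Newton-Raphson conditional logistic regression for 1:1 matched pairs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and len(pair_ids) > 1:
        X = X.T
    D = pair_differences(X, pair_ids, case_indicator)
    fit = _fit_pair_difference_logistic(D, tol=tol, max_iter=max_iter)
    if verify_equivalence and not fit.flagged:
        ll_direct = _clogit_loglik_direct(fit.beta, X, pair_ids, case_indicator)
        if abs(ll_direct - fit.loglik) > 1e-6 * max(1.0, abs(fit.loglik)):
            raise AssertionError(
                "conditional and pair-difference likelihoods disagree: "
                f"{ll_direct} vs {fit.loglik}"
            )
    return fit


def _fit_pair_difference_logistic(
    D: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> ModelFit:
    n, p = D.shape
    beta = np.zeros(p)
    ll = clogit_loglik(beta, D)
    flagged = False
    reason = ""
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = D @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        grad = D.T @ (1.0 - prob)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = prob * (1.0 - prob)
        H = (D * w[:, None]).T @ D
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        new_ll = clogit_loglik(beta + step, D)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_ll = clogit_loglik(beta + step, D)
            halvings += 1
        beta = beta + step
        ll = new_ll
        if np.max(np.abs(beta)) > 20.0:
            flagged = True
            reason = "separation: unbounded conditional likelihood"
            break
    eta = D @ beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    w = prob * (1.0 - prob)
    H = (D * w[:, None]).T @ D
    se = np.full(p, np.inf)
    cov = None
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if (diag > 0).all() and np.isfinite(diag).all():
            se = np.sqrt(diag)
        else:
            flagged, reason = True, reason or "singular information matrix"
    except np.linalg.LinAlgError:
        flagged, reason = True, reason or "singular information matrix"
    if flagged:
        se = np.full(p, np.inf)
    if not converged and not flagged:
        # zero-information columns (e.g. all differences zero) land here
        if np.max(np.abs(D.T @ (1.0 - prob))) < 1e-6:
            converged = True
        else:
            flagged, reason = True, "no convergence"
    if not flagged and np.max(np.abs(beta)) > 15.0:
        flagged = True
        reason = "separation: unbounded conditional likelihood"
    return ModelFit(
        beta=beta, se=se, loglik=ll, converged=converged,
        flagged=flagged, flag_reason=reason, n_iter=it, cov=cov,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


def cox_loglik_grad_hess(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
    want_hess: bool = True,
):
    """Partial log-likelihood, gradient and (negative) Hessian.

    Subjects are processed in decreasing-time order so that running sums
    over the risk set are O(n) per event-time group.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    n, p = X.shape
    order = np.argsort(-np.asarray(time, dtype=float), kind="mergesort")
    Xs = X[order]
    ts = np.asarray(time, dtype=float)[order]
    es = np.asarray(event).astype(int)[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p)) if want_hess else None
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p)) if want_hess else None

    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        for k in range(i, j):  # everyone at this time enters the risk set
            s0 += w[k]
            s1 += w[k] * Xs[k]
            if want_hess:
                s2 += w[k] * np.outer(Xs[k], Xs[k])
        dead = [k for k in range(i, j) if es[k] == 1]
        d = len(dead)
        if d > 0:
            d0 = sum(w[k] for k in dead)
            d1 = np.sum([w[k] * Xs[k] for k in dead], axis=0)
            d2 = (
                np.sum([w[k] * np.outer(Xs[k], Xs[k]) for k in dead], axis=0)
                if want_hess
                else None
            )
            ll += float(np.sum(eta[dead]))
            for l in range(d):
                frac = l / d if ties == "efron" else 0.0
                a0 = s0 - frac * d0
                a1 = s1 - frac * d1
                ll -= np.log(a0)
                grad_term = a1 / a0
                grad -= grad_term
                if want_hess:
                    a2 = s2 - frac * d2
                    hess += a2 / a0 - np.outer(grad_term, grad_term)
            grad += np.sum([Xs[k] for k in dead], axis=0)
        i = j
    return (ll, grad, hess) if want_hess else (ll, grad)


def fit_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
    names: list | None = None,
) -> ModelFit:
    """Newton-Raphson Cox PH fit with step-halving.

    Monotone likelihoods (perfect risk separation) are flagged with
    infinite standard errors rather than raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if (time <= 0).any():
        raise ValueError("event/censoring times must be positive")
    if event.sum() < 1:
        raise ValueError("at least one event required")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    n, p = X.shape
    beta = np.zeros(p)
    ll, grad, hess = cox_loglik_grad_hess(beta, X, time, event, ties)
    flagged = False
    reason = ""
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        new_beta = beta + step
        new_ll, new_grad, new_hess = cox_loglik_grad_hess(new_beta, X, time, event, ties)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_hess = cox_loglik_grad_hess(
                new_beta, X, time, event, ties
            )
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > 25.0:
            flagged = True
            reason = "monotone likelihood: perfect risk separation"
            break
    if not converged and not flagged:
        if np.max(np.abs(grad)) < 1e-6:
            converged = True
        else:
            flagged, reason = True, "no convergence"
    if not flagged and np.max(np.abs(beta)) > 15.0:
        # the gradient flattens exponentially under a monotone likelihood,
        # so Newton can "converge" at an absurd estimate
        flagged = True
        reason = "monotone likelihood: perfect risk separation"
    se = np.full(p, np.inf)
    cov = None
    if not flagged:
        try:
            cov = np.linalg.inv(hess)
            diag = np.diag(cov)
            if (diag > 0).all():
                se = np.sqrt(diag)
            else:
                flagged, reason = True, "singular information matrix"
        except np.linalg.LinAlgError:
            flagged, reason = True, "singular information matrix"
    return ModelFit(
        beta=beta, se=se, loglik=ll, converged=converged, flagged=flagged,
        flag_reason=reason, n_iter=it, cov=cov, names=list(names) if names else [],
    )


def _unconditional_logistic(X, y, tol=1e-8, max_iter=100) -> ModelFit:
    """Plain logistic regression (sensitivity route), own Newton solver."""
    X = np.column_stack([np.ones(len(y)), np.atleast_2d(np.asarray(X, float))])
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    beta = np.zeros(p)
    flagged, converged, reason = False, False, ""
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -500, 500)
        prob = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - prob)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = np.maximum(prob * (1 - prob), 1e-12)
        H = (X * w[:, None]).T @ X
        beta = beta + np.linalg.solve(H, grad)
        if np.max(np.abs(beta)) > 25:
            flagged, reason = True, "separation"
            break
    eta = np.clip(X @ beta, -500, 500)
    prob = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(prob + 1e-300) + (1 - y) * np.log(1 - prob + 1e-300)))
    w = np.maximum(prob * (1 - prob), 1e-12)
    H = (X * w[:, None]).T @ X
    try:
        se = np.sqrt(np.diag(np.linalg.inv(H)))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
        flagged = True
    return ModelFit(beta=beta, se=se, loglik=ll, converged=converged,
                    flagged=flagged, flag_reason=reason)


def run_univariate_screen(
    expr_values: np.ndarray,
    feature_ids: np.ndarray,
    pheno: pd.DataFrame,
    model: str = "clogit",
    adjusted: bool = True,
    add_atn: bool = False,
    sensitivity_unconditional: bool = False,
) -> pd.DataFrame:
    """One association model per feature, BH-adjusted across the family.

    ``model='clogit'`` contrasts matched case/control status (sex cancels
    by matching); the sensitivity route fits unconditional logistic
    regression additionally adjusted for sex.  ``model='cox'`` regresses
    conversion hazard on each feature; ``add_atn`` appends the baseline
    case indicator to the adjustment set.
    """
    expr_values = np.atleast_2d(np.asarray(expr_values, dtype=float))
    if model not in ("clogit", "cox"):
        raise ValueError("model must be 'clogit' or 'cox'")
    adj = None
    if adjusted:
        adj = design_matrix(pheno, include_sex=(model == "cox")).to_numpy()
    rows = []
    pair_ids = pheno["pair_id"].to_numpy()
    case = pheno["atn_case"].to_numpy()
    time = pheno["followup_years"].to_numpy()
    event = pheno["ad_event"].to_numpy()
    if model == "clogit" and sensitivity_unconditional:
        sex = pheno["sex"].to_numpy()[:, None].astype(float)
    for i, fid in enumerate(feature_ids):
        x = expr_values[i][:, None]
        cols = [x]
        if adjusted:
            cols.append(adj)
        if model == "cox" and add_atn:
            cols.append(case[:, None].astype(float))
        Xf = np.hstack(cols)
        try:
            if model == "clogit":
                if sensitivity_unconditional:
                    fit = _unconditional_logistic(np.hstack([Xf, sex]), case)
                    est, se_, flg = fit.beta[1], fit.se[1], fit.flagged
                else:
                    fit = fit_conditional_logistic(Xf, pair_ids, case)
                    est, se_, flg = fit.beta[0], fit.se[0], fit.flagged
            else:
                fit = fit_cox(Xf, time, event)
                est, se_, flg = fit.beta[0], fit.se[0], fit.flagged
        except Exception as exc:  # noqa: BLE001
            log.warning("feature %s: fit failed (%s)", fid, exc)
            est, se_, flg = np.nan, np.nan, True
        if flg or not np.isfinite(se_) or se_ <= 0:
            p = np.nan
        else:
            p = 2.0 * stats.norm.sf(abs(est / se_))
        rows.append(
            {
                "feature_id": fid,
                "estimate": est,
                "se": se_,
                "exp_estimate": np.exp(est) if np.isfinite(est) else np.nan,
                "ci95_low": np.exp(est - 1.959963984540054 * se_)
                if np.isfinite(se_) else np.nan,
                "ci95_high": np.exp(est + 1.959963984540054 * se_)
                if np.isfinite(se_) else np.nan,
                "p": p,
                "flagged": flg,
            }
        )
    df = pd.DataFrame(rows)
    df["padj"] = bh_adjust(df["p"].to_numpy())
    tag = "adjusted" if adjusted else "unadjusted"
    if model == "cox" and add_atn:
        tag = "adjusted_plus_atn"
    if model == "clogit" and sensitivity_unconditional:
        tag = "sensitivity_unconditional"
    df["model_tag"] = tag
    return df
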