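"""Elastic-net penalized selection of sncRNA signatures.

Two penalized likelihoods are solved by IRLS + coordinate descent:

* conditional logistic for the matched case-control endpoint, through the
  exact 1:1 pair-difference reduction (intercept-free logistic loss on
  case-minus-control covariate differences), and
* Cox proportional hazards (Breslow ties inside the penalized solver) for
  the conversion endpoint.

Both minimize ``(1/n) * loss + lambda * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2)``.

Hyperparameters are tuned by repeated 90/10 splits with 10-fold
cross-validation inside the training part; the selected pair is then used
for 100-iteration stability selection, keeping features that recur in at
least ``occurrence_threshold`` iterations and weighting them by their mean
coefficient over the selecting iterations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sncsig._cd import cd_wls
from sncsig.assoc import cox_loglik_grad_hess

log = logging.getLogger(__name__)

_Z975 = 1.959963984540054


@dataclass
class EnetConfig:
    """Hyperparameter-search and stability-selection settings."""

    alpha_grid: tuple = tuple(np.round(np.arange(0.10, 1.0001, 0.05), 2))
    n_lambda: int = 25
    lambda_min_ratio: float = 0.05
    lambda_path: tuple | None = None  # explicit decreasing path overrides auto
    cv_folds: int = 10
    cv_rule: str = "1se"  # '1se' or 'best' for the per-alpha CV lambda choice
    tuning_reps: int = 20
    train_fraction: float = 0.90
    stability_iters: int = 100
    occurrence_threshold: int = 90
    strict_threshold: bool = False  # True -> strictly more than the threshold
    bootstrap_reps: int = 1000
    seed: int = 0

    def validate(self) -> None:
        a = np.asarray(self.alpha_grid, dtype=float)
        if (a <= 0).any() or (a > 1).any():
            raise ValueError("alpha grid must lie in (0, 1] (pure ridge excluded)")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.occurrence_threshold > self.stability_iters:
            raise ValueError("occurrence_threshold exceeds stability_iters")
        if self.cv_folds < 2 or self.n_lambda < 1 or self.tuning_reps < 1:
            raise ValueError("cv_folds, n_lambda and tuning_reps must be positive")


@dataclass
class EndpointData:
    """Subject-level feature matrix plus the endpoint structure.

    ``V`` holds log-normalized (not necessarily standardized) expression,
    samples x features; standardization is recomputed on every training
    subsample and applied to its held-out part.
    """

    endpoint: str  # 'atn' | 'ad'
    V: np.ndarray
    feature_ids: np.ndarray
    pair_case_idx: np.ndarray | None = None
    pair_ctrl_idx: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return 0 if self.pair_case_idx is None else len(self.pair_case_idx)


def make_atn_data(expr, pheno: pd.DataFrame) -> EndpointData:
    case_idx, ctrl_idx = [], []
    sample_pos = {s: i for i, s in enumerate(expr.sample_ids)}
    for pid, grp in pheno.groupby("pair_id", sort=True):
        if len(grp) != 2:
            raise ValueError(f"pair {pid} is not 1:1")
        c = grp[grp["atn_case"] == 1]["sample_id"].iloc[0]
        k = grp[grp["atn_case"] == 0]["sample_id"].iloc[0]
        case_idx.append(sample_pos[c])
        ctrl_idx.append(sample_pos[k])
    return EndpointData(
        endpoint="atn",
        V=np.ascontiguousarray(expr.values.T),
        feature_ids=np.asarray(expr.feature_ids),
        pair_case_idx=np.asarray(case_idx),
        pair_ctrl_idx=np.asarray(ctrl_idx),
    )


def make_ad_data(expr, pheno: pd.DataFrame) -> EndpointData:
    order = pd.Index(expr.sample_ids)
    ph = pheno.set_index("sample_id").loc[order]
    return EndpointData(
        endpoint="ad",
        V=np.ascontiguousarray(expr.values.T),
        feature_ids=np.asarray(expr.feature_ids),
        time=ph["followup_years"].to_numpy(dtype=float),
        event=ph["ad_event"].to_numpy(dtype=int),
    )


def _standardize_fit(V: np.ndarray, rows: np.ndarray):
    mean = V[rows].mean(axis=0)
    sd = V[rows].std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


# ---------------------------------------------------------------------------
# penalized solvers


def clogit_enet(
    D: np.ndarray,
    alpha: float,
    lam: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-7,
    max_irls: int = 100,
) -> np.ndarray:
    """Elastic-net conditional logistic fit on pair differences.

    Objective: ``(1/n) sum_i log(1 + exp(-d_i' b)) + lam*(alpha*||b||_1
    + (1-alpha)/2*||b||_2^2)``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    D = np.ascontiguousarray(np.atleast_2d(np.asarray(D, dtype=float)))
    n, p = D.shape
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    lam1 = lam * alpha
    lam2 = lam * (1.0 - alpha)
    if lam == 0.0 and np.linalg.matrix_rank(D) < p:
        warnings.warn(
            "lambda=0 with rank-deficient differences: solution not unique",
            RuntimeWarning,
            stacklevel=2,
        )
    for _ in range(max_irls):
        eta = np.clip(D @ beta, -30, 30)
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(prob * (1.0 - prob), 1e-5)
        z = eta + (1.0 - prob) / w
        u = w / n
        old = beta.copy()
        cd_wls(D, u, z, beta, lam1, lam2, tol * 0.1, 10_000)
        if np.max(np.abs(beta - old)) < tol:
            break
    return beta


def clogit_smooth_grad(D: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Gradient of the (1/n) logistic loss on pair differences."""
    D = np.atleast_2d(np.asarray(D, dtype=float))
    eta = np.clip(D @ beta, -500, 500)
    prob = 1.0 / (1.0 + np.exp(-eta))
    return -(D.T @ (1.0 - prob)) / D.shape[0]


def clogit_lambda_max(D: np.ndarray, alpha: float) -> float:
    g0 = clogit_smooth_grad(np.atleast_2d(D), np.zeros(np.atleast_2d(D).shape[1]))
    return float(np.max(np.abs(g0))) / alpha


def _cox_eta_derivs(eta: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Per-subject gradient/diagonal-Hessian of the Breslow partial loglik."""
    n = len(eta)
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    e = event[order]
    w = np.exp(np.clip(eta[order], -200, 200))
    # risk-set sums at each (ascending) position: S0_i = sum_{t_k >= t_i} w_k
    uniq, first = np.unique(t, return_index=True)
    suffix = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    s0_at = suffix[first]  # S0 at each unique time
    d_at = np.array([e[(t == ut)].sum() for ut in uniq], dtype=float)
    ratio1 = np.where(s0_at > 0, d_at / s0_at, 0.0)
    ratio2 = np.where(s0_at > 0, d_at / s0_at**2, 0.0)
    cum1 = np.cumsum(ratio1)
    cum2 = np.cumsum(ratio2)
    pos = np.searchsorted(uniq, t, side="right") - 1
    c1 = cum1[pos]
    c2 = cum2[pos]
    g_sorted = e - w * c1
    h_sorted = w * c1 - w**2 * c2
    g = np.empty(n)
    h = np.empty(n)
    g[order] = g_sorted
    h[order] = h_sorted
    return g, h


def cox_enet(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alpha: float,
    lam: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-7,
    max_irls: int = 100,
) -> np.ndarray:
    """Elastic-net Cox fit (Breslow ties) via IRLS + coordinate descent."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() < 1:
        raise ValueError("at least one event required")
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    lam1 = lam * alpha
    lam2 = lam * (1.0 - alpha)
    for _ in range(max_irls):
        eta = X @ beta
        g, h = _cox_eta_derivs(eta, time, event)
        h = np.maximum(h, 1e-8)
        z = eta + g / h
        u = h / n
        old = beta.copy()
        cd_wls(X, u, z, beta, lam1, lam2, tol * 0.1, 10_000)
        if np.max(np.abs(beta - old)) < tol:
            break
        if np.max(np.abs(beta)) > 50:
            warnings.warn("cox_enet: diverging coefficients", RuntimeWarning)
            break
    return beta


def cox_smooth_grad(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Gradient of (1/n) * negative Breslow partial log-likelihood."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, grad = cox_loglik_grad_hess(
        beta, X, np.asarray(time, float), np.asarray(event, int),
        ties="breslow", want_hess=False,
    )
    return -grad / X.shape[0]


def cox_lambda_max(X, time, event, alpha: float) -> float:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    g0 = cox_smooth_grad(X, time, event, np.zeros(X.shape[1]))
    return float(np.max(np.abs(g0))) / alpha


def kkt_violation(
    grad_smooth: np.ndarray, beta: np.ndarray, alpha: float, lam: float
) -> float:
    """Maximum violation of the elastic-net KKT conditions.

    Active coefficients must satisfy stationarity; zero coefficients the
    subgradient bound ``|g_j| <= lam*alpha``.
    """
    lam1 = lam * alpha
    lam2 = lam * (1.0 - alpha)
    g = np.asarray(grad_smooth, dtype=float)
    b = np.asarray(beta, dtype=float)
    active = b != 0.0
    v_active = (
        np.max(np.abs(g[active] + lam2 * b[active] + lam1 * np.sign(b[active])))
        if active.any()
        else 0.0
    )
    v_zero = max(0.0, float(np.max(np.abs(g[~active])) - lam1)) if (~active).any() else 0.0
    return max(float(v_active), v_zero)


def _lambda_path(lmax: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    return lmax * np.geomspace(1.0, min_ratio, n_lambda)


def fit_path(fit_fn, lambdas: np.ndarray, p: int) -> np.ndarray:
    """Warm-started fits along a decreasing lambda path; returns (L, p)."""
    betas = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for k, lam in enumerate(lambdas):
        beta = fit_fn(lam, beta)
        betas[k] = beta
    return betas


# ---------------------------------------------------------------------------
# tuning and stability selection


def _split_units(data: EndpointData, frac: float, rng: np.random.Generator):
    """Train/test index sets over design units (pairs or subjects)."""
    if data.endpoint == "atn":
        n = data.n_pairs
        n_train = max(2, int(round(frac * n)))
        perm = rng.permutation(n)
        return perm[:n_train], perm[n_train:]
    ev = np.flatnonzero(data.event == 1)
    ce = np.flatnonzero(data.event == 0)
    tr = []
    te = []
    for grp in (ev, ce):
        g = rng.permutation(grp)
        k = int(round(frac * len(g)))
        tr.append(g[:k])
        te.append(g[k:])
    return np.concatenate(tr), np.concatenate(te)


def _folds(units: np.ndarray, k: int, rng: np.random.Generator, strata=None):
    """k roughly equal folds; with strata, each stratum is spread evenly."""
    if strata is None:
        perm = rng.permutation(units)
        return [perm[i::k] for i in range(k)]
    folds = [[] for _ in range(k)]
    for s in np.unique(strata):
        sub = rng.permutation(units[strata == s])
        for i, x in enumerate(sub):
            folds[i % k].append(x)
    return [np.asarray(f, dtype=int) for f in folds]


def _prepare_atn(data: EndpointData, pair_units: np.ndarray, ref_units: np.ndarray):
    """Standardize on ref pairs' subjects, return difference rows for pair_units."""
    subj = np.concatenate(
        [data.pair_case_idx[ref_units], data.pair_ctrl_idx[ref_units]]
    )
    mean, sd = _standardize_fit(data.V, subj)
    zc = (data.V[data.pair_case_idx[pair_units]] - mean) / sd
    zk = (data.V[data.pair_ctrl_idx[pair_units]] - mean) / sd
    return zc - zk, zc, zk


def _score_atn(beta: np.ndarray, zc: np.ndarray, zk: np.ndarray) -> float:
    from sncsig.evaluate import roc_auc

    risk = np.concatenate([zc @ beta, zk @ beta])
    labels = np.concatenate([np.ones(len(zc)), np.zeros(len(zk))])
    return roc_auc(labels, risk)


def _score_ad(beta, z, time, event) -> float:
    from sncsig.evaluate import harrell_c

    return harrell_c(time, event, z @ beta)


@dataclass
class TuningResult:
    alpha_star: float
    lambda_star: float
    trace: pd.DataFrame


def tune_hyperparameters(
    data: EndpointData, config: EnetConfig, rng: np.random.Generator | None = None
) -> TuningResult:
    """Repeated 90/10 split + 10-fold CV search over (alpha, lambda).

    Within each repetition's training part, 10-fold CV picks the best
    lambda per alpha (ties resolved toward the larger lambda); the
    resulting candidate is scored by AUC (matched endpoint) or Harrell's C
    (survival endpoint) on the held-out 10%.  ``alpha_star`` maximizes the
    mean held-out score over repetitions (ties toward the larger alpha,
    i.e. the sparser model) and ``lambda_star`` is the median of the
    per-repetition selections at ``alpha_star``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = data.V.shape[1]
    alphas = np.asarray(config.alpha_grid, dtype=float)
    rows = []
    for rep in range(config.tuning_reps):
        tr_units, te_units = _split_units(data, config.train_fraction, rng)
        if data.endpoint == "ad":
            # guard: held-out part must contain an event to be scoreable
            attempts = 0
            while data.event[te_units].sum() == 0 and attempts < 10:
                log.info("refolding rep %d: zero-event test split", rep)
                tr_units, te_units = _split_units(data, config.train_fraction, rng)
                attempts += 1
        if data.endpoint == "atn":
            strata = None
        else:
            strata = data.event[tr_units]
        fold_sets = _folds(tr_units, config.cv_folds, rng, strata=strata)
        for alpha in alphas:
            lam_hat, cv_best = _cv_select_lambda(
                data, tr_units, fold_sets, alpha, config
            )
            beta = _fit_units(data, tr_units, tr_units, alpha, lam_hat)
            score = _score_units(data, beta, te_units, tr_units)
            rows.append(
                {
                    "rep": rep,
                    "alpha": float(alpha),
                    "lambda_selected": lam_hat,
                    "cv_deviance": cv_best,
                    "heldout_score": score,
                }
            )
    trace = pd.DataFrame(rows)
    mean_scores = trace.groupby("alpha")["heldout_score"].mean()
    best = mean_scores.max()
    alpha_star = float(max(a for a, s in mean_scores.items() if s >= best - 1e-12))
    lams = np.sort(
        trace.loc[trace["alpha"] == alpha_star, "lambda_selected"].to_numpy()
    )
    lambda_star = float(lams[len(lams) // 2])  # upper median: ties toward larger
    return TuningResult(alpha_star=alpha_star, lambda_star=lambda_star, trace=trace)


def _fit_units(data, fit_units, ref_units, alpha, lam, beta0=None):
    """Fit the endpoint model on ``fit_units``, standardized on ``ref_units``."""
    if data.endpoint == "atn":
        D, _, _ = _prepare_atn(data, fit_units, ref_units)
        return clogit_enet(D, alpha, lam, beta0=beta0)
    subj = fit_units
    mean, sd = _standardize_fit(data.V, subj)
    z = (data.V[subj] - mean) / sd
    return cox_enet(z, data.time[subj], data.event[subj], alpha, lam, beta0=beta0)


def _score_units(data, beta, score_units, ref_units) -> float:
    if data.endpoint == "atn":
        _, zc, zk = _prepare_atn(data, score_units, ref_units)
        return _score_atn(beta, zc, zk)
    mean, sd = _standardize_fit(data.V, ref_units)
    z = (data.V[score_units] - mean) / sd
    return _score_ad(beta, z, data.time[score_units], data.event[score_units])


def _cv_deviance(data, beta, held, cv_train, tr_units):
    """Held-out deviance contribution of one CV fold (lower is better).

    Matched endpoint: mean logistic loss on held-out pair differences.
    Survival endpoint: Verweij-Van Houwelingen partial-likelihood deviance,
    ``-2 * (pll(train) - pll(train \\ fold))`` evaluated at ``beta``.
    """
    if data.endpoint == "atn":
        D, _, _ = _prepare_atn(data, held, cv_train)
        return float(np.mean(np.logaddexp(0.0, -(D @ beta))))
    mean, sd = _standardize_fit(data.V, cv_train)
    z_all = (data.V[tr_units] - mean) / sd
    z_cv = (data.V[cv_train] - mean) / sd
    ll_all, _ = cox_loglik_grad_hess(
        beta, z_all, data.time[tr_units], data.event[tr_units],
        ties="breslow", want_hess=False,
    )
    ll_cv, _ = cox_loglik_grad_hess(
        beta, z_cv, data.time[cv_train], data.event[cv_train],
        ties="breslow", want_hess=False,
    )
    return float(-2.0 * (ll_all - ll_cv))


def _cv_select_lambda(data, tr_units, fold_sets, alpha, config):
    """k-fold CV of the deviance over a warm-started lambda path.

    The per-alpha lambda is the deviance minimizer, or with the default
    one-standard-error rule the largest lambda whose mean CV deviance lies
    within one SE of the minimum (guards against chasing noise on flat
    curves; ties resolve toward the larger lambda either way).
    """
    p = data.V.shape[1]
    if config.lambda_path is not None:
        path = np.asarray(config.lambda_path, dtype=float)
    elif data.endpoint == "atn":
        D_all, _, _ = _prepare_atn(data, tr_units, tr_units)
        lmax = clogit_lambda_max(D_all, alpha)
        path = _lambda_path(lmax, config.n_lambda, config.lambda_min_ratio)
    else:
        mean, sd = _standardize_fit(data.V, tr_units)
        z_all = (data.V[tr_units] - mean) / sd
        lmax = cox_lambda_max(z_all, data.time[tr_units], data.event[tr_units], alpha)
        path = _lambda_path(lmax, config.n_lambda, config.lambda_min_ratio)
    dev = np.full((len(fold_sets), len(path)), np.nan)
    for f, held in enumerate(fold_sets):
        if len(held) == 0:
            continue
        cv_train = np.concatenate([fs for g, fs in enumerate(fold_sets) if g != f])
        # saturation guard: stop the path once the active set approaches the
        # effective sample size (overfit region, fits become very slow)
        if data.endpoint == "ad":
            dfmax = 0.85 * data.event[cv_train].sum()
        else:
            dfmax = 0.85 * len(cv_train)
        beta = np.zeros(p)
        for k, lam in enumerate(path):
            beta = _fit_units(data, cv_train, cv_train, alpha, lam, beta0=beta)
            dev[f, k] = _cv_deviance(data, beta, held, cv_train, tr_units)
            if np.count_nonzero(beta) > dfmax:
                break
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_dev = np.nanmean(dev, axis=0)
        n_ok = np.sum(np.isfinite(dev), axis=0)
        sd_dev = np.nanstd(dev, axis=0, ddof=1)
    mean_dev = np.where(np.isfinite(mean_dev), mean_dev, np.inf)
    k_best = int(np.argmin(mean_dev))
    best = mean_dev[k_best]
    if config.cv_rule == "1se":
        se = sd_dev[k_best] / np.sqrt(max(n_ok[k_best], 1))
        if not np.isfinite(se):
            se = 0.0
        k_best = int(np.min(np.flatnonzero(mean_dev <= best + se)))
    else:
        k_best = int(np.min(np.flatnonzero(mean_dev <= best)))
    return float(path[k_best]), float(best)


@dataclass
class SignatureResult:
    """Stability-selected feature signature with weights and performance."""

    endpoint: str
    alpha_star: float
    lambda_star: float
    feature_ids: list
    occurrences: np.ndarray
    selected_features: list
    mean_coef: np.ndarray  # per selected feature
    coef_ci95: np.ndarray  # (k, 2)
    performance: dict = field(default_factory=dict)
    stability_iters: int = 100
    occurrence_threshold: int = 90

    @property
    def weights(self) -> dict:
        return dict(zip(self.selected_features, self.mean_coef.tolist()))

    def to_table(self, feature_class: dict | None = None) -> pd.DataFrame:
        occ = dict(zip(self.feature_ids, np.asarray(self.occurrences).tolist()))
        rows = []
        for f, w, (lo, hi) in zip(
            self.selected_features, self.mean_coef, self.coef_ci95
        ):
            rows.append(
                {
                    "feature_id": f,
                    "feature_class": (feature_class or {}).get(f, ""),
                    "occurrences": occ[f],
                    "mean_coef": w,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "feature_id", "feature_class", "occurrences",
                "mean_coef", "ci_low", "ci_high",
            ],
        )

    def to_json(self, path: str | Path) -> None:
        payload = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            payload[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureResult":
        d = json.loads(Path(path).read_text())
        d["occurrences"] = np.asarray(d["occurrences"])
        d["mean_coef"] = np.asarray(d["mean_coef"], dtype=float)
        d["coef_ci95"] = np.asarray(d["coef_ci95"], dtype=float).reshape(-1, 2)
        return cls(**d)


def stability_select(
    data: EndpointData,
    alpha_star: float,
    lambda_star: float,
    config: EnetConfig,
    rng: np.random.Generator | None = None,
) -> SignatureResult:
    """Stability selection at fixed hyperparameters.

    Each of ``stability_iters`` iterations refits the penalized model on a
    fresh ``train_fraction`` subsample (pairs for the matched endpoint,
    event-stratified subjects for survival); a feature's occurrence is the
    number of iterations with a non-zero coefficient.  The signature keeps
    features at or above ``occurrence_threshold`` (strictly above with
    ``strict_threshold``).  Weights are mean coefficients over selecting
    iterations with percentile 95% CIs.  Performance is the full-cohort
    AUC / C-statistic of the weighted score with a subject-bootstrap CI,
    plus the spread of per-iteration held-out scores.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = data.V.shape[1]
    coefs = np.zeros((config.stability_iters, p))
    heldout_scores = []
    for it in range(config.stability_iters):
        tr_units, te_units = _split_units(data, config.train_fraction, rng)
        beta = _fit_units(data, tr_units, tr_units, alpha_star, lambda_star)
        coefs[it] = beta
        if len(te_units) and (
            data.endpoint == "atn" or data.event[te_units].sum() > 0
        ):
            s = _score_units(data, beta, te_units, tr_units)
            if np.isfinite(s):
                heldout_scores.append(s)
    nz = np.abs(coefs) > 1e-10
    occurrences = nz.sum(axis=0)
    if config.strict_threshold:
        keep = occurrences > config.occurrence_threshold
    else:
        keep = occurrences >= config.occurrence_threshold
    # a feature never selected has no coefficient draws; threshold 0 means
    # "every feature ever selected", not "every feature"
    keep &= occurrences > 0
    selected = [str(f) for f in np.asarray(data.feature_ids)[keep]]
    if not selected:
        warnings.warn(
            "stability selection produced an empty signature", RuntimeWarning
        )
    mean_coef = np.array(
        [coefs[nz[:, j], j].mean() for j in np.flatnonzero(keep)], dtype=float
    )
    ci = np.array(
        [
            np.percentile(coefs[nz[:, j], j], [2.5, 97.5])
            for j in np.flatnonzero(keep)
        ],
        dtype=float,
    ).reshape(-1, 2)
    perf = _signature_performance(
        data, keep, mean_coef, heldout_scores, config, rng
    )
    return SignatureResult(
        endpoint=data.endpoint,
        alpha_star=float(alpha_star),
        lambda_star=float(lambda_star),
        feature_ids=[str(f) for f in data.feature_ids],
        occurrences=occurrences,
        selected_features=selected,
        mean_coef=mean_coef,
        coef_ci95=ci,
        performance=perf,
        stability_iters=config.stability_iters,
        occurrence_threshold=config.occurrence_threshold,
    )


def _signature_performance(data, keep, mean_coef, heldout_scores, config, rng):
    from sncsig.evaluate import bootstrap_ci, harrell_c, roc_auc

    perf: dict = {"n_selected": int(keep.sum())}
    if heldout_scores:
        hs = np.asarray(heldout_scores, dtype=float)
        perf["iteration_scores"] = {
            "mean": float(hs.mean()),
            "ci95_low": float(np.percentile(hs, 2.5)),
            "ci95_high": float(np.percentile(hs, 97.5)),
            "n": int(hs.size),
        }
    if not keep.any() or not np.any(mean_coef != 0):
        return perf
    all_rows = np.arange(data.V.shape[0])
    mean, sd = _standardize_fit(data.V, all_rows)
    z = (data.V - mean) / sd
    score = z[:, keep] @ mean_coef
    if data.endpoint == "atn":
        labels = np.zeros(len(score))
        labels[data.pair_case_idx] = 1.0
        est, lo, hi, _ = bootstrap_ci(
            lambda idx: roc_auc(labels[idx], score[idx]),
            len(score),
            reps=config.bootstrap_reps,
            rng=rng,
        )
        perf["metric"] = "auc"
    else:
        est, lo, hi, _ = bootstrap_ci(
            lambda idx: harrell_c(data.time[idx], data.event[idx], score[idx]),
            len(score),
            reps=config.bootstrap_reps,
            rng=rng,
        )
        perf["metric"] = "c_statistic"
    perf["subject_bootstrap"] = {
        "estimate": float(est), "ci95_low": float(lo), "ci95_high": float(hi)
    }
    return perf
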