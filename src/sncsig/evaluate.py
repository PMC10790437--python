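"""Weighted scores, concordance metrics and the nested Cox model ladder.

``model_sequence`` reproduces the four-model comparison: M1 conventional
risk factors, M2 = M1 + biomarker status, M3 = M1 + signature score,
M4 = M2 + signature score.  Likelihood-ratio tests are reported for the
nested pairs (M1->M2, M1->M3, M2->M4, M3->M4); the non-nested M2 vs M3
contrast is summarized by a bootstrap difference in C-statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sncsig.assoc import ModelFit, design_matrix, fit_cox

log = logging.getLogger(__name__)


def compute_score(expr, signature) -> np.ndarray:
    """Weighted sum of signature features, z-transformed over the cohort.

    ``signature`` needs ``selected_features`` and ``mean_coef`` (any
    object shaped like :class:`sncsig.penalized.SignatureResult`).
    """
    feats = list(signature.selected_features)
    weights = np.asarray(signature.mean_coef, dtype=float)
    if len(feats) == 0:
        raise ValueError("signature is empty; no score can be computed")
    if not np.any(weights != 0):
        raise ValueError("signature weights are all zero (degenerate signature)")
    index = {str(f): i for i, f in enumerate(expr.feature_ids)}
    rows = []
    for f in feats:
        if str(f) not in index:
            raise ValueError(f"signature feature {f!r} not present in expression matrix")
        rows.append(index[str(f)])
    vals = expr.values[rows, :]
    score = weights @ vals
    sd = score.std(ddof=0)
    if sd == 0:
        raise ValueError("score is constant across samples")
    return (score - score.mean()) / sd


def harrell_c(time, event, risk_score) -> float:
    """Harrell's concordance: comparable pairs are those where the subject
    with the strictly shorter time had an event; risk ties count 0.5.

    Returns NaN when no pair is comparable.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    r = np.asarray(risk_score, dtype=float)
    # pair (i, j) comparable iff t_i < t_j and e_i == 1
    ti = t[:, None]
    tj = t[None, :]
    comp = (ti < tj) & (e[:, None] == 1)
    n_comp = comp.sum()
    if n_comp == 0:
        return float("nan")
    ri = r[:, None]
    rj = r[None, :]
    conc = (comp & (ri > rj)).sum()
    tied = (comp & (ri == rj)).sum()
    return float((conc + 0.5 * tied) / n_comp)


def roc_auc(labels, score) -> float:
    """Mann-Whitney AUC with ties counted 0.5; NaN if one class absent."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(score, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_ci(
    metric_fn,
    n: int,
    reps: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_redraws: int = 20,
):
    """Subject-level percentile bootstrap of ``metric_fn(index_array)``.

    ``metric_fn`` receives an array of subject indices (with replacement)
    and must return a scalar, NaN signalling a degenerate resample (which
    is redrawn, up to ``max_redraws`` times each).  Returns
    ``(estimate, ci95_low, ci95_high, n_redrawn)``.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    estimate = float(metric_fn(np.arange(n)))
    vals = np.empty(reps)
    n_redrawn = 0
    for b in range(reps):
        v = float("nan")
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            v = float(metric_fn(idx))
            if np.isfinite(v):
                break
            n_redrawn += 1
        vals[b] = v
    vals = vals[np.isfinite(vals)]
    if n_redrawn:
        log.info("bootstrap: %d degenerate resamples redrawn", n_redrawn)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return estimate, float(lo), float(hi), n_redrawn


@dataclass
class ModelReport:
    model_id: str
    signature_label: str
    hr_per_sd: float | None
    hr_ci95: tuple | None
    hr_p: float | None
    c_statistic: float
    c_ci95: tuple
    loglik: float
    df: int
    lrt_p: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _lrt(fit_big: ModelFit, fit_small: ModelFit, df: int) -> float:
    stat = 2.0 * (fit_big.loglik - fit_small.loglik)
    return float(stats.chi2.sf(max(stat, 0.0), df))


def model_sequence(
    pheno: pd.DataFrame,
    atn_score: np.ndarray | None = None,
    ad_score: np.ndarray | None = None,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> list[ModelReport]:
    """Fit the M1-M4 nested Cox ladder for each provided signature score.

    Scores must be aligned with the rows of ``pheno`` and standardized
    (the reported HR is per z-score / per SD).  When both scores are given
    the ladder is reported once per signature (M1/M2 are shared fits).
    """
    if atn_score is None and ad_score is None:
        raise ValueError("at least one signature score is required")
    time = pheno["followup_years"].to_numpy(dtype=float)
    event = pheno["ad_event"].to_numpy(dtype=int)
    base = design_matrix(pheno, include_sex=True)
    atn = pheno["atn_case"].to_numpy(dtype=float)[:, None]
    rng = np.random.default_rng(seed)

    def fit(Xdf: np.ndarray, names: list) -> ModelFit:
        f = fit_cox(Xdf, time, event, names=names)
        if f.flagged or not f.converged:
            raise RuntimeError(
                f"Cox model with terms {names} failed: {f.flag_reason or 'no convergence'}"
            )
        return f

    Xb = base.to_numpy()
    names_b = list(base.columns)
    m1 = fit(Xb, names_b)
    m2 = fit(np.hstack([Xb, atn]), names_b + ["atn_case"])

    def c_with_ci(fitres: ModelFit, X: np.ndarray):
        lp = X @ fitres.beta
        est, lo, hi, _ = bootstrap_ci(
            lambda idx: harrell_c(time[idx], event[idx], lp[idx]),
            len(time),
            reps=bootstrap_reps,
            rng=rng,
        )
        return est, (lo, hi), lp

    reports: list[ModelReport] = []
    c1, ci1, lp1 = c_with_ci(m1, Xb)
    c2, ci2, lp2 = c_with_ci(m2, np.hstack([Xb, atn]))
    for label, score in (("atn", atn_score), ("ad", ad_score)):
        if score is None:
            continue
        s = np.asarray(score, dtype=float)[:, None]
        X3 = np.hstack([Xb, s])
        X4 = np.hstack([Xb, atn, s])
        m3 = fit(X3, names_b + [f"{label}_score"])
        m4 = fit(X4, names_b + ["atn_case", f"{label}_score"])
        c3, ci3, lp3 = c_with_ci(m3, X3)
        c4, ci4, _ = c_with_ci(m4, X4)

        # non-nested M2 vs M3: bootstrap difference in C
        dvals = np.empty(bootstrap_reps)
        for b in range(bootstrap_reps):
            idx = rng.integers(0, len(time), size=len(time))
            dvals[b] = harrell_c(time[idx], event[idx], lp3[idx]) - harrell_c(
                time[idx], event[idx], lp2[idx]
            )
        dvals = dvals[np.isfinite(dvals)]
        delta_c = {
            "estimate": float(c3 - c2),
            "ci95_low": float(np.percentile(dvals, 2.5)),
            "ci95_high": float(np.percentile(dvals, 97.5)),
        }

        def hr_terms(fitres: ModelFit, term: str):
            i = fitres.names.index(term)
            b_, se_ = fitres.beta[i], fitres.se[i]
            return (
                float(np.exp(b_)),
                (float(np.exp(b_ - 1.96 * se_)), float(np.exp(b_ + 1.96 * se_))),
                float(2 * stats.norm.sf(abs(b_ / se_))),
            )

        hr2 = hr_terms(m2, "atn_case")
        hr3 = hr_terms(m3, f"{label}_score")
        hr4 = hr_terms(m4, f"{label}_score")
        reports.extend(
            [
                ModelReport(
                    "M1", label, None, None, None, c1, ci1, m1.loglik, len(m1.beta)
                ),
                ModelReport(
                    "M2", label, hr2[0], hr2[1], hr2[2], c2, ci2, m2.loglik,
                    len(m2.beta), lrt_p={"vs_M1": _lrt(m2, m1, 1)},
                ),
                ModelReport(
                    "M3", label, hr3[0], hr3[1], hr3[2], c3, ci3, m3.loglik,
                    len(m3.beta), lrt_p={"vs_M1": _lrt(m3, m1, 1)},
                    extra={"delta_c_vs_M2": delta_c},
                ),
                ModelReport(
                    "M4", label, hr4[0], hr4[1], hr4[2], c4, ci4, m4.loglik,
                    len(m4.beta),
                    lrt_p={"vs_M2": _lrt(m4, m2, 1), "vs_M3": _lrt(m4, m3, 1)},
                ),
            ]
        )
    return reports


def reports_to_frame(reports: list[ModelReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "signature": r.signature_label,
                "model": r.model_id,
                "hr_per_sd": r.hr_per_sd,
                "hr_ci95_low": r.hr_ci95[0] if r.hr_ci95 else None,
                "hr_ci95_high": r.hr_ci95[1] if r.hr_ci95 else None,
                "hr_p": r.hr_p,
                "c_statistic": r.c_statistic,
                "c_ci95_low": r.c_ci95[0],
                "c_ci95_high": r.c_ci95[1],
                "loglik": r.loglik,
                "df": r.df,
                **{f"lrt_p_{k}": v for k, v in r.lrt_p.items()},
            }
        )
    return pd.DataFrame(rows)
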