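"""Negative-binomial Wald differential expression with BH FDR adjustment.

One NB GLM (log link, ``design = intercept + group``, offset = log size
factor) is fitted per feature; the group-coefficient Wald statistic gives a
two-sided normal p-value which is Benjamini-Hochberg adjusted across the
feature family.  This is a screening-grade NB test: no empirical-Bayes
dispersion shrinkage, Cook's filtering or independent filtering.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from sncsig.simcohort import CountMatrix

log = logging.getLogger(__name__)

_LN2 = np.log(2.0)


def estimate_dispersion(
    counts: np.ndarray,
    size_factors: np.ndarray,
    groups: np.ndarray | None = None,
    shrink: bool = False,
) -> np.ndarray:
    """Method-of-moments per-feature NB dispersion on normalized counts.

    ``phi = max(0, (s^2 - mean) / mean^2)`` computed within each group (so
    the group effect does not inflate the estimate) and pooled by degrees
    of freedom.  ``shrink=True`` pulls estimates halfway toward a fitted
    ``a/mean + b`` trend.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    norm = counts / np.asarray(size_factors, dtype=float)[None, :]
    if groups is None:
        groups = np.zeros(norm.shape[1], dtype=int)
    groups = np.asarray(groups)
    phi_num = np.zeros(norm.shape[0])
    df_tot = 0.0
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        if sub.shape[1] < 2:
            continue
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = (s2 - mu) / mu**2
        phi_g = np.where(np.isfinite(phi_g), phi_g, 0.0)
        df = sub.shape[1] - 1
        phi_num += np.maximum(phi_g, 0.0) * df
        df_tot += df
    if df_tot == 0:
        raise ValueError("need at least 2 samples in some group")
    phi = phi_num / df_tot
    const = norm.std(axis=1) == 0
    if const.any():
        log.warning("%d constant feature(s): dispersion set to 0", const.sum())
        phi[const] = 0.0
    if shrink:
        mu_all = norm.mean(axis=1)
        ok = (mu_all > 0) & (phi > 0)
        if ok.sum() >= 10:
            a, b = np.polyfit(1.0 / mu_all[ok], phi[ok], 1)
            trend = np.maximum(a / np.maximum(mu_all, 1e-8) + b, 0.0)
            phi = np.maximum(0.5 * (phi + trend), 0.0)
    return phi


def nb_wald_test(
    counts_g: np.ndarray,
    group_labels: np.ndarray,
    size_factors: np.ndarray,
    phi_g: float,
) -> dict:
    """Wald test for the group coefficient of a single-feature NB GLM.

    Returns a dict with ``log2_fold_change``, ``se`` (log2 scale), ``stat``,
    ``pvalue`` and ``converged``; non-converged fits carry NaN statistics.
    """
    y = np.asarray(counts_g, dtype=float)
    g = np.asarray(group_labels, dtype=float)
    if len(np.unique(g)) != 2:
        raise ValueError("exactly two groups required")
    g = (g == np.max(g)).astype(float)
    X = np.column_stack([np.ones_like(g), g])
    offset = np.log(np.asarray(size_factors, dtype=float))
    family = (
        sm.families.Poisson()
        if phi_g <= 1e-10
        else sm.families.NegativeBinomial(alpha=float(phi_g))
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=family, offset=offset).fit(maxiter=100)
        beta, se = res.params[1], res.bse[1]
        if not (np.isfinite(beta) and np.isfinite(se) and se > 0 and se < 50):
            raise ValueError("degenerate fit")
        stat = beta / se
        from scipy.stats import norm as _norm

        p = 2.0 * _norm.sf(abs(stat))
        return {
            "log2_fold_change": beta / _LN2,
            "se": se / _LN2,
            "stat": stat,
            "pvalue": max(p, np.finfo(float).tiny),
            "converged": True,
        }
    except Exception:  # noqa: BLE001 - any GLM failure is a flagged result
        return {
            "log2_fold_change": np.nan,
            "se": np.nan,
            "stat": np.nan,
            "pvalue": np.nan,
            "converged": False,
        }


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN inputs stay NaN.

    NaN p-values are excluded from the family size ``m``.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if not ok.any():
        return out
    pv = p[ok]
    if (pv <= 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def run_de(
    counts: CountMatrix,
    group_labels: np.ndarray,
    size_factors: np.ndarray | None = None,
    shrink_dispersion: bool = False,
) -> pd.DataFrame:
    """Per-feature NB Wald DE table with BH-adjusted p-values.

    Missing cells are excluded from each feature's fit.  Non-converged
    features are reported with NaN and excluded from the BH family (the
    count is logged).
    """
    from sncsig.preprocess import size_factors_median_of_ratios

    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts)
    size_factors = np.asarray(size_factors, dtype=float)
    labels = np.asarray(group_labels)
    phi = estimate_dispersion(
        np.where(counts.missing, np.round(counts.counts.mean(1))[:, None], counts.counts),
        size_factors,
        groups=labels,
        shrink=shrink_dispersion,
    )
    rows = []
    for i in range(counts.n_features):
        obs = ~counts.missing[i]
        r = nb_wald_test(
            counts.counts[i, obs], labels[obs], size_factors[obs], phi[i]
        )
        norm = counts.counts[i, obs] / size_factors[obs]
        rows.append(
            {
                "feature_id": counts.feature_ids[i],
                "feature_class": counts.feature_class[i],
                "baseMean": norm.mean(),
                "log2FoldChange": r["log2_fold_change"],
                "lfcSE": r["se"],
                "stat": r["stat"],
                "pvalue": r["pvalue"],
                "converged": r["converged"],
            }
        )
    df = pd.DataFrame(rows)
    n_bad = int((~df["converged"]).sum())
    if n_bad:
        log.warning("%d feature(s) failed to converge; excluded from FDR family", n_bad)
    df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    df["direction"] = np.where(df["log2FoldChange"] >= 0, "up", "down")
    return df
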