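"""Count preprocessing: filtering, outlier masking, imputation, normalization.

The canonical chain is :func:`preprocess_pipeline`:

1. drop features with fewer than ``min_total_reads`` total reads,
2. median-of-ratios size factors and ``log2(count/size_factor + pseudo)``,
3. mask cells whose per-feature z-score exceeds the threshold,
4. impute masked/missing cells,
5. z-standardize each feature (mean 0, SD 1).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sncsig.simcohort import CountMatrix

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Normalized (optionally standardized) expression with a missing mask."""

    values: np.ndarray  # features x samples; NaN at masked cells pre-imputation
    mask: np.ndarray  # True where originally missing or outlier-masked
    size_factors: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray
    transform_log: list = field(default_factory=list)
    outlier_ref: tuple | None = None  # (mean, sd, threshold) frozen at first masking

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            mask=self.mask.copy(),
            size_factors=self.size_factors.copy(),
            feature_ids=self.feature_ids.copy(),
            sample_ids=self.sample_ids.copy(),
            transform_log=list(self.transform_log),
            outlier_ref=self.outlier_ref,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)
        df.index.name = "feature_id"
        return df

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.to_frame().to_csv(
            prefix.with_suffix(".tsv"), sep="\t", na_rep="NA", float_format="%.10g"
        )
        sidecar = {
            "size_factors": dict(
                zip(map(str, self.sample_ids), self.size_factors.tolist())
            ),
            "masked_cells": np.argwhere(self.mask).tolist(),
            "transform_log": self.transform_log,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def filter_low_expression(
    counts: CountMatrix, min_total_reads: int = 1000
) -> CountMatrix:
    """Retain features with total reads >= ``min_total_reads`` (order kept)."""
    obs = np.where(counts.missing, 0, counts.counts)
    keep = obs.sum(axis=1) >= min_total_reads
    if not keep.any():
        raise ValueError(
            f"no features with >= {min_total_reads} total reads; nothing to analyse"
        )
    return CountMatrix(
        counts=counts.counts[keep],
        feature_ids=counts.feature_ids[keep],
        feature_class=counts.feature_class[keep],
        sample_ids=counts.sample_ids,
        missing=counts.missing[keep],
    )


def size_factors_median_of_ratios(counts: CountMatrix) -> np.ndarray:
    """DESeq-style median-of-ratios size factors.

    Reference features are those with strictly positive counts in every
    sample; when none exist, geometric means are computed over positive
    counts only ("poscounts" fallback) with a warning.
    """
    c = np.where(counts.missing, np.nan, counts.counts.astype(float))
    all_pos = np.nan_to_num(c, nan=1.0) > 0
    ref = all_pos.all(axis=1) & ~counts.missing.any(axis=1)
    if ref.any():
        sub = c[ref]
        geo = np.exp(np.mean(np.log(sub), axis=1))
        ratios = sub / geo[:, None]
        factors = np.median(ratios, axis=0)
    else:
        warnings.warn(
            "no feature has all-positive counts; using poscounts-style geometric means",
            RuntimeWarning,
            stacklevel=2,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            logc = np.log(c)
        logc[~np.isfinite(logc)] = np.nan
        geo = np.exp(np.nanmean(logc, axis=1))
        ratios = c / geo[:, None]
        ratios[~(np.nan_to_num(c, nan=0.0) > 0)] = np.nan
        factors = np.nanmedian(ratios, axis=0)
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise ValueError("degenerate size factors; check the count matrix")
    return factors


def normalize_and_standardize(
    counts: CountMatrix,
    size_factors: np.ndarray | None = None,
    pseudocount: float = 0.5,
    standardize: bool = True,
) -> ExpressionMatrix:
    """``log2(count/size_factor + pseudocount)``, optionally z-standardized.

    Missing cells carry NaN values and remain flagged in the mask.
    """
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts)
    size_factors = np.asarray(size_factors, dtype=float)
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    vals = np.log2(counts.counts / size_factors[None, :] + pseudocount)
    vals[counts.missing] = np.nan
    em = ExpressionMatrix(
        values=vals,
        mask=counts.missing.copy(),
        size_factors=size_factors,
        feature_ids=counts.feature_ids.copy(),
        sample_ids=counts.sample_ids.copy(),
        transform_log=[f"log2(count/size_factor + {pseudocount})"],
    )
    if standardize:
        em = standardize_features(em)
    return em


def standardize_features(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature z-transform over unmasked (or imputed) values.

    Constant features are left centred at zero with a warning.
    """
    em = expr.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(em.values, axis=1)
        sd = np.nanstd(em.values, axis=1, ddof=0)
    zero = ~(sd > 0)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} constant feature(s) left unstandardized",
            RuntimeWarning,
            stacklevel=2,
        )
    sd = np.where(zero, 1.0, sd)
    em.values = (em.values - mean[:, None]) / sd[:, None]
    em.transform_log.append("z-standardize per feature")
    return em


def mask_outliers(expr: ExpressionMatrix, z_threshold: float = 3.0) -> ExpressionMatrix:
    """Flag cells whose per-feature |z| exceeds ``z_threshold`` as missing.

    The per-feature mean/SD used for the z-scores are computed from
    currently unmasked cells and frozen on the returned matrix, so a second
    call with the same threshold is a no-op (idempotence).
    """
    em = expr.copy()
    if em.outlier_ref is not None and em.outlier_ref[2] == z_threshold:
        mean, sd = em.outlier_ref[0], em.outlier_ref[1]
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(np.where(em.mask, np.nan, em.values), axis=1)
            sd = np.nanstd(np.where(em.mask, np.nan, em.values), axis=1, ddof=1)
        const = ~(sd > 0)
        if const.any():
            log.warning(
                "%d constant feature(s): outlier z undefined, skipped", const.sum()
            )
        sd = np.where(const, np.inf, sd)
    if np.isinf(z_threshold):
        return em
    with np.errstate(invalid="ignore"):
        z = (em.values - mean[:, None]) / sd[:, None]
    new = np.abs(z) > z_threshold
    new &= ~np.isnan(em.values)
    em.mask |= new
    em.values[em.mask] = np.nan
    em.outlier_ref = (mean, sd, z_threshold)
    em.transform_log.append(
        f"masked {int(new.sum())} outlier cells at |z| > {z_threshold}"
    )
    return em


def impute_missing(
    expr: ExpressionMatrix,
    method: str = "iterative_forest",
    seed: int = 0,
    n_estimators: int = 20,
    max_sweeps: int = 10,
    tol: float = 1e-3,
    n_neighbors: int = 5,
) -> ExpressionMatrix:
    """Fill masked cells; non-masked cells are untouched.

    ``iterative_forest`` runs a round-robin per-feature random-forest
    regression (missForest-style) until the largest imputed-value change
    drops below ``tol`` times the matrix SD, or ``max_sweeps`` sweeps.
    ``knn`` and ``feature_median`` are fast deterministic alternatives.
    """
    em = expr.copy()
    if not em.mask.any():
        em.transform_log.append("impute: nothing to do")
        return em
    whole_row = em.mask.all(axis=1)
    if whole_row.any():
        bad = em.feature_ids[whole_row][0]
        raise ValueError(f"feature {bad!r} is entirely missing; cannot impute")

    vals = em.values
    med = np.nanmedian(np.where(em.mask, np.nan, vals), axis=1)
    filled = np.where(em.mask, med[:, None], vals)

    if method == "feature_median":
        em.values = filled
    elif method == "knn":
        from sklearn.impute import KNNImputer

        x = np.where(em.mask, np.nan, vals).T  # samples x features
        em.values = KNNImputer(n_neighbors=n_neighbors).fit_transform(x).T
    elif method == "iterative_forest":
        from sklearn.ensemble import RandomForestRegressor

        rng = np.random.default_rng(seed)
        x = filled.T.copy()  # samples x features
        maskT = em.mask.T
        feat_order = np.argsort(maskT.sum(axis=0))  # fewest missing first
        scale = np.nanstd(np.where(em.mask, np.nan, vals))
        for sweep in range(max_sweeps):
            max_change = 0.0
            for j in feat_order:
                rows = maskT[:, j]
                if not rows.any():
                    continue
                other = np.delete(np.arange(x.shape[1]), j)
                rf = RandomForestRegressor(
                    n_estimators=n_estimators,
                    max_features="sqrt",
                    random_state=int(rng.integers(2**31 - 1)),
                    n_jobs=1,
                )
                rf.fit(x[~rows][:, other], x[~rows, j])
                pred = rf.predict(x[rows][:, other])
                max_change = max(max_change, float(np.max(np.abs(pred - x[rows, j]))))
                x[rows, j] = pred
            if max_change < tol * scale:
                break
        em.values = x.T
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    em.transform_log.append(f"imputed {int(em.mask.sum())} cells ({method})")
    return em


def preprocess_pipeline(
    counts: CountMatrix,
    min_total_reads: int = 1000,
    z_threshold: float = 3.0,
    impute_method: str = "iterative_forest",
    pseudocount: float = 0.5,
    seed: int = 0,
    min_sample_reads: int | None = None,
) -> tuple[ExpressionMatrix, CountMatrix]:
    """Full chain: filter -> normalize -> mask outliers -> impute -> standardize.

    ``min_sample_reads`` optionally drops low-depth samples before anything
    else (no default cut-off is applied).
    """
    if min_sample_reads is not None:
        obs = np.where(counts.missing, 0, counts.counts)
        keep = obs.sum(axis=0) >= min_sample_reads
        dropped = int((~keep).sum())
        if dropped:
            log.warning("dropping %d low-depth sample(s)", dropped)
        counts = CountMatrix(
            counts=counts.counts[:, keep],
            feature_ids=counts.feature_ids,
            feature_class=counts.feature_class,
            sample_ids=counts.sample_ids[keep],
            missing=counts.missing[:, keep],
        )
    filtered = filter_low_expression(counts, min_total_reads)
    factors = size_factors_median_of_ratios(filtered)
    em = normalize_and_standardize(filtered, factors, pseudocount, standardize=False)
    em = mask_outliers(em, z_threshold)
    em = impute_missing(em, method=impute_method, seed=seed)
    em = standardize_features(em)
    return em, filtered
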