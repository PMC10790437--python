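"""Synthetic nested case-control cohort generator.

Generates feature x sample negative-binomial count matrices together with a
matched 1:1 case-control phenotype table and right-censored conversion
outcomes.  Planted effects (case-associated features, hazard-associated
features, covariate effects on the hazard) are recorded in a
:class:`TruthRecord` so downstream recovery tests can score themselves
against ground truth.

Counts follow the mean-dispersion negative-binomial convention
``Var = mu + phi * mu**2`` with per-feature dispersion ``phi`` and
per-sample depth factors.  Case-associated features shift the log-scale
mean between cases and controls by a configurable number of log-odds units
per standard deviation of log-expression; hazard-associated features enter
an exponential proportional-hazards model through their standardized
log-expression.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("miRNA", "piRNA", "tRNA", "snoRNA", "rRNA", "other")
_CLASS_PROBS = (0.60, 0.10, 0.10, 0.08, 0.05, 0.07)

PHENOTYPE_COLUMNS = [
    "sample_id", "pair_id", "sex", "atn_case", "a_pos", "t_pos", "n_pos",
    "age", "bmi", "apoe4", "education", "smoking",
    "med_antidep_anxio", "med_antihtn", "med_statin", "med_other_lipid",
    "mmse", "followup_years", "ad_event",
]


class UnderpoweredCohortError(ValueError):
    """Raised when a configuration yields too few events for recovery tests."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Effect sizes are per standard deviation of (log-scale) expression:
    ``effect_log_or`` is the planted case-control log-odds shift for each
    case-associated feature and ``effect_log_hr`` the planted log-hazard
    ratio for each hazard-associated feature.
    """

    n_pairs: int = 95
    n_features: int = 250
    n_atn_signal: int = 6
    n_ad_signal: int = 15
    signal_overlap: int = 3
    effect_log_or: float = 0.8
    effect_log_hr: float = 0.5
    baseline_hazard: float = 0.08
    admin_censor_years: float = 5.0
    depth_lognormal_sd: float = 0.35
    nb_dispersion: float | None = None  # None -> per-feature Uniform(0.05, 0.5)
    missing_frac: float = 0.01
    outlier_frac: float = 0.005
    outlier_factor: float = 10.0
    # covariate effects on the conversion hazard (log-HR scale)
    atn_log_hr: float = 1.6
    age_log_hr: float = 0.03
    apoe4_log_hr: float = 0.5
    min_expected_events: int = 10
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_pairs, self.n_features, self.n_atn_signal, self.n_ad_signal) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_pairs < 1 or self.n_features < 1:
            raise ValueError("n_pairs and n_features must be positive")
        for name in ("missing_frac", "outlier_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.signal_overlap > min(self.n_atn_signal, self.n_ad_signal):
            raise ValueError("signal_overlap exceeds a signal set size")
        if self.n_atn_signal + self.n_ad_signal - self.signal_overlap > self.n_features:
            raise ValueError("planted signal sets exceed feature count")
        if self.baseline_hazard <= 0 or self.admin_censor_years <= 0:
            raise ValueError("baseline_hazard and admin_censor_years must be positive")


@dataclass
class CountMatrix:
    """Raw feature x sample integer counts with class annotations.

    ``missing`` marks cells whose value is unobserved (written as NA on
    disk); the stored count at a missing cell is meaningless.
    """

    counts: np.ndarray
    feature_ids: np.ndarray
    feature_class: np.ndarray
    sample_ids: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.feature_class = np.asarray(self.feature_class, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (features x samples)")
        nf, ns = self.counts.shape
        if len(self.feature_ids) != nf or len(self.feature_class) != nf:
            raise ValueError("feature annotation length mismatch")
        if len(self.sample_ids) != ns:
            raise ValueError("sample id length mismatch")
        if len(set(self.feature_ids)) != nf:
            raise ValueError("feature_ids must be unique")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("sample_ids must be unique")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.missing is None:
            self.missing = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.counts.shape:
                raise ValueError("missing mask shape mismatch")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.copy(),
            feature_ids=self.feature_ids.copy(),
            feature_class=self.feature_class.copy(),
            sample_ids=self.sample_ids.copy(),
            missing=self.missing.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts.astype(float), index=self.feature_ids, columns=self.sample_ids
        )
        df[pd.DataFrame(self.missing, index=df.index, columns=df.columns)] = np.nan
        df.index.name = "feature_id"
        return df

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.insert(0, "feature_class", self.feature_class)
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        classes = df.pop("feature_class").to_numpy()
        missing = df.isna().to_numpy()
        counts = df.fillna(0).to_numpy()
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("count matrix contains non-integer values")
        return cls(
            counts=np.round(counts).astype(np.int64),
            feature_ids=df.index.to_numpy(),
            feature_class=classes,
            sample_ids=df.columns.to_numpy(),
            missing=missing,
        )


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for recovery tests."""

    atn_feature_idx: np.ndarray
    ad_feature_idx: np.ndarray
    atn_feature_ids: list
    ad_feature_ids: list
    effect_log_or: float
    effect_log_hr: float
    feature_log_shift: np.ndarray  # natural-log case/control mean shift per feature
    dispersion: np.ndarray
    baseline_mean: np.ndarray
    depth: np.ndarray
    hazard_lp: np.ndarray  # linear predictor of the conversion hazard per sample
    clean_counts: np.ndarray  # counts before artifact injection
    missing_cells: np.ndarray  # (k, 2) feature/sample indices
    outlier_cells: np.ndarray

    def to_json(self, path: str | Path, include_counts: bool = True) -> None:
        payload = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "clean_counts" and not include_counts:
                continue
            payload[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        Path(path).write_text(json.dumps(payload))


@dataclass
class ArtifactFlags:
    missing_cells: np.ndarray
    outlier_cells: np.ndarray


def _draw_feature_panel(config: SimConfig, rng: np.random.Generator):
    """Baseline means, dispersions and class labels for the feature panel."""
    base = rng.lognormal(mean=3.1, sigma=1.5, size=config.n_features)
    if config.nb_dispersion is None:
        phi = rng.uniform(0.05, 0.5, size=config.n_features)
    else:
        phi = np.full(config.n_features, float(config.nb_dispersion))
    classes = rng.choice(FEATURE_CLASSES, size=config.n_features, p=_CLASS_PROBS)
    ids = np.array(
        [f"snc-{cls}-{i:04d}" for i, cls in enumerate(classes)], dtype=object
    )
    return base, phi, classes, ids


def _pick_signal_features(config: SimConfig, base: np.ndarray, rng: np.random.Generator):
    """Plant signals only on features that will comfortably survive filtering."""
    eligible = np.flatnonzero(base >= 10.0)
    need = config.n_atn_signal + config.n_ad_signal - config.signal_overlap
    if len(eligible) < need:
        eligible = np.argsort(base)[-need:]
    chosen = rng.choice(eligible, size=need, replace=False)
    atn_idx = np.sort(chosen[: config.n_atn_signal])
    ad_idx = np.sort(
        np.concatenate(
            [
                chosen[: config.signal_overlap],
                chosen[config.n_atn_signal : need],
            ]
        )
    )
    return atn_idx, ad_idx


def _draw_phenotypes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Covariates for n_pairs matched pairs; one case + one control per pair."""
    n = config.n_pairs
    sex = rng.binomial(1, 0.48, size=n)  # shared within pair (matching factor)
    rows = []
    for p in range(n):
        for case in (1, 0):
            if case:
                age = rng.normal(76.0, 5.0)
                bmi = rng.normal(25.8, 3.0)
                apoe4 = rng.binomial(1, 0.61)
                smoking = rng.choice(
                    ["never", "former", "current"], p=[0.70, 0.23, 0.07]
                )
                antidep = rng.binomial(1, 0.34)
                mmse = int(np.clip(round(rng.normal(25.3, 2.0)), 0, 30))
                t_pos = rng.binomial(1, 0.97)
                n_pos = rng.binomial(1, 0.70)
                if t_pos == 0 and n_pos == 0:
                    t_pos = 1
                a_pos = 1
            else:
                age = rng.normal(69.0, 6.0)
                bmi = rng.normal(27.0, 3.0)
                apoe4 = rng.binomial(1, 0.14)
                smoking = rng.choice(
                    ["never", "former", "current"], p=[0.68, 0.19, 0.13]
                )
                antidep = rng.binomial(1, 0.59)
                mmse = int(np.clip(round(rng.normal(27.3, 1.8)), 0, 30))
                a_pos = t_pos = n_pos = 0
            rows.append(
                {
                    "sample_id": f"S{p:03d}{'C' if case else 'K'}",
                    "pair_id": f"P{p:03d}",
                    "sex": int(sex[p]),
                    "atn_case": case,
                    "a_pos": a_pos,
                    "t_pos": t_pos,
                    "n_pos": n_pos,
                    "age": float(np.clip(age, 50.0, 95.0)),
                    "bmi": float(np.clip(bmi, 16.0, 45.0)),
                    "apoe4": int(apoe4),
                    "education": int(np.clip(round(rng.normal(8.5, 3.5)), 0, 22)),
                    "smoking": smoking,
                    "med_antidep_anxio": int(antidep),
                    "med_antihtn": int(rng.binomial(1, 0.41 if case else 0.35)),
                    "med_statin": int(rng.binomial(1, 0.30 if case else 0.25)),
                    "med_other_lipid": int(rng.binomial(1, 0.07)),
                    "mmse": mmse,
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(
    config: SimConfig, inject: bool = True
) -> tuple[CountMatrix, pd.DataFrame, TruthRecord]:
    """Simulate one matched nested case-control cohort.

    Returns the (possibly artifact-injected) count matrix, the phenotype
    table (one row per sample, columns :data:`PHENOTYPE_COLUMNS`) and the
    :class:`TruthRecord` with planted effects and artifact coordinates.

    Raises :class:`UnderpoweredCohortError` when the realized number of
    conversion events falls below ``config.min_expected_events``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    base, phi, classes, ids = _draw_feature_panel(config, rng)
    atn_idx, ad_idx = _pick_signal_features(config, base, rng)

    pheno = _draw_phenotypes(config, rng)
    n_samples = len(pheno)
    case = pheno["atn_case"].to_numpy()

    # per-SD log-mean shift: case-associated features move by
    # effect_log_or standard deviations of log-expression between groups
    log_sd = np.sqrt(np.log1p(phi + 1.0 / base))
    shift = np.zeros(config.n_features)
    shift[atn_idx] = config.effect_log_or * log_sd[atn_idx]

    depth = rng.lognormal(mean=0.0, sigma=config.depth_lognormal_sd, size=n_samples)
    # +shift/2 for cases, -shift/2 for controls keeps the marginal mean stable
    signed = np.where(case == 1, 0.5, -0.5)
    mu = depth[None, :] * base[:, None] * np.exp(shift[:, None] * signed[None, :])

    # NB via gamma-Poisson mixing; phi -> 0 degenerates to Poisson
    phi_eff = np.maximum(phi, 1e-8)
    shape = np.broadcast_to((1.0 / phi_eff)[:, None], mu.shape)
    lam = rng.gamma(shape, 1.0) / shape * mu
    counts = rng.poisson(lam).astype(np.int64)

    # hazard operates on realized standardized log expression
    logx = np.log2(counts / depth[None, :] + 0.5)
    sd = logx.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    z = (logx - logx.mean(axis=1, keepdims=True)) / sd[:, None]

    lp = (
        config.atn_log_hr * case
        + config.age_log_hr * (pheno["age"].to_numpy() - 72.0)
        + config.apoe4_log_hr * pheno["apoe4"].to_numpy()
        + config.effect_log_hr * z[ad_idx, :].sum(axis=0)
    )
    hazard = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    dropout = rng.uniform(0.25, config.admin_censor_years, size=n_samples)
    censor = np.minimum(dropout, config.admin_censor_years)
    followup = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    if event.sum() < config.min_expected_events:
        raise UnderpoweredCohortError(
            f"only {int(event.sum())} events realized "
            f"(< {config.min_expected_events}); recovery tests are underpowered"
        )
    pheno["followup_years"] = np.maximum(followup, 1e-6)
    pheno["ad_event"] = event
    pheno = pheno[PHENOTYPE_COLUMNS]

    cm = CountMatrix(
        counts=counts,
        feature_ids=ids,
        feature_class=classes,
        sample_ids=pheno["sample_id"].to_numpy(),
    )
    clean = counts.copy()
    if inject:
        cm, flags = inject_artifacts(cm, config, rng=rng)
    else:
        flags = ArtifactFlags(
            missing_cells=np.empty((0, 2), dtype=int),
            outlier_cells=np.empty((0, 2), dtype=int),
        )
    truth = TruthRecord(
        atn_feature_idx=atn_idx,
        ad_feature_idx=ad_idx,
        atn_feature_ids=[str(i) for i in ids[atn_idx]],
        ad_feature_ids=[str(i) for i in ids[ad_idx]],
        effect_log_or=config.effect_log_or,
        effect_log_hr=config.effect_log_hr,
        feature_log_shift=shift,
        dispersion=phi,
        baseline_mean=base,
        depth=depth,
        hazard_lp=lp,
        clean_counts=clean,
        missing_cells=flags.missing_cells,
        outlier_cells=flags.outlier_cells,
    )
    return cm, pheno, truth


def inject_artifacts(
    counts: CountMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, ArtifactFlags]:
    """Flag random cells missing and multiply others by an outlier factor.

    Returns a new :class:`CountMatrix` plus the coordinates of the injected
    artifacts.  With both fractions zero the counts are returned unchanged.
    """
    for name in ("missing_frac", "outlier_frac"):
        v = getattr(config, name)
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = counts.copy()
    nf, ns = out.counts.shape
    miss = rng.random((nf, ns)) < config.missing_frac
    # only nonzero cells can become multiplicative outliers
    outl = (rng.random((nf, ns)) < config.outlier_frac) & ~miss & (out.counts > 0)
    out.missing |= miss
    out.counts[outl] = np.round(out.counts[outl] * config.outlier_factor).astype(
        np.int64
    )
    return out, ArtifactFlags(
        missing_cells=np.argwhere(miss), outlier_cells=np.argwhere(outl)
    )


def validate_phenotype(pheno: pd.DataFrame) -> None:
    """Check the matched-pair structure invariants; raise ValueError on breach."""
    missing_cols = set(PHENOTYPE_COLUMNS) - set(pheno.columns)
    if missing_cols:
        raise ValueError(f"phenotype table missing columns: {sorted(missing_cols)}")
    for pid, grp in pheno.groupby("pair_id"):
        if len(grp) != 2:
            raise ValueError(f"pair {pid} has {len(grp)} members (expected 2)")
        if grp["sex"].nunique() != 1:
            raise ValueError(f"pair {pid} is sex-discordant")
        if sorted(grp["atn_case"]) != [0, 1]:
            raise ValueError(f"pair {pid} is not case/control discordant")
    if (pheno["followup_years"] <= 0).any():
        raise ValueError("followup_years must be positive")
    cases = pheno[pheno["atn_case"] == 1]
    if not ((cases["a_pos"] == 1) & ((cases["t_pos"] == 1) | (cases["n_pos"] == 1))).all():
        raise ValueError("cases must be A+ and T+ or N+")
    ctrls = pheno[pheno["atn_case"] == 0]
    if ctrls[["a_pos", "t_pos", "n_pos"]].to_numpy().any():
        raise ValueError("controls must be A-T-N-")


def write_cohort(
    outdir: str | Path,
    counts: CountMatrix,
    pheno: pd.DataFrame,
    truth: TruthRecord | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.write_tsv(outdir / "counts.tsv")
    pheno.to_csv(outdir / "phenotype.csv", index=False, float_format="%.10g")
    if truth is not None:
        truth.to_json(outdir / "truth.json")
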