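"""End-to-end chained run: simulate -> preprocess -> DE -> univariate
association -> penalized signatures -> score evaluation.

Every stochastic stage draws from child generators spawned off one master
seed, so a repeated run with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from sncsig import diffexpr, evaluate, penalized, preprocess, simcohort
from sncsig.assoc import run_univariate_screen

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "sim": {},
    "preprocess": {
        "min_total_reads": 1000,
        "z_threshold": 3.0,
        "impute_method": "feature_median",
    },
    "enet": {
        "tuning_reps": 3,
        "n_lambda": 15,
        "alpha_grid": [0.1, 0.3, 0.5, 0.7, 0.9, 1.0],
        "stability_iters": 100,
        "occurrence_threshold": 90,
        "bootstrap_reps": 200,
    },
    "evaluate": {"bootstrap_reps": 200},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: dict(v) for k, v in base.items()}
    for k, v in (override or {}).items():
        out.setdefault(k, {})
        out[k].update(v)
    return out


def run_all(config: dict | None, outdir: str | Path, seed: int = 0) -> dict:
    """Run the whole pipeline into ``outdir``; returns a summary dict."""
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(seed)
    s_sim, s_pre, s_tune_atn, s_tune_ad, s_stab_atn, s_stab_ad, s_eval = (
        int(c.generate_state(1)[0]) for c in master.spawn(7)
    )

    sim_cfg = simcohort.SimConfig(**{**cfg["sim"], "seed": s_sim})
    counts, pheno, truth = simcohort.generate_cohort(sim_cfg)
    simcohort.write_cohort(outdir, counts, pheno, truth)

    em, filtered = preprocess.preprocess_pipeline(
        counts,
        min_total_reads=cfg["preprocess"]["min_total_reads"],
        z_threshold=cfg["preprocess"]["z_threshold"],
        impute_method=cfg["preprocess"]["impute_method"],
        seed=s_pre,
    )
    em.write(outdir / "expression")

    # outlier cells masked during preprocessing are excluded from DE as well
    filtered = filtered.copy()
    filtered.missing |= em.mask

    de_atn = diffexpr.run_de(filtered, pheno["atn_case"].to_numpy(), em.size_factors)
    de_atn.to_csv(outdir / "de_atn.tsv", sep="\t", index=False, float_format="%.10g")
    de_ad = diffexpr.run_de(filtered, pheno["ad_event"].to_numpy(), em.size_factors)
    de_ad.to_csv(outdir / "de_ad.tsv", sep="\t", index=False, float_format="%.10g")

    screen = run_univariate_screen(
        em.values, em.feature_ids, pheno, model="clogit", adjusted=True
    )
    screen.to_csv(outdir / "assoc_clogit.tsv", sep="\t", index=False,
                  float_format="%.10g")
    screen_cox = run_univariate_screen(
        em.values, em.feature_ids, pheno, model="cox", adjusted=True, add_atn=True
    )
    screen_cox.to_csv(outdir / "assoc_cox.tsv", sep="\t", index=False,
                      float_format="%.10g")

    enet_kwargs = dict(cfg["enet"])
    enet_kwargs["alpha_grid"] = tuple(enet_kwargs.get("alpha_grid", []))
    signatures = {}
    summary = {"seed": seed, "config": cfg, "signatures": {}}
    for endpoint, s_tune, s_stab, maker in (
        ("atn", s_tune_atn, s_stab_atn, penalized.make_atn_data),
        ("ad", s_tune_ad, s_stab_ad, penalized.make_ad_data),
    ):
        data = maker(em, pheno)
        econf = penalized.EnetConfig(**{**enet_kwargs, "seed": s_tune})
        tuning = penalized.tune_hyperparameters(data, econf)
        tuning.trace.to_csv(
            outdir / f"tuning_{endpoint}.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        sig = penalized.stability_select(
            data, tuning.alpha_star, tuning.lambda_star, econf,
            rng=np.random.default_rng(s_stab),
        )
        sig.to_json(outdir / f"signature_{endpoint}.json")
        classes = dict(zip(map(str, filtered.feature_ids), filtered.feature_class))
        sig.to_table(classes).to_csv(
            outdir / f"signature_{endpoint}.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        signatures[endpoint] = sig
        summary["signatures"][endpoint] = {
            "alpha_star": sig.alpha_star,
            "lambda_star": sig.lambda_star,
            "selected": sig.selected_features,
            "performance": sig.performance,
        }
        log.info(
            "%s signature: alpha=%.2f lambda=%.6g, %d features",
            endpoint, sig.alpha_star, sig.lambda_star, len(sig.selected_features),
        )

    scores = {}
    for endpoint, sig in signatures.items():
        try:
            scores[endpoint] = evaluate.compute_score(em, sig)
        except ValueError as exc:
            log.warning("%s score unavailable: %s", endpoint, exc)
            scores[endpoint] = None
    if scores.get("atn") is not None or scores.get("ad") is not None:
        reports = evaluate.model_sequence(
            pheno,
            atn_score=scores.get("atn"),
            ad_score=scores.get("ad"),
            bootstrap_reps=cfg["evaluate"]["bootstrap_reps"],
            seed=s_eval,
        )
        evaluate.reports_to_frame(reports).to_csv(
            outdir / "model_reports.tsv", sep="\t", index=False, float_format="%.10g"
        )
        summary["models"] = json.loads(
            evaluate.reports_to_frame(reports).to_json(orient="records")
        )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
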