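# sncsig

Discovery and evaluation of plasma small-non-coding-RNA (sncRNA) signatures
in a matched nested case–control cohort with a survival endpoint:

* **`sncsig.simcohort`** — synthetic cohort generator: negative-binomial
  counts (`Var = mu + phi*mu^2`) with per-sample depth variation, 1:1
  sex-matched case–control pairs, planted case-associated and
  hazard-associated feature sets, right-censored conversion times,
  missingness and outlier artifacts, and a `TruthRecord` for recovery
  tests.
* **`sncsig.preprocess`** — low-count filtering (total reads ≥ 1000),
  median-of-ratios size factors, `log2(count/sf + 0.5)` normalization,
  per-feature |z| > 3 outlier masking, missForest-style / kNN / median
  imputation, z-standardization.
* **`sncsig.diffexpr`** — per-feature negative-binomial Wald differential
  expression with method-of-moments dispersion and Benjamini–Hochberg FDR.
* **`sncsig.assoc`** — univariate conditional-logistic (exact 1:1
  pair-difference reduction, Newton–Raphson) and Cox proportional-hazards
  (Efron/Breslow ties) association screens, adjusted or unadjusted.
* **`sncsig.penalized`** — elastic-net conditional-logistic and Cox
  solvers (IRLS + coordinate descent, numba-accelerated), repeated 90/10
  split + 10-fold CV hyperparameter search over an alpha grid
  (0.10–1.00) and lambda paths, 100-iteration stability selection with the
  ≥ 90/100 occurrence rule, mean-coefficient weights with percentile CIs.
* **`sncsig.evaluate`** — weighted z-scored signature scores, Harrell's C,
  ROC AUC, subject bootstrap CIs, and the nested Cox model ladder
  (M1 risk factors, M2 +biomarker status, M3 +signature, M4 +both) with
  likelihood-ratio tests for nested pairs and bootstrap ΔC for M2 vs M3.

## CLI

Every stage is exposed under one entry point (seeded, hence reproducible):

```bash
sncsig simulate   --out cohort/ --seed 1
sncsig preprocess --counts cohort/counts.tsv --min-total 1000 --z-thresh 3 \
                  --out cohort/expression
sncsig de         --counts cohort/counts.tsv --pheno cohort/phenotype.csv \
                  --contrast atn_case --out de_atn.tsv
sncsig assoc      --expr cohort/expression.tsv --pheno cohort/phenotype.csv \
                  --model clogit --out assoc.tsv
sncsig signature  --expr cohort/expression.tsv --pheno cohort/phenotype.csv \
                  --endpoint atn --out atn_signature.json
sncsig evaluate   --expr cohort/expression.tsv --pheno cohort/phenotype.csv \
                  --atn-sig atn_signature.json --ad-sig ad_signature.json \
                  --out models.tsv
sncsig run-all    --config pipeline.yaml --out results/ --seed 1
```

`run-all` chains simulate → preprocess → DE → univariate screens →
signature selection (both endpoints) → model ladder with one master seed;
two runs with the same seed are byte-identical.

## Notes

* The elastic-net objective is
  `(1/n)*loss + lambda*(alpha*||b||_1 + (1-alpha)/2*||b||_2^2)`; solutions
  satisfy the KKT conditions to 1e-5 and match dense grid-search oracles on
  small problems (see the test suite).
* The per-alpha CV lambda is chosen by held-out deviance with the
  one-standard-error rule (`EnetConfig.cv_rule`), and the final
  (alpha, lambda) by mean held-out AUC / C-statistic across split
  repetitions.
* Standardization is recomputed inside every training subsample and
  applied to held-out data; no information leaks across splits.
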