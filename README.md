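# targetmr

Drug-target Mendelian randomization (MR) with cis-instrument
construction, a multi-estimator sensitivity battery, two-step mediation
analysis, and a synthetic GWAS generator that makes every stage
verifiable by parameter recovery.

## The problem

Genetic variants in or near a drug's target gene that alter the drug's
biomarker (e.g. LDL cholesterol or triglycerides) act as lifelong,
randomized proxies for pharmacological modulation of that target.
Two-sample MR combines per-variant effects on the biomarker (β_X, from an
exposure GWAS) with effects on a disease (β_Y, from an outcome GWAS) to
estimate the causal effect θ of the target on disease risk — here, of
lipid-lowering targets (HMGCR, PCSK9, LPL, ANGPTL3, APOC3, LDLR, …) on
inflammatory bowel disease and its subtypes. A two-step extension asks
how much of that effect runs through intermediate traits (gut microbial
taxa, circulating cytokines): step 1 estimates the mediator→disease
effect *b*, step 2 the target→mediator effect *a*, and the mediated
proportion is *a·b / θ_total*.

The statistical core, per harmonized variant *j* with Wald ratio
β_Yj / β_Xj:

- **IVW** (primary): θ̂ = Σ w_j β_Xj β_Yj / Σ w_j β_Xj², w_j = 1/se_Yj²;
  fixed-effect or multiplicative random-effects SE.
- **MR-Egger**: weighted regression β_Yj = α + θ β_Xj; the intercept α
  estimates average directional pleiotropy.
- **Weighted median / weighted mode**: consistent when ≥50% of the weight
  (resp. the largest cluster) comes from valid instruments.
- **Robust IVW**: IVW through the origin by IRLS with Huber loss.
- **RAPS**: robust adjusted profile score with additive overdispersion
  τ² for systematic pleiotropy.
- **MR-PRESSO**: simulation-based global residual-sum-of-squares test,
  per-variant outlier detection, distortion test, outlier-corrected IVW.

Instrument construction follows the standard drug-target cascade: cis
window (gene ± 250 kb; ± 500 kb for pQTL instruments), p < 5×10⁻⁸
(1×10⁻⁵ for mediators), per-variant F = (β/se)² > 10, MAF ≥ 0.01, greedy
LD clumping at r² < 0.2 within 10,000 kb, allele harmonization with LD
proxies (r² ≥ 0.8) and frequency-based palindrome resolution, and Steiger
directionality filtering. Benjamini–Hochberg FDR at 0.05 corrects the
primary target × outcome family; estimates are reported per 1 mmol/l
*decrease* in the lipid (38.7 mg/dl for LDL-C, 88.9 mg/dl for TG).

Consortium GWAS downloads are deliberately out of scope: the
`synthetic_gwas` module generates summary statistics, LD panels and
mediation chains with known ground truth, so the pipeline is validated by
recovering planted parameters rather than by re-downloading data.

## Worked example

Simulate a two-sample study with true θ = 0.3 (log-odds per exposure
unit), run the cascade and the full estimator battery:

```bash
targetmr simulate --n-variants 60 --block-size 3 --rho 0.6 --k 20 \
    --theta 0.3 --pleiotropy none --seed 11 --out-dir demo
targetmr select --exposure demo/exposure.tsv \
    --panel-variants demo/panel_variants.tsv --panel-matrix demo/panel_matrix.tsv \
    --out demo/instruments.tsv --audit-out demo/audit.tsv
# kept 26 of 60 variants
targetmr harmonize --exposure demo/instruments.tsv --outcome demo/outcome.tsv \
    --panel-variants demo/panel_variants.tsv --panel-matrix demo/panel_matrix.tsv \
    --out demo/harmonized.tsv
targetmr mr --harmonized demo/harmonized.tsv --seed 1 --out demo/mr.tsv
```

`demo/mr.tsv` (abridged):

```
         method  estimate     se  ci_low  ci_high  n_snps  odds_ratio
            ivw   -0.3102 0.0179 -0.3452  -0.2751      26      0.7333
weighted_median   -0.3079 0.0246 -0.3561  -0.2597      26      0.7350
  weighted_mode   -0.3000 0.0382 -0.3750  -0.2251      26      0.7408
     robust_ivw   -0.3023 0.0186 -0.3389  -0.2658      26      0.7391
          egger   -0.3091 0.0458 -0.4037  -0.2145      26      0.7341
           raps   -0.3090 0.0103 -0.3293  -0.2888      26      0.7342
         presso   -0.3102 0.0179 -0.3452  -0.2751      26      0.7333
```

Estimates are reported per unit *decrease* in the exposure, so the
planted θ = +0.3 appears as −0.31 ± 0.02: a protective odds ratio of
0.73 for pharmacological lowering, recovered consistently by all seven
estimators. The 60-variant panel collapses to 26 approximately
independent instruments after clumping; `demo/audit.tsv` records why each
of the other 34 was dropped.

The same flow is available as a library (`targetmr.pipeline.run_cascade`,
`targetmr.mr_core.all_estimators`, `targetmr.mediation.two_step_mediation`),
and `targetmr run --config study.yaml` drives a full multi-target,
multi-outcome, multi-mediator study with FDR correction, sensitivity
reports and tidy TSV outputs that reproduce bit-for-bit under a fixed
config.

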