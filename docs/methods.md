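# Methods

## Model

Two-sample summary-data MR treats each harmonized variant *j* as an
instrument with observed associations β̂_Xj ~ N(γ_j, se_Xj²) on the
exposure and β̂_Yj ~ N(θγ_j + α_j, se_Yj²) on the outcome, where θ is the
causal effect of interest and α_j a possible direct (pleiotropic) effect.
Binary outcomes are analysed on the log-odds scale throughout, so θ for a
disease outcome is a log odds ratio per exposure unit. All estimators
consume the same harmonized quadruples (β_X, se_X, β_Y, se_Y) aligned to
the exposure's effect allele; drug-action estimates are re-signed to a
per-1-mmol/l-decrease convention at the reporting stage (conversion
factors 38.7 mg/dl for LDL-C and 88.9 mg/dl for TG when the exposure GWAS
is in mg/dl).

Assumptions by estimator: IVW requires all instruments valid (α = 0) for
unbiasedness and is the primary analysis. Egger requires InSIDE
(instrument strength independent of direct effects) and estimates the
mean α as its intercept. The weighted median tolerates up to 50% invalid
weight; the weighted mode requires only the largest cluster of Wald
ratios to be valid. Robust IVW and RAPS downweight or absorb idiosyncratic
and systematic pleiotropy (RAPS via an additive overdispersion τ² on the
outcome variance). PRESSO assumes a majority of clean instruments to
build its leave-one-out null.

## Instrument cascade

Filters run in order: cis window → significance → F → MAF → LD clump →
harmonization → Steiger. All thresholds are parameters with defaults:
±250 kb flank (±500 kb in pQTL mode), p < 5×10⁻⁸ (strict, mediators
1×10⁻⁵), single-instrument F = (β/se)² > 10 (strict), MAF ≥ 0.01
(removal strict below), clump r² < 0.2 within 10,000 kb, proxy r² ≥ 0.8,
palindrome exclusion for MAF ∈ (0.4, 0.5]. The stored GWAS p-value is
filtered as-is, never recomputed from β/se — summary files routinely
carry p-values from a different test than the printed β/se imply, and
silently recomputing them would change the selected set.

Decisions that the wording of common practice leaves open, fixed here:

- Steiger filtering runs after clumping (configurable), using
  r² = z²/(z² + n − 2) per trait with n = n_case + n_control for binary
  traits; ties are kept.
- Clumping breaks p-value ties by position then variant id, making the
  kept set independent of input order; a brute-force greedy reference is
  part of the verification suite.
- Palindrome strand inference treats EAF ∈ [0.45, 0.55] as ambiguous;
  this zone nests inside the (0.4, 0.5] MAF exclusion applied at
  harmonization, so an ambiguous-but-not-excluded state cannot occur.
- Proxy choice takes the highest r², ties by distance then id; the
  proxy's outcome effect is phased onto the instrument's alleles through
  the sign of the panel correlation, and the instrument's panel frequency
  stands in when the outcome file lacks one.
- Coordinates are 1-based inclusive internally; BED input is converted on
  read. Window boundaries are inclusive.

Every dropped variant carries a reason code
(out_of_window, not_significant, weak_instrument, low_maf, clumped,
palindrome_unresolved, steiger_reversed, not_in_panel,
missing_in_outcome, incompatible_alleles), and
|input| = |kept| + |audited| holds at every stage.

## Estimator numerics

- IVW: fixed-effect when k ≤ 3, multiplicative random effects otherwise
  (SE scaled by √max(1, Q/(k−1)), never credited below the fixed SE);
  both selectable. A single instrument falls back to the Wald ratio.
- Egger: inputs re-oriented to β_X ≥ 0; covariance scaled by
  max(1, residual variance); t inference with k − 2 df; a constant β_X
  design is refused (slope unidentified).
- Weighted median: cumulative-weight interpolation at 0.5; SE by
  parametric bootstrap (default 2,000 draws, seeded).
- Weighted mode: normal-kernel density over Wald ratios, bandwidth =
  bandwidth_factor × 0.9 × min(weighted SD, 1.4826 × weighted MAD) ×
  k^(−1/5), evaluated on a 2,048-point grid; exact density ties break
  toward the smaller estimate and are flagged.
- Robust IVW: IRLS with Huber c = 1.345 on residuals standardized by
  se_Y and a per-iteration MAD scale; converged at 10⁻¹⁰ or 100
  iterations (non-convergence raises with the estimate trace); sandwich
  SE floored at the IVW fixed-effect SE.
- RAPS: profile estimating equation in θ with
  t_j = (β_Yj − θβ_Xj)/√(se_Yj² + θ²se_Xj² + τ²), Huber ψ (c = 1.345,
  E[ψ(Z)Z] = 2Φ(c) − 1), τ² ≥ 0 solved by bracketing and bisection
  jointly with θ; sandwich SE with τ² held at its estimate.
- PRESSO: observed RSS uses leave-one-out IVW predictions; the null is
  2,000 (default) parametric simulations under the fitted no-pleiotropy
  model; per-variant outliers at Bonferroni-corrected 0.05; a distortion
  test compares the corrected-vs-raw shift against random same-size
  removals. When a gross outlier contaminates every leave-one-out
  prediction and removal would leave fewer than two variants, flags are
  reported and the corrected re-fit is skipped rather than raising.

Stochastic estimators are bit-reproducible given (inputs, seed, rep
count); `n_boot=0` skips the bootstrap and returns a point estimate with
NaN uncertainty for Monte-Carlo studies of the point estimator.

## Mediation

Two-step product of coefficients: *a* (target → mediator, cis
instruments), *b* (mediator → outcome, mediator instruments at 1×10⁻⁵),
total (target → outcome); indirect = a·b, proportion = a·b/total.
The two steps' instrument sets are kept disjoint — the target's cis
instruments are excluded from the mediator's instrument pool, because
through the exposure they carry the ratio total/a rather than *b* and
would bias step 1; disjointness is also what justifies treating â and b̂
as independent.

The 95% CI is a percentile parametric bootstrap (default 10,000 draws)
drawing a, b and the total independently. Holding the total at its point
estimate was evaluated and rejected as the default: the total's
outcome-side sampling noise contributes real variance to the proportion
(to first order the exposure-side noise cancels in a/total, the
outcome-side term (ab/total²)²·Var(total) does not), and the fixed-total
interval measured 0.845–0.895 coverage in the verification chain versus
0.935–0.97 when the total is resampled. The fixed-total variant remains
available (`resample_total=False`) for totals estimated near zero, where
a resampled denominator makes the proportion heavy-tailed. Proportions
outside [0, 1] (opposing direct and indirect paths) are reported verbatim
with a flag, never truncated; a delta-method SE over (a, b) is emitted for
cross-checking.

## Synthetic data

The generator works at the summary level: for a unit-variance continuous
trait, se = 1/√(2·maf·(1−maf)·n) exactly; for case-control traits,
se = √(1/(2·maf·(1−maf)) · (1/n_case + 1/n_control)) on the log-odds
scale. LD enters both through the marginal effects (R·β on the
standardized scale) and through correlated estimation noise (L·z with
L Lᵀ = R), so clumping and proxy search are exercised against honest
summary statistics. Panels use AR(1) blocks (r = ρ^|i−j| within a block,
0 between), which are positive semidefinite by construction. Pleiotropy
regimes: none, balanced, directional (InSIDE holds), correlated (InSIDE
violated), single planted outlier. One root seed drives everything;
identical inputs reproduce outputs byte-for-byte.

What the generator does not emulate — and hence what passing tests do not
establish about real data: individual-level confounding and selection,
sample overlap between exposure and outcome GWAS, imputation quality and
allele-frequency mismatch between cohorts, winner's curse in instrument
discovery, and trans-ethnic LD differences.

## Verification regimes and problem sizes

The acceptance harnesses fix these study conditions (chosen once):

- Recovery: k = 50 instruments with per-allele effects 0.1–0.3 SD (cis
  lead-variant scale; this puts the instrument-strength heterogeneity
  statistic I²_GX near 0.99, the regime MR-Egger's NOME condition
  requires — at weaker effect spreads Egger attenuates by several percent
  as a property of the estimator), exposure n = 100,000, case-control
  outcome 25,000/25,000, θ = 0.3, 500 replicates.
- Type-I: θ = 0, k = 20, 1,000 replicates for IVW (fixed-effect variant:
  the one with exact nominal calibration; the random-effects variant is
  conservative by design), 500 × 1,000 simulations for the PRESSO global
  test.
- Directional pleiotropy: k = 100, α ~ N(0.1, 0.01²), consortium-scale
  exposure GWAS (n = 1.3 million) so exposure-side noise cannot attenuate
  the Egger slope; IVW bias checked against its analytic value
  Σwγα/Σwγ². The weighted-median 40%-invalid check runs against a
  5-million outcome GWAS and a ±0.05 band: one-sided contamination
  leaves an O(ratio-SD) finite-sample bias at any realistic sample size,
  so "unbiased" is an asymptotic statement for this estimator.
- Outlier: one direct effect of 1.5 among 20 clean instruments, 200
  replicates (PRESSO flag rate, robust-vs-plain IVW error).
- Oracles: 1,000 random ≤12-variant panels (clumping), 1,000 random
  p-vectors (BH), 50 simulated sets (leave-one-out), 200 single-variant
  and 1,000 double-flip cases.
- Mediation: a = 0.2, b = 0.5, direct = 0.1 (true proportion 0.5),
  disjoint 15 + 15 instrument sets, all GWAS n = 200,000, 200 replicates
  with 10,000 bootstrap draws each.

## Known limitations

Single-proxy substitution only (no LD-based imputation of missing outcome
associations); biallelic variants only; no multivariable MR, so the
mediation "direct effect" is total-minus-indirect rather than
adjustment-based; the PRESSO distortion null uses random same-size
removals, which is conservative when outliers are few; RAPS standard
errors hold τ² fixed at its estimate; phenome-screen exclusion takes a
user-supplied association table (no live PheWAS queries), with a
Bonferroni default of 0.05/(n_SNPs × n_phenotypes).
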