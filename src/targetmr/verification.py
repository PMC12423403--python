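"""Monte-Carlo verification harnesses for the whole pipeline.

Each harness fixes a data-generating regime with known ground truth, runs
the relevant pipeline stage many times, and returns summary statistics
(means, Monte-Carlo standard errors, rates, agreement fractions). They
back both the property-based test suite and the reproduction script.

Regimes (chosen once as the package's study conditions):

* recovery — k = 50 strong instruments (per-allele effects 0.1-0.3 on a
  unit-variance exposure, i.e. cis lead-variant effect sizes giving
  instrument-strength heterogeneity I2_GX ~ 0.99, exposure GWAS
  n = 100,000), theta = 0.3 on a case-control outcome of 25,000/25,000,
  no pleiotropy. MR-Egger is only well calibrated when I2_GX is near 1
  (the NOME condition), which is what "strong instruments" buys;
* calibration — the same machinery at theta = 0;
* directional pleiotropy — k = 100, direct effects alpha ~ N(0.1, 0.01^2)
  drawn independently of instrument strength (InSIDE), with a
  consortium-scale exposure GWAS (n = 1,300,000) so exposure-side noise
  cannot attenuate the Egger slope;
* majority-valid — 40% of instruments carry a +1 Wald-ratio bias; the
  weighted median's consistency is asymptotic in instrument strength, so
  this regime uses a very large outcome GWAS (n = 5,000,000);
* outlier — one direct effect of 1.5 planted among 20 clean instruments;
* mediation — a = 0.2, b = 0.5, direct = 0.1 (true mediated proportion
  0.5) with disjoint instrument sets of 15 and GWAS n = 200,000.

Point-estimate harnesses run the stochastic estimators with ``n_boot = 0``
(no bootstrap SE) since only the sampling distribution of the point
estimate is under study.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import LDPanel, SummaryDataset, VariantAssociation
from .harmonization import harmonize
from .mr_core import (
    egger,
    ivw,
    presso,
    raps,
    robust_ivw,
    weighted_median,
    weighted_mode,
)
from .mediation import mediated_proportion
from .pipeline import bh_fdr, run_cascade
from .sensitivity import leave_one_out
from .synthetic_gwas import (
    SimulationTruth,
    make_truth,
    simulate_ld_panel,
    simulate_mediation_scenario,
    simulate_two_sample,
)

__all__ = [
    "estimator_recovery",
    "ivw_type1_calibration",
    "presso_global_calibration",
    "directional_pleiotropy_behavior",
    "majority_valid_median",
    "outlier_detection",
    "clump_oracle_agreement",
    "bh_oracle_agreement",
    "loo_oracle_agreement",
    "double_flip_identity_rate",
    "single_snp_wald_equality",
    "mediation_recovery",
    "planted_cascade_audit",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n) & 0x7FFFFFFF).astype(np.int64)


def _mean_and_mcse(values) -> tuple[float, float]:
    v = np.asarray(values, float)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))


def estimator_recovery(
    seed: int = 0,
    n_reps: int = 500,
    k: int = 50,
    theta: float = 0.3,
    n_exposure: int = 100_000,
    n_case: int = 25_000,
    n_control: int = 25_000,
    presso_n_sim: int = 200,
) -> dict[str, dict[str, float]]:
    """Sampling distribution of all seven estimators under no pleiotropy.

    Returns {method: {mean, mc_se, n_reps}} for the point estimates.
    """
    panel = simulate_ld_panel(k, 1, 0.0, seed=seed)
    seeds = _child_seeds(seed, n_reps)
    ests: dict[str, list[float]] = {
        m: [] for m in ("ivw", "egger", "weighted_median", "weighted_mode",
                        "robust_ivw", "raps", "presso")
    }
    for s in seeds:
        truth = make_truth(
            k, theta, n_exposure=n_exposure, n_outcome=n_case + n_control,
            n_case=n_case, n_control=n_control, gamma_range=(0.1, 0.3), seed=int(s),
        )
        e, o = simulate_two_sample(truth, panel, outcome_type="binary")
        h = harmonize(e, o, panel)
        ests["ivw"].append(ivw(h).estimate)
        ests["egger"].append(egger(h).estimate)
        ests["weighted_median"].append(weighted_median(h, n_boot=0).estimate)
        ests["weighted_mode"].append(weighted_mode(h, n_boot=0).estimate)
        ests["robust_ivw"].append(robust_ivw(h).estimate)
        ests["raps"].append(raps(h).estimate)
        ests["presso"].append(presso(h, n_sim=presso_n_sim, seed=int(s)).estimate)
    out = {}
    for m, v in ests.items():
        mean, mcse = _mean_and_mcse(v)
        out[m] = {"mean": mean, "mc_se": mcse, "n_reps": n_reps}
    return out


def ivw_type1_calibration(
    seed: int = 0, n_reps: int = 1000, k: int = 20, alpha: float = 0.05
) -> dict[str, float]:
    """Rejection rate of the fixed-effect IVW test at the null theta = 0.

    The fixed-effect variant is the one with exact nominal calibration
    under a homogeneous null; the multiplicative random-effects variant
    is conservative by construction (its SE floor never credits
    underdispersion)."""
    panel = simulate_ld_panel(k, 1, 0.0, seed=seed)
    seeds = _child_seeds(seed + 1, n_reps)
    rejections = 0
    for s in seeds:
        truth = make_truth(k, 0.0, seed=int(s))
        e, o = simulate_two_sample(truth, panel)
        rejections += ivw(harmonize(e, o, panel), model="fixed").pval < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps}


def presso_global_calibration(
    seed: int = 0, n_reps: int = 500, n_sim: int = 1000, k: int = 20, alpha: float = 0.05
) -> dict[str, float]:
    """Rejection rate of the PRESSO global RSS test under no pleiotropy."""
    panel = simulate_ld_panel(k, 1, 0.0, seed=seed)
    seeds = _child_seeds(seed + 2, n_reps)
    rejections = 0
    for s in seeds:
        truth = make_truth(k, 0.3, seed=int(s))
        e, o = simulate_two_sample(truth, panel)
        res = presso(harmonize(e, o, panel), n_sim=n_sim, seed=int(s) + 1)
        rejections += res.extras["presso_global_p"] < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps}


def directional_pleiotropy_behavior(
    seed: int = 0,
    n_reps: int = 200,
    k: int = 100,
    theta: float = 0.3,
    alpha_mean: float = 0.1,
    alpha_sd: float = 0.01,
) -> dict[str, dict[str, float]]:
    """IVW bias and Egger slope/intercept under directional pleiotropy.

    The IVW bias is compared against its analytic value
    sum(w gamma alpha) / sum(w gamma^2) computed from each rep's realized
    direct effects (an inverse-variance weighted mean direct effect per
    unit of instrument strength).
    """
    panel = simulate_ld_panel(k, 1, 0.0, seed=seed)
    seeds = _child_seeds(seed + 3, n_reps)
    ivw_bias, expected_bias, slopes, intercepts = [], [], [], []
    for s in seeds:
        truth = make_truth(
            k, theta, pleiotropy="directional", n_exposure=1_300_000,
            pleiotropy_mean=alpha_mean, pleiotropy_scale=alpha_sd,
            gamma_range=(0.1, 0.3), seed=int(s),
        )
        e, o = simulate_two_sample(truth, panel)
        h = harmonize(e, o, panel)
        sy = h.df["se_y"].to_numpy(float)
        w = 1.0 / sy**2
        expected_bias.append(
            np.sum(w * truth.gamma * truth.alpha) / np.sum(w * truth.gamma**2)
        )
        ivw_bias.append(ivw(h).estimate - theta)
        res = egger(h)
        slopes.append(res.estimate)
        intercepts.append(res.extras["egger_intercept"])
    out = {}
    for name, vals in (
        ("ivw_bias", ivw_bias),
        ("expected_ivw_bias", expected_bias),
        ("egger_slope", slopes),
        ("egger_intercept", intercepts),
    ):
        mean, mcse = _mean_and_mcse(vals)
        out[name] = {"mean": mean, "mc_se": mcse, "n_reps": n_reps}
    return out


def majority_valid_median(
    seed: int = 0,
    n_reps: int = 200,
    k: int = 50,
    theta: float = 0.5,
    invalid_fraction: float = 0.4,
    n_outcome: int = 5_000_000,
) -> dict[str, float]:
    """Weighted median with a minority of +1-ratio-biased instruments,
    in the strong-instrument (large outcome GWAS) regime where its
    consistency guarantee applies."""
    panel = simulate_ld_panel(k, 1, 0.0, seed=seed)
    seeds = _child_seeds(seed + 4, n_reps)
    n_invalid = int(round(invalid_fraction * k))
    ests = []
    for s in seeds:
        truth = make_truth(k, theta, n_outcome=n_outcome, gamma_range=(0.1, 0.3), seed=int(s))
        truth.alpha[:n_invalid] = truth.gamma[:n_invalid]  # ratio bias +1
        e, o = simulate_two_sample(truth, panel)
        ests.append(weighted_median(harmonize(e, o, panel), n_boot=0).estimate)
    mean, mcse = _mean_and_mcse(ests)
    return {"mean": mean, "mc_se": mcse, "n_reps": n_reps}


def outlier_detection(
    seed: int = 0,
    n_reps: int = 200,
    k_clean: int = 20,
    outlier_alpha: float = 1.5,
    theta: float = 0.3,
    n_sim: int = 1000,
) -> dict[str, float]:
    """PRESSO flag rate for one planted outlier and the fraction of reps
    where robust IVW beats plain IVW in absolute error."""
    k = k_clean + 1
    panel = simulate_ld_panel(k, 1, 0.0, seed=seed)
    seeds = _child_seeds(seed + 5, n_reps)
    flagged = robust_wins = 0
    for s in seeds:
        truth = make_truth(k, theta, seed=int(s))
        out_idx = int(np.random.default_rng(int(s)).integers(k))
        truth.alpha[:] = 0.0
        truth.alpha[out_idx] = outlier_alpha
        e, o = simulate_two_sample(truth, panel)
        h = harmonize(e, o, panel)
        outlier_id = h.df["snp_id"].iloc[out_idx]
        res = presso(h, n_sim=n_sim, seed=int(s) + 1)
        flagged += outlier_id in res.extras["outlier_ids"]
        err_robust = abs(robust_ivw(h).estimate - theta)
        err_plain = abs(ivw(h).estimate - theta)
        robust_wins += err_robust < err_plain
    return {
        "presso_flag_rate": flagged / n_reps,
        "robust_beats_ivw_rate": robust_wins / n_reps,
        "n_reps": n_reps,
    }


# --- oracle equalities -------------------------------------------------------


def _brute_force_clump(assocs, panel, r2_max, window_kb):
    remaining = sorted(assocs, key=lambda a: (a.pval, a.pos, a.snp_id))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            o
            for o in remaining
            if not (
                abs(o.pos - best.pos) <= window_kb * 1000
                and panel.r_between(best.snp_id, o.snp_id) ** 2 >= r2_max
            )
        ]
    return [a.snp_id for a in kept]


def clump_oracle_agreement(seed: int = 0, n_cases: int = 1000) -> dict[str, float]:
    """Greedy clumping vs an exhaustive reference on random panels of up
    to 12 variants."""
    from .instrument_selection import ld_clump

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        n = int(rng.integers(2, 13))
        A = rng.normal(size=(n, max(2, n // 2)))
        r = np.corrcoef(A)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000, 997), size=n, replace=False))
        ids = [f"v{i}" for i in range(n)]
        variants = pd.DataFrame(
            {"snp_id": ids, "chrom": "1", "pos": pos, "allele1": "A", "allele2": "G"}
        )
        panel = LDPanel(variants, r)
        assocs = [
            VariantAssociation(
                snp_id=ids[i], chrom="1", pos=int(pos[i]), effect_allele="A",
                other_allele="G", eaf=0.3, beta=0.1, se=0.01,
                pval=float(rng.uniform(1e-30, 1e-8)), n=100_000,
            )
            for i in range(n)
        ]
        got = [a.snp_id for a in ld_clump(assocs, panel, 0.2, 1_500)]
        agree += got == _brute_force_clump(assocs, panel, 0.2, 1_500)
    return {"agreement": agree / n_cases, "n_cases": n_cases}


def _brute_force_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        adjusted[idx] = min(
            1.0, min(p[order[j - 1]] * m / j for j in range(rank_pos, m + 1))
        )
    return adjusted


def bh_oracle_agreement(seed: int = 0, n_cases: int = 1000) -> dict[str, float]:
    """BH adjustment vs brute-force step-up on random p-vectors."""
    rng = np.random.default_rng(seed + 6)
    agree = 0
    for _ in range(n_cases):
        p = rng.uniform(size=int(rng.integers(1, 21)))
        adjusted, _ = bh_fdr(p)
        agree += np.allclose(adjusted, _brute_force_bh(p), atol=1e-12)
    return {"agreement": agree / n_cases, "n_cases": n_cases}


def loo_oracle_agreement(seed: int = 0, n_cases: int = 50) -> dict[str, float]:
    """Leave-one-out rows vs direct IVW on the corresponding subsets."""
    agree = total = 0
    seeds = _child_seeds(seed + 7, n_cases)
    for s in seeds:
        k = int(np.random.default_rng(int(s)).integers(3, 12))
        panel = simulate_ld_panel(k, 1, 0.0, seed=int(s))
        truth = make_truth(k, 0.25, seed=int(s))
        e, o = simulate_two_sample(truth, panel)
        h = harmonize(e, o, panel)
        loo = leave_one_out(h)
        for _, row in loo.iterrows():
            direct = ivw(h.drop([row["left_out"]]))
            agree += abs(row["estimate"] - direct.estimate) < 1e-12
            total += 1
    return {"agreement": agree / total, "n_cases": total}


def single_snp_wald_equality(seed: int = 0, n_cases: int = 200) -> dict[str, float]:
    """Single-instrument IVW equals the Wald ratio exactly."""
    rng = np.random.default_rng(seed + 8)
    agree = 0
    for _ in range(n_cases):
        bx, by = rng.normal(0.2, 0.05), rng.normal(0.05, 0.05)
        sy = rng.uniform(0.01, 0.1)
        df = pd.DataFrame(
            {
                "snp_id": ["rs1"], "beta_x": [bx], "se_x": [0.01], "beta_y": [by],
                "se_y": [sy], "eaf_x": [0.3], "eaf_y": [0.3],
                "n_x": [100_000], "n_y": [50_000],
            }
        )
        from .datatypes import HarmonizedSet

        res = ivw(HarmonizedSet(df))
        agree += res.estimate == by / bx and res.se == sy / abs(bx)
    return {"agreement": agree / n_cases, "n_cases": n_cases}


def double_flip_identity_rate(seed: int = 0, n_cases: int = 1000) -> dict[str, float]:
    """Harmonizing an outcome whose alleles were swapped twice equals
    harmonizing the original, over random non-palindromic variant pairs."""
    rng = np.random.default_rng(seed + 9)
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
    agree = 0
    for _ in range(n_cases):
        ea, oa = pairs[rng.integers(len(pairs))]
        x = VariantAssociation(
            "rs1", "1", 100, ea, oa, float(rng.uniform(0.05, 0.95)),
            float(rng.normal(0, 0.2)) or 0.1, 0.01, 1e-10, 100_000,
        )
        swap = rng.random() < 0.5
        y = VariantAssociation(
            "rs1", "1", 100, oa if swap else ea, ea if swap else oa,
            float(rng.uniform(0.05, 0.95)), float(rng.normal(0, 0.2)), 0.02,
            1e-4, 50_000,
        )
        h0 = harmonize([x], [y])
        h2 = harmonize([x], [y.flipped().flipped()])
        agree += np.allclose(
            h0.df[["beta_y", "eaf_y"]].to_numpy(float),
            h2.df[["beta_y", "eaf_y"]].to_numpy(float),
        )
    return {"agreement": agree / n_cases, "n_cases": n_cases}


def mediation_recovery(
    seed: int = 0,
    n_reps: int = 200,
    a: float = 0.2,
    b: float = 0.5,
    direct: float = 0.1,
    k: int = 15,
    n: int = 200_000,
    n_boot: int = 10_000,
) -> dict[str, float]:
    """Coverage of the bootstrap CI for the mediated proportion and the
    sampling mean of its point estimate, running the full two-step
    pipeline per rep (instrument selection at 5e-8 for the exposure and
    1e-5 for the mediator, harmonization, IVW for a, b and the total)."""
    from .instrument_selection import select_instruments

    panel = simulate_ld_panel(2 * k, 1, 0.0, seed=seed)
    seeds = _child_seeds(seed + 10, n_reps)
    true_prop = a * b / (direct + a * b)
    covered = 0
    points = []
    for s in seeds:
        truth = SimulationTruth(
            theta=direct,
            gamma=np.random.default_rng(int(s)).uniform(0.05, 0.15, k),
            alpha=np.zeros(k),
            n_exposure=n, n_outcome=n,
            a=a, b=b,
            gamma_mediator=np.random.default_rng(int(s) + 1).uniform(0.05, 0.15, k),
            n_mediator=n,
            seed=int(s),
        )
        exposure, mediator, outcome = simulate_mediation_scenario(truth, panel)
        exp_inst = select_instruments(exposure.assocs(), panel).kept
        exp_ids = {v.snp_id for v in exp_inst}
        # disjoint instrument sets: the exposure's cis instruments reach the
        # mediator through the exposure (ratio total/a, not b) and must not
        # double as mediator instruments
        med_pool = [a for a in mediator.assocs() if a.snp_id not in exp_ids]
        med_inst = select_instruments(med_pool, panel, p_threshold=1e-5).kept
        exp_ds = SummaryDataset.from_assocs(exp_inst, "exposure")
        med_ds = SummaryDataset.from_assocs(med_inst, "mediator")
        a_res = ivw(harmonize(exp_ds, mediator, panel))
        b_res = ivw(harmonize(med_ds, outcome, panel))
        t_res = ivw(harmonize(exp_ds, outcome, panel))
        est = mediated_proportion(
            a_res.estimate, a_res.se, b_res.estimate, b_res.se,
            t_res.estimate, t_res.se, n_boot=n_boot, seed=int(s) + 2,
        )
        points.append(est.proportion)
        covered += est.ci_low <= true_prop <= est.ci_high
    mean, mcse = _mean_and_mcse(points)
    return {
        "coverage": covered / n_reps,
        "mean_proportion": mean,
        "mc_se": mcse,
        "n_reps": n_reps,
        "true_proportion": true_prop,
    }


def planted_cascade_audit() -> dict[str, dict[str, str] | bool]:
    """Filter-cascade contract fixture: five planted violations among
    clean instruments, each of which must be dropped with its specific
    reason code.

    Planted: a variant at exactly p = 5e-8 (stored p-value at the
    threshold), a weak instrument whose stored p passes but whose beta/se
    give F = 9, a rare variant (MAF 0.005), a palindromic variant with
    EAF 0.48, and a Steiger-reversed variant explaining far more outcome
    than exposure variance.
    """
    n = 10
    pos = [1_000_000 + 50_000 * i for i in range(n)]
    ids = [f"clean_{i}" for i in range(5)] + [
        "planted_psig", "planted_weak", "planted_rare", "planted_palin", "planted_steiger",
    ]
    alleles = [("A", "G")] * 8 + [("A", "T"), ("C", "G")]
    variants = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": "1",
            "pos": pos,
            "allele1": [a[0] for a in alleles],
            "allele2": [a[1] for a in alleles],
            "eaf": [0.3] * n,
        }
    )
    panel = LDPanel(variants, np.eye(n))

    def assoc(i, eaf=0.3, beta=0.1, se=0.01, pval=1e-12, n_=100_000):
        return VariantAssociation(
            snp_id=ids[i], chrom="1", pos=pos[i], effect_allele=alleles[i][0],
            other_allele=alleles[i][1], eaf=eaf, beta=beta, se=se, pval=pval, n=n_,
        )

    exposure_assocs = [assoc(i) for i in range(5)] + [
        assoc(5, pval=5e-8),                          # exactly at the threshold
        assoc(6, beta=0.03, se=0.01, pval=1e-12),     # stored p passes, F = 9
        assoc(7, eaf=0.005),                          # MAF below 0.01
        assoc(8, eaf=0.48),                           # ambiguous palindrome
        assoc(9, beta=0.06, se=0.01, pval=1e-8),      # weak on the exposure...
    ]
    outcome_assocs = [
        VariantAssociation(
            snp_id=ids[i], chrom="1", pos=pos[i], effect_allele=alleles[i][0],
            other_allele=alleles[i][1], eaf=0.3 if i != 8 else 0.48,
            beta=0.03 if i != 9 else 0.9,             # ...but huge on the outcome
            se=0.01, pval=1e-3, n=50_000,
        )
        for i in range(n)
    ]
    exposure = SummaryDataset.from_assocs(exposure_assocs, "exposure")
    outcome = SummaryDataset.from_assocs(outcome_assocs, "outcome")
    hset = run_cascade(exposure, outcome, panel)
    reasons = {r.snp_id: r.reason.value for r in hset.audit}
    expected = {
        "planted_psig": "not_significant",
        "planted_weak": "weak_instrument",
        "planted_rare": "low_maf",
        "planted_palin": "palindrome_unresolved",
        "planted_steiger": "steiger_reversed",
    }
    kept = sorted(hset.df["snp_id"])
    return {
        "reasons": reasons,
        "expected": expected,
        "exact_match": reasons == expected and kept == sorted(ids[:5]),
    }
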