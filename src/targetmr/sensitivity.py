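"""Heterogeneity, pleiotropy and robustness diagnostics around the MR core.

Cochran's Q over Wald ratios, leave-one-out IVW, phenome-screen-driven SNP
exclusion with re-analysis, and a positive-control direction check (the
lipid instruments are expected to protect against coronary artery disease;
a control run failing that check invalidates the instrument set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HarmonizedSet, MRResult
from .harmonization import wald_components
from .mr_core import egger, ivw

__all__ = [
    "cochran_q",
    "leave_one_out",
    "flag_phenome_snps",
    "exclude_and_rerun",
    "positive_control",
    "SensitivityReport",
    "sensitivity_report",
]


def cochran_q(hset: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP Wald ratios with first-order weights.

    Q = sum_j w_j (ratio_j - theta_ivw)^2, w_j = 1 / se_ratio_j^2;
    p from chi-square with k - 1 df. Note w_j = (beta_x / se_y)^2, so this
    Q equals the one reported by the IVW fit.
    """
    if hset.n_snps < 2:
        raise ValueError("cochran_q requires at least 2 SNPs")
    wc = wald_components(hset)
    w = 1.0 / wc["se_ratio"].to_numpy(float) ** 2
    r = wc["ratio"].to_numpy(float)
    theta = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - theta) ** 2))
    df = len(r) - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(hset: HarmonizedSet, model: str = "auto") -> pd.DataFrame:
    """IVW re-fit omitting each SNP in turn.

    Returns one row per left-out SNP with the subset estimate, SE and p,
    plus the deviation from the full-set estimate and a sign-change flag.
    """
    if hset.n_snps < 3:
        raise ValueError("leave_one_out requires at least 3 SNPs")
    full = ivw(hset, model=model)
    rows = []
    for snp in hset.df["snp_id"]:
        sub = ivw(hset.drop([snp]), model=model)
        rows.append(
            {
                "left_out": snp,
                "estimate": sub.estimate,
                "se": sub.se,
                "pval": sub.pval,
                "deviation": sub.estimate - full.estimate,
                "sign_change": np.sign(sub.estimate) != np.sign(full.estimate),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["full_estimate"] = full.estimate
    df.attrs["max_abs_deviation"] = float(df["deviation"].abs().max())
    return df


def flag_phenome_snps(
    phenome: pd.DataFrame,
    snp_ids: Sequence[str],
    alpha: float = 0.05,
    threshold: Optional[float] = None,
) -> list[str]:
    """SNPs associated with any screened phenotype below the threshold.

    ``phenome`` holds (snp_id, phenotype, p_value) rows from a
    phenome-wide screen. The default threshold is Bonferroni:
    alpha / (n_snps x n_phenotypes).
    """
    need = {"snp_id", "phenotype", "p_value"}
    if not need <= set(phenome.columns):
        raise ValueError(f"phenome table must have columns {sorted(need)}")
    sub = phenome[phenome["snp_id"].isin(set(snp_ids))]
    if threshold is None:
        n_phen = sub["phenotype"].nunique()
        if n_phen == 0:
            return []
        threshold = alpha / (len(set(snp_ids)) * n_phen)
    hits = sub[sub["p_value"] < threshold]
    return sorted(hits["snp_id"].unique())


def exclude_and_rerun(
    hset: HarmonizedSet,
    flagged: Sequence[str],
    consistency_factor: float = 0.5,
    model: str = "auto",
) -> tuple[MRResult, MRResult, float]:
    """Re-run IVW after excluding flagged (e.g. phenome-pleiotropic) SNPs.

    Returns (before, after, delta = after - before). The ``after`` result
    carries a ``consistent`` verdict: |delta| < consistency_factor x
    SE_before.
    """
    ids = set(hset.df["snp_id"])
    missing = [s for s in flagged if s not in ids]
    if missing:
        raise ValueError(f"flagged SNPs absent from harmonized set: {missing}")
    before = ivw(hset, model=model)
    after = ivw(hset.drop(list(flagged)), model=model) if flagged else before
    delta = after.estimate - before.estimate
    after.extras["rerun_delta"] = delta
    after.extras["consistent"] = bool(abs(delta) < consistency_factor * before.se)
    after.extras["excluded_snps"] = list(flagged)
    return before, after, delta


def positive_control(
    hset_control: HarmonizedSet,
    expected_direction: int = -1,
    alpha: float = 0.05,
    model: str = "auto",
) -> dict:
    """Direction check on a control outcome with a known expected effect.

    PASS iff the IVW estimate's sign matches ``expected_direction`` and
    p < alpha; otherwise FAIL with a reason ("no significant effect" or
    "direction mismatch").
    """
    if expected_direction not in (-1, 1):
        raise ValueError("expected_direction must be -1 or +1")
    res = ivw(hset_control, model=model)
    if res.pval >= alpha:
        verdict, reason = "FAIL", "no significant effect"
    elif np.sign(res.estimate) != expected_direction:
        verdict, reason = "FAIL", "direction mismatch"
    else:
        verdict, reason = "PASS", ""
    return {
        "verdict": verdict,
        "reason": reason,
        "estimate": res.estimate,
        "se": res.se,
        "pval": res.pval,
        "expected_direction": expected_direction,
    }


@dataclass
class SensitivityReport:
    """Bundle of diagnostics for one exposure/outcome pair."""

    q: float
    q_df: int
    q_p: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    loo: pd.DataFrame
    excluded_snps: list[str] = field(default_factory=list)
    rerun_delta: float = np.nan
    positive_control: Optional[dict] = None

    def to_row(self) -> dict:
        return {
            "q": self.q,
            "q_df": self.q_df,
            "q_p": self.q_p,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
            "loo_max_abs_deviation": self.loo.attrs.get("max_abs_deviation", np.nan),
            "loo_any_sign_change": bool(self.loo["sign_change"].any()),
            "excluded_snps": ";".join(self.excluded_snps),
            "rerun_delta": self.rerun_delta,
            "positive_control": (self.positive_control or {}).get("verdict", ""),
        }


def sensitivity_report(
    hset: HarmonizedSet,
    phenome: Optional[pd.DataFrame] = None,
    control: Optional[HarmonizedSet] = None,
    expected_direction: int = -1,
) -> SensitivityReport:
    """Assemble Q, Egger intercept, LOO, phenome exclusion and positive
    control into one report."""
    q, df, q_p = cochran_q(hset)
    eg = egger(hset)
    loo = leave_one_out(hset)
    excluded: list[str] = []
    delta = np.nan
    if phenome is not None:
        excluded = flag_phenome_snps(phenome, hset.df["snp_id"].tolist())
        if excluded:
            _, _, delta = exclude_and_rerun(hset, excluded)
    control_res = positive_control(control, expected_direction) if control is not None else None
    return SensitivityReport(
        q=q,
        q_df=df,
        q_p=q_p,
        egger_intercept=eg.extras["egger_intercept"],
        egger_intercept_se=eg.extras["intercept_se"],
        egger_intercept_p=eg.extras["intercept_p"],
        loo=loo,
        excluded_snps=excluded,
        rerun_delta=delta,
        positive_control=control_res,
    )
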