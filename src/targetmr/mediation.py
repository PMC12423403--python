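"""Two-step mediation MR with mediated proportions and bootstrap CIs.

Step 1 screens candidate mediators (gut microbial taxa, cytokines) for a
causal effect on the outcome, using a looser instrument p-value threshold
(1e-5) appropriate for traits with few genome-wide-significant hits. Step
2 estimates the drug-target (exposure) effect on each qualifying mediator
using the cis instruments. The indirect effect is the product a x b and
the mediated proportion is (a x b) / total; its CI comes from a parametric
bootstrap drawing a, b and the total independently (justified by
non-overlapping instrument sets for a and b; the total's sampling noise
contributes real variance to the proportion, and omitting it makes the
interval under-cover). Holding the total at its point estimate is
available behind a flag for totals estimated near zero, where the
resampled denominator makes the proportion heavy-tailed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    AuditRecord,
    HarmonizedSet,
    LDPanel,
    MediationEstimate,
    MRResult,
    SummaryDataset,
)
from .harmonization import harmonize
from .instrument_selection import select_instruments, steiger_filter
from .mr_core import ivw

__all__ = ["screen_mediators", "exposure_to_mediator", "mediated_proportion", "two_step_mediation"]


def _cascade_and_ivw(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    panel: LDPanel,
    iv_p: float,
    apply_steiger: bool = True,
    exclude_ids: Optional[set[str]] = None,
) -> tuple[Optional[MRResult], HarmonizedSet]:
    assocs = exposure.assocs()
    if exclude_ids:
        assocs = [a for a in assocs if a.snp_id not in exclude_ids]
    kept = select_instruments(assocs, panel, p_threshold=iv_p).kept
    hset = harmonize(
        SummaryDataset.from_assocs(kept, exposure.trait, exposure.trait_scale),
        outcome,
        panel,
    )
    if apply_steiger and len(hset):
        hset = steiger_filter(hset)
    if hset.n_snps < 2:
        return None, hset
    return ivw(hset), hset


def screen_mediators(
    mediator_sets: dict[str, SummaryDataset],
    outcome: SummaryDataset,
    panel: LDPanel,
    iv_p: float = 1e-5,
    alpha: float = 0.05,
    exclude_ids: Optional[set[str]] = None,
) -> tuple[dict[str, MRResult], list[AuditRecord]]:
    """Step 1: mediator -> outcome MR for every candidate mediator.

    Each mediator gets the full instrument cascade (at the looser ``iv_p``)
    plus harmonization and IVW; it qualifies when IVW p < ``alpha``.
    Mediators left with fewer than 2 instruments are skipped with an audit
    record. ``exclude_ids`` removes the exposure's cis instruments from
    the mediator's instrument pool, keeping the two steps' instrument
    sets disjoint (the premise under which the a and b estimates are
    independent). Returns ({mediator: MRResult with
    extras['qualifies']}, audit).
    """
    results: dict[str, MRResult] = {}
    audit: list[AuditRecord] = []
    for name, mset in mediator_sets.items():
        res, hset = _cascade_and_ivw(mset, outcome, panel, iv_p, exclude_ids=exclude_ids)
        if res is None:
            from .datatypes import DropReason

            audit.append(
                AuditRecord(name, DropReason.WEAK_INSTRUMENT, f"{hset.n_snps} instrument(s)")
            )
            continue
        res.extras["qualifies"] = bool(res.pval < alpha)
        results[name] = res
    return results, audit


def exposure_to_mediator(hset: HarmonizedSet) -> MRResult:
    """Step 2: IVW of the drug-target cis instruments on a mediator GWAS."""
    return ivw(hset)


def mediated_proportion(
    a: float,
    a_se: float,
    b: float,
    b_se: float,
    total: float,
    total_se: float,
    n_boot: int = 10_000,
    seed: int = 0,
    resample_total: bool = True,
    labels: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
) -> MediationEstimate:
    """Product-of-coefficients mediated proportion with a bootstrap CI.

    Draws a* ~ N(a, a_se^2), b* ~ N(b, b_se^2) and total* ~
    N(total, total_se^2) independently; the CI is the percentile 2.5/97.5
    interval of (a* b*) / total*. With ``resample_total=False`` the
    denominator is held at its point estimate (narrower, under-covering
    intervals, but immune to heavy tails when the total is near zero).
    Proportions outside [0, 1] are reported verbatim with
    ``out_of_range`` set, never truncated. A delta-method SE of the
    proportion (over a and b only) is recorded for cross-checking.
    """
    if total == 0:
        raise ValueError("total effect is zero; proportion undefined")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    a_star = rng.normal(a, a_se, size=n_boot)
    b_star = rng.normal(b, b_se, size=n_boot)
    denom = rng.normal(total, total_se, size=n_boot) if resample_total else total
    props = a_star * b_star / denom
    ci_low, ci_high = np.percentile(props, [2.5, 97.5])
    point = a * b / total
    # first-order delta method on (a, b) with total fixed
    delta_se = abs(1.0 / total) * np.sqrt(b**2 * a_se**2 + a**2 * b_se**2)
    return MediationEstimate(
        exposure=labels[0],
        mediator=labels[1],
        outcome=labels[2],
        a=a,
        a_se=a_se,
        b=b,
        b_se=b_se,
        total=total,
        total_se=total_se,
        n_boot=n_boot,
        seed=seed,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        delta_se=float(delta_se),
        out_of_range=bool(not (0.0 <= point <= 1.0)),
    )


def two_step_mediation(
    exposure: SummaryDataset,
    mediator_sets: dict[str, SummaryDataset],
    outcome: SummaryDataset,
    panel: LDPanel,
    exposure_iv_p: float = 5e-8,
    mediator_iv_p: float = 1e-5,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full two-step analysis for one exposure/outcome pair.

    Runs the mediator screen, estimates a (exposure -> mediator via the
    cis instruments), b (mediator -> outcome from the screen) and the
    total effect (exposure -> outcome), and returns one mediation row per
    qualifying mediator.
    """
    total_res, total_hset = _cascade_and_ivw(exposure, outcome, panel, exposure_iv_p)
    if total_res is None:
        raise ValueError("exposure has fewer than 2 usable instruments against the outcome")
    # keep the two steps' instrument sets disjoint: the drug target's cis
    # instruments must not double as mediator instruments
    cis_ids = set(total_hset.df["snp_id"])
    screened, _ = screen_mediators(
        mediator_sets, outcome, panel, iv_p=mediator_iv_p, exclude_ids=cis_ids
    )
    rows = []
    for name, b_res in screened.items():
        a_res, _ = _cascade_and_ivw(exposure, mediator_sets[name], panel, exposure_iv_p)
        if a_res is None:
            continue
        est = mediated_proportion(
            a_res.estimate,
            a_res.se,
            b_res.estimate,
            b_res.se,
            total_res.estimate,
            total_res.se,
            n_boot=n_boot,
            seed=seed,
            labels=(exposure.trait or "exposure", name, outcome.trait or "outcome"),
        )
        est.qualifies = bool(b_res.extras.get("qualifies", False))
        rows.append(est.to_row())
    return pd.DataFrame(rows)
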