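"""Allele harmonization between exposure and outcome summary statistics.

Aligns every outcome association to the exposure's effect allele:
same-order alleles are copied; swapped alleles flip the outcome beta and
complement its frequency; strand differences (A/G vs T/C) are resolved by
complementing; palindromic (A/T, C/G) variants are resolved from allele
frequencies and excluded outright when the exposure MAF falls in
(0.4, 0.5], where frequency carries no strand information. Instruments the
outcome GWAS lacks are replaced by their best LD proxy (r^2 >= 0.8 by
default), with the effect-allele phase carried by the sign of the panel
correlation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    HARMONIZED_COLUMNS,
    AuditRecord,
    DropReason,
    HarmonizedSet,
    LDPanel,
    SummaryDataset,
    VariantAssociation,
)
from .instrument_selection import infer_palindrome_strand

__all__ = ["harmonize", "wald_components"]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return "".join(_COMP.get(b, "N") for b in allele)


def _align_to(target_ea: str, target_oa: str, assoc: VariantAssociation):
    """Align ``assoc`` so its effect allele equals ``target_ea``.

    Returns (aligned association, flipped?) or None when the allele pairs
    are incompatible even after strand complementing. Palindromic variants
    must not be routed here (complementing is ambiguous for them).
    """
    ea, oa = assoc.effect_allele, assoc.other_allele
    if (ea, oa) == (target_ea, target_oa):
        return assoc, False
    if (ea, oa) == (target_oa, target_ea):
        return assoc.flipped(), True
    cea, coa = _complement(ea), _complement(oa)
    if (cea, coa) == (target_ea, target_oa):
        return assoc, False
    if (cea, coa) == (target_oa, target_ea):
        return assoc.flipped(), True
    return None


def _best_proxy(
    instrument: VariantAssociation,
    panel: LDPanel,
    outcome_ids: set[str],
    proxy_r2_min: float,
) -> Optional[tuple[str, float]]:
    """Highest-r^2 panel proxy available in the outcome; ties broken by
    distance then id."""
    i = panel.index_of(instrument.snp_id)
    if i is None:
        return None
    pos_i = int(panel.variants["pos"].iloc[i])
    best = None
    for j, snp_j in enumerate(panel.variants["snp_id"]):
        if j == i or snp_j not in outcome_ids:
            continue
        r2 = float(panel.r[i, j]) ** 2
        if r2 < proxy_r2_min:
            continue
        dist = abs(int(panel.variants["pos"].iloc[j]) - pos_i)
        key = (-r2, dist, snp_j)
        if best is None or key < best[0]:
            best = (key, snp_j, r2)
    if best is None:
        return None
    return best[1], best[2]


def _proxy_outcome(
    instrument: VariantAssociation,
    proxy_id: str,
    outcome_by_id: dict[str, VariantAssociation],
    panel: LDPanel,
) -> Optional[VariantAssociation]:
    """Express the proxy's outcome association on the instrument's alleles.

    Both variants are first put on the panel's allele1 scale; the signed
    panel correlation then phases the proxy's effect onto the instrument's
    allele1, and the result is reported with the instrument's allele pair.
    """
    i = panel.index_of(instrument.snp_id)
    j = panel.index_of(proxy_id)
    r = float(panel.r[i, j])
    prow = panel.variants.iloc[j]
    aligned = _align_to(prow["allele1"], prow["allele2"], outcome_by_id[proxy_id])
    if aligned is None:
        return None
    proxy_on_a1, _ = aligned
    sign = 1.0 if r >= 0 else -1.0
    irow = panel.variants.iloc[i]
    eaf = proxy_on_a1.eaf if sign > 0 else 1.0 - proxy_on_a1.eaf
    if "eaf" in panel.variants.columns and not np.isnan(panel.variants["eaf"].iloc[i]):
        eaf = float(panel.variants["eaf"].iloc[i])
    return VariantAssociation(
        snp_id=instrument.snp_id,
        chrom=instrument.chrom,
        pos=instrument.pos,
        effect_allele=str(irow["allele1"]),
        other_allele=str(irow["allele2"]),
        eaf=eaf,
        beta=sign * proxy_on_a1.beta,
        se=proxy_on_a1.se,
        pval=proxy_on_a1.pval,
        n=proxy_on_a1.n,
        trait_scale=proxy_on_a1.trait_scale,
        n_case=proxy_on_a1.n_case,
        n_control=proxy_on_a1.n_control,
    )


def harmonize(
    exposure: Sequence[VariantAssociation] | SummaryDataset,
    outcome: Sequence[VariantAssociation] | SummaryDataset,
    panel: Optional[LDPanel] = None,
    proxy_r2_min: float = 0.8,
    palindrome_maf_exclude: tuple[float, float] = (0.4, 0.5),
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> HarmonizedSet:
    """Align exposure and outcome associations to a common effect allele.

    An empty result is returned (with a full audit) rather than raising
    when no variant survives; duplicate snp_ids on either side raise.
    """
    if isinstance(exposure, SummaryDataset):
        exposure_label = exposure.trait or exposure_label
        exposure = exposure.assocs()
    if isinstance(outcome, SummaryDataset):
        outcome_label = outcome.trait or outcome_label
        outcome = outcome.assocs()

    exp_ids = [a.snp_id for a in exposure]
    if len(set(exp_ids)) != len(exp_ids):
        raise ValueError("duplicate snp_ids in exposure")
    out_by_id: dict[str, VariantAssociation] = {}
    for a in outcome:
        if a.snp_id in out_by_id:
            raise ValueError(f"duplicate snp_id in outcome: {a.snp_id}")
        out_by_id[a.snp_id] = a

    lo, hi = palindrome_maf_exclude
    rows = []
    audit: list[AuditRecord] = []
    for x in exposure:
        proxy_id, r2_proxy = None, np.nan
        y = out_by_id.get(x.snp_id)
        if y is None:
            if panel is not None:
                found = _best_proxy(x, panel, set(out_by_id), proxy_r2_min)
                if found is not None:
                    proxy_id, r2_proxy = found
                    y = _proxy_outcome(x, proxy_id, out_by_id, panel)
            if y is None:
                audit.append(AuditRecord(x.snp_id, DropReason.MISSING_IN_OUTCOME))
                continue

        flipped = False
        if x.is_palindromic:
            if lo < x.maf <= hi:
                audit.append(
                    AuditRecord(
                        x.snp_id,
                        DropReason.PALINDROME_UNRESOLVED,
                        f"maf={x.maf:.3f} in ({lo}, {hi}]",
                    )
                )
                continue
            # order by allele letters first, then let frequency decide strand
            if y.effect_allele == x.effect_allele:
                pass
            elif y.effect_allele == x.other_allele:
                y = y.flipped()
                flipped = True
            else:
                audit.append(AuditRecord(x.snp_id, DropReason.INCOMPATIBLE_ALLELES))
                continue
            resolved = infer_palindrome_strand(x, y)
            if resolved is None:
                audit.append(
                    AuditRecord(x.snp_id, DropReason.PALINDROME_UNRESOLVED, "ambiguous EAF")
                )
                continue
            if resolved[1].beta != y.beta:  # strand flip applied
                flipped = not flipped
            y = resolved[1]
        else:
            aligned = _align_to(x.effect_allele, x.other_allele, y)
            if aligned is None:
                audit.append(AuditRecord(x.snp_id, DropReason.INCOMPATIBLE_ALLELES))
                continue
            y, flipped = aligned

        rows.append(
            {
                "snp_id": x.snp_id,
                "beta_x": x.beta,
                "se_x": x.se,
                "beta_y": y.beta,
                "se_y": y.se,
                "eaf_x": x.eaf,
                "eaf_y": y.eaf,
                "n_x": x.n,
                "n_y": y.n,
                "flipped": flipped,
                "palindromic": x.is_palindromic,
                "proxy_used": proxy_id is not None,
                "proxy_id": proxy_id,
                "r2_proxy": r2_proxy,
            }
        )
    df = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    return HarmonizedSet(df, exposure_label, outcome_label, audit)


def wald_components(hset: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratios beta_y / beta_x with first-order SE se_y / |beta_x|.

    Rows with beta_x = 0 are dropped and recorded in the set's audit.
    """
    d = hset.df
    zero = d["beta_x"] == 0
    for snp in d.loc[zero, "snp_id"]:
        hset.audit.append(AuditRecord(snp, DropReason.ZERO_EXPOSURE_BETA))
    d = d[~zero]
    return pd.DataFrame(
        {
            "snp_id": d["snp_id"].to_numpy(),
            "ratio": d["beta_y"].to_numpy(float) / d["beta_x"].to_numpy(float),
            "se_ratio": d["se_y"].to_numpy(float) / np.abs(d["beta_x"].to_numpy(float)),
        }
    )
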