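"""Cis-instrument construction for drug-target genes.

The filter cascade mirrors standard drug-target MR practice: restrict to a
cis window around the target gene, keep genome-wide-significant variants
(p < 5e-8 for lipid exposures; a looser 1e-5 default is used for mediator
GWAS), require single-instrument F = (beta/se)^2 > 10, remove rare
variants (MAF < 0.01), LD-clump greedily at r^2 < 0.2 within 10,000 kb,
and finally apply Steiger directionality filtering against the outcome.

Significance and F thresholds are strict inequalities as is conventional;
boundary behaviour is pinned down in the test suite. Every dropped variant
is recorded with a reason code so |input| = |kept| + |dropped| at every
stage.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .datatypes import (
    AuditRecord,
    DropReason,
    GeneRegion,
    HarmonizedSet,
    InstrumentSet,
    LDPanel,
    VariantAssociation,
)

__all__ = [
    "select_cis",
    "filter_significance",
    "f_statistic",
    "filter_weak",
    "filter_maf",
    "ld_clump",
    "steiger_filter",
    "infer_palindrome_strand",
    "select_instruments",
]


def select_cis(
    assocs: Sequence[VariantAssociation],
    region: GeneRegion | Iterable[GeneRegion],
    audit: Optional[list[AuditRecord]] = None,
) -> list[VariantAssociation]:
    """Keep variants inside the cis window of one region or a region union.

    The window is [start - flank, end + flank], both ends inclusive, per
    region; for a union (e.g. adjacent ABCG5/ABCG8 loci analysed jointly)
    a variant is kept if any region's window contains it. Chromosome
    labels are compared after normalizing an optional 'chr' prefix.
    """
    regions = [region] if isinstance(region, GeneRegion) else list(region)
    if not regions:
        raise ValueError("at least one gene region required")
    kept = []
    for a in assocs:
        if any(r.contains(a.chrom, a.pos) for r in regions):
            kept.append(a)
        elif audit is not None:
            audit.append(AuditRecord(a.snp_id, DropReason.OUT_OF_WINDOW))
    return kept


def filter_significance(
    assocs: Sequence[VariantAssociation],
    p_threshold: float = 5e-8,
    audit: Optional[list[AuditRecord]] = None,
) -> list[VariantAssociation]:
    """Keep variants with p strictly below the threshold (default 5e-8)."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    kept = []
    for a in assocs:
        if a.pval < p_threshold:
            kept.append(a)
        elif audit is not None:
            audit.append(
                AuditRecord(a.snp_id, DropReason.NOT_SIGNIFICANT, f"p={a.pval:.3g}")
            )
    return kept


def f_statistic(assoc: VariantAssociation) -> float:
    """Single-instrument F statistic, F = (beta / se)^2."""
    return (assoc.beta / assoc.se) ** 2


def filter_weak(
    assocs: Sequence[VariantAssociation],
    f_min: float = 10.0,
    audit: Optional[list[AuditRecord]] = None,
) -> list[VariantAssociation]:
    """Keep variants with F strictly above ``f_min`` (default 10)."""
    kept = []
    for a in assocs:
        f = f_statistic(a)
        if f > f_min:
            kept.append(a)
        elif audit is not None:
            audit.append(AuditRecord(a.snp_id, DropReason.WEAK_INSTRUMENT, f"F={f:.3g}"))
    return kept


def filter_maf(
    assocs: Sequence[VariantAssociation],
    maf_min: float = 0.01,
    audit: Optional[list[AuditRecord]] = None,
) -> list[VariantAssociation]:
    """Remove variants with minor allele frequency strictly below ``maf_min``."""
    kept = []
    for a in assocs:
        if a.maf >= maf_min:
            kept.append(a)
        elif audit is not None:
            audit.append(AuditRecord(a.snp_id, DropReason.LOW_MAF, f"maf={a.maf:.4g}"))
    return kept


def _clump_sort_key(a: VariantAssociation):
    # p ascending, then position, then id: deterministic and order-free
    return (a.pval, a.pos, a.snp_id)


def ld_clump(
    assocs: Sequence[VariantAssociation],
    panel: LDPanel,
    r2_max: float = 0.2,
    window_kb: float = 10_000.0,
    audit: Optional[list[AuditRecord]] = None,
) -> list[VariantAssociation]:
    """Greedy LD clumping: keep the most significant remaining variant,
    discard everything within ``window_kb`` at r^2 >= ``r2_max`` against it.

    Variants absent from the panel are dropped with an audit record rather
    than raising. The result is independent of input order (ties on p are
    broken by position, then id).
    """
    in_panel = []
    for a in assocs:
        if a.snp_id in panel:
            in_panel.append(a)
        elif audit is not None:
            audit.append(AuditRecord(a.snp_id, DropReason.NOT_IN_PANEL))
    ordered = sorted(in_panel, key=_clump_sort_key)
    window_bp = window_kb * 1000.0

    kept: list[VariantAssociation] = []
    removed: set[str] = set()
    for a in ordered:
        if a.snp_id in removed:
            continue
        kept.append(a)
        for b in ordered:
            if b.snp_id in removed or b.snp_id == a.snp_id:
                continue
            if abs(b.pos - a.pos) <= window_bp and panel.r2_between(a.snp_id, b.snp_id) >= r2_max:
                removed.add(b.snp_id)
                if audit is not None:
                    audit.append(
                        AuditRecord(
                            b.snp_id,
                            DropReason.CLUMPED,
                            f"r2={panel.r2_between(a.snp_id, b.snp_id):.3f} with {a.snp_id}",
                        )
                    )
    return kept


def _variance_explained(z: np.ndarray, n: np.ndarray) -> np.ndarray:
    """r^2 = z^2 / (z^2 + n - 2), the squared-correlation identity."""
    z2 = z**2
    return z2 / (z2 + n - 2.0)


def steiger_filter(hset: HarmonizedSet) -> HarmonizedSet:
    """Drop variants explaining less variance in the exposure than in the
    outcome (reverse-causation guard); ties are kept.

    For binary traits the same z^2 / (z^2 + n - 2) approximation is used
    with n = n_case + n_control.
    """
    if len(hset) == 0:
        return hset
    bx, sx, by, sy = hset.arrays()
    n_x = hset.df["n_x"].to_numpy(float)
    n_y = hset.df["n_y"].to_numpy(float)
    if np.any(n_x <= 2) or np.any(n_y <= 2):
        raise ValueError("Steiger filtering requires per-trait n > 2")
    r2_x = _variance_explained(bx / sx, n_x)
    r2_y = _variance_explained(by / sy, n_y)
    reversed_mask = r2_x < r2_y
    dropped = hset.df.loc[reversed_mask, "snp_id"].tolist()
    out = hset.drop(dropped)
    for i, snp in zip(np.flatnonzero(reversed_mask), dropped):
        out.audit.append(
            AuditRecord(
                snp,
                DropReason.STEIGER_REVERSED,
                f"r2_x={r2_x[i]:.3g} < r2_y={r2_y[i]:.3g}",
            )
        )
    return out


def infer_palindrome_strand(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    ambiguous_zone: tuple[float, float] = (0.45, 0.55),
) -> tuple[VariantAssociation, VariantAssociation] | None:
    """Resolve strand for a palindromic (A/T or C/G) variant from allele
    frequencies.

    Both EAFs below the ambiguous zone or both above it: same strand, no
    change. Opposite sides: the outcome is flipped (beta negated, eaf
    complemented). Either EAF inside the zone: returns None (unresolved;
    downstream harmonization excludes it).
    """
    if not exposure.is_palindromic:
        raise ValueError(f"{exposure.snp_id} is not palindromic")
    lo, hi = ambiguous_zone
    ex, oy = exposure.eaf, outcome.eaf
    if ex is None or oy is None or np.isnan(ex) or np.isnan(oy):
        return None
    if lo <= ex <= hi or lo <= oy <= hi:
        return None
    if (ex < lo) == (oy < lo):
        return exposure, outcome
    return exposure, outcome.flipped()


def select_instruments(
    assocs: Sequence[VariantAssociation],
    panel: LDPanel,
    region: GeneRegion | Iterable[GeneRegion] | None = None,
    p_threshold: float = 5e-8,
    f_min: float = 10.0,
    maf_min: float = 0.01,
    clump_r2: float = 0.2,
    clump_kb: float = 10_000.0,
) -> InstrumentSet:
    """Run the pre-harmonization filter cascade and return kept + audit.

    Order: cis window (if a region is given) -> significance -> F ->
    MAF -> LD clumping. Steiger filtering needs outcome statistics and is
    applied after harmonization (see ``pipeline.run_cascade``).
    """
    audit: list[AuditRecord] = []
    current = list(assocs)
    if region is not None:
        current = select_cis(current, region, audit)
    current = filter_significance(current, p_threshold, audit)
    current = filter_weak(current, f_min, audit)
    current = filter_maf(current, maf_min, audit)
    current = ld_clump(current, panel, clump_r2, clump_kb, audit)
    return InstrumentSet(kept=current, audit=audit)
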