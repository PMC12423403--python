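"""Reading and writing the pipeline's plain-text formats.

Summary statistics travel as GWAS-SSF-like TSV; LD panels as a variant TSV
plus a dense matrix TSV; gene regions as BED-like files (0-based
half-open, converted to 1-based inclusive on read); simulation truth as a
YAML sidecar; harmonized sets as TSV with a ``#``-comment header recording
labels and drop audit.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    GWAS_COLUMNS,
    AuditRecord,
    DropReason,
    GeneRegion,
    HarmonizedSet,
    LDPanel,
    SummaryDataset,
)
from .synthetic_gwas import SimulationTruth

__all__ = [
    "read_summary",
    "write_summary",
    "read_panel",
    "write_panel",
    "read_regions_bed",
    "write_harmonized",
    "read_harmonized",
    "write_truth",
    "read_truth",
]


def read_summary(path: str | Path, trait: str = "", trait_scale: str | None = None) -> SummaryDataset:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chromosome": str})
    if trait_scale is None:
        trait_scale = "log-odds" if df.get("n_case") is not None and df["n_case"].notna().any() else "continuous"
    return SummaryDataset(df, trait=trait or Path(path).stem, trait_scale=trait_scale)


def write_summary(ds: SummaryDataset, path: str | Path) -> None:
    ds.df.to_csv(path, sep="\t", index=False, columns=GWAS_COLUMNS)


def write_panel(panel: LDPanel, variants_path: str | Path, matrix_path: str | Path) -> None:
    panel.variants.to_csv(variants_path, sep="\t", index=False)
    np.savetxt(matrix_path, panel.r, delimiter="\t", fmt="%.10g")


def read_panel(variants_path: str | Path, matrix_path: str | Path) -> LDPanel:
    variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
    r = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    return LDPanel(variants, r)


def read_regions_bed(path: str | Path, flank_kb: float = 250.0) -> list[GeneRegion]:
    """BED-like region file: chrom, start (0-based), end (half-open),
    symbol, optional per-row flank_kb."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "symbol", "flank_kb"][:5],
    )
    regions = []
    for row in df.itertuples(index=False):
        fk = flank_kb
        if hasattr(row, "flank_kb") and not pd.isna(row.flank_kb):
            fk = float(row.flank_kb)
        regions.append(
            GeneRegion(
                symbol=str(row.symbol),
                chrom=str(row.chrom),
                start=int(row.start) + 1,  # BED 0-based -> 1-based inclusive
                end=int(row.end),
                flank_kb=fk,
            )
        )
    return regions


def write_harmonized(hset: HarmonizedSet, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write(f"# exposure: {hset.exposure_label}\n")
    buf.write(f"# outcome: {hset.outcome_label}\n")
    for rec in hset.audit:
        buf.write(f"# dropped\t{rec.snp_id}\t{rec.reason.value}\t{rec.detail}\n")
    hset.df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_harmonized(path: str | Path) -> HarmonizedSet:
    exposure_label, outcome_label = "exposure", "outcome"
    audit: list[AuditRecord] = []
    lines = Path(path).read_text().splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        content = line[1:].strip()
        if content.startswith("exposure:"):
            exposure_label = content.split(":", 1)[1].strip()
        elif content.startswith("outcome:"):
            outcome_label = content.split(":", 1)[1].strip()
        elif content.startswith("dropped"):
            parts = content.split("\t")
            audit.append(
                AuditRecord(parts[1], DropReason(parts[2]), parts[3] if len(parts) > 3 else "")
            )
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t")
    if "proxy_id" in df.columns:
        df["proxy_id"] = df["proxy_id"].where(df["proxy_id"].notna(), None)
    return HarmonizedSet(df, exposure_label, outcome_label, audit)


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    payload = {
        "theta": float(truth.theta),
        "gamma": [float(x) for x in truth.gamma],
        "alpha": [float(x) for x in truth.alpha],
        "maf": None if truth.maf is None else [float(x) for x in truth.maf],
        "n_exposure": int(truth.n_exposure),
        "n_outcome": int(truth.n_outcome),
        "n_case": truth.n_case,
        "n_control": truth.n_control,
        "a": truth.a,
        "b": truth.b,
        "gamma_mediator": None
        if truth.gamma_mediator is None
        else [float(x) for x in truth.gamma_mediator],
        "n_mediator": truth.n_mediator,
        "seed": int(truth.seed),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_truth(path: str | Path) -> SimulationTruth:
    payload = yaml.safe_load(Path(path).read_text())
    for key in ("gamma", "alpha", "maf", "gamma_mediator"):
        if payload.get(key) is not None:
            payload[key] = np.asarray(payload[key], dtype=float)
    return SimulationTruth(**payload)
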