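"""Study orchestration: the full filter cascade, multiple-testing
correction and the end-to-end target x outcome x mediator run.

``run_cascade`` chains cis selection, the significance/F/MAF filters, LD
clumping, harmonization (with proxy substitution and palindrome handling)
and Steiger filtering, carrying a unified audit in which every input
variant appears exactly once. ``run_study`` drives the whole design from a
YAML config and writes tidy TSVs; identical configs reproduce outputs bit
for bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .datatypes import (
    GeneRegion,
    HarmonizedSet,
    LDPanel,
    SummaryDataset,
)
from .harmonization import harmonize
from .instrument_selection import select_instruments, steiger_filter
from .mediation import two_step_mediation
from .mr_core import all_estimators, scale_to_unit_decrease
from .sensitivity import sensitivity_report

__all__ = ["bh_fdr", "run_cascade", "StudyConfig", "run_study"]


def bh_fdr(pvals: Iterable[float], level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask).

    adjusted_(i) = min_{j >= rank(i)} p_(j) * m / j, capped at 1; reject
    when adjusted <= level.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < level < 1.0):
        raise ValueError("FDR level must lie in (0, 1)")
    _, adjusted, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return adjusted, adjusted <= level


def run_cascade(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    panel: LDPanel,
    region: GeneRegion | list[GeneRegion] | None = None,
    p_threshold: float = 5e-8,
    f_min: float = 10.0,
    maf_min: float = 0.01,
    clump_r2: float = 0.2,
    clump_kb: float = 10_000.0,
    proxy_r2_min: float = 0.8,
    apply_steiger: bool = True,
) -> HarmonizedSet:
    """Instrument cascade + harmonization + Steiger for one pair.

    The returned set's ``audit`` accumulates every drop across all stages,
    so |exposure variants in window| = |kept| + |audit|.
    """
    inst = select_instruments(
        exposure.assocs(),
        panel,
        region=region,
        p_threshold=p_threshold,
        f_min=f_min,
        maf_min=maf_min,
        clump_r2=clump_r2,
        clump_kb=clump_kb,
    )
    hset = harmonize(
        SummaryDataset.from_assocs(inst.kept, exposure.trait, exposure.trait_scale)
        if inst.kept
        else [],
        outcome,
        panel,
        proxy_r2_min=proxy_r2_min,
        exposure_label=exposure.trait,
        outcome_label=outcome.trait,
    )
    hset.audit = inst.audit + hset.audit
    if apply_steiger and len(hset):
        hset = steiger_filter(hset)
    return hset


@dataclass
class StudyConfig:
    """Configuration of a full drug-target MR study run."""

    output_dir: Path
    panel_variants: Path
    panel_matrix: Path
    targets: list[dict]  # {symbol, exposure, conversion?, regions?: [{chrom,start,end}], flank_kb?}
    outcomes: list[dict]  # {label, path}
    mediators: list[dict] = field(default_factory=list)  # {label, path}
    control: Optional[dict] = None  # {label, path, expected_direction}
    phenome: Optional[Path] = None
    seed: int = 0
    fdr_level: float = 0.05
    fdr_scope: str = "across_outcomes"  # or "per_outcome"
    p_threshold: float = 5e-8
    mediator_iv_p: float = 1e-5
    f_min: float = 10.0
    maf_min: float = 0.01
    clump_r2: float = 0.2
    clump_kb: float = 10_000.0
    proxy_r2_min: float = 0.8
    n_boot: int = 2000
    n_sim: int = 2000
    mediation_n_boot: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_level < 1.0):
            raise ValueError("fdr_level must lie in (0, 1)")
        for name in ("panel_variants", "panel_matrix"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p}")
        for group in (self.targets, self.outcomes, self.mediators):
            for entry in group:
                key = "exposure" if "exposure" in entry else "path"
                if not Path(entry[key]).exists():
                    raise FileNotFoundError(f"{entry.get('symbol', entry.get('label'))}: {entry[key]}")
        if self.control is not None and not Path(self.control["path"]).exists():
            raise FileNotFoundError(f"control: {self.control['path']}")
        if self.phenome is not None:
            self.phenome = Path(self.phenome)
            if not self.phenome.exists():
                raise FileNotFoundError(f"phenome: {self.phenome}")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in sorted(self.__dict__.items())}
        return hashlib.sha256(str(payload).encode()).hexdigest()[:12]


def _target_regions(entry: dict, default_flank: float = 250.0) -> Optional[list[GeneRegion]]:
    if "regions" not in entry:
        return None
    flank = float(entry.get("flank_kb", default_flank))
    return [
        GeneRegion(
            symbol=entry["symbol"],
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            flank_kb=flank,
        )
        for r in entry["regions"]
    ]


def run_study(config: StudyConfig) -> int:
    """Execute the full study; returns an exit code (0 ok, 3 partial
    failure: some pairs failed but others completed).

    Per target x outcome: cascade -> all estimators -> sensitivity; then
    BH-FDR over the primary (IVW) family; mediation for FDR-significant
    pairs. Outputs: mr_results.tsv, sensitivity.tsv, audit.tsv,
    mediation.tsv and run_log.yaml under ``config.output_dir``.
    """
    from .io import read_panel, read_summary

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = read_panel(config.panel_variants, config.panel_matrix)
    outcomes = {o["label"]: read_summary(o["path"], trait=o["label"]) for o in config.outcomes}
    mediators = {m["label"]: read_summary(m["path"], trait=m["label"]) for m in config.mediators}
    phenome = pd.read_csv(config.phenome, sep="\t") if config.phenome else None
    control_ds = (
        read_summary(config.control["path"], trait=config.control.get("label", "control"))
        if config.control
        else None
    )

    mr_rows, sens_rows, audit_rows, med_frames, failures = [], [], [], [], []
    hsets: dict[tuple[str, str], HarmonizedSet] = {}

    for t in config.targets:
        symbol = t["symbol"]
        exposure = read_summary(t["exposure"], trait=symbol)
        regions = _target_regions(t)
        conversion = float(t.get("conversion", 1.0))
        for label, outcome in outcomes.items():
            try:
                hset = run_cascade(
                    exposure,
                    outcome,
                    panel,
                    region=regions,
                    p_threshold=config.p_threshold,
                    f_min=config.f_min,
                    maf_min=config.maf_min,
                    clump_r2=config.clump_r2,
                    clump_kb=config.clump_kb,
                    proxy_r2_min=config.proxy_r2_min,
                )
                for rec in hset.audit:
                    audit_rows.append(
                        {
                            "target": symbol,
                            "outcome": label,
                            "snp_id": rec.snp_id,
                            "reason": rec.reason.value,
                            "detail": rec.detail,
                        }
                    )
                if hset.n_snps < 2:
                    raise ValueError(f"{hset.n_snps} instrument(s) after cascade")
                hsets[(symbol, label)] = hset
                results = all_estimators(
                    hset, seed=config.seed, n_boot=config.n_boot, n_sim=config.n_sim
                )
                skipped = results.pop("_skipped", {})
                for name, res in results.items():
                    scaled = scale_to_unit_decrease(res, conversion)
                    row = {"target": symbol, "outcome": label, **scaled.to_row()}
                    mr_rows.append(row)
                for name, msg in skipped.items():  # type: ignore[union-attr]
                    failures.append(f"{symbol}x{label}:{name}: {msg}")
                control_hset = None
                if control_ds is not None:
                    control_hset = run_cascade(
                        exposure,
                        control_ds,
                        panel,
                        region=regions,
                        p_threshold=config.p_threshold,
                        f_min=config.f_min,
                        maf_min=config.maf_min,
                        clump_r2=config.clump_r2,
                        clump_kb=config.clump_kb,
                        proxy_r2_min=config.proxy_r2_min,
                    )
                report = sensitivity_report(
                    hset,
                    phenome=phenome,
                    control=control_hset if control_hset is not None and control_hset.n_snps >= 2 else None,
                    expected_direction=int((config.control or {}).get("expected_direction", -1)),
                )
                sens_rows.append({"target": symbol, "outcome": label, **report.to_row()})
            except (ValueError, RuntimeError) as exc:
                failures.append(f"{symbol}x{label}: {exc}")

    mr_df = pd.DataFrame(mr_rows)
    if not mr_df.empty:
        primary = mr_df["method"].isin(["ivw", "wald_ratio"])
        if config.fdr_scope == "per_outcome":
            mr_df["p_adjusted"] = np.nan
            for label in mr_df["outcome"].unique():
                mask = primary & (mr_df["outcome"] == label)
                if mask.any():
                    adj, _ = bh_fdr(mr_df.loc[mask, "pval"], config.fdr_level)
                    mr_df.loc[mask, "p_adjusted"] = adj
        else:
            mr_df["p_adjusted"] = np.nan
            if primary.any():
                adj, _ = bh_fdr(mr_df.loc[primary, "pval"], config.fdr_level)
                mr_df.loc[primary, "p_adjusted"] = adj

        significant = mr_df[primary & (mr_df["p_adjusted"] <= config.fdr_level)]
        for _, row in significant.iterrows():
            if not mediators:
                break
            symbol, label = row["target"], row["outcome"]
            t = next(t for t in config.targets if t["symbol"] == symbol)
            exposure = read_summary(t["exposure"], trait=symbol)
            try:
                med = two_step_mediation(
                    exposure,
                    mediators,
                    outcomes[label],
                    panel,
                    exposure_iv_p=config.p_threshold,
                    mediator_iv_p=config.mediator_iv_p,
                    n_boot=config.mediation_n_boot,
                    seed=config.seed,
                )
                med_frames.append(med)
            except (ValueError, RuntimeError) as exc:
                failures.append(f"mediation {symbol}x{label}: {exc}")

    header = (
        f"# targetmr {__version__} | config {config.config_hash()} | seed {config.seed}\n"
    )

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    _write(mr_df, "mr_results.tsv")
    _write(pd.DataFrame(sens_rows), "sensitivity.tsv")
    _write(pd.DataFrame(audit_rows), "audit.tsv")
    med_df = pd.concat(med_frames, ignore_index=True) if med_frames else pd.DataFrame()
    _write(med_df, "mediation.tsv")
    log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_pairs_attempted": len(config.targets) * len(config.outcomes),
        "n_pairs_completed": len(hsets),
        "failures": failures,
        "thresholds": {
            "p_threshold": config.p_threshold,
            "mediator_iv_p": config.mediator_iv_p,
            "f_min": config.f_min,
            "maf_min": config.maf_min,
            "clump_r2": config.clump_r2,
            "clump_kb": config.clump_kb,
            "proxy_r2_min": config.proxy_r2_min,
            "fdr_level": config.fdr_level,
            "fdr_scope": config.fdr_scope,
        },
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
    return 3 if failures else 0
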