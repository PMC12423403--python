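"""Core domain containers shared across the pipeline.

Conventions used throughout the package:

* positions are 1-based inclusive; BED-like inputs (0-based half-open) are
  converted on read;
* binary traits (case-control GWAS) carry effects on the log-odds scale;
* every filtering stage accounts for each input variant exactly once, either
  in the kept set or in the audit trail with a machine-readable reason code.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "GeneRegion",
    "SummaryDataset",
    "LDPanel",
    "DropReason",
    "AuditRecord",
    "InstrumentSet",
    "HarmonizedSet",
    "MRResult",
    "MediationEstimate",
]

PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (trait units for continuous traits, log-odds for binary ones). ``pval``
    is stored as reported, never recomputed from ``beta``/``se``.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int
    trait_scale: str = "continuous"  # or "log-odds"
    n_case: Optional[int] = None
    n_control: Optional[int] = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.snp_id}: eaf must lie in (0, 1), got {self.eaf}")
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.snp_id}: pval must lie in (0, 1], got {self.pval}")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in PALINDROMIC_PAIRS

    def flipped(self) -> "VariantAssociation":
        """Re-express the association with the alleles swapped."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=1.0 - self.eaf,
        )


@dataclass(frozen=True)
class GeneRegion:
    """A drug-target gene locus plus its cis flank (kb each side)."""

    symbol: str
    chrom: str
    start: int
    end: int
    flank_kb: float = 250.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.symbol}: start > end")
        if self.flank_kb < 0:
            raise ValueError(f"{self.symbol}: negative flank")

    @property
    def window(self) -> tuple[int, int]:
        flank = int(round(self.flank_kb * 1000))
        return (self.start - flank, self.end + flank)

    def contains(self, chrom: str, pos: int) -> bool:
        lo, hi = self.window
        return normalize_chrom(chrom) == normalize_chrom(self.chrom) and lo <= pos <= hi


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' so 'chr8' and '8' compare equal."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


GWAS_COLUMNS = [
    "snp_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
    "n_case",
    "n_control",
]


@dataclass
class SummaryDataset:
    """GWAS summary statistics for one trait, GWAS-SSF-like columns."""

    df: pd.DataFrame
    trait: str = ""
    trait_scale: str = "continuous"

    def __post_init__(self) -> None:
        missing = [c for c in GWAS_COLUMNS[:10] if c not in self.df.columns]
        if missing:
            raise ValueError(f"summary dataset missing columns: {missing}")
        for col in ("n_case", "n_control"):
            if col not in self.df.columns:
                self.df[col] = np.nan
        if self.df["snp_id"].duplicated().any():
            dups = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_ids in {self.trait or 'dataset'}: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    def assocs(self) -> list[VariantAssociation]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                VariantAssociation(
                    snp_id=row.snp_id,
                    chrom=str(row.chromosome),
                    pos=int(row.base_pair_location),
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    eaf=float(row.effect_allele_frequency),
                    beta=float(row.beta),
                    se=float(row.standard_error),
                    pval=float(row.p_value),
                    n=int(row.n),
                    trait_scale=self.trait_scale,
                    n_case=None if pd.isna(row.n_case) else int(row.n_case),
                    n_control=None if pd.isna(row.n_control) else int(row.n_control),
                )
            )
        return out

    @classmethod
    def from_assocs(
        cls, assocs: list[VariantAssociation], trait: str = "", trait_scale: str | None = None
    ) -> "SummaryDataset":
        rows = [
            {
                "snp_id": a.snp_id,
                "chromosome": a.chrom,
                "base_pair_location": a.pos,
                "effect_allele": a.effect_allele,
                "other_allele": a.other_allele,
                "effect_allele_frequency": a.eaf,
                "beta": a.beta,
                "standard_error": a.se,
                "p_value": a.pval,
                "n": a.n,
                "n_case": np.nan if a.n_case is None else a.n_case,
                "n_control": np.nan if a.n_control is None else a.n_control,
            }
            for a in assocs
        ]
        scale = trait_scale or (assocs[0].trait_scale if assocs else "continuous")
        return cls(pd.DataFrame(rows, columns=GWAS_COLUMNS), trait=trait, trait_scale=scale)

    def lookup(self, snp_id: str) -> Optional[VariantAssociation]:
        sub = self.df[self.df["snp_id"] == snp_id]
        if sub.empty:
            return None
        return SummaryDataset(sub.reset_index(drop=True), self.trait, self.trait_scale).assocs()[0]


@dataclass
class LDPanel:
    """Signed allelic correlations over an ordered variant set.

    ``r[i, j]`` is the correlation between allele1 dosages of variants i and
    j; its sign therefore phases effect alleles between a variant and its
    proxy. ``variants`` has columns snp_id, chrom, pos, allele1, allele2 and
    optionally eaf (allele1 frequency), used when an outcome file lacks the
    proxy's frequency.
    """

    variants: pd.DataFrame
    r: np.ndarray

    def __post_init__(self) -> None:
        need = {"snp_id", "chrom", "pos", "allele1", "allele2"}
        missing = need - set(self.variants.columns)
        if missing:
            raise ValueError(f"LD panel variant table missing columns: {sorted(missing)}")
        n = len(self.variants)
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (n, n):
            raise ValueError(f"r must be {n}x{n}, got {self.r.shape}")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("diag(r) must be 1")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("r must be symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("|r| must not exceed 1")
        if self.variants["snp_id"].duplicated().any():
            raise ValueError("duplicate variant ids in LD panel")
        self._index = {s: i for i, s in enumerate(self.variants["snp_id"])}

    def __len__(self) -> int:
        return len(self.variants)

    def index_of(self, snp_id: str) -> Optional[int]:
        return self._index.get(snp_id)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r_between(self, a: str, b: str) -> float:
        ia, ib = self._index[a], self._index[b]
        return float(self.r[ia, ib])

    def r2_between(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2


class DropReason(str, enum.Enum):
    OUT_OF_WINDOW = "out_of_window"
    NOT_SIGNIFICANT = "not_significant"
    WEAK_INSTRUMENT = "weak_instrument"
    LOW_MAF = "low_maf"
    CLUMPED = "clumped"
    STEIGER_REVERSED = "steiger_reversed"
    PALINDROME_UNRESOLVED = "palindrome_unresolved"
    NOT_IN_PANEL = "not_in_panel"
    MISSING_IN_OUTCOME = "missing_in_outcome"
    INCOMPATIBLE_ALLELES = "incompatible_alleles"
    ZERO_EXPOSURE_BETA = "zero_exposure_beta"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class AuditRecord:
    snp_id: str
    reason: DropReason
    detail: str = ""


@dataclass
class InstrumentSet:
    """Result of the instrument-construction cascade: kept variants + audit."""

    kept: list[VariantAssociation]
    audit: list[AuditRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        kept_ids = {a.snp_id for a in self.kept}
        dropped_ids = {a.snp_id for a in self.audit}
        overlap = kept_ids & dropped_ids
        if overlap:
            raise ValueError(f"variants both kept and dropped: {sorted(overlap)}")

    @property
    def kept_ids(self) -> list[str]:
        return [a.snp_id for a in self.kept]

    def reasons(self) -> dict[str, str]:
        return {rec.snp_id: rec.reason.value for rec in self.audit}

    def audit_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"snp_id": r.snp_id, "reason": r.reason.value, "detail": r.detail} for r in self.audit],
            columns=["snp_id", "reason", "detail"],
        )


HARMONIZED_COLUMNS = [
    "snp_id",
    "beta_x",
    "se_x",
    "beta_y",
    "se_y",
    "eaf_x",
    "eaf_y",
    "n_x",
    "n_y",
    "flipped",
    "palindromic",
    "proxy_used",
    "proxy_id",
    "r2_proxy",
]


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to the exposure effect allele."""

    df: pd.DataFrame
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    audit: list[AuditRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in HARMONIZED_COLUMNS[:9] if c not in self.df.columns]
        if missing:
            raise ValueError(f"harmonized set missing columns: {missing}")
        for col, default in (
            ("flipped", False),
            ("palindromic", False),
            ("proxy_used", False),
            ("proxy_id", None),
            ("r2_proxy", np.nan),
        ):
            if col not in self.df.columns:
                self.df[col] = default
        if len(self.df):
            if (self.df["se_x"] <= 0).any() or (self.df["se_y"] <= 0).any():
                raise ValueError("harmonized SEs must be positive")
            bad = self.df["proxy_used"] != self.df["proxy_id"].notna()
            if bad.any():
                raise ValueError("proxy_id must be set iff proxy_used")
        if self.df["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_ids in harmonized set")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_x, se_x, beta_y, se_y) as float arrays."""
        d = self.df
        return (
            d["beta_x"].to_numpy(float),
            d["se_x"].to_numpy(float),
            d["beta_y"].to_numpy(float),
            d["se_y"].to_numpy(float),
        )

    def subset(self, snp_ids: list[str]) -> "HarmonizedSet":
        keep = self.df["snp_id"].isin(set(snp_ids))
        return HarmonizedSet(
            self.df[keep].reset_index(drop=True),
            self.exposure_label,
            self.outcome_label,
            list(self.audit),
        )

    def drop(self, snp_ids: list[str]) -> "HarmonizedSet":
        keep = ~self.df["snp_id"].isin(set(snp_ids))
        return HarmonizedSet(
            self.df[keep].reset_index(drop=True),
            self.exposure_label,
            self.outcome_label,
            list(self.audit),
        )


@dataclass
class MRResult:
    """One estimator's causal estimate with 95% CI and diagnostics."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low <= self.estimate + 1e-12 and self.estimate - 1e-12 <= self.ci_high):
                raise ValueError(
                    f"{self.method}: estimate {self.estimate} outside CI "
                    f"({self.ci_low}, {self.ci_high})"
                )

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_row(self) -> dict:
        row = {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci[0],
            "or_ci_high": self.or_ci[1],
        }
        for k, v in self.extras.items():
            if np.isscalar(v) or v is None:
                row[k] = v
            else:
                row[k] = ";".join(str(x) for x in np.atleast_1d(v))
        return row


@dataclass
class MediationEstimate:
    """Product-of-coefficients mediation summary with bootstrap CI."""

    exposure: str
    mediator: str
    outcome: str
    a: float
    a_se: float
    b: float
    b_se: float
    total: float
    total_se: float
    n_boot: int
    seed: int
    ci_low: float
    ci_high: float
    delta_se: float
    out_of_range: bool
    qualifies: bool = True

    @property
    def indirect(self) -> float:
        return self.a * self.b

    @property
    def proportion(self) -> float:
        return self.indirect / self.total

    def __post_init__(self) -> None:
        if self.total == 0:
            raise ValueError("total effect is zero; mediated proportion undefined")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low > ci_high")

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "a": self.a,
            "a_se": self.a_se,
            "b": self.b,
            "b_se": self.b_se,
            "total": self.total,
            "total_se": self.total_se,
            "indirect": self.indirect,
            "proportion": self.proportion,
            "prop_ci_low": self.ci_low,
            "prop_ci_high": self.ci_high,
            "prop_delta_se": self.delta_se,
            "out_of_range": self.out_of_range,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "qualifies": self.qualifies,
        }
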