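"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works directly at the summary level: for a unit-variance
exposure, the sampling distribution of a per-allele effect estimate at a
variant with minor allele frequency ``maf`` and sample size ``n`` is

    beta_hat ~ Normal(beta_true, se^2),   se = 1 / sqrt(2 * maf * (1 - maf) * n)

and for a case-control trait analysed on the log-odds scale

    se = sqrt( 1 / (2 * maf * (1 - maf)) * (1 / n_case + 1 / n_control) ).

Linkage disequilibrium enters twice: marginal true effects are the LD
convolution of the causal effects (on the standardized-genotype scale,
``beta_marginal = R @ beta_causal``), and estimation errors at variants in
LD are correlated with correlation matrix R. Instruments carry causal
effects ``gamma`` on the exposure and optional direct (pleiotropic) effects
``alpha`` on the outcome; every other panel variant is causally null but
still shows the LD-induced marginal signal, so clumping and proxy search
can be exercised end to end.

Mediation scenarios add a mediator trait: exposure instruments act on the
mediator through the exposure (effect ``a * gamma``), a disjoint set of
mediator instruments acts on it directly, and the outcome receives the
total effect ``theta + a * b`` from exposure instruments plus ``b`` times
the mediator instrument effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datatypes import GWAS_COLUMNS, LDPanel, SummaryDataset

__all__ = [
    "SimulationTruth",
    "simulate_ld_panel",
    "simulate_two_sample",
    "simulate_mediation_scenario",
    "make_truth",
]

_BASES = ("A", "C", "G", "T")
_MIN_P = 1e-300


@dataclass
class SimulationTruth:
    """Ground-truth parameters of a simulated two-sample (or mediation) study.

    ``theta`` is the causal effect of the exposure on the outcome (the
    *direct* effect in mediation scenarios, where the total effect is
    ``theta + a * b``). ``gamma`` and ``alpha`` are per-instrument causal
    effects on the exposure and direct effects on the outcome; ``maf``
    holds the instrument minor allele frequencies (taken from the panel
    when None).
    """

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    n_exposure: int
    n_outcome: int
    maf: Optional[np.ndarray] = None
    n_case: Optional[int] = None
    n_control: Optional[int] = None
    a: Optional[float] = None
    b: Optional[float] = None
    gamma_mediator: Optional[np.ndarray] = None
    n_mediator: Optional[int] = None
    seed: int = 0
    instrument_indices: Optional[np.ndarray] = None
    mediator_indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.alpha.shape != self.gamma.shape:
            raise ValueError(
                f"gamma and alpha must share length, got {self.gamma.shape} vs {self.alpha.shape}"
            )
        if self.maf is not None:
            self.maf = np.atleast_1d(np.asarray(self.maf, dtype=float))
            if self.maf.shape != self.gamma.shape:
                raise ValueError("maf must share length with gamma")
            if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
                raise ValueError("maf must lie in (0, 0.5]")
        for name in ("n_exposure", "n_outcome"):
            if getattr(self, name) < 4:
                raise ValueError(f"{name} must be at least 4")
        if self.instrument_indices is not None:
            self.instrument_indices = np.asarray(self.instrument_indices, dtype=int)
        if self.mediator_indices is not None:
            self.mediator_indices = np.asarray(self.mediator_indices, dtype=int)
        if self.gamma_mediator is not None:
            self.gamma_mediator = np.atleast_1d(np.asarray(self.gamma_mediator, dtype=float))

    @property
    def k(self) -> int:
        return len(self.gamma)

    @property
    def theta_total(self) -> float:
        """Total exposure->outcome effect (direct plus mediated)."""
        if self.a is None or self.b is None:
            return self.theta
        return self.theta + self.a * self.b

    @property
    def mediated_proportion(self) -> float:
        if self.a is None or self.b is None:
            raise ValueError("mediation coefficients a, b not set")
        total = self.theta_total
        if total == 0:
            return np.nan
        return self.a * self.b / total


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    a1 = rng.choice(_BASES, size=n)
    a2 = np.empty(n, dtype=object)
    for i, b in enumerate(a1):
        a2[i] = rng.choice([x for x in _BASES if x != b])
    return a1, a2.astype(str)


def simulate_ld_panel(
    n_variants: int,
    block_size: int,
    rho: float,
    maf_range: tuple[float, float] = (0.05, 0.40),
    seed: int = 0,
    chrom: str = "1",
    start_pos: int = 1_000_000,
) -> LDPanel:
    """Generate an LD reference panel with AR(1) correlation blocks.

    Within a block, ``r[i, j] = rho ** |i - j|``; between blocks the
    correlation is zero. The Kac-Murdock-Szego structure guarantees the
    matrix is positive semidefinite. Positions are strictly increasing on
    one chromosome; allele-1 frequencies are drawn uniformly from
    ``maf_range`` (default (0.05, 0.40), typical of post-QC GWAS
    instruments and clear of the palindrome-ambiguity zone).
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")

    rng = np.random.default_rng(seed)
    r = np.zeros((n_variants, n_variants))
    for b0 in range(0, n_variants, block_size):
        b1 = min(b0 + block_size, n_variants)
        idx = np.arange(b0, b1)
        r[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])

    gaps = rng.integers(500, 5_000, size=n_variants)
    pos = start_pos + np.cumsum(gaps)
    a1, a2 = _random_alleles(rng, n_variants)
    eaf = rng.uniform(lo, hi, size=n_variants)
    variants = pd.DataFrame(
        {
            "snp_id": [f"snp_{i + 1:05d}" for i in range(n_variants)],
            "chrom": chrom,
            "pos": pos,
            "allele1": a1,
            "allele2": a2,
            "eaf": eaf,
        }
    )
    return LDPanel(variants, r)


def _ld_factor(r: np.ndarray) -> np.ndarray:
    """Factor L with L @ L.T = r, tolerant of semidefinite input."""
    try:
        return linalg.cholesky(r, lower=True)
    except linalg.LinAlgError:
        w, v = linalg.eigh(r)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def _default_instrument_indices(n_panel: int, k: int) -> np.ndarray:
    """Spread k instruments evenly across the panel."""
    if k > n_panel:
        raise ValueError(f"{k} instruments requested but panel has {n_panel} variants")
    idx = np.unique(np.round(np.linspace(0, n_panel - 1, k)).astype(int))
    if len(idx) != k:
        raise ValueError("could not place instruments at distinct panel positions")
    return idx


def _simulate_trait(
    panel: LDPanel,
    causal_per_allele: np.ndarray,
    n: int,
    rng: np.random.Generator,
    trait: str,
    binary: bool = False,
    n_case: Optional[int] = None,
    n_control: Optional[int] = None,
) -> SummaryDataset:
    """Draw one trait's summary statistics over every panel variant."""
    m = len(panel)
    eaf = panel.variants["eaf"].to_numpy(float)
    var_g = 2.0 * eaf * (1.0 - eaf)
    sd_g = np.sqrt(var_g)

    beta_std = causal_per_allele * sd_g
    marginal_std = panel.r @ beta_std

    if binary:
        if not (n_case and n_control):
            raise ValueError("binary trait requires n_case and n_control")
        se_std = np.sqrt(1.0 / n_case + 1.0 / n_control)
        n_eff = n_case + n_control
    else:
        se_std = 1.0 / np.sqrt(n)
        n_eff = n
    se = se_std / sd_g

    L = _ld_factor(panel.r)
    z = L @ rng.standard_normal(m)
    beta_hat = marginal_std / sd_g + z * se
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(beta_hat / se)), _MIN_P, 1.0)

    df = pd.DataFrame(
        {
            "snp_id": panel.variants["snp_id"].to_numpy(),
            "chromosome": panel.variants["chrom"].to_numpy(),
            "base_pair_location": panel.variants["pos"].to_numpy(),
            "effect_allele": panel.variants["allele1"].to_numpy(),
            "other_allele": panel.variants["allele2"].to_numpy(),
            "effect_allele_frequency": eaf,
            "beta": beta_hat,
            "standard_error": se,
            "p_value": pvals,
            "n": n_eff,
            "n_case": n_case if binary else np.nan,
            "n_control": n_control if binary else np.nan,
        },
        columns=GWAS_COLUMNS,
    )
    return SummaryDataset(df, trait=trait, trait_scale="log-odds" if binary else "continuous")


def simulate_two_sample(
    truth: SimulationTruth,
    panel: LDPanel,
    outcome_type: Literal["continuous", "binary"] = "continuous",
) -> tuple[SummaryDataset, SummaryDataset]:
    """Simulate non-overlapping exposure and outcome GWAS over a panel.

    Instruments (``truth.instrument_indices``, evenly spread over the panel
    by default) carry causal effects ``gamma`` on the exposure and
    ``theta * gamma + alpha`` on the outcome; all other panel variants are
    causally null. Identical (truth, panel) including seed reproduce the
    output bit for bit.
    """
    if outcome_type not in ("continuous", "binary"):
        raise ValueError(f"unknown outcome_type {outcome_type!r}")
    idx = truth.instrument_indices
    if idx is None:
        idx = _default_instrument_indices(len(panel), truth.k)
    if len(idx) != truth.k:
        raise ValueError("instrument_indices length must match gamma")
    if np.any(idx < 0) or np.any(idx >= len(panel)):
        raise ValueError("instrument index outside panel")

    panel_maf = panel.variants["eaf"].to_numpy(float)[idx]
    if truth.maf is not None and not np.allclose(truth.maf, panel_maf, atol=1e-9):
        raise ValueError("truth.maf disagrees with panel allele frequencies at instruments")

    rng = np.random.default_rng(truth.seed)
    m = len(panel)

    gamma_full = np.zeros(m)
    gamma_full[idx] = truth.gamma
    exposure = _simulate_trait(panel, gamma_full, truth.n_exposure, rng, trait="exposure")

    outcome_causal = np.zeros(m)
    outcome_causal[idx] = truth.theta * truth.gamma + truth.alpha
    binary = outcome_type == "binary"
    outcome = _simulate_trait(
        panel,
        outcome_causal,
        truth.n_outcome,
        rng,
        trait="outcome",
        binary=binary,
        n_case=truth.n_case,
        n_control=truth.n_control,
    )
    return exposure, outcome


def simulate_mediation_scenario(
    truth: SimulationTruth,
    panel: LDPanel,
    outcome_type: Literal["continuous", "binary"] = "continuous",
) -> tuple[SummaryDataset, SummaryDataset, SummaryDataset]:
    """Simulate an exposure -> mediator -> outcome chain with known a, b.

    Exposure instruments and mediator instruments are disjoint panel
    subsets (by default the front and back halves of an even spread). The
    outcome encodes the total effect ``theta + a * b`` through exposure
    instruments; the mediator GWAS encodes ``a * gamma`` at exposure
    instruments and the mediator's own instrument effects elsewhere.
    """
    if truth.a is None or truth.b is None:
        raise ValueError("mediation scenario requires truth.a and truth.b")
    if truth.gamma_mediator is None:
        raise ValueError("mediation scenario requires truth.gamma_mediator")
    k_x, k_m = truth.k, len(truth.gamma_mediator)

    if truth.instrument_indices is None or truth.mediator_indices is None:
        all_idx = _default_instrument_indices(len(panel), k_x + k_m)
        idx_x = all_idx[:k_x]
        idx_m = all_idx[k_x:]
    else:
        idx_x, idx_m = truth.instrument_indices, truth.mediator_indices
    if set(idx_x.tolist()) & set(idx_m.tolist()):
        raise ValueError("exposure and mediator instrument sets must be disjoint")

    total = truth.theta_total
    prop = truth.mediated_proportion
    if not np.isnan(prop) and not (0.0 <= prop <= 1.0):
        warnings.warn(
            f"true mediated proportion {prop:.3f} lies outside [0, 1] "
            "(indirect and direct effects oppose); reported, not truncated",
            stacklevel=2,
        )

    rng = np.random.default_rng(truth.seed)
    m = len(panel)
    n_med = truth.n_mediator or truth.n_exposure

    gamma_full = np.zeros(m)
    gamma_full[idx_x] = truth.gamma
    exposure = _simulate_trait(panel, gamma_full, truth.n_exposure, rng, trait="exposure")

    med_causal = np.zeros(m)
    med_causal[idx_x] = truth.a * truth.gamma
    med_causal[idx_m] = truth.gamma_mediator
    mediator = _simulate_trait(panel, med_causal, n_med, rng, trait="mediator")

    out_causal = np.zeros(m)
    out_causal[idx_x] = total * truth.gamma + truth.alpha
    out_causal[idx_m] = truth.b * truth.gamma_mediator
    binary = outcome_type == "binary"
    outcome = _simulate_trait(
        panel,
        out_causal,
        truth.n_outcome,
        rng,
        trait="outcome",
        binary=binary,
        n_case=truth.n_case,
        n_control=truth.n_control,
    )
    return exposure, mediator, outcome


def make_truth(
    k: int,
    theta: float,
    n_exposure: int = 100_000,
    n_outcome: int = 50_000,
    gamma_range: tuple[float, float] = (0.05, 0.15),
    pleiotropy: Literal["none", "balanced", "directional", "correlated", "outlier"] = "none",
    pleiotropy_scale: float = 0.05,
    pleiotropy_mean: float = 0.1,
    outlier_alpha: float = 1.5,
    seed: int = 0,
    **kwargs,
) -> SimulationTruth:
    """Convenience constructor drawing instrument effects for a named
    pleiotropy regime.

    Regimes: ``none`` (alpha = 0); ``balanced`` (alpha ~ N(0, scale^2));
    ``directional`` (alpha ~ N(mean, scale^2), InSIDE holds because alpha
    is drawn independently of gamma); ``correlated`` (alpha proportional to
    gamma plus noise, violating InSIDE); ``outlier`` (one instrument gets a
    large direct effect, the rest none).
    """
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(*gamma_range, size=k)
    if pleiotropy == "none":
        alpha = np.zeros(k)
    elif pleiotropy == "balanced":
        alpha = rng.normal(0.0, pleiotropy_scale, size=k)
    elif pleiotropy == "directional":
        alpha = rng.normal(pleiotropy_mean, pleiotropy_scale, size=k)
    elif pleiotropy == "correlated":
        alpha = pleiotropy_mean * gamma / gamma.mean() + rng.normal(0, pleiotropy_scale, size=k)
    elif pleiotropy == "outlier":
        alpha = np.zeros(k)
        alpha[rng.integers(k)] = outlier_alpha
    else:
        raise ValueError(f"unknown pleiotropy regime {pleiotropy!r}")
    return SimulationTruth(
        theta=theta,
        gamma=gamma,
        alpha=alpha,
        n_exposure=n_exposure,
        n_outcome=n_outcome,
        seed=seed,
        **kwargs,
    )
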