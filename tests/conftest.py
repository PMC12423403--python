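"""Shared fixtures: tiny panels, hand-built harmonized sets, and helpers
for constructing variant associations with minimal boilerplate."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from targetmr.datatypes import (
    HARMONIZED_COLUMNS,
    HarmonizedSet,
    LDPanel,
    VariantAssociation,
)


def make_assoc(
    snp_id="rs1",
    chrom="1",
    pos=1_000_000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pval=1e-20,
    n=100_000,
    **kw,
):
    return VariantAssociation(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
        **kw,
    )


def make_hset(bx, sx, by, sy, n_x=100_000, n_y=50_000, ids=None):
    bx = np.atleast_1d(np.asarray(bx, float))
    k = len(bx)
    sx, by, sy = (np.broadcast_to(np.asarray(v, float), (k,)).copy() for v in (sx, by, sy))
    ids = ids or [f"rs{i + 1}" for i in range(k)]
    df = pd.DataFrame(
        {
            "snp_id": ids,
            "beta_x": bx,
            "se_x": sx,
            "beta_y": by,
            "se_y": sy,
            "eaf_x": 0.3,
            "eaf_y": 0.3,
            "n_x": n_x,
            "n_y": n_y,
            "flipped": False,
            "palindromic": False,
            "proxy_used": False,
            "proxy_id": None,
            "r2_proxy": np.nan,
        },
        columns=HARMONIZED_COLUMNS,
    )
    return HarmonizedSet(df)


def make_panel(ids, pos, r, alleles=None, eaf=None, chrom="1"):
    n = len(ids)
    alleles = alleles or [("A", "G")] * n
    variants = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chrom,
            "pos": pos,
            "allele1": [a[0] for a in alleles],
            "allele2": [a[1] for a in alleles],
            "eaf": eaf if eaf is not None else [0.3] * n,
        }
    )
    return LDPanel(variants, np.asarray(r, float))


@pytest.fixture
def identity_panel():
    return make_panel(
        [f"rs{i + 1}" for i in range(5)],
        [1_000_000 + 10_000 * i for i in range(5)],
        np.eye(5),
    )


@pytest.fixture
def exact_hset():
    """Exact-model data: beta_y = 0.5 * beta_x, no noise in the relation."""
    bx = np.array([0.1, 0.15, 0.2, 0.12, 0.18])
    return make_hset(bx, 0.01 * np.ones(5), 0.5 * bx, 0.02 * np.ones(5))
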