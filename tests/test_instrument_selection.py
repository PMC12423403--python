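"""Filter-cascade semantics: boundary conventions at every threshold, a
brute-force oracle for greedy clumping, Steiger plug-in values, and the
audit-completeness / order-invariance / idempotence contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetmr.datatypes import DropReason, GeneRegion
from targetmr.instrument_selection import (
    f_statistic,
    filter_maf,
    filter_significance,
    filter_weak,
    infer_palindrome_strand,
    ld_clump,
    select_cis,
    select_instruments,
    steiger_filter,
)

from conftest import make_assoc, make_hset, make_panel


class TestSelectCis:
    region = GeneRegion("LPL", "8", 19_796_764, 19_824_770, flank_kb=250)

    def test_boundary_inclusive(self):
        a = make_assoc(chrom="8", pos=self.region.start - 250_000)
        assert select_cis([a], self.region) == [a]

    def test_one_past_boundary_dropped(self):
        audit = []
        a = make_assoc(chrom="8", pos=self.region.end + 250_001)
        assert select_cis([a], self.region, audit) == []
        assert audit[0].reason is DropReason.OUT_OF_WINDOW

    def test_chr_prefix_normalized(self):
        a = make_assoc(chrom="chr8", pos=19_800_000)
        assert select_cis([a], self.region) == [a]

    def test_region_union_spans_both_windows(self):
        """Adjacent loci analysed jointly keep variants near either gene."""
        abcg5 = GeneRegion("ABCG5", "2", 44_039_611, 44_066_004, flank_kb=250)
        abcg8 = GeneRegion("ABCG8", "2", 44_066_103, 44_105_605, flank_kb=250)
        near_first = make_assoc(snp_id="a", chrom="2", pos=44_039_611 - 200_000)
        near_second = make_assoc(snp_id="b", chrom="2", pos=44_105_605 + 200_000)
        between = make_assoc(snp_id="c", chrom="2", pos=44_066_050)
        far = make_assoc(snp_id="d", chrom="2", pos=50_000_000)
        kept = select_cis([near_first, near_second, between, far], [abcg5, abcg8])
        assert [a.snp_id for a in kept] == ["a", "b", "c"]

    def test_pqtl_mode_uses_wider_flank(self):
        region = GeneRegion("ANGPTL3", "1", 63_063_158, 63_071_830, flank_kb=500)
        a = make_assoc(chrom="1", pos=63_063_158 - 400_000)
        assert select_cis([a], region) == [a]


class TestThresholdFilters:
    def test_significance_strictly_below(self):
        kept = make_assoc(snp_id="keep", pval=4.9e-8)
        dropped = make_assoc(snp_id="drop", pval=5e-8)
        audit = []
        out = filter_significance([kept, dropped], 5e-8, audit)
        assert [a.snp_id for a in out] == ["keep"]
        assert audit[0].reason is DropReason.NOT_SIGNIFICANT

    def test_mediator_threshold(self):
        a = make_assoc(pval=9e-6)
        assert filter_significance([a], 1e-5) == [a]

    @pytest.mark.parametrize(
        "beta,se,expected", [(0.1, 0.01, 100.0), (0.03, 0.01, 9.0), (0.0, 0.05, 0.0)]
    )
    def test_f_statistic_values(self, beta, se, expected):
        assert f_statistic(make_assoc(beta=beta, se=se)) == pytest.approx(expected)

    def test_weak_filter_strictly_above_10(self):
        strong = make_assoc(snp_id="s", beta=0.1, se=0.01)  # F = 100
        weak = make_assoc(snp_id="w", beta=0.03, se=0.01)  # F = 9
        audit = []
        assert [a.snp_id for a in filter_weak([strong, weak], 10.0, audit)] == ["s"]
        assert audit[0].reason is DropReason.WEAK_INSTRUMENT

    @pytest.mark.parametrize(
        "eaf,kept", [(0.995, False), (0.01, True), (0.5, True), (0.005, False)]
    )
    def test_maf_removal_strict(self, eaf, kept):
        a = make_assoc(eaf=eaf)
        assert (filter_maf([a]) == [a]) is kept


def brute_force_clump(assocs, panel, r2_max, window_kb):
    """Independent reference: explicit greedy scan, no shared code."""
    remaining = sorted(assocs, key=lambda a: (a.pval, a.pos, a.snp_id))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        survivors = []
        for other in remaining:
            close = abs(other.pos - best.pos) <= window_kb * 1000
            r2 = panel.r_between(best.snp_id, other.snp_id) ** 2
            if not (close and r2 >= r2_max):
                survivors.append(other)
        remaining = survivors
    return kept


class TestClumping:
    def _three_snp_setup(self):
        r = np.array(
            [
                [1.0, np.sqrt(0.5), np.sqrt(0.05)],
                [np.sqrt(0.5), 1.0, np.sqrt(0.1)],
                [np.sqrt(0.05), np.sqrt(0.1), 1.0],
            ]
        )
        panel = make_panel(["s1", "s2", "s3"], [1_000_000, 1_010_000, 1_020_000], r)
        assocs = [
            make_assoc(snp_id="s1", pos=1_000_000, pval=1e-10),
            make_assoc(snp_id="s2", pos=1_010_000, pval=1e-9),
            make_assoc(snp_id="s3", pos=1_020_000, pval=1e-8),
        ]
        return assocs, panel

    def test_greedy_keeps_best_and_uncorrelated(self):
        assocs, panel = self._three_snp_setup()
        kept = ld_clump(assocs, panel, r2_max=0.2, window_kb=10_000)
        assert [a.snp_id for a in kept] == ["s1", "s3"]
        assert kept == brute_force_clump(assocs, panel, 0.2, 10_000)

    def test_r2_below_threshold_both_kept(self):
        r = np.array([[1.0, np.sqrt(0.19)], [np.sqrt(0.19), 1.0]])
        panel = make_panel(["a", "b"], [1_000_000, 1_010_000], r)
        assocs = [
            make_assoc(snp_id="a", pos=1_000_000, pval=1e-10),
            make_assoc(snp_id="b", pos=1_010_000, pval=1e-9),
        ]
        assert len(ld_clump(assocs, panel, 0.2, 10_000)) == 2

    def test_outside_window_both_kept(self):
        r = np.array([[1.0, 0.9], [0.9, 1.0]])
        panel = make_panel(["a", "b"], [1_000_000, 1_000_000 + 10_001_000], r)
        assocs = [
            make_assoc(snp_id="a", pos=1_000_000, pval=1e-10),
            make_assoc(snp_id="b", pos=1_000_000 + 10_001_000, pval=1e-9),
        ]
        assert len(ld_clump(assocs, panel, 0.2, 10_000)) == 2

    def test_missing_from_panel_audited_not_raised(self):
        panel = make_panel(["a"], [1_000_000], np.eye(1))
        audit = []
        kept = ld_clump(
            [make_assoc(snp_id="a"), make_assoc(snp_id="zz", pos=2_000_000)],
            panel,
            0.2,
            10_000,
            audit,
        )
        assert [a.snp_id for a in kept] == ["a"]
        assert audit[0].reason is DropReason.NOT_IN_PANEL

    @pytest.mark.parametrize("seed", range(30))
    def test_random_panels_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        A = rng.normal(size=(n, max(2, n // 2)))
        r = np.corrcoef(A) if n > 1 else np.eye(1)
        pos = np.sort(rng.choice(np.arange(1, 2_000_000, 1000), size=n, replace=False))
        ids = [f"v{i}" for i in range(n)]
        panel = make_panel(ids, pos, r)
        assocs = [
            make_assoc(snp_id=ids[i], pos=int(pos[i]), pval=float(rng.uniform(1e-30, 1e-8)))
            for i in range(n)
        ]
        got = ld_clump(assocs, panel, 0.2, 1_000)
        want = brute_force_clump(assocs, panel, 0.2, 1_000)
        assert [a.snp_id for a in got] == [a.snp_id for a in want]

    def test_order_invariance(self):
        assocs, panel = self._three_snp_setup()
        forward = {a.snp_id for a in ld_clump(assocs, panel, 0.2, 10_000)}
        backward = {a.snp_id for a in ld_clump(assocs[::-1], panel, 0.2, 10_000)}
        assert forward == backward


class TestSteiger:
    def test_tie_kept(self):
        h = make_hset([0.1], [0.01], [0.1], [0.01], n_x=1000, n_y=1000)
        assert steiger_filter(h).n_snps == 1

    def test_plug_in_removal(self):
        # z_x = 3, z_y = 10, equal n: exposure explains less variance
        h = make_hset([0.03], [0.01], [0.1], [0.01], n_x=1000, n_y=1000)
        out = steiger_filter(h)
        assert out.n_snps == 0
        assert out.audit[-1].reason is DropReason.STEIGER_REVERSED

    def test_zero_outcome_z_always_kept(self):
        h = make_hset([0.001], [0.01], [0.0], [0.01], n_x=1000, n_y=1000)
        assert steiger_filter(h).n_snps == 1

    def test_small_n_rejected(self):
        h = make_hset([0.1], [0.01], [0.1], [0.01], n_x=2, n_y=1000)
        with pytest.raises(ValueError, match="n > 2"):
            steiger_filter(h)


class TestPalindromeInference:
    def test_concordant_frequencies_no_flip(self):
        x = make_assoc(ea="A", oa="T", eaf=0.2)
        y = make_assoc(ea="A", oa="T", eaf=0.22)
        rx, ry = infer_palindrome_strand(x, y)
        assert ry.beta == y.beta and ry.eaf == y.eaf

    def test_discordant_frequencies_flip(self):
        x = make_assoc(ea="A", oa="T", eaf=0.2)
        y = make_assoc(ea="A", oa="T", eaf=0.78, beta=0.05)
        _, ry = infer_palindrome_strand(x, y)
        assert ry.beta == pytest.approx(-0.05)
        assert ry.eaf == pytest.approx(0.22)

    def test_ambiguous_zone_unresolved(self):
        x = make_assoc(ea="A", oa="T", eaf=0.48)
        y = make_assoc(ea="A", oa="T", eaf=0.52)
        assert infer_palindrome_strand(x, y) is None

    def test_non_palindrome_rejected(self):
        with pytest.raises(ValueError):
            infer_palindrome_strand(make_assoc(ea="A", oa="G"), make_assoc(ea="A", oa="G"))


@st.composite
def cascade_inputs(draw):
    n = draw(st.integers(2, 10))
    rng = np.random.default_rng(draw(st.integers(0, 10_000)))
    pos = np.sort(rng.choice(np.arange(1, 500_000, 500), size=n, replace=False))
    ids = [f"v{i}" for i in range(n)]
    A = rng.normal(size=(n, max(2, n)))
    r = np.corrcoef(A)
    panel = make_panel(ids, pos, r)
    assocs = [
        make_assoc(
            snp_id=ids[i],
            pos=int(pos[i]),
            eaf=float(rng.uniform(0.005, 0.995)),
            beta=float(rng.normal(0, 0.1)) or 0.01,
            se=float(rng.uniform(0.005, 0.05)),
            pval=float(10 ** rng.uniform(-12, -4)),
        )
        for i in range(n)
    ]
    return assocs, panel


class TestCascadeProperties:
    @given(cascade_inputs())
    @settings(max_examples=40, deadline=None)
    def test_audit_completeness(self, inputs):
        """Every input variant lands in kept or audit, exactly once."""
        assocs, panel = inputs
        out = select_instruments(assocs, panel)
        ids = sorted(a.snp_id for a in assocs)
        accounted = sorted([a.snp_id for a in out.kept] + [r.snp_id for r in out.audit])
        assert accounted == ids

    @given(cascade_inputs())
    @settings(max_examples=40, deadline=None)
    def test_idempotence(self, inputs):
        """Re-running the cascade on its own output changes nothing."""
        assocs, panel = inputs
        once = select_instruments(assocs, panel)
        twice = select_instruments(once.kept, panel)
        assert [a.snp_id for a in twice.kept] == [a.snp_id for a in once.kept]
        assert not twice.audit

    @given(cascade_inputs(), st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None)
    def test_order_invariance(self, inputs, rand):
        assocs, panel = inputs
        shuffled = list(assocs)
        rand.shuffle(shuffled)
        a = {v.snp_id for v in select_instruments(assocs, panel).kept}
        b = {v.snp_id for v in select_instruments(shuffled, panel).kept}
        assert a == b
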