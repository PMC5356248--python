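import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import comb

from cnvburden.association import (
    ContingencyTable,
    build_contingency,
    by_fdr,
    fisher_exact_two_sided,
    odds_ratio_cmle,
    run_association,
)
from cnvburden.errors import ValidationError
from cnvburden.simulate import generate_cohort, SimConfig
from cnvburden.annotate import assign_cnv_regions, collapse_transcripts

from conftest import make_samples


def enumerate_fisher_p(a, b, c, d):
    """Independent oracle: enumerate every table with the observed margins."""
    m1, m2, k = a + b, c + d, a + c
    lo, hi = max(0, k - m2), min(k, m1)
    probs = {
        x: comb(m1, x, exact=True) * comb(m2, k - x, exact=True)
        for x in range(lo, hi + 1)
    }
    total = sum(probs.values())
    obs = probs[a]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-7)) / total


class TestFisher:
    def test_identical_rows_give_p_one(self):
        assert fisher_exact_two_sided(4, 6, 4, 6) == pytest.approx(1.0)

    def test_dock5_style_table(self):
        p = fisher_exact_two_sided(29, 171, 7, 286)
        assert p == pytest.approx(5.3e-07, rel=0.01)

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    @settings(max_examples=300, deadline=None)
    def test_matches_full_enumeration(self, a, b, c, d):
        """Property: equality with the all-tables enumeration oracle."""
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            with pytest.raises(ValidationError):
                fisher_exact_two_sided(a, b, c, d)
            return
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
            enumerate_fisher_p(a, b, c, d), rel=1e-9
        )

    def test_invariant_under_row_and_column_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 60, 4)
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                fisher_exact_two_sided(d, c, b, a), rel=1e-9
            )


class TestOddsRatioCmle:
    def test_symmetric_table_is_exactly_one(self):
        est, lo, hi = odds_ratio_cmle(7, 13, 7, 13)
        assert est == pytest.approx(1.0, abs=1e-9)
        assert lo < 1.0 < hi

    def test_dock5_table_reproduces_published_convention(self):
        est, lo, hi = odds_ratio_cmle(29, 171, 7, 286)
        assert round(est, 1) == 6.9
        assert (round(lo, 1), round(hi, 1)) == (2.9, 19.1)

    def test_zero_cell_degenerates_to_zero(self):
        est, lo, hi = odds_ratio_cmle(0, 10, 3, 7)
        assert (est, lo) == (0.0, 0.0)
        assert np.isfinite(hi)

    def test_full_row_degenerates_to_infinity(self):
        est, lo, hi = odds_ratio_cmle(10, 0, 3, 7)
        assert est == np.inf and hi == np.inf
        assert np.isfinite(lo) and lo > 0

    def test_row_swap_inverts_the_odds_ratio(self):
        est, lo, hi = odds_ratio_cmle(29, 171, 7, 286)
        est2, lo2, hi2 = odds_ratio_cmle(7, 286, 29, 171)
        assert est2 == pytest.approx(1 / est, rel=1e-8)
        assert lo2 == pytest.approx(1 / hi, rel=1e-6)
        assert hi2 == pytest.approx(1 / lo, rel=1e-6)

    def test_matches_reference_implementation(self):
        """Random tables agree with scipy's conditional odds ratio to 1e-6."""
        rng = np.random.default_rng(6)
        for _ in range(25):
            a, b, c, d = (int(v) for v in rng.integers(1, 80, 4))
            est, lo, hi = odds_ratio_cmle(a, b, c, d)
            ref = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
            ci = ref.confidence_interval(0.95)
            assert est == pytest.approx(ref.statistic, rel=1e-6)
            assert lo == pytest.approx(ci.low, rel=1e-6)
            assert hi == pytest.approx(ci.high, rel=1e-6)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            odds_ratio_cmle(0, 0, 3, 7)


class TestByFdr:
    def test_single_p_unchanged(self):
        assert by_fdr([0.03]) == pytest.approx([0.03])

    def test_equal_ps_scale_by_harmonic_sum(self):
        m, p = 7, 0.004
        cm = sum(1 / i for i in range(1, m + 1))
        np.testing.assert_allclose(by_fdr([p] * m), min(1.0, cm * p))

    @given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_matches_direct_definition(self, ps):
        """Property: equality with direct min-over-j evaluation of the definition."""
        m = len(ps)
        cm = sum(1.0 / i for i in range(1, m + 1))
        order = np.argsort(ps, kind="mergesort")
        sorted_p = np.array(ps)[order]
        expected_sorted = [
            min(1.0, min(m * cm * sorted_p[j] / (j + 1) for j in range(i, m)))
            for i in range(m)
        ]
        expected = np.empty(m)
        expected[order] = expected_sorted
        np.testing.assert_allclose(by_fdr(ps), expected, rtol=1e-12)

    def test_dominates_benjamini_hochberg(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1, 40)
        m = len(p)
        order = np.argsort(p)
        bh_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        bh = np.empty(m)
        bh[order] = np.minimum(1.0, bh_sorted)
        assert (by_fdr(p) >= bh - 1e-12).all()

    @pytest.mark.parametrize("bad", [[0.0], [1.2], [-0.1], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            by_fdr(bad)


def region_events(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_symbol", "sample_id", "state_class", "chrom",
                 "start", "end", "copy_number", "call_index"],
    )


class TestBuildContingency:
    GROUPS = make_samples(
        [("S1", "case"), ("S2", "case"), ("S3", "control"), ("S4", "control"),
         ("S5", "control")]
    )

    def test_control_only_region(self):
        ev = region_events([("G", "S3", "loss", "chr1", 0, 10, 1, 0),
                            ("G", "S4", "loss", "chr1", 0, 10, 1, 1)])
        (tab,) = build_contingency(ev, self.GROUPS)
        assert (tab.a, tab.b, tab.c, tab.d) == (0, 2, 2, 1)

    def test_sample_with_two_events_is_one_carrier(self):
        ev = region_events([("G", "S1", "loss", "chr1", 0, 10, 1, 0),
                            ("G", "S1", "loss", "chr1", 20, 30, 0, 1)])
        (tab,) = build_contingency(ev, self.GROUPS)
        assert (tab.a, tab.c) == (1, 0)

    def test_each_state_emits_two_tables(self):
        ev = region_events([("G", "S1", "loss", "chr1", 0, 10, 1, 0),
                            ("G", "S3", "gain", "chr1", 0, 10, 3, 1)])
        tabs = build_contingency(ev, self.GROUPS, mode="each_state")
        assert [t.state_class for t in tabs] == ["loss", "gain"]

    def test_dominant_state_tie_resolves_to_loss(self):
        ev = region_events([("G", "S1", "loss", "chr1", 0, 10, 1, 0),
                            ("G", "S3", "gain", "chr1", 0, 10, 3, 1)])
        tabs = build_contingency(ev, self.GROUPS, mode="dominant_state")
        assert len(tabs) == 1 and tabs[0].state_class == "loss"

    def test_random_cohort_matches_per_sample_scan(self):
        rng = np.random.default_rng(9)
        sids = ["S1", "S2", "S3", "S4", "S5"]
        rows = [
            ("G", rng.choice(sids), rng.choice(["loss", "gain"]), "chr1", 0, 10, 1, i)
            for i in range(30)
        ]
        ev = region_events(rows)
        for tab in build_contingency(ev, self.GROUPS, mode="each_state"):
            carriers = {r[1] for r in rows if r[2] == tab.state_class}
            group_of = dict(zip(self.GROUPS["sample_id"], self.GROUPS["group"]))
            a = sum(1 for s in carriers if group_of[s] == "case")
            c = len(carriers) - a
            assert (tab.a, tab.c) == (a, c)
            assert tab.a + tab.b == 2 and tab.c + tab.d == 3

    def test_unknown_sample_rejected(self):
        ev = region_events([("G", "GHOST", "loss", "chr1", 0, 10, 1, 0)])
        with pytest.raises(ValidationError, match="without a group"):
            build_contingency(ev, self.GROUPS)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable("G", "loss", -1, 2, 3, 4)


class TestRunAssociation:
    def test_single_region_adjusted_equals_raw(self):
        groups = make_samples(
            [(f"S{i}", "case") for i in range(5)]
            + [(f"S{i}", "control") for i in range(5, 12)]
        )
        ev = region_events([("G", "S0", "loss", "chr1", 0, 10, 1, 0),
                            ("G", "S1", "loss", "chr1", 0, 10, 1, 1)])
        res = run_association(ev, groups)
        assert len(res) == 1
        assert res.iloc[0]["p_adjusted"] == pytest.approx(res.iloc[0]["p_value"])
        assert res.iloc[0]["p_adjusted"] >= res.iloc[0]["p_value"]

    def test_spiked_locus_attains_smallest_p(self):
        """A strongly spiked risk locus ranks first among null regions."""
        cfg = SimConfig(
            seed=77, n_cases=100, n_controls=150, n_genes=80,
            genome=(("chr1", 20_000_000), ("chr2", 20_000_000)),
            mean_deletions_control=5.0, mean_gains_control=3.0,
            deletion_enrichment=1.0,
            spiked_loci=((12, "loss", 0.5, 0.02),),
        )
        calls, samples, transcripts, _ = generate_cohort(cfg)
        events = assign_cnv_regions(calls, collapse_transcripts(transcripts))
        res = run_association(events, samples, compute_or=False)
        assert res.iloc[0]["gene_symbol"] == "GENE0012"
        assert res.iloc[0]["state_class"] == "loss"
        assert res["p_value"].is_monotonic_increasing

    def test_empty_events_rejected(self):
        with pytest.raises(ValidationError):
            run_association(region_events([]), make_samples([("S1", "case")]))
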