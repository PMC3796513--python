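"""Group statistics: summaries, t-tests, ANOVA equivalence, Spearman."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import limbpet as lp
from limbpet.errors import DegenerateStatisticsError
from limbpet.stats import records_to_frame


def _round_half_away(x, nd=1):
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -nd
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class TestSummaries:
    def test_published_group_means(self, table2):
        """The four group-mean rows of the published table, reproduced at
        printed precision from the raw per-arm rows."""
        summaries = {s.label: s for s in lp.summarize_groups(table2)}
        ab = summaries["affected before"]
        assert ab.n == 10
        assert _round_half_away(ab.means["volume_ml"]) == 149.7
        assert _round_half_away(ab.means["mean_z"]) == 5.2
        assert _round_half_away(ab.means["vis"]) == 892.3
        ub = summaries["unaffected before"]
        assert _round_half_away(ub.means["vis"]) == 11.5
        aa = summaries["affected after"]
        assert aa.n == 8
        assert _round_half_away(aa.means["volume_ml"], 0) == 212
        assert _round_half_away(aa.means["vis"], 0) == 1038
        assert _round_half_away(aa.means["pain_vas"], 0) == 25
        ua = summaries["unaffected after"]
        assert _round_half_away(ua.means["volume_ml"]) == 0.9

    def test_single_record_group(self, table2_records):
        one = [r for r in table2_records if r.subject_id == "4"]
        summaries = lp.summarize_groups(one)
        aff = [s for s in summaries if s.label == "affected before"][0]
        assert aff.n == 1
        assert aff.means["volume_ml"] == 31.8

    def test_empty_input_errors(self):
        with pytest.raises(DegenerateStatisticsError):
            lp.summarize_groups([])


class TestTTest:
    def test_identical_paired_samples(self):
        res = lp.t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "paired")
        assert res.statistic == 0.0
        assert res.p_two_tailed == 1.0

    @pytest.mark.parametrize("mode", ["paired", "pooled", "welch"])
    def test_published_volume_contrast(self, table2, mode):
        """Affected vs unaffected before-treatment suprathreshold volumes:
        p < 0.001 regardless of the pairing assumption."""
        before = table2[table2["timepoint"] == "before"]
        wide = before.pivot(index="subject", columns="arm", values="volume_ml")
        res = lp.t_test(wide["affected"], wide["unaffected"], mode)
        assert res.p_two_tailed < 0.001
        assert res.statistic > 0

    def test_pooled_t_equals_anova_for_two_groups(self, table2):
        """F = t^2 with identical p — the pooled two-sample t and the
        unbalanced one-way ANOVA are the same test for two groups."""
        before = table2[table2["timepoint"] == "before"]
        x = before.loc[before["arm"] == "affected", "volume_ml"].to_numpy()
        y = before.loc[before["arm"] == "unaffected", "volume_ml"].to_numpy()
        t_res = lp.t_test(x, y, "pooled")
        f_res = lp.oneway_anova_unbalanced([x, y])
        assert f_res.statistic == pytest.approx(t_res.statistic**2, rel=1e-10)
        assert f_res.p_two_tailed == pytest.approx(t_res.p_two_tailed, rel=1e-10)

    def test_shift_invariance_and_sign_flip(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 8)
        res = lp.t_test(x, y, "welch")
        shifted = lp.t_test(x + 100, y + 100, "welch")
        assert shifted.statistic == pytest.approx(res.statistic, rel=1e-9)
        flipped = lp.t_test(y, x, "welch")
        assert flipped.statistic == pytest.approx(-res.statistic, rel=1e-9)
        assert flipped.p_two_tailed == pytest.approx(res.p_two_tailed, rel=1e-9)

    def test_degenerate_cases(self):
        with pytest.raises(DegenerateStatisticsError):
            lp.t_test([1.0, 1.0, 1.0], [2.0, 2.0], "pooled")
        with pytest.raises(DegenerateStatisticsError):
            lp.t_test([1.0, 2.0], [1.0, 2.0, 3.0], "paired")


class TestAnova:
    def test_unequal_group_sizes_accepted(self):
        rng = np.random.default_rng(2)
        res = lp.oneway_anova_unbalanced([rng.normal(0, 1, 10), rng.normal(0, 1, 8)])
        assert res.degrees_of_freedom == 16

    def test_all_identical_errors(self):
        with pytest.raises(DegenerateStatisticsError):
            lp.oneway_anova_unbalanced([[1.0, 1.0], [1.0, 1.0, 1.0]])

    def test_three_group_type_one_error_calibrated(self):
        """Three equal-mean Gaussian groups: rejection rate at alpha=0.05
        stays within (0.04, 0.06) over 2000 replicates."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            groups = [rng.normal(0, 1, n) for n in (10, 8, 6)]
            if lp.oneway_anova_unbalanced(groups).p_two_tailed < 0.05:
                rejections += 1
        assert 0.04 < rejections / n_rep < 0.06


class TestSpearman:
    def test_monotone_pair(self):
        assert lp.spearman([1, 2, 3, 4], [10, 20, 25, 100]) == pytest.approx(1.0)

    def test_published_correlations(self, table2):
        """Pain VAS vs Volume intensity score: 0.70 over all 36 arm rows,
        0.30 over the 18 affected-arm rows (average-rank tie handling)."""
        r_all = lp.spearman(table2["pain_vas"], table2["vis"])
        assert round(r_all, 2) == 0.70
        aff = table2[table2["arm"] == "affected"]
        r_aff = lp.spearman(aff["pain_vas"], aff["vis"])
        assert round(r_aff, 2) == 0.30

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=20, unique=True))
    def test_no_tie_closed_form(self, y):
        """With no ties, Spearman equals 1 - 6*sum(d^2)/(n(n^2-1))."""
        x = list(range(len(y)))
        n = len(y)
        rank_y = np.argsort(np.argsort(y))
        d = np.arange(n) - rank_y
        closed = 1 - 6 * np.sum(d**2) / (n * (n**2 - 1))
        assert lp.spearman(x, y) == pytest.approx(closed, abs=1e-12)

    def test_constant_sample_errors(self):
        with pytest.raises(DegenerateStatisticsError):
            lp.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_records_roundtrip_to_frame(table2_records, table2):
    df = records_to_frame(table2_records)
    assert len(df) == 36
    merged = df.merge(table2, on=["subject", "timepoint", "arm"], suffixes=("", "_ref"))
    assert len(merged) == 36
    np.testing.assert_allclose(merged["vis"], merged["vis_ref"])
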