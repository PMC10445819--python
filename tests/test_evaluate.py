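"""Agreement analysis, DDD conversion, and extreme-change flagging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmpec.evaluate import (
    DDDEntry,
    DDDRegistry,
    InsufficientDataError,
    PairedWeights,
    UndefinedDDDError,
    bland_altman,
    categorise_flags,
    compare_sources,
    ddd_to_grams,
    flag_extreme_changes,
    load_ddd_panel,
    load_extreme_change_annotations,
)
from pharmpec.filters import AnnualAPIWeight


def _series(api, values, start=2016):
    return [AnnualAPIWeight(api, start + i, v) for i, v in enumerate(values)]


class TestBlandAltman:
    def test_identical_datasets_have_zero_mean_and_sd(self):
        pairs = [PairedWeights(f"a{i}", 10.0 ** i, 10.0 ** i) for i in range(1, 5)]
        s = bland_altman(pairs)
        assert s.mean_difference == 0.0 and s.sd_difference == 0.0
        assert not s.outliers

    def test_two_pair_hand_example(self):
        s = bland_altman([PairedWeights("a", 10, 1), PairedWeights("b", 1, 10)])
        assert s.mean_difference == pytest.approx(0.0, abs=1e-12)
        assert s.sd_difference == pytest.approx(math.sqrt(2), rel=1e-12)
        assert s.lower_limit == pytest.approx(-1.96 * math.sqrt(2), rel=1e-12)
        assert s.upper_limit == pytest.approx(+1.96 * math.sqrt(2), rel=1e-12)

    def test_discrepant_pair_detected(self):
        pairs = [
            PairedWeights("a", 100, 100),
            PairedWeights("b", 1000, 1000),
            PairedWeights("c", 10, 1000),
        ]
        s = bland_altman(pairs)
        third = next(d for _, d, api in s.points if api == "c")
        assert third == pytest.approx(-2.0)
        # limits of agreement bound individual points, so the discrepant
        # pair stays inside them; the CI-of-mean mode flags it
        assert not s.outliers
        s_ci = bland_altman(pairs, ci_of_mean=True)
        assert s_ci.outliers == ["c"]

    def test_antisymmetry_under_swap(self):
        pairs = [PairedWeights(f"a{i}", w, v) for i, (w, v) in
                 enumerate([(10, 3), (250, 400), (7, 7), (1e6, 2e5)])]
        swapped = [PairedWeights(p.api_name, p.weight_b, p.weight_a) for p in pairs]
        s1, s2 = bland_altman(pairs), bland_altman(swapped)
        assert s1.mean_difference == pytest.approx(-s2.mean_difference, rel=1e-12)
        assert s1.lower_limit == pytest.approx(-s2.upper_limit, rel=1e-12)
        for (m1, d1, _), (m2, d2, _) in zip(s1.points, s2.points):
            assert m1 == pytest.approx(m2) and d1 == pytest.approx(-d2)

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    @settings(derandomize=True)
    def test_scale_invariance_of_differences(self, scale):
        pairs = [PairedWeights("a", 12.0, 30.0), PairedWeights("b", 45.0, 2.0),
                 PairedWeights("c", 7.0, 7.0)]
        scaled = [PairedWeights(p.api_name, p.weight_a * scale, p.weight_b * scale)
                  for p in pairs]
        s1, s2 = bland_altman(pairs), bland_altman(scaled)
        assert s1.mean_difference == pytest.approx(s2.mean_difference, abs=1e-9)
        assert s1.sd_difference == pytest.approx(s2.sd_difference, abs=1e-9)

    def test_nonpositive_pairs_excluded_and_counted(self):
        pairs = [PairedWeights("a", 10, 1), PairedWeights("b", 1, 10),
                 PairedWeights("c", 0, 5), PairedWeights("d", 3, -1)]
        s = bland_altman(pairs)
        assert s.n_pairs == 2 and s.n_excluded == 2

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([PairedWeights("a", 1, 1)])


class TestDDD:
    def test_count_times_dose(self):
        reg = load_ddd_panel()
        assert ddd_to_grams(1000, reg.highest("N02BE01")) == pytest.approx(3000.0)

    def test_highest_value_selected(self):
        reg = load_ddd_panel()
        assert reg.highest("J01CA04").ddd_value == pytest.approx(3.0)

    def test_undefined_ddd_raises(self):
        reg = load_ddd_panel()
        with pytest.raises(UndefinedDDDError):
            reg.highest("QJ01CA04")  # veterinary code with no assigned DDD

    def test_zero_count(self):
        assert ddd_to_grams(0, DDDEntry("C07AB02", 0.15, "oral")) == 0.0

    def test_registry_multiple_routes(self):
        reg = DDDRegistry([DDDEntry("G03DA04", 0.03, "oral"),
                           DDDEntry("G03DA04", 0.09, "vaginal")])
        assert len(reg.entries("G03DA04")) == 2
        assert reg.highest("G03DA04").route == "vaginal"


class TestCompareSources:
    def test_ratio_and_log_difference(self):
        w = AnnualAPIWeight("paracetamol", 2019, 150.0)
        ratio, logdiff = compare_sources(w, 100.0)
        assert ratio == pytest.approx(1.5)
        w2 = AnnualAPIWeight("xylometazoline", 2019, 1000.0)
        _, logdiff2 = compare_sources(w2, 1.0)
        assert logdiff2 == pytest.approx(3.0)
        ratio3, _ = compare_sources(AnnualAPIWeight("m", 2019, 5.0), 5.0)
        assert ratio3 == pytest.approx(1.0)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            compare_sources(AnnualAPIWeight("a", 2019, 1.0), 0.0)


class TestExtremeChanges:
    def test_small_side_flag(self):
        flags, _ = flag_extreme_changes(_series("w", [1000, 1000, 1000, 1]))
        f = flags[0]
        assert f.mean_grams == pytest.approx(750.25)
        assert f.min_ratio == pytest.approx(1 / 750.25, rel=1e-9)
        assert f.flagged

    def test_flat_series_not_flagged(self):
        flags, _ = flag_extreme_changes(_series("w", [10, 10, 10, 10]))
        assert not flags[0].flagged

    def test_rule_disagreement_on_single_year_spike(self):
        series = _series("w", [1, 1, 1, 100])
        overall, _ = flag_extreme_changes(series, rule="overall_mean")
        loo, _ = flag_extreme_changes(series, rule="leave_one_out")
        # the overall mean absorbs the spike on the large side...
        assert overall[0].max_ratio == pytest.approx(100 / 25.75, rel=1e-9)
        assert overall[0].max_ratio < 10
        # ...while leave-one-out sees the full factor
        assert loo[0].max_ratio == pytest.approx(100.0)
        assert loo[0].flagged

    def test_four_year_large_side_bound(self):
        # with n strictly positive years max/mean < n, so the factor-10
        # rule can never fire on the large side of a 4-year series
        rng = np.random.default_rng(2024)
        for _ in range(10_000):
            values = rng.lognormal(mean=0.0, sigma=3.0, size=4)
            assert values.max() / values.mean() < 4.0

    def test_single_year_series_excluded_with_reason(self):
        flags, excluded = flag_extreme_changes(_series("solo", [5.0]))
        assert not flags
        assert excluded[0][0] == "solo" and "two years" in excluded[0][1]

    def test_invariance_to_order_and_joint_rescaling(self):
        series = _series("a", [3, 500, 20, 8]) + _series("b", [7, 7, 9, 7])
        flags1, _ = flag_extreme_changes(series)
        flags2, _ = flag_extreme_changes(list(reversed(series)))
        scaled = [AnnualAPIWeight(w.api_name, w.year, w.grams * 1e6) for w in series]
        flags3, _ = flag_extreme_changes(scaled)
        decisions = lambda fl: {f.api_name: f.flagged for f in fl}
        assert decisions(flags1) == decisions(flags2) == decisions(flags3)


class TestCategorisation:
    def test_packaged_shortlist_counts(self):
        annotations = load_extreme_change_annotations()
        weights = []
        for api in annotations:
            weights += _series(api, [1000, 1000, 1000, 1])
        flags, _ = flag_extreme_changes(weights)
        shortlist, summary = categorise_flags(flags, annotations)
        assert summary.total == 31
        assert summary.counts["authorisation_change"] == 23
        assert summary.counts["supply_shortage"] == 3
        assert summary.counts["unexplained"] == 5
        assert summary.percentages["unexplained"] == pytest.approx(16.1, abs=0.05)

    def test_empty_annotations_leave_unclassified(self):
        flags, _ = flag_extreme_changes(_series("mystery", [1000, 1000, 1000, 1]))
        shortlist, summary = categorise_flags(flags, {})
        assert shortlist[0].category == "unclassified"
        assert summary.counts["unclassified"] == 1
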