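"""Expected accuracy, AUC and odds-ratio calculators."""

import numpy as np
import pytest

from gprelate.accuracy import (
    TraitDesign,
    accuracy_case_control,
    accuracy_phenotypic,
    accuracy_quantitative,
    captured_fraction,
    expected_auc,
    expected_or,
)
from gprelate.liability import liability_quantities, percentile_quantities
from gprelate.me_theory import PopulationGenomeSpec, me_closed_form_genome

LIA = liability_quantities(0.1)
CC_DESIGN = TraitDesign(h2=0.5, N=3000, P=0.5)


def genome_me(ne):
    return me_closed_form_genome(
        PopulationGenomeSpec(Ne=ne, n_chr=30, chr_length=1.0, mutation_correction=True)
    )


class TestCapturedFraction:
    def test_dense_markers_capture_everything(self):
        assert captured_fraction(10**9, 5000) == pytest.approx(1.0, abs=1e-4)

    def test_equal_marker_and_segment_count(self):
        assert captured_fraction(500, 500.0) == pytest.approx(500 / (500 + 500))

    def test_increasing_in_marker_count(self):
        bs = [captured_fraction(m, 1000.0) for m in (100, 1000, 10000)]
        assert bs[0] < bs[1] < bs[2]


class TestQuantitativeAccuracy:
    def test_limits(self):
        d = TraitDesign(h2=0.5, N=1000)
        assert accuracy_quantitative(d, 1e-9) == pytest.approx(1.0, abs=1e-4)
        assert accuracy_quantitative(TraitDesign(h2=0.5, N=10**9), 100.0) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_small_ne_design_phenotype_correlation(self):
        assert accuracy_phenotypic(TraitDesign(h2=0.5, N=3000), genome_me(100)) == pytest.approx(
            0.65, abs=0.005
        )

    def test_large_ne_design_phenotype_correlation(self):
        assert accuracy_phenotypic(TraitDesign(h2=0.5, N=3000), genome_me(10000)) == pytest.approx(
            0.18, abs=0.005
        )

    @pytest.mark.parametrize(
        "h2, me, expected",
        [(0.8, 4434, 0.551), (0.45, 31080, 0.145)],
    )
    def test_empirical_me_designs(self, h2, me, expected):
        assert accuracy_phenotypic(TraitDesign(h2=h2, N=3394), me) == pytest.approx(
            expected, abs=0.0005
        )

    def test_markers_reduce_accuracy_via_captured_fraction(self):
        dense = TraitDesign(h2=0.5, N=2000)
        sparse = TraitDesign(h2=0.5, N=2000, M=500)
        assert accuracy_quantitative(sparse, 1000.0) < accuracy_quantitative(dense, 1000.0)


class TestCaseControlAccuracy:
    def test_monotone_in_sample_size(self):
        vals = [
            accuracy_case_control(TraitDesign(h2=0.5, N=n, P=0.5), 1000.0, LIA)
            for n in (100, 1000, 10000, 10**7)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0

    def test_vanishes_with_infinite_segments(self):
        assert accuracy_case_control(CC_DESIGN, 1e12, LIA) == pytest.approx(0.0, abs=1e-3)

    def test_requires_case_proportion(self):
        with pytest.raises(ValueError):
            accuracy_case_control(TraitDesign(h2=0.5, N=3000), 100.0, LIA)


class TestExpectedAuc:
    def test_no_accuracy_means_chance(self):
        assert expected_auc(CC_DESIGN, 1e12, LIA) == pytest.approx(0.5, abs=1e-3)

    def test_theory_curve_endpoints(self):
        assert expected_auc(CC_DESIGN, genome_me(100), LIA) == pytest.approx(0.85, abs=0.005)
        assert expected_auc(CC_DESIGN, genome_me(10000), LIA) == pytest.approx(0.60, abs=0.005)

    @pytest.mark.parametrize(
        "h2, me, printed",
        [(0.8, 3247, 0.682), (0.45, 29479, 0.537)],
    )
    def test_small_discovery_designs(self, h2, me, printed):
        auc = expected_auc(TraitDesign(h2=h2, N=680, P=0.5), me, LIA)
        assert auc == pytest.approx(printed, rel=0.02)

    def test_strictly_increasing_in_accuracy(self):
        mes = [100, 500, 2000, 10000, 50000]
        aucs = [expected_auc(CC_DESIGN, me, LIA) for me in mes]
        assert all(a > b for a, b in zip(aucs, aucs[1:]))


class TestExpectedOr:
    def test_no_accuracy_means_unit_odds(self):
        c = percentile_quantities(0.2)
        assert expected_or(CC_DESIGN, 1e12, LIA, c, "top_vs_bottom") == pytest.approx(
            1.0, abs=1e-2
        )
        assert expected_or(CC_DESIGN, 1e12, LIA, c, "top_vs_population") == pytest.approx(
            1.0, abs=1e-2
        )

    def test_top_bottom_twenty_percent_small_ne(self):
        c = percentile_quantities(0.2)
        v = expected_or(CC_DESIGN, genome_me(100), LIA, c, "top_vs_bottom")
        assert v == pytest.approx(131.9, rel=0.02)

    def test_top_one_percent_vs_population_small_ne(self):
        c = percentile_quantities(0.01, 0.01)
        v = expected_or(CC_DESIGN, genome_me(100), LIA, c, "top_vs_population")
        assert v == pytest.approx(23.0, rel=0.02)

    def test_large_ne_curve_endpoints(self):
        me = genome_me(10000)
        assert expected_or(
            CC_DESIGN, me, LIA, percentile_quantities(0.2), "top_vs_bottom"
        ) == pytest.approx(2.7, abs=0.05)
        assert expected_or(
            CC_DESIGN, me, LIA, percentile_quantities(0.01, 0.01), "top_vs_population"
        ) == pytest.approx(2.3, abs=0.05)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            expected_or(CC_DESIGN, 100.0, LIA, percentile_quantities(0.2), "sideways")


def test_all_quantities_monotone_on_grids():
    """More data or fewer segments never hurt any expected quantity."""
    c = percentile_quantities(0.2)
    for n_lo, n_hi in [(500, 2000), (2000, 8000)]:
        lo = TraitDesign(h2=0.5, N=n_lo, P=0.5)
        hi = TraitDesign(h2=0.5, N=n_hi, P=0.5)
        for me in (254.0, 4506.0, 21248.0):
            assert accuracy_quantitative(lo, me) < accuracy_quantitative(hi, me)
            assert expected_auc(lo, me, LIA) < expected_auc(hi, me, LIA)
            assert expected_or(lo, me, LIA, c) < expected_or(hi, me, LIA, c)
    for me_lo, me_hi in [(254.0, 1188.0), (4506.0, 21248.0)]:
        d = CC_DESIGN
        assert accuracy_quantitative(d, me_lo) > accuracy_quantitative(d, me_hi)
        assert expected_auc(d, me_lo, LIA) > expected_auc(d, me_hi, LIA)
        assert expected_or(d, me_lo, LIA, c) > expected_or(d, me_hi, LIA, c)
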