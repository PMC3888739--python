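import math

import pytest

from rletox import (
    SyntheticConfig,
    ToxicityRecord,
    ToxicitySeries,
    compare_reported_vs_calculated,
    fit_ols,
    fit_rle,
    generate_series,
    internal_from_ambient,
    ln_nlt_from_fit,
    predict_lc50,
    predict_lt50,
    species_calculated_nlt,
    toxicity_constant,
    two_point_fit,
)
from rletox.errors import (
    InconsistentInputsError,
    InsufficientDataError,
    InsufficientDatasetsError,
    NegativeExtrapolationError,
    NoToxicityTrendError,
    ValidationError,
)
from rletox.regression import LinearFit

from conftest import series_on_line


def linfit(a, b):
    return LinearFit(slope_a=a, intercept_b=b, r_squared=1.0, n_points=4)


class TestFitRLE:
    def test_exact_line(self):
        s = series_on_line(-100, 300, [1, 2, 4])
        f = fit_rle(s)
        assert f.slope_a == pytest.approx(-100)
        assert f.intercept_b == pytest.approx(300)
        assert f.r_squared == pytest.approx(1)
        assert not f.screen_flags

    def test_constant_lc50_flagged(self):
        s = ToxicitySeries("sp", "tox", [ToxicityRecord(t, 50) for t in (1, 2, 4)])
        f = fit_rle(s)
        assert "constant_lc50" in f.screen_flags
        assert "low_r2" in f.screen_flags  # R² reported as 0

    def test_rising_lc50_flagged_not_rejected(self):
        s = ToxicitySeries("sp", "tox",
                           [ToxicityRecord(1, 10), ToxicityRecord(2, 20), ToxicityRecord(4, 40)])
        f = fit_rle(s)
        assert "nonneg_slope" in f.screen_flags

    def test_single_time_rejected(self):
        s = ToxicitySeries("sp", "tox", [ToxicityRecord(1, 10), ToxicityRecord(1, 12)])
        with pytest.raises(InsufficientDataError):
            fit_rle(s)

    def test_matches_regression_module_on_noisy_data(self):
        cfg = SyntheticConfig(true_slope_a=-100, true_intercept_b=300,
                              noise_sd=5, n_series=1, seed=1)
        [s] = generate_series(cfg)
        f = fit_rle(s)
        oracle = fit_ols([(math.log(t), c) for t, c in zip(s.times_days, s.lc50s_ugL)])
        assert f.slope_a == pytest.approx(oracle.slope_a, rel=1e-10)
        assert f.intercept_b == pytest.approx(oracle.intercept_b, rel=1e-10)


class TestLnNLT:
    def test_table_coefficients(self):
        est = ln_nlt_from_fit(linfit(-9400, 100000))
        assert est.ln_nlt == pytest.approx(100000 / 9400)
        assert est.nlt_days == pytest.approx(math.exp(100000 / 9400))
        assert est.method == "single_fit"

    def test_unit_case_and_boundary(self):
        assert ln_nlt_from_fit(linfit(-1, 1)).ln_nlt == pytest.approx(1)
        with pytest.raises(NegativeExtrapolationError):
            ln_nlt_from_fit(linfit(-1, 0))

    def test_nonnegative_slope_rejected(self):
        with pytest.raises(NoToxicityTrendError):
            ln_nlt_from_fit(linfit(0.5, 100))

    @pytest.mark.parametrize("c", [0.001, 1.0, 1000.0])
    def test_concentration_rescaling_invariance(self, c):
        base = ln_nlt_from_fit(linfit(-9400, 100000)).ln_nlt
        scaled = ln_nlt_from_fit(linfit(-9400 * c, 100000 * c)).ln_nlt
        assert scaled == pytest.approx(base, rel=1e-12)


class TestToxicityConstant:
    def test_values(self):
        assert toxicity_constant(linfit(-0.5, 1)).d_value == pytest.approx(2)
        assert toxicity_constant(linfit(-9400, 1)).d_value == pytest.approx(1 / 9400)

    def test_zero_slope_rejected(self):
        with pytest.raises(NoToxicityTrendError):
            toxicity_constant(LinearFit(0.0, 5.0, 0.0, 3))


class TestPredict:
    fit = linfit(-5800, 36000)  # dimethoate / O. niloticus acute line

    def test_lc50_at_one_day_is_intercept(self):
        assert predict_lc50(self.fit, 1).lc50_ugL == pytest.approx(36000)

    def test_lc50_at_four_days(self):
        p = predict_lc50(self.fit, 4)
        assert p.lc50_ugL == pytest.approx(36000 - 5800 * math.log(4), rel=1e-12)
        assert p.lc50_ugL == pytest.approx(27959.49, abs=0.01)

    def test_lc50_at_nlt_is_zero_and_beyond_is_floored(self):
        nlt = math.exp(36000 / 5800)
        assert predict_lc50(self.fit, nlt).lc50_ugL == pytest.approx(0, abs=1e-6)
        p = predict_lc50(self.fit, nlt * 10)
        assert p.lc50_ugL == 0
        assert p.beyond_nlt

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValidationError):
            predict_lc50(self.fit, 0)

    def test_lt50_at_zero_conc_is_nlt(self):
        p = predict_lt50(self.fit, 0)
        assert p.lt50_days == pytest.approx(math.exp(36000 / 5800))
        assert p.fraction_of_nlt == pytest.approx(1)

    def test_lt50_at_conc_b_is_one_day(self):
        assert predict_lt50(self.fit, 36000).lt50_days == pytest.approx(1)

    @pytest.mark.parametrize("c", [1.0, 100.0, 17999.0, 35999.0])
    def test_round_trip_inverse(self, c):
        lt = predict_lt50(self.fit, c).lt50_days
        assert predict_lc50(self.fit, lt).lc50_ugL == pytest.approx(c, rel=1e-9)

    def test_monotonicity(self):
        nlt = math.exp(36000 / 5800)
        times = [nlt * q for q in (0.001, 0.01, 0.1, 0.5, 0.99)]
        preds = [predict_lc50(self.fit, t).lc50_ugL for t in times]
        assert all(p1 > p2 for p1, p2 in zip(preds, preds[1:]))
        concs = [0, 100, 1000, 10000, 30000]
        lts = [predict_lt50(self.fit, c).lt50_days for c in concs]
        assert all(l1 > l2 for l1, l2 in zip(lts, lts[1:]))


class TestTwoPoint:
    def test_round_numbers(self):
        nlt = 4 * math.exp(2)  # ln NLT − ln 4 = 2
        f = two_point_fit(100, 4, nlt)
        assert f.slope_a == pytest.approx(-50)
        assert f.intercept_b == pytest.approx(50 * (math.log(4) + 2))

    def test_reproduces_anchor_points(self):
        f = two_point_fit(123.4, 4, 900)
        assert predict_lc50(f, 4).lc50_ugL == pytest.approx(123.4, rel=1e-12)
        assert predict_lc50(f, 900).lc50_ugL == pytest.approx(0, abs=1e-9)
        assert f.method == "two_point"

    def test_recovers_acute_line_coefficients(self):
        lc50_4d = 36000 - 5800 * math.log(4)
        f = two_point_fit(lc50_4d, 4, math.exp(36000 / 5800))
        assert f.slope_a == pytest.approx(-5800, rel=1e-9)
        assert f.intercept_b == pytest.approx(36000, rel=1e-9)

    def test_time_at_or_past_nlt_rejected(self):
        with pytest.raises(InconsistentInputsError):
            two_point_fit(100, 5, 5)


class TestSpeciesAverage:
    def test_mean_of_equal_fits_is_exact(self):
        from rletox.rle import RLEFit
        fits = [RLEFit(fit=linfit(-10, 42), species="sp") for _ in range(4)]
        est = species_calculated_nlt(fits)
        assert est.ln_nlt == pytest.approx(4.2)
        assert est.method == "species_average"
        assert est.n_datasets == 4

    def test_too_few_datasets_rejected(self):
        from rletox.rle import RLEFit
        fits = [RLEFit(fit=linfit(-10, 42), species="sp") for _ in range(3)]
        with pytest.raises(InsufficientDatasetsError):
            species_calculated_nlt(fits)

    def test_mixed_species_rejected(self):
        from rletox.rle import RLEFit
        fits = [RLEFit(fit=linfit(-10, 42), species=s) for s in "abcd"]
        with pytest.raises(ValidationError):
            species_calculated_nlt(fits)

    def test_r2_filter_drops_datasets(self):
        from rletox.rle import RLEFit
        good = [RLEFit(fit=linfit(-10, 40), species="sp") for _ in range(4)]
        bad = RLEFit(fit=LinearFit(-10, 80, 0.5, 4), species="sp")
        with_all = species_calculated_nlt(good + [bad])
        filtered = species_calculated_nlt(good + [bad], r2_min=0.8)
        assert filtered.n_datasets == 4
        assert filtered.ln_nlt == pytest.approx(4.0)
        assert with_all.ln_nlt == pytest.approx((4 * 4 + 8) / 5)


class TestInternalConcentration:
    def test_scaling(self):
        assert internal_from_ambient(100, 10) == 1000
        assert internal_from_ambient(0, 5) == 0
        with pytest.raises(ValidationError):
            internal_from_ambient(10, 0)

    def test_internal_scale_fit_preserves_ln_nlt(self):
        # refitting on ILC50 = K_B·LC50 leaves the x-intercept unchanged
        s = series_on_line(-100, 300, [1, 2, 3, 4])
        k_b = 37.5
        s_int = ToxicitySeries(s.species, s.toxicant,
                               [ToxicityRecord(r.time_days, internal_from_ambient(r.lc50_ugL, k_b))
                                for r in s.records])
        assert ln_nlt_from_fit(fit_rle(s_int)).ln_nlt == pytest.approx(
            ln_nlt_from_fit(fit_rle(s)).ln_nlt, rel=1e-9)


class TestReportedVsCalculated:
    def test_identity_pairs(self):
        cmp = compare_reported_vs_calculated([(x, x) for x in (1, 2, 5, 9)])
        assert cmp.day_scale.slope == pytest.approx(1)
        assert cmp.day_scale.r_squared == pytest.approx(1)
        assert cmp.ln_scale.slope == pytest.approx(1)

    def test_hand_computed_slope(self):
        cmp = compare_reported_vs_calculated([(1, 2), (2, 3)])
        assert cmp.day_scale.slope == pytest.approx(8 / 5)

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_reported_vs_calculated([(1, 2)])

    def test_fixture_species_slope_near_one_on_ln_scale(self, table1_by_species):
        from rletox.cli import _fit_from_entry
        pairs = []
        for sp, entries in table1_by_species.items():
            if len(entries) < 4:
                continue
            est = species_calculated_nlt([_fit_from_entry(e) for e in entries])
            pairs.append((est.nlt_days, entries[0].reported_nlt_days))
        assert len(pairs) == 10
        cmp = compare_reported_vs_calculated(pairs)
        assert cmp.ln_scale.slope == pytest.approx(1.0, abs=0.1)
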