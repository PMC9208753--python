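"""Time-course normalization, rate estimators, and specificity ratios."""

import numpy as np
import pytest

import paraspec as ps
from paraspec.errors import (
    InsufficientDataError,
    InvalidInputError,
    MissingTimepointError,
    UndefinedRatioError,
)


def course(times, intensities, pair="HK:RR", normalized=False):
    return ps.TimeCourse(
        pair=pair,
        times=np.asarray(times, float),
        intensity=np.asarray(intensities, float),
        normalized=normalized,
    )


class TestNormalize:
    def test_divides_by_t0(self):
        tc = ps.normalize_timecourse(course([0, 30, 60], [100, 50, 25]))
        np.testing.assert_allclose(tc.intensity, [1.0, 0.5, 0.25])
        assert tc.normalized

    def test_idempotent(self):
        tc = ps.normalize_timecourse(course([0, 30], [200, 80]))
        again = ps.normalize_timecourse(tc)
        np.testing.assert_array_equal(tc.intensity, again.intensity)

    def test_zero_t0_intensity_rejected(self):
        with pytest.raises(InvalidInputError):
            ps.normalize_timecourse(course([0, 30], [0, 10]))


class TestInitialRate:
    def test_cognate_window_arithmetic(self):
        tc = course([0, 30, 300], [1.0, 0.4, 0.05], normalized=True)
        rate = ps.initial_rate(tc, 30)
        assert rate.value == pytest.approx((1 - 0.4) / 30)
        assert rate.method == "window"

    def test_noncognate_window_arithmetic(self):
        tc = course([0, 30, 300], [1.0, 0.97, 0.7], normalized=True)
        rate = ps.initial_rate(tc, 300)
        assert rate.value == pytest.approx((1 - 0.7) / 300)

    def test_nearest_observation_within_tolerance_used(self):
        tc = course([0, 28, 300], [1.0, 0.44, 0.1], normalized=True)
        rate = ps.initial_rate(tc, 30)
        assert rate.value == pytest.approx((1 - 0.44) / 28)

    def test_noise_driven_rise_reported_with_warning(self):
        tc = course([0, 30], [1.0, 1.05], normalized=True)
        rate = ps.initial_rate(tc, 30)
        assert rate.value < 0
        assert rate.warning is not None

    def test_missing_timepoint_rejected(self):
        tc = course([0, 120], [1.0, 0.5], normalized=True)
        with pytest.raises(MissingTimepointError):
            ps.initial_rate(tc, 30)

    def test_first_order_consistency_bound(self):
        # for exponential decay with k*w <= 0.1 the window estimate is
        # within (1 - e^-x)/x >= 1 - x/2, i.e. within ~5-6% of k
        k, w = 0.1 / 30, 30.0
        times = np.array([0.0, w])
        tc = course(times, np.exp(-k * times), normalized=True)
        est = ps.initial_rate(tc, w).value
        assert est <= k
        assert est >= k * (1 - k * w / 2)
        assert abs(est - k) / k < 0.06


class TestFitDecayRate:
    def test_exact_exponential_recovered(self):
        times = np.array([0.0, 30.0, 60.0, 120.0])
        tc = course(times, np.exp(-0.01 * times), normalized=True)
        rate = ps.fit_decay_rate(tc)
        assert rate.value == pytest.approx(0.01, abs=1e-10)
        assert rate.method == "loglinear"

    def test_floor_excludes_depleted_points(self):
        times = np.array([0.0, 30.0, 600.0])
        y = np.exp(-0.01 * times)  # last point ~0.0025 < floor
        rate = ps.fit_decay_rate(course(times, y, normalized=True))
        assert rate.n_points == 2
        assert rate.value == pytest.approx(0.01, abs=1e-10)

    def test_single_usable_point_rejected(self):
        tc = course([0, 600], [1.0, 0.001], normalized=True)
        with pytest.raises(InsufficientDataError):
            ps.fit_decay_rate(tc)

    @pytest.mark.parametrize("kt", [1e-4, 1e-3, 1e-2])
    def test_recovers_pseudo_first_order_rate_from_simulation(self, kt):
        # noiseless mass-action course, RR in 4x excess: HK~P decay rate
        # should approach kt * [RR]0 (residual bias from RR depletion)
        k_eff = kt * 4.0
        half_life = np.log(2) / k_eff
        times = np.unique(np.concatenate([[0.0], np.linspace(
            half_life / 8, half_life, 8
        )]))
        params = ps.KineticParameters(
            transfer_rate_constant=kt,
            phosphatase_rate_constant=0.0,
            noise_sd=0.0,
        )
        tc = ps.simulate_phosphotransfer(params, times)
        rate = ps.fit_decay_rate(tc)
        assert rate.value == pytest.approx(k_eff, rel=0.10)


class TestSpecificityRatio:
    def test_fold_and_direction(self):
        a = ps.RateEstimate(value=0.02, method="window", pair="HK1:RR1")
        b = ps.RateEstimate(value=0.001, method="window", pair="HK1:RR2")
        ratio = ps.specificity_ratio(a, b)
        assert ratio.fold == pytest.approx(20.0)
        assert ratio.direction == "HK1:RR1"

    def test_equal_rates_mean_no_preference(self):
        a = ps.RateEstimate(value=0.01, method="window", pair="x")
        b = ps.RateEstimate(value=0.01, method="window", pair="y")
        ratio = ps.specificity_ratio(a, b)
        assert ratio.fold == 1.0
        assert ratio.direction == "none"

    def test_zero_rate_rejected(self):
        a = ps.RateEstimate(value=0.01, method="window")
        b = ps.RateEstimate(value=0.0, method="window")
        with pytest.raises(UndefinedRatioError):
            ps.specificity_ratio(a, b)

    def test_antisymmetric_in_argument_order(self):
        a = ps.RateEstimate(value=0.004, method="window", pair="p")
        b = ps.RateEstimate(value=0.03, method="window", pair="q")
        fwd = ps.specificity_ratio(a, b)
        rev = ps.specificity_ratio(b, a)
        assert fwd.fold == rev.fold
        assert fwd.direction == rev.direction == "q"


def quartet_courses(rates, noise_sd=0.0, seed=0):
    """Simulate one time course per HK x RR reaction of a quartet."""
    courses = []
    for i, (pair, kt) in enumerate(sorted(rates.items())):
        k_eff = kt * 4.0
        half_life = np.log(2) / k_eff
        times = np.unique(np.concatenate(
            [[0.0, 30.0, 300.0], np.linspace(half_life / 8, half_life, 8)]
        ))
        params = ps.KineticParameters(
            transfer_rate_constant=kt,
            phosphatase_rate_constant=0.0,
            noise_sd=noise_sd,
            seed=seed * 100 + i,
        )
        courses.append(ps.simulate_phosphotransfer(params, times, pair=pair))
    return courses


QUARTET_DESIGN = ps.MatrixDesign(
    cognate_pairs=frozenset({("HK1", "RR1"), ("HK2", "RR2")})
)


class TestSpecificityMatrix:
    def test_equal_planted_rates_give_unit_folds(self):
        rates = {p: 1e-3 for p in
                 ("HK1:RR1", "HK1:RR2", "HK2:RR1", "HK2:RR2")}
        table = ps.specificity_matrix(
            quartet_courses(rates), QUARTET_DESIGN, method="loglinear"
        )
        np.testing.assert_allclose(table["fold"], 1.0, rtol=1e-6)

    def test_planted_directions_recovered(self):
        rates = {
            "HK1:RR1": 9e-4,
            "HK1:RR2": 9e-4,
            "HK2:RR1": 2e-4,
            "HK2:RR2": 5.6e-3,
        }
        table = ps.specificity_matrix(
            quartet_courses(rates), QUARTET_DESIGN, method="loglinear"
        ).set_index("protein")
        assert table.loc["HK2", "preferred"] == "RR2"
        assert table.loc["RR1", "preferred"] == "HK1"
        assert table.loc["RR2", "preferred"] == "HK2"
        assert table.loc["HK2", "fold"] == pytest.approx(28.0, rel=0.15)

    def test_missing_course_names_the_pair(self):
        rates = {"HK1:RR1": 1e-3, "HK1:RR2": 1e-3, "HK2:RR1": 1e-3}
        courses = quartet_courses(rates)
        design = ps.MatrixDesign(
            cognate_pairs=frozenset({("HK1", "RR1"), ("HK2", "RR2")}),
            hk_compare={"HK1": ("RR1", "RR2"), "HK2": ("RR1", "RR2")},
            rr_compare={"RR1": ("HK1", "HK2"), "RR2": ("HK1", "HK2")},
        )
        with pytest.raises(InvalidInputError, match="HK2:RR2"):
            ps.specificity_matrix(courses, design)
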