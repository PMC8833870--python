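"""Exponential fitting and analytic integration of time-activity curves."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from dosepipe import (
    ExponentialModel,
    PhysicalConstants,
    TimeActivityCurve,
    cumulated_activity,
    fit_exponential,
    integrate_model,
    normalized_cumulated_activity,
)
from dosepipe.kinetics import SampleMode
from dosepipe.synthetic_data import IMAGING_SCHEDULE_H

IMAGING = np.array(IMAGING_SCHEDULE_H)


def make_curve(times, values, region="skeleton", injected=5780.0):
    return TimeActivityCurve.from_arrays(region, times, values, injected)


class TestFitExponential:
    def test_noiseless_single_exponential_recovered_exactly(self):
        y = 100.0 * np.exp(-0.1 * IMAGING)
        model = fit_exponential(make_curve(IMAGING, y), max_terms=2)
        assert model.n_terms == 1
        (amp, rate), = model.terms
        assert amp == pytest.approx(100.0, rel=1e-6)
        assert rate == pytest.approx(0.1, rel=1e-6)

    def test_noiseless_biexponential_recovered(self):
        # uptake-washout shape: one negative amplitude on the fast rate
        y = 80.0 * (np.exp(-0.01 * IMAGING) - np.exp(-0.5 * IMAGING))
        model = fit_exponential(make_curve(IMAGING, y), max_terms=2)
        assert model.n_terms == 2
        (a_slow, r_slow), (a_fast, r_fast) = model.terms
        assert a_slow == pytest.approx(80.0, rel=0.01)
        assert r_slow == pytest.approx(0.01, rel=0.01)
        assert a_fast == pytest.approx(-80.0, rel=0.01)
        assert r_fast == pytest.approx(0.5, rel=0.01)

    def test_all_zero_curve_returns_flagged_zero_model(self):
        model = fit_exponential(make_curve(IMAGING, np.zeros(5)))
        assert model.terms == ()
        assert model.zero_curve
        assert integrate_model(model) == 0.0

    def test_fewer_than_two_samples_rejected(self):
        curve = make_curve([1.5], [10.0])
        with pytest.raises(ValueError, match="at least 2"):
            fit_exponential(curve)

    def test_measured_curve_terminal_rate_at_least_physical_decay(self):
        # biological clearance cannot be negative: data decaying slower
        # than Lu-177 physical decay pins the rate at the bound
        constants = PhysicalConstants()
        y = 50.0 * np.exp(-0.5 * constants.lambda_phys * IMAGING)
        model = fit_exponential(make_curve(IMAGING, y), constants=constants)
        assert min(r for _, r in model.terms) >= constants.lambda_phys * (1 - 1e-3)

    def test_decay_corrected_curve_may_fit_slower_rates(self):
        constants = PhysicalConstants()
        y = 50.0 * np.exp(-0.5 * constants.lambda_phys * IMAGING)
        curve = TimeActivityCurve.from_arrays(
            "skeleton", IMAGING, y, 5780.0, decay_corrected=True
        )
        model = fit_exponential(curve, constants=constants)
        assert min(r for _, r in model.terms) < constants.lambda_phys

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(7)
        y = 90.0 * (np.exp(-0.008 * IMAGING) - np.exp(-1.2 * IMAGING))
        y *= rng.lognormal(sigma=0.05, size=5)
        curve = make_curve(IMAGING, y)
        m1 = fit_exponential(curve)
        m2 = fit_exponential(curve)
        assert m1.terms == m2.terms
        assert m1.sse == m2.sse

    def test_scaling_data_scales_cumulated_activity_exactly(self):
        rng = np.random.default_rng(3)
        y = 70.0 * (np.exp(-0.01 * IMAGING) - np.exp(-0.9 * IMAGING))
        y *= rng.lognormal(sigma=0.03, size=5)
        base = cumulated_activity(make_curve(IMAGING, y), policy="fit")
        for c in (0.25, 3.0, 17.5):
            scaled = cumulated_activity(make_curve(IMAGING, c * y), policy="fit")
            assert scaled == pytest.approx(c * base, rel=1e-6)


class TestIntegrateModel:
    def test_single_term_closed_form(self):
        model = ExponentialModel(terms=((100.0, 0.1),))
        assert integrate_model(model) == pytest.approx(1000.0)

    def test_linearity_of_integral(self):
        model = ExponentialModel(terms=((-80.0, 0.5), (80.0, 0.01)))
        assert integrate_model(model) == pytest.approx(80 / 0.01 - 80 / 0.5)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            ExponentialModel(terms=((10.0, -0.1),))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        amp_slow=st.floats(1.0, 1e4),
        rate_slow=st.floats(4.4e-3, 0.2),
        rate_ratio=st.floats(1.5, 200.0),
        uptake=st.booleans(),
    )
    def test_closed_form_matches_quadrature_oracle(
        self, amp_slow, rate_slow, rate_ratio, uptake
    ):
        """Closed-form integral vs adaptive quadrature within 0.1%."""
        rate_fast = rate_slow * rate_ratio
        amp_fast = -amp_slow if uptake else 0.5 * amp_slow
        model = ExponentialModel(terms=((amp_slow, rate_slow), (amp_fast, rate_fast)))
        closed = integrate_model(model)
        t_max = 20.0 / rate_slow
        numeric, _ = quad(lambda t: model(t), 0, t_max, limit=200)
        tail = sum(a / r * math.exp(-r * t_max) for a, r in model.terms)
        assert closed == pytest.approx(numeric + tail, rel=1e-3)


class TestCumulatedActivity:
    def test_fit_policy_matches_closed_form_on_exact_data(self):
        y = 100.0 * np.exp(-0.1 * IMAGING)
        value = cumulated_activity(make_curve(IMAGING, y), policy="fit")
        assert value == pytest.approx(1000.0, rel=1e-6)

    def test_hybrid_policy_trapezoid_plus_physical_tail(self):
        constants = PhysicalConstants()
        curve = make_curve([1.5, 170.0], [10.0, 10.0])
        expected = (
            0.5 * 1.5 * 10.0  # rise from (0, 0)
            + 0.5 * (10.0 + 10.0) * (170.0 - 1.5)  # trapezoid
            + 10.0 / constants.lambda_phys  # physical-decay tail
        )
        value = cumulated_activity(curve, policy="hybrid", constants=constants)
        assert value == pytest.approx(expected, rel=1e-12)
        assert value == pytest.approx(3994.0, rel=1e-3)

    def test_zero_curve_integrates_to_zero(self):
        assert cumulated_activity(make_curve(IMAGING, np.zeros(5))) == 0.0

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            cumulated_activity(make_curve(IMAGING, np.ones(5)), policy="spline")


class TestNormalizedCumulatedActivity:
    @pytest.mark.parametrize(
        ("cumulated", "injected", "expected"),
        [(5780.0, 5780.0, 1.0), (0.0, 5780.0, 0.0), (7840.0, 5780.0, 7840.0 / 5780.0)],
    )
    def test_residence_time_is_ratio(self, cumulated, injected, expected):
        assert normalized_cumulated_activity(cumulated, injected) == pytest.approx(
            expected
        )

    def test_nonpositive_injected_rejected(self):
        with pytest.raises(ValueError):
            normalized_cumulated_activity(100.0, 0.0)


class TestTimeActivityCurve:
    def test_times_must_strictly_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_curve([1.5, 1.5, 6.0], [1.0, 2.0, 3.0])

    def test_mixed_modes_rejected(self):
        from dosepipe import ActivitySample

        with pytest.raises(ValueError, match="mode"):
            TimeActivityCurve(
                "blood",
                (
                    ActivitySample(1.0, 1.0, SampleMode.ACTIVITY),
                    ActivitySample(2.0, 1.0, SampleMode.CONCENTRATION),
                ),
                5780.0,
            )

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            make_curve([1.0, 2.0], [1.0, -0.5])
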