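"""Source-organ construction: marrow formula, leg scaling, skeleton split,
masses, remainder subtraction."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosepipe import (
    PhantomConstants,
    TimeActivityCurve,
    build_source_set,
    cumulated_activity,
    kidney_mass,
    red_marrow_activity,
    remainder_curve,
    scale_for_legs,
    split_skeleton,
    tumor_activity_and_mass,
)
from dosepipe.source_mapping import PatientBundle

CONST = PhantomConstants()


class TestRedMarrowActivity:
    @pytest.mark.parametrize(
        ("conc", "rmblr", "expected"),
        [
            (0.07, 1.0, 100.0),  # 0.07 * 1500/1.05 = 100 exactly
            (0.0, 1.0, 0.0),
            (0.001, 0.36, 0.001 * 0.36 * 1500.0 / 1.05),
        ],
    )
    def test_blood_to_marrow_formula(self, conc, rmblr, expected):
        constants = PhantomConstants(rmblr=rmblr)
        assert red_marrow_activity(conc, constants) == pytest.approx(expected)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            red_marrow_activity(-0.1, CONST)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(conc=st.floats(0, 10), rmblr=st.floats(0.01, 2), c=st.floats(0.1, 10))
    def test_linear_in_concentration_and_rmblr(self, conc, rmblr, c):
        constants = PhantomConstants(rmblr=rmblr)
        base = red_marrow_activity(conc, constants)
        assert red_marrow_activity(c * conc, constants) == pytest.approx(
            c * base, rel=1e-12, abs=1e-12
        )
        scaled_ratio = PhantomConstants(rmblr=rmblr * c)
        assert red_marrow_activity(conc, scaled_ratio) == pytest.approx(
            c * base, rel=1e-12, abs=1e-12
        )


class TestLegScaling:
    @pytest.mark.parametrize(
        ("value", "expected"), [(66.4, 100.0), (0.0, 0.0), (1000.0, 1000.0 / 0.664)]
    )
    def test_restores_legs_share(self, value, expected):
        assert scale_for_legs(value, CONST) == pytest.approx(expected)

    def test_factor_is_1506(self):
        assert CONST.leg_scale_factor == pytest.approx(1.506, abs=5e-4)

    def test_roundtrip_with_leg_removal_is_identity(self):
        for v in (0.1, 17.0, 5780.0):
            assert scale_for_legs(v * 0.664, CONST) == pytest.approx(v, rel=1e-12)


class TestSkeletonSplit:
    @pytest.mark.parametrize(
        ("total", "expected"),
        [(100.0, (80.0, 20.0)), (0.0, (0.0, 0.0)), (57.3, (45.84, 11.46))],
    )
    def test_cortical_trabecular_split(self, total, expected):
        cortical, trabecular = split_skeleton(total, CONST)
        assert (cortical, trabecular) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(total=st.floats(0, 1e6))
    def test_split_conserves_total_exactly(self, total):
        cortical, trabecular = split_skeleton(total, CONST)
        assert cortical + trabecular == total


class TestMasses:
    def test_tumor_activity_and_mass(self):
        assert tumor_activity_and_mass(2.0, 1.0, CONST) == pytest.approx((2.0, 1.92))
        assert tumor_activity_and_mass(0.5, 10.4, CONST) == pytest.approx(
            (5.2, 19.968)
        )
        assert tumor_activity_and_mass(0.0, 3.0, CONST)[0] == 0.0

    def test_kidney_mass_from_ct_volume(self):
        assert kidney_mass(100.0, CONST) == pytest.approx(106.0)
        assert kidney_mass(283.5, CONST) == pytest.approx(300.51)
        with pytest.raises(ValueError):
            kidney_mass(0.0, CONST)


def _flat_curve(region, value, times=(1.5, 6.0, 24.0, 48.0, 170.0), injected=5780.0):
    return TimeActivityCurve.from_arrays(
        region, times, [value] * len(times), injected
    )


class TestRemainderCurve:
    def test_pointwise_subtraction(self):
        total = _flat_curve("total_body", 100.0)
        remainder, clamps = remainder_curve(
            total, [_flat_curve("a", 60.0), _flat_curve("b", 30.0)]
        )
        assert np.allclose(remainder.values, 10.0)
        assert clamps == ()

    def test_negative_remainder_clamped_and_logged(self):
        total = _flat_curve("total_body", 50.0)
        remainder, clamps = remainder_curve(total, [_flat_curve("a", 60.0)])
        assert np.all(remainder.values == 0.0)
        assert len(clamps) == 5


class TestBuildSourceSet:
    def test_missing_blood_curve_is_named_in_error(self, noiseless_patient):
        bundle, _ = noiseless_patient
        curves = {k: v for k, v in bundle.curves.items() if k != "blood"}
        broken = PatientBundle(
            patient_id="x",
            injected_activity_mbq=bundle.injected_activity_mbq,
            kidney_volume_ml=bundle.kidney_volume_ml,
            curves=curves,
            lesions=bundle.lesions,
        )
        with pytest.raises(KeyError, match="blood"):
            build_source_set(broken)

    def test_tumor_free_bundle_identical_with_and_without_reinclusion(
        self, noiseless_patient
    ):
        bundle, _ = noiseless_patient
        no_tumors = PatientBundle(
            patient_id="x",
            injected_activity_mbq=bundle.injected_activity_mbq,
            kidney_volume_ml=bundle.kidney_volume_ml,
            curves=bundle.curves,
            lesions=(),
        )
        off = build_source_set(no_tumors, tumors_in_bone=False)
        on = build_source_set(no_tumors, tumors_in_bone=True)
        for region in off.curves:
            assert np.array_equal(
                off.curves[region].values, on.curves[region].values
            )

    def test_tumors_in_bone_adds_lesion_activity_to_skeleton_curve(
        self, noiseless_patient
    ):
        bundle, _ = noiseless_patient
        off = build_source_set(bundle, tumors_in_bone=False)
        on = build_source_set(bundle, tumors_in_bone=True)
        grid = off.curves["cortical_surface"].times
        lesion_total = np.zeros_like(grid)
        for lesion in bundle.lesions:
            lesion_total += lesion.conc_curve.values * lesion.volume_ml
        skel_off = (
            off.curves["cortical_surface"].values
            + off.curves["trabecular_surface"].values
        )
        skel_on = (
            on.curves["cortical_surface"].values
            + on.curves["trabecular_surface"].values
        )
        assert np.allclose(skel_on - skel_off, lesion_total, rtol=1e-12)
        # remainder is unaffected: lesions are modeled regions either way
        assert np.allclose(
            off.curves["remainder"].values, on.curves["remainder"].values
        )

    def test_source_set_recovers_generator_ground_truth(self, noiseless_patient):
        """Round trip: each fitted source region matches the generating
        model's closed-form cumulated activity (noise-free, <=1%; the
        derived remainder only to its schedule-identifiability limit)."""
        bundle, truth = noiseless_patient
        sources = build_source_set(bundle)
        for region in (
            "cortical_surface",
            "trabecular_surface",
            "red_marrow",
            "kidneys",
            "bladder_content",
        ):
            est = cumulated_activity(sources.curves[region], policy="fit")
            assert est == pytest.approx(truth.cumulated_mbq_h[region], rel=0.01), region
        est = cumulated_activity(sources.curves["remainder"], policy="fit")
        assert est == pytest.approx(truth.cumulated_mbq_h["remainder"], rel=0.05)

    def test_marrow_dose_not_lower_with_tumors_in_bone(self, noiseless_patient):
        from dosepipe import RunConfig, analyze_patient

        bundle, _ = noiseless_patient
        off = analyze_patient(bundle, RunConfig(tumors_in_bone=False))
        on = analyze_patient(bundle, RunConfig(tumors_in_bone=True))
        assert (
            on.dose_result.doses_gy_per_gbq["red_marrow"]
            >= off.dose_result.doses_gy_per_gbq["red_marrow"]
        )
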