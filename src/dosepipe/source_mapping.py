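"""Source-organ construction from raw patient measurements.

Maps the measured curves (skeleton, kidneys, bladder content, total body,
blood, lesions) onto the MIRD source-organ model:

* blood concentration -> red-marrow activity via the standard
  A_rm = AC_blood * RMBLR * 1500 g / (1.05 g/mL) conversion;
* skeleton and total body (segmented without the legs) scaled by
  1/(1-0.336) = 1.506 to restore the legs' bone share;
* skeletal cumulated activity split 80%/20% between the cortical and
  trabecular bone mineral surfaces (done pointwise on the curve, which is
  equivalent because the integral is linear);
* remainder of body = total body minus all explicit sources, clamped at 0;
* tumor activity = mean lesion concentration x volume, with lesion mass at
  cortical-bone density 1.92 g/mL and kidney mass at 1.06 g/mL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import PhantomConstants
from .kinetics import SampleMode, TimeActivityCurve

logger = logging.getLogger(__name__)

__all__ = [
    "PatientBundle",
    "Lesion",
    "SourceOrganSet",
    "red_marrow_activity",
    "scale_for_legs",
    "split_skeleton",
    "tumor_activity_and_mass",
    "kidney_mass",
    "remainder_curve",
    "build_source_set",
]

#: Curves a patient bundle must provide to build the source-organ set.
REQUIRED_REGIONS = ("skeleton", "kidneys", "bladder_content", "total_body", "blood")


@dataclass(frozen=True)
class Lesion:
    """One tumor lesion: id, CT/PET volume (mL) and its concentration curve."""

    lesion_id: str
    volume_ml: float
    conc_curve: TimeActivityCurve  # MBq/mL samples

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("lesion volume must be > 0 mL")
        if self.conc_curve.mode is not SampleMode.CONCENTRATION:
            raise ValueError("lesion curve must be in concentration mode")


@dataclass(frozen=True)
class PatientBundle:
    """All measured inputs for one patient."""

    patient_id: str
    injected_activity_mbq: float
    kidney_volume_ml: float
    curves: dict[str, TimeActivityCurve]
    lesions: tuple[Lesion, ...] = ()

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be > 0")
        if self.kidney_volume_ml <= 0:
            raise ValueError("kidney volume must be > 0")
        object.__setattr__(self, "lesions", tuple(self.lesions))

    def require(self, region: str) -> TimeActivityCurve:
        try:
            return self.curves[region]
        except KeyError:
            raise KeyError(f"patient bundle is missing the {region!r} curve") from None


@dataclass(frozen=True)
class SourceOrganSet:
    """The six MIRD source regions as activity curves, with provenance notes."""

    curves: dict[str, TimeActivityCurve]
    provenance: dict[str, str] = field(default_factory=dict)
    clamp_events: tuple[str, ...] = ()

    SOURCE_REGIONS = (
        "cortical_surface",
        "trabecular_surface",
        "red_marrow",
        "kidneys",
        "bladder_content",
        "remainder",
    )

    def __post_init__(self) -> None:
        missing = [r for r in self.SOURCE_REGIONS if r not in self.curves]
        if missing:
            raise ValueError(f"source set missing regions: {missing}")


def red_marrow_activity(blood_conc_mbq_per_ml: float, constants: PhantomConstants) -> float:
    """Red-marrow activity (MBq) from a blood concentration (MBq/mL).

    A_rm = AC_blood * RMBLR * m_rm / rho_rm with the standard marrow mass
    (1500 g) and density (1.05 g/mL); linear in both the concentration and
    the red-marrow-to-blood ratio.
    """
    if blood_conc_mbq_per_ml < 0:
        raise ValueError("blood concentration must be >= 0")
    marrow_volume_ml = constants.red_marrow_mass_g / constants.red_marrow_density_g_per_ml
    return blood_conc_mbq_per_ml * constants.rmblr * marrow_volume_ml


def scale_for_legs(value: float, constants: PhantomConstants) -> float:
    """Restore the legs' share to a skeleton/total-body measurement.

    The segmentation excludes the legs (33.6% of bone mass), so measured
    values are divided by 0.664, i.e. multiplied by 1.506.
    """
    if value < 0:
        raise ValueError("value must be >= 0")
    return value * constants.leg_scale_factor


def split_skeleton(
    skeleton_cumulated: float, constants: PhantomConstants
) -> tuple[float, float]:
    """Split skeletal cumulated activity into (cortical, trabecular) surfaces.

    Bisphosphonates bind to the bone mineral surface; 80% is assigned to
    cortical and 20% to trabecular surface. The two parts sum to the input
    exactly.
    """
    if skeleton_cumulated < 0:
        raise ValueError("cumulated activity must be >= 0")
    cortical = constants.cortical_fraction * skeleton_cumulated
    return cortical, skeleton_cumulated - cortical


def tumor_activity_and_mass(
    mean_conc_mbq_per_ml: float, volume_ml: float, constants: PhantomConstants
) -> tuple[float, float]:
    """Lesion activity (MBq) and mass (g) from concentration and volume."""
    if volume_ml <= 0:
        raise ValueError("lesion volume must be > 0")
    if mean_conc_mbq_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    return (
        mean_conc_mbq_per_ml * volume_ml,
        volume_ml * constants.tumor_density_g_per_ml,
    )


def kidney_mass(volume_ml: float, constants: PhantomConstants) -> float:
    """Total kidney mass (g) from the CT volume at density 1.06 g/mL."""
    if volume_ml <= 0:
        raise ValueError("kidney volume must be > 0")
    return volume_ml * constants.kidney_density_g_per_ml


def _interp_onto(curve: TimeActivityCurve, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of a curve onto a time grid (no extrapolation
    beyond the end values; before the first sample, a linear rise from 0)."""
    t, v = curve.times, curve.values
    out = np.interp(grid, t, v)
    early = grid < t[0]
    if np.any(early) and t[0] > 0:
        out[early] = v[0] * grid[early] / t[0]
    return out


def remainder_curve(
    total_body: TimeActivityCurve,
    sources: list[TimeActivityCurve],
) -> tuple[TimeActivityCurve, tuple[str, ...]]:
    """Remainder-of-body curve: total body minus all explicit sources.

    All source curves are linearly interpolated onto the total-body
    (imaging) time grid; negative differences are clamped to zero and each
    clamp is logged and returned. ``total_body`` must already be leg-scaled.
    """
    grid = total_body.times
    total = total_body.values.copy()
    for src in sources:
        total -= _interp_onto(src, grid)
    clamps = []
    for i, (t, v) in enumerate(zip(grid, total)):
        if v < 0:
            clamps.append(f"remainder clamped to 0 at t={t:g} h (was {v:.4g})")
            total[i] = 0.0
    for msg in clamps:
        logger.warning(msg)
    curve = TimeActivityCurve.from_arrays(
        "remainder", grid, total, total_body.injected_activity_mbq
    )
    return curve, tuple(clamps)


def build_source_set(
    bundle: PatientBundle,
    constants: PhantomConstants | None = None,
    tumors_in_bone: bool = False,
) -> SourceOrganSet:
    """Assemble the six source-organ curves from a patient bundle.

    Applies leg scaling to skeleton and total body, the blood->marrow
    conversion, the 80/20 cortical/trabecular split (pointwise), and the
    remainder subtraction. Lesion activities (concentration x volume) are
    always subtracted from the remainder — they are explicitly modeled
    regions, not unassigned tissue. With ``tumors_in_bone`` they are in
    addition added back into the skeleton before splitting: the
    segmentation excludes tumor voxels from the skeleton VOI, but bone
    metastases do sit in bone and cross-irradiate the marrow.
    """
    constants = constants or PhantomConstants()
    for region in REQUIRED_REGIONS:
        bundle.require(region)

    prov: dict[str, str] = {}
    skeleton = bundle.curves["skeleton"].scaled(
        constants.leg_scale_factor, region="skeleton"
    )
    total_body = bundle.curves["total_body"].scaled(
        constants.leg_scale_factor, region="total_body"
    )
    prov["skeleton"] = f"measured skeleton x {constants.leg_scale_factor:.4f} (leg scaling)"
    prov["total_body"] = f"measured total body x {constants.leg_scale_factor:.4f} (leg scaling)"

    tumor_curves = [
        lesion.conc_curve.scaled(lesion.volume_ml, region=lesion.lesion_id)
        for lesion in bundle.lesions
    ]
    if tumors_in_bone and tumor_curves:
        grid = skeleton.times
        extra = np.zeros_like(grid)
        for activity in tumor_curves:
            extra += _interp_onto(activity, grid)
        skeleton = TimeActivityCurve.from_arrays(
            "skeleton", grid, skeleton.values + extra, skeleton.injected_activity_mbq
        )
        prov["skeleton"] += "; tumor activity re-included"

    blood = bundle.curves["blood"]
    marrow_values = [
        red_marrow_activity(v, constants) for v in blood.values
    ]
    red_marrow = TimeActivityCurve.from_arrays(
        "red_marrow", blood.times, marrow_values, bundle.injected_activity_mbq
    )
    prov["red_marrow"] = (
        f"blood concentration x RMBLR({constants.rmblr:g}) x "
        f"{constants.red_marrow_mass_g:g} g / {constants.red_marrow_density_g_per_ml:g} g/mL"
    )

    kidneys = bundle.curves["kidneys"]
    bladder = bundle.curves["bladder_content"]
    prov["kidneys"] = "measured kidney activity"
    prov["bladder_content"] = "measured urinary bladder content activity"

    subtract = [skeleton, kidneys, bladder, red_marrow]
    if not tumors_in_bone:
        subtract.extend(tumor_curves)  # already inside skeleton otherwise
    remainder, clamps = remainder_curve(total_body, subtract)
    prov["remainder"] = (
        "total body minus skeleton, kidneys, bladder, red marrow, lesions"
    )

    cortical = skeleton.scaled(constants.cortical_fraction, region="cortical_surface")
    trabecular = skeleton.scaled(
        constants.trabecular_fraction, region="trabecular_surface"
    )
    prov["cortical_surface"] = f"skeleton x {constants.cortical_fraction:g}"
    prov["trabecular_surface"] = f"skeleton x {constants.trabecular_fraction:g}"

    return SourceOrganSet(
        curves={
            "cortical_surface": cortical,
            "trabecular_surface": trabecular,
            "red_marrow": red_marrow,
            "kidneys": kidneys,
            "bladder_content": bladder,
            "remainder": remainder,
        },
        provenance=prov,
        clamp_events=clamps,
    )
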