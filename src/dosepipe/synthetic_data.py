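"""Synthetic patient generator with closed-form ground truth.

Emulates the kinetics a bone-seeking Lu-177 bisphosphonate shows in
patients: fast skeletal uptake with long retention, rapid biexponential
blood clearance, low renal uptake, and high lesion retention. Each
compartment follows an uptake-washout model in *measured* (decayed)
activity,

    A(t) = A_inj * f * (1 - e^{-k_u t}) * e^{-(lambda_phys + k_b) t},

whose integral on [0, inf) is available in closed form,

    integral = A_inj * f * ( 1/mu - 1/(mu + k_u) ),   mu = lambda_phys + k_b,

so every pipeline stage can be checked against exact ground truth. Blood
concentration is a biexponential (per-mL fractions of the injected
activity). Default parameters are calibrated so that, with a 5500 g
skeleton, skeletal uptake peaks near 9.6e-3 %IA/g around 2 h, the
blood-derived marrow concentration is ~1.4e-3 %IA/g at 1.5 h, and lesion
concentration ~2.1e-2 %IA/g at 6 h — the magnitudes typical of this
tracer. Sampling uses the nominal study schedules: SPECT at 1.5, 6, 24,
48, 170 h; blood at 5, 15, 30 min and 1.5, 6, 24, 48, 170 h.

Measured skeleton and total-body curves are emitted with the legs outside
the field of view (x 0.664), matching how such data are segmented; the
source-mapping stage undoes this with the 1.506 leg factor.

Noise is multiplicative lognormal, mean-corrected (multiplier
exp(sigma*z - sigma^2/2) has expectation 1), applied per sample from a
seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import PhantomConstants, PhysicalConstants
from .kinetics import SampleMode, TimeActivityCurve
from .source_mapping import Lesion, PatientBundle

__all__ = [
    "LesionParams",
    "PatientKineticsParams",
    "GroundTruth",
    "generate_patient",
    "generate_cohort",
    "IMAGING_SCHEDULE_H",
    "BLOOD_SCHEDULE_H",
]

#: Nominal SPECT imaging times (h post-injection).
IMAGING_SCHEDULE_H: tuple[float, ...] = (1.5, 6.0, 24.0, 48.0, 170.0)
#: Nominal venous sampling times (5, 15, 30 min; 1.5, 6, 24, 48, 170 h).
BLOOD_SCHEDULE_H: tuple[float, ...] = (
    5.0 / 60.0, 15.0 / 60.0, 30.0 / 60.0, 1.5, 6.0, 24.0, 48.0, 170.0,
)


@dataclass(frozen=True)
class LesionParams:
    """One synthetic lesion: volume, concentration scale and kinetics.

    ``conc_scale_per_ml`` is the peak-free amplitude of the concentration
    model as a fraction of injected activity per mL.
    """

    volume_ml: float = 10.0
    conc_scale_per_ml: float = 4.164e-4
    uptake_rate_per_h: float = 0.88
    washout_rate_per_h: float = 1.75e-4

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("lesion volume must be > 0")
        if self.conc_scale_per_ml < 0:
            raise ValueError("conc scale must be >= 0")
        if self.uptake_rate_per_h <= 0 or self.washout_rate_per_h < 0:
            raise ValueError("lesion rates must be positive (washout >= 0)")


@dataclass(frozen=True)
class PatientKineticsParams:
    """Generating model for one synthetic patient.

    Fractions are of injected activity; rates are biological (1/h) — the
    physical decay constant is added on top when curves are evaluated.
    """

    patient_id: str = "synthetic-1"
    injected_activity_mbq: float = 5780.0
    # blood biexponential, per-mL fractions of injected activity
    blood_c1_frac_per_ml: float = 8.19e-5
    blood_k1_per_h: float = 2.0
    blood_c2_frac_per_ml: float = 1.25e-5
    blood_k2_per_h: float = 0.10
    blood_volume_ml: float = 5000.0
    # skeleton uptake-washout
    skeleton_fraction: float = 0.535
    skeleton_uptake_per_h: float = 3.12
    skeleton_washout_per_h: float = 1.66e-3
    # kidneys (low uptake for most patients)
    kidney_fraction: float = 0.015
    kidney_uptake_per_h: float = 4.0
    kidney_washout_per_h: float = 0.05
    kidney_volume_ml: float = 283.0
    # urinary bladder content
    bladder_fraction: float = 0.04
    bladder_uptake_per_h: float = 1.5
    bladder_washout_per_h: float = 0.15
    # soft-tissue remainder compartment
    remainder_fraction: float = 0.15
    remainder_uptake_per_h: float = 5.0
    remainder_washout_per_h: float = 0.03
    lesions: tuple[LesionParams, ...] = (
        LesionParams(volume_ml=8.0, conc_scale_per_ml=4.2e-4),
        LesionParams(volume_ml=15.0, conc_scale_per_ml=2.9e-4,
                     uptake_rate_per_h=1.4, washout_rate_per_h=6.0e-4),
        LesionParams(volume_ml=4.0, conc_scale_per_ml=5.4e-4,
                     uptake_rate_per_h=0.55, washout_rate_per_h=1.0e-4),
    )
    noise_sigma: float = 0.0
    seed: int = 0
    imaging_schedule_h: tuple[float, ...] = IMAGING_SCHEDULE_H
    blood_schedule_h: tuple[float, ...] = BLOOD_SCHEDULE_H

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be > 0")
        fracs = {
            "skeleton_fraction": self.skeleton_fraction,
            "kidney_fraction": self.kidney_fraction,
            "bladder_fraction": self.bladder_fraction,
            "remainder_fraction": self.remainder_fraction,
        }
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if sum(fracs.values()) > 1.0:
            raise ValueError("organ fractions must sum to <= 1")
        for name in (
            "blood_k1_per_h", "blood_k2_per_h", "skeleton_uptake_per_h",
            "kidney_uptake_per_h", "bladder_uptake_per_h",
            "remainder_uptake_per_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact cumulated activities (MBq*h) implied by the generating model.

    Keys cover both raw regions (skeleton, total_body, blood per-mL
    concentration integral under ``blood_conc_mbq_h_per_ml``) and the
    derived source regions the pipeline produces (cortical/trabecular
    surface, red_marrow, remainder, tumor:<i>), so recovery can be checked
    at any stage. All skeleton/total-body truths refer to the leg-scaled
    (whole-body) quantities.
    """

    cumulated_mbq_h: dict[str, float]
    blood_conc_mbq_h_per_ml: float
    params: PatientKineticsParams = field(repr=False, default=None)  # type: ignore[assignment]

    def residence_time_h(self, region: str) -> float:
        return self.cumulated_mbq_h[region] / self.params.injected_activity_mbq


def _uptake_washout(
    t: np.ndarray, amplitude: float, k_u: float, mu: float
) -> np.ndarray:
    return amplitude * (1.0 - np.exp(-k_u * t)) * np.exp(-mu * t)


def _uptake_washout_integral(amplitude: float, k_u: float, mu: float) -> float:
    return amplitude * (1.0 / mu - 1.0 / (mu + k_u))


def _noise(rng: np.random.Generator, sigma: float, size: int) -> np.ndarray:
    if sigma == 0:
        return np.ones(size)
    z = rng.standard_normal(size)
    return np.exp(sigma * z - 0.5 * sigma**2)


def generate_patient(
    params: PatientKineticsParams,
    constants: PhysicalConstants | None = None,
    phantom: PhantomConstants | None = None,
) -> tuple[PatientBundle, GroundTruth]:
    """Generate one measured patient bundle plus its exact ground truth.

    The bundle mimics the measurement process: skeleton and total-body
    curves are emitted with the legs outside the field of view, lesion
    curves as mean concentrations, blood as concentration samples. Noise
    (if any) is applied per sample with the parameter seed; the ground
    truth always refers to the noiseless model.
    """
    constants = constants or PhysicalConstants()
    phantom = phantom or PhantomConstants()
    lam = constants.lambda_phys
    a0 = params.injected_activity_mbq
    rng = np.random.default_rng(params.seed)
    t_img = np.asarray(params.imaging_schedule_h, dtype=float)
    t_blood = np.asarray(params.blood_schedule_h, dtype=float)

    mu_skel = lam + params.skeleton_washout_per_h
    mu_kid = lam + params.kidney_washout_per_h
    mu_blad = lam + params.bladder_washout_per_h
    mu_rem = lam + params.remainder_washout_per_h

    skeleton_true = _uptake_washout(
        t_img, a0 * params.skeleton_fraction, params.skeleton_uptake_per_h, mu_skel
    )
    kidneys = _uptake_washout(
        t_img, a0 * params.kidney_fraction, params.kidney_uptake_per_h, mu_kid
    )
    bladder = _uptake_washout(
        t_img, a0 * params.bladder_fraction, params.bladder_uptake_per_h, mu_blad
    )
    remainder_comp = _uptake_washout(
        t_img, a0 * params.remainder_fraction, params.remainder_uptake_per_h, mu_rem
    )

    def blood_conc(t: np.ndarray) -> np.ndarray:
        return a0 * (
            params.blood_c1_frac_per_ml * np.exp(-(params.blood_k1_per_h + lam) * t)
            + params.blood_c2_frac_per_ml * np.exp(-(params.blood_k2_per_h + lam) * t)
        )

    # Lesions are sub-volumes of the skeleton compartment (bone metastases
    # sit in bone): the measured skeleton VOI excludes the tumor voxels,
    # so its activity is the skeletal compartment minus the lesions.
    lesion_conc_img = [
        _uptake_washout(
            t_img, a0 * lp.conc_scale_per_ml, lp.uptake_rate_per_h,
            lam + lp.washout_rate_per_h,
        )
        for lp in params.lesions
    ]
    tumor_activity_img = sum(
        (conc * lp.volume_ml for conc, lp in zip(lesion_conc_img, params.lesions)),
        start=np.zeros_like(t_img),
    )
    skeleton_voi = skeleton_true - tumor_activity_img
    if np.any(skeleton_voi < 0):
        raise ValueError(
            "lesion activity exceeds the skeletal compartment; reduce lesion "
            "volumes/concentrations or raise skeleton_fraction"
        )

    blood_pool_img = blood_conc(t_img) * params.blood_volume_ml
    total_true = (
        skeleton_true + kidneys + bladder + remainder_comp + blood_pool_img
    )

    legs_out = 1.0 - phantom.leg_bone_fraction  # 0.664: legs outside the FOV

    def curve(region, times, values, mode=SampleMode.ACTIVITY):
        noisy = np.maximum(values * _noise(rng, params.noise_sigma, len(values)), 0.0)
        return TimeActivityCurve.from_arrays(
            region, times, noisy, a0, mode=mode
        )

    curves = {
        "skeleton": curve("skeleton", t_img, skeleton_voi * legs_out),
        "kidneys": curve("kidneys", t_img, kidneys),
        "bladder_content": curve("bladder_content", t_img, bladder),
        "total_body": curve("total_body", t_img, total_true * legs_out),
        "blood": curve(
            "blood", t_blood, blood_conc(t_blood), mode=SampleMode.CONCENTRATION
        ),
    }
    lesions = tuple(
        Lesion(
            lesion_id=f"tumor:{i + 1}",
            volume_ml=lp.volume_ml,
            conc_curve=curve(
                f"tumor:{i + 1}", t_img,
                _uptake_washout(
                    t_img, a0 * lp.conc_scale_per_ml, lp.uptake_rate_per_h,
                    lam + lp.washout_rate_per_h,
                ),
                mode=SampleMode.CONCENTRATION,
            ),
        )
        for i, lp in enumerate(params.lesions)
    )

    # --- exact integrals of the noiseless generating model ---
    skel_cum = _uptake_washout_integral(
        a0 * params.skeleton_fraction, params.skeleton_uptake_per_h, mu_skel
    )
    kid_cum = _uptake_washout_integral(
        a0 * params.kidney_fraction, params.kidney_uptake_per_h, mu_kid
    )
    blad_cum = _uptake_washout_integral(
        a0 * params.bladder_fraction, params.bladder_uptake_per_h, mu_blad
    )
    rem_comp_cum = _uptake_washout_integral(
        a0 * params.remainder_fraction, params.remainder_uptake_per_h, mu_rem
    )
    blood_conc_cum = a0 * (
        params.blood_c1_frac_per_ml / (params.blood_k1_per_h + lam)
        + params.blood_c2_frac_per_ml / (params.blood_k2_per_h + lam)
    )
    marrow_volume_ml = phantom.red_marrow_mass_g / phantom.red_marrow_density_g_per_ml
    marrow_cum = blood_conc_cum * phantom.rmblr * marrow_volume_ml
    blood_pool_cum = blood_conc_cum * params.blood_volume_ml
    tumor_cums = {
        f"tumor:{i + 1}": lp.volume_ml * _uptake_washout_integral(
            a0 * lp.conc_scale_per_ml, lp.uptake_rate_per_h,
            lam + lp.washout_rate_per_h,
        )
        for i, lp in enumerate(params.lesions)
    }
    total_cum = skel_cum + kid_cum + blad_cum + rem_comp_cum + blood_pool_cum
    # skeleton VOI excludes the lesions; remainder excludes all explicit
    # source regions and lesions (pipeline convention)
    skel_voi_cum = skel_cum - sum(tumor_cums.values())
    remainder_cum = blood_pool_cum + rem_comp_cum - marrow_cum

    truth = GroundTruth(
        cumulated_mbq_h={
            "skeleton": skel_voi_cum,
            "skeleton_with_tumors": skel_cum,
            "cortical_surface": phantom.cortical_fraction * skel_voi_cum,
            "trabecular_surface": phantom.trabecular_fraction * skel_voi_cum,
            "kidneys": kid_cum,
            "bladder_content": blad_cum,
            "red_marrow": marrow_cum,
            "remainder": remainder_cum,
            "total_body": total_cum,
            **tumor_cums,
        },
        blood_conc_mbq_h_per_ml=blood_conc_cum,
        params=params,
    )
    bundle = PatientBundle(
        patient_id=params.patient_id,
        injected_activity_mbq=a0,
        kidney_volume_ml=params.kidney_volume_ml,
        curves=curves,
        lesions=lesions,
    )
    return bundle, truth


#: Multiplicative jitter (lognormal sigma, scaled by ``variability``)
#: applied per parameter when generating a cohort. Magnitudes follow the
#: between-patient spread such cohorts show: ~25% on skeletal uptake,
#: ~50% on lesion concentration, broad on renal uptake.
_COHORT_JITTER = {
    "skeleton_fraction": 0.25,
    "skeleton_uptake_per_h": 0.30,
    "skeleton_washout_per_h": 0.30,
    "blood_c1_frac_per_ml": 0.20,
    "blood_c2_frac_per_ml": 0.20,
    "blood_k1_per_h": 0.20,
    "blood_k2_per_h": 0.20,
    "kidney_fraction": 0.40,
    "bladder_fraction": 0.30,
    "remainder_fraction": 0.20,
    "kidney_volume_ml": 0.15,
}


def generate_cohort(
    n: int,
    master_seed: int = 0,
    variability: float = 1.0,
    base_params: PatientKineticsParams | None = None,
    noise_sigma: float | None = None,
    preset: str = "typical",
    constants: PhysicalConstants | None = None,
    phantom: PhantomConstants | None = None,
) -> list[tuple[PatientBundle, GroundTruth]]:
    """Generate ``n`` patients with parameters jittered around defaults.

    Per-patient seeds derive deterministically from ``master_seed`` via a
    NumPy SeedSequence. ``preset`` "typical" keeps low renal uptake;
    "high-kidney" multiplies the kidney fraction tenfold, mimicking the
    minority of patients with visible renal retention.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if preset not in ("typical", "high-kidney"):
        raise ValueError(f"unknown preset {preset!r}")
    base = base_params or PatientKineticsParams()
    if noise_sigma is not None:
        base = replace(base, noise_sigma=noise_sigma)
    if preset == "high-kidney":
        base = replace(base, kidney_fraction=min(base.kidney_fraction * 10.0, 1.0))

    children = np.random.SeedSequence(master_seed).spawn(n)
    out: list[tuple[PatientBundle, GroundTruth]] = []
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2**31))
        jrng = np.random.default_rng(seed)
        injected = float(
            max(jrng.normal(5780.0, 329.0 * variability), 1000.0)
        )
        updates: dict[str, object] = {
            "patient_id": f"synthetic-{i + 1}",
            "injected_activity_mbq": injected,
            "seed": seed,
        }
        for name, sigma in _COHORT_JITTER.items():
            factor = math.exp(
                sigma * variability * jrng.standard_normal()
                - 0.5 * (sigma * variability) ** 2
            )
            updates[name] = getattr(base, name) * factor
        lesions = []
        for lp in base.lesions:
            factor = math.exp(
                0.5 * variability * jrng.standard_normal()
                - 0.5 * (0.5 * variability) ** 2
            )
            lesions.append(replace(lp, conc_scale_per_ml=lp.conc_scale_per_ml * factor))
        updates["lesions"] = tuple(lesions)
        # keep jittered organ fractions physical (sum <= 1)
        frac_names = (
            "skeleton_fraction", "kidney_fraction",
            "bladder_fraction", "remainder_fraction",
        )
        total_frac = sum(
            float(updates.get(name, getattr(base, name))) for name in frac_names
        )
        if total_frac > 0.95:
            for name in frac_names:
                updates[name] = (
                    float(updates.get(name, getattr(base, name))) * 0.95 / total_frac
                )
        params = replace(base, **updates)
        out.append(generate_patient(params, constants=constants, phantom=phantom))
    return out
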