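"""Physical and phantom constants used across the pipeline.

All constants live in small frozen dataclasses so that a run can swap in
alternative values (e.g. a different red-marrow-to-blood ratio) without
touching code. Units are carried in field names or docstrings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class PhysicalConstants:
    """Decay data for the therapeutic nuclide.

    The default is Lu-177 with a physical half-life of 6.647 d.
    ``lambda_phys`` (1/h) is the corresponding decay constant; measured
    (non-decay-corrected) time-activity curves cannot clear more slowly
    than physical decay, which the fitter enforces through this value.
    """

    half_life_h: float = 6.647 * 24.0  # 159.528 h

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be > 0")

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant in 1/h."""
        return math.log(2.0) / self.half_life_h


@dataclass(frozen=True)
class PhantomConstants:
    """Reference-man constants for source-organ construction.

    red_marrow_mass_g / red_marrow_density:
        standard red-marrow mass (1500 g) and density (1.05 g/mL) used to
        convert a blood activity concentration into a marrow activity.
    rmblr:
        red-marrow-to-blood activity-concentration ratio; 1.0 is the
        conservative choice for Lu-177 therapy.
    leg_bone_fraction:
        fraction of total bone mass in the legs (0.336). Skeleton and
        total-body measurements that exclude the legs are divided by
        (1 - leg_bone_fraction), i.e. scaled by 1.506.
    cortical_fraction / trabecular_fraction:
        split of skeletal cumulated activity between the cortical (80%)
        and trabecular (20%) bone mineral surfaces.
    total_bone_mass_g:
        5500 g skeleton reference mass (used e.g. for %IA/g bookkeeping).
    tumor_density_g_per_ml:
        osteoblastic lesions are assigned the cortical-bone density
        1.92 g/mL; kidney tissue 1.06 g/mL.
    """

    red_marrow_mass_g: float = 1500.0
    red_marrow_density_g_per_ml: float = 1.05
    rmblr: float = 1.0
    leg_bone_fraction: float = 0.336
    cortical_fraction: float = 0.8
    trabecular_fraction: float = 0.2
    total_bone_mass_g: float = 5500.0
    tumor_density_g_per_ml: float = 1.92
    kidney_density_g_per_ml: float = 1.06

    def __post_init__(self) -> None:
        if abs(self.cortical_fraction + self.trabecular_fraction - 1.0) > 1e-12:
            raise ValueError("cortical_fraction + trabecular_fraction must equal 1")
        if not 0.0 < self.leg_bone_fraction < 1.0:
            raise ValueError("leg_bone_fraction must lie in (0, 1)")
        if self.rmblr <= 0:
            raise ValueError("rmblr must be > 0")
        for name in (
            "red_marrow_mass_g",
            "red_marrow_density_g_per_ml",
            "total_bone_mass_g",
            "tumor_density_g_per_ml",
            "kidney_density_g_per_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def leg_scale_factor(self) -> float:
        """Multiplier restoring the legs: 1/(1-0.336) = 1.506."""
        return 1.0 / (1.0 - self.leg_bone_fraction)


#: Organ dose limits in Gy used for maximum-tolerated-activity planning.
DEFAULT_DOSE_LIMITS_GY: dict[str, float] = {
    "red_marrow": 2.0,
    "kidneys": 23.0,
    "bone_surfaces": 10.0,
}

#: Fixed organ order for deterministic tie-breaking in planning.
ORGAN_ORDER: tuple[str, ...] = ("red_marrow", "kidneys", "bone_surfaces")


@dataclass(frozen=True)
class DoseLimits:
    """Maximum tolerated absorbed doses (Gy) per organ at risk."""

    limits_gy: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_LIMITS_GY)
    )

    def __post_init__(self) -> None:
        for organ, limit in self.limits_gy.items():
            if limit <= 0:
                raise ValueError(f"dose limit for {organ!r} must be > 0")

    def __getitem__(self, organ: str) -> float:
        return self.limits_gy[organ]

    def __contains__(self, organ: str) -> bool:
        return organ in self.limits_gy

    def organs(self) -> list[str]:
        return list(self.limits_gy)
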