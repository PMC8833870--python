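"""Treatment-planning arithmetic: maximum tolerated activity, therapeutic
indices, red-marrow sensitivity, and cohort summary statistics.

The maximum tolerated injected activity (MTA) is the largest activity for
which no organ at risk exceeds its absorbed-dose limit: with normalized
doses d_organ (Gy/GBq) and limits L_organ (Gy),

    MTA = min_organ  L_organ / d_organ          (GBq).

Therapeutic index = mean tumor dose / organ-at-risk dose, both in Gy/GBq.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from statistics import median as _median

from .constants import DoseLimits, ORGAN_ORDER
from .dose_engine import OrganDoseResult

logger = logging.getLogger(__name__)

__all__ = [
    "PlanResult",
    "max_tolerated_activity",
    "therapeutic_index",
    "rmblr_sensitivity",
    "cohort_summary",
    "plan_patient",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report-table convention, 5.95 -> 6.0).

    Values a float-representation hair below a rounding boundary (e.g.
    (5.8 + 6.1)/2 = 5.949999...) are snapped to it before flooring.
    """
    factor = 10.0**ndigits
    y = abs(x) * factor + 0.5
    nearest = round(y)
    if abs(y - nearest) <= 1e-9 * max(1.0, abs(y)):
        y = nearest
    return math.copysign(math.floor(y), x) / factor


@dataclass(frozen=True)
class PlanResult:
    """Per-patient planning summary mirroring a dosimetry report row."""

    patient_id: str
    organ_doses_gy_per_gbq: dict[str, float]
    effective_dose_msv_per_mbq: float | None
    tumor_doses_gy_per_gbq: tuple[float, ...]
    mean_tumor_dose_gy_per_gbq: float | None
    mta_gbq: float
    limiting_organ: str
    per_organ_mta_gbq: dict[str, float]
    therapeutic_indices: dict[str, float] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        finite = {o: m for o, m in self.per_organ_mta_gbq.items() if math.isfinite(m)}
        if finite:
            best = min(finite.values())
            if abs(self.mta_gbq - best) > 1e-9 * max(best, 1.0):
                raise ValueError("mta must equal the minimum per-organ MTA")
            if abs(finite[self.limiting_organ] - best) > 1e-9 * max(best, 1.0):
                raise ValueError("limiting organ must attain the minimum MTA")


def max_tolerated_activity(
    doses_gy_per_gbq: dict[str, float],
    limits: DoseLimits | None = None,
) -> tuple[float, str, dict[str, float]]:
    """Maximum tolerated injected activity (GBq) and the limiting organ.

    Per-organ MTA is limit/dose; organs with zero dose get infinite MTA
    (flagged via a log warning) and are excluded from the minimum. Ties are
    broken by the fixed organ order red_marrow, kidneys, bone_surfaces.
    Dosed organs without a limit are ignored with a logged note.
    """
    limits = limits or DoseLimits()
    if not doses_gy_per_gbq:
        raise ValueError("dose map must be non-empty")
    per_organ: dict[str, float] = {}
    for organ, dose in doses_gy_per_gbq.items():
        if dose < 0:
            raise ValueError(f"dose for {organ!r} must be >= 0")
        if organ not in limits:
            logger.info("no dose limit for %r; organ ignored in MTA", organ)
            continue
        if dose == 0:
            logger.warning("zero dose for %r: per-organ MTA is infinite", organ)
            per_organ[organ] = math.inf
            continue
        per_organ[organ] = limits[organ] / dose

    finite = {o: m for o, m in per_organ.items() if math.isfinite(m)}
    if not finite:
        raise ValueError("all per-organ MTAs are infinite; MTA undefined")
    mta = min(finite.values())
    ordering = list(ORGAN_ORDER) + [o for o in finite if o not in ORGAN_ORDER]
    limiting = next(
        o for o in ordering if o in finite and abs(finite[o] - mta) <= 1e-12 * max(mta, 1.0)
    )
    tied = [o for o, m in finite.items() if abs(m - mta) <= 1e-12 * max(mta, 1.0)]
    if len(tied) > 1:
        logger.info("MTA tie between %s; resolved to %r by fixed order", tied, limiting)
    return mta, limiting, per_organ


def therapeutic_index(
    mean_tumor_dose_gy_per_gbq: float, organ_dose_gy_per_gbq: float
) -> float:
    """Mean tumor dose divided by an organ-at-risk dose (dimensionless)."""
    if organ_dose_gy_per_gbq <= 0:
        raise ValueError("organ dose must be > 0")
    return mean_tumor_dose_gy_per_gbq / organ_dose_gy_per_gbq


def rmblr_sensitivity(
    total_marrow_dose_gy_per_gbq: float,
    self_fraction: float,
    rmblr_ref: float,
    rmblr_new: float,
) -> tuple[float, float]:
    """Marrow dose under a different red-marrow-to-blood ratio (RMBLR).

    Only the blood-derived self-contribution (fraction ``self_fraction`` of
    the total) scales with RMBLR; cross-irradiation is unaffected:

        D_new = D * (1 - f) + D * f * r_new / r_ref
        pct_change = -100 * f * (1 - r_new / r_ref)

    Returns (new_dose, percent change). With f = 0.30 and RMBLR 1.0 -> 0.36
    the dose drops by 19.2%.
    """
    if not 0.0 <= self_fraction <= 1.0:
        raise ValueError("self_fraction must lie in [0, 1]")
    if rmblr_ref <= 0:
        raise ValueError("rmblr_ref must be > 0")
    if rmblr_new < 0:
        raise ValueError("rmblr_new must be >= 0")
    ratio = rmblr_new / rmblr_ref
    new_dose = total_marrow_dose_gy_per_gbq * (
        (1.0 - self_fraction) + self_fraction * ratio
    )
    pct_change = -100.0 * self_fraction * (1.0 - ratio)
    return new_dose, pct_change


def cohort_summary(
    values: list[float], ddof: int = 0
) -> tuple[float, float, float]:
    """(median, mean, SD) of a cohort of values.

    Median uses the midpoint rule for even n. The default SD is the
    population convention (denominator n), matching dosimetry report
    tables; pass ddof=1 for the sample convention.
    """
    if not values:
        raise ValueError("values must be non-empty")
    n = len(values)
    if ddof >= n:
        raise ValueError("ddof must be smaller than the number of values")
    med = float(_median(values))
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - ddof)
    return med, mean, math.sqrt(var)


def plan_patient(
    dose_result: OrganDoseResult,
    tumor_doses_gy_per_gbq: list[float],
    limits: DoseLimits | None = None,
    patient_id: str = "",
) -> PlanResult:
    """Assemble the per-patient planning summary.

    Computes MTA and limiting organ from the organ doses, and therapeutic
    indices (mean tumor dose over organ dose) for red marrow and bone
    surfaces when lesion doses are available. Kidneys are excluded from the
    indices (their doses are typically too low to be informative).
    """
    limits = limits or DoseLimits()
    doses = dose_result.doses_gy_per_gbq
    missing = [o for o in limits.organs() if o not in doses]
    if missing:
        raise ValueError(f"dose result missing limited organs: {missing}")
    mta, limiting, per_organ = max_tolerated_activity(
        {o: doses[o] for o in limits.organs()}, limits
    )
    flags: list[str] = []
    tumor_doses = tuple(tumor_doses_gy_per_gbq)
    if tumor_doses:
        mean_tumor = sum(tumor_doses) / len(tumor_doses)
        indices = {
            organ: therapeutic_index(mean_tumor, doses[organ])
            for organ in ("red_marrow", "bone_surfaces")
            if doses.get(organ, 0.0) > 0
        }
    else:
        mean_tumor = None
        indices = {}
        flags.append("no_tumor_doses")
    return PlanResult(
        patient_id=patient_id,
        organ_doses_gy_per_gbq=dict(doses),
        effective_dose_msv_per_mbq=dose_result.effective_dose_msv_per_mbq,
        tumor_doses_gy_per_gbq=tumor_doses,
        mean_tumor_dose_gy_per_gbq=mean_tumor,
        mta_gbq=mta,
        limiting_organ=limiting,
        per_organ_mta_gbq=per_organ,
        therapeutic_indices=indices,
        flags=tuple(flags),
    )
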