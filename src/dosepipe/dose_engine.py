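"""MIRD-style absorbed dose engine.

The absorbed dose to a target region is

    D(target) = sum_source  tau(source) * S(target <- source),

where tau is the normalized cumulated activity (residence time, h) and S is
the phantom- and nuclide-specific dose factor in Gy/(MBq*h). Doses are
reported normalized to injected activity in Gy/GBq (numerically equal to
mGy/MBq). Self-dose terms are rescaled by reference_mass/patient_mass when a
patient-specific organ mass is supplied (first-order mass correction; cross
terms are left untouched).

Tumor lesions are treated with a sphere model: an electron mean energy per
decay Delta (Gy*g per MBq*h) and a mass-dependent absorbed fraction
phi(m), log-log interpolated between table nodes,

    D_sphere = tau_tumor * Delta * phi(m) / m.

S-values, reference masses and the sphere table are configuration (CSV),
not code; the packaged Lu-177 tables are illustrative and clearly labelled
non-authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SValueMatrix",
    "ResidenceTimeSet",
    "SphereModelTable",
    "OrganDoseResult",
    "organ_doses",
    "sphere_dose",
    "effective_dose",
    "dose_contributions",
]


@dataclass(frozen=True)
class ResidenceTimeSet:
    """Normalized cumulated activities (h) per source region."""

    residence_times_h: dict[str, float]
    injected_activity_mbq: float

    def __post_init__(self) -> None:
        for region, tau in self.residence_times_h.items():
            if tau < 0:
                raise ValueError(f"residence time for {region!r} must be >= 0")
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be > 0")

    def items(self):
        return self.residence_times_h.items()


@dataclass(frozen=True)
class SValueMatrix:
    """Source -> target dose factors in Gy/(MBq*h) with reference masses (g)."""

    sources: tuple[str, ...]
    targets: tuple[str, ...]
    values: np.ndarray  # shape (n_targets, n_sources)
    reference_masses_g: dict[str, float] = field(default_factory=dict)
    phantom: str = "unspecified"
    nuclide: str = "Lu-177"
    provenance: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "targets", tuple(self.targets))
        if values.shape != (len(self.targets), len(self.sources)):
            raise ValueError("S-matrix shape must be (n_targets, n_sources)")
        if np.any(values < 0):
            raise ValueError("S-values must be >= 0")
        for region in set(self.sources) & set(self.targets):
            if self.s(region, region) <= 0:
                raise ValueError(f"self S-value for {region!r} must be > 0")
        for region, mass in self.reference_masses_g.items():
            if mass <= 0:
                raise ValueError(f"reference mass for {region!r} must be > 0")

    def s(self, target: str, source: str) -> float:
        return float(
            self.values[self.targets.index(target), self.sources.index(source)]
        )


@dataclass(frozen=True)
class SphereModelTable:
    """Electron sphere self-dose model: Delta and phi(mass) nodes.

    delta_gy_g_per_mbq_h is the (electron) mean energy emitted per unit
    cumulated activity; phi_nodes are (mass g, absorbed fraction) pairs,
    log-log interpolated and clamped to the end values outside the range.
    """

    delta_gy_g_per_mbq_h: float
    phi_nodes: tuple[tuple[float, float], ...]
    tissue_density_g_per_ml: float = 1.92

    def __post_init__(self) -> None:
        nodes = tuple(sorted((float(m), float(p)) for m, p in self.phi_nodes))
        object.__setattr__(self, "phi_nodes", nodes)
        if self.delta_gy_g_per_mbq_h <= 0:
            raise ValueError("delta must be > 0")
        if not nodes:
            raise ValueError("phi table must be non-empty")
        for m, p in nodes:
            if m <= 0 or not 0.0 <= p <= 1.0:
                raise ValueError("phi nodes need mass > 0 and phi in [0, 1]")
        phis = [p for _, p in nodes]
        if any(b < a for a, b in zip(phis, phis[1:])):
            raise ValueError("phi must be non-decreasing with sphere mass")

    def phi(self, mass_g: float) -> float:
        """Absorbed fraction at the given mass (log-log interpolation)."""
        if mass_g <= 0:
            raise ValueError("mass must be > 0")
        masses = np.array([m for m, _ in self.phi_nodes])
        phis = np.array([p for _, p in self.phi_nodes])
        if mass_g <= masses[0]:
            return float(phis[0])
        if mass_g >= masses[-1]:
            return float(phis[-1])
        return float(
            np.exp(np.interp(np.log(mass_g), np.log(masses), np.log(phis)))
        )


@dataclass(frozen=True)
class OrganDoseResult:
    """Normalized doses per target (Gy/GBq) with per-source breakdown."""

    doses_gy_per_gbq: dict[str, float]
    contributions_gy_per_gbq: dict[str, dict[str, float]]
    effective_dose_msv_per_mbq: float | None = None


def organ_doses(
    rt: ResidenceTimeSet,
    smatrix: SValueMatrix,
    patient_masses_g: dict[str, float] | None = None,
) -> OrganDoseResult:
    """Organ absorbed doses from residence times and an S-value matrix.

    Each target dose is the sum over sources of tau * S(target<-source),
    converted to Gy/GBq (x1000 from Gy/MBq). Self-dose terms are scaled by
    reference_mass/patient_mass for organs with a patient-specific mass.
    """
    patient_masses_g = patient_masses_g or {}
    for region, mass in patient_masses_g.items():
        if mass <= 0:
            raise ValueError(f"patient mass for {region!r} must be > 0")
    unknown = [s for s in rt.residence_times_h if s not in smatrix.sources]
    if unknown:
        raise KeyError(f"residence times for regions absent from S-matrix: {unknown}")

    doses: dict[str, float] = {}
    contributions: dict[str, dict[str, float]] = {}
    for target in smatrix.targets:
        per_source: dict[str, float] = {}
        for source, tau in rt.items():
            s = smatrix.s(target, source)
            if (
                source == target
                and target in patient_masses_g
                and target in smatrix.reference_masses_g
            ):
                s *= smatrix.reference_masses_g[target] / patient_masses_g[target]
            per_source[source] = tau * s * 1000.0  # Gy/MBq -> Gy/GBq
        contributions[target] = per_source
        doses[target] = float(sum(per_source.values()))
    return OrganDoseResult(doses_gy_per_gbq=doses, contributions_gy_per_gbq=contributions)


def sphere_dose(
    tumor_residence_time_h: float,
    tumor_mass_g: float,
    table: SphereModelTable,
) -> float:
    """Tumor self-dose (Gy/GBq) from the sphere model.

    D = tau * Delta * phi(m) / m, converted to Gy/GBq.
    """
    if tumor_mass_g <= 0:
        raise ValueError("tumor mass must be > 0")
    if tumor_residence_time_h < 0:
        raise ValueError("residence time must be >= 0")
    dose_gy_per_mbq = (
        tumor_residence_time_h
        * table.delta_gy_g_per_mbq_h
        * table.phi(tumor_mass_g)
        / tumor_mass_g
    )
    return dose_gy_per_mbq * 1000.0


def effective_dose(
    equivalent_doses_msv_per_mbq: dict[str, float],
    weights: dict[str, float],
) -> float:
    """Tissue-weighted effective dose E = sum_T w_T * H_T (mSv/MBq).

    Targets without a weight contribute nothing; weights over the provided
    targets must sum to at most 1 (a partial, "remainder-bucket" scheme is
    allowed).
    """
    total_w = 0.0
    for organ, w in weights.items():
        if w < 0:
            raise ValueError(f"negative tissue weight for {organ!r}")
        if organ in equivalent_doses_msv_per_mbq:
            total_w += w
    if total_w > 1.0 + 1e-12:
        raise ValueError("tissue weights over provided targets exceed 1")
    return float(
        sum(
            weights[organ] * h
            for organ, h in equivalent_doses_msv_per_mbq.items()
            if organ in weights
        )
    )


def dose_contributions(
    result: OrganDoseResult, target: str
) -> tuple[dict[str, float], bool]:
    """Fractional per-source contributions to one target's dose.

    Returns (fractions, zero_dose_flag); fractions sum to 1 unless the
    total dose is zero, in which case all fractions are 0 and the flag is
    set.
    """
    if target not in result.contributions_gy_per_gbq:
        raise KeyError(f"target {target!r} not in dose result")
    per_source = result.contributions_gy_per_gbq[target]
    total = sum(per_source.values())
    if total <= 0:
        return {s: 0.0 for s in per_source}, True
    return {s: c / total for s, c in per_source.items()}, False
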