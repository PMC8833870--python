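"""Time-activity curves, sum-of-exponential fitting and analytic integration.

The quantity of interest for internal dosimetry is the cumulated activity
(time-integrated activity, MBq*h) in each source region: the total number of
decays occurring there. Measured organ activities at ~5 imaging time points
(and blood concentrations at ~8 sampling times) are fitted with a sum of
exponentials

    A(t) = sum_i  A_i * exp(-lambda_i * t),      lambda_i > 0,

which integrates in closed form to sum_i A_i / lambda_i on [0, inf).
Curves are measured activity (not decay-corrected), so every fitted rate is
constrained to be at least the physical decay constant: tissue cannot shed
activity more slowly than the nuclide decays.

Fitting is deterministic: a fixed log-spaced multi-start grid of rates seeds
a bounded least-squares refinement, and model order (1 or 2 terms; 3 only
with at least 7 samples) is selected by a small-sample-corrected information
criterion. One negative amplitude is allowed so that an uptake phase
(A*(e^{-k1 t} - e^{-k2 t})) can be represented; the fitted curve must remain
non-negative on a dense grid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import PhysicalConstants

__all__ = [
    "SampleMode",
    "ActivitySample",
    "TimeActivityCurve",
    "ExponentialModel",
    "fit_exponential",
    "integrate_model",
    "cumulated_activity",
    "normalized_cumulated_activity",
]

#: Relative tolerance by which a fitted terminal rate may undershoot the
#: physical decay constant (guards against float noise at the bound).
RATE_CONSTRAINT_TOL = 1e-3


class SampleMode(str, Enum):
    ACTIVITY = "activity"  # MBq
    CONCENTRATION = "concentration"  # MBq/mL


@dataclass(frozen=True)
class ActivitySample:
    """One measurement: hours post-injection and activity (or concentration)."""

    time_h: float
    value: float
    mode: SampleMode = SampleMode.ACTIVITY

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("sample time must be >= 0 h")
        if self.value < 0:
            raise ValueError("sample value must be >= 0")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Measured time-activity data for one region of one patient.

    ``region`` identifiers follow the source-organ vocabulary:
    skeleton, kidneys, bladder_content, total_body, blood, red_marrow,
    remainder, or ``tumor:<n>`` for lesions. Values are measured (decayed)
    activity unless ``decay_corrected`` is set.
    """

    region: str
    samples: tuple[ActivitySample, ...]
    injected_activity_mbq: float
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected_activity_mbq must be > 0")
        times = [s.time_h for s in self.samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        modes = {s.mode for s in self.samples}
        if len(modes) > 1:
            raise ValueError("all samples in a curve must share one mode")

    @property
    def mode(self) -> SampleMode:
        return self.samples[0].mode if self.samples else SampleMode.ACTIVITY

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_h for s in self.samples], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([s.value for s in self.samples], dtype=float)

    def scaled(self, factor: float, region: str | None = None) -> "TimeActivityCurve":
        """Return a copy with every sample value multiplied by ``factor``."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return TimeActivityCurve(
            region=region if region is not None else self.region,
            samples=tuple(
                ActivitySample(s.time_h, s.value * factor, s.mode)
                for s in self.samples
            ),
            injected_activity_mbq=self.injected_activity_mbq,
            decay_corrected=self.decay_corrected,
        )

    @classmethod
    def from_arrays(
        cls,
        region: str,
        times_h: Iterable[float],
        values: Iterable[float],
        injected_activity_mbq: float,
        mode: SampleMode = SampleMode.ACTIVITY,
        decay_corrected: bool = False,
    ) -> "TimeActivityCurve":
        samples = tuple(
            ActivitySample(float(t), float(v), mode)
            for t, v in zip(times_h, values, strict=True)
        )
        return cls(region, samples, injected_activity_mbq, decay_corrected)


@dataclass(frozen=True)
class ExponentialModel:
    """Fitted sum of exponentials A(t) = sum_i amp_i * exp(-rate_i * t).

    ``terms`` is sorted by rate ascending (slowest first). The empty model
    (no terms) represents an all-zero curve and carries ``zero_curve``.
    ``fallback_recommended`` is set when no multi-start converged to an
    admissible model; callers should then integrate by the hybrid
    trapezoid+tail policy instead.
    """

    terms: tuple[tuple[float, float], ...]  # (amplitude, rate 1/h)
    sse: float = 0.0
    aicc: float = float("-inf")
    n_samples: int = 0
    zero_curve: bool = False
    fallback_recommended: bool = False
    constraint_record: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(map(tuple, self.terms)))
        for _, rate in self.terms:
            if rate <= 0:
                raise ValueError("all rates must be > 0")
        n_negative = sum(1 for amp, _ in self.terms if amp < 0)
        if n_negative > 1:
            raise ValueError("at most one amplitude may be negative")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for amp, rate in self.terms:
            out = out + amp * np.exp(-rate * t)
        return out


def _model_valid(
    amps: np.ndarray, rates: np.ndarray, t_last: float, scale: float
) -> bool:
    """Admissibility: <=1 negative amplitude, non-negative on a dense grid."""
    if np.sum(amps < 0) > 1:
        return False
    grid = np.linspace(0.0, max(t_last * 1.2, 1.0), 400)
    vals = np.zeros_like(grid)
    for a, r in zip(amps, rates):
        vals += a * np.exp(-r * grid)
    return bool(np.min(vals) >= -1e-9 * scale)


def _aicc(sse: float, n: int, k: int, scale: float) -> float:
    """Corrected AIC with the denominator clamped for tiny samples.

    With 5 imaging points a 2-term model (k=4) makes the textbook
    correction denominator n-k-1 vanish; clamping keeps the criterion
    finite while still penalising parameters. SSE is floored so that
    noiseless (near machine-zero) fits compare by parameter count.
    """
    floor = n * (1e-10 * max(scale, 1e-300)) ** 2
    mse = max(sse, floor) / n
    denom = max(n - k - 1, 1)
    return n * math.log(mse) + 2 * k + (2 * k * (k + 1)) / denom


def _rate_grid(lam_min: float, t_first: float, t_last: float) -> np.ndarray:
    """Fixed, deterministic log-spaced grid of candidate rates (1/h)."""
    hi = max(10.0 / max(t_first, 1e-3), 5.0 / max(t_last, 1.0), 10.0 * lam_min)
    return np.geomspace(lam_min * 1.0000001, hi, 8)


def _solve_amplitudes(
    t: np.ndarray, y: np.ndarray, w: np.ndarray, rates: np.ndarray
) -> np.ndarray:
    basis = np.exp(-np.outer(t, rates))
    amps, *_ = np.linalg.lstsq(w[:, None] * basis, w * y, rcond=None)
    return amps


def _fit_n_terms(
    t: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    n_terms: int,
    lam_min: float,
) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Best admissible n-term fit over the multi-start grid, or None.

    Variable projection: the optimizer searches over log-rates only, with
    amplitudes solved by linear least squares at every step. A final
    full-parameter polish tightens the optimum. This is far more robust
    than a joint search for near-degenerate exponential mixtures.
    """
    scale = float(np.max(np.abs(y)))
    grid = _rate_grid(lam_min, float(t[0]), float(t[-1]))
    if n_terms == 1:
        starts: list[tuple[float, ...]] = [(g,) for g in grid]
    else:
        starts = list(itertools.combinations(grid, n_terms))

    log_lo, log_hi = math.log(lam_min), math.log(1e4)

    # transient NaN/overflow during optimizer exploration is mapped to a
    # large finite residual, so warnings are suppressed locally
    def varpro_residuals(log_rates: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", over="ignore"):
            rates = np.exp(log_rates)
            amps = _solve_amplitudes(t, y, w, rates)
            pred = np.exp(-np.outer(t, rates)) @ amps
            resid = w * (pred - y)
        if not np.all(np.isfinite(resid)):
            return np.full_like(resid, 1e6)
        return resid

    def full_residuals(x: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", over="ignore"):
            amps, rates = x[:n_terms], x[n_terms:]
            pred = np.exp(-np.outer(t, rates)) @ amps
            resid = w * (pred - y)
        if not np.all(np.isfinite(resid)):
            return np.full_like(resid, 1e6)
        return resid

    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for rates0 in starts:
        try:
            sol = least_squares(
                varpro_residuals,
                np.log(np.array(rates0, dtype=float)),
                bounds=(np.full(n_terms, log_lo), np.full(n_terms, log_hi)),
                method="trf",
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=100,
            )
        except (ValueError, np.linalg.LinAlgError):  # pragma: no cover
            continue
        rates = np.exp(sol.x)
        amps = _solve_amplitudes(t, y, w, rates)
        order = np.argsort(rates)
        amps, rates = amps[order], rates[order]
        if not _model_valid(amps, rates, float(t[-1]), scale):
            continue
        sse = float(np.sum(full_residuals(np.concatenate([amps, rates])) ** 2))
        if best is None or sse < best[2] * (1.0 - 1e-12):
            best = (amps, rates, sse)

    if best is None:
        return None
    # full-parameter polish of the winning start only
    amps, rates, sse = best
    lower = np.concatenate([np.full(n_terms, -np.inf), np.full(n_terms, lam_min)])
    upper = np.concatenate([np.full(n_terms, np.inf), np.full(n_terms, 1e4)])
    try:
        polish = least_squares(
            full_residuals,
            np.clip(np.concatenate([amps, rates]), lower, upper),
            bounds=(lower, upper),
            method="trf",
            ftol=1e-15,
            xtol=1e-15,
            gtol=1e-15,
            max_nfev=200,
        )
        p_amps, p_rates = polish.x[:n_terms], polish.x[n_terms:]
        order = np.argsort(p_rates)
        p_amps, p_rates = p_amps[order], p_rates[order]
        p_sse = float(np.sum(full_residuals(np.concatenate([p_amps, p_rates])) ** 2))
        if p_sse <= sse and _model_valid(p_amps, p_rates, float(t[-1]), scale):
            best = (p_amps, p_rates, p_sse)
    except (ValueError, np.linalg.LinAlgError):  # pragma: no cover
        pass
    return best


def fit_exponential(
    tac: TimeActivityCurve,
    max_terms: int = 2,
    constants: PhysicalConstants | None = None,
    weighting: str = "none",
) -> ExponentialModel:
    """Fit a sum of exponentials to a time-activity curve.

    Parameters
    ----------
    tac:
        Curve with at least two samples.
    max_terms:
        Maximum number of exponential terms (1..3). Three terms are
        attempted only with at least 7 samples; the number of free
        parameters (2 per term) never exceeds the number of samples.
    constants:
        Decay data; measured curves are constrained to terminal rates of
        at least ``lambda_phys * (1 - RATE_CONSTRAINT_TOL)``.
    weighting:
        "none" (default, unweighted) or "inverse" for 1/value weights
        (zero values get the smallest positive weight present).

    Returns
    -------
    ExponentialModel
        The information-criterion-selected model. All-zero input returns
        the zero model with ``zero_curve`` set; if no admissible fit
        converges, ``fallback_recommended`` is set on an empty model.
    """
    constants = constants or PhysicalConstants()
    if len(tac.samples) < 2:
        raise ValueError("fitting requires at least 2 samples")
    if not 1 <= max_terms <= 3:
        raise ValueError("max_terms must be in 1..3")

    t, y = tac.times, tac.values
    n = len(t)
    if np.all(y == 0):
        return ExponentialModel(
            terms=(),
            n_samples=n,
            zero_curve=True,
            constraint_record=("zero_curve",),
        )

    if weighting == "none":
        w = np.ones(n)
    elif weighting == "inverse":
        pos = y[y > 0]
        floor = float(np.min(pos))
        w = 1.0 / np.sqrt(np.maximum(y, floor))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    if tac.decay_corrected:
        lam_min = 1e-6
    else:
        lam_min = constants.lambda_phys * (1.0 - RATE_CONSTRAINT_TOL)

    # normalise so the optimiser sees O(1) values; amplitudes scale back
    # exactly, making cumulated activity exactly linear in the data.
    scale = float(np.max(y))
    y_n = y / scale

    candidates: list[tuple[float, int, np.ndarray, np.ndarray, float]] = []
    record: list[str] = []
    for n_terms in range(1, max_terms + 1):
        if 2 * n_terms > n:
            record.append(f"skipped {n_terms} terms: too few samples")
            continue
        if n_terms == 3 and n < 7:
            record.append("skipped 3 terms: needs >=7 samples")
            continue
        best = _fit_n_terms(t, y_n, w, n_terms, lam_min)
        if best is None:
            record.append(f"{n_terms}-term fit: no admissible solution")
            continue
        amps, rates, sse = best
        aicc = _aicc(sse, n, 2 * n_terms, 1.0)
        candidates.append((aicc, n_terms, amps, rates, sse))

    if not candidates:
        return ExponentialModel(
            terms=(),
            n_samples=n,
            fallback_recommended=True,
            constraint_record=tuple(record) + ("no_convergence",),
        )

    # minimal AICc; ties (within 1e-9) resolved toward fewer terms
    candidates.sort(key=lambda c: (round(c[0] / 1e-9) * 1e-9, c[1]))
    aicc, n_terms, amps, rates, sse = candidates[0]
    at_bound = [
        f"rate[{i}]_at_physical_decay_bound"
        for i, r in enumerate(rates)
        if abs(r - lam_min) <= 1e-12 + 1e-9 * lam_min
    ]
    return ExponentialModel(
        terms=tuple((float(a * scale), float(r)) for a, r in zip(amps, rates)),
        sse=float(sse * scale**2),
        aicc=float(aicc),
        n_samples=n,
        constraint_record=tuple(record + at_bound),
    )


def integrate_model(model: ExponentialModel) -> float:
    """Closed-form integral of the model on [0, inf): sum_i A_i / lambda_i.

    Units follow the fitted data: MBq*h for activity curves, MBq*h/mL for
    concentration curves. The zero model integrates to 0.
    """
    if model.fallback_recommended and not model.terms:
        raise ValueError(
            "model did not converge; use the hybrid integration policy"
        )
    total = 0.0
    for amp, rate in model.terms:
        if rate <= 0:
            raise ValueError("all rates must be > 0")
        total += amp / rate
    return total


def _hybrid_integral(tac: TimeActivityCurve, lam_phys: float) -> float:
    """Trapezoid over the samples, linear rise from (0,0), physical tail."""
    t, y = tac.times, tac.values
    rise = 0.5 * t[0] * y[0]
    body = float(np.trapezoid(y, t)) if len(t) > 1 else 0.0
    tail = y[-1] / lam_phys
    return float(rise + body + tail)


def cumulated_activity(
    tac: TimeActivityCurve,
    policy: str = "fit",
    max_terms: int = 2,
    constants: PhysicalConstants | None = None,
    weighting: str = "none",
) -> float:
    """Cumulated activity (MBq*h) of one curve, from 0 to infinity.

    policy "fit": exponential fit then closed-form integral (raises if no
    admissible fit converged). policy "hybrid": trapezoid over the sampled
    interval, a linear rise from (0, 0) to the first sample, and a physical
    decay tail A_last/lambda_phys. policy "auto": fit with hybrid fallback.
    """
    constants = constants or PhysicalConstants()
    if np.all(tac.values == 0):
        return 0.0
    if policy == "hybrid":
        return _hybrid_integral(tac, constants.lambda_phys)
    if policy not in ("fit", "auto"):
        raise ValueError(f"unknown policy {policy!r}")
    model = fit_exponential(tac, max_terms=max_terms, constants=constants,
                            weighting=weighting)
    if model.fallback_recommended and not model.terms:
        if policy == "auto":
            return _hybrid_integral(tac, constants.lambda_phys)
        raise ValueError(
            f"fit did not converge for region {tac.region!r}; "
            "use policy='hybrid'"
        )
    return integrate_model(model)


def normalized_cumulated_activity(cumulated_mbq_h: float, injected_mbq: float) -> float:
    """Residence time (h): cumulated activity divided by injected activity."""
    if injected_mbq <= 0:
        raise ValueError("injected activity must be > 0")
    return cumulated_mbq_h / injected_mbq
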