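# Methods

This note documents the models implemented in `dosepipe`, the numerical
choices behind them, what the synthetic data does and does not emulate,
and the known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Kinetic model and integration

Measured time–activity curves (not corrected for physical decay) are
described by sums of exponentials A(t) = Σᵢ Aᵢ e^(−λᵢt). The cumulated
activity — the total number of decays in a region, the quantity MIRD
dosimetry needs — is the closed-form integral Σᵢ Aᵢ/λᵢ over [0, ∞).

**Constraints.** All rates are positive. For measured curves the smallest
rate must be ≥ λ_phys(1 − 10⁻³), with λ_phys = ln 2 / 159.528 h (Lu-177
half-life 6.647 d; configurable — some sources round to 6.7 d): tissue
cannot shed measured activity more slowly than the nuclide decays, and
the bound keeps tail extrapolation finite. One negative amplitude is
allowed so an uptake phase A(e^(−λ₁t) − e^(−λ₂t)) can be expressed; the
fitted curve must be non-negative on a dense grid over [0, 1.2·t_last].

**Fitting.** Weighted (default: unweighted; optional 1/value) least
squares via variable projection: the optimizer searches log-rates only,
amplitudes are solved linearly at every step, and the winning start is
polished over all parameters. Starts come from a fixed log-spaced grid of
rates (pairs of grid nodes for two terms), so fitting is fully
deterministic — identical inputs give identical models, and rescaling
the data rescales amplitudes exactly (the curve is normalized by its
maximum before fitting). No random state exists anywhere in the fit.

**Model order.** One or two terms are tried (three only with ≥ 7 samples;
free parameters never exceed the sample count — five imaging points
cannot support more). Selection uses a small-sample-corrected AIC. With
n = 5 and k = 4 the textbook correction term 2k(k+1)/(n−k−1) diverges, so
the denominator is clamped at 1 and the SSE is floored at the numerical-
noise level; ties prefer fewer terms. Consequences: noiseless
single-exponential data yields one term, noiseless biexponential data
two; on curves that are truly mixtures of more than two exponentials the
strong k = 4 penalty can select a single term whose tail extrapolation is
biased. For the directly measured source regions this stays within the
tolerances the tests assert; see "Limitations" for the remainder region.

**t = 0 and fallback.** The fitted model is evaluated from t = 0 (uptake
terms handle the rise; bisphosphonate uptake is fast but not
instantaneous). If no start converges to an admissible model, the fit is
flagged and the hybrid rule is used (policy `auto`, the pipeline
default): linear rise from (0, 0) to the first sample, trapezoid across
the samples, physical-decay tail A_last/λ_phys.

## Source-organ construction

- Red marrow from blood: A_rm = AC_blood × RMBLR × 1500 g / 1.05 g/mL,
  with RMBLR = 1.0 by default (conservative for Lu-177 therapy;
  configurable).
- Leg scaling: skeleton and total-body segmentations exclude the legs
  (33.6% of bone mass), so both are multiplied by 1/0.664 = 1.506. The
  factor applies only to these two regions.
- Skeleton split: cumulated skeletal activity is assigned 80% to the
  cortical and 20% to the trabecular bone mineral surface. The split is
  applied pointwise on the curve, which is equivalent (fitting is
  scale-equivariant) and keeps each surface a proper curve object.
- Remainder of body: total body minus skeleton, kidneys, bladder
  content, red marrow and lesions, after linear interpolation onto the
  imaging grid (five points; splines would overfit). Negative differences
  — possible with segmentation noise — are clamped to zero and logged.
- Lesions are subtracted from the remainder in all cases because they are
  explicitly modeled regions. The `tumors_in_bone` option additionally
  adds lesion activity back into the skeleton before the 80/20 split:
  the skeleton VOI excludes tumor voxels, but bone metastases do sit in
  bone and cross-irradiate the marrow, so the default (off) tends to
  underestimate the marrow dose; on enables the bounding variant.
- Masses: tumors at cortical-bone density 1.92 g/mL; total kidney mass
  from the CT volume at 1.06 g/mL, used to rescale the kidney self-dose.
- Bladder content is integrated like any other region; no voiding model.

## Dose engine

D(target) = Σ_source τ(source) · S(target←source), reported as Gy/GBq
(≡ mGy/MBq). Patient-specific organ masses rescale the self-dose term by
reference_mass/patient_mass (first-order correction; cross-terms
untouched). Equivalent dose equals absorbed dose (radiation weighting 1
for β/γ), so the tissue-weighted effective dose is in mSv/MBq on the same
numerical scale before weighting.

S-values are configuration, not code. The packaged matrix is an
illustrative construction from the Lu-177 electron mean energy per decay
(Δ ≈ 0.085 Gy·g/(MBq·h)) and simple absorbed-fraction reasoning; it is
labelled non-authoritative and is not a reproduction of any published
phantom engine. Doses are exactly linear in each residence time and in
the matrix, so swapping in a validated matrix changes doses linearly and
nothing else.

The tumor sphere model is electron-only by default: D = τ·Δ·φ(m)/m with
φ(m) log-log interpolated between table nodes and clamped outside the
range. For Lu-177-sized spheres the electron term dominates; a photon
component can be expressed by adjusting Δ and φ via configuration.

## Planning arithmetic

Per-organ maximum tolerated activity = limit/dose, with default limits
2 Gy (red marrow), 23 Gy (kidneys), 10 Gy (bone surfaces). The MTA is the
minimum; organs with zero dose are excluded with a warning instead of
silently reporting an infinite MTA; exact ties resolve in the fixed order
red marrow, kidneys, bone surfaces. Therapeutic index = mean tumor dose /
organ dose, computed for red marrow and bone surfaces (kidney doses are
typically too low to be informative). RMBLR sensitivity is closed-form:
only the blood-derived self-fraction f of the marrow dose scales with the
ratio, so the percent change is −100·f·(1 − r_new/r_ref); with f = 0.30
and 1.0 → 0.36 this is −19.2%.

Cohort tables use the midpoint median and, by default, the population SD
(denominator n) — the convention that matches published dosimetry
cohort tables of this kind; sample SD (n−1) is available via `ddof=1`.
Report tables round half away from zero: one decimal for GBq, three for
Gy/GBq (so a median MTA of 5.95 GBq prints as 6.0).

## Synthetic data

Each compartment (skeleton, kidneys, bladder content, soft-tissue
remainder; lesions as sub-volumes of the skeleton) follows measured-
activity kinetics A(t) = A_inj·f·(1 − e^(−k_u t))·e^(−(λ_phys+k_b)t);
blood is a biexponential concentration. All integrals exist in closed
form and are returned as ground truth, so recovery can be asserted
end-to-end. Defaults are calibrated to the magnitudes such cohorts show:
skeletal uptake peaking near 9.6×10⁻³ %IA/g at ~2 h (5500 g bone), blood
≈ 1.4×10⁻³ %IA/g (marrow-equivalent) at 1.5 h and ≈ 9.7×10⁻⁵ at 24 h,
lesions ≈ 2.1×10⁻² %IA/g at 6 h with ≈ 1×10⁻² retained at 170 h,
injected activity Normal(5780, 329) MBq across a cohort. Renal uptake is
near zero by default, with a `high-kidney` preset (10× fraction) for the
minority of patients with visible renal retention. Sampling uses the
nominal protocol schedules (SPECT 1.5/6/24/48/170 h; blood 5/15/30 min +
1.5/6/24/48/170 h); jitter within the acquisition windows is off by
default for reproducibility.

Noise is multiplicative lognormal, mean-corrected (E[multiplier] = 1),
applied per sample from a seeded generator; cohort parameters are
jittered lognormally (≈25% on skeletal uptake, ≈50% on lesion
concentration, broader on kidneys) with per-patient seeds derived from a
master seed via a SeedSequence, so reruns are bit-identical.

What the generator does **not** emulate: image formation (no partial
volume, scatter, reconstruction bias), patient motion, lesion-shape
effects, urinary voiding, or inter-time-point registration error.
Passing recovery tests therefore demonstrate correctness of the fitting
and integration chain under the stated noise model, not robustness to
SPECT systematics.

## Numerical choices

- Fit tolerances: optimizer ftol/xtol/gtol 10⁻¹² (10⁻¹⁵ in the polish);
  admissibility checked on a 400-point grid with a −10⁻⁹·scale slack.
- Degenerate inputs: all-zero curves return a flagged zero model that
  integrates to 0; curves with fewer than two samples are rejected.
- Zero-dose targets report flagged zero contribution fractions rather
  than dividing by zero.
- Half-way rounding in report tables snaps values within 10⁻⁹ of a
  rounding boundary before flooring, so 5.949999… (a float artifact of
  (5.8 + 6.1)/2) still prints as 6.0.

## Limitations

- The derived remainder region is only observable at the five imaging
  times. Roughly 2% of its true time-integral (the blood-pool fast phase)
  lies before the first scan at 1.5 h and is invisible to any estimator,
  so its recovery is verified at a looser 5% bound than the ≤1%
  asserted for directly sampled regions. Its dose contribution is small.
- With five samples, model order is capped at two exponential terms;
  curves that are genuinely richer mixtures (remainder, total body) incur
  small extrapolation bias, as discussed under "Model order".
- The packaged S-matrix, sphere table and tissue weights are
  illustrative; absolute organ doses and effective doses are only as good
  as the configured tables. Between validated engines, published
  red-marrow doses differ by tens of percent, which is why the matrix is
  data, not code.
- Cross-fire from lesions to organs other than via the `tumors_in_bone`
  skeleton route is not modeled; lesion doses are self-dose only.
- No biologically effective dose, multi-cycle scheduling, or
  tumor-control modelling.
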