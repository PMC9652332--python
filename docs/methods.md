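# Methods

This note records the models behind each module, the defaults and why
they were chosen, and what the synthetic fixtures do and do not emulate.

## Spectral dosimetry

Spectra are sampled wavelength→value curves interpolated linearly inside
their support and defined as **zero outside it** — an emission spectrum
has physical bounds and extrapolation would invent light. The spectral
efficiency of a source S against an absorber A, relative to a laser line
at λ_ref, is

    ε = [∫S(λ)A(λ)dλ / ∫S(λ)dλ] / A(λ_ref),

the absorption-weighted mean of the source normalised to the absorption
at the reference line. ε ≤ 1 whenever A(λ_ref) is the maximum of A over
the source support, and ε → 1 as the source collapses onto the line. The
powermeter correction has the same form with the responsivity R in place
of A; it is applied to the irradiance **reading** (reading → true
irradiance, dividing by the correction) *before* any fluence is
integrated, so effective dose = fluence × ε only ever sees corrected
irradiance. The reference laser is treated as an exact line rather than
its narrow measured spectrum, matching the normalisation to A(λ_ref).

Integration runs on the union grid of all input samples, restricted to
the source support, with a per-interval Simpson rule. Between two knots
every factor is linear, so the integrand — a product of two spectra,
optionally weighted by λ for the photon-counting variant — is a
polynomial of degree ≤ 3, which Simpson with the interval midpoint
integrates *exactly*; a plain trapezoid on the same grid would be exact
for each factor but not their product. The energy-weighted form is the
default; `weighting="photon"` weights each integrand by λ (photon number
∝ power × λ). On the synthetic fixtures the two differ by well under 2 %,
and no claim is made about which a given published figure used.

FWHM extraction linearly interpolates the outermost half-maximum
crossings around the global peak. Real LED spectra carry measurement
ripple, so secondary local maxima with prominence below 5 % of the peak
are ignored; anything larger raises as multimodal, as does a flat curve.

## PWM irradiance control

With a carrier at f_c and DAQ output samples at f_s, each period holds
N = f_s/f_c samples (the rates must divide evenly), so the representable
duty cycles are k/N, k = 1…N — at the default 250 Hz / 5 kHz, twenty
levels in 5 % steps. Irradiance is linear in duty; the calibration is a
least-squares line with free intercept through measured
(duty, irradiance) points, with a lookup-table mode for hardware whose
phototransistor-style saturation bends the top of the range. A target
irradiance maps to the representable duty with the nearest calibrated
value; **ties break toward the lower duty**, because under-dosing is the
safer failure mode in a cytotoxicity assay.

Exposure time is t = dose/irradiance, *not* re-quantised to whole PWM
periods: the residual sub-period dose error is bounded by one carrier
period of irradiance (≤ 0.4 mJ/cm² per visit at 100 mW/cm² and 250 Hz)
and is reported in the plan metadata instead of silently rounded.
Exposures are computed against the *achieved* (quantised) irradiance, so
each visit delivers its requested dose exactly while the
requested-vs-achieved irradiance difference is surfaced per visit.

## Plate automation

Plate geometry follows the ANSI/SLAS standards (9.0 mm pitch for
96-well, 19.3 mm for 24-well) — the underlying instrument never states
plate dimensions, so these are the field's defaults. Wells are indexed
0-based internally with the "A1" convention only at parse/serialize
boundaries. The canonical dose-response layout packs 16 groups × 6
replicates onto a 96-well plate: two treatment series over the dose
ladder 2–12 J/cm² plus DNL/LND/NDNL/MO controls, each group a 2×3 block.
The two series are *staggered* so equal-dose groups never occupy
adjacent blocks; layout validation enforces this (along with
disjointness, replicate counts and control presence), because a plate
misaligned by one group pitch then produces a visibly scrambled curve
rather than a plausible wrong one.

Motion planning rounds each axis displacement to whole 25 µm steps
(residual ≤ 12.5 µm, far below the instrument's measured placement
spread) on two independent axes. The printed 25 µm/step coexists with a
5 mm-pitch/400-step screw (12.5 µm), so step size is configuration, not
physics. Visit order is row-major by default and configurable; the
light-with-no-drug control is appended at the maximum treatment dose, as
standard PDT controls require. Planning with an empty dose map yields a
valid controls-only plan with no illumination visits.

## Sensor circuits and the electrical budget

Both on-board sensors sit in voltage dividers (5 kΩ fixed for the
thermistor, 10 kΩ for the phototransistor) across 12 V, oriented sensor
on the supply side so output **rises** with temperature or light — the
orientation is a design choice exposed in the circuit config. The NTC
uses the beta model R(T) = r0·exp(β(1/T − 1/T0)) with config-exposed
defaults r0 = 10 kΩ at 25 °C, β = 3950 K (commodity-thermistor values;
the deployed board's constants are not public). Divider and beta model
are both analytically invertible, so voltage→temperature round-trips to
numerical precision, and a β fit from ≥ 3 synthetic calibration points
is a log-linear regression. The phototransistor calibration is a linear
fit whose worst residual is reported in optical-power units — the
bounded-error contract a saturating sensor must satisfy.

The budget model: total current = parallel branches × LED current
(5 × 0.6 A = 3 A), series voltage = 5 × 2.4 V = 12 V, lead resistance
ρL/(wh) with copper ρ = 1.68×10⁻⁸ Ω·m, and the trace cross-section
mapped to the nearest standard AWG gauge by area (ties toward the
thinner gauge). Lead length is a config input; 222 mm reproduces a
0.04 V drop at 3 A (~0.3 % of the series voltage).

## Irradiance field

Each LED is a radially symmetric emitter with Gaussian angular intensity
I(θ) = I₀·exp(−ln2·θ²/θ_h²), normalised over the hemisphere so the
profile carries the emitter's optical power (520 mW), with
inverse-square falloff and cosine obliquity at the sample plane. The
default half-intensity half-angle is 12° — reading the catalogue's "24
degrees" as a full cone — and is config-exposed. The 5×5 array spans
33 mm edge-to-edge (pitch 33/4 mm, an assumption; only the extent is
documented). The Fresnel lens + diffuser is *not* ray-traced: its effect
is absorbed into the effective angular profile plus a transmission
factor, which `EmitterArray.calibrated()` scales so the peak field
matches 400 mW/cm² at full duty. Plane-integrated power is conserved to
better than 2 % on a sufficiently wide grid, and masked fields can only
lose energy.

The 3×3 uniformity metric is 100·(centre − min(corners))/centre over
per-well disc means. Simulation shows the metric is **not** monotone in
the emitter half-angle: narrow beams leave per-LED hot spots, wide beams
spill power past the block and leave it centre-heavy, so there is an
interior optimum (near 10° for the default geometry at z = 25.4 mm).
The tests therefore assert the interior optimum and the robust ordering
— the LED array is flatter than a matched circular-Gaussian laser beam
(default waist 50 mm, config-exposed since no beam radius is public) —
rather than any particular printed percentage, which would require the
actual optics.

## Thermal model

Sample heating is a single Newtonian compartment:
T(t) = T∞ − (T∞ − T_env)e^(−t/τ) with T∞ = T_env + gain(I)·I. The
measured steady-state rises (15.6 °C at 100 mW/cm², 28.8 °C at
200 mW/cm² from 20.2 °C) are *not* proportional to irradiance, so gain
is a per-irradiance table interpolated linearly and clamped at its ends,
reproducing the observed asymptotes exactly by construction. τ is not
directly reported anywhere; the default anchors it to the observed 37 °C
crossing 780 s into a 200 mW/cm² run, giving τ = 780/ln(28.8/12) ≈ 891 s.
All τ-dependent outputs are model-relative and labelled as such.

`time_to_threshold` is the closed form τ·ln((T∞−T_env)/(T∞−T_thresh)),
returning 0 below ambient and infinity ("never") when T∞ never reaches
the threshold — at 100 mW/cm², T∞ = 35.8 °C < 37 °C, so typical-power
PDT cannot overheat. `max_safe_plan` scans the duty-quantised irradiance
ladder downward; its default criterion is the temperature at the end of
the finite exposure (short high-power exposures can be safe), and
`criterion="steady_state"` gives the conservative sustained-illumination
answer (highest level ≤ 100 mW/cm² for a 37 °C threshold on the default
calibration). The distinction matters because with τ ≈ 15 min a
12 J/cm² dose at 400 mW/cm² lasts only 30 s and heats the sample ~2 °C.

## Dose-response analysis

Viability anchors to the plate's own controls
(v = 100·(raw − mean MO)/(mean NDNL − mean MO)), which makes the
normalised values invariant to any affine rescaling of the raw
luminescence. The 4PL is fitted by nonlinear least squares with EC50
parameterised as log₁₀EC50 (positivity built in, numeric Jacobian);
initial guesses take top/bottom from the extreme-dose means, EC50 from
the interpolated 50 % crossing in log dose, and h = 1. Top and bottom
are free by default (the "variable slope" model); a constraint flag pins
them to 100/0. A negative fitted slope is renormalised to the canonical
orientation (top = low-dose asymptote). Flat responses and fewer than 4
distinct nonzero doses raise instead of returning a meaningless EC50.
Standard errors come from the fit covariance; the EC50's is propagated
from the log-scale parameter. Effective EC50 = EC50 × ε, with ε = 1 for
laser data.

## Virtual rig and fixtures

The simulator executes a plan on a virtual clock (no wall-clock sleeps):
move both axes simultaneously at a configured step rate, optional
settling dwell (default 0 s), then illuminate, sampling the sensors at a
configured rate with seeded Gaussian noise (0.1 °C thermistor,
1 mW/cm²-equivalent photosensor). Fluence accounting is exact by
construction — each well of the visit's open aperture receives achieved
irradiance × on-time, and no light is emitted during motion — so the
conservation checks are identities, not approximations. The sample
temperature relaxes toward T∞(I) while lit and toward ambient otherwise.
A noise-free thermal projection of the whole plan gates execution behind
a 37 °C interlock (overridable); targets outside the travel range abort
with a partial log. Identical seeds and plans give identical logs.

The fixture generator emulates: a slightly asymmetric LED emission
peaked at 690 nm with half-maximum crossings at 676/702 nm plus 0.2 %
measurement ripple; a photosensitizer Q-band of ~10 nm FWHM at 690 nm on
a weak sloping baseline; a near-flat (3 % tilt) powermeter responsivity;
a 20-point duty calibration with ~1 % top-end saturation droop and
seeded read noise; and plate-reader tables where viability follows a 4PL
ground truth with multiplicative measurement noise (default 5 % CV) and
optional per-well dose jitter. It does **not** emulate spatial dose
gradients within a well, photobleaching, oxygen depletion, plate-edge
evaporation effects, or inter-plate batch variation — so passing tests
demonstrate the correctness of the computational chain under the stated
noise model, not biological generality.

## Problem sizes and numerical choices

Default test/analysis sizes: spectra on 0.25 nm grids (~720 samples);
field simulations on 181×181 grids over ±45 mm; the replicate-fit
ensemble uses 200 seeded 6-dose × 6-replicate plates; the thermal
recovery check uses 60 points at 0.2 °C noise. Degenerate inputs raise
with named conditions (flat spectra, non-monotone calibrations,
inverted controls, zero-area traces, out-of-range voltages). All
randomness flows through `numpy.random.default_rng` seeds; nothing reads
global RNG state.
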