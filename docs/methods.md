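# Methods

This note documents the models behind `flowspec`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical choices that affect results.

## Optical forward model

Absorbance through the flow cell follows Beer–Lambert:
A(λ) = Σ_d ε_d(λ)·C_d·L with ε in mL·µg⁻¹·mm⁻¹, C in µg/mL and L in mm,
and normalized transmission I/I0 = 10^(−A). The cell geometry defaults to the
Z-flow cell values: L = 10 mm path, 26 µL internal volume.

The true absorptivity spectra of Erioglaucine and Tartrazine are not publicly
tabulated, so each dye is synthesized as a Gaussian band (σ = 30 nm) centred
on its known peak (EG 631 nm, TZ 424 nm) plus a weak secondary band at the
*other* dye's peak (2% of the EG amplitude at 424 nm, 3% of the TZ amplitude
at 631 nm, σ = 45 nm). The secondary bands exist to make the cross terms of
the unmixing problem nonzero — with pure Gaussians 207 nm apart the cross
absorption would be numerically zero and the two channels would decouple,
hiding any error in the joint solve. Peak amplitudes (EG 0.0048, TZ 0.0012)
are set so each syringe stock attenuates its own channel to I/I0 ≈ 0.06,
a strongly attenuating but non-opaque working range for calibration.

The wavelength grid is 350–700 nm at 0.5 nm (the compact spectrometer's range
and resolution class). "Intensity at a wavelength" means the nearest grid
pixel by default; a ±band mean is available (`band_half_width`). The pixel
convention was chosen over band averaging because the grid step already
matches the instrument line width, and because averaging intensities over a
band introduces a small convexity (Jensen) bias relative to the log-linear
model that the exact 2×2 solve does not represent; with pixel sampling the
inversion is the exact algebraic inverse of the forward model.

Detector noise is multiplicative Gaussian per wavelength with relative sd
0.005 (0.5%) by default, clipped at zero. No instrument noise model is
published for this setup; 0.5% is a typical short-integration CCD figure and
is the single knob controlling measurement noise throughout the package.

## Calibration

The single-exponential calibration I/I0 = a·10^(−b·C) + c (a > 0, b > 0,
c ≥ 0) nests ideal Beer–Lambert behaviour (a = 1, c = 0, b = ε·L) and allows
a stray-light baseline c. Fitting uses bounded least squares with a
deterministic initialisation: a = 1, c = half the smallest observed I/I0, and
b from a log-linear regression of (I/I0 − c) on C. A fitted curve must be
strictly decreasing over the data range, and its blank-end prediction must be
a physical transmission (≤ 1 plus a 2% fit-noise allowance); otherwise the
fit is refused rather than silently inverted. Inversion is closed-form;
measured values outside the curve's predicted range by more than a tolerance
(default 0.005 in transmission units, the noise scale) are errors, within it
they clamp to the boundary. Calibration points with I/I0 > 1 are flagged
(warning + `suspect` attribute), never clipped.

## Two-dye unmixing

With one measurement wavelength per dye, the absorbance-space system
A_w = Σ_d K[w][d]·C_d, K[w][d] = ε_d(λ_w)·L, is square and solved exactly;
the implementation accepts n dyes × n wavelengths. The matrix is rejected as
degenerate above a condition number of 1e8. Negative solutions are screened
by a floor of 0.5% of each dye's stock concentration — small enough to catch
genuine model violations, generous enough for roundoff — plus, when the
caller declares the detector noise level, a 5σ allowance for propagated
measurement noise (multiplicative intensity noise of relative sd s produces
absorbance noise ≈ s/ln 10 per channel, mapped through the rows of K⁻¹).
The noise allowance matters in practice: near the blank, per-sample
concentration noise for EG is ≈ 0.045 µg/mL, so over an hour-long run at 1 Hz
the strict 0.125 µg/mL floor alone would be crossed by routine noise.
Negatives within the floor clip to zero; beyond it they raise
`inconsistent_intensities`.

## Infusion-line digital twin

Junction mixing is instantaneous and volumetric: C_d = Q_d·C0_d/Q_tot.
Transport from manifold to cell is a tanks-in-series chain: n ideal mixed
volumes of V/n each (default n = 5), updated explicitly at the detector
sampling interval with a stability guard (the step must not exceed half the
smallest tank residence time, else `unstable_timestep`). n = 1 is a single
mixing chamber; a plug-flow option provides the pure-delay limit (the cell
sees fluid that entered exactly one dead volume of pumped throughput
earlier), useful for analytic tests. The dead volume defaults to 1.0 mL —
the order of a manifold plus catheter lumen; it is a configuration field,
not a measured value, and transient shapes depend on it directly.

The line starts filled with saline (zero dye) and pumps start at t = 0.
Fluid density is fixed at 1.0 g/mL (dye mass fractions are ≤ 1e−4).
Cumulative outflow mass is integrated exactly for the piecewise-constant
schedules; the balance readout adds Gaussian noise (default sd 1e−5 g, the
order of the instrument's 0.01 mg sensitivity) and quantizes at 1e−5 g with
round-half-even. Trial-to-trial variation is measurement noise only
(independent seeds spawned from the master seed); pump-rate errors are not
modelled.

## Inference

Total flow is a centred finite difference of balance mass over a window
(default 30 s) divided by density, with an optional moving average of the
same width; the multi-sample window is needed because quantization, not
noise, limits the derivative at low flows. Decreasing mass beyond 1e−4 g
sets a warning flag rather than failing. The saline fraction is
1 − (C/C0)_EG − (C/C0)_TZ; values below −0.01 raise
`mass_balance_violation`, which is the expected signature of the transient
regime where dead-volume lag makes flow inference invalid. Per-stream flows
Q_i = (C/C0)_i·Q_tot sum to Q_tot exactly because saline is computed as the
remainder.

Steady-state statistics are computed per time point across trials: SEM =
sample sd/√n, accuracy = |expected − cross-trial mean|; the report carries
the maxima over the steady window. The window defaults to the last 5 min of
each phase (no canonical choice exists; the lag analysis below shows the
residual transient there is ≪ the 0.005 fraction tolerance used in tests).

## Validation programmes and problem sizes

Presets `exp_a` (1.5/0.5/1 mL/h for 60 min), `exp_b` (7/3/3 then 3/7/3 at
15 min, ending 35 min) and `exp_c` (the TZ-side mirror) encode the packaged
validation schedules, with expected fractions self-checked against
Q_d/Q_tot at load (displayed at three decimals below 0.2, two above —
matching how such fraction tables are conventionally printed). Full-length
runs at the 1 s default sampling are 2101–3601 samples and run in well under
a second, so tests and the acceptance script mostly use full scale; a
`fast` mode scales all times and the dead volume by 0.1, preserving the
dimensionless lag V/(Q·T), for interactive work. With V = 1 mL and
Q_tot = 3–13 mL/h the line time constant V/Q is 280–1200 s, so phase ends
sit 3+ time constants after the last change; the n = 5 Erlang residual there
is below 1e−3 of the step, which is why the noiseless pipeline recovers the
expected fractions to better than 0.005 absolute.

## What the synthetic data does not show

The generator emulates the *structure* of the bench system — spectra,
attenuation range, sampling, schedules, lag, balance — not its measured
noise magnitudes. Published accuracy/SEM figures for the physical rig
reflect that rig's optics, pump ripple and unreported line volume; passing
tests here demonstrate the correctness of the estimators and the
self-consistency of the method, not the absolute performance of any
hardware. Other known simplifications: no laminar-dispersion physics beyond
the mixing chain, no pump start-up transients or backflow, no stray-light,
drift or temperature effects in the optics, and solutes are assumed
exclusively localized one-per-syringe (mixtures in one syringe break the
saline-fraction closure by construction).
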