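# Methods

This note documents the models behind `ovclamp`, the parameters that matter,
the calibration of the presets, and the limits of what the simulations can
show about a real all-optical voltage-clamp rig.

## The plant: a minimal controllable cell

The controlled system is deliberately the simplest membrane model able to
reproduce the closed-loop behaviour of interest — the controllers, not the
biology, are the subject of the package.

Single compartment, explicit-Euler integrated with a fixed inner substep of
0.1 ms regardless of the camera period (stable for activation time constants
≥ 1 ms; halving the substep moves a 1 s trajectory endpoint by < 0.5%, which
the test suite asserts):

    C dV/dt = g_L (E_L − V) + I_dep + I_hyp + I_Ca + I_event + I_inject + I_noise

Each photocurrent is a first-order activation variable relaxing toward the
spectral drive with time constant `activation_tau` (7 ms in the presets),
multiplied by a normalized driving force `(V − E_rev)/(V_ref − E_rev)` that
equals 1 at the preset resting potential and reverses at `E_rev`. The
spectral drive is a Gaussian action spectrum times monochromator intensity,
plus a constant crosstalk term when the 637 nm imaging laser is on (the red
actuator is partially excited by the imaging light; the compensation
wavelength that re-zeros the net photocurrent at rest is the closed-loop
operating point and the start wavelength of every preset). Drives are capped
at 1. Depolarizing current is positive throughout.

### Preset calibration

The body-wall-muscle (bwm) channel parameters were fitted jointly (least
squares) to the system-level observables the presets are meant to reproduce:
a current–wavelength relation of slope ≈ −1.2 pA/nm spanning ≈ 190 pA
between 420 and 580 nm at rest (patch-clamp sign convention, inward
negative), a compensation wavelength of ≈ 520 nm with the laser on, a
≈ 16 mV hyperpolarization under 470 nm light from dark, a steady +5% ΔF/F₀
clamp wavelength near 550 nm, reachability of −5% above the 400 nm limit,
and near-uniform closed-loop wavelength spacing across the ±5% range.
The resulting constants (σ_dep 52 nm, σ_hyp 62 nm, peak currents 77/115 pA,
crosstalk 0.12, leak 2.7 nS, 20 pF) are recorded in `plant.make_preset`.

One deliberate departure from the textbook picture: the hyperpolarizer's
*effective* drive spectrum peaks at 430 nm rather than at the channel's
nominal 470 nm absorption maximum. With the peak at 470 the spectral
derivative vanishes exactly where the −5% clamp operates (≈ 475–485 nm),
collapsing the loop gain there and bending the wavelength–ΔF/F₀ relation,
which contradicts the near-linearity the system exhibits. The blue-shifted
effective peak restores a roughly uniform actuation slope; it should be read
as an effective spectrum of drive, not an absorption measurement.

Mutant presets modify the reference: *unc-13* lowers the leak conductance
(homeostatically raised excitability — the same depolarization needs less
red drive, hence a blue-shifted steady clamp wavelength); *egl-19(gof)* adds
a Boltzmann-gated L-type-like Ca²⁺ current (0.55 nS, V½ −15 mV, slope 4 mV)
whose threshold sits below the wild-type activation range, with the leak
reversal rebalanced so the dark resting potential is unchanged. The pharynx
and DVB presets differ in size, actuator strength and intrinsic events; the
mammalian preset rests at −75 mV with the anion-channel reversal 3 mV below
rest (hence the narrow hyperpolarizing range such cells show).

### Intrinsic action potentials

Spontaneous APs are injected as bi-exponential current waveforms (rise and
decay time constants), not regenerative channel models. The current
amplitude and decay constant are calibrated numerically at preset
construction so that the simulated *voltage* response — on the full plant
held at its compensation wavelength with the laser on, i.e. under the
photoconductance shunt of the imaging condition — matches the prescribed AP
amplitude and FWHM (pharynx: 57 mV, 150 ms, 15 ms rise at 4 Hz; DVB:
75.3 mV from rest, peaking at +26.3 mV, 359 ms, every 45 s). A pure
alpha-function cannot produce both the fast rise and the long plateau, hence
the bi-exponential.

The event current carries a voltage gate with a per-attempt latch: a
Boltzmann factor of the instantaneous voltage (V½ ≈ 8 mV below rest) that is
latched to its running minimum during the rising phase. Free-running, the
gate is ≈ 1 and the stereotyped waveform is unchanged; under dynamic
clamping, the controller's hyperpolarizing push during the rising phase
collapses the gate and the attempt is aborted for good. This is the minimal
stand-in for the all-or-none regenerative nature of real spikes — without
it, a prescribed current cannot be suppressed below roughly half of its
free-running amplitude at a 100 Hz control rate no matter how strong the
actuators, because the injected current simply persists. Events are
scheduled (periodic or fixed-interval), never threshold-triggered: light
pulses modulate the membrane and can coincide with events but do not
initiate them.

### Membrane noise

Physiological voltage fluctuations (EPSP-driven in muscle) are modelled as
an Ornstein–Uhlenbeck *current* whose stationary amplitude is parameterized
as the voltage SD it produces through the leak (`noise_sd`, mV) with
correlation time `noise_tau`. For the reference muscle, `noise_sd` is
calibrated so that a light-on, feedback-off recording shows a ΔF/F₀
fluctuation SD of 1.89% — the free-running fluctuation level of
indicator-only cells — and `noise_tau` is set to 900 ms, a slow
synaptic-drive timescale. Under closed-loop clamping the same noise is
suppressed to ≈ 0.5% SD. Note an honest tension: the real system reports a
clamped SD of ≈ 0.78% *and* 84% of time points within ±1%, a combination
slightly lighter-tailed than Gaussian (SD 0.78% alone would predict ~80%);
this plant cannot reproduce all three numbers at once, and the noise
calibration follows the free-running level, which is the prescribed
condition for the control-accuracy analysis.

## The sensor

Expected photon count per frame:

    N(V, k) = N₀ · (1 + s·(V − V_ref)/100) · B(k)/B(0),   B(k) = a·e^(−b·k) + c

with `s` the tissue fluorescence–voltage slope (% ΔF/F₀ per mV; 10/22 in
muscle, 10/65 in DVB, 0.21 in hippocampal neurons — an empirical constant
per tissue, reflecting the unknown membrane fraction of the indicator, not
modelled mechanistically). Bleaching is multiplicative on the whole signal,
which makes the ratio correction below exact. Camera output is Gaussian
shot noise `Normal(N, √N)` (valid at the ≥ 10⁴ photons/frame of every
preset) times a unit ADU gain, rounded to integer gray values. Defaults:
1.8 × 10⁶ photons per 10 ms frame (noise floor 1/√N ≈ 0.075%), bleach
amplitude/offset 0.3/0.7 with decay 0.002 per frame (≈ 30% signal loss over
a long recording).

## Bleach correction and ΔF/F₀

The calibration-phase gray values are fitted with `a·e^(−b·k) + c` by
nonlinear least squares (initial guesses: `c` last-decile mean, `a`
first-decile mean − c, `b` log-linear fit of the residual; non-convergence
falls back to a flagged flat fit, making the correction the identity and
surfacing a low R² warning). Every frame is multiplied by
`offset(0)/offset(k)`; R² = 1 − SSE/SSD is reported in the results header.
F₀ is the arithmetic mean of the first 50 corrected frames, computed at the
end of the calibration phase. Applying the generating parameters inverts the
bleach exactly (asserted to machine precision).

Two practical consequences the simulations expose: (1) events during the
calibration phase contaminate the fit (the pharynx preset routinely yields
R² < 0.8, and the warning says so); (2) with slow membrane noise, a short
calibration lets the noise leak into the fitted parameters, and the
extrapolated correction then drifts by up to a few percent ΔF/F₀ over the
clamp phase — the reason a ~20 s calibration is the default
(`ProtocolSpec.calibration_frames = 2000`) and shorter calibrations trade
accuracy for speed. The pooled control-accuracy analysis uses 800 frames
(8 s), a problem-size choice that keeps the pooled runs fast while leaving
the extrapolation bias well inside the tolerance band.

## Controllers

*Tolerance-band I-controller.* Error `e = |target − ΔF/F₀|` (the decision-tree
form keeps the magnitude and a separate direction sign);
inside the inclusive band the wavelength is held, outside it moves by
`K_I·e` nm per frame in the direction `increment_sign · sign(target − ΔF/F₀)`
and is clipped to the monochromator limits, with status holding / adapting /
limit-reached recorded per frame. `K_I` is an empirical per-tissue constant:
7 nm/% for the muscle presets (chosen so one correction roughly cancels a
band-edge error given the plant's ≈ 0.1–0.17 %ΔF/F₀ per nm loop slope —
"deadbeat" sizing; larger gains limit-cycle because of the one-frame
actuation delay), and 10 nm/% with a ±0.005% tolerance for the dynamic-clamp
presets, the most aggressive setting short of instability.

*PID.* Signed error, integral `e_sum` accumulated per frame with anti-windup
(frozen while the command is clipped — the original software does not state
its behaviour at the limits; freezing is standard practice), derivative on
the error difference. Ziegler–Nichols tuning ramps the proportional gain on
a geometric grid until the closed loop sustains oscillation (non-decaying
sign-alternating error), reads the period off the zero crossings, and sets
kp = 0.6·kp_crit, Tn = 0.5·T_crit, Tv = 0.12·T_crit, K_I = kp/Tn,
K_D = kp·Tv. At a 100 Hz loop the critical period sits near two frames
(the delay-dominated limit), so the tuned loop retains visible ringing —
consistent with the observation that the PID variant does not outperform
the simpler I-controller here.

*Kalman filter.* Scalar, A = H = 1, standard predict/correct; initialization
x̂₀ = first calibration ΔF/F₀, p₀ = r. Its stationary prior variance solves
p* = (q + √(q² + 4qr))/2 (algebraic Riccati fixed point), asserted in tests.

*Session loop.* One controller update per camera frame (the sampling-rate-
limited regime of the real system); the commanded wavelength takes effect on
the next frame's plant integration, i.e. a one-frame actuation delay, with
the ~100 µs monochromator latency itself neglected. Runs are deterministic
for a given seed down to byte-identical results files.

## Calibration statistics and synthetic experiments

`fit_calibration` is OLS with HC0 (White) heteroscedasticity-consistent
standard errors and the White test in its standard auxiliary-regression
form. The packaged default conversion lines are the reference calibration
constants (mV = −30.27 + 2.25·ΔF/F₀; pA = 607.06 − 1.21·λ).

The synthetic calibration experiments mirror the simultaneous
optical/electrical measurements: the voltage calibration takes the
closed-loop fixed points of the reference muscle across −5…+5% targets
(found by inverting the plant's static light→voltage map) and adds
heteroscedastic cell-to-cell noise scaled to R² ≈ 0.8, matching the
reference fit quality; the current calibration evaluates the steady-state photocurrent
on a 420–580 nm grid at the resting potential (sign-flipped to the
patch-clamp convention) with noise scaled the same way. The generating
slopes are 2.20 mV/% and −1.28 pA/nm — within a few percent of the
reference 2.25 and −1.21 — and recovery within two robust standard errors
is asserted across 100 seeds.

`difference_iv` reports the *inferred additional intrinsic current* of one
pseudo-I/V curve relative to another: at each steady clamp step the
compensating photocurrent balances the intrinsic currents, so the extra
intrinsic current of curve *a* relative to *b* equals minus the photocurrent
difference, converted through the calibration lines and normalized by
capacitance. A cell with a gain-of-function inward conductance therefore
shows an inward (negative) difference at depolarized steps — the purpose of
the measurement is extracting exactly that channel current.

AP detection finds peaks by prominence, takes the amplitude above the local
prominence baseline, interpolates the half-maximum crossings linearly for
FWHM, and fits the rise time constant on the 10–90% rising flank (the exact
fit window is a package choice; none is prescribed). For
spontaneous-versus-clamped amplitude comparisons,
`aligned_event_amplitudes` measures at known event times against a
pre-event baseline, which is robust to the slow bleach-extrapolation drift
that inflates prominence-based amplitudes on long traces.

## Problem sizes

Defaults were chosen so everything runs on one CPU in seconds: the pooled
control-accuracy analysis uses 20 seeded four-step runs of 8 s calibration +
8 s clamping at 100 Hz (16,000 pooled clamp frames); calibration-regression
recovery uses 100 seeded experiments of 80 and 72 observations; dynamic
clamp suppression uses 10 s pharynx recordings. The full test suite runs in
about half a minute and the acceptance script in under ten seconds.

## What passing tests do and do not show

The synthetic generator emulates: linear indicator response, shot-noise-
limited counting, single-exponential bleaching, first-order actuator
kinetics with overlapping spectra, laser crosstalk, slow membrane noise and
stereotyped spontaneous APs. It does not emulate: actuator inactivation and
photocycle intermediates, irradiance nonlinearity, two-component bleaching,
spatial/ROI effects, movement artefacts, cell-to-cell variability in
resting potential, or genuinely regenerative spiking (the latched gate is a
caricature). Results here therefore validate the control and analysis
software and the internal consistency of the reference observables — not
the biology; quantities tied to animal-derived absolute scales (transition
times in ms, absolute AP amplitudes per tissue) are checked as orderings and
ratios, not absolute values.
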