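# Methods

This package is a hardware-free reimplementation of the software side of a
preclinical MR-guided focused ultrasound (MRgFUS) therapy system: PRF-shift
MR thermometry, CEM43 thermal dosimetry with automatic shut-off, a
constrained PID controller closing the loop between focal temperature and
transducer drive voltage, MR-ARFI displacement reconstruction, and a
"virtual rig" — a Pennes-bioheat plant plus synthetic scanner — that stands
in for the magnet, transducer, and animal so the whole loop can be exercised
and validated on a desk.

## PRF-shift thermometry

The water proton resonance frequency shifts with temperature by
alpha ≈ −0.01 ppm/°C, so between two gradient-echo acquisitions

    ΔT = Δφ / (2π · γ · α · B0 · TE),

with γ = 42.576 MHz/T. Both constants are config-overridable; the defaults
are the standard literature values. Δφ is taken as the angle of the
complex-conjugate product of the current and baseline frames, which cancels
each frame's absolute phase offset and avoids the spurious wraps of naive
angle subtraction. At 4.7 T and TE = 10 ms one degree is 0.126 rad, so
hyperthermic rises (≤ 12 °C) stay well inside one phase cycle; per-pixel
temporal unwrapping is implemented but off by default.

Pixels whose baseline magnitude falls below 10 % of the image's
95th-percentile magnitude are masked invalid — they are air/noise pixels
that otherwise display spurious heating. Scanner field drift is removed by
subtracting the mean apparent temperature over an unheated reference ROI;
the subtraction is done in temperature units, which is equivalent to a
phase-space subtraction under the linear map above. The first one or two
frames of a stream are dummy scans (steady-state stabilisation) and are
skipped; the first retained frame is the baseline.

ROIs are given in mm and rounded to whole pixels (minimum one). The focal
ROI defaults to 2.6 mm × 3.2 mm, drift references to 4.6 mm × 4.6 mm.

## CEM43 dosimetry

Thermal dose is accumulated in cumulative equivalent minutes at 43 °C:
an interval dt at absolute temperature T contributes R^(43−T)·dt, with
R = 0.5 at or above 43 °C and R = 0.25 below (Sapareto–Dewey constants;
exposed in config since conventions vary). `baseline_body_C` (default
37 °C) maps the measured *rise* onto absolute temperature, so an in vivo
+6 °C set point sits exactly at the breakpoint. Dose is computed on the
drift-corrected focal mean — a scalar per frame, not a per-pixel map — and
the accumulator latches a `reached` flag at the configured threshold, after
which the commanded voltage is forced to zero for the rest of the run while
imaging and logging continue.

## Constrained PID control

The error e = setpoint − measured focal rise drives

    v = clip( Kp·e + Ki·∫e dτ + Kd·de/dt , 0 , v_max ),

discretised at the 3 s frame period with a rectangle-rule integral and a
backward-difference derivative (zero on the first controlled frame).
Defaults are the hand-tuned bench values Kp = 1e−3 V/°C, Ki = 1e−5 V/(°C·s),
Kd = 5e−3 V·s/°C, and v_max = 70 mV (pre-amplifier peak-to-peak) — a safety
clamp against cavitation, skin burns and transducer damage sitting far
above the drive hyperthermia needs. The lower clamp at 0 V reflects that
negative drive is physically meaningless. Anti-windup is by conditional
integration: the integral freezes while the output is clamped and the error
would push it further into saturation; without it, long saturated rises
overshoot badly. A non-finite temperature measurement (corrupt frame) holds
the previous voltage and leaves the controller state untouched.

The treatment loop consumes any iterator of complex frames (in-memory
generator, directory reader), so file-polling is an implementation detail
of the frame source. On stream end *or any exception*, a final zero-voltage
command is emitted to the generator sink before control returns — the
software equivalent of the bench system's automatic output kill.

## MR-ARFI reconstruction

A bipolar motion-encoding gradient (MEG) makes phase proportional to
displacement along its axis. Per MEG polarity, the FUS-off phase image is
subtracted from the FUS-on image, cancelling eddy-current phase exactly;
the two corrected maps are then subtracted and scaled:

    Δx = Δφ / (2 γ G l),

with γ in angular units (2π·42.576e6 rad s⁻¹ T⁻¹), G the lobe amplitude
(default 0.1 T/m, i.e. 10 G/cm) and l the single-lobe duration (4 ms of the
8 ms bipolar pair). The lobe is approximated as a rectangle, accurate for
trapezoids whose rise time (~52 µs) is small against the lobe. Focal-spot
metrics subtract the map median as a background estimate and read the FWHM
by linear interpolation between the half-maximum crossings of the two
in-plane profiles through the peak pixel, averaged.

## The virtual rig

The plant solves the Pennes bioheat equation

    ρc ∂T/∂t = k ∇²T − ρc·w·(T − T_a) + Q(x)

for the temperature rise T on a cell-centred finite-volume grid (default
12 mm cube, 0.5 mm cells) with zero-flux boundaries via mirror ghost cells.
Conduction and deposition are stepped explicitly, sub-stepped to the
stability bound dt ≤ h²ρc/6k (≈ 0.29 s at defaults); the linear sink w is
applied as an exact per-substep exponential factor, so a pure decay matches
its closed form to machine precision and the scheme is unconditionally
stable in w. With w = 0 the total thermal energy grows by exactly
gain·v²·dt — a bookkeeping identity the tests assert. The solution
converges at second order in h; halving the default spacing moves the
10-min focal rise by well under 2 %.

Q is a separable 3-D Gaussian with the transducer's ellipsoidal focal FWHM
(1.4 × 1.4 × 10 mm at 1.1 MHz, long axis along propagation), integrated
over each voxel (erf differences) so coarse grids see the same total power,
and normalised to gain·v²·duty watts: intensity scales with pressure
squared and pressure with drive voltage.

The synthetic scanner images the plane containing the beam axis, averaging
the field through a 3 mm slice — and, importantly, averaging over the whole
3 s frame period, as a real acquisition integrates over its TR window
rather than snapshotting the field. Temperature maps to phase through the
inverse PRF relation; spatially uniform drift (rad/s) and per-pixel complex
Gaussian noise are added, seeded per frame index from one run seed so every
run is bit-reproducible. The per-pixel phase noise of each preset is
derived from a target focal-ROI mean temperature std of 0.25 °C — the
thermometry precision a fiber-optic comparison of this class of system
reports — via sigma_phase = 0.25·√n_ROI·|dφ/dT|.

### Presets and calibration

Two shipped presets (TOML files under `mrgfus/data/`):

* **agar-phantom** — k = 0.6 W/m/K, ρc = 4.2e6 J/m³/K (agar is mostly
  water), lumped loss w = 0.005 s⁻¹ representing coupling of the small
  phantom to the water bath and bore. The source gain (1079.3 W/V²) is
  calibrated so a constant 10 mV drive settles the focal-ROI mean at +6 °C.
* **mouse-tumor** — same thermal constants with blood perfusion
  w = 0.01 s⁻¹ and a hotter coupling (5500 W/V², ≈ +6 °C at 5.2 mV):
  tumor tissue absorbs more strongly and the in vivo geometry couples more
  of the beam into the slice, which is what gives the fast initial rise and
  somewhat noisier steady state seen in animal runs.

The anchors were fixed once, as rig design, by requiring that the
*published* controller gains reproduce on this rig the closed-loop
phenomenology of the bench system they were tuned on: set points of 2–10 °C
reached within a few minutes, drive voltages levelling off in the ~10 mV
range far below the 70 mV clamp, initial overshoot under ~1 °C, and
steady-state precision near the reported 0.25–0.28 °C. With power ∝ v², an
anchor much above ~10 mV makes the integral term (Ki = 1e−5 V/°C/s) too
slow to reach any set point inside a 10-minute sonication; an anchor much
below ~5 mV makes the derivative term amplify measurement noise into
visible temperature ripple. The shipped values sit in the narrow band that
does both jobs; they were not adjusted afterwards.

A closed-loop run that never crosses its set point has no defined
"post-rise" window; the experiments module drops such runs from ensemble
statistics and reports the count. None occur at the shipped defaults.

### What the rig does and does not emulate

It reproduces the *control-relevant* physics: a distributed thermal plant
with realistic gain and time constants, measurement noise at the documented
precision, field drift, perfusion disturbances, and the exact acquisition
timing. It does not model acoustic propagation (no refraction, standing
waves, near-field structure), nonlinear absorption, cavitation, skin or
bone heating, motion/susceptibility artifacts, or tissue property changes
with temperature. Passing closed-loop tests therefore demonstrates that the
control software behaves correctly against a faithful *thermal* stand-in,
not that a particular animal would heat identically.

## Reference experiments

`mrgfus.experiments` encodes the two bench-validation protocols:

* **Set-point sweep** — 10-minute closed-loop phantom sonications at 2, 4,
  6, 8 and 10 °C, ten seeds each, fixed gains. Reported per run: initial
  overshoot (maximum excursion above the set point after the focal mean
  first crosses it) and the std / RMSE of the error over the post-crossing
  frames.
* **Disturbance rejection** — 12 minutes on the mouse-tumor preset at
  +6 °C with the perfusion coefficient doubled for 30 s at 4, 7 and 10
  minutes (emulating breathing-rate changes); reported: post-rise RMSE,
  transient dip depths, and whether the mean drive voltage rises during
  each disturbance window.

`scripts/acceptance.py` runs both from scratch and writes the summary
figures as JSON; `tests/test_acceptance.py` asserts the published bounds on
the same ensembles.

## Numerical and design notes

* The focal step response is bi-modal — a fast conductive transient
  (seconds) plus a slow bulk mode (1/w) — so a single-exponential fit from
  t = 0 cannot represent it; the lumped first-order characterisation in the
  tests fits from 60 s on, where the slow mode dominates, and recovers the
  steady gain within 5 %.
* Frame-series files store magnitude and phase as float64 NIfTI pairs;
  complex reconstruction is exact to rounding (~1 ulp).
* The PID integral advances by e·dt on the first controlled frame, with
  elapsed time measured from the baseline acquisition.
* Dose uses the same drift-corrected focal mean the controller sees; a
  non-finite mean skips the dose frame and holds the previous voltage.
* Determinism: one integer seed per run; frame k draws from
  `default_rng(seed + k)`, so logs are bit-identical across replays and
  independent of chunking.

## Known limitations

* Single-slice thermometry only; no fat-referenced, multi-baseline, or
  motion-robust reconstruction.
* The dose model is scalar CEM43 at the focal mean; no dose-volume maps or
  Arrhenius models.
* The PID runs at the frame period with no auto-tuning; gains appropriate
  for one plant may need retuning for tissues with very different
  properties, exactly as on the bench.
* Steady-state precision on the default rig averages ≈ 0.29 °C against the
  0.25 °C measurement-noise floor; the derivative term's amplification of
  frame-to-frame noise and the slow integral closure bound how much lower
  any setting of the rig can push this under the published gains.
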