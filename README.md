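# mrgfus

Closed-loop MR-guided focused ultrasound (MRgFUS) therapy software, fully
exercisable without hardware. The package implements the real-time software
chain of a preclinical small-animal MRgFUS system — proton resonance
frequency (PRF) shift thermometry, CEM43 thermal dosimetry with automatic
shut-off, a constrained PID controller for focal temperature, and MR
acoustic radiation force imaging (MR-ARFI) reconstruction — together with a
*virtual rig*: a Pennes-bioheat tissue plant, virtual transducer, and
synthetic MR scanner that close the loop for development, testing, and
method validation.

It is aimed at therapeutic-ultrasound and interventional-MRI researchers
who need a tested, scriptable reference implementation of the monitoring
and control loop — for controller development, protocol design, or as the
software half of a bench system whose frame source and generator interface
are swapped in behind the same APIs.

## The core loop

Per 3 s imaging frame, with baseline subtraction:

* temperature:  ΔT = Δφ / (2π γ α B0 TE), α = −0.01 ppm/°C, γ = 42.576 MHz/T;
  Δφ from the complex-conjugate product; ROI-based drift correction
* dose:  CEM43 += R^(43 − T) · Δt, R = 0.5 above 43 °C, 0.25 below
* control:  V_out = min{ Kp e + Ki ∫e dτ + Kd de/dt, V_max }, clamped at
  0 V below and latched to 0 once the dose threshold is reached
  (defaults Kp = 1e−3, Ki = 1e−5, Kd = 5e−3, V_max = 70 mV)
* ARFI:  Δx = Δφ / (2 γ G l) after on/off eddy-current correction

See `docs/methods.md` for the full model description, rig calibration, and
limitations.

## Worked example

A 10-minute closed-loop hyperthermia sonication at a +6 °C set point on the
built-in agar-phantom rig:

```bash
mrgfus simulate --setpoint 6 --duration 600 --seed 1 --out demo/
```

prints

```
frames=200 final_T=5.77 degC final_v=11.55 mV dose=3.47 CEM43 min shutoff=False
log written to demo/sonication_log.csv
```

meaning: 200 controlled frames were processed; the focal mean sits at
5.77 °C (the set point, within the 0.25 °C per-frame measurement noise);
the drive has levelled off at 11.5 mV — well below the 70 mV safety clamp —
and the accumulated thermal dose is 3.5 equivalent minutes at 43 °C, below
any shut-off threshold (none was set). The output directory holds the
per-frame CSV log (`timestamp_s, focal_mean_C, v_out, cem43_min,
shutoff_flag`), a temperature/voltage plot, and a provenance record with
the config echo and seed.

The same loop is available as a library:

```python
from mrgfus import PIDParams, load_preset, with_seed, run_virtual_sonication
from mrgfus.metrics import initial_overshoot, post_rise_stats

rig = with_seed(load_preset("agar-phantom"), 1)
log = run_virtual_sonication(
    rig.tissue, rig.source, rig.scanner,
    PIDParams(setpoint_C=6.0), duration_s=600.0,
    focus_roi=rig.focus_roi, dummy_frames=rig.dummy_frames,
)
print(initial_overshoot(log, 6.0), post_rise_stats(log, 6.0))
```

Other commands: `mrgfus treat` (run the controller over a frame series on
disk), `mrgfus recon-thermo`, `mrgfus recon-arfi`, and
`mrgfus make-phantom-series` (emit a synthetic series for offline testing).
Frame series are magnitude/phase NIfTI pairs with a JSON sidecar; configs
are JSON or TOML.

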