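# Graphite-agar phantom rig preset.
# perfusion_per_s is an effective loss to the surrounding water bath / bore.
# power_gain_W_per_V2 is calibrated so a constant 10 mV drive settles the
# focal-ROI mean at +6 degC on this grid (see docs/methods.md).

[tissue]
conductivity_W_mK = 0.6
vol_heat_capacity_J_m3K = 4.2e6
perfusion_per_s = 0.005
arterial_dT_C = 0.0
domain_mm = [12.0, 12.0, 12.0]
grid_mm = 0.5

[source]
focus_center_mm = [6.0, 6.0, 6.0]
fwhm_mm = [1.4, 1.4, 10.0]
power_gain_W_per_V2 = 1079.3
duty = 1.0

[scanner]
focal_noise_std_C = 0.25
drift_rate_rad_per_s = 0.0
slice_center_mm = 6.0
slice_thickness_mm = 3.0
frame_period_s = 3.0
te_s = 0.010
b0_T = 4.7

[rois]
focus_center_mm = [6.0, 6.0]
focus_size_mm = [2.6, 3.2]
drift_center_mm = [2.3, 2.3]
drift_size_mm = [4.6, 4.6]

[dose]
baseline_body_C = 37.0

[loop]
dummy_frames = 2
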