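# Murine-tumor rig preset: soft-tissue thermal properties with nonzero
# blood perfusion.  The deposited power per squared volt is higher than in
# the phantom preset (stronger tumor absorption / tighter coupling), giving
# the fast initial rise seen in vivo (see docs/methods.md).

[tissue]
conductivity_W_mK = 0.6
vol_heat_capacity_J_m3K = 4.2e6
perfusion_per_s = 0.01
arterial_dT_C = 0.0
domain_mm = [12.0, 12.0, 12.0]
grid_mm = 0.5

[source]
focus_center_mm = [6.0, 6.0, 6.0]
fwhm_mm = [1.4, 1.4, 10.0]
power_gain_W_per_V2 = 5500.0
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
focus_size_mm = [2.5, 2.5]
drift_center_mm = [2.3, 2.3]
drift_size_mm = [4.6, 4.6]

[dose]
baseline_body_C = 37.0

[loop]
dummy_frames = 2
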