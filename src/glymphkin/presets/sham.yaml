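# Base simulation parameters for the sham (uninjured) condition.
#
# Geometry: x increases anterior, y toward the animal's left, origin at
# bregma, mm.  The field spans x in [-6.4, 6.4], y in [-3.2, 3.2] at
# 0.1 mm/px (128 x 64 px), covering all analysis ROIs.  The injection site
# sits 1.6 mm posterior and 1.3 mm right-lateral of bregma (right lateral
# ventricle).
#
# Acquisition: 61 frames at 1 frame/min (t = 0..60 min), with imaging
# starting 15 min after infusion; the plume therefore evolves for a 15-min
# pre-roll before frame 0.
#
# Transport: anterior-directed bulk flow over the whole field — brisk in
# the anterior half, slow in the posterior half so the plume lingers near
# the injection level and keeps feeding the periventricular ROIs laterally.
# No flow magnitudes are available from in-vivo measurements; the values
# below are calibration choices that keep every ROI above threshold within
# the 60-min window with anterior influx latencies of minutes to ~15 min.
grid_shape: [64, 128]
pixel_size_mm: 0.1
origin_mm: [-6.4, -3.2]
bregma_mm: [0.0, 0.0]
frame_interval_min: 1.0
n_frames: 61
t0_offset_min: 15.0
pre_roll_min: 15.0
injection_center_mm: [-1.6, -1.3]
bolus_amount_au: 200000.0
bolus_sigma_mm: 0.6
diffusivity_mm2_min: 0.025
velocity_field:
  split_x_mm: 0.0
  anterior_mm_min: [0.08, 0.0]
  posterior_mm_min: [0.01, 0.0]
decay_rate_per_min: 0.002
background_level_au: 10.0
camera_gain_au_per_unit: 1.0
noise_sigma_au: 1.0
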