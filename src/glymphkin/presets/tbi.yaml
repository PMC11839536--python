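# Base simulation parameters for the injured (TBI) condition.
#
# Identical to the sham preset except for the velocity field: anterior
# transport is suppressed in the anterior half of the field and the
# posterior half carries a posterior-directed component, reproducing the
# slower-anterior / faster-posterior perfusion pattern after injury.
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
  anterior_mm_min: [0.03, 0.0]
  posterior_mm_min: [-0.03, 0.0]
decay_rate_per_min: 0.002
background_level_au: 10.0
camera_gain_au_per_unit: 1.0
noise_sigma_au: 1.0
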