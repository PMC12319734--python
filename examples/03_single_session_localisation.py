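"""Simulate one OPM session and localise the beta modulation.

Plants a subject with bilateral sensory sources, synthesises the session
(beta ERD/rebound + evoked responses + sensor noise), runs the
preprocessing and the LCMV pseudo-T contrast, and compares the image peaks
with the planted source positions.
"""

import numpy as np

from megfingerprint import build_array, build_source_space, compute_leadfield, sample_cohort_params, simulate_dataset
from megfingerprint.pipeline import RunConfig, process_dataset

cfg = RunConfig.desk_scale(seed=0)
opm = build_array("opm")
space = build_source_space(spacing_m=cfg.source_spacing_m)
lf = compute_leadfield(space, opm)

params = sample_cohort_params(1, seed=3)[0]
rec = simulate_dataset(params, opm, lf, n_trials=cfg.n_trials, subject="sub-01", run=1, seed=42)
print(f"session: {rec.data.shape[0]} channels x {rec.n_samples} samples "
      f"({rec.n_samples / rec.sampling_rate_hz:.0f} s)")

result = process_dataset(rec, lf, cfg)
print(f"channels removed by screening: {result.log['n_channels_removed']}, "
      f"stimulus epochs rejected: {result.log['n_stim_epochs_removed']}")
for side in ("left", "right"):
    true_pos = params.pos_left if side == "left" else params.pos_right
    peak = space.positions[result.peak_voxels[side]]
    err_mm = 1e3 * np.linalg.norm(peak - true_pos)
    print(f"{side} pseudo-T peak at {np.round(peak, 3)} m, "
          f"{err_mm:.1f} mm from the planted source")
# Errors of roughly half a voxel indicate the beamformer found the
# planted sensory sources from the early/late beta power contrast.
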