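"""Render a synthetic crystal video and recover its transition map.

Builds a 128x128 stack of a crystal transitioning around t = 75 s with a
spatial T1 gradient, then runs the ROI-size analysis: concentric square
regions, per-superpixel transition detection, and k-means classification
of the recovered times.
"""

import numpy as np

from sspt.pvm import cluster_t1, roi_size_sweep
from sspt.synthetic import SyntheticCrystalSpec, render_video

spec = SyntheticCrystalSpec(
    duration_s=240.0,
    t1_mean_s=75.0,
    t1_gradient_s_per_um=3.0,  # transition sweeps across the crystal
    noise_sd=2.0,
    seed=5,
)
stack, truth = render_video(spec)
print(f"rendered {stack.n_frames} frames of {stack.shape[1]}x{stack.shape[2]} px;"
      f" ground-truth T1 spans {np.nanmin(truth.values):.1f}-"
      f"{np.nanmax(truth.values):.1f} s")

summary, events = roi_size_sweep(stack, center=(64, 64), bin_px=2)
print("\nROI size sweep (concentric squares, boxcar 39, bin 2):")
print(summary[["roi_size_px", "roi_size_um", "n", "mean_t1_s", "sd_t1_s",
               "mean_hwhm_s"]].to_string(index=False, float_format="%.2f"))
print("\nsd(T1) grows with ROI size because a larger region spans more of "
      "the T1 gradient — the transition is less uniform over larger areas.")

ok = events[events["error"].isna() & (events["roi_size_px"] == 42)]
res = cluster_t1(ok["t1_s"].to_numpy(), k=2, seed=0)
cents = sorted(round(float(c), 1) for c in res.centroids)
print(f"\nk-means (k=2) on the 42-px ROI transition times: centroids at "
      f"{cents} s — the early- and late-transitioning halves of the gradient.")
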