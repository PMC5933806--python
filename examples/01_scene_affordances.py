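"""Render a synthetic indoor scene and recover its doorway directions.

Builds one scene with two doorways, simulates raters drawing walking paths
from the bottom center, bins the path mass into 180 one-degree angular bins,
smooths and z-scores the histogram, and compares the recovered peaks with
the planted azimuths (0 deg = rightward horizontal, 90 = straight ahead).
"""

import numpy as np

from navaff import SceneSpec, render_scene, simulate_rater_paths
from navaff.affordance import histogram_from_map

spec = SceneSpec(opening_azimuths=(55.0, 125.0), opening_widths=18.0, seed=7)
scene = render_scene(spec)
print(f"scene {scene.shape} with doorways at {scene.azimuths} degrees")

heat = simulate_rater_paths(spec.opening_azimuths, n_raters=32,
                            angular_noise_sd=8.0, image_size=spec.image_size,
                            seed=7)
hist = histogram_from_map(heat.values)

smoothed = hist.smoothed.copy()
peaks = []
for _ in range(2):
    b = int(np.argmax(smoothed))
    peaks.append(b + 0.5)
    smoothed[max(0, b - 15): b + 15] = -np.inf
print(f"smoothed histogram peaks: {sorted(peaks)} (truth: 55, 125)")
print(f"normalized histogram: mean={hist.normalized.mean():+.1e}, "
      f"sd={hist.normalized.std(ddof=1):.3f} across bins")
print("each peak marks a direction raters walk toward; the z-scored profile "
      "is the scene's affordance pattern used for RDMs")
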