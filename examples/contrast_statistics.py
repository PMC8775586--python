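"""First-order statistics of one synthetic upper-field scene.

Generates a two-channel scene, preprocesses it, and prints the Weibull
scale (beta) and shape (gamma) of the |LoG| local-contrast distribution per
channel and filter width, plus the median RMS contrast of each channel.
"""

import numpy as np

from mouseview import normalize_minmax
from mouseview.config import PipelineConfig
from mouseview.firstorder import contrast_weibull_per_scene
from mouseview.patches import chromatic_contrast, circular_patch_stats, fit_chromatic_weibull
from mouseview.pipeline import preprocess_scene
from mouseview.preprocess import SceneMetadata, estimate_projective
from mouseview.synthetic import make_control_points, make_scene_pair, study_params

params = study_params("up", seed=0, height_px=192, width_px=192)
raw_uv, raw_green, reference, truth = make_scene_pair(params)
src, dst = make_control_points(truth, 12, jitter_px=0.5, seed=1)
pair = preprocess_scene(
    raw_uv, raw_green, reference,
    SceneMetadata(stem="demo", elevation="up"),
    estimate_projective(src, dst),
)
pair = normalize_minmax(pair)

print(f"registered pair {pair.shape}, {pair.angular_extent_deg()[1]:.2f} deg across")
fits = contrast_weibull_per_scene(pair, sigmas=(5, 10))
for (channel, sigma), fit in sorted(fits.items()):
    print(f"  {channel:5s} sigma={sigma:4.0f}px  beta={fit.beta_scale:.5f}  "
          f"gamma={fit.gamma_shape:.3f}  (n={fit.n_samples})")
print("-> smaller gamma = heavier-tailed contrast; the UV channel of an")
print("   upper-field scene carries the stronger silhouette contrast.")

cfg = PipelineConfig()
maps = {
    ch: circular_patch_stats(img, cfg.patch_radius_px, "rms_contrast", ch)
    for ch, img in (("UV", pair.uv), ("Green", pair.green))
}
for ch, m in maps.items():
    print(f"  median RMS contrast {ch}: {np.nanmedian(m.values):.3f}")
cfits = fit_chromatic_weibull(chromatic_contrast(maps["UV"], maps["Green"]))
print(f"  chromatic contrast tails: right beta={cfits['right'].beta_scale:.3f} "
      f"(n={cfits['n_right']}), left beta="
      f"{cfits['left'].beta_scale:.3f} (n={cfits['n_left']})")
print("-> a heavier right tail means more pixels with higher contrast in UV")
print("   than in green.")
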