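"""Preprocessing and augmentation on a small batch of windows.

Shows the model-ready pipeline: drop windows with missing samples, z-score
per channel with statistics fitted on the labeled pool only, reshape to the
(100, 4, 3) sensor-grouped layout, and build the weak/strong views used by
consistency training.
"""

import numpy as np

from cmpl.augmentation import AugmentationConfig, strong_augment, weak_augment
from cmpl.preprocessing import (
    apply_normalizer,
    drop_missing_windows,
    fit_normalizer,
    reshape_4d,
)
from cmpl.synthetic_data import StreamSpec, make_dataset

dataset = make_dataset(StreamSpec(n_labeled_per_class=20, n_unlabeled=50, missing_rate=0.1, seed=3))

labeled = drop_missing_windows(dataset.labeled)
print(f"missing-value removal: {len(dataset.labeled)} -> {len(labeled)} labeled windows")

stats = fit_normalizer(labeled)
normed = apply_normalizer(labeled, stats)
flat = normed.values.reshape(-1, 12)
print(f"post z-score per-channel |mean| <= {np.abs(flat.mean(axis=0)).max():.2e}, "
      f"|sd-1| <= {np.abs(flat.std(axis=0) - 1).max():.2e}")

window = normed.values[0]
window4d = reshape_4d(window)
print(f"layouts: flat {window.shape} -> sensor-grouped {window4d.shape}")
print(f"  gyro row at t=0: {window[0, :3].round(3)} == {window4d[0, 0].round(3)}")

cfg = AugmentationConfig(jitter_sd=0.05)
weak = weak_augment(window, cfg, seed=7)
strong = strong_augment(window4d, cfg, seed=7)
print(f"weak view moved each sample by ~{np.abs(weak - window).mean():.3f} (jitter)")
print("strong view reversed time and permuted the (x, y, z) axes:")
print(f"  original t=0 acc: {window4d[0, 1].round(3)}")
print(f"  strong  t=-1 acc: {strong[-1, 1].round(3)}  (same values, reordered)")
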