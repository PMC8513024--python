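"""Detect lesions from the low-intensity tail of local skin histograms.

Healthy skin in a small tile has a near-Gaussian intensity histogram; a
lesion adds a dark tail in green and blue. The detector thresholds each tile
at 2*mode - max (mode minus the right-half width of the skin distribution)
and OR-combines the overlapping tiles.
"""

import numpy as np

from lesionscan import synthgen
from lesionscan.histogram_detector import ChannelHistogram, channel_threshold, detect_histogram
from lesionscan.preprocess import detect_skin

scene = synthgen.generate(synthgen.standard_suite(seed=0)[1])
skin = detect_skin(scene.image)

# peek at one tile's green-channel model
tile = scene.image.green[64:192, 192:320]
hist = ChannelHistogram.from_values(tile, smooth_window=5, right_edge_percentile=99.9)
print(f"example tile: green mode={hist.mode}, right edge={hist.max_intensity}, "
      f"tail threshold={channel_threshold(hist)}")

labels = detect_histogram(scene.image, skin)
print(f"detected {labels.max()} lesions (truth: {scene.truth_labels.max()})")
for k in range(1, labels.max() + 1):
    rows, cols = np.nonzero(labels == k)
    d_mm = 2 * np.sqrt(rows.size / np.pi) * scene.image.mm_per_px
    print(f"  lesion {k}: centre ({rows.mean():5.1f},{cols.mean():5.1f})  "
          f"equivalent diameter {d_mm:4.2f} mm")
print("\nEach detected component should pair 1:1 with a planted lesion; the")
print("threshold sits ~3 sigma below the tile's healthy-skin mode.")
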