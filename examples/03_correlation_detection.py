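"""Template-matching detection with active-contour segmentation.

A bank of dark-blob templates at three physical scales is correlated with
the green channel (normalized cross-correlation, so skin tone and lighting
drop out); blobs of above-threshold correlation become seed points, and a
region-based active contour grows each seed on the luma channel.
"""

from lesionscan import synthgen
from lesionscan.correlation_detector import TemplateBank, detect_correlation, ncc
from lesionscan.preprocess import detect_skin

scene = synthgen.generate(synthgen.standard_suite(seed=0)[1])
skin = detect_skin(scene.image)
bank = TemplateBank.gaussian_blobs((1.5, 3.0, 6.0), scene.image.mm_per_px)

gamma = ncc(scene.image.green.astype(float), bank.templates[1].pixels)
print(f"NCC map for the 3 mm template: max gamma = {gamma.max():.3f} "
      f"(1.0 would be a perfect affine match)")

labels, records = detect_correlation(scene.image, skin, bank)
print(f"detected {len(records)} lesions (truth: {scene.truth_labels.max()})")
for rec in records:
    geo_d = 2 * (rec.area_px / 3.14159) ** 0.5 * scene.image.mm_per_px
    print(f"  lesion {rec.id}: centre ({rec.centroid[0]:5.1f},{rec.centroid[1]:5.1f})  "
          f"gamma={rec.score:.2f}  segmented diameter {geo_d:4.2f} mm")
print("\ngamma is the peak template correlation; the mask comes from the")
print("active contour, not the template, so sizes adapt to each lesion.")
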