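"""Bounding-box workflow: frame planning, NMS, in-box Otsu segmentation.

An external detector (here the built-in deterministic dark-blob stub) emits
boxes per overlapping 416 px frame; duplicates from overlapping frames are
removed by non-maximum suppression and each box is segmented with a median
filter plus Otsu threshold, keeping the darker class.
"""

from lesionscan import synthgen
from lesionscan.box_adapter import nms, plan_frames, segment_boxes, stub_detector
from lesionscan.preprocess import detect_skin

scene = synthgen.generate(synthgen.standard_suite(seed=0)[1])
skin = detect_skin(scene.image)

plan = plan_frames(scene.image.shape)
print(f"frame plan: {len(plan.offsets)} frames of {plan.frame_size_px} px, "
      f"overlap {plan.overlap_px} px")

boxes = stub_detector(scene.image, skin)
kept = nms(boxes, iou_threshold=0.5)
print(f"stub detector proposed {len(boxes)} boxes, {len(kept)} after NMS")

labels, records = segment_boxes(scene.image, boxes, skin)
print(f"segmented {len(records)} lesions (truth: {scene.truth_labels.max()})")
for rec in records[:5]:
    print(f"  lesion {rec.id}: centre ({rec.centroid[0]:5.1f},{rec.centroid[1]:5.1f})  "
          f"area {rec.area_px} px  confidence {rec.score:.2f}")
print("\nAny detector that writes boxes JSON can replace the stub; the")
print("segmentation inside each box is detector-agnostic.")
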