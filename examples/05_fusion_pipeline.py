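"""Full pipeline with majority-vote fusion and evaluation.

Runs preprocessing, all three detectors and 2-of-3 fusion on a hairy scene,
then scores every method against the generated ground truth. A lesion counts
as detected (TP) when a method's mask overlaps it; fusion accepts lesions
reported by at least two methods and unions their masks.
"""

from lesionscan import RunConfig, run_pipeline, synthgen
from lesionscan.evaluation import counts_table, precision, sensitivity

scene = synthgen.generate(synthgen.standard_suite(seed=0)[2])  # hairy scene
result = run_pipeline(scene.image, RunConfig(), truth_labels=scene.truth_labels)

print(counts_table(result.counts).to_string(index=False))
for method, c in result.counts.items():
    s = sensitivity(c.tp, c.fn) if c.t else float("nan")
    p = precision(c.tp, c.fp) if (c.tp + c.fp) else float("nan")
    print(f"{method:11s} sensitivity={s:.2f} precision={p:.2f}")

print("\nGeometry accuracy of the fused segmentation (mean % error per stratum):")
print(result.geometry["fusion"].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\nThe union of member masks counteracts each method's tendency to")
print("segment slightly inside the true lesion border.")
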