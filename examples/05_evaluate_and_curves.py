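"""Detection evaluation walkthrough on hand-placed boxes.

Three images, two classes: one perfect class, one class with a false
positive.  Prints the per-class AP, the mAP and the confusion matrix, and
writes the precision-recall curves as a PNG.
"""

import tempfile
from pathlib import Path

from esadet.metrics import Detection, GroundTruth, evaluate, plot_pr_curves

gts = {
    "a": [GroundTruth((0, 0, 10, 10), 0, "a")],
    "b": [GroundTruth((20, 20, 30, 30), 0, "b")],
    "c": [GroundTruth((0, 0, 8, 8), 1, "c")],
}
dets = {
    "a": [Detection((0, 0, 10, 10), 0.90, 0, "a")],      # true positive
    "b": [Detection((40, 40, 50, 50), 0.80, 0, "b"),     # false positive
          Detection((20, 20, 30, 30), 0.70, 0, "b")],    # true positive
    "c": [Detection((0, 0, 8, 8), 0.95, 1, "c")],        # true positive
}

res = evaluate(dets, gts, num_classes=2, class_names=["glioma", "meningioma"],
               apply_nms=False)
print("AP@0.5 per class:", {res.class_names[c]: round(v, 4)
                            for c, v in res.ap50.items()})
print(f"mAP@0.5 = {res.map50:.4f}   (class 0: 5/6 from the precision "
      f"envelope, class 1: 1.0 -> mean 11/12)")
print(f"max-F1 operating point: threshold {res.f1_threshold:.2f}, "
      f"P={res.precision:.3f}, R={res.recall:.3f}")
print("confusion matrix (rows=pred, cols=true, last=background):")
print(res.confusion)

out = Path(tempfile.mkdtemp()) / "pr_curves.png"
plot_pr_curves(res, out)
print(f"PR curves written to {out}")
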