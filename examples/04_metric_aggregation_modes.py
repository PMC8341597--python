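"""Why the aggregation mode of mean IoU must be reported explicitly.

Constructs two frames where one prediction is perfect on a large lumen and
the other misses a tiny lumen entirely, then prints the pooled and
per-image-macro lumen IoU — which disagree substantially.
"""

import numpy as np

from ivusseg import LabelMask, aggregate

big_truth = np.zeros((64, 64), dtype=np.uint8)
big_truth[16:48, 16:48] = 1  # 1024-px lumen
big_pred = big_truth.copy()  # segmented perfectly

small_truth = np.zeros((64, 64), dtype=np.uint8)
small_truth[30:32, 30:32] = 1  # 4-px lumen
small_pred = np.zeros((64, 64), dtype=np.uint8)  # missed entirely

pairs = [
    (LabelMask(big_pred), LabelMask(big_truth)),
    (LabelMask(small_pred), LabelMask(small_truth)),
]

pooled = aggregate(pairs, "pooled")
macro = aggregate(pairs, "macro_per_image")
print(f"pooled lumen IoU:         {pooled.iou_per_class['lumen']:.3f}   (1024/1028 pixels)")
print(f"macro per-image lumen IoU: {macro.iou_per_class['lumen']:.3f}   (mean of 1.0 and 0.0)")
# Pooling weights frames by pixel count, macro weights them equally; a
# published mean IoU is not interpretable without this tag, which is why
# every report in this package carries one.
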