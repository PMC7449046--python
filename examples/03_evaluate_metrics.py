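"""Accuracy assessment on a worked 2x2 example.

Walks the confusion matrix through pixel accuracy, per-class accuracy and
mean IoU so each number can be checked by hand.
"""

import numpy as np

from lprseg import confusion, mean_iou, per_class_accuracy, pixel_accuracy

truth = np.array([[1, 1],
                  [2, 0]])   # leaf, leaf / panicle, background
pred = np.array([[1, 2],
                 [2, 0]])    # one leaf pixel called panicle

cm = confusion(pred, truth)
print("confusion matrix (rows=truth, cols=pred):")
print(cm)
print("pixel accuracy:", pixel_accuracy(cm))          # 3 of 4 = 0.75
print("per-class accuracy:", per_class_accuracy(cm))  # leaf recall = 0.5
print("mean IoU:", round(mean_iou(cm), 4))            # (1 + .5 + .5)/3
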