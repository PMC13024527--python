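"""Diagnostic metrics from a published 3-class screening confusion matrix.

Collapses normal / non-tumor-lesion / polypoid-lesion counts to a binary
lesion-vs-normal table and derives the standard diagnostic summary.
"""

from dudem.evaluation import (WORKED_EXAMPLE_CONFUSION, WORKED_EXAMPLE_CLASSES,
                              binary_collapse, binary_metrics)

print("3-class confusion matrix (rows = truth):")
for name, row in zip(WORKED_EXAMPLE_CLASSES, WORKED_EXAMPLE_CONFUSION):
    print(f"  {name:<40s} {row}")

m = binary_collapse(WORKED_EXAMPLE_CONFUSION, positive_classes={1, 2})
print(f"\nlesion-vs-normal collapse: TP={m[0,0]} FN={m[0,1]} "
      f"FP={m[1,0]} TN={m[1,1]}  (total {m.sum()})")

rep = binary_metrics(m)
print(f"sensitivity {100*rep.sensitivity:.1f}%  specificity {100*rep.specificity:.1f}%  "
      f"precision {100*rep.precision:.1f}%")
print(f"Youden index {rep.youden:.3f}  F1 {rep.f1:.3f}  accuracy {100*rep.accuracy:.1f}%")
print("\nA Youden index near 1 indicates the reader separates lesion from "
      "normal frames almost perfectly.")
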