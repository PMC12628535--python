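"""Confusion-matrix metrics on the balanced 86+/86- worked example.

The fixture holds the unique non-negative counts consistent with a
sensitivity of 83.72% and specificity of 77.91% on a balanced test split of
86 positives and 86 negatives; the metric formulas then yield the full row.
"""

from methylcl import metrics, worked_confusion_fixture

counts = worked_confusion_fixture()
print(f"TP={counts.tp} FN={counts.fn} TN={counts.tn} FP={counts.fp}")

rep = metrics(counts)
for name, value in rep.as_dict().items():
    print(f"{name:>4}: {value * 100:6.2f}%")
# Acc is the fraction of the 172 windows called correctly; MCC summarises
# the whole confusion matrix in [-1, 1] (printed here as a percentage).
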