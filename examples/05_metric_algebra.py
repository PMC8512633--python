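"""Score a confusion matrix with the six detector metrics.

The metric definitions include two nonstandard forms used in the QRS
detection literature: DER = (FP+FN)/TP and Accuracy = TP/(TP+FP+FN)
(true negatives excluded), plus Recall = TP/(TP+TN). The example scores
published whole-database confusion counts for a detector evaluated on the
MIT-BIH arrhythmia database.
"""

from ecgpeaks import ConfusionCounts, classification_metrics

counts = ConfusionCounts(tp=109415, fp=43, tn=22102, fn=20)
metrics = classification_metrics(counts).rounded()

print(f"confusion counts: TP={counts.tp} FP={counts.fp} TN={counts.tn} FN={counts.fn}")
for name, value in metrics.items():
    print(f"  {name:>11}: {value:6.2f} %")
print("\nsensitivity ~100% means almost no missed beat; DER near zero means")
print("false alarms + misses are a vanishing fraction of true detections.")
print("recall is low by construction: its denominator includes the many")
print("correctly rejected noise windows (TN).")
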