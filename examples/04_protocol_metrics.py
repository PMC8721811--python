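"""The community scoring protocol on a tiny worked example.

Six predictions over two classes illustrate how UF1 (macro F1), UAR
(balanced accuracy) and plain accuracy differ under class imbalance.
"""

from microres import accuracy, confusion, uar, uf1

true = [1, 1, 1, 1, 2, 2]
pred = [1, 1, 1, 2, 2, 1]
counts = confusion(true, pred, classes=[1, 2])

print("true:", true)
print("pred:", pred)
for cls, tp, fp, fn, n in zip(counts.classes, counts.tp, counts.fp,
                              counts.fn, counts.support):
    print(f"  class {cls}: TP={tp} FP={fp} FN={fn} support={n}")

print(f"UF1      = {uf1(counts):.3f}  (mean of per-class F1: 0.75 and 0.50)")
print(f"UAR      = {uar(counts):.3f}  (mean of per-class recall: 3/4 and 1/2)")
print(f"accuracy = {accuracy(counts):.3f}  (4 of 6 correct)")
print("UF1/UAR weight both classes equally; accuracy favours the larger class")
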