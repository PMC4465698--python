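"""Chart-review performance arithmetic with the truncating percent formatter.

Inputs are review counts: of 267 algorithm-identified cases, 138 were
confirmed definite and 67 potential; of 300 reviewed controls, 5 showed
glaucoma evidence.  PPV = TP/(TP+FP), NPV = TN/(TN+FN), and accuracy =
(TP+TN)/(positives+negatives) are computed as exact fractions and printed
as percentages truncated at one decimal — the convention that reproduces
published phenotyping reports of this design.
"""

from poagpheno import ConfusionCounts, accuracy, format_percent_trunc, npv, ppv

definite = ConfusionCounts(tp=138, fp=267 - 138, tn=300 - 5, fn=5)
print("definite cases:")
print(f"  PPV      = {format_percent_trunc(ppv(definite))}%   ({definite.tp}/{definite.tp + definite.fp})")
print(f"  accuracy = {format_percent_trunc(accuracy(definite))}%   "
      f"({definite.tp + definite.tn}/{definite.total})")

inclusive = ConfusionCounts(tp=138 + 67, fp=267 - 138 - 67, tn=295, fn=5)
print("definite + potential cases:")
print(f"  PPV      = {format_percent_trunc(ppv(inclusive))}%   ({inclusive.tp}/{inclusive.tp + inclusive.fp})")

print("controls:")
print(f"  NPV      = {format_percent_trunc(npv(definite))}%   ({definite.tn}/{definite.tn + definite.fn})")
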