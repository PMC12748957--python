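"""Chance thresholds for small validation sets.

With a finite validation set an accuracy slightly above 50% can easily
happen by luck. A classifier counts as better than chance only when the
lower bound of the 95% Wilson score interval of its accuracy exceeds
50%. This prints the minimum accuracy achieving that for the two
validation-set sizes of the protocol (120 windows per held-out subject
in leave-one-subject-out; 48 windows in the subject-dependent split).
"""

from qfnirs import min_significant_accuracy, wilson_lower_bound

for n, label in ((120, "subject-independent"), (48, "subject-dependent")):
    thr = min_significant_accuracy(n)
    lb = wilson_lower_bound(thr / 100.0, n)
    print(f"{label:>20s}  n={n:3d}  threshold = {thr:.2f}%  "
          f"(Wilson lower bound at threshold = {lb:.4f})")

print("\nAnything below these accuracies is statistically indistinguishable "
      "from a random classifier at the 95% level.")
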