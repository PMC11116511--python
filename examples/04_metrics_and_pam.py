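"""Classifier evaluation, including the polygon area metric (PAM).

Scores a synthetic set of sex predictions on every reported metric and
shows the two PAM closed forms: the unit hexagon normalizes to 1, and
uniform radii r give PAM = r^2.
"""

import numpy as np

import sdetnet as sd

# 20 subjects, balanced; the classifier is good but not perfect
labels = np.array([1] * 10 + [0] * 10)
probs = np.array([0.9, 0.8, 0.95, 0.7, 0.6, 0.85, 0.9, 0.4, 0.75, 0.8,
                  0.1, 0.2, 0.05, 0.3, 0.55, 0.15, 0.1, 0.25, 0.2, 0.35])

r = sd.evaluate_classifier(labels, probs)
for name, value in r.as_dict().items():
    print(f"{name:>4s} = {value:.3f}")
print("SEN is the male hit rate, SPE the female hit rate; BR is the mean "
      "squared probability error (lower is better); PAM folds ACC, SEN, "
      "SPE, AUC, JI and FM into one hexagon area.")

print(f"\nPAM closed forms: all-ones -> {sd.pam(1, 1, 1, 1, 1, 1):.4f}; "
      f"all 0.5 -> {sd.pam(*[0.5] * 6):.4f} (= 0.5^2)")
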