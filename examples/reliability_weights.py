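"""Reliability weights from ensemble precision and bias.

Builds two single-compound scenarios — an unreliable training instance and a
highly reliable one — and prints the weight W = (1 - STD) x agreement that
RDN multiplies into the instance's neighbourhood radius, plus the vote and
probability agreement variants on a small concrete ensemble.
"""

import numpy as np

from rdnad import (
    EnsemblePredictionMatrix,
    agreement_probability,
    agreement_vote,
    ensemble_std,
    reliability_weight,
)

# Scenario 1: imprecise (STD 70%) and biased (agreement 35%)
w = reliability_weight(0.70, 0.35)
print(f"STD=0.70, agreement=0.35  ->  W = {w:.3f} "
      f"({w:.1%} reliability, {1 - w:.1%} radius reduction)")

# Scenario 2: precise (STD 1%) and unbiased (agreement 99%)
w = reliability_weight(0.01, 0.99)
print(f"STD=0.01, agreement=0.99  ->  W = {w:.4f} "
      f"(~{round(w * 100)}% reliability, ~{round((1 - w) * 100)}% reduction)")

# A concrete 5-member ensemble for a compound observed in class 1
row = np.array([0.9, 0.8, 0.3, 0.7, 0.6])
print(f"\nmember probabilities {row.tolist()} (observed class 1):")
print(f"  ensemble STD          = {ensemble_std(row):.4f}")
print(f"  vote agreement        = {agreement_vote(row, 1):.2f}  "
      "(fraction of members calling class 1)")
print(f"  probability agreement = {agreement_probability(row.mean(), 1):.2f}  "
      "(1 - |1 - mean prob|; stricter than the vote)")

epm = EnsemblePredictionMatrix(ids=["cmpd"], members=row[None, :], y_observed=[1])
rw = epm.weights("vote")
print(f"  W (vote variant)      = {rw.w[0]:.4f}")
print("\nLow W shrinks the compound's neighbourhood: an unreliable training "
      "instance vouches for less of the surrounding chemical space.")
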