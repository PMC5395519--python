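"""Scoring AD robustness from two external-set accuracy curves.

An AD is only useful if it ranks reliability the same way on data it has
never seen.  This script traces the RDN profile of two i.i.d. external sets,
scores the pair (lower = better; identical strictly falling curves score
exactly 1), and contrasts with the score after destroying the curve
structure by permuting the accuracies.
"""

import numpy as np

from rdnad import ad_score, ad_score_from_profile, rdn_profile, simulate_study

study = simulate_study(seed=3)
prof = rdn_profile(study["X_train"], study["W"], study["externals"], k_max=65)

result = ad_score_from_profile(prof, "external_1", "external_2")
print(f"AD score (matched external sets): {result.score:.3f}")
print(f"  F_added = {result.f_added:.3f} (coverage gained after the first "
      f"iteration; small values inflate the score — poor core resolution)")
worst = max(result.segments, key=lambda s: s.summand)
print(f"  largest summand at segment {worst.index}: SMP={worst.smp}, "
      f"{worst.n_added} compounds added, accuracy gap {worst.accuracy_gap:.3f}")

rng = np.random.default_rng(0)
cy, cz = prof.counts("external_1"), prof.counts("external_2")
ay, az = prof.accuracies("external_1"), prof.accuracies("external_2")
keep = ~(np.isnan(ay) | np.isnan(az))
shuffled = ad_score(cy[keep], rng.permutation(ay[keep]),
                    cz[keep], rng.permutation(az[keep]),
                    n_total_y=prof.dataset_sizes["external_1"],
                    n_total_z=prof.dataset_sizes["external_2"])
print(f"\nAD score after permuting accuracies: {shuffled.score:.3f}")
print("Permutation introduces rising segments (penalty 4 per curve, up to "
      "16 per pair) and larger gaps, so the matched pair scores lower — the "
      "profile shape is real, not an artefact of one particular split.")
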