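"""Where RDN beats precision-only reliability: planted systematic bias.

Simulates the three-region study (reliable core, precise-but-wrong pocket,
sparse fringe), profiles the first external set with RDN and with STD tiers,
and prints when the biased pocket's compounds first enter each AD.  A good
AD keeps systematically mispredicted compounds out of its core.
"""

import numpy as np

from rdnad import rdn_profile, simulate_study, std_profile

study = simulate_study(seed=11)
prof_rdn = rdn_profile(study["X_train"], study["W"], study["externals"], k_max=65)
prof_std = std_profile(study["ext_std"]["external_1"],
                       study["externals"]["external_1"].correct)

regions = study["data"].regions["external_1"]
f_rdn = prof_rdn.first_inclusion_fraction("external_1")
f_std = prof_std.first_inclusion_fraction("external")

print("median coverage fraction at which compounds first enter the AD")
print(f"{'region':<10}{'RDN':>8}{'STD tiers':>12}")
for region in ("core", "biased", "sparse"):
    mask = regions == region
    print(f"{region:<10}{np.median(f_rdn[mask]):>8.2f}{np.median(f_std[mask]):>12.2f}")

acc = prof_rdn.accuracies("external_1")
frac = prof_rdn.fraction_included("external_1")
defined = ~np.isnan(acc)
print(f"\nRDN profile: core accuracy {acc[defined][0]:.2f} at "
      f"{frac[defined][0]:.0%} coverage -> {acc[-1]:.2f} at {frac[-1]:.0%} coverage")
print("\nThe biased pocket has near-zero ensemble STD (the members agree), so "
      "STD tiers admit it immediately — at the AD core.  Its vote agreement "
      "is ~0, so RDN collapses those neighbourhoods and defers the pocket "
      "until far out in the expansion (1.00 = never included).")
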