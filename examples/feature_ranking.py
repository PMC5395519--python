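"""ReliefF descriptor ranking for AD construction.

The distance underlying a neighbourhood AD is only as good as its
descriptors.  ReliefF rewards features that separate the classes within
local neighbourhoods and zeroes out noise — here demonstrated on synthetic
data whose informative and noise features are known, with rank averaging
over subsampled runs.
"""

import numpy as np

from rdnad import average_ranks, default_config, relieff_weights, select_top_k, simulate_dataset

data = simulate_dataset(default_config(), seed=5)
train = data.train
# make the labels depend on one informative descriptor so the contrast
# between signal and noise columns is visible
y = (train.X[:, 0] > np.median(train.X[:, 0])).astype(int)

runs = [
    relieff_weights(train.X, y, n_neighbors=10, sigma=2.0,
                    n_sample=int(0.8 * train.n_compounds), seed=100 + r,
                    feature_names=train.feature_names)
    for r in range(5)
]
avg = average_ranks(runs)

print("mean ReliefF rank over 5 subsampled runs (1 = most class-informative):")
for name, rank in sorted(zip(avg.names, avg.metadata["mean_rank"]), key=lambda t: t[1]):
    print(f"  {name:<10} {rank:5.1f}")
print(f"\ntop-3 selection: {select_top_k(avg, 3)}")
print("desc_1 carries the class signal and ranks first; the noise_* columns "
      "sink to the bottom — using only top-ranked descriptors keeps the AD's "
      "distance measure focused on class-relevant chemistry.")
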