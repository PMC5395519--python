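# Methods

This note records the models implemented in `rdnad`, the parameters that
matter, the numerical conventions, and what the synthetic benchmarks do and
do not demonstrate.

## Problem setting

A binary QSAR classifier maps a vector of molecular descriptors to a class
(active/inactive, substrate/non-substrate, …). Its error is not uniform:
predictions degrade in sparse regions, near activity cliffs, and in pockets
where the training labels or the learned model are systematically off. An
applicability domain (AD) should therefore be *continuous* — a reliability
landscape over descriptor space — rather than a single in/out boundary, and
it should be *robust*: two independent external sets should recover the same
accuracy-versus-coverage relationship. All inputs are consumed as tabular
descriptor matrices; the package does no structure parsing or descriptor
calculation.

## The RDN expansion

At each neighbour count k (default 1…65):

1. **Local density.** For each training compound, the mean Euclidean
   distance to its k nearest training neighbours (self excluded; neighbours
   tie-broken by stable (distance, index) sort, tied neighbours beyond the
   k-th excluded).
2. **Tukey fence.** RefVal = Q3 + 1.5 × IQR over those per-compound
   averages, quartiles by linear interpolation ("type 7"). The fence bounds
   which neighbours count as local, so outlying distances cannot inflate a
   radius.
3. **Radii.** D_i = mean distance to neighbours with distance ≤ RefVal
   (closed inequality); D_i = 0 when none qualify.
4. **Scaling.** effective radius = D_i × step(k) × W_i. The default step
   schedule is 1/3 for k ≤ 30, 1/2 for 31–40, 1 for k > 40: early iterations
   probe the dense core, where an unscaled first-neighbour radius would
   already swallow half the data and destroy resolution. The schedule is a
   user-overridable list of (k-upper-bound, factor) pairs.
5. **Coverage.** A query is in-AD once ≥ `min_neighbors` (default 1)
   training radii cover it (closed balls). Inclusion accumulates as the
   union over iterations; accuracy is the cumulative fraction of included
   external compounds whose model prediction was correct. Accuracy over an
   empty set is reported as undefined (`None`/NA), never 0.

RefVal and the radii are recomputed at every k; dk-NN is the exact special
case W ≡ 1 with a unit schedule, and shares the code path.

Both RefVal recomputation per k and union-accumulated coverage make the
profile monotone in coverage by construction; monotonicity in W (shrinking
any single W_i never gains coverage) follows from the closed-ball rule and
is property-tested.

## Reliability weights

W = (1 − STD) × agreement, both factors in [0, 1]:

- **STD** — sample standard deviation (denominator M − 1) of the M ensemble
  members' class-1 probabilities for the compound; measures *precision*.
- **agreement** — vote variant: fraction of members whose class call
  (p ≥ 0.5 → class 1; ties to 1) matches the observed class. Probability
  variant: 1 − |Y − ȳ| on the ensemble mean, for when member-level outputs
  are unavailable; it is the stricter of the two, since a right-side-of-0.5
  majority no longer suffices. Measures *bias*.

The ensemble is produced by `bag_ensemble`: n_models = 10 clones of any
learner exposing `fit`/`predict_proba`, each trained on an 80% resample
drawn with replacement; single-class resamples are redrawn (max 100
attempts). Training-set weights default to in-sample ensemble predictions;
out-of-bag or cross-validated predictions can be supplied by the caller
instead (the choice is the caller's — both are defensible and the package
does not impose one). Probability calibration (e.g. Laplace smoothing of
tree leaves) is the base learner's concern; the harness stays
model-agnostic.

## Comparator ADs

- **STD tiers**: expand by an increasing STD cutoff; default edges are the
  pooled unique STD values thinned evenly to ≤ 50. Deliberately blind to
  bias — this is the behaviour RDN is designed to fix, and the synthetic
  benchmark exploits exactly that.
- **KDE**: Gaussian KDE on the first principal component of the training
  matrix (sign fixed so the largest-magnitude loading is positive);
  bandwidth "auto" is Silverman's rule on the training projection, and any
  explicit bandwidth is accepted for reproducibility. A compound is in-AD at
  percentile p when its density reaches the p-th percentile of training
  densities; the default grid is 95, 90, …, 0.

## The AD score

Two cumulative curves on one iteration grid are compared segment-wise
(i = 2…P). Slopes are taken on accuracy versus the *combined* cumulative
fraction included; |m| ≤ 1e−9 counts as flat. Per-curve penalties are
1 (falling), 2 (flat), 4 (rising); SMP is their product; WP_i = SMP_i ×
N_added,i / N_total over both datasets; the summand is WP_i × (1 + |y_i −
z_i|), and the sum is divided by F_added = (combined coverage at P −
combined coverage at 1) / N_total. Segments adding nothing contribute
WP_i = 0 regardless of slope. With this grouping every summand is ≥
N_added,i/N_total, so the score is ≥ 1, with equality exactly for identical
strictly falling curves.

F_added has a second defensible reading — total combined coverage at P.
Both are computed and reported (`f_added`, `f_added_total`); the score uses
the difference form, which makes the core-resolution argument literal: a
method that swallows half the data in its first iteration is penalised
because that coverage never enters F_added.

## ReliefF

Standard binary ReliefF: each anchor's k = 10 nearest hits and misses
(Manhattan distance on features scaled to [0, 1] over the full dataset)
update each feature weight by the miss-diff minus the hit-diff, averaged
over anchors; diff = |a − b| / range, so constant features score exactly 0
and weights are invariant to positive rescaling. `sigma` (default 2)
controls optional exponential rank-based weighting of neighbour
contributions, influence ∝ exp(−(j/σ)²) normalised over j = 1…k — a
declared convention, off by default. "Runs initiated from different points
of the data" are realised as subsampled runs under distinct seeds whose
ranks are averaged; a full-pass run is deterministic and needs no
averaging. Ties in weight break lexicographically by feature name.

## Synthetic study conditions

The default generator plants three regions in 5 informative + 3 noise
standard-normal features (scalar centres are broadcast over the informative
features):

| region | centre | spread | n_train | n_ext | flip rate | dispersion | correct_prob |
|--------|-------:|-------:|--------:|------:|----------:|-----------:|-------------:|
| core   |    0   |  1.0   |   120   |  60   |   0.02    |    0.05    |     0.90     |
| biased |    4   |  0.6   |    25   |  20   |   0.00    |    0.02    |     0.10     |
| sparse |   −5   |  2.5   |    12   |  12   |   0.25    |    0.30    |     0.55     |

Labels are Bernoulli(1/2) per region, flipped at the region's rate. Ensemble
members draw Normal(target, dispersion) class-1 probabilities, clipped to
[0, 1] (clipping, not a logit transform — simpler and declared); the target
anchors on the *true* class when true labels are supplied, so label noise
becomes irreducible error. The "biased" row is the precise-but-wrong regime:
dispersion 0.02 gives near-zero STD while correct_prob 0.1 puts the ensemble
mean on the wrong side, which only the agreement term can detect. Two
external sets are drawn i.i.d. from the same mixture. Sizes are deliberately
small (157 training compounds) so a full 65-iteration profile runs in well
under a second; the published benchmarks of this family of methods use
thousands of compounds and real descriptor distributions, and nothing here
emulates real chemistry — passing the synthetic benchmarks shows the
*mechanism* (bias deferral, robustness ordering) works, not that any
particular dataset will profile well.

Ensemble predictions are simulated directly rather than via trained
classifiers, isolating the AD logic from learner variance; the
`bag_ensemble` harness covers the trained path separately.

## Numerical and interface conventions

- Standardization: z-scores with training-set mean and sample SD (ddof = 1);
  zero-variance descriptors dropped and logged; external sets always use the
  training parameters.
- Tables are comma-separated UTF-8 with a header; rows with missing
  descriptors are dropped and counted, never imputed. Profiles are TSV
  (iteration, threshold_param, dataset, n_included_cum, accuracy_cum) with a
  two-line comment header carrying method and dataset sizes; accuracies are
  written with full repr precision so round-trips are exact.
- All randomness flows through explicit integer seeds;
  `simulate_study` derives per-stage sub-seeds from one seed via
  `SeedSequence`.
- `first_inclusion_fraction` assigns compounds never included the value 1.0
  (they sit at or beyond full coverage), which keeps medians well-defined.

## Known limitations

- The full pairwise distance matrix is materialised (O(n²) memory); fine to
  a few thousand compounds, no spatial indexing is attempted.
- KDE uses only PC1, as the comparator is defined; it is a deliberately
  coarse global-density baseline, not a recommended AD.
- Binary endpoints only; regression and multi-class are out of scope.
- The AD score requires both curves on one grid and at least one compound
  added after the first iteration; profiles whose accuracy is undefined at
  the start are truncated to the first jointly defined iteration.
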