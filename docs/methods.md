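# Methods

## Model and procedure

`xhclust` segments hyperspectral reflectance cubes without labels.  The
data model is a dense signature matrix **X** ∈ ℝ^{m×n}: one column per
unmasked pixel, one row per wavelength.  Segmentation proceeds in three
stages:

1. **Tree decomposition.**  A binary tree is grown over the columns.  At
   each node two pivot signatures are found by a farthest-point heuristic
   (seeded start → farthest point **b** → farthest-from-**b** point **a**),
   all members are projected onto the pivot line, and the projections are
   split at the threshold minimising the summed per-side mean squared
   deviation.  Children receive the members satisfying
   `Proj(x) ≤ θ` (success) and the rest (failure).  Because the pivots are
   extreme points of the node, the splits follow the data's archetypes
   rather than its dense center — which is what distinguishes the resulting
   clusters from flat Kmeans on skewed data.
2. **Pruning.**  The leaf-mean spectra (typically tens per tree) are
   clustered with Lloyd Kmeans into k representatives.  This decouples the
   tree's granularity from the number of reported clusters.
3. **Assignment.**  Every signature of every image is labelled with its
   nearest representative by Euclidean distance.

Assumptions: Euclidean distance on smoothed reflectance spectra is a
meaningful dissimilarity (reasonable after calibration and smoothing);
clusters are separable along 1D projections between extreme points;
leaf means are adequate summaries for pruning (leaves are approximately
homogeneous when `min_leaf` is small relative to cluster sizes).

## Projection variants

The default projection is the plain-distance form
`(Dist(a,x) + Dist(a,b) − Dist(b,x)) / (2·Dist(a,b))`, which maps the
pivots to 0 and 1 and is bounded in [0, 1] by the triangle inequality.  The
classical FastMap coordinate from the law of cosines,
`(Dist(a,x)² + Dist(a,b)² − Dist(b,x)²) / (2·Dist(a,b))`, is available as
`variant="law_of_cosines"`.  Both produce valid 1D orderings but different
thresholds; which is preferable cannot be settled in general, so both are
implemented and the variant is recorded in the model.  Likewise the split
cost normalises each side by its own count (the sum of the two within-side
mean squared deviations), which slightly penalises unbalanced splits
relative to a pooled weighted variance; it is implemented in exactly this
per-side form.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_depth` | 10 | tree depth cap; 2^10 leaf budget |
| `min_leaf` | 100 | minimum signatures per leaf; a node splits only if its size ≥ 2·min_leaf |
| `k` | 7 | final representatives after pruning |
| `kmeans_iters` | 1000 | Lloyd iteration cap (pruning and baseline) |
| `variant` | `as_printed` | projection formula (see above) |
| `polyorder`, `half_window` | 5, 7 | Savitzky–Golay degree and points per side (window 15) |
| `lo_nm`, `hi_nm` | 450, 790 | retained spectral window (closed interval), since reflectance is noisy at the sensor extremes |
| `background_threshold` | 0.05 | mean reflectance below which a pixel is background |
| `overexposure_threshold` | 1.0 | max reflectance above which a pixel is masked as fluid/specular |
| `seed` | 0 | master seed; logged in every artifact |

`min_leaf = 100` balances leaf-count tractability against resolving ~7
tissue clusters on megapixel images; tests and examples lower it (40–50)
for desk-scale scenes with a few thousand signatures.

## Determinism and tie-breaking

Every random choice (start pivot, Kmeans seeding) derives from a seed;
per-node child seeds are spawned from the parent's seed sequence, so the
tree is a pure function of (X, parameters, seed) regardless of traversal
order.  Ties resolve deterministically: smallest split index for equal
costs, first index for farthest-point argmax, lowest representative index
for equidistant assignment.  The split cost is computed with cumulative
sums for speed; near-minimal candidates are re-scored by direct summation
so that exact ties resolve to the smallest index rather than to floating-
point noise.  Kmeans uses deterministic farthest-point seeding from a
seeded start, and convergence is declared when the assignment stops
changing.  Representatives are canonically ordered (mean reflectance, then
lexicographic), so cluster ids are stable across runs.

The per-subset trees of the parallel path get seeds derived from the
master seed and the subset's image ids — not its position — so the pooled
leaf-mean matrix **Y** is invariant (up to row permutation) under subset
reordering; **Y** is sorted lexicographically before pruning, making the
final model a pure function of the multiset of subsets.  A single-subset
call uses the master seed directly and is therefore bit-identical to the
serial grow-then-prune path.

## Degenerate inputs

A node whose points all coincide, whose projections are all equal, or
whose best threshold fails to separate any member (possible with duplicated
projection values, since θ = (sᵢ+sᵢ₊₁)/2 collapses onto a repeated value)
becomes a leaf.  `best_split` itself always returns the literal minimiser
over i = 1..n−1; the guard against empty children lives in the tree
builder.  Calibration refuses any band where white − dark ≤ 0, naming the
band.  Pruning with fewer leaf means than k raises an error telling the
user to deepen the tree or lower k.

## Savitzky–Golay edge handling

Interior bands match the classical convolution filter exactly.  Near the
spectrum ends the fit window is shrunk to the available points (same
polynomial order) instead of padding or extrapolating beyond the measured
range; consequently smoothing reproduces any polynomial up to the fit
order across the entire spectrum, ends included.  The pipeline smooths
before cropping to 450–790 nm — the filter window then still sees the
about-to-be-discarded edge bands — and this order is fixed and
regression-tested, since the two orders do not commute.

## Synthetic scenes: what they emulate and what they do not

The generator emulates the structure of wound-model imagery: a disc of
tissue on a dark low-reflectance dish, three concentric regions (periphery,
wound margin, wound bed) each carrying one smooth endmember spectrum
(2–4 Gaussian bumps over 450–790 nm at 2.73 nm steps, peak ≤ 0.9, enforced
pairwise separation), iid additive Gaussian noise per band (default
sd 0.01), and randomly placed fluid pixels with reflectance 1.05–1.5.  The
timecourse builder shrinks the wound-bed disc over days 0/5/10 for the
control condition and leaves it unchanged for treated conditions.

Deliberately absent: spectral gradients within a region (scenes are
piecewise-constant so the ground-truth partition is unambiguous for ARI
scoring), chromophore/hemoglobin absorption features, spatially correlated
noise, camera point-spread effects, and megapixel scale (default scenes
are 64×64×125).  Passing recovery tests therefore demonstrates that the
algorithm separates spectrally distinct, well-separated tissue classes
under moderate noise — not that it resolves subtle biological spectra;
on real data the clusters additionally depend on calibration quality and
on k.

## Problem sizes used in tests and the acceptance script

Recovery runs use 64×64×125 scenes (~2 600 tissue signatures) over 10
seeds in the test suite and 5 seeds in the acceptance script; the
timecourse uses 48×48 scenes; the split-oracle check draws 500–1 000
random lists of up to 200 projections.  These sizes were chosen so the
whole verification cycle runs in seconds on one CPU while still exercising
every stage at realistic dimensionality (125 bands); scale is a
configuration knob, not a structural limit.

## Known limitations

- Euclidean distance on raw reflectance weights all bands equally; no
  derivative or scatter-correction preprocessing is provided.
- The tree assigns training signatures via hard rules but final labels via
  nearest representative, so leaf boundaries and final cluster boundaries
  need not coincide.
- Background masking by mean-reflectance threshold presumes a dark dish;
  bright backgrounds need a user-supplied mask.
- Lloyd Kmeans with farthest-point seeding is deterministic but, like all
  Kmeans, only locally optimal; k must be chosen by the user.
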