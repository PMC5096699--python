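# Methods

## Data model

All analyses operate on a trial tensor `R` of non-negative spike counts
with shape `S x T x N` (trials x time bins x neurons), obtained by binning
spike times relative to stimulus onset into fixed-width bins (10 ms by
default, 0-based half-open intervals `[t, t + Δ)`; a spike exactly at the
window end is out of window).  Bins are deliberately coarse relative to
spike timing jitter: the package is about the structure of population
responses at the ten-millisecond scale, not sub-millisecond spike timing.

Two matricizations connect the tensor to standard matrix methods: the
spatiotemporal form `S x (T·N)` (each trial flattened time-major) and the
spatial form `(S·T) x N` (rows ordered trial-major, then bin).  Both are
exact bijections.  The time-major flattening order is a convention of this
package and is fixed so that reshaped modules are well defined.

## Decomposition models

**Spatiotemporal (matrix) decomposition.**  Each trial's `T x N` response
is modeled as a linear combination of `K` trial-independent spatiotemporal
modules `b_k` with trial-dependent scalar coefficients:
`R^s ≈ Σ_k h_k^s b_k`, i.e. `R = H B` on the `S x (T·N)` matricization.
Four engines solve it:

- **NMF** — multiplicative updates minimizing the Frobenius norm, which
  provably never increase the reconstruction error.  Non-negativity makes
  modules directly interpretable as firing patterns and coefficients as
  recruitment strengths.
- **PCA** — orthonormal modules ordered by explained variance
  (scikit-learn).
- **ICA** — FastICA fixed-point iteration.  The *modules* are the
  independent components: they are estimated on the transposed
  matricization so that independence is imposed across the time x neuron
  axis, matching the interpretation of modules as statistically
  independent firing patterns.  Coefficients are then refit by least
  squares.
- **FA** — EM-fit latent factor model with per-variable noise
  (scikit-learn); loadings are the modules, coefficients are refit by
  least squares so reconstruction is well defined.

PCA/ICA/FA operate on mean-centred data; the training mean is stored and
reused for held-out trials.  All modules are returned with unit norm and
scales absorbed into the coefficients, so module comparisons are
scale-free.

**Space-only decomposition.**  The same four engines applied to the
`(S·T) x N` matricization give `L` spatial modules with time-resolved
coefficients `h^s_k(t)`.

**Space-by-time (Tucker-2) decomposition.**  The tensor model
`R^s ≈ B_tem H^s B_spa` factorizes responses into `P` temporal modules
(columns of `B_tem`, `T x P`), `L` spatial modules (rows of `B_spa`,
`L x N`) and a trial-specific core `H^s` (`P x L`).  Two constraint sets:

- **space-by-time NMF** (non-negative Tucker-2 / sample-based non-negative
  matrix tri-factorization): alternating multiplicative updates on
  `B_spa`, `B_tem` and the per-trial cores, minimizing
  `Σ_s ||R^s − B_tem H^s B_spa||²_F`.  The per-trial update loops are
  expressed as einsum contractions over the trial axis; the intermediates
  are exactly the stacked products of the published update rules.  At
  convergence each temporal column and spatial row is scaled to unit norm
  with scales absorbed into the core (this is the error-preserving reading
  of the normalization step, whose row/column orientation is ambiguous in
  the original description).
- **orthogonal Tucker-2**: higher-order orthogonal iteration (HOOI) with
  HOSVD initialization; each factor is the leading left singular subspace
  of the tensor unfolded after projection on the other factor.  The fit is
  deterministic; sign indeterminacy is fixed by making the
  largest-magnitude entry of each factor column positive.  The core is the
  closed-form orthogonal projection.

The dimension convention is `R^s ∈ R^{T x N}` throughout (the transposed
orientation that sometimes appears in pseudocode for these updates is
treated as a notational variant).

**Numerical defaults.**  NMF variants: i.i.d. uniform(0, 1)
initialization, `tol = 1e-6` relative objective decrease, `max_iter = 500`,
`n_restarts = 5` (best final error returned), denominators floored at
machine epsilon.  These control the optimizer only; results at the
defaults are stable across restarts on block-structured data.  Held-out
coefficients always come from frozen-module inference: coefficient-only
multiplicative updates (NMF) or least-squares projection (linear models),
so the frozen-module reconstruction error can never beat a joint fit.

## Module comparison

The geodesic similarity between two modules is the principal angle between
their directions mapped linearly to [0, 1]:
`sim(u, v) = 1 − (2/π)·arccos(<u, v>/(||u||·||v||))` — 1 for identical
directions, 0 for orthogonal ones, scale-invariant and symmetric.  Module
*sets* are compared by the one-to-one assignment maximizing total
similarity (Hungarian algorithm, verified against brute-force enumeration
for small sets); the matched-pair mean in percent is the **module
recovery similarity**.  Space-by-time factors are first expanded into
their `P·L` outer-product modules.  Sign-indeterminate methods
(PCA/ICA/FA/orthogonal Tucker-2) are compared up to sign per pair.

## Synthetic data

The simulator draws per-bin spike counts as Poisson(rate x bin width) from
block-patterned rate maps: rectangular foreground regions at `SNR x`
background rate (background 2 Hz by default) on a `T = 30 x N = 20` grid
of 10 ms bins.  It emulates trial-to-trial variability of a stationary
population code: patterns are fixed; only their presence and the Poisson
draw vary across trials.  It deliberately omits refractoriness,
non-Poisson dispersion, trial-to-trial gain drift and rate co-fluctuations
(noise correlations), so passing tests demonstrate correctness of the
methods under the model's own assumptions, not robustness to every
property of real recordings.

Geometry of the presets (all overridable):

- **separable** — four 6-neuron x 8-bin blocks arranged as two neuron
  groups x two time intervals, adjacent groups sharing 2 neurons and
  adjacent intervals 2 bins.  Each block is exactly an outer product, so
  (P, L) = (2, 2) is the generating model.
- **overlap levels 0-3** — the same 2 x 2 layout with shared
  (neurons, bins) per level set to (1,2), (2,2), (1,4), (3,5).  These were
  calibrated once so the mean pairwise geodesic overlap of the foreground
  patterns spans ~9.8% to ~32.2% monotonically with constant block area,
  matching the documented overlap range of the reference simulations.
- **sequential** — staircases of three 2-neuron x 8-bin sub-blocks at
  successive 8-bin offsets, two onsets x two neuron groups: non-separable
  in space and time by construction.
- **mixture sets** — four disjoint base blocks plus four 0/1 mixing
  tables; observable patterns are exact sums of base foregrounds.
- **info_type** — three equal-area patterns for the shuffling control:
  pattern 0 unique in space and time, pattern 1 sharing pattern 0's time
  course (space-only information), pattern 2 sharing its neurons
  (time-only information).

Presence designs: *independent mixture* (each pattern present with
probability 0.5 per trial; 900 trials is the canonical size) or *fixed
conditions* (canonically the 6 unordered pairs of 4 blocks, one pair per
stimulus).  Co-active patterns superimpose **additively**: the trial rate
is background plus the sum of the active foreground excesses, which is the
exact rate of superimposed independent Poisson processes, one per pattern.
An element-wise-max rule is available as an option; it models competing
rather than superimposing sources, but it dilutes the effective weight of
overlap cells and therefore caps module recovery well below what the
additive model attains, which is why additive is the default.  Pattern
overlap is computed on background-subtracted maps, making it independent
of the SNR and zero for disjoint supports.

## Decoding

Multiclass LDA on the single-trial coefficients, with a strict
training/test separation: modules, the zero-variance coefficient mask, and
the classifier are all estimated on training trials only; test-trial
coefficients come from frozen-module inference.  The pooled within-class
covariance always carries a tiny shrinkage toward the scaled identity
(1e-6) so that the classifier is defined even for singular predictor sets
such as raw `T·N` count vectors ("raw LDA").  Accuracy is percent correct
on the test set.

**Module-count selection** is leave-one-out cross-validation within the
training set: for each candidate count, one trial per stimulus is held out
per fold; modules are fit on the rest and the validation accuracy is
averaged over folds.  The selected counts maximize validation accuracy;
ties break to the minimum total count, then the smallest temporal count,
then the smallest spatial count.  Per-fold fits default to 2 restarts,
300 iterations and `tol = 1e-5` — selection only ranks candidates, so it
does not need final-fit precision.

The selection validation study uses SNR 50, overlap level 1 and 20 trials
per stimulus (10 training).  The SNR sits deliberately inside the regime
where decoding at the generating counts saturates — the premise of the
max-accuracy/minimum-count rule.  Below saturation, validation accuracy
keeps rising with extra modules and the rule has no ceiling to tie-break
on; at extreme SNR (~150), coefficient *magnitudes* become discriminative
enough that even fewer-than-generating counts decode perfectly and the
minimum-count tie-break undershoots.  Both failure modes are properties of
the selection rule itself, not of an implementation.

**Generalization to unseen stimuli**: modules are fit on the training
trials of `n` stimuli drawn from a module-training pool; coefficients are
then inferred for trials of the remaining stimuli, on which the classifier
is trained and tested.  This probes whether the module dictionary learned
from some stimuli spans responses to others.

**Rank-order decoding**: neurons are ranked by first-spike latency within
each trial (average ranks for ties; silent neurons share the maximal
rank); each stimulus' template is the mean training rank vector; test
trials go to the template with the highest correlation between rank
vectors (a Spearman-type statistic), ties resolving to the smallest label
and undefined correlations (constant rank vectors) counting as zero.

## Space/time information via shuffling

Permuting time bins within each trial destroys timing information while
conserving per-neuron totals exactly (space-only condition); permuting
neuron identities destroys spatial information while conserving per-bin
pooled counts (time-only condition).  By default one permutation per trial
is applied jointly across the untouched axis — the minimal destruction of
the targeted dimension — with independent per-neuron/per-bin permutations
as options.  Shuffles are applied to the full dataset before splitting so
train and test see the same manipulation; shuffled accuracies are compared
against the unshuffled space-and-time accuracy.  `coarsen_precision`
permutes bins within non-overlapping groups of `k` consecutive bins
(independently per neuron by default), reducing the effective temporal
precision to `k x` bin width while conserving per-group counts; the first
`k` at which accuracy is unchanged estimates the code's effective temporal
precision.  The latency code is isolated by deleting every spike after
each neuron's first (idempotent by construction).

## Reference values and problem sizes

The validation suite and `scripts/acceptance.py` regenerate the canonical
simulations at the sizes used throughout: 900-trial mixtures for module
recovery (averaged over 5-10 simulated datasets), 10 datasets of 20 trials
per stimulus for the selection study.  These sizes keep every study a
desk-scale computation while leaving the Monte-Carlo error of each
reported similarity well under a percentage point.

Module recovery similarities reproduced at these conditions: space-by-time
NMF ~98.6% (high SNR) and ~87.6% (low SNR); spatiotemporal NMF ~82% at low
SNR; orthogonal Tucker-2, spatiotemporal PCA and FA below 60% on the
overlapping non-orthogonal patterns; space-by-time NMF below 61% on the
non-separable sequential patterns.  Two quantities come out *better* in
this implementation than the single-run reference values they are compared
against: spatiotemporal NMF on clean high-SNR additive mixtures reaches
~97.5% (the data are exactly linear, and the multi-restart multiplicative
updates reliably find the parts-based optimum), and likewise ~97.5% on the
sequential patterns.  Two come out lower: ICA recovers the overlapping
blocks to ~77% rather than failing below 60% (on additive independent-
presence mixtures, the linear-mixing assumption of ICA is in fact close to
satisfied), and spatiotemporal PCA on the sequential, nearly disjoint
patterns lands near ~40%: with equal presence probabilities and equal
pattern norms the signal covariance spectrum is nearly degenerate, so the
principal axes are an arbitrary rotation of the pattern subspace.  These
deviations are stable across seeds and are properties of the study design
as specified, not optimizer noise.

## Known limitations

- The Poisson simulator has no spike-history or gain structure; claims
  about robustness to real retinal variability are outside its reach.
- PARAFAC-family models (identity core) are not implemented.
- LDA is the only decoder; the pipeline interface would admit others, but
  nonlinear decoders are out of scope.
- KL-divergence NMF objectives are not implemented (Euclidean only).
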