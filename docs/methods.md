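# Methods

## The model

`mfsacec` implements an ensemble classifier for samples × genes expression
matrices built from three mechanisms:

1. **Class-balanced bootstrapping.** From a training set of U samples, D
   replicates are drawn by sampling U indices uniformly with replacement.
   Each draw is then balanced by random oversampling: entries of every
   minority class *already present in the draw* are replicated uniformly at
   random until all class counts equal the majority count m, so a replicate
   has N·m ≥ U samples. A draw that misses a class entirely is redrawn (up
   to 100 times) and, failing that, replaced by a stratified per-class draw
   with sizes proportional to class frequency (minimum 1); oversampling is
   undefined on an absent class. An alternative reading — oversampling from
   the parent minority pool rather than the replicate — would admit samples
   the bootstrap never drew; we replicate drawn entries only.

2. **Multiple-filter supervised attribute clustering (the feature
   selector).** For each replicate and each of up to seven filter
   statistics (Fisher score, Welch t, chi-square, mutual information,
   Pearson vs the class indicator, SNR, Relief-F), every gene is scored
   against the class labels and the top P genes form a pool. The pool is
   then greedily partitioned: the highest-scoring remaining gene seeds a
   cluster with representative R; each remaining pool gene g is visited
   once, in descending score order, forming R + g and R − g; the
   better-scoring of the two (direct merge wins ties) is accepted only if
   it *strictly* improves the score of R, in which case g is absorbed with
   its sign and removed from the pool. Sign-flipped merging lets negatively
   co-expressed genes reinforce the representative instead of cancelling
   it. After the pass R is divided by the member count — the representative
   is the signed mean of the member profiles — and its score is recomputed
   on the divided vector. The Q highest-scoring representatives define a
   reduced sub-dataset of Q derived features. Unseen samples are projected
   by the same signed-mean map, the unique linear map consistent with how R
   was built from training profiles.

3. **Majority voting.** One base learner (naive Bayes, KNN, CART decision
   tree with Gini splitting, or an RBF-kernel SVM — exactly one type per
   ensemble) is trained per reduced sub-dataset, giving D × |filters|
   base models. Prediction takes the modal label over all votes; ties go to
   the label earliest in the training data's first-appearance order
   (deterministic, rather than randomized, tie-breaking).

Genes are additionally ranked by **occurrence frequency**: the number of
reduced sub-datasets whose selected clusters contain the gene. Clusters
within one sub-dataset are disjoint, so presence counting and
membership-multiplicity counting coincide. Genes in discarded clusters do
not count by default (`selected_only=False` counts them too).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| D | 10 | bootstrap replicates; accuracy plateaus near 10 in practice |
| P | 200 | genes kept per filter (100 used in the reference runs on the 1000-gene fixture to keep the pool/genome ratio comparable to microarray-scale use) |
| Q | 3 | representatives per sub-dataset |
| filters | all 7 | each filter contributes a differently biased view |
| base learner | KNN, k=5 | k sensible in 3..7; deterministic |
| bins | ⌈log₂U⌉+1, ≥2 | equal-frequency bins for chi2/MI, recomputed per scored vector so augmented representatives are re-binned |
| relief_k | min(10, min class size − 1), ≥1 | neighbours per class |
| relief_m | all | deterministic Relief-F; an integer uses the first m samples (no randomness may enter the clustering) |
| seed | — | master seed; replicate seeds are master + replicate index |

## Numerical choices

* Population (divide-by-n) variances everywhere, for determinism.
* Signed statistics (Pearson, t) return absolute values: an anti-correlated
  gene is maximally informative, and sign handling belongs to the merge
  step, not the score.
* Zero denominators: σ-sums in SNR/t/Fisher carry ε = 1e-12; Pearson
  instead handles a zero denominator exactly (score 0), because an ε there
  would make score(2g) strictly exceed score(g) by ~1e-12 and an exact
  duplicate gene would be absorbed — the scale-invariance of |r| is load-
  bearing for the duplicate-rejection behaviour of the clustering.
* Constant features score 0 under every filter.
* Relief-F weights can be negative; they are clipped at 0 so relevance
  scores are nonnegative. Whole-matrix scoring uses the native
  multivariate Relief-F (Manhattan distance in the range-normalized gene
  space); inside the clustering, where augmented vectors must be re-scored
  one at a time, Relief-F degrades to neighbours in the 1-D space of the
  scored vector, and the seed's score is likewise recomputed 1-D so
  accept/reject comparisons never mix the two scales.
* All batch score reductions run along the contiguous axis of the
  transposed batch, so a column's score is bit-identical whether computed
  alone or inside a batch. The clustering's accept/reject decisions are
  therefore exactly reproducible, and a naive list-based transcription of
  the greedy loop agrees with the production path bit-for-bit (this is
  tested on random instances).
* Tie rules, all deterministic: top-P and ranking ties break by ascending
  gene index; seed selection by lowest index; R + g beats R − g on equal
  scores; equal representative scores prefer the earlier cluster; equal
  vote counts prefer the earlier label.
* The clustering makes a single pass per cluster (no re-scanning after R
  changes), matching the narrative order of consideration; genes are
  visited by descending *initial* filter score on a frozen snapshot.

## Cross-validation protocol

`kfold_eval` re-runs the entire pipeline — bootstraps, filter scoring,
clustering, learner training — inside every training fold (stratified
folds by default; k = U gives LOOCV), so no information from held-out
samples reaches feature selection. A permissive `mode="preselect"` fixes
the reduced sub-datasets once on the full data and only retrains base
learners per fold; it is provided for comparison because the stricter
protocol is not the only defensible reading of common practice, but the
no-leakage mode is the default. `random_split_eval` runs repeated
stratified 2/3–1/3 splits and always reports the full accuracy
distribution with best and mean, never the best alone. ROC analysis is
restricted to binary tasks; the positive-class score is the ensemble's
vote fraction and AUC uses the rank (Mann–Whitney) formulation with
midranks, which equals the trapezoidal ROC integral. Multi-class runs
report the N×N confusion matrix instead.

## The synthetic generator

There is no public reference simulation for this method, so the generator
is this package's own design, built to exercise every bespoke mechanism
with known ground truth: class imbalance (the oversampling path),
negatively co-expressed planted genes (the sign-flip path), correlated
signal blocks (the clustering), and a large Gaussian noise background
(the filters). For class c, an informative gene takes
`sign·(δ·sd·μ_c + sd·√ρ·z) + sd·√(1−ρ)·ε` with μ_c ∈ {0,…,N−1}, a shared
per-sample latent z, and independent ε — unit-variance noise around a
class mean shifted by δ SDs, pairwise correlation ±ρ within the block.
Noise genes are N(0, sd). The frozen reference fixture has 60 samples
(40/20), 1000 genes, 20 informative (half anti-correlated), δ = 3,
ρ = 0.7, sd = 1, fixed seed.

What the generator does *not* emulate: microarray technical artifacts
(spatial effects, probe saturation, background), heavy-tailed or
intensity-dependent noise, batch effects, and realistic gene-gene
correlation beyond one latent factor per signal block. Passing tests
demonstrate that the mechanics work as specified, not that the method is
robust on real microarray data.

## Reference run sizes

The reference evaluation uses the frozen fixture with D = 10, P = 100,
Q = 3, all seven filters and the KNN learner: a 10-fold cross-validation
(ten full re-fits), one full-data fit for the ranking, and one 2/3–1/3
hold-out fit for ROC. These sizes were chosen as the smallest
configuration that exercises the full default filter roster at the
fixture's scale.

## Known limitations

* The greedy clustering capitalizes on chance: with small sample sizes,
  pure-noise genes are absorbed into clusters more often than intuition
  suggests, because the better of the two signed merges strictly improves
  a noise correlation with appreciable probability. This is a property of
  the algorithm itself (the naive oracle reproduces it exactly); the
  occurrence ranking compensates in the ensemble because hitch-hiking
  noise genes vary across replicates while planted genes recur.
* Relief-F scores are not scale-invariant under division of the
  representative by its member count, so Q-selection under Relief-F
  depends on the choice (made here) to re-score the divided vector.
* With very small P or strongly clustered pools, fewer than Q clusters may
  form; the fit fails with a contextual error rather than silently
  shrinking Q.
* Oversampling replicates drawn entries only; extremely small minority
  classes therefore appear as many copies of few distinct samples, which
  inflates within-class homogeneity in the replicates.
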