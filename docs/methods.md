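# Methods

## Model

The classifier targets binary (or multiclass) subtype prediction from a
samples × genes expression matrix in the n ≪ d regime. Input preprocessing
is deliberately minimal: raw counts are length-corrected within-sample to
TPM (each row sums to 10⁶) and transformed elementwise by log₂(x + 1); no
quantile normalization or batch correction is applied. Matrices that are
already TPM or log-scale can be supplied directly by flagging the stage.

Dimensionality reduction uses dense Gaussian random projection: a d × k
matrix **R** with i.i.d. N(0, 1/k) entries, so that E‖x**R**‖² = ‖x‖² and
pairwise Euclidean distances are approximately preserved
(Johnson–Lindenstrauss). Sparse/ternary RP variants are intentionally not
offered; the Gaussian construction is the one whose distance-preservation
behaviour the evaluation harness quantifies. No centering or column scaling
is applied before projection — the projection consumes the log matrix as-is.

m independent projections (seeds `base_seed + i`, i = 0…m−1) are
concatenated column-wise into an n × (m·k) fused block. Fusion, not score
averaging, is the design commitment: the comparator strategy — train one
classifier per projection and average the m probability vectors — is kept
in the package (`score_ensemble_fit_predict`) precisely so the two can be
compared under paired evaluation.

Ten heterogeneous base classifiers are fit on the fused block: k-NN with
distance and uniform weighting, random forests with gini and entropy
criteria, extra-trees with gini and entropy, LightGBM, histogram gradient
boosting, XGBoost, and a small two-hidden-layer feed-forward network.
Hyperparameters are the libraries' defaults, pinned in
`make_base_registry` with seeds threaded through and trees/boosters forced
to a single thread so runs are reproducible.

The meta-learner consumes the composite z(x) = [fused features |
base-model predictions]. "The original input x" in the composite is the
fused RP representation, not the d-dimensional transcriptome: the
meta-learner should see the same geometry the base models saw. Base
predictions enter either as hard labels (default; a single {0,1} column per
model in the binary case, one-hot for multiclass) or as full per-class
probability vectors (`meta_mode="probabilities"`, N·C columns, richer but
wider). Both modes are first-class.

The meta-learner g(·) is a fully connected network, hidden sizes
128-64-32-16, ReLU, dropout 0.2, softmax output; trained with cross-entropy,
Adam at learning rate 1e-4, 1000 epochs by default, batch size 64, and
class-weighted random sampling: each epoch draws n examples with
replacement with probability proportional to 1/(class frequency), so
minority and majority classes contribute equally in expectation. There is
no early stopping. The network is implemented directly in numpy (He
initialization, inverted dropout, bias-corrected Adam); it is small enough
that a framework would add nothing, and a single `numpy` RNG seeded from
the global seed makes training bit-reproducible. Inputs are z-scored
inside the model (means/scales stored with the weights) — a numerical
choice that makes the fixed 1e-4 learning rate well-behaved regardless of
the scale of the projected features.

## Leakage control

Base predictions used to train the meta-learner are out-of-fold: an inner
stratified 5-fold split is made, each base model is trained on 4/5 and
predicts the held-out 1/5, and only those predictions enter z(x). The base
models are then refit on all training rows for inference. The test suite
contains a constructed "memorizing" classifier that returns a sample's own
training label when it has seen the sample; out-of-fold stacking reduces it
to a constant fallback while fit-on-all stacking would reproduce the labels
perfectly — the regression test that guards the leakage property.

## Evaluation machinery

Metrics per fold: accuracy; F1 for a user-designated positive class
(macro-F1 via flag); MCC from the 2×2 confusion matrix with the
zero-marginal convention MCC = 0; AUC as the Mann–Whitney probability that
a random positive outscores a random negative, ties counted ½ (computed via
midranks). All four are cross-checked in tests against brute-force
counting/all-pairs oracles.

Model evaluation is repeated stratified k-fold CV (default 10 × 5-fold);
each repeat uses an independent partition seeded `seed + repeat`, and fold
assignments are cached in the result so two models can be compared on
identical partitions. The paired test is the two-sided Wilcoxon signed-rank
on per-fold differences (exact at these sample counts; verified against
sign-flip enumeration in tests); a paired t-test is available via flag. No
multiple-testing correction is applied. All-zero differences return p = 1.

Distance preservation between an original and a reduced representation is
the Pearson correlation of the two n(n−1)/2 pairwise-distance vectors,
pairs ordered (i < j) row-major so the vectors align exactly; coincident
point sets (zero-variance distances) return 0 with a warning. The harness
accepts any externally reduced matrix, so PCA/t-SNE/UMAP outputs can be
scored without the package reimplementing them.

## Synthetic cohorts

The generator emulates the statistical shape of a two-subtype bulk RNA-seq
cohort directly on the log-TPM scale: per-gene baseline means drawn from
Gamma(2, 2) (mean 4, right-skewed, a plausible spread of log₂-TPM means);
co-expressed gene blocks from shared latent factors (genes assigned to
blocks round-robin, loadings uniform in block_strength·[0.5, 1.5], factor
scores N(0,1)); class-differential signal as a ±δ/2 mean shift on a random
subset of genes; i.i.d. Gaussian noise (sd 1.0); values clipped at 0.
Class labels are drawn with a minority fraction of 0.45 — the class balance
typical of a two-subtype lung cohort — with deterministic counts and
seed-shuffled order.

The benchmark suite fixes four configurations: `strong_signal` (n=300,
d=2000, 100 signal genes, δ=2.0 — nearly separable; a nearest-centroid
oracle reaches ≥0.90 CV accuracy), `mid_signal` (δ=0.8), `null` (δ=0, no
signal genes), and `high_dim_small_n` (n=120, d=10000 — the regime that
motivates projection).

What the generator does not model: batch effects, library-size artifacts,
count-level noise (values are simulated on the log scale, not as negative
binomial counts), realistic gene-length distributions, or outlier samples.
Passing tests therefore demonstrate the pipeline's mechanics, calibration
under the null, and relative ordering of strategies — not absolute
performance on real tumor cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at reduced
operating points chosen to exercise the same qualitative properties the
full-scale configuration exhibits: k=100 with m=5 for the stacking
benchmark, k=100 with m=10 for the fusion-vs-ensemble comparison, k=50 with
m=3 on null data, meta-learner budgets of 200–300 epochs (training
accuracy saturates on these benchmark sizes well before the 1000-epoch
default). The fusion-vs-ensemble comparison uses five paired 80/20
hold-out splits, the standard protocol for comparing exactly these two
strategies. Seeds fan out from one global seed by fixed offsets (RP +0,
inner split +101, base models +211, meta-learner +307), recorded in run
manifests.

Degenerate inputs are defined rather than left to chance: all-zero count
rows normalize to all-zero TPM rows with a warning; single-class truths
give NaN AUC with a warning; k ≥ d warns but proceeds; an empty base
registry makes the composite equal the fused features.

## Known limitations

- Binary tasks are the tuned path; multiclass is supported by every formula
  (one-hot composites, softmax output, macro-F1) but not benchmarked.
- Probability calibration of the meta-learner is out of scope.
- The model archive is a joblib bundle; it is reproducible across runs on
  one platform but, like all pickled estimators, not a long-term storage
  format across library versions.
- No GPU path; all training is single-threaded CPU by design for
  reproducibility.
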