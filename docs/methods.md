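# Methods

## Model

The core model assumes that the microbiome composition and the metabolome
of a sample are two views of a shared low-dimensional latent state. A
3-layer fully connected encoder (hidden sizes 128 and 64, elu activation,
dropout between the hidden layers) maps the preprocessed microbiome
matrix `Mi` (samples × features) to the representation `Z` (samples ×
`latent_dim`, default 10). The decoder is linear and is *not* a free
parameter: on every forward pass the relation matrix is the least-squares
solution

    A = (Z'Z + λI)^(-1) Z' Me,   λ = 1e-8,

i.e. the Moore–Penrose pseudo-inverse of `Z` applied to the preprocessed
metabolite matrix `Me`, with a tiny ridge jitter that keeps the normal
equations well-posed without measurably changing the solution. `A` is
then replaced by its best rank-`r` approximation `A* = SVD_r(A)`
(`lowrank_rank`, default 6 — the default of the randomized-SVD routine
this construction mirrors; an exact truncated SVD is used and tested
against the full decomposition). The loss is the mean squared error
between `Me` and `Z A*`, averaged over samples *and* metabolites (the
per-sample-only normalization differs by a constant factor that the Adam
learning rate absorbs), plus an L2 penalty (1e-4) on the encoder weights.

Training is full batch: the relation matrix is recomputed from the entire
training set on every step, so the loss is well-defined and `A` is well
conditioned, and the whole system is trained at once — gradients
propagate through the rank truncation (exact SVD backward formula, with
clamped denominators for near-degenerate spectra) and through the
least-squares solve (standard linear-solve vector–Jacobian products) into
the encoder. No autodiff framework is used; the complete backward pass is
hand-derived and verified against central finite differences to ~1e-9
relative error in the test suite. Adam (lr 1e-3) runs for 200 epochs by
default; a dropout-free loss is traced every epoch, and the final `A*` is
frozen from the last epoch (optionally the best-loss epoch via
`use_best_epoch`). Runs are bit-reproducible given a seed.

Inference needs only the microbiome: `Z = encoder(Mi)` embeds samples
without metabolite data, and `Z A*` predicts their metabolites on the
z-scored log scale. These hyperparameters are fixed defaults chosen once
(the original per-dataset search space is: activation in {relu, elu,
tanh}, dropout, L2, learning rate); no tuning happens anywhere in the
package's analyses.

## Preprocessing

Microbiome chain: amplicon features are merged to a taxonomy level
(order by default) either by **mean** (arithmetic mean of member columns,
used by the non-negative linear analyses on relative data) or by
**sub-PCA** (per-taxon-group PCA of the log-transformed members, keeping
the smallest prefix of leading components whose cumulative explained
variance exceeds one half, at least one per group; component signs are
fixed by making the largest-magnitude loading positive). Merged values
are transformed `x -> log10(x + 0.1)` and z-scored per feature with
population (ddof = 0) statistics. Because sub-PCA scores are signed, the
log step necessarily precedes sub-PCA merging. The pseudocount 0.1 means
a zero maps to −1 and a count of 9.9 to 1; on *relative* data (entries
mostly below 0.05) the same transform is nearly affine — the log scale is
only really active on count-scale values, which is why the count layer of
the generator matters for log-linear analyses (below).

Metabolome chain: per-sample relative normalization (rows sum to one),
then the same log10 pseudocount transform and per-metabolite z-scoring.

Z-score statistics are always estimated on training samples only and
reused on held-out samples; in cross-cohort transfer each cohort is
normalized separately and no statistic of the test cohort ever enters
training (asserted in code). Zero-variance features get unit standard
deviation and are flagged; all-zero rows or columns in relative
normalization are left as zeros with a warning.

## Baselines

**Non-negative linear model.** `Me ≈ Mi A` with `A ≥ 0` and an L1
penalty, the fixed-left-factor special case of non-negative matrix
factorization. It is fit by seeded multiplicative updates on the
objective `0.5‖Me − Mi A‖² + λ‖A‖₁` (uniform[0,1] initialization,
monotone decrease asserted every iteration, relative-change tolerance
1e-6, max 2000 iterations); sklearn's `non_negative_factorization` on the
transposed problem is the independent oracle in tests. The default λ = 10
is kept from the reference analysis; because the exact minimizer is
identically zero when the data scale is too small relative to λ (the KKT
condition), the shipped `dominance_analysis` fixes the conventions that
put λ in its operative range: the microbiome is normalized **taxon-wise**
(each taxon divided by its sum across samples — this equalizes column
norms, which is what makes rare producer taxa discoverable at all), and
the metabolites are sample-relative **percentages** (rows sum to 100).
Dominance statistics per metabolite: the coefficient column normalized to
sum one (relative contributions), the top contribution and the fraction
of metabolites whose top taxon exceeds 0.8, the self-weighted expectation
Σ c_i² of the contribution vector, and the Spearman correlation between
top coefficients and the producers' population frequencies (mean relative
abundance on the original compositions).

**Shuffled null.** The sample order of the microbiome is permuted
independently of the metabolites, the relation refit, and the
per-metabolite expectations recomputed. The primary p-value is a
two-sided permutation test of the mean expectation against 49
shuffled-fit means — chosen because the two-sample (and paired) t-test
between real and shuffled expectations is structurally conservative
here: the two fits share all marginals and differ only in pairing, so
under the null their expectations are nearly identical per metabolite and
the t-test essentially never rejects (empirical rate 0/50). The Welch t
statistic is still reported for the descriptive comparison. A
taxon-identity shuffle is available as an alternative
(`shuffle_taxa=True`).

**Log-linear network.** `A = lstsq(Mi_log, Me_log)` on the z-scored log
chains, truncated to a given rank by exact SVD. A caution discovered
while validating it: truncating the *coefficient* matrix regularizes only
when the design is reasonably conditioned. If the features are many and
almost noise-free (low-rank signal plus a tiny isotropic floor), the
least-squares coefficients inflate along the design's noise directions
and the truncation retains exactly those; this is a property of the
estimator, not an implementation defect (the untruncated fit and a ridge
oracle behave as expected). At order-level dimensionality (20–30
features) the estimator behaves as intended.

## Evaluation

All protocols use 80/20 train/test splits repeated 10 times; metrics are
computed per repeat and then averaged with standard errors over repeats.
Metabolite prediction is scored by the Spearman correlation per metabolite
(average-rank ties; a constant true or predicted column scores 0 and is
flagged). Binary conditions: logistic regression with the fixed inverse
regularization strength C = 1, scored by AUC; continuous conditions:
Ridge at α = 1, scored by Spearman; no hyperparameter tuning. Model
comparisons use Welch's t-test (one- or two-sided) with a variance floor
for degenerate inputs and the star code * ≤0.05, ** ≤0.01, *** ≤0.001,
**** ≤0.0001 (a three-tier variant is available).

Canonical correlation with metadata is solved in closed form through the
SVD of the ridge-whitened cross-covariance `Sxx^(-1/2) Sxy Syy^(-1/2)`
(ridge 1e-6 on the covariance inverses), which is deterministic and
exactly equivariant under metadata column permutation — an iterative
NIPALS implementation was rejected for failing that invariance
numerically; it serves instead as the independent cross-check in tests.
Metadata is standardized, categorical covariates one-hot encoded,
constant columns dropped with a warning; a single-covariate metadata
degenerates to a ridge-fit best linear correlate. Per split the CCA is
fit on training samples and the held-out first canonical variates are
Spearman-correlated; weights of the first two components are reported in
absolute value with per-level stacking for categorical covariates.

Cross-cohort analyses match taxa by name at a chosen taxonomy level
(order by default, where cohort intersections are largest) and
metabolites by chemical formula via a user-supplied name→formula table —
formulas are parsed to element counts (condensed forms and parenthesized
groups supported) and compared canonically in Hill order, so `CH3COOH`
matches `C2H4O2` and isomers merge by summation. The core microbiome
scores each taxon by the sum over cohorts of its per-cohort presence
fraction (presence = relative abundance above a configurable floor,
default 0).

## Synthetic cohorts

The generator emulates paired cohorts under four regimes, each realizing
one conceptual model of the microbiome–metabolome relation, and stores
its exact ground truth (latent factors, loadings, producer maps) so that
recovery can be tested.

* **latent** — `U ~ N(0, I)` (samples × `latent_dim_true`); the binary
  condition shifts the first half of the latent coordinates by
  `condition_effect`. Microbiome log-signal `s·U B'` is softmax-normalized
  into compositions; metabolite log-signal `s·U C'` is exponentiated into
  concentrations; `s = signal_scale` sets the dynamic range (decades of
  concentration). Loading rows of `B` and `C` are random **unit-norm**
  vectors: every feature carries the latent signal at the same scale.
  (With iid Gaussian rows, occasional near-zero-norm rows produce
  metabolites that even a regression on the true factors cannot predict,
  which would confound recovery tests; unit norms realize the intended
  construction.) Gaussian noise of sd `noise_sd_mic`/`noise_sd_met` is
  added to the log signals.
* **linear** — Dirichlet compositions and `Me = Mi W + noise` with a
  sparse non-negative `W` (production-network view).
* **dominant** — heterogeneous taxon frequencies (log-normal base
  abundances); each metabolite is `w_j` times its single producer taxon's
  abundance, with the producer drawn from the rare tercile with
  probability `dominant_rarity_bias` (default 0.7) and
  `w_j ~ U(0.5, 2)/freq(producer)`: concentration units are set by the
  chemistry, not by the producer's community share, which is what makes
  rare taxa dominate without their coefficients tracking frequency.
* **multiview** — the condition shifts disjoint feature channels of each
  view; the views are conditionally independent given the label (no
  shared latent layer).

An optional counts layer resamples each composition multinomially at a
configurable sequencing depth (off by default). Count emission is what
makes the `log10(x + 0.1)` chain behave as a genuine log scale, so
log-linear ("multiplicative") analyses use it; analyses on relative data
do not need it. The multi-cohort generator draws loadings per *global*
feature (shared taxa keep their relation to the latent factors across
cohorts), overlaps consecutive cohorts' feature sets by a configurable
fraction, and either reuses the metabolite loadings across cohorts
(transfer should succeed) or draws them independently per cohort
(context-dependent relations; transfer should collapse). Cohort-specific
metabolite names with deterministic synthetic formulas exercise the
formula-matching harmonization end to end.

What the generator does **not** emulate: phylogenetic correlation among
taxa, overdispersed zero-inflated counts beyond multinomial sampling,
batch effects within a cohort, longitudinal autocorrelation, and
mechanistic consumer–resource dynamics. Passing tests therefore show that
the implementations recover the structures they model under their own
assumptions — not that those structures hold in any particular real
cohort.

## Analysis problem sizes

The shipped validation analyses use cohorts of 150–300 samples with
30–100 taxa and 25–50 metabolites, 10-fold repeated splits, 49-shuffle
permutation tests and 50-replicate calibration runs; together they
complete in a couple of minutes on one CPU. Recovery-style analyses set
the decoder rank equal to the generator's true latent dimension (a rank-6
decoder cannot represent a rank-10 relation, which would confound the
recovery question); the shipped default rank stays 6.

## Known limitations

* The encoder is a fixed 3-layer architecture; deeper or convolutional
  variants are out of scope.
* Full-batch training holds the entire cohort in memory — appropriate for
  typical cohort sizes (hundreds of samples), not for tens of thousands.
* The latent representation is cohort-specific: it is not comparable
  across experiments without a cross-platform extension, and transfer of
  the metabolite predictor across cohorts is reliable only when the
  underlying microbe–metabolite relations are shared.
* Formula-level metabolite matching merges isomers by construction.
* The dominance analysis' absolute coefficient scale depends on the
  chosen data conventions (taxon-wise microbiome, percent metabolites);
  relative contributions, which all reported statistics use, are the
  stable quantity.
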