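# Methods

## The problem and the model

Plasma cell-free DNA (cfDNA) is cut non-randomly by nucleases, so the
4-mer of reference sequence at each fragment's 5′ end (the *end motif*,
EM) carries a tissue- and disease-dependent signature. A sample is
summarised as a 256-dimensional frequency vector over the
lexicographically ordered 4-mers; in cancer patients thymine-prefixed
motifs rise and cytosine-prefixed motifs fall relative to healthy
controls. This package classifies cancer vs. control from such profiles
by treating the 256-point profile as a 1-D signal, decomposing it into
regular subsequences, and stacking per-subsequence machine-learning
models under a small sequence-aware neural meta-model.

The pipeline has three stages:

1. **Signal decomposition.** Either singular spectrum analysis (SSA:
   Hankel embedding with window L, SVD, component grouping, anti-diagonal
   averaging; groups {1}, {2,3}, {4..L} give subsequences SSA1–SSA3) or
   empirical mode decomposition (EMD: cubic-spline-envelope sifting into
   intrinsic mode functions plus a monotone residual, then pooling of
   IMFs by normalised permutation entropy into a high-PE subsequence E1
   (PE ≥ 0.8) and a low-PE subsequence E2). Both decompositions are
   additively exact: the subsequences sum back to the profile.
2. **Base learners.** Each subsequence matrix (samples × 256) is fit by
   five families — L1 logistic regression, elastic-net logistic
   regression, random forest, gradient-boosted trees, multilayer
   perceptron — with hyperparameters chosen by stratified 10-fold
   cross-validated AUC. Class-1 probabilities are the meta-features:
   out-of-fold during training (leakage control), full-data refits at
   prediction time. The SSA variant yields 15 columns, the EMD variant 10.
3. **Meta-network.** The meta-feature row is read as a sequence (one
   timestep per base model, subsequence-major order, feature dimension
   1) through two stacked LSTM layers, scaled dot-product self-attention
   (Q, K, V from three learned linear maps; softmax(QKᵀ/√d_k)V), global
   average pooling over timesteps, and a dense sigmoid head. Training
   minimises binary cross-entropy with Adam.

Benchmark scores are computed alongside: the motif diversity score
MDS = Σᵢ −Pᵢ·log Pᵢ / log 256 (normalised Shannon entropy, ∈ [0,1]);
its decomposition variants MDS_Sub = entropy of the softmax-normalised
subsequence (softmax because subsequences carry negative values), with
composites MDS-SSA (singular-value-mass-weighted mean of the three SSA
scores) and MDS-EMD (plain mean of the two EMD scores); and six
founder-profile (F-profile) mixture weights estimated by non-negative
least squares against a user-supplied 256 × 6 founder matrix.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| `max_insert` | 600 bp | fragment-length filter before end-motif counting |
| `min_mapq` | 20 | BAM mapping-quality floor (configurable; base-quality filtering happens upstream) |
| SSA window `L` | 8 | trajectory-matrix height; must satisfy 2 ≤ L ≤ N/2; groups {1},{2,3},{4..8} |
| PE order `m`, delay τ | 4, 1 | 24 ordinal patterns are well estimated from ≤ 256 points, making the 0.8 threshold meaningful |
| PE threshold | 0.8 | splits IMFs into E1 (irregular) / E2 (trend; the residual always joins E2) |
| CV folds | 10 | hyperparameter selection and out-of-fold stacking |
| LSTM units | 20 (SSA) / 10 (EMD) | two stacked layers; d_k equals the hidden size |
| epochs / lr / batch | 50 / 0.001 / 64 | Adam on binary cross-entropy |

## Numerical choices

- EMD sifting stops a mode when the extrema/zero-crossing counts differ
  by at most one **and** either the mean envelope is below 5% of the
  mode's amplitude or the Cauchy SD between consecutive sifts drops
  below 0.2; at most 100 sifts per mode, at most 10 modes. Decomposition
  stops on a monotone or numerically negligible residual. Envelope
  splines mirror two extrema across each boundary to suppress end
  swings.
- Permutation entropy breaks ties by index order (stable sort), so a
  constant series scores 0.
- Softmax is computed with max-subtraction (shift-invariant); entropy
  uses the 0·log 0 := 0 convention; the log base cancels in the
  normalised ratio.
- AUC is the Mann–Whitney statistic with half credit for ties; its CI
  uses the DeLong structural-components variance (or a seeded percentile
  bootstrap); the paired DeLong test returns p = 1 when the variance of
  the AUC difference degenerates with equal AUCs. Wilcoxon rank-sum
  tests use the exact null for small tie-free samples and the
  continuity-corrected normal approximation otherwise.
- NNLS contributions are reported raw and as percentages of their sum.
- The meta-network is implemented directly in NumPy (forward, exact
  reverse-mode gradients, Adam); gradients are validated against central
  finite differences in the test suite. All randomness (weight
  initialisation, batch shuffling, fold assignment) is seeded, so runs
  are bit-reproducible on one machine.

## The synthetic cohort generator

Real end-motif cohorts are controlled-access, so tests and the worked
examples run on synthetic data. The control baseline is a smooth,
deterministic product of per-position base propensities with a strongly
cytosine-dominated first position, mirroring the nuclease cleavage
preference that makes CCC-prefixed motifs the most frequent in healthy
plasma. The cancer baseline multiplies thymine-prefixed motifs by
exp(effect) and cytosine-prefixed motifs by exp(−effect) and
renormalises; because the shift erodes the dominant motif class, motif
diversity rises in cancer, reproducing the reported direction. Samples
are logistic-normal draws around their class baseline: per-motif
Gaussian noise on log frequencies with standard deviation
1/√concentration (default concentration 50, ≈14% coefficient of
variation), then renormalisation. Defaults are 50 samples per group,
effect 0.5.

The generator emulates compositional profiles with a class mean shift
and independent per-motif dispersion. It does **not** emulate
sequencing-depth multinomial noise, batch/modality effects, inter-motif
covariance, or cancer-type heterogeneity — so passing the end-to-end
checks demonstrates that the machinery recovers a planted signal of
realistic shape and size, not that real-cohort accuracy is guaranteed.

A companion fragment simulator plants 12-bp fragment spans on a
synthetic reference so that both 5′-end 4-mers are i.i.d. draws from a
target distribution; extraction then provably converges to the target,
which closes the loop on the extractor. The bundled founder matrix
generator produces six Dirichlet columns (sum 1, rank 6) and is a
labelled synthetic stand-in: real founder profiles are user-supplied
input and are never bundled.

## Problem sizes used by the test suite

End-to-end checks train on 60 + 60 simulated samples and evaluate on a
held-out 20 + 20 set, sweeping effect sizes {0, 0.1, 0.25, 0.5} over
five seeds with a reduced hyperparameter grid per algorithm (a single
point or a short path); full grids are the library defaults. The null
calibration of the motif scan uses 200 replicates of 40 + 40 samples.
These sizes match the scale of the cohorts the method targets while
keeping the whole suite runnable on one CPU in minutes.

## Design choices where the design was open

- **Stacking protocol:** the meta-network trains on out-of-fold base
  probabilities; hyperparameters are selected once per
  (subsequence, algorithm) by grid search and reused for the OOF pass
  (full nested CV would multiply cost without changing the leakage
  argument).
- **Sequence shaping:** the meta-feature vector enters the LSTM as
  n_models timesteps of dimension 1, in the recorded
  subsequence-major/algorithm-minor manifest order. The manifest is
  stored with the model; a column mismatch at prediction time is an
  error, never silent reordering.
- **Normalisation:** per-feature z-scores frozen from the training set.
- **Both 5′ ends always counted**, including for fragments shorter than
  8 bp where the windows overlap.
- **Crick-end motif** is the reverse complement of the reference window
  at the fragment's right end (the 5′ end read on the minus strand).
- **Residual assignment:** the EMD residual always joins the low-PE
  pool, since it is by construction the trend.
- **MLP solver:** lbfgs without early stopping; with cohorts of tens of
  samples, a validation split for early stopping starves the optimiser.

## Known limitations

- EMD is sensitive to boundary handling; different envelope conventions
  yield slightly different IMF splits (the E1/E2 *sum* is always exact).
- With ~100-sample cohorts the meta-network operates far below the data
  sizes deep models usually need; it works here because its input is 10
  or 15 already-calibrated probabilities, not the raw 256-mer profile.
- The DeLong CI is asymptotic and can touch the [0,1] clamp for AUCs
  near 1 at small n; the bootstrap option avoids the clamp.
- Multi-class (per-cancer-type) prediction, model fusion across
  decomposition variants, and plotting are out of scope.
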