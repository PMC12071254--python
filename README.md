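# emdeepsd

Cancer-vs-control classification from plasma cell-free DNA (cfDNA)
**end-motif profiles** — the frequency vector of the 256 possible 4-mers
of reference sequence at cfDNA fragments' 5′ ends. Nucleases cut cfDNA
non-randomly, and the cut-site sequence context shifts in cancer
(thymine-prefixed motifs rise, cytosine-prefixed motifs fall), so the
profile is a liquid-biopsy biomarker. This package is for computational
biologists who have aligned cfDNA fragments (BAM/BED + reference FASTA)
or precomputed profile matrices and want a full decomposition-based
classification and benchmarking stack.

## What it computes

Treating a sample's 256-point profile X = (X₁ … X₂₅₆) as a signal:

- **Signal decomposition.** Singular spectrum analysis (SSA; Hankel
  embedding with window L = 8, SVD, grouping {1}, {2,3}, {4..8},
  anti-diagonal averaging → subsequences SSA1–SSA3) and empirical mode
  decomposition (EMD; spline-envelope sifting into intrinsic mode
  functions + residual, pooled by permutation entropy into a high-PE
  subsequence E1 and low-PE subsequence E2). Both reconstruct X exactly.
- **Diversity scores.** MDS = Σᵢ −Pᵢ log Pᵢ / log 256 (normalised
  Shannon entropy ∈ [0,1]); per-subsequence MDS_Sub via softmax
  normalisation; composites MDS-SSA (singular-value-weighted) and
  MDS-EMD (mean).
- **Founder-profile deconvolution.** Non-negative least squares of a
  profile against six founder end-motif profiles (user-supplied 256 × 6
  matrix), A ≈ Σᵢ Pᵢ·Fᵢ with Pᵢ ≥ 0.
- **Stacked classifier.** Five learner families (LASSO, elastic net,
  random forest, XGBoost, MLP) per subsequence, tuned by 10-fold CV AUC;
  their out-of-fold probabilities feed a meta-network of two LSTM
  layers, scaled dot-product self-attention softmax(QKᵀ/√d_k)V, global
  average pooling and a sigmoid head (the SSA variant stacks 15 models,
  the EMD variant 10).
- **Evaluation.** SEN/SPE/ACC/F1 with exact binomial CIs, Mann–Whitney
  AUC with DeLong or bootstrap CIs, the paired DeLong test for
  correlated AUCs, Benjamini–Hochberg/Bonferroni adjustment, and a
  per-motif Wilcoxon differential scan.
- **Synthetic cohorts.** A seeded generator that reproduces the cancer
  shift direction on a realistic C-dominated baseline, plus fragment /
  reference / founder fixtures, so everything runs without downloads.

## Worked example

```bash
python examples/04_train_classifier.py
```

trains the SSA variant on a simulated 60 + 60 cohort and scores a
held-out 20 + 20 set:

```
base learners fitted: 15
meta-network loss: 0.673 (epoch 1) -> 0.002 (epoch 50)
held-out AUC = 1.000 (95% CI 1.000-1.000)
sensitivity = 1.000, specificity = 1.000, accuracy = 1.000, F1 = 1.000
```

The 15 base learners are the 3 SSA subsequences × 5 algorithms; the
falling loss shows the meta-network fitting their stacked probabilities;
the held-out AUC of 1.0 means the planted effect (log-scale shift 0.5 on
thymine-/cytosine-prefixed motifs) is fully recovered on unseen samples.
`examples/01–03` cover extraction from fragments, decomposition +
diversity scores, and the differential motif scan; for instance the scan
on a simulated cohort prints

```
significant motifs: 65 up, 64 down (adjusted p < 0.05)
first bases among up-motifs:   ['G', 'T']
first bases among down-motifs: ['C']
```

— the up-regulated motifs are (mostly) thymine-prefixed and the
down-regulated ones cytosine-prefixed, matching the planted shift.

## Command line

A thin CLI wraps the library:

```bash
emdeepsd simulate --n-cancer 50 --n-control 50 --effect-size 0.5 --seed 1 --out profiles.tsv
emdeepsd extract --bed fragments.bed --ref genome.fa --sample-id S1 --out profile.tsv
emdeepsd score --profiles profiles.tsv --out scores.tsv
emdeepsd motif-scan --profiles profiles.tsv --out scan.tsv
emdeepsd train --profiles profiles.tsv --variant ssa --seed 0 --out bundle/
emdeepsd predict --bundle bundle/ --profiles profiles.tsv --out preds.tsv
emdeepsd evaluate --predictions preds.tsv
```

Profiles are TSV (sample_id, 256 motif columns AAAA…TTTT, optional
binary label); trained models are saved as a bundle directory with a
JSON manifest.

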