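# pepmhc

Anchor-position-aware prediction of MHC class I peptide binding
affinity.

## The problem

MHC class I molecules present short endogenous peptides (8–13 residues)
to cytotoxic T cells. Whether a peptide binds a given MHC-I allele is
dominated by a few *anchor residues* — canonically peptide position 2
and the C-terminus — that sit in pockets of the binding groove, and the
anchor geometry shifts with peptide length. Predicting the binding
affinity of an arbitrary (peptide, allele) pair is a core step in
epitope discovery and neoantigen vaccine design. Pan-specific
predictors represent the allele by its 34-residue *pseudo sequence*
(the groove residues in peptide contact), so a single model covers all
alleles; most such models simply concatenate the two sequences, which
blurs anchor positions for non-9-mer peptides.

## The model

`pepmhc` implements a pan-specific regression network built around two
ideas:

1. **Position-wise gated layer.** Each peptide position *i* passes
   through its own gated linear unit,
   `x̄_i = σ(W_i x_i + b_i) ⊙ (V_i x_i + c_i)`,
   letting the model amplify or suppress residue information per
   position — the mechanism for anchor awareness across lengths.
2. **Binding-interaction convolution layers (BICL).** The convolution
   kernels that scan the peptide are not free parameters: kernel *i* of
   size *k* is generated from the MHC embedding matrix `Y ∈ R^{34×d}`
   as `K_i^k = f(U_i Y)`, so the filter bank is conditioned on the
   allele. Two BICLs (one on the raw peptide embedding, one on the
   gated embedding) are combined residually:
   `C⁰ = f(norm(BICL₁(X, Y)) + norm(BICL₂(X̄, Y)))`.
   Kernel sizes 9/11/13 (128/64/32 kernels) cover common peptide
   lengths; all size classes emit width L − 9 + 1 = 7.
3. Position-wise fully connected layers (256, 128), max-pooling over
   the 7 positions, and a sigmoid head produce an affinity ŷ ∈ (0, 1)
   on the transformed IC50 scale `1 − log(IC50 nM)/log(50000)`
   (500 nM, the conventional binder cutoff, maps to 0.426).

Training minimizes mean squared error with Adadelta (lr 0.9, weight
decay 1e-4), batch size 128, and a plateau scheduler; the full protocol
is 10 repeats of 5-fold cross-validation with the 50 resulting models
averaged at prediction time. Because real benchmark compilations are
external downloads, the package ships a planted-motif simulator that
generates alleles with known anchor PSSMs — legible from their pseudo
sequences — so the whole pipeline (training, evaluation, motif
extraction) is testable offline against ground truth.

## Worked example

```bash
# 1. simulate 4 alleles with planted anchors (6000 records)
pepmhc simulate --out sim --n-alleles 4 --peptides-per-length 250 --seed 42

# 2. train a small ensemble (scaled well down from the 10x5x50-epoch default)
pepmhc train --binding sim/binding.tsv --pseudo sim/pseudo.tsv \
             --out models --repeats 1 --folds 2 --epochs 10 --seed 0

# 3. predict, evaluate, and extract a motif
printf 'SYN-00 ACDEFGHIK\n' > pairs.tsv
pepmhc predict --models models --pairs pairs.tsv --pseudo sim/pseudo.tsv --out preds.tsv
pepmhc motif --models models --pseudo sim/pseudo.tsv --allele SYN-00 \
             --length 9 --n 20000 --out motif9.tsv --seed 0
```

`preds.tsv` holds one row per pair:

```
allele  peptide    length  pred_affinity  pred_ic50_nm  binder
SYN-00  ACDEFGHIK  9       0.070177       23399.64      0
```

`pred_affinity` is on the [0, 1] transformed scale, `pred_ic50_nm` its
inverse transform, and `binder` applies the IC50 < 500 nM rule (this
random peptide matches neither planted anchor, hence a weak ~23 µM
prediction). In `motif9.tsv` each row is one peptide position: 20
residue frequencies plus an information-content column in bits. Even
this briefly trained ensemble nails the dominant planted anchor —
position 2 carries IC 4.32 bits (the maximum, log2 20) against ≤ 0.24
everywhere else; fully trained 50-epoch models sharpen the C-terminal
anchor as well, which the benchmark suite measures.

Library use mirrors the CLI: `generate_dataset`, `train_ensemble`,
`ensemble_predict`, `build_report`, `extract_motif`.

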