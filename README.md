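# m1apred

Identification of 1-methyladenosine (m1A) sites in RNA sequences from
sequence alone, using moment-based positional/compositional features and
ensemble classifiers.

m1A is a post-transcriptional modification carrying a methyl group at
position 1 of adenosine; it occurs at tRNA position 58 and in mRNA/rRNA,
and is implicated in translation, RNA stability and several diseases.
Experimental mapping (mass spectrometry, site-directed mutagenesis) is
slow, so sequence-based prediction is the practical screen.  This package
is for computational biologists who want a self-contained, testable
implementation of the full pipeline: window extraction, feature encoding,
ensemble training, evaluation protocols and per-site prediction — plus a
synthetic-data generator so every stage can be exercised and validated
without any external dataset.

## The encoding

Each candidate site is a 41-nt window *B(A) = B₋₂₀ … B₋₁ A B₊₁ … B₊₂₀*
with the candidate adenosine at the center.  Bases are coded A=1, C=2,
G=3, U=4, and six feature groups are concatenated into one 522-value
vector **f′** = [f₁ … f₅₂₂]ᵀ:

| group  | size | content |
|--------|------|---------|
| PRIM   | 90   | moments of the position-relative incidence matrix at k-mer levels 1, 2, 3 (4×4, 16×16, 64×64): cell *V*ᵢ→ⱼ accumulates the distance *q − p* over ordered occurrence pairs of k-mers *i* (at *p*) and *j* (at *q > p*) |
| RPRIM  | 90   | the same on the reversed sequence |
| FV     | 84   | overlapping k-mer counts Ᵹ, k = 1, 2, 3 (4 + 16 + 64) |
| AAPIV  | 84   | per-k-mer accumulated occurrence positions δᵢ = Σₖ pₖ |
| RAAPIV | 84   | AAPIV of the reversed sequence |
| SEQMAT | 90   | moments of the row-major sequence matrix at k = 1, 2, 3 |

Matrix-valued groups are reduced to a fixed 30-coefficient set per k-mer
level: the raw moments *N*ⱼₖ = Σ c^j d^k β_cd, the central moments
*n*ᵢⱼ about the matrix centroid, and the discrete Hahn moments
*H*ᵢⱼ = Σ β_pq h  ᵢ(p, N) h  ⱼ(q, N), each at the ten orders with
j + k ≤ 3.  Windows are standardized per column (train-partition scaling
only) and fed to one of nine ensemble configurations — one blending
stack (ANN + kNN + SVM + decision tree under a gradient-boost
meta-learner), four bagging models and four boosting models — evaluated
by stratified 70/30 independent testing and 10-fold cross-validation with
Acc, Sp, Sn, MCC, F1 and AUROC.

## Worked example

```bash
python examples/02_simulate_and_train.py
```

generates 300 labeled synthetic windows with a planted upstream-AG signal,
trains the histogram-gradient-boosting configuration on a stratified 70%
partition and prints the held-out report:

```
trained boosting/hist_gradient_boost on 210 windows, tested on 90
  Acc       0.900
  Sp        0.800
  Sn        1.000
  MCC       0.816
  F1-score  0.909
  AUROC     0.881
```

Acc is the fraction of correct calls on the 90 held-out windows; Sn and Sp
are the recall of true m1A and non-m1A windows respectively; MCC balances
all four confusion cells; AUROC is the probability that a random positive
window outscores a random negative one.  The other examples cover raw
feature encoding (`01`), per-site scanning of arbitrary sequences (`03`)
and statistical model comparison (`04`).  The same capabilities are
available from the shell:

```bash
m1apred simulate --n-pos 200 --n-neg 200 --out train.fa
m1apred train --fasta train.fa --model boosting/hist_gradient_boost --bundle model.joblib
m1apred predict --bundle model.joblib --fasta query.fa
```

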