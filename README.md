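# tcrbind

Sequence-only prediction of T-cell receptor (TCR) binding to antigenic
peptides, with a cross-attention layer built to be *interpreted*: attention
weights are called at residue level, mapped onto TCR–pMHC complex
structures, and tested for association with hydrogen-bond patterns.

The package is aimed at computational immunologists who want (a) a
self-contained CDR3αβ–peptide binding classifier that consumes nothing but
amino-acid sequences, and (b) the downstream analysis machinery —
dataset-construction protocol, residue-level attention calling, geometric
H-bond detection, paired statistics — that turns a trained model into
structural hypotheses.

## The model

Each record is a triplet (CDR3α, CDR3β, peptide) with a binary binding
label. The TCR side is the single token sequence `CDR3α : CDR3β` (colon =
connection token), padded to the training maxima; the peptide is encoded
alone. After learned token + positional embeddings and per-side Transformer
self-attention encoders, a single cross-attention layer with four heads per
side relates the two sequences:

```
Attention(Q, K, V) = softmax(QKᵀ / d) V,     d = √(D/heads)

H_TCR     = softmax(Q_peptide K_TCRᵀ / d) V_TCR        (peptide queries)
H_Peptide = softmax(Q_TCR K_peptideᵀ / d) V_peptide    (TCR queries)
```

so each peptide position distributes one unit of attention over the TCR
residues and vice versa. `[H_Peptide ; H_TCR]` is concatenated along the
length direction, averaged over non-padded query positions, and passed
through an MLP with a sigmoid head, giving a binding confidence in [0, 1].
Training minimizes binary cross-entropy (Adam) with early stopping after 10
non-improving epoch evaluations, restoring the best weights. The network is
implemented in NumPy on a small reverse-mode autodiff engine
(`tcrbind.autodiff`), so it runs anywhere and its gradients are
unit-checked against finite differences.

Interpretation: in head *h*, residue *t* is **largely attended** when

```
max_p a_{t,p}  >  mean(A_h) + γ · sd(A_h)
```

with γ = 4.5 (TCR side) / 5.5 (peptide side) by default; calls are
concatenated over heads as a multiset. Calls are combined with per-residue
structural properties (H-bonded to peptide / CDR3 of own or opposite chain
/ non-CDR3 TCR; loop-edge flags; closest distances; H-bond counts from a
3.5 Å heavy-atom N/O/S detector) and compared between the large- and
small-attention groups with two-sided paired t-tests across complexes,
Benjamini–Hochberg adjustment, and an FDR ladder (*** 0.05, ** 0.10,
\* 0.15). An input-perturbation scanner substitutes single residues and
records confidence and attention-call changes.

## Worked example

`examples/02_train_and_evaluate.py` generates 1,500 synthetic records under
a plantable binding rule (positive iff CDR3β and the peptide share a
trigram, 5% label noise), trains a small model, and evaluates a held-out
split:

```
monitored BCE: 0.6945 -> 0.2418 (best epoch 5)
held-out ROC AUC 0.9489, APS 0.9420
confusion at F1-max threshold 0.717: TP=159 FP=12 FN=7 TN=122 (F1 0.944)
```

The ROC AUC measures recovery of the planted rule: with 5% flipped labels
the achievable ceiling is ≈0.95, so ≈0.95 means the model has essentially
learned the rule. The other examples each demonstrate one capability —
dataset curation and 5:1 negative augmentation (`01`), attention maps and
residue calling (`03`), H-bond detection and property tables on a toy PDB
(`04`), the paired-t/BH comparison table (`05`), and perturbation scans
(`06`). A thin CLI (`tcrbind simulate|build-dataset|train|predict|
evaluate|attention|perturb`) wires the same functions for shell use.

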