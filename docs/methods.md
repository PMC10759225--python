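# Methods

## Problem and data model

The unit of data is an interaction record: a CDR3α sequence, a CDR3β
sequence, and a peptide, with a binary label for whether the TCR carrying
those CDR3 loops responds to the peptide (a cellular-assay-level event; MHC
context, V/J genes and the rest of the receptor are deliberately not used).
Datasets are ordered collections of such records with a train/test role;
padded sequence widths are always the observed maxima of the *training*
role, and at inference longer sequences are rejected rather than truncated.

Curation follows the standard protocol for this kind of benchmark:

1. drop records missing any of the three sequences or containing
   non-standard residues (only the 20 canonical one-letter codes pass;
   B/J/O/U/X/Z, gaps and lowercase all cause a drop);
2. deduplicate exact (CDR3α, CDR3β, peptide) triplets — first occurrence
   wins, and a conflicting label on a later duplicate warns;
3. remove from the test set every triplet also present in training.
   Overlaps of a *single* element (same peptide, or same CDR3 pair, paired
   differently) are retained on purpose: the same TCR legitimately occurs
   with several peptides, and the overlap-report machinery quantifies
   exactly this leakage (unique-element counts and per-record seen/unseen
   partitions);
4. augment positives with ratio × negatives (default 5, giving a positive
   rate of exactly 1/6) by uniformly re-pairing CDR pairs and peptides
   *drawn from the same dataset*. Negatives never duplicate a positive
   triplet or each other; if the combinatorial space cannot supply enough
   distinct negatives the operation fails loudly rather than degrading the
   ratio. Note this cannot exclude pairs that would bind in reality but
   are absent from the dataset — assumed-negative noise is inherent to the
   protocol.

Virtual screens are built by sliding a 9-residue window at stride 1 over a
protein and crossing every CDR pair with every window peptide; counts are
available without materializing the product, since screens reach millions
of records.

## Network

Per side: token embedding + learned positional embedding (indexed
0…pad_to−1) → `encoder_layers` post-norm Transformer blocks (multi-head
self-attention, 2×-wide ReLU feed-forward, residuals + LayerNorm) → one
cross-attention layer with `heads_per_side` heads in which the *other*
side supplies the queries. The TCR-side hidden values are indexed by
peptide positions and vice versa; the two are concatenated along the
length direction, averaged over non-padded query positions, and fed to a
ReLU MLP with a sigmoid output.

Defaults: embed_dim 64, 4 heads per side, 2 encoder layers, mlp_hidden
128, dropout 0.1, scaling d = √(embed_dim/heads). These are chosen as
standard small-Transformer ratios that train comfortably on one CPU; all
are config-overridable and serialized with the checkpoint (weights +
config + vocabulary in one `.npz`).

Numerical/design choices worth knowing:

- **Pad masking.** Padding tokens are masked out of every attention
  softmax (additive −1e30 before normalization). This is a choice, not a
  necessity — unmasked pads would also "work" but leak length information
  into attention rows; the flag `mask_pads` records it in the config so it
  can be toggled.
- **Cross-attention inputs** are the *encoder outputs*, not raw
  embeddings. The alternative wiring (cross-attention on embeddings) is
  coherent but discards per-side context before the sides meet.
- **Pooling** excludes padded query positions; each record's average is
  over its true lengths, so confidence is invariant to the padded widths
  and to batch composition (checked to 1e-6).
- **Sigmoid head**: the output must live in [0, 1]; sigmoid is the
  canonical link for a BCE loss.
- The implementation is float64 NumPy over a ~300-line reverse-mode
  autodiff tape; analytic gradients are tested against central differences
  (rel. 1e-4) on every block, and the max-shift inside softmax is exact
  (softmax is shift-invariant).

## Training and evaluation

Adam (default moments), BCE loss, early stopping: the monitored BCE
(training-set BCE in eval mode by default; a validation split is
available) is evaluated once per epoch, with the initial weights as
evaluation 0; after `patience` (default 10) consecutive evaluations
without strict improvement, training stops and the best weights are
restored. "10 updates" is interpreted at epoch granularity; the
step-granular reading is configurable via `max_epochs`/`patience`.

Metrics: ROC AUC (rank formulation; unit-tested against the O(n²)
pairwise oracle), average precision (step summation), confusion at a
threshold with the convention *score ≥ θ is positive*, the F1-maximizing
threshold over the observed scores (ties → smallest θ), fold enrichment =
precision / base positive rate, and per-peptide breakdowns for the top-k
most frequent peptides.

## Attention calling

For head h let A_h be the side's attention matrix. On the TCR side, entry
a_{t,p} is the weight on TCR position t given peptide query p, and each
query row sums to 1. Residue t is called **large** when
max_p a_{t,p} > ā + γσ, where ā and σ are the mean and *population*
standard deviation of all entries of A_h; "small" uses strict < against
the same bound. Thresholds are therefore per-structure and per-head.
Defaults γ_TCR = 4.5, γ_peptide = 5.5 — at these values a trained model
calls roughly 10–30% of residues once the four heads are concatenated
(multiset concatenation: a residue called in two heads counts twice).
The colon connection token occupies a TCR-axis position but has no
residue; it is excluded from calling and from structural mapping. The
"small" group defined by the strict-< rule is, at these γ values, close to
the complement of the large group; the complement itself can be obtained
by excluding the large calls, and both conventions coexist in the API
(calls are explicit index sets, so either group can be built).

Monotonicity (large sets shrink weakly as γ grows) and equality with a
brute-force per-residue oracle are asserted over random matrices.

## Structural properties

PDB complexes are parsed with gemmi (altloc A, heavy atoms, no
waters/hetero). CDR3 spans arrive as annotations (author numbering,
1-based inclusive); a C…F heuristic helper exists for convenience but is
never applied silently. H-bonds: any inter-residue pair of N/O/S heavy
atoms within 3.5 Å, excluding the backbone N–O contact across a peptide
bond; no hydrogens or angle criteria (most crystal structures lack
hydrogens), so absolute counts are cutoff-sensitive — the cutoff is a
parameter, and the detector is validated against an all-pairs oracle on
toy structures rather than against any external program.

Per residue (CDR3 spans of both chains + peptide): booleans for H-bonding
to the peptide, to CDR3 of the own/opposite chain, to non-CDR3 TCR, to any
TCR ("non-CDR3 TCR" = any residue of either TCR chain outside both
annotated spans); the loop-edge flag (within 4 residues of either CDR3
terminus; 3 for the peptide); the closest heavy-atom distance to the
peptide (to the TCR, for peptide residues); and three H-bond counts
(total, with own-chain CDR3, with peptide). Derived-boolean consistency
(hb_tcr ⇔ hb_cdr3 ∨ hb_noncdr3_tcr, own/opposite partitions) is asserted.
Annotated residues missing from the density are flagged and excluded from
group statistics.

## Attention-vs-structure statistics

Per complex and group (large/small), a boolean property contributes the
proportion P = A/B of called residues exhibiting it (continuous
properties: the per-residue mean); head multiplicity weights the
proportion. Complexes with an empty group are dropped pairwise per
property, with a warning. Across complexes, each property is tested with
a two-sided paired Student's t (each complex contributes one paired
observation); the table's p-values are BH-adjusted *within* the table
(TCR side: 11 properties, peptide side: 7 — adjusted per table, matching
each table's own adjusted column), and symbols follow BH rejection at FDR
0.05/0.10/0.15. Zero-variance differences short-circuit: identical groups
warn and report NaN; constant non-zero differences warn and report the
p → 0 limit.

Calibration is simulated rather than assumed: on null fixtures
(39 complexes, ~20% large groups, base rate 0.3) the rejection rate at
α = 0.05 sits in [0.03, 0.07] over 1,000 replicates, and a +0.25
proportion shift in the large group is detected with power ≈ 1.

## Synthetic generators — what they emulate and what they don't

- `gen_interactions`: CDR3α/β lengths uniform on 8–20, peptides 8–12
  (inside the envelope observed in curated databases), uniform residue
  usage, CDR pairs reused across several peptides. The binding rule —
  positive iff CDR3β and the peptide share a trigram — is planted via a
  fixed repeated-residue motif (`WWW`) inserted into ~70.7% of CDR3βs and
  peptides independently (≈50% positives); labels always follow the
  *actual* k-mer intersection (chance collisions included) and are then
  flipped with ε (default 0.05). The repeated-residue motif makes the rule
  visible in residue composition, which is what lets a 1-layer model reach
  AUC > 0.9 in minutes; real binding signal is of course not compositional
  in this way, so passing the learnability check demonstrates the training
  loop and architecture function, not biological validity.
- `gen_structure_fixture` / `simulate_rejection_rate`: per-structure
  residue counts 20–34, ~20% large groups, Bernoulli properties at base
  rate p0 = 0.3 (large-group rate p1 = 0.55 under the planted effect).
  They emulate the *statistical* shape of a 39-complex analysis, not
  geometry.
- `write_toy_pdb`: single-letter chains, sequential numbering, occupancy
  1.00, B 0.00 — the minimum that exercises the real PDB parser.
- All generators are deterministic under their seed.

## Problem sizes

Desk-scale defaults used by the test suite and the acceptance script:
learnability runs on 3,000 records (2,400 train / 600 held out) with a
32-dim, 1-encoder-layer, 4-head model for 8 epochs; calibration uses
1,000 replicates of 39 structures; screen combinatorics are computed
without materializing the 2.1M-record product. These sizes were chosen so
the whole pipeline reruns from scratch in minutes on a single CPU while
keeping every statistical check well-powered.

## Known limitations

- Real benchmark corpora (curated databases, virtual screens, crystal
  structures) are not bundled; loaders support their formats, and the
  desk-scale experiments stand in for full-scale training.
- The H-bond detector is distance-only; programs that model donor/acceptor
  geometry will disagree on individual bonds.
- Assumed-negative sampling cannot rule out true binders among the
  generated negatives.
- The learnability benchmark's noise ceiling (AUC ≈ 0.95 at ε = 0.05)
  means small configuration changes can move the result by a few
  hundredths; the acceptance margin (≥ 0.90) absorbs this.
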