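"""Dataset construction: clean, deduplicate, augment with 5:1 negatives.

Builds a small synthetic interaction table, runs the standard curation steps
and prints the overlap statistics a train/test split report would contain.
"""

import tcrbind as tb

# a synthetic table of (CDR3a, CDR3b, peptide) triplets; each CDR pair is
# reused against several peptides, as in curated databases
ds = tb.gen_interactions(n_cdr_pairs=80, n_peptides=50,
                         rule=tb.MotifRule(seed=0), records_per_pair=5)
ds = tb.dedup_triplets(tb.clean(ds))
print(f"curated records: {len(ds)} (positive rate {ds.positive_rate:.3f})")

# keep the positives and re-pair CDRs with peptides to add 5x negatives;
# the resulting positive rate is exactly 1/6
positives = tb.InteractionDataset([r for r in ds.records if r.label == 1])
augmented = tb.sample_negatives(positives, ratio=5, seed=0)
print(f"after 5:1 augmentation: {len(augmented)} records, "
      f"positive rate {augmented.positive_rate:.4f}")

# overlap accounting between two splits: how many records reuse a peptide
# or CDR pair already seen in training
train = tb.InteractionDataset(augmented.records[: len(augmented) // 2])
test = tb.InteractionDataset(augmented.records[len(augmented) // 2:])
test = tb.remove_test_overlap(train, test)
rep = tb.overlap_report(test, train)
print(f"test records: {rep.interaction_count}; "
      f"with a peptide seen in training: {rep.records_with_seen_peptide}; "
      f"with a CDR pair seen in training: {rep.records_with_seen_cdr3ab}")
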