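"""Paired t-tests with BH adjustment on attention/property fixtures.

Simulates 39 complexes where one boolean property is enriched in the
large-attention group (+0.25 proportion shift) and a second property is
null, then builds the comparison table: per-group means +- SD, paired-t p,
BH-adjusted p, and FDR-ladder significance symbols.
"""

import numpy as np

import tcrbind as tb
from tcrbind.stats import build_comparison_table, render_table

rng = np.random.default_rng(0)
structures = []
for i in range(39):
    n = int(rng.integers(20, 35))
    k = max(1, round(0.2 * n))                      # ~20% largely attended
    perm = rng.permutation(n)
    props = {
        "hb_cdr3_own": np.where(np.isin(np.arange(n), perm[:k]),
                                rng.random(n) < 0.55,      # planted
                                rng.random(n) < 0.30).astype(float),
        "hb_peptide": (rng.random(n) < 0.10).astype(float),  # null
    }
    structures.append(tb.StructureGroupData(f"s{i:02d}", perm[:k], perm[k:],
                                            props))

table = build_comparison_table(structures, properties=[
    ("hb_cdr3_own", "H-bonded to any CDR3 residue of its own chain", False),
    ("hb_peptide", "H-bonded to any peptide residue", False),
])
print(render_table(table).to_string(index=False))
print("\n'***' marks rejection at FDR 0.05 (BH); '**' at 0.10; '*' at 0.15.")

cal = tb.simulate_rejection_rate(effect="null", n_reps=1000, seed=0)
print(f"null calibration: rejection rate {cal:.3f} at alpha=0.05 "
      f"over 1,000 replicates")
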