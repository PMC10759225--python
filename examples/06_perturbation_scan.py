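"""Input perturbation: substitute one residue and watch the prediction.

Scans all 20 amino acids at one CDR3b position.  Substituting the wild-type
residue for itself always leaves the confidence unchanged (delta exactly 0);
for a trained model, large |delta| flags positions the prediction depends on.
"""

import tcrbind as tb

cfg = tb.ModelConfig(max_len_cdr3a=15, max_len_cdr3b=14, max_len_peptide=9,
                     embed_dim=32, heads_per_side=4, encoder_layers=1, seed=0)
model = tb.CrossAttentionModel(cfg)   # untrained; demonstrates the scan API

rec = tb.InteractionRecord("CAASFIIQGAQKLVF", "CASSLLGGWSEAFF", "GILGFVFTL", 1)
results = tb.scan_position(model, rec, side="cdr3b", position=9,
                           with_calls=False)

wild_type = next(r for r in results if r.substituted == r.original)
print(f"wild type {wild_type.original} at CDR3b position 9: "
      f"confidence {wild_type.confidence:.4f} (delta {wild_type.delta_confidence})")
ranked = sorted(results, key=lambda r: -abs(r.delta_confidence))[:3]
for r in ranked:
    print(f"  {r.original}{r.position}{r.substituted}: "
          f"confidence {r.confidence:.4f} (delta {r.delta_confidence:+.4f})")
print(f"{len(results)} substitutions scanned; identity delta is exactly 0")
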