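"""Geometric H-bond detection and per-residue structural properties.

Writes a toy TCR-pMHC complex (chains A/B = TCR, C = peptide) with one
planted N...O contact, detects hydrogen bonds with the 3.5 A heavy-atom
criterion, and tabulates the per-residue property booleans used in the
attention-vs-structure comparison.
"""

import tempfile
from pathlib import Path

import numpy as np

from tcrbind.structure import (ComplexAnnotation, detect_hbonds,
                               read_complex, residue_properties)
from tcrbind.synthetic import write_toy_pdb

AA3 = {"C": "CYS", "A": "ALA", "V": "VAL", "G": "GLY", "S": "SER",
       "L": "LEU", "I": "ILE"}


def backbone(chain, seq, origin):
    out = []
    for i, aa in enumerate(seq, start=1):
        base = np.array(origin) + [10.0 * i, 0, 0]
        out.append((chain, i, AA3[aa], "CA", "C", base))
    return out


atoms = (backbone("A", "CAVG", (0, 0, 0))
         + backbone("B", "CASSL", (0, 50, 0))
         + backbone("C", "GIL", (0, 100, 0))
         # planted contact: CDR3a residue A3 donates to peptide residue C2
         + [("A", 3, "VAL", "ND1", "N", np.array([500.0, 0.0, 0.0])),
            ("C", 2, "ILE", "OD1", "O", np.array([500.0, 0.0, 2.9]))])

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy.pdb"
    write_toy_pdb(atoms, path)
    ann = ComplexAnnotation("TOY1", chain_alpha="A", chain_beta="B",
                            chain_peptide="C", cdr3a_start=2, cdr3a_end=4,
                            cdr3b_start=2, cdr3b_end=5)
    model = read_complex(path, ann)
    bonds = detect_hbonds(model)
    print(f"H-bonds found: {len(bonds)}")
    for b in bonds:
        print(f"  donor {b.donor} -> acceptor {b.acceptor} "
          f"({b.distance:.2f} A)")
    props = residue_properties(model, ann, bonds)
    row = props[(props.chain == "A") & (props.seqid == 3)].iloc[0]
    print(f"CDR3a residue A3 ({row.aa}): H-bonded to peptide = "
          f"{row.hb_peptide}, total H-bonds = {row.n_hbonds}, "
          f"edge residue = {row.edge}")
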