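"""Structural properties of TCR-pMHC complexes.

Parses PDB files (via gemmi), detects hydrogen bonds with a geometric
heavy-atom criterion, and tabulates per-residue properties — H-bond partner
categories (peptide / CDR3 of own or opposite chain / non-CDR3 TCR), edge
flags, closest distances, per-residue H-bond counts — for the CDR3 spans of
both TCR chains and the peptide.

H-bond criterion: a donor/acceptor-capable heavy-atom pair (N, O or S) from
two different residues within 3.5 A.  No hydrogen positions or angle terms
are used (most PDB entries lack hydrogens), so counts are approximate
relative to tools that model geometry fully; the cutoff is configurable.
CDR3 spans are consumed as annotations (author residue numbering, 1-based
inclusive); a conservative C...F heuristic helper is provided but never
applied silently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ComplexAnnotation", "HBond", "ComplexModel", "Residue",
    "read_annotations", "read_complex", "detect_hbonds",
    "residue_properties", "map_calls_to_structure", "cdr3_span_heuristic",
    "HBOND_CUTOFF", "TCR_EDGE_MARGIN", "PEPTIDE_EDGE_MARGIN",
]

HBOND_CUTOFF = 3.5          # Angstrom, heavy-atom donor-acceptor distance
HBOND_ELEMENTS = {"N", "O", "S"}
TCR_EDGE_MARGIN = 4         # residues from either CDR3 terminus
PEPTIDE_EDGE_MARGIN = 3     # residues from either peptide terminus

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class ComplexAnnotation:
    """Chain ids and CDR3 spans (author numbering, 1-based inclusive)."""

    pdb_id: str
    chain_alpha: str
    chain_beta: str
    chain_peptide: str
    cdr3a_start: int
    cdr3a_end: int
    cdr3b_start: int
    cdr3b_end: int


def read_annotations(path) -> list[ComplexAnnotation]:
    """Read the annotation TSV (pdb_id, chain_alpha, chain_beta, chain_peptide,
    cdr3a_start, cdr3a_end, cdr3b_start, cdr3b_end)."""
    df = pd.read_csv(path, sep="\t")
    return [ComplexAnnotation(
        pdb_id=str(r.pdb_id), chain_alpha=str(r.chain_alpha),
        chain_beta=str(r.chain_beta), chain_peptide=str(r.chain_peptide),
        cdr3a_start=int(r.cdr3a_start), cdr3a_end=int(r.cdr3a_end),
        cdr3b_start=int(r.cdr3b_start), cdr3b_end=int(r.cdr3b_end))
        for r in df.itertuples(index=False)]


@dataclass(frozen=True)
class HBond:
    """A putative hydrogen bond between heavy atoms of two residues.

    Donor/acceptor assignment without hydrogens is heuristic: when exactly one
    partner is nitrogen it is taken as the donor, otherwise order is arbitrary.
    """

    donor: tuple[str, int, str]      # (chain, author seqid, atom name)
    acceptor: tuple[str, int, str]
    distance: float

    def residues(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.donor[:2], self.acceptor[:2])


@dataclass
class Residue:
    chain: str
    seqid: int
    name: str                        # three-letter code
    atoms: list[tuple[str, str, np.ndarray]] = field(default_factory=list)
    # (atom name, element symbol, xyz)

    @property
    def aa(self) -> str:
        return _THREE_TO_ONE.get(self.name, "X")


@dataclass
class ComplexModel:
    """Heavy-atom coordinates indexed by chain and author residue number."""

    structure_id: str
    chains: dict[str, list[Residue]]

    def residue(self, chain: str, seqid: int) -> Residue | None:
        for r in self.chains.get(chain, []):
            if r.seqid == seqid:
                return r
        return None

    def span(self, chain: str, start: int, end: int) -> list[Residue]:
        return [r for r in self.chains.get(chain, []) if start <= r.seqid <= end]


def read_complex(pdb_path, annotation: ComplexAnnotation) -> ComplexModel:
    """Load heavy-atom coordinates; altloc A kept, waters/hetero dropped."""
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for ch in model:
        residues = []
        for res in ch:
            if res.het_flag != "A" or res.name == "HOH":
                continue
            atoms = []
            for at in res:
                if at.altloc not in ("\0", "", " ", "A"):
                    continue
                el = at.element.name.upper()
                if el == "H":
                    continue
                atoms.append((at.name, el,
                              np.array([at.pos.x, at.pos.y, at.pos.z])))
            if atoms:
                residues.append(Residue(ch.name, res.seqid.num, res.name, atoms))
        if residues:
            chains[ch.name] = residues
    for needed in (annotation.chain_alpha, annotation.chain_beta,
                   annotation.chain_peptide):
        if needed not in chains:
            raise ValueError(
                f"{annotation.pdb_id}: chain {needed!r} not found "
                f"(present: {sorted(chains)})")
    return ComplexModel(structure_id=annotation.pdb_id, chains=chains)


def detect_hbonds(model: ComplexModel, cutoff: float = HBOND_CUTOFF) -> list[HBond]:
    """All inter-residue N/O/S heavy-atom pairs within ``cutoff``.

    Intra-residue pairs and the backbone N-O contact across a peptide bond
    (adjacent residues of the same chain) are excluded.
    """
    atoms = []   # (chain, seqid, atom name, element, xyz)
    for chain, residues in model.chains.items():
        for r in residues:
            for name, el, xyz in r.atoms:
                if el in HBOND_ELEMENTS:
                    atoms.append((chain, r.seqid, name, el, xyz))
    bonds = []
    for (c1, s1, n1, e1, x1), (c2, s2, n2, e2, x2) in itertools.combinations(atoms, 2):
        if c1 == c2 and s1 == s2:
            continue
        if c1 == c2 and abs(s1 - s2) == 1 and {n1, n2} <= {"N", "O"}:
            continue  # backbone contact across the peptide bond
        d = float(np.linalg.norm(x1 - x2))
        if d <= cutoff:
            a, b = (c1, s1, n1), (c2, s2, n2)
            if e2 == "N" and e1 != "N":
                a, b = b, a
            bonds.append(HBond(donor=a, acceptor=b, distance=d))
    return bonds


def _edge_positions(length: int, margin: int) -> set[int]:
    return {i for i in range(1, length + 1)
            if i <= margin or i > length - margin}


def residue_properties(model: ComplexModel, annotation: ComplexAnnotation,
                       hbonds: list[HBond]) -> pd.DataFrame:
    """Per-residue property table for CDR3 spans and the peptide.

    One row per residue with boolean H-bond-partner categories, the edge
    flag, the closest heavy-atom distance to the peptide (for peptide
    residues: to the TCR chains), and per-residue H-bond counts.  Residues of
    an annotated span missing from the structure are flagged
    (``missing=True``) and excluded from distance statistics.
    """
    a, b, p = annotation.chain_alpha, annotation.chain_beta, annotation.chain_peptide
    span_a = {(a, s) for s in range(annotation.cdr3a_start, annotation.cdr3a_end + 1)}
    span_b = {(b, s) for s in range(annotation.cdr3b_start, annotation.cdr3b_end + 1)}
    cdr3_all = span_a | span_b
    pep_ids = {(p, r.seqid) for r in model.chains[p]}

    partners: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for hb in hbonds:
        r1, r2 = hb.residues()
        partners.setdefault(r1, []).append(r2)
        partners.setdefault(r2, []).append(r1)

    def in_tcr(rid):
        return rid[0] in (a, b)

    pep_atoms = np.array([xyz for r in model.chains[p] for _, _, xyz in r.atoms])
    tcr_atoms = np.array([xyz for c in (a, b) for r in model.chains[c]
                          for _, _, xyz in r.atoms])

    rows = []

    def make_row(res: Residue | None, chain, seqid, role, pos, length, own_span,
                 opp_span, edge_margin, target_atoms):
        if res is None:
            return {"chain": chain, "seqid": seqid, "aa": "?", "role": role,
                    "pos": pos, "missing": True}
        rid = (chain, seqid)
        pl = partners.get(rid, [])
        own_chain_tcr = [q for q in pl if q[0] == chain and in_tcr(q)]
        opp = {a: b, b: a}.get(chain)
        row = {
            "chain": chain, "seqid": seqid, "aa": res.aa, "role": role,
            "pos": pos, "missing": False,
            "hb_peptide": any(q in pep_ids for q in pl),
            "hb_cdr3": any(q in cdr3_all for q in pl),
            "hb_noncdr3_tcr": any(in_tcr(q) and q not in cdr3_all for q in pl),
            "hb_tcr": any(in_tcr(q) for q in pl),
            "hb_cdr3_own": any(q in own_span for q in pl),
            "hb_cdr3_opp": any(q in opp_span for q in pl),
            "hb_tcr_own": bool(own_chain_tcr) if role != "peptide" else False,
            "hb_tcr_opp": any(q[0] == opp for q in pl) if role != "peptide" else False,
            "edge": pos in _edge_positions(length, edge_margin),
            "n_hbonds": len(pl),
            "n_hbonds_self_cdr3": sum(q in own_span for q in pl),
            "n_hbonds_peptide": sum(q in pep_ids for q in pl),
        }
        coords = np.array([xyz for _, _, xyz in res.atoms])
        if len(target_atoms):
            d = np.linalg.norm(coords[:, None, :] - target_atoms[None, :, :], axis=-1)
            row["closest_distance"] = float(d.min())
        else:
            row["closest_distance"] = float("nan")
        return row

    for chain, start, end, role in ((a, annotation.cdr3a_start, annotation.cdr3a_end, "cdr3a"),
                                    (b, annotation.cdr3b_start, annotation.cdr3b_end, "cdr3b")):
        own_span = span_a if chain == a else span_b
        opp_span = span_b if chain == a else span_a
        length = end - start + 1
        for pos, seqid in enumerate(range(start, end + 1), start=1):
            rows.append(make_row(model.residue(chain, seqid), chain, seqid, role,
                                 pos, length, own_span, opp_span,
                                 TCR_EDGE_MARGIN, pep_atoms))

    pep_residues = model.chains[p]
    for pos, res in enumerate(pep_residues, start=1):
        # for the peptide side, 'own span' H-bonds are within-peptide bonds
        rows.append(make_row(res, p, res.seqid, "peptide", pos,
                             len(pep_residues), set(), cdr3_all,
                             PEPTIDE_EDGE_MARGIN, tcr_atoms))

    df = pd.DataFrame(rows)
    return df


def map_calls_to_structure(positions, record, annotation: ComplexAnnotation,
                           model: ComplexModel) -> list[tuple[str, int, str]]:
    """Map 1-based TCR-side model token positions to structure residues.

    The model's TCR axis is ``cdr3a + ':' + cdr3b``; the colon (which has no
    residue) is skipped.  Returns (chain, author seqid, one-letter aa) and
    raises if the annotated span residues do not match the record sequences.
    """
    colon = len(record.cdr3a) + 1
    span_a = model.span(annotation.chain_alpha,
                        annotation.cdr3a_start, annotation.cdr3a_end)
    span_b = model.span(annotation.chain_beta,
                        annotation.cdr3b_start, annotation.cdr3b_end)
    for seq, span, label in ((record.cdr3a, span_a, "CDR3a"),
                             (record.cdr3b, span_b, "CDR3b")):
        structural = "".join(r.aa for r in span)
        if structural != seq:
            raise ValueError(
                f"{annotation.pdb_id}: {label} sequence mismatch: "
                f"record {seq!r} vs structure span {structural!r}")
    out = []
    for t in positions:
        if t == colon:
            continue
        if t < colon:
            res = span_a[t - 1]
        else:
            res = span_b[t - colon - 1]
        out.append((res.chain, res.seqid, res.aa))
    return out


def cdr3_span_heuristic(chain_residues: list[Residue]) -> tuple[int, int] | None:
    """Crude C...F span guess: first Cys to the next Phe at least 7 on.

    Provided as a convenience for building annotation tables by hand; it is
    never applied automatically.
    """
    seq = [(r.seqid, r.aa) for r in chain_residues]
    for i, (sid, aa) in enumerate(seq):
        if aa == "C":
            for sid2, aa2 in seq[i + 7:]:
                if aa2 == "F":
                    return (sid, sid2)
    return None
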