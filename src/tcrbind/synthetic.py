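"""Synthetic data generators: sequence datasets with a plantable binding
rule, per-structure attention/property fixtures, and toy PDB files.

These generators make every stage of the pipeline testable at desk scale
without external downloads.  They emulate the shape of real interaction data
— duplicated CDR3 pairs appearing against many peptides, CDR3 lengths of
8-20 and peptide lengths of 8-12, a roughly balanced binding signal — but
not its biophysics: the "binding rule" is a shared k-mer between CDR3b and
the peptide, planted via a fixed trigram motif.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._alphabet import AMINO_ACIDS
from .dataset_io import InteractionDataset, InteractionRecord
from .stats import StructureGroupData

__all__ = [
    "MotifRule", "SyntheticStructureSet",
    "gen_interactions", "shares_kmer",
    "gen_structure_fixture", "simulate_rejection_rate", "write_toy_pdb",
]


@dataclass
class MotifRule:
    """Plantable binding rule: positive iff CDR3b and peptide share a k-mer.

    ``motif`` is planted into a fraction ``plant_rate`` of CDR3b sequences
    and of peptides independently (the default ~0.707 per side yields ~50%
    positives).  A repeated-residue trigram is used so that motif presence is
    visible in residue composition, keeping the rule learnable by a small
    model in minutes.  Labels always follow the actual k-mer-intersection
    rule — chance k-mer collisions count — and are then flipped with
    probability ``epsilon``.
    """

    k: int = 3
    motif: str = "WWW"
    plant_rate: float = float(np.sqrt(0.5))
    epsilon: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must be in [0, 0.5)")
        if len(self.motif) != self.k:
            raise ValueError("motif length must equal k")


def shares_kmer(a: str, b: str, k: int) -> bool:
    """True iff ``a`` and ``b`` share at least one common k-mer."""
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))


def _random_seq(rng, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


def _maybe_plant(rng, seq: str, motif: str, rate: float) -> str:
    if rng.random() < rate:
        pos = int(rng.integers(0, len(seq) - len(motif) + 1))
        seq = seq[:pos] + motif + seq[pos + len(motif):]
    return seq


def gen_interactions(n_cdr_pairs: int, n_peptides: int,
                     rule: MotifRule | None = None,
                     records_per_pair: int = 5) -> InteractionDataset:
    """Generate a motif-rule interaction dataset.

    CDR3a/CDR3b lengths are uniform on 8-20, peptides on 8-12.  Each CDR pair
    is paired with ``records_per_pair`` distinct peptides (emulating the
    many-interactions-per-CDR structure of curated databases), so the output
    has ``n_cdr_pairs * records_per_pair`` records.  Deterministic under
    ``rule.seed``.
    """
    if n_cdr_pairs < 1 or n_peptides < 1:
        raise ValueError("counts must be >= 1")
    rule = rule or MotifRule()
    rng = np.random.default_rng(rule.seed)
    pairs = [(_random_seq(rng, 8, 20),
              _maybe_plant(rng, _random_seq(rng, 8, 20), rule.motif, rule.plant_rate))
             for _ in range(n_cdr_pairs)]
    peptides = [_maybe_plant(rng, _random_seq(rng, 8, 12), rule.motif, rule.plant_rate)
                for _ in range(n_peptides)]
    records = []
    k = min(records_per_pair, n_peptides)
    for a, b in pairs:
        for j in rng.choice(n_peptides, size=k, replace=False):
            pep = peptides[int(j)]
            label = int(shares_kmer(b, pep, rule.k))
            if rng.random() < rule.epsilon:
                label = 1 - label
            records.append(InteractionRecord(a, b, pep, label, source="synthetic"))
    return InteractionDataset(records=records)


@dataclass
class SyntheticStructureSet:
    """Parameters for per-structure attention/property fixtures.

    Emulates an analysis over ~39 complexes: per structure, residue counts in
    a CDR3-loop-like range, ~20% of residues in the large-attention group,
    boolean properties at base rate ``p0`` (small group) and ``p1`` (large
    group; equal to ``p0`` under the null).
    """

    n_structures: int = 39
    min_residues: int = 20
    max_residues: int = 34
    large_fraction: float = 0.2
    p0: float = 0.3
    p1: float = 0.55          # p0 + 0.25 planted shift
    seed: int = 0


def gen_structure_fixture(cfg: SyntheticStructureSet | None = None,
                          effect: str = "null") -> list[StructureGroupData]:
    """One replicate of synthetic per-structure group/property data.

    ``effect='null'`` draws the property at rate ``p0`` in both groups;
    ``'planted'`` uses ``p1`` in the large group.
    """
    cfg = cfg or SyntheticStructureSet()
    if effect not in ("null", "planted"):
        raise ValueError("effect must be 'null' or 'planted'")
    rng = np.random.default_rng(cfg.seed)
    p_large = cfg.p1 if effect == "planted" else cfg.p0
    out = []
    for i in range(cfg.n_structures):
        n = int(rng.integers(cfg.min_residues, cfg.max_residues + 1))
        n_large = max(1, int(round(cfg.large_fraction * n)))
        perm = rng.permutation(n)
        large, small = perm[:n_large], perm[n_large:]
        prop = np.zeros(n)
        prop[large] = rng.random(n_large) < p_large
        prop[small] = rng.random(n - n_large) < cfg.p0
        out.append(StructureGroupData(
            structure_id=f"synth{i:03d}", large=large, small=small,
            properties={"prop": prop}))
    return out


def simulate_rejection_rate(cfg: SyntheticStructureSet | None = None,
                            effect: str = "null", n_reps: int = 1000,
                            alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of replicates where the paired t-test rejects at ``alpha``.

    Vectorized over replicates: group sizes are drawn once per structure,
    per-replicate binomial property counts give the paired group proportions,
    and a two-sided paired t-test is applied per replicate — the same test
    :func:`tcrbind.stats.paired_t` performs structure-set by structure-set.
    """
    from scipy import stats as sps
    cfg = cfg or SyntheticStructureSet()
    rng = np.random.default_rng(seed)
    p_large = cfg.p1 if effect == "planted" else cfg.p0
    n = rng.integers(cfg.min_residues, cfg.max_residues + 1, size=cfg.n_structures)
    n_large = np.maximum(1, np.round(cfg.large_fraction * n).astype(int))
    n_small = n - n_large
    a = rng.binomial(n_large[None, :], p_large, size=(n_reps, cfg.n_structures))
    b = rng.binomial(n_small[None, :], cfg.p0, size=(n_reps, cfg.n_structures))
    large = a / n_large[None, :]
    small = b / n_small[None, :]
    _, p = sps.ttest_rel(large, small, axis=1)
    return float(np.mean(p < alpha))


# ---------------------------------------------------------------------------
# toy PDB files

_PDB_ATOM = ("ATOM  {serial:5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
             "{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
             "{b:6.2f}          {element:>2s}\n")


def write_toy_pdb(atoms, path) -> None:
    """Write standards-conformant ATOM records for a toy structure.

    ``atoms`` is an iterable of (chain, resseq, resname, atom name, element,
    (x, y, z)); occupancy 1.00 and B-factor 0.00 throughout.  An empty list
    yields a valid empty-model file.
    """
    with open(path, "w") as fh:
        for serial, (chain, resseq, resname, name, element, xyz) in enumerate(
                atoms, start=1):
            element = element.upper()
            if element not in {e.upper() for e in
                               ("C", "N", "O", "S", "P", "H", "FE", "ZN", "MG")}:
                raise ValueError(f"unexpected element symbol {element!r}")
            # short atom names are indented one column per PDB convention
            name_field = f" {name:<3s}" if len(name) < 4 else name
            fh.write(_PDB_ATOM.format(
                serial=serial, name=name_field, altloc="", resname=resname,
                chain=chain, resseq=resseq, icode="",
                x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0, element=element))
        fh.write("END\n")
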