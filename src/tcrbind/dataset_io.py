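"""Interaction-table construction: loading, cleaning, deduplication, splits and
negative augmentation for CDR3ab-peptide binding datasets.

A dataset is a flat list of :class:`InteractionRecord` triplets
(CDR3a, CDR3b, peptide) with a binary binding label.  The construction
protocol mirrors common practice for benchmark TCR-pMHC sets: drop records
with missing chains or non-standard residues, keep one record per triplet,
remove test triplets that also occur in training (single-element overlaps are
deliberately retained), and augment positives with randomly paired negatives
at a fixed ratio (default 5:1, giving a positive rate of 1/6).
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._alphabet import is_standard

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "InteractionDataset",
    "OverlapReport",
    "FormatError",
    "load_interactions",
    "write_interactions",
    "clean",
    "dedup_triplets",
    "remove_test_overlap",
    "sample_negatives",
    "overlap_report",
    "window_peptides",
    "all_vs_all",
    "all_vs_all_counts",
]


class FormatError(ValueError):
    """Raised when an input table cannot be mapped to the canonical columns."""


@dataclass(frozen=True)
class InteractionRecord:
    """One (CDR3a, CDR3b, peptide, label) triplet with a free-text source tag."""

    cdr3a: str
    cdr3b: str
    peptide: str
    label: int
    source: str = ""

    @property
    def triplet(self) -> tuple[str, str, str]:
        return (self.cdr3a, self.cdr3b, self.peptide)

    @property
    def cdr_pair(self) -> tuple[str, str]:
        return (self.cdr3a, self.cdr3b)


@dataclass
class InteractionDataset:
    """An ordered collection of interaction records plus optional role metadata.

    ``max_len_*`` are the observed sequence-length maxima; they are computed on
    the training role and reused to pad/validate test data.
    """

    records: list[InteractionRecord] = field(default_factory=list)
    role: str | None = None
    max_len_cdr3a: int | None = None
    max_len_cdr3b: int | None = None
    max_len_peptide: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def positive_rate(self) -> float:
        return float(self.labels.mean()) if self.records else float("nan")

    def triplets(self) -> set[tuple[str, str, str]]:
        return {r.triplet for r in self.records}

    def compute_length_limits(self) -> "InteractionDataset":
        """Set ``max_len_*`` from the observed maxima of this dataset."""
        self.max_len_cdr3a = max((len(r.cdr3a) for r in self.records), default=0)
        self.max_len_cdr3b = max((len(r.cdr3b) for r in self.records), default=0)
        self.max_len_peptide = max((len(r.peptide) for r in self.records), default=0)
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records],
                            columns=["cdr3a", "cdr3b", "peptide", "label", "source"])


# Column-name synonyms for the ERGO-II-style CSV layout (case-insensitive).
_ERGO_SYNONYMS = {
    "cdr3a": "cdr3a", "tcra": "cdr3a", "cdr3α": "cdr3a", "cdr3.alpha": "cdr3a",
    "cdr3b": "cdr3b", "tcrb": "cdr3b", "cdr3β": "cdr3b", "cdr3.beta": "cdr3b",
    "peptide": "peptide", "epitope": "peptide",
    "label": "label", "sign": "label", "binder": "label",
    "source": "source", "dataset": "source",
}

_CANONICAL = ["cdr3a", "cdr3b", "peptide", "label"]


def _map_columns(columns: Sequence[str], dialect: str) -> dict[str, str]:
    if dialect == "ergo_csv":
        mapping = {c: _ERGO_SYNONYMS[c.strip().lower()]
                   for c in columns if c.strip().lower() in _ERGO_SYNONYMS}
    elif dialect == "plain_tsv":
        mapping = {c: c for c in columns if c in _CANONICAL + ["source"]}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [k for k in _CANONICAL if k not in mapping.values()]
    if missing:
        raise FormatError(
            f"input table is missing required column(s) {missing} "
            f"(dialect={dialect}, columns={list(columns)})")
    return mapping


def _parse_label(value, row_number: int) -> int:
    if isinstance(value, (bool, np.bool_)):
        return int(value)
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise FormatError(f"row {row_number}: non-binary label {value!r}") from None
    if f not in (0.0, 1.0):
        raise FormatError(f"row {row_number}: non-binary label {value!r}")
    return int(f)


def load_interactions(path, dialect: str = "plain_tsv",
                      source: str | None = None) -> InteractionDataset:
    """Read an interaction table into an :class:`InteractionDataset`.

    ``dialect='ergo_csv'`` maps the ERGO-II-style column names (tcra/tcrb/
    peptide/sign, comma-separated); ``'plain_tsv'`` expects canonical lowercase
    headers ``cdr3a, cdr3b, peptide, label`` in a TSV.  Records are returned in
    file order, uncleaned; missing sequences become empty strings.
    """
    sep = "," if dialect == "ergo_csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    mapping = _map_columns(df.columns, dialect)
    df = df.rename(columns=mapping)
    default_source = source if source is not None else ""
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        d = dict(zip(df.columns, row))
        records.append(InteractionRecord(
            cdr3a=str(d["cdr3a"]).strip(),
            cdr3b=str(d["cdr3b"]).strip(),
            peptide=str(d["peptide"]).strip(),
            label=_parse_label(d["label"], i),
            source=str(d.get("source", default_source)) or default_source,
        ))
    return InteractionDataset(records=records)


def write_interactions(ds: InteractionDataset, path) -> None:
    """Write the canonical TSV layout (cdr3a, cdr3b, peptide, label, source)."""
    ds.to_frame().to_csv(path, sep="\t", index=False)


def clean(ds: InteractionDataset) -> InteractionDataset:
    """Drop records with a missing sequence or non-standard residues.

    Only the 20 standard one-letter residues are kept; anything else
    (B/J/O/U/X/Z, gaps, lowercase) causes the record to be dropped.
    """
    kept = [r for r in ds.records
            if is_standard(r.cdr3a) and is_standard(r.cdr3b) and is_standard(r.peptide)]
    n_dropped = len(ds.records) - len(kept)
    if n_dropped:
        logger.info("clean: dropped %d of %d records", n_dropped, len(ds.records))
    return InteractionDataset(records=kept, role=ds.role)


def dedup_triplets(ds: InteractionDataset) -> InteractionDataset:
    """Keep exactly one record per (cdr3a, cdr3b, peptide) triplet.

    First occurrence wins; a later duplicate with a conflicting label triggers
    a warning but is still discarded.
    """
    seen: dict[tuple[str, str, str], int] = {}
    kept: list[InteractionRecord] = []
    for r in ds.records:
        if r.triplet in seen:
            if r.label != seen[r.triplet]:
                warnings.warn(
                    f"conflicting labels for triplet {r.triplet}; "
                    f"keeping first occurrence (label={seen[r.triplet]})")
            continue
        seen[r.triplet] = r.label
        kept.append(r)
    return InteractionDataset(records=kept, role=ds.role)


def remove_test_overlap(train: InteractionDataset,
                        test: InteractionDataset) -> InteractionDataset:
    """Remove from ``test`` every triplet that also occurs in ``train``.

    Only full-triplet matches are removed; records sharing just the CDR3 pair
    or just the peptide with training are retained (the same TCR legitimately
    appears with several different peptides).
    """
    train_triplets = train.triplets()
    kept = [r for r in test.records if r.triplet not in train_triplets]
    return InteractionDataset(records=kept, role=test.role)


def sample_negatives(ds: InteractionDataset, ratio: int = 5,
                     seed: int = 0) -> InteractionDataset:
    """Augment an all-positive dataset with ``ratio`` x negatives.

    Negatives are formed by uniformly pairing a (CDR3a, CDR3b) pair with a
    peptide, both drawn from ``ds`` itself.  Generated negatives never
    duplicate an existing positive triplet or one another, so the output
    positive rate is exactly ``1/(1+ratio)``.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if any(r.label != 1 for r in ds.records):
        raise ValueError("sample_negatives expects an all-positive dataset")
    pairs = sorted({r.cdr_pair for r in ds.records})
    peptides = sorted({r.peptide for r in ds.records})
    positives = ds.triplets()
    n_pos = len(ds.records)
    n_neg = ratio * n_pos
    capacity = len(pairs) * len(peptides) - len(positives)
    if capacity < n_neg:
        raise ValueError(
            f"cannot sample {n_neg} distinct negatives: only {capacity} "
            f"non-positive combinations exist (shortfall {n_neg - capacity})")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str, str]] = set()
    if capacity <= max(4 * n_neg, 100_000):
        # Small space: enumerate and choose without replacement.
        space = [(a, b, p) for (a, b) in pairs for p in peptides
                 if (a, b, p) not in positives]
        idx = rng.choice(len(space), size=n_neg, replace=False)
        chosen = {space[i] for i in idx}
    else:
        while len(chosen) < n_neg:
            need = n_neg - len(chosen)
            pi = rng.integers(0, len(pairs), size=2 * need)
            qi = rng.integers(0, len(peptides), size=2 * need)
            for a_b, p in zip((pairs[i] for i in pi), (peptides[i] for i in qi)):
                t = (a_b[0], a_b[1], p)
                if t not in positives and t not in chosen:
                    chosen.add(t)
                    if len(chosen) == n_neg:
                        break
    negatives = [InteractionRecord(a, b, p, 0, source="sampled_negative")
                 for (a, b, p) in sorted(chosen)]
    return InteractionDataset(records=list(ds.records) + negatives, role=ds.role)


@dataclass
class OverlapReport:
    """Unique-element counts and train-overlap statistics for one dataset."""

    unique_cdr3ab_count: int
    unique_peptide_count: int
    interaction_count: int
    positive_rate: float
    dup_cdr3ab_with_train: int = 0
    dup_peptide_with_train: int = 0
    records_with_seen_peptide: int = 0
    records_with_seen_cdr3ab: int = 0

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def overlap_report(ds: InteractionDataset,
                   train: InteractionDataset | None = None) -> OverlapReport:
    """Unique counts for ``ds`` and, if ``train`` is given, overlap statistics.

    ``dup_*_with_train`` count unique elements shared with training;
    ``records_with_seen_*`` count records of ``ds`` whose peptide (resp. CDR3
    pair) appears anywhere in training.
    """
    pairs = {r.cdr_pair for r in ds.records}
    peps = {r.peptide for r in ds.records}
    rep = OverlapReport(
        unique_cdr3ab_count=len(pairs),
        unique_peptide_count=len(peps),
        interaction_count=len(ds.records),
        positive_rate=ds.positive_rate if ds.records else 0.0,
    )
    if train is not None:
        tr_pairs = {r.cdr_pair for r in train.records}
        tr_peps = {r.peptide for r in train.records}
        rep.dup_cdr3ab_with_train = len(pairs & tr_pairs)
        rep.dup_peptide_with_train = len(peps & tr_peps)
        rep.records_with_seen_peptide = sum(r.peptide in tr_peps for r in ds.records)
        rep.records_with_seen_cdr3ab = sum(r.cdr_pair in tr_pairs for r in ds.records)
    return rep


def window_peptides(protein: str, k: int = 9, stride: int = 1) -> list[str]:
    """All length-``k`` windows of ``protein`` at the given stride.

    Returns floor((L-k)/stride)+1 peptides; raises if the protein is shorter
    than ``k``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if len(protein) < k:
        raise ValueError(f"protein length {len(protein)} < window {k}")
    return [protein[i:i + k] for i in range(0, len(protein) - k + 1, stride)]


def _check_positive_elements(cdr_pairs, peptides, positives):
    pair_set, pep_set = set(cdr_pairs), set(peptides)
    for (a, b, p) in positives:
        if (a, b) not in pair_set or p not in pep_set:
            raise ValueError(
                f"positive triplet {(a, b, p)} uses elements absent from the inputs")


def all_vs_all(cdr_pairs: Sequence[tuple[str, str]], peptides: Sequence[str],
               positives: Iterable[tuple[str, str, str]] = (),
               source: str = "all_vs_all") -> InteractionDataset:
    """Cartesian-product dataset: every CDR pair against every peptide.

    Triplets listed in ``positives`` get label 1, everything else 0.  For
    large products prefer :func:`all_vs_all_counts`, which never materializes
    the records.
    """
    positives = set(positives)
    _check_positive_elements(cdr_pairs, peptides, positives)
    records = [
        InteractionRecord(a, b, p, int((a, b, p) in positives), source=source)
        for (a, b), p in itertools.product(cdr_pairs, peptides)
    ]
    return InteractionDataset(records=records)


def all_vs_all_counts(cdr_pairs: Sequence[tuple[str, str]], peptides: Sequence[str],
                      positives: Iterable[tuple[str, str, str]] = ()) -> dict:
    """Record counts and base positive rate of the all-vs-all product,
    computed without materializing it."""
    positives = set(positives)
    _check_positive_elements(cdr_pairs, peptides, positives)
    total = len(set(cdr_pairs)) * len(set(peptides))
    n_pos = len(positives)
    return {
        "total_records": total,
        "n_positive": n_pos,
        "n_negative": total - n_pos,
        "base_positive_rate": n_pos / total if total else float("nan"),
    }
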