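"""Token encoding: amino acids to integer indices, the colon connection token,
end-padding and length bookkeeping.

The TCR side of the model consumes the single sequence ``CDR3a + ":" + CDR3b``;
the peptide side consumes the peptide alone.  Both are padded at the end to the
fixed lengths observed in training.  Positional information is added downstream
as learned positional embeddings indexed by the padded position 0..pad_to-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._alphabet import AMINO_ACIDS, CONNECTION_TOKEN

__all__ = ["Vocabulary", "TokenBatch", "encode_tcr", "encode_peptide", "build_batch"]

PAD_TOKEN = "-"


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token<->index map: pad (index 0), 20 amino acids, colon."""

    tokens: tuple[str, ...] = (PAD_TOKEN,) + tuple(AMINO_ACIDS) + (CONNECTION_TOKEN,)

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def connection_index(self) -> int:
        return self.tokens.index(CONNECTION_TOKEN)

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            raise KeyError(f"unknown token {token!r}") from None

    def encode(self, seq: str) -> list[int]:
        out = []
        for pos, c in enumerate(seq, start=1):
            if c not in self.tokens or c == PAD_TOKEN:
                raise ValueError(f"unknown residue {c!r} at position {pos}")
            out.append(self.tokens.index(c))
        return out

    def decode(self, indices) -> str:
        return "".join(self.tokens[i] for i in indices)

    def to_json(self, path=None) -> str:
        s = json.dumps({"tokens": list(self.tokens)})
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, s: str) -> "Vocabulary":
        return cls(tokens=tuple(json.loads(s)["tokens"]))


def encode_tcr(cdr3a: str, cdr3b: str, pad_to: int,
               vocab: Vocabulary | None = None) -> tuple[np.ndarray, int]:
    """Encode ``cdr3a:cdr3b`` with end padding.

    Returns (token index array of length ``pad_to``, true content length).
    """
    vocab = vocab or Vocabulary()
    content = vocab.encode(cdr3a) + [vocab.connection_index] + vocab.encode(cdr3b)
    if len(content) > pad_to:
        raise ValueError(
            f"TCR sequence length {len(content)} (incl. connection token) "
            f"exceeds pad_to={pad_to}")
    arr = np.full(pad_to, vocab.pad_index, dtype=np.int64)
    arr[:len(content)] = content
    return arr, len(content)


def encode_peptide(peptide: str, pad_to: int,
                   vocab: Vocabulary | None = None) -> tuple[np.ndarray, int]:
    """Encode a peptide with end padding; returns (indices, true length)."""
    vocab = vocab or Vocabulary()
    if not peptide:
        raise ValueError("empty peptide")
    content = vocab.encode(peptide)
    if len(content) > pad_to:
        raise ValueError(f"peptide length {len(content)} exceeds pad_to={pad_to}")
    arr = np.full(pad_to, vocab.pad_index, dtype=np.int64)
    arr[:len(content)] = content
    return arr, len(content)


@dataclass
class TokenBatch:
    """Padded token matrices for a batch of records, one row per record."""

    tcr_tokens: np.ndarray        # (batch, L_tcr) int64
    peptide_tokens: np.ndarray    # (batch, L_pep) int64
    tcr_lengths: np.ndarray       # (batch,) true content lengths
    peptide_lengths: np.ndarray
    vocab: Vocabulary = field(default_factory=Vocabulary)

    @property
    def L_tcr(self) -> int:
        return self.tcr_tokens.shape[1]

    @property
    def L_pep(self) -> int:
        return self.peptide_tokens.shape[1]

    def __len__(self) -> int:
        return self.tcr_tokens.shape[0]

    def select(self, idx) -> "TokenBatch":
        return TokenBatch(self.tcr_tokens[idx], self.peptide_tokens[idx],
                          self.tcr_lengths[idx], self.peptide_lengths[idx],
                          self.vocab)


def build_batch(records, max_len_cdr3a: int, max_len_cdr3b: int,
                max_len_peptide: int, vocab: Vocabulary | None = None) -> TokenBatch:
    """Assemble a :class:`TokenBatch` from interaction records, order-preserving.

    Padded widths come from the training-set maxima: the TCR side is padded to
    ``max_len_cdr3a + 1 + max_len_cdr3b`` (the +1 is the connection token).
    Records exceeding the maxima are rejected, listing their indices.
    """
    vocab = vocab or Vocabulary()
    L_tcr = max_len_cdr3a + 1 + max_len_cdr3b
    L_pep = max_len_peptide
    oversize = [i for i, r in enumerate(records)
                if len(r.cdr3a) > max_len_cdr3a or len(r.cdr3b) > max_len_cdr3b
                or len(r.peptide) > max_len_peptide]
    if oversize:
        raise ValueError(f"records exceed training length limits: indices {oversize}")
    n = len(records)
    tcr = np.full((n, L_tcr), vocab.pad_index, dtype=np.int64)
    pep = np.full((n, L_pep), vocab.pad_index, dtype=np.int64)
    tlen = np.zeros(n, dtype=np.int64)
    plen = np.zeros(n, dtype=np.int64)
    for i, r in enumerate(records):
        tcr[i], tlen[i] = encode_tcr(r.cdr3a, r.cdr3b, L_tcr, vocab)
        pep[i], plen[i] = encode_peptide(r.peptide, L_pep, vocab)
    return TokenBatch(tcr, pep, tlen, plen, vocab)
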