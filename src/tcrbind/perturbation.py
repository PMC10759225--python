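"""Input-perturbation scans: substitute one residue at a time and record how
the binding confidence and the large-attention call sets respond.

Substituting the wild-type residue for itself is the identity and always
yields a confidence change of exactly zero; substitutions preserve sequence
length, so perturbed inputs can never exceed the model's length limits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from ._alphabet import AMINO_ACIDS
from .attention_analysis import AttentionCallConfig, call_record_residues
from .dataset_io import InteractionRecord
from .encoding import build_batch
from .model import CrossAttentionModel

__all__ = ["PerturbationResult", "scan_position", "scan_called_residues"]

_SIDES = ("cdr3a", "cdr3b", "peptide")


@dataclass
class PerturbationResult:
    record_id: str
    side: str
    position: int                  # 1-based within the side's sequence
    original: str
    substituted: str
    confidence: float
    delta_confidence: float        # vs wild type; identity => exactly 0
    calls_gained: dict[str, list[int]] | None = None
    calls_lost: dict[str, list[int]] | None = None


def _substitute(record: InteractionRecord, side: str, position: int,
                aa: str) -> InteractionRecord:
    seq = getattr(record, side)
    if not (1 <= position <= len(seq)):
        raise ValueError(f"position {position} out of range for {side} "
                         f"(length {len(seq)})")
    new = seq[:position - 1] + aa + seq[position:]
    return dc_replace(record, **{side: new})


def scan_position(model: CrossAttentionModel, record: InteractionRecord,
                  side: str, position: int,
                  call_config: AttentionCallConfig | None = None,
                  with_calls: bool = True,
                  record_id: str = "") -> list[PerturbationResult]:
    """Substitute every amino acid (wild type included) at one position.

    Returns 20 results; each carries the new confidence, the change versus
    wild type, and (optionally) the symmetric difference of the per-side
    large-call sets.
    """
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}")
    seq = getattr(record, side)
    if not (1 <= position <= len(seq)):
        raise ValueError(f"position {position} out of range for {side} "
                         f"(length {len(seq)})")
    wt = seq[position - 1]

    variants = [_substitute(record, side, position, aa) for aa in AMINO_ACIDS]
    cfg = model.cfg
    batch = build_batch([record] + variants, cfg.max_len_cdr3a,
                        cfg.max_len_cdr3b, cfg.max_len_peptide, model.vocab)
    conf = model.forward(batch).confidence
    wt_conf = float(conf[0])

    wt_calls = (call_record_residues(model, record, call_config, record_id)
                if with_calls else None)
    results = []
    for aa, c in zip(AMINO_ACIDS, conf[1:]):
        gained = lost = None
        if aa == wt:
            delta, c_out = 0.0, wt_conf
            if with_calls:
                gained = {s: [] for s in ("tcr", "peptide")}
                lost = {s: [] for s in ("tcr", "peptide")}
        else:
            c_out = float(c)
            delta = c_out - wt_conf
            if with_calls:
                var_calls = call_record_residues(
                    model, _substitute(record, side, position, aa),
                    call_config, record_id)
                gained, lost = {}, {}
                for s in ("tcr", "peptide"):
                    a = set(wt_calls[s].unique_positions)
                    b = set(var_calls[s].unique_positions)
                    gained[s] = sorted(b - a)
                    lost[s] = sorted(a - b)
        results.append(PerturbationResult(
            record_id=record_id, side=side, position=position,
            original=wt, substituted=aa, confidence=c_out,
            delta_confidence=delta, calls_gained=gained, calls_lost=lost))
    return results


def scan_called_residues(model: CrossAttentionModel, record: InteractionRecord,
                         calls, record_id: str = "",
                         call_config: AttentionCallConfig | None = None
                         ) -> pd.DataFrame:
    """Run :func:`scan_position` at every large-called residue.

    ``calls`` is the per-side dict from
    :func:`tcrbind.attention_analysis.call_record_residues`.  Returns a tidy
    table sorted by the maximum absolute confidence change per position.
    """
    rows = []
    colon = len(record.cdr3a) + 1
    targets = []
    for t in calls["tcr"].unique_positions:
        if t < colon:
            targets.append(("cdr3a", t))
        elif t > colon:
            targets.append(("cdr3b", t - colon))
    targets += [("peptide", p) for p in calls["peptide"].unique_positions]
    for side, pos in targets:
        for r in scan_position(model, record, side, pos, call_config,
                               with_calls=False, record_id=record_id):
            rows.append({"side": r.side, "position": r.position,
                         "original": r.original, "substituted": r.substituted,
                         "confidence": r.confidence,
                         "delta_confidence": r.delta_confidence})
    df = pd.DataFrame(rows, columns=["side", "position", "original",
                                     "substituted", "confidence",
                                     "delta_confidence"])
    if len(df):
        rank = (df.groupby(["side", "position"])["delta_confidence"]
                .transform(lambda s: s.abs().max()))
        df = (df.assign(_rank=rank)
              .sort_values(["_rank", "side", "position", "substituted"],
                           ascending=[False, True, True, True])
              .drop(columns="_rank").reset_index(drop=True))
    return df
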