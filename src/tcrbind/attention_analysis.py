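"""Residue-level attention calling and heatmap export.

A residue is "largely attended" in head h when its maximum attention weight,
taken over the opposing sequence's positions, exceeds mean + gamma*sigma of
that head's whole attention matrix (population sigma).  The thresholds are
therefore per-structure and per-head.  Default gamma: 4.5 on the TCR side,
5.5 on the peptide side — calibrated so that roughly 20% of residues are
called large once the four heads are concatenated.  "Small" calls use the
mirrored strict < rule.  Head-level calls are concatenated as a multiset: a
residue called in two heads appears twice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._alphabet import CONNECTION_TOKEN
from .encoding import build_batch
from .model import AttentionMap, CrossAttentionModel

__all__ = [
    "AttentionCallConfig", "ResidueCallSet",
    "call_residues", "concat_heads", "extract_attention",
    "call_record_residues", "export_heatmap",
]

GAMMA_TCR_DEFAULT = 4.5
GAMMA_PEPTIDE_DEFAULT = 5.5


@dataclass
class AttentionCallConfig:
    """Thresholding parameters for large/small residue calling."""

    gamma_tcr: float = GAMMA_TCR_DEFAULT
    gamma_peptide: float = GAMMA_PEPTIDE_DEFAULT
    direction: str = "large"                 # "large" or "small"

    def __post_init__(self):
        if self.gamma_tcr < 0 or self.gamma_peptide < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class ResidueCallSet:
    """Per-head residue calls for one record/structure and one side.

    Indices are 1-based positions along the called sequence (the key axis of
    the attention maps); the colon connection token on the TCR side is never
    called.  ``all_heads`` is the multiset concatenation over heads.
    """

    record_id: str
    side: str                                  # "tcr" or "peptide"
    gamma: float
    direction: str = "large"
    per_head: dict[int, list[int]] = field(default_factory=dict)
    head_mean: dict[int, float] = field(default_factory=dict)
    head_std: dict[int, float] = field(default_factory=dict)

    @property
    def all_heads(self) -> Counter:
        return concat_heads(list(self.per_head.values()))

    @property
    def unique_positions(self) -> list[int]:
        return sorted(set().union(*map(set, self.per_head.values()))
                      if self.per_head else set())


def call_residues(values: np.ndarray, gamma: float,
                  direction: str = "large",
                  exclude: set[int] | None = None) -> list[int]:
    """Apply the calling rule to one head's attention matrix.

    ``values`` has queries on rows and keys on columns (each row sums to 1);
    called positions index the key axis, 1-based.  A key-axis position j is
    called large when max over queries of values[:, j] > mean + gamma*sigma,
    with mean/sigma over the whole matrix; "small" uses strict <.
    ``exclude`` lists 1-based key positions never to call (e.g. the colon).
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty attention matrix")
    a_bar = values.mean()
    sigma = values.std()          # population standard deviation
    thr = a_bar + gamma * sigma
    col_max = values.max(axis=0)
    if direction == "large":
        hits = np.nonzero(col_max > thr)[0]
    elif direction == "small":
        hits = np.nonzero(col_max < thr)[0]
    else:
        raise ValueError(f"direction must be 'large' or 'small', got {direction!r}")
    exclude = exclude or set()
    return [int(j) + 1 for j in hits if int(j) + 1 not in exclude]


def concat_heads(calls: list[list[int]]) -> Counter:
    """Multiset union of per-head call sets (multiplicity preserved)."""
    out: Counter = Counter()
    for c in calls:
        out.update(c)
    return out


def extract_attention(model: CrossAttentionModel, record) -> dict[str, list[AttentionMap]]:
    """Per-head attention maps for one record, both sides, pads stripped.

    Returns ``{"tcr_side": [...], "peptide_side": [...]}``.  TCR-side maps
    have peptide queries on rows and TCR positions (CDR3a + ":" + CDR3b) on
    columns; axes are annotated with residue letters.
    """
    cfg = model.cfg
    batch = build_batch([record], cfg.max_len_cdr3a, cfg.max_len_cdr3b,
                        cfg.max_len_peptide, model.vocab)
    out = model.forward(batch)
    lt = int(batch.tcr_lengths[0])
    lp = int(batch.peptide_lengths[0])
    tcr_seq = record.cdr3a + CONNECTION_TOKEN + record.cdr3b
    tcr_labels = [f"{c}{i}" for i, c in enumerate(tcr_seq, start=1)]
    pep_labels = [f"{c}{i}" for i, c in enumerate(record.peptide, start=1)]
    maps = {"tcr_side": [], "peptide_side": []}
    for h in range(cfg.heads_per_side):
        maps["tcr_side"].append(AttentionMap(
            head=h, side="tcr_given_peptide",
            values=out.attention_tcr_side[0, h, :lp, :lt].copy(),
            query_axis=pep_labels, key_axis=tcr_labels))
        maps["peptide_side"].append(AttentionMap(
            head=h, side="peptide_given_tcr",
            values=out.attention_peptide_side[0, h, :lt, :lp].copy(),
            query_axis=tcr_labels, key_axis=pep_labels))
    return maps


def call_record_residues(model: CrossAttentionModel, record,
                         config: AttentionCallConfig | None = None,
                         record_id: str = "") -> dict[str, ResidueCallSet]:
    """Large/small residue calls for one record on both sides.

    The colon position on the TCR side is excluded from calling (it carries
    no residue).
    """
    config = config or AttentionCallConfig()
    maps = extract_attention(model, record)
    colon_pos = len(record.cdr3a) + 1
    out = {}
    for side, gamma, exclude in (
            ("tcr", config.gamma_tcr, {colon_pos}),
            ("peptide", config.gamma_peptide, set())):
        cs = ResidueCallSet(record_id=record_id, side=side, gamma=gamma,
                            direction=config.direction)
        for m in maps[f"{side}_side"]:
            cs.per_head[m.head] = call_residues(m.values, gamma,
                                                config.direction, exclude)
            cs.head_mean[m.head] = float(m.values.mean())
            cs.head_std[m.head] = float(m.values.std())
        out[side] = cs
    return out


def export_heatmap(maps: list[AttentionMap], path_prefix, render: bool = False) -> list[str]:
    """Write each map as a TSV matrix (rows=queries, cols=keys, labelled).

    With ``render=True`` also writes a PNG per map.  Returns written paths.
    """
    import pandas as pd
    written = []
    for m in maps:
        df = pd.DataFrame(m.values, index=m.query_axis, columns=m.key_axis)
        p = f"{path_prefix}_{m.side}_head{m.head}.tsv"
        df.to_csv(p, sep="\t")
        written.append(p)
        if render:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(max(4, len(m.key_axis) * 0.3),
                                            max(3, len(m.query_axis) * 0.3)))
            im = ax.imshow(m.values, aspect="auto", cmap="viridis")
            ax.set_xticks(range(len(m.key_axis)), m.key_axis, rotation=90, fontsize=6)
            ax.set_yticks(range(len(m.query_axis)), m.query_axis, fontsize=6)
            fig.colorbar(im, ax=ax, label="attention")
            ax.set_title(f"{m.side} head {m.head}")
            png = f"{path_prefix}_{m.side}_head{m.head}.png"
            fig.savefig(png, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(png)
    return written
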