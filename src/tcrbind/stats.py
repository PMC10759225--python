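"""Attention-vs-structure statistics.

Combines residue attention calls with per-residue structural properties:
within each complex, the proportion P = A/B of called residues exhibiting a
property (or the per-residue mean for continuous properties) is computed for
the large- and small-attention groups; across complexes, a two-sided paired
Student's t-test compares the groups, p-values are Benjamini-Hochberg
adjusted per table, and significance symbols follow an FDR ladder
(*** at 0.05, ** at 0.10, * at 0.15).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StructureGroupData", "TCR_PROPERTIES", "PEPTIDE_PROPERTIES",
    "group_proportions", "paired_t", "bh_adjust", "significance_symbols",
    "build_comparison_table", "structure_group_data", "render_table",
]

#: Table rows for the TCR side: (column name, human label, continuous?)
TCR_PROPERTIES = [
    ("hb_peptide", "H-bonded to any peptide residue", False),
    ("hb_cdr3", "H-bonded to any CDR3 residue", False),
    ("hb_noncdr3_tcr", "H-bonded to any non-CDR3 TCR residue", False),
    ("hb_tcr", "H-bonded to any TCR residue", False),
    ("hb_cdr3_own", "H-bonded to any CDR3 residue of its own chain", False),
    ("hb_tcr_own", "H-bonded to any TCR residue of its own chain", False),
    ("hb_tcr_opp", "H-bonded to any TCR residue of the opposite chain", False),
    ("hb_cdr3_opp", "H-bonded to any CDR3 residue of the opposite chain", False),
    ("edge", "In the edge", False),
    ("closest_distance", "Closest distance to the peptide (A)", True),
    ("n_hbonds", "Number of H-bonds formed", True),
]

#: Table rows for the peptide side.
PEPTIDE_PROPERTIES = [
    ("hb_peptide", "H-bonded to any peptide residue", False),
    ("hb_cdr3", "H-bonded to any CDR3 residue", False),
    ("hb_tcr", "H-bonded to any TCR residue", False),
    ("hb_noncdr3_tcr", "H-bonded to any non-CDR3 TCR residue", False),
    ("edge", "In the edge", False),
    ("closest_distance", "Closest distance to the TCR (A)", True),
    ("n_hbonds", "Number of H-bonds formed", True),
]


@dataclass
class StructureGroupData:
    """One complex's large/small residue groups plus per-residue properties.

    ``large``/``small`` hold indices into the property vectors; repeated
    indices encode the head-concatenated multiset (a residue called in two
    heads contributes twice).
    """

    structure_id: str
    large: np.ndarray
    small: np.ndarray
    properties: dict[str, np.ndarray] = field(default_factory=dict)


def group_proportions(sgd: StructureGroupData, prop: str,
                      continuous: bool = False) -> tuple[float, float] | None:
    """Per-group proportion (or per-residue mean) of ``prop`` for one complex.

    Returns (large, small), or None when either group is empty — the complex
    is then excluded pairwise from that comparison.
    """
    if len(sgd.large) == 0 or len(sgd.small) == 0:
        warnings.warn(f"{sgd.structure_id}: empty attention group; "
                      f"structure dropped for {prop!r}")
        return None
    v = np.asarray(sgd.properties[prop], float)
    lv, sv = v[np.asarray(sgd.large)], v[np.asarray(sgd.small)]
    lv, sv = lv[~np.isnan(lv)], sv[~np.isnan(sv)]
    if len(lv) == 0 or len(sv) == 0:
        return None
    return float(lv.mean()), float(sv.mean())


def paired_t(large: np.ndarray, small: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Student's t-test on per-structure group values."""
    large, small = np.asarray(large, float), np.asarray(small, float)
    if large.shape != small.shape:
        raise ValueError("paired vectors must have equal length")
    if len(large) < 2:
        raise ValueError("paired t-test needs n >= 2")
    diff = large - small
    if diff.std(ddof=1) <= 1e-12 * max(1.0, float(np.abs(diff).max())):
        if diff.mean() == 0.0:
            warnings.warn("degenerate paired t-test: identical groups")
            return float("nan"), float("nan")
        warnings.warn("zero variance of nonzero differences; p -> 0 limit")
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = sps.ttest_rel(large, small)
    return float(t), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_FDR_LADDER = [(0.05, "***"), (0.10, "**"), (0.15, "*")]


def significance_symbols(pvalues) -> list[str]:
    """FDR-ladder symbols from raw p-values via BH rejection at each level."""
    p = np.asarray(pvalues, float)
    symbols = [""] * len(p)
    for alpha, sym in reversed(_FDR_LADDER):  # loosest first, tighter overrides
        ok = ~np.isnan(p)
        reject = np.zeros(len(p), bool)
        if ok.any():
            reject[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
        for i, r in enumerate(reject):
            if r:
                symbols[i] = sym
    return symbols


def build_comparison_table(structures: list[StructureGroupData],
                           side: str = "tcr",
                           properties=None) -> pd.DataFrame:
    """One comparison row per structural property for the given side.

    Per property: per-structure paired group values, their means +- SD across
    structures, the paired t statistic and p, the BH-adjusted p (adjusted
    within this table), and the FDR-ladder symbol.
    """
    if properties is None:
        properties = TCR_PROPERTIES if side == "tcr" else PEPTIDE_PROPERTIES
    rows = []
    for prop, label, continuous in properties:
        pairs = [gp for s in structures
                 if (gp := group_proportions(s, prop, continuous)) is not None]
        if len(pairs) < 2:
            raise ValueError(f"fewer than 2 structures with non-empty groups "
                             f"for property {prop!r}")
        lv = np.array([x[0] for x in pairs])
        sv = np.array([x[1] for x in pairs])
        t, p = paired_t(lv, sv)
        rows.append({
            "property": label, "column": prop, "n_structures": len(pairs),
            "large_mean": lv.mean(), "large_sd": lv.std(ddof=1),
            "small_mean": sv.mean(), "small_sd": sv.std(ddof=1),
            "t": t, "p_value": p,
        })
    df = pd.DataFrame(rows)
    valid = ~df["p_value"].isna()
    df["p_adjusted"] = np.nan
    df.loc[valid, "p_adjusted"] = bh_adjust(df.loc[valid, "p_value"])
    df["symbol"] = significance_symbols(df["p_value"].to_numpy())
    return df


def render_table(df: pd.DataFrame, path=None) -> pd.DataFrame:
    """Human-readable layout: Property, Large/Small attention (mean+-SD), p, symbol."""
    out = pd.DataFrame({
        "Property": df["property"],
        "Large attention": [f"{m:.4f} ± {s:.4f}"
                            for m, s in zip(df["large_mean"], df["large_sd"])],
        "Small attention": [f"{m:.4f} ± {s:.4f}"
                            for m, s in zip(df["small_mean"], df["small_sd"])],
        "p-value": df["p_value"].map(lambda v: f"{v:.4g}"),
        "p-adjusted": df["p_adjusted"].map(lambda v: f"{v:.4g}"),
        "": df["symbol"],
    })
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out


def structure_group_data(large_calls, small_calls, props: pd.DataFrame,
                         side: str, record=None,
                         structure_id: str = "") -> StructureGroupData:
    """Bridge residue call sets and a property table into group data.

    ``props`` is the table from :func:`tcrbind.structure.residue_properties`.
    For ``side='tcr'`` the call positions index ``cdr3a + ':' + cdr3b``
    (colon skipped, 1-based); properties are taken from the cdr3a/cdr3b rows
    in span order.  For ``side='peptide'`` positions index the peptide.
    Head multiplicity is preserved.
    """
    if side == "tcr":
        sub = pd.concat([props[props.role == "cdr3a"].sort_values("pos"),
                         props[props.role == "cdr3b"].sort_values("pos")])
        if record is None:
            raise ValueError("record required for side='tcr' position mapping")
        colon = len(record.cdr3a) + 1

        def to_index(t):
            return t - 1 if t < colon else len(record.cdr3a) + (t - colon - 1)
    else:
        sub = props[props.role == "peptide"].sort_values("pos")

        def to_index(t):
            return t - 1
    n = len(sub)
    missing = sub["missing"].to_numpy(bool)
    properties = {}
    for col in sub.columns:
        if col in ("chain", "seqid", "aa", "role", "pos", "missing"):
            continue
        v = sub[col].to_numpy(float)
        v[missing] = np.nan   # excluded from group statistics
        properties[col] = v

    def indices(callset):
        out = []
        for head_calls in callset.per_head.values():
            for t in head_calls:
                i = to_index(t)
                if 0 <= i < n:
                    out.append(i)
        return np.array(out, int)

    return StructureGroupData(
        structure_id=structure_id or getattr(large_calls, "record_id", ""),
        large=indices(large_calls), small=indices(small_calls),
        properties=properties)
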