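"""Per-residue annotation tracks and guide-level annotation attachment.

Annotations are consumed as tables produced by external predictors:
PROVEAN single-residue deletion scores (more negative = more conserved),
disorder propensities in [0, 1] (1 = disordered), per-tool secondary
structure probability tables over helix/strand/coil, and domain intervals
(1-based inclusive).  This module merges them into one track per protein
and attaches residue-level values to each guide's two mapped amino acids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AA_CLASSES",
    "AnnotationTrack",
    "consensus_secondary_structure",
    "classify_residue",
    "attach_annotations",
    "read_residue_table",
    "read_domain_table",
]

SS_STATES = ("H", "B", "C")  # helix, strand (sheet), coil

# 13 non-mutually-exclusive amino-acid classes
AA_CLASSES: dict[str, frozenset[str]] = {
    "polar": frozenset("STYNQ"),
    "nonpolar": frozenset("GAVCPLIMWF"),
    "hydrophobic": frozenset("AVILMFYW"),
    "hydrophilic": frozenset("STHNQEDKR"),
    "positively_charged": frozenset("RHK"),
    "negatively_charged": frozenset("DE"),
    "aliphatic": frozenset("AGILPV"),
    "aromatic": frozenset("FWY"),
    "acidic": frozenset("DE"),
    "basic": frozenset("RHK"),
    "hydroxylic": frozenset("ST"),
    "sulfur_containing": frozenset("CM"),
    "amidic": frozenset("NQ"),
}

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AnnotationTrack:
    """Per-residue annotations for one protein (arrays of length L)."""

    protein_id: str
    length: int
    provean: np.ndarray | None = None
    disorder: np.ndarray | None = None
    ss_label: np.ndarray | None = None   # array of 'H'/'B'/'C'
    ss_weight: np.ndarray | None = None  # consensus weight of the label
    domains: list[tuple[int, int, str]] = field(default_factory=list)
    sequence: str | None = None          # one-letter amino acids
    codons: list[str] | None = None

    def __post_init__(self) -> None:
        for name in ("provean", "disorder", "ss_label", "ss_weight"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != self.length:
                raise ValueError(f"{name} length {len(arr)} != L={self.length}")

    def in_domain(self, position: int) -> bool:
        """True when the 1-based residue lies in any domain interval
        (inclusive ends)."""
        return any(a <= position <= b for a, b, _ in self.domains)


def consensus_secondary_structure(tables) -> tuple[np.ndarray, np.ndarray]:
    """Weighted consensus over per-tool secondary-structure probabilities.

    Each table is a DataFrame with columns among {H, B, C}, one row per
    residue.  Per residue, the tools' probabilities are summed per state
    and divided by the grand sum, giving a weight per state; the state
    with the highest weight is the consensus label (exact ties -> C).

    Returns (labels, weights): the label and its weight per residue.
    """
    if not tables:
        raise ValueError("need at least one secondary-structure table")
    mats = []
    n = None
    for t in tables:
        df = pd.DataFrame(t).reindex(columns=list(SS_STATES), fill_value=0.0)
        if n is None:
            n = len(df)
        elif len(df) != n:
            raise ValueError("secondary-structure tables differ in length")
        mats.append(df.to_numpy(dtype=float))
    total = np.sum(mats, axis=0)                  # residues x 3
    weights = total / total.sum(axis=1, keepdims=True)
    labels = np.empty(n, dtype="<U1")
    best = np.empty(n)
    c_idx = SS_STATES.index("C")
    ties = 0
    for i in range(n):
        w = weights[i]
        m = w.max()
        winners = np.flatnonzero(w == m)
        if winners.size > 1:
            labels[i] = "C"
            best[i] = w[c_idx]
            ties += 1
        else:
            labels[i] = SS_STATES[winners[0]]
            best[i] = m
    if ties:
        warnings.warn(f"{ties} residues had tied consensus weights; "
                      "labeled C", stacklevel=2)
    return labels, best


def classify_residue(aa: str) -> set[str]:
    """Class memberships of a one-letter amino acid (empty for
    non-canonical letters such as selenocysteine U, with a warning)."""
    aa = aa.upper()
    if aa not in _CANONICAL:
        warnings.warn(f"non-canonical amino acid {aa!r}: no class assigned",
                      stacklevel=2)
        return set()
    return {name for name, members in AA_CLASSES.items() if aa in members}


def attach_annotations(
    guides: pd.DataFrame, tracks: dict[str, AnnotationTrack]
) -> pd.DataFrame:
    """Attach residue-level annotations to each guide's aa1/aa2.

    Adds provean1/2, disorder1/2, ss1/2, aa1_letter/aa2_letter, codon1/2
    and ``in_domain`` (true when either mapped residue overlaps any domain
    interval).  Guides of proteins without a track get nulls.
    """
    out = guides.copy()
    cols = ["provean1", "provean2", "disorder1", "disorder2", "ss1", "ss2",
            "aa1_letter", "aa2_letter", "codon1", "codon2", "in_domain"]
    for c in cols:
        out[c] = None
    missing: set[str] = set()
    for idx, row in guides.iterrows():
        track = tracks.get(row["gene_id"])
        if track is None:
            missing.add(str(row["gene_id"]))
            continue
        if pd.isna(row["aa1"]) or pd.isna(row["aa2"]):
            continue
        a1, a2 = int(row["aa1"]), int(row["aa2"])

        def _get(arr, pos):
            if arr is None or not (1 <= pos <= track.length):
                return None
            v = arr[pos - 1]
            return v.item() if hasattr(v, "item") else v

        out.at[idx, "provean1"] = _get(track.provean, a1)
        out.at[idx, "provean2"] = _get(track.provean, a2)
        out.at[idx, "disorder1"] = _get(track.disorder, a1)
        out.at[idx, "disorder2"] = _get(track.disorder, a2)
        out.at[idx, "ss1"] = _get(track.ss_label, a1)
        out.at[idx, "ss2"] = _get(track.ss_label, a2)
        if track.sequence is not None:
            out.at[idx, "aa1_letter"] = track.sequence[a1 - 1]
            out.at[idx, "aa2_letter"] = track.sequence[a2 - 1]
        if track.codons is not None:
            out.at[idx, "codon1"] = track.codons[a1 - 1]
            out.at[idx, "codon2"] = track.codons[a2 - 1]
        out.at[idx, "in_domain"] = track.in_domain(a1) or track.in_domain(a2)
    if missing:
        warnings.warn(
            f"no annotation track for {sorted(missing)}; nulls attached",
            stacklevel=2,
        )
    for c in ("provean1", "provean2", "disorder1", "disorder2"):
        out[c] = pd.to_numeric(out[c])
    return out


def read_residue_table(path: str, value_col: str) -> dict[str, np.ndarray]:
    """Read a per-residue TSV (protein_id, position, <value>) into arrays
    keyed by protein, positions 1-based and dense."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for pid, grp in df.groupby("protein_id"):
        L = int(grp["position"].max())
        arr = np.full(L, np.nan)
        arr[grp["position"].to_numpy(int) - 1] = grp[value_col].to_numpy(float)
        out[str(pid)] = arr
    return out


def read_domain_table(path: str) -> dict[str, list[tuple[int, int, str]]]:
    """Read domain intervals (protein_id, start, end, domain_id), 1-based
    inclusive."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[int, int, str]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["protein_id"]), []).append(
            (int(row["start"]), int(row["end"]), str(row["domain_id"]))
        )
    return out
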