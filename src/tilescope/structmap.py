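"""Map functional scores onto protein structures and linear tracks.

Structure chains are aligned to the protein sequence by Smith-Waterman
local alignment (BLOSUM62, gap open -10, gap extend -0.5); per-residue
scores (LOESS-smoothed by default) are written into the B-factor column of
a recolored PDB copy, together with a text color table and an optional
viewer command script.  The color scale is symmetric around 0: the
outermost bin edges sit at whichever of the 5th/95th score percentiles is
farther from 0, computed over the whole dataset so proteins are visually
comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NO_DATA_BFACTOR",
    "NO_DATA_COLOR",
    "BinSpec",
    "StructureAlignment",
    "align_structure",
    "structure_sequence",
    "bin_scores",
    "assign_bin",
    "write_colored_structure",
    "render_linear_map",
]

NO_DATA_BFACTOR = 999.0  # sentinel written for residues without a score
NO_DATA_COLOR = "#ffff00"  # yellow


@dataclass
class BinSpec:
    """Symmetric score bins with one color per bin (blue to dark purple)."""

    n_bins: int
    edges: np.ndarray  # length n_bins + 1, ascending, symmetric around 0
    colors: list[str] = field(default_factory=list)
    no_data_color: str = NO_DATA_COLOR


@dataclass
class StructureAlignment:
    """Mapping from structure residue numbers to protein positions."""

    pdb_id: str
    chain: str
    residue_map: dict[int, int | None]  # resnum -> 1-based position or None
    coverage: float


def structure_sequence(pdb_file: str, chain: str) -> tuple[str, list[int]]:
    """One-letter sequence and residue numbers of a PDB chain."""
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", pdb_file)
    ch = structure[0][chain]
    seq, numbers = [], []
    for res in ch:
        if res.id[0] != " ":
            continue
        letter = protein_letters_3to1.get(res.get_resname().upper(), "X")
        seq.append(letter)
        numbers.append(res.id[1])
    return "".join(seq), numbers


def align_structure(
    struct_seq: str,
    protein_seq: str,
    residue_numbers=None,
    pdb_id: str = "",
    chain: str = "A",
) -> StructureAlignment:
    """Local alignment of a structure chain to the full protein sequence.

    Smith-Waterman with BLOSUM62, gap open -10, gap extend -0.5.  Aligned
    residues — including mismatched-but-aligned ones — map to protein
    positions; unalignable structure residues map to None.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if not struct_seq or not protein_seq:
        raise ValueError("both sequences must be non-empty")
    if residue_numbers is None:
        residue_numbers = list(range(1, len(struct_seq) + 1))
    aligner = Align.PairwiseAligner(
        mode="local", open_gap_score=-10.0, extend_gap_score=-0.5
    )
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    residue_map: dict[int, int | None] = {r: None for r in residue_numbers}
    try:
        aln = aligner.align(struct_seq, protein_seq)[0]
    except (IndexError, ValueError):
        warnings.warn("no local alignment found; empty mapping", stacklevel=2)
        return StructureAlignment(pdb_id, chain, residue_map, 0.0)
    if aln.score <= 0:
        warnings.warn("alignment score <= 0; empty mapping", stacklevel=2)
        return StructureAlignment(pdb_id, chain, residue_map, 0.0)
    aligned = 0
    for (s_start, s_end), (p_start, p_end) in zip(*aln.aligned):
        for off in range(s_end - s_start):
            residue_map[residue_numbers[s_start + off]] = p_start + off + 1
            aligned += 1
    coverage = aligned / len(struct_seq)
    return StructureAlignment(pdb_id, chain, residue_map, coverage)


def bin_scores(all_scores, n_bins: int = 17) -> BinSpec:
    """Symmetric bin edges and colors from the dataset-wide distribution.

    The outermost edge magnitude is ``max(|p5|, |p95|)``; edges are evenly
    spaced on [-B, B] and scores beyond fall into the outermost bins.
    """
    x = np.asarray(all_scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError("need at least 20 scores to calibrate bins")
    p5, p95 = np.percentile(x, [5, 95])
    B = max(abs(p5), abs(p95))
    if B == 0:
        raise ValueError("degenerate (constant) score distribution")
    edges = np.linspace(-B, B, n_bins + 1)
    from matplotlib.colors import LinearSegmentedColormap, to_hex

    cmap = LinearSegmentedColormap.from_list(
        "score", ["#08519c", "#f7f7f7", "#3f007d"]
    )
    colors = [to_hex(cmap(i / (n_bins - 1))) for i in range(n_bins)]
    return BinSpec(n_bins=n_bins, edges=edges, colors=colors)


def assign_bin(score: float, spec: BinSpec) -> int:
    """0-based bin index of a finite score (monotone; out-of-range scores
    clip to the outermost bins)."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    idx = int(np.digitize(score, spec.edges[1:-1]))
    return min(max(idx, 0), spec.n_bins - 1)


def write_colored_structure(
    pdb_file: str,
    alignment: StructureAlignment,
    residue_scores: dict[int, float],
    binspec: BinSpec,
    out_pdb: str,
    color_table: str | None = None,
    pymol_script: str | None = None,
) -> pd.DataFrame:
    """Write per-residue scores into B-factors of a recolored PDB copy.

    Every atom of a residue whose protein position has a score receives
    that score (2 decimals); residues without data get the sentinel
    B-factor 999.00 and the no-data color (yellow) in the emitted color
    table.  Optionally writes a PyMOL-syntax command script reproducing
    the coloring.  Returns the color table (chain, resi, bin, color).
    """
    from Bio.PDB import PDBIO, PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", pdb_file)
    except Exception as exc:
        raise ValueError(f"malformed PDB {pdb_file}: {exc}") from exc
    rows = []
    n_missing = 0
    for res in structure[0][alignment.chain]:
        if res.id[0] != " ":
            continue
        resnum = res.id[1]
        pos = alignment.residue_map.get(resnum)
        score = residue_scores.get(pos) if pos is not None else None
        if score is None or not np.isfinite(score):
            bfac, bin_idx, color = NO_DATA_BFACTOR, None, binspec.no_data_color
            n_missing += 1
        else:
            bfac = round(float(score), 2)
            bin_idx = assign_bin(score, binspec)
            color = binspec.colors[bin_idx]
        for atom in res:
            atom.set_bfactor(bfac)
        rows.append({"chain": alignment.chain, "resi": resnum,
                     "bin": bin_idx, "color": color})
    if rows and n_missing == len(rows):
        warnings.warn("no residue received a score; all colored no-data",
                      stacklevel=2)
    io = PDBIO()
    io.set_structure(structure)
    io.save(out_pdb)
    # prepend a remark documenting the sentinel
    with open(out_pdb) as fh:
        body = fh.read()
    with open(out_pdb, "w") as fh:
        fh.write(
            "REMARK   3 B-FACTOR COLUMN CARRIES FUNCTIONAL SCORES; "
            f"{NO_DATA_BFACTOR:.2f} = NO DATA\n"
        )
        fh.write(body)
    table = pd.DataFrame(rows)
    if color_table:
        table.to_csv(color_table, sep="\t", index=False)
    if pymol_script:
        with open(pymol_script, "w") as fh:
            fh.write(f"load {out_pdb}\n")
            for r in rows:
                hexcol = r["color"].lstrip("#")
                fh.write(
                    f"color 0x{hexcol}, chain {r['chain']} and resi {r['resi']}\n"
                )
    return table


def render_linear_map(
    gene_id: str,
    score_track,
    annotation_track=None,
    guides: pd.DataFrame | None = None,
    out_figure: str | None = None,
    out_table: str | None = None,
):
    """Stacked linear tracks: guide scores, LOESS curve, annotations.

    Renders per-guide points and the smoothed score curve, plus PROVEAN,
    disorder, secondary structure, and domain tracks when an annotation
    track is present; omitted tracks leave no empty panel.  The underlying
    per-residue table can be exported alongside and is byte-deterministic
    for a fixed input.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    L = score_track.length
    pos = np.arange(1, L + 1)
    table = score_track.to_frame()
    panels = 1
    if annotation_track is not None:
        if annotation_track.provean is not None:
            table["provean"] = annotation_track.provean
            panels += 1
        if annotation_track.disorder is not None:
            table["disorder"] = annotation_track.disorder
            panels += 1
        if annotation_track.ss_label is not None:
            table["ss_label"] = annotation_track.ss_label
            panels += 1
        if annotation_track.domains:
            table["in_domain"] = [annotation_track.in_domain(p) for p in pos]
            panels += 1

    fig, axes = plt.subplots(
        panels, 1, figsize=(10, 1.6 * panels), sharex=True, squeeze=False
    )
    axes = axes.ravel()
    ax = axes[0]
    if guides is not None and len(guides):
        ax.scatter(guides["aa1"], guides["score"], s=8, color="0.4",
                   label="guides")
    ax.plot(pos, score_track.smoothed, color="#b2182b", label="smoothed")
    ax.axhline(0, lw=0.5, color="0.7")
    ax.set_ylabel("score")
    ax.legend(loc="upper right", fontsize=7)
    ax.set_title(gene_id)
    i = 1
    if "provean" in table:
        axes[i].plot(pos, table["provean"], color="#2166ac")
        axes[i].set_ylabel("PROVEAN")
        i += 1
    if "disorder" in table:
        axes[i].plot(pos, table["disorder"], color="#762a83")
        axes[i].set_ylim(-0.05, 1.05)
        axes[i].set_ylabel("disorder")
        i += 1
    if "ss_label" in table:
        colors = {"H": "#d6604d", "B": "#4393c3", "C": "0.8"}
        for p, lab in zip(pos, table["ss_label"]):
            axes[i].axvspan(p - 0.5, p + 0.5, color=colors.get(lab, "0.9"))
        axes[i].set_yticks([])
        axes[i].set_ylabel("SS")
        i += 1
    if "in_domain" in table:
        dom = table["in_domain"].to_numpy(bool)
        axes[i].fill_between(pos, 0, dom.astype(int), step="mid",
                             color="#1b7837")
        axes[i].set_yticks([])
        axes[i].set_ylabel("domain")
        i += 1
    axes[-1].set_xlabel("residue")
    fig.tight_layout()
    if out_figure:
        fig.savefig(out_figure, dpi=150)
    plt.close(fig)
    if out_table:
        table.to_csv(out_table, sep="\t", index=False,
                     float_format="%.6g")
    return table
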