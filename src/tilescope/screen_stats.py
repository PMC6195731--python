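"""Per-gene summaries, hit calling, and annotation association tests.

A gene is a screen hit when at least 75% of its guide scores share a sign,
i.e. the interquartile range of (control-normalized) scores excludes 0.
Associations between guide scores and annotations use Spearman correlation
for continuous annotations, two-sided Mann-Whitney for binary ones, and
Kruskal-Wallis for multi-level ones; pooled analyses z-score each gene's
scores first so no single gene dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSummary",
    "CONTINUOUS_ANNOTATIONS",
    "BINARY_ANNOTATIONS",
    "MULTICLASS_ANNOTATIONS",
    "summarize_gene",
    "call_hits",
    "test_associations",
    "grouped_means",
]

CONTINUOUS_ANNOTATIONS = (
    "provean1", "provean2", "disorder1", "disorder2", "efficiency_score",
    "isoform_fraction", "dist_5p_exon_border", "dist_3p_exon_border",
    "protein_fraction",
)
BINARY_ANNOTATIONS = (
    "in_domain", "nmd_escape", "exon_multiple_of_3", "same_strand_as_gene",
)
MULTICLASS_ANNOTATIONS = ("aa1_letter", "aa2_letter", "codon1", "ss1")


@dataclass
class GeneSummary:
    """Distributional summary of one gene's guide scores."""

    gene_id: str
    n_guides: int
    mean: float
    sd: float
    q1: float
    median: float
    q3: float
    iqr: float
    emd_vs_controls: float | None = None
    guide_density: float | None = None
    mean_guide_distance: float | None = None
    hit: bool = False
    direction: str = "none"


def summarize_gene(
    gene_id: str,
    scores,
    control_scores=None,
    protein_length: int | None = None,
    aa1_positions=None,
) -> GeneSummary:
    """Summary statistics of a gene's guide scores.

    Quartiles use linear interpolation.  ``emd_vs_controls`` is the 1-D
    Wasserstein-1 (earth mover's) distance between the gene's score
    distribution and the negative-control distribution — the cost of
    turning one into the other.  ``guide_density`` is guides per residue;
    ``mean_guide_distance`` averages successive gaps in sorted aa1
    positions.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one guide score")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    emd = None
    if control_scores is not None and len(control_scores) > 0:
        emd = float(stats.wasserstein_distance(x, np.asarray(control_scores,
                                                             dtype=float)))
    density = x.size / protein_length if protein_length else None
    mgd = None
    if aa1_positions is not None and len(aa1_positions) > 1:
        pos = np.sort(np.asarray(aa1_positions, dtype=float))
        mgd = float(np.diff(pos).mean())
    return GeneSummary(
        gene_id=gene_id, n_guides=int(x.size),
        mean=float(x.mean()), sd=float(x.std(ddof=0)),
        q1=float(q1), median=float(med), q3=float(q3), iqr=float(q3 - q1),
        emd_vs_controls=emd, guide_density=density, mean_guide_distance=mgd,
    )


def call_hits(
    summaries: list[GeneSummary], user_hits: list[str] | None = None
) -> list[GeneSummary]:
    """Flag hit genes in place and return the list.

    Default rule: hit iff q1 > 0 or q3 < 0 (the IQR excludes 0, i.e. at
    least 75% of guides agree in sign); direction is positive when the
    median exceeds 0, else negative.  A user-supplied hit list overrides
    the rule entirely.
    """
    for s in summaries:
        if user_hits is not None:
            s.hit = s.gene_id in user_hits
        else:
            s.hit = s.q1 > 0 or s.q3 < 0
        s.direction = ("positive" if s.median > 0 else "negative") if s.hit else "none"
    return summaries


def _zscore_by_gene(df: pd.DataFrame, score_col: str) -> pd.Series:
    def z(s):
        sd = s.std(ddof=0)
        return (s - s.mean()) / sd if sd > 0 else s * 0.0
    return df.groupby("gene_id")[score_col].transform(z)


def test_associations(
    guides: pd.DataFrame,
    hit_genes: list[str] | None = None,
    scope: str = "pooled",
    score_col: str = "score",
    annotations: list[str] | None = None,
    bh: bool = False,
) -> pd.DataFrame:
    """Association tests between guide scores and annotations.

    Pooled scope z-scores each gene's scores before pooling (restricted to
    ``hit_genes`` when given); gene scope tests every hit gene separately.
    Test choice follows annotation arity: Spearman (continuous),
    Mann-Whitney two-sided (binary), Kruskal-Wallis (multi-level, plus the
    amino-acid classes one-vs-rest).  Raw p-values are reported; ``bh``
    adds a Benjamini-Hochberg column.  Annotations with fewer than 3
    complete pairs or a single level are skipped with a reason.
    """
    from .annotate import AA_CLASSES

    if scope not in ("pooled", "gene"):
        raise ValueError(f"scope must be 'pooled' or 'gene', got {scope!r}")
    df = guides.copy()
    if hit_genes is not None:
        df = df[df["gene_id"].isin(hit_genes)]
    if annotations is None:
        annotations = [c for c in CONTINUOUS_ANNOTATIONS + BINARY_ANNOTATIONS
                       + MULTICLASS_ANNOTATIONS if c in df.columns]
        if "aa1_letter" in df.columns:
            annotations += [f"class_{name}" for name in AA_CLASSES]

    groups = [("all", df)] if scope == "pooled" else list(df.groupby("gene_id"))
    if scope == "pooled":
        df = df.assign(**{score_col: _zscore_by_gene(df, score_col)})
        groups = [("all", df)]

    rows = []
    for gname, g in groups:
        for ann in annotations:
            row = {"annotation": ann, "scope": scope,
                   "gene_id": None if scope == "pooled" else gname}
            if ann.startswith("class_"):
                cls = ann[len("class_"):]
                members = AA_CLASSES[cls]
                sub = g.dropna(subset=[score_col, "aa1_letter"])
                values = sub["aa1_letter"].isin(members)
                test = "kruskal"
            elif ann in CONTINUOUS_ANNOTATIONS:
                sub = g.dropna(subset=[score_col, ann])
                values = pd.to_numeric(sub[ann])
                test = "spearman"
            elif ann in BINARY_ANNOTATIONS:
                sub = g.dropna(subset=[score_col, ann])
                values = sub[ann].astype(bool)
                test = "mannwhitney"
            else:
                sub = g.dropna(subset=[score_col, ann])
                values = sub[ann]
                test = "kruskal"
            y = sub[score_col].to_numpy(dtype=float)
            row.update({"test": test, "n": int(len(sub))})
            if len(sub) < 3:
                row.update(statistic=np.nan, p_value=np.nan,
                           reason="fewer than 3 complete pairs")
                rows.append(row)
                continue
            if test == "spearman":
                if values.nunique() < 2:
                    row.update(statistic=np.nan, p_value=np.nan,
                               reason="degenerate annotation (single level)")
                else:
                    r = stats.spearmanr(values.to_numpy(float), y)
                    row.update(statistic=float(r.statistic),
                               p_value=float(r.pvalue), reason=None)
            else:
                levels = [y[values.to_numpy() == lv]
                          for lv in pd.unique(values)]
                levels = [lv for lv in levels if lv.size > 0]
                if len(levels) < 2:
                    row.update(statistic=np.nan, p_value=np.nan,
                               reason="degenerate annotation (single level)")
                elif test == "mannwhitney":
                    r = stats.mannwhitneyu(levels[0], levels[1],
                                           alternative="two-sided")
                    row.update(statistic=float(r.statistic),
                               p_value=float(r.pvalue), reason=None)
                else:
                    r = stats.kruskal(*levels)
                    row.update(statistic=float(r.statistic),
                               p_value=float(r.pvalue), reason=None)
            rows.append(row)
    out = pd.DataFrame(rows)
    if bh and not out.empty:
        from statsmodels.stats.multitest import multipletests

        mask = out["p_value"].notna()
        out["p_bh"] = np.nan
        if mask.any():
            out.loc[mask, "p_bh"] = multipletests(
                out.loc[mask, "p_value"], method="fdr_bh"
            )[1]
    return out


def grouped_means(
    guides: pd.DataFrame,
    score_col: str = "score",
    conservation_col: str = "provean1",
    conservation_threshold: float = -6.0,
    second_col: str = "in_domain",
    second_threshold: float | None = None,
) -> pd.DataFrame:
    """2x2 table of mean score and guide percentage by conservation and a
    second annotation.

    Guides are split by ``conservation <= threshold`` (default -6, the
    conserved side) and by the second annotation — boolean as-is, or
    ``value <= second_threshold`` when a threshold is given (e.g. disorder
    0.5).  Percentages sum to 100 over the four cells; empty cells have a
    null mean.
    """
    df = guides.dropna(subset=[score_col, conservation_col, second_col])
    a = pd.to_numeric(df[conservation_col]) <= conservation_threshold
    if second_threshold is None:
        b = df[second_col].astype(bool)
    else:
        b = pd.to_numeric(df[second_col]) <= second_threshold
    total = len(df)
    rows = []
    for av in (True, False):
        for bv in (True, False):
            cell = df[(a == av) & (b == bv)]
            rows.append({
                "conserved": av,
                second_col: bv,
                "mean_score": float(cell[score_col].mean()) if len(cell) else None,
                "n": len(cell),
                "pct": 100.0 * len(cell) / total if total else 0.0,
            })
    return pd.DataFrame(rows)
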