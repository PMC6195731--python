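"""Guide counting from FASTQ, QC metrics, and functional-score computation.

A functional score is the log2 fold change of a guide's abundance between a
test and a control condition, computed from library-size-normalized counts
with a pseudocount, averaged over replicates (ALFC), optionally shrunk
toward 0 for low-count guides, and normalized so the median negative
control scores 0.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "QCReport",
    "ScoreTable",
    "count_guides",
    "gini",
    "compute_scores",
    "normalize_to_controls",
    "filter_offtarget",
]


@dataclass
class CountMatrix:
    """Raw read counts per (guide, sample) plus sample metadata."""

    counts: pd.DataFrame  # index: guide_id, columns: sample names
    sample_meta: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["condition", "replicate"])
    )

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def add_sample(self, name: str, column: pd.Series) -> None:
        self.counts[name] = column.reindex(self.counts.index).fillna(0).astype(int)


@dataclass
class QCReport:
    """Per-sample sequencing and mapping quality metrics."""

    per_sample: pd.DataFrame  # index: sample; columns: totals + count summaries
    pearson: pd.DataFrame | None = None  # sample x sample correlation of raw counts

    @classmethod
    def from_counts(
        cls, counts: pd.DataFrame, totals: dict[str, int] | None = None
    ) -> "QCReport":
        """Summarize a count matrix; ``totals`` gives raw read totals per
        sample (defaults to the mapped totals, i.e. 100% mapped)."""
        rows = {}
        for sample in counts.columns:
            x = counts[sample].to_numpy(dtype=float)
            mapped = int(x.sum())
            total = int(totals.get(sample, mapped)) if totals else mapped
            rows[sample] = {
                "total_reads": total,
                "mapped_reads": mapped,
                "pct_mapped": mapped / total if total else float("nan"),
                "gini": gini(x) if x.sum() > 0 else float("nan"),
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=0)),
                "min": float(x.min()),
                "p10": float(np.percentile(x, 10)),
                "median": float(np.median(x)),
                "p90": float(np.percentile(x, 90)),
                "max": float(x.max()),
            }
        pearson = counts.corr(method="pearson") if counts.shape[1] > 1 else None
        return cls(per_sample=pd.DataFrame(rows).T, pearson=pearson)


@dataclass
class ScoreTable:
    """Per-guide functional scores for one or more named comparisons."""

    scores: pd.DataFrame  # index: guide_id, one column per comparison
    normalized: bool = False
    method: str = "alfc"


def _open_maybe_gzip(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def count_guides(
    fastq_path: str,
    library: dict[str, str],
    offset: int = 0,
    anchor: str | None = None,
) -> tuple[pd.Series, dict[str, int]]:
    """Count spacer occurrences in a FASTQ file.

    ``library`` maps spacer sequence -> guide_id; spacers must be unique.
    A read maps when the 20-nt window at ``offset`` equals a library spacer;
    with ``anchor`` set, the window starts right after the first occurrence
    of the anchor sequence instead.  Returns the count column (indexed by
    guide_id, zeros included) and ``{"total": ..., "mapped": ...}``.
    """
    if len(set(library.values())) != len(library):
        raise ValueError("guide_ids not unique in library")
    spacer_len = len(next(iter(library))) if library else 20
    if any(len(s) != spacer_len for s in library):
        raise ValueError("library spacers must share one length")
    counts = {gid: 0 for gid in library.values()}
    total = mapped = 0
    with _open_maybe_gzip(fastq_path) as fh:
        for lineno, line in enumerate(fh):
            if lineno % 4 != 1:
                continue
            total += 1
            read = line.strip()
            if anchor is not None:
                pos = read.find(anchor)
                if pos < 0:
                    continue
                window = read[pos + len(anchor) : pos + len(anchor) + spacer_len]
            else:
                window = read[offset : offset + spacer_len]
            gid = library.get(window)
            if gid is not None:
                counts[gid] += 1
                mapped += 1
    if total == 0:
        warnings.warn(f"empty FASTQ {fastq_path}", stacklevel=2)
    return pd.Series(counts, name="count"), {"total": total, "mapped": mapped}


def gini(counts) -> float:
    """Gini coefficient of a non-negative count vector.

    ``G = sum_i (2i - n - 1) x_(i) / (n sum_i x_i)`` with ``x_(i)``
    ascending and ``i = 1..n``; 0 for perfect equality, ``(n-1)/n`` for a
    single point mass.
    """
    x = np.sort(np.asarray(counts, dtype=float))
    if x.size == 0:
        raise ValueError("empty vector")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    s = x.sum()
    if s == 0:
        raise ValueError("Gini undefined for all-zero vector")
    n = x.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * s))


def compute_scores(
    counts: CountMatrix,
    comparisons: dict[str, tuple[list[str], list[str]]],
    method: str = "alfc",
    pseudocount: float = 1.0,
    tau: float = 100.0,
) -> ScoreTable:
    """Per-guide log2 fold changes for named test-vs-control comparisons.

    ALFC: per replicate pair, ``log2((t_i + c)/N_t) - log2((u_i + c)/N_u)``
    with pseudocount ``c`` and library sizes ``N`` (counts-per-million
    scaling), averaged over replicates.  The shrinkage method multiplies the
    ALFC estimate by ``w = S/(S + tau)`` where ``S`` is the guide's total
    count across the comparison's samples, pulling low-count guides toward
    0 (the behavior a count-model shrinkage estimator would produce).
    """
    if method not in ("alfc", "shrinkage"):
        raise ValueError(f"unknown method {method!r}")
    df = counts.counts
    lib_sizes = df.sum(axis=0)
    if (lib_sizes[[s for pair in comparisons.values() for grp in pair for s in grp]] == 0).any():
        raise ValueError("zero library size in a compared sample")
    out = {}
    for name, (test, control) in comparisons.items():
        missing = [s for s in test + control if s not in df.columns]
        if missing:
            raise KeyError(f"samples {missing} not in count matrix")
        def _log_cpm(samples):
            cols = []
            for s in samples:
                cols.append(np.log2((df[s] + pseudocount) / lib_sizes[s] * 1e6))
            return cols
        t_cols, u_cols = _log_cpm(test), _log_cpm(control)
        if len(t_cols) == len(u_cols):
            lfc = pd.concat(
                [t - u for t, u in zip(t_cols, u_cols)], axis=1
            ).mean(axis=1)
        else:  # unpaired replicates: difference of mean log-cpm
            lfc = pd.concat(t_cols, axis=1).mean(axis=1) - pd.concat(
                u_cols, axis=1
            ).mean(axis=1)
        if method == "shrinkage":
            total = df[test + control].sum(axis=1)
            lfc = lfc * (total / (total + tau))
        out[name] = lfc
    return ScoreTable(pd.DataFrame(out), normalized=False, method=method)


def normalize_to_controls(
    scores: ScoreTable, control_guide_ids: list[str]
) -> ScoreTable:
    """Subtract the median negative-control score from every guide score.

    After normalization the control median is 0 in every comparison.  With
    no scored controls the table is passed through unchanged with a
    warning and ``normalized=False``.
    """
    present = [g for g in control_guide_ids if g in scores.scores.index]
    if not present:
        warnings.warn("no control guides with scores; normalization skipped",
                      stacklevel=2)
        return ScoreTable(scores.scores.copy(), normalized=False,
                          method=scores.method)
    medians = scores.scores.loc[present].median(axis=0)
    return ScoreTable(scores.scores - medians, normalized=True,
                      method=scores.method)


def filter_offtarget(
    guides: pd.DataFrame, threshold: float = 5.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a guide table into (kept, removed) by specificity score.

    Removes guides whose MIT off-target score (0-100; low = promiscuous)
    is strictly below ``threshold`` (default 5).  Guides with a missing
    score are kept and flagged with a warning.
    """
    scores = guides["offtarget_score"]
    if scores.isna().all() and len(guides):
        warnings.warn("all off-target scores missing; nothing filtered",
                      stacklevel=2)
    elif scores.isna().any():
        warnings.warn(
            f"{int(scores.isna().sum())} guides lack an off-target score "
            "and were kept", stacklevel=2
        )
    removed_mask = scores.notna() & (scores < threshold)
    return guides[~removed_mask].copy(), guides[removed_mask].copy()
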