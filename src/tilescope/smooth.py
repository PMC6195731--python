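"""Local quadratic (LOESS) smoothing of guide scores along a protein.

Guides land only where PAMs allow, so many residues carry no score.  A
locally weighted quadratic regression with tricube weights, evaluated at
every residue 1..L, both smooths the observed scores and interpolates the
untargeted residues.  The span is the fraction of guide positions entering
each local fit and defaults to 100 residues' worth of data,
``min(1, 100/L)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ResidueScoreTrack", "loess_fit", "loess_track"]

MIN_LOCAL_POINTS = 4  # a quadratic fit needs >3 points to be determined
MIN_POSITIONS_FOR_LOESS = 8


@dataclass
class ResidueScoreTrack:
    """Per-residue raw (mean of mapped guides) and smoothed scores."""

    protein_id: str
    length: int
    raw: np.ndarray        # length L, NaN where no guide maps
    smoothed: np.ndarray   # length L, finite everywhere
    span_aa: float = 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "raw": self.raw,
                "smoothed": self.smoothed,
            }
        )


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    eval_x: np.ndarray,
    span: float,
    degree: int = 2,
) -> np.ndarray:
    """Tricube-weighted local polynomial regression.

    For each evaluation point, the nearest ``ceil(span * n)`` data points
    (at least 4) are fit by weighted least squares with tricube weights
    ``(1 - (d/d_max)^3)^3``; no robustness iterations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("insufficient data: need at least 2 points")
    q = min(n, max(MIN_LOCAL_POINTS, int(np.ceil(span * n))))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(eval_x.size)
    for j, x0 in enumerate(np.asarray(eval_x, dtype=float)):
        dist = np.abs(xs - x0)
        idx = np.argsort(dist, kind="stable")[:q]
        d = dist[idx]
        dmax = d.max()
        if dmax == 0:
            out[j] = ys[idx].mean()
            continue
        w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
        if (w > 0).sum() <= degree:
            # boundary points carry zero tricube weight; nudge so the
            # local system stays determined
            w = np.clip(1 - (d / (dmax * (1 + 1e-9))) ** 3, 0, None) ** 3
        keep = w > 0
        deg = min(degree, keep.sum() - 1)
        coeffs = np.polyfit(xs[idx][keep] - x0, ys[idx][keep], deg,
                            w=np.sqrt(w[keep]))
        out[j] = coeffs[-1]
    return out


def loess_track(
    points,
    length: int,
    protein_id: str = "",
    span_aa: float = 100.0,
) -> ResidueScoreTrack:
    """Smooth (position, score) guide data onto every residue of a protein.

    Multiple scores at one residue are averaged before fitting.  Proteins
    with fewer than 8 distinct guide positions fall back to linear
    interpolation with constant edge extension (quadratic LOESS is
    degenerate at tiny n), with a warning.

    Parameters
    ----------
    points : iterable of (position, score)
        1-based residue positions with guide scores.
    length : int
        Protein length L; the track is evaluated at 1..L.
    span_aa : float
        Residues of data per local fit; the span fraction is
        ``min(1, span_aa / L)``.
    """
    df = pd.DataFrame(list(points), columns=["position", "score"])
    if df.empty or df["position"].nunique() < 2:
        raise ValueError("insufficient data: need >= 2 distinct positions")
    per_res = df.groupby("position")["score"].mean()
    x = per_res.index.to_numpy(dtype=float)
    y = per_res.to_numpy(dtype=float)
    positions = np.arange(1, length + 1, dtype=float)

    raw = np.full(length, np.nan)
    in_range = (x >= 1) & (x <= length)
    raw[x[in_range].astype(int) - 1] = y[in_range]

    if x.size < MIN_POSITIONS_FOR_LOESS:
        warnings.warn(
            f"{protein_id or 'protein'}: only {x.size} guide positions; "
            "falling back to linear interpolation", stacklevel=2
        )
        smoothed = np.interp(positions, x, y)
    else:
        span = min(1.0, span_aa / length)
        smoothed = loess_fit(x, y, positions, span)
    return ResidueScoreTrack(
        protein_id=protein_id,
        length=length,
        raw=raw,
        smoothed=smoothed,
        span_aa=span_aa,
    )
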