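"""Gradient-boosted prediction of guide functional scores from features.

Targets are made comparable across genes by flipping each gene's scores
when their mean is negative (so high always means strong effect) and
z-scoring within the gene.  Features combine one-hot spacer nucleotide and
dinucleotide identities, protein-level annotations of the two targeted
residues, and transcript-level context.  Evaluation is gene-grouped:
cross-validation folds hold out all guides of 10% of genes, and
performance is the Spearman correlation between observed and predicted
scaled scores per held-out gene.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "DEFAULT_HYPERPARAMS",
    "gc_content",
    "transform_targets",
    "FeatureBuilder",
    "GuideScorePredictor",
    "CVReport",
    "cross_validate",
]

# boosting hyperparameters (LightGBM); all other parameters at defaults
DEFAULT_HYPERPARAMS = {
    "bagging_freq": 0,
    "colsample_bytree": 1 / 3,
    "learning_rate": 0.01,
    "max_depth": -1,
    "min_child_samples": 32,
    "n_estimators": 1024,
    "max_bin": 63,
}

NUMERIC_FEATURES = (
    "provean1", "provean2", "protein_fraction", "disorder1", "disorder2",
    "gc_content", "exon_length", "offtarget_score",
    "dist_3p_exon_border", "dist_5p_exon_border",
)
BOOLEAN_FEATURES = (
    "in_domain", "exon_multiple_of_3", "nmd_escape", "same_strand_as_gene",
)
AA_LETTERS = tuple("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDES = tuple("ACGT")
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)


def gc_content(spacer: str) -> float:
    """(#G + #C) / 20 of a 20-nt spacer."""
    spacer = spacer.upper()
    if len(spacer) != 20:
        raise ValueError(f"spacer must be 20 nt, got {len(spacer)}")
    if set(spacer) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in spacer {spacer!r}")
    return (spacer.count("G") + spacer.count("C")) / 20.0


def transform_targets(
    scores: pd.DataFrame,
    score_col: str = "score",
    gene_col: str = "gene_id",
    mean_filter: float | None = None,
) -> pd.DataFrame:
    """Per-gene sign-align and z-score guide scores.

    Each gene's scores are multiplied by -1 when their mean is negative,
    then centered and scaled to unit (population) standard deviation, so
    the highest scaled score marks the strongest effect regardless of
    screen direction.  Genes with fewer than 2 guides or zero variance are
    dropped with a warning.  ``mean_filter`` optionally drops genes whose
    raw mean score exceeds the threshold before transforming (training-set
    outlier filter; -1 in the fitness-screen setting).

    Returns the input rows that survive, with columns ``scaled``,
    ``flipped``, ``gene_mean``, ``gene_sd`` added.
    """
    out = []
    dropped = []
    for gene, grp in scores.groupby(gene_col, sort=False):
        x = grp[score_col].to_numpy(dtype=float)
        m = x.mean()
        if mean_filter is not None and m > mean_filter:
            dropped.append((gene, f"mean {m:.3g} > filter {mean_filter}"))
            continue
        if x.size < 2:
            dropped.append((gene, "fewer than 2 guides"))
            continue
        flipped = m < 0
        if flipped:
            x = -x
        sd = x.std(ddof=0)
        if sd == 0:
            dropped.append((gene, "zero variance"))
            continue
        g = grp.copy()
        g["scaled"] = (x - x.mean()) / sd
        g["flipped"] = flipped
        g["gene_mean"] = m
        g["gene_sd"] = sd
        out.append(g)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} genes from target transform: "
            + "; ".join(f"{g} ({r})" for g, r in dropped[:5]),
            stacklevel=2,
        )
    if not out:
        raise ValueError("no genes survived the target transform")
    return pd.concat(out, axis=0)


class FeatureBuilder:
    """Build the guide feature matrix with a frozen column schema.

    One-hot blocks: targeted amino-acid identities (aa1, aa2), spacer
    single-nucleotide identity at positions 0-19 and dinucleotide identity
    at positions 0-18 (0-indexed from the 5' end), plus boolean context
    flags.  Numeric annotations are imputed with the training median and
    paired with a missingness indicator.
    """

    def __init__(self) -> None:
        self.medians_: dict[str, float] | None = None
        self.columns_: list[str] | None = None

    @staticmethod
    def _raw_frame(guides: pd.DataFrame) -> pd.DataFrame:
        df = guides.copy()
        if "gc_content" not in df:
            df["gc_content"] = df["spacer"].map(gc_content)
        blocks = [df[list(NUMERIC_FEATURES)].apply(pd.to_numeric)]
        for col in BOOLEAN_FEATURES:
            blocks.append(
                df[col].astype("boolean").fillna(False).astype(int).rename(col)
            )
        for col, cats in (("aa1_letter", AA_LETTERS), ("aa2_letter", AA_LETTERS)):
            onehot = pd.DataFrame(
                {f"{col}_{c}": (df[col] == c).astype(int) for c in cats},
                index=df.index,
            )
            blocks.append(onehot)
        spacers = df["spacer"].str.upper()
        for p in range(20):
            nt = spacers.str[p]
            blocks.append(pd.DataFrame(
                {f"nt{p}_{c}": (nt == c).astype(int) for c in NUCLEOTIDES},
                index=df.index,
            ))
        for p in range(19):
            dn = spacers.str[p : p + 2]
            blocks.append(pd.DataFrame(
                {f"dn{p}_{c}": (dn == c).astype(int) for c in DINUCLEOTIDES},
                index=df.index,
            ))
        return pd.concat(blocks, axis=1)

    def fit_transform(self, guides: pd.DataFrame) -> pd.DataFrame:
        X = self._raw_frame(guides)
        self.medians_ = {}
        for col in NUMERIC_FEATURES:
            med = float(X[col].median()) if X[col].notna().any() else 0.0
            self.medians_[col] = med
            if X[col].isna().any():
                X[f"{col}_missing"] = X[col].isna().astype(int)
                X[col] = X[col].fillna(med)
        self.columns_ = list(X.columns)
        return X

    def transform(self, guides: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise ValueError("FeatureBuilder not fitted")
        X = self._raw_frame(guides)
        n_imputed = 0
        for col in NUMERIC_FEATURES:
            if f"{col}_missing" in self.columns_:
                X[f"{col}_missing"] = X[col].isna().astype(int)
            n_imputed += int(X[col].isna().sum())
            X[col] = X[col].fillna(self.medians_[col])
        if n_imputed:
            warnings.warn(f"imputed {n_imputed} missing numeric values with "
                          "training medians", stacklevel=2)
        missing_cols = [c for c in self.columns_ if c not in X.columns]
        if missing_cols:
            raise ValueError(f"feature schema mismatch; missing {missing_cols}")
        return X[self.columns_]


@dataclass
class GuideScorePredictor:
    """Gradient-boosted decision tree regressor for scaled guide scores."""

    hyperparams: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMS))
    seed: int = 7
    model_: object | None = None
    feature_names_: list[str] | None = None

    def fit(self, X: pd.DataFrame, y) -> "GuideScorePredictor":
        import lightgbm as lgb

        if len(X) != len(y):
            raise ValueError("feature/target length mismatch")
        self.model_ = lgb.LGBMRegressor(
            **self.hyperparams, random_state=self.seed, n_jobs=1, verbose=-1
        )
        self.model_.fit(X, np.asarray(y, dtype=float))
        self.feature_names_ = list(X.columns)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.model_ is None:
            raise ValueError("model not trained")
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise ValueError(f"feature schema mismatch; missing {missing}")
        return self.model_.predict(X[self.feature_names_])

    def feature_importance(self) -> pd.DataFrame:
        """Features ranked by total information gain of their splits."""
        if self.model_ is None:
            raise ValueError("model not trained")
        gains = self.model_.booster_.feature_importance(importance_type="gain")
        df = pd.DataFrame({"feature": self.feature_names_, "gain": gains})
        return df.sort_values("gain", ascending=False, kind="stable",
                              ignore_index=True)

    def save(self, path: str) -> None:
        """Persist as a self-describing JSON archive (schema +
        hyperparameters + LightGBM text model)."""
        if self.model_ is None:
            raise ValueError("model not trained")
        payload = {
            "hyperparams": self.hyperparams,
            "seed": self.seed,
            "feature_names": self.feature_names_,
            "model": self.model_.booster_.model_to_string(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "GuideScorePredictor":
        import lightgbm as lgb

        with open(path) as fh:
            payload = json.load(fh)
        obj = cls(hyperparams=payload["hyperparams"], seed=payload["seed"])
        booster = lgb.Booster(model_str=payload["model"])

        class _BoosterShim:
            def __init__(self, b):
                self.booster_ = b

            def predict(self, X):
                return self.booster_.predict(X)

        obj.model_ = _BoosterShim(booster)
        obj.feature_names_ = payload["feature_names"]
        return obj


@dataclass
class CVReport:
    """Gene-grouped cross-validation results."""

    per_gene: pd.DataFrame    # gene_id, n_guides, rho (NaN if < 3 guides)
    predictions: pd.Series    # held-out prediction per guide row
    mean_rho: float
    folds: pd.Series          # fold index per guide row


def cross_validate(
    X: pd.DataFrame,
    y,
    genes,
    k: int = 10,
    hyperparams: dict | None = None,
    seed: int = 7,
) -> CVReport:
    """Gene-grouped k-fold cross-validation of the GBDT predictor.

    Folds partition genes — all guides of a gene are held out together —
    and performance is the per-gene Spearman correlation between observed
    and held-out predicted scaled scores (genes with < 3 guides get a null
    correlation).
    """
    from sklearn.model_selection import GroupKFold

    genes = pd.Series(np.asarray(genes), index=X.index, name="gene_id")
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    if genes.nunique() < k:
        raise ValueError(f"need at least k={k} genes, got {genes.nunique()}")
    preds = pd.Series(np.nan, index=X.index)
    folds = pd.Series(-1, index=X.index)
    gkf = GroupKFold(n_splits=k)
    for fold, (tr, te) in enumerate(gkf.split(X, y, groups=genes)):
        tr_idx, te_idx = X.index[tr], X.index[te]
        overlap = set(genes.loc[tr_idx]) & set(genes.loc[te_idx])
        assert not overlap, f"gene leakage across folds: {overlap}"
        model = GuideScorePredictor(
            hyperparams=dict(hyperparams or DEFAULT_HYPERPARAMS), seed=seed
        )
        model.fit(X.loc[tr_idx], y.loc[tr_idx])
        preds.loc[te_idx] = model.predict(X.loc[te_idx])
        folds.loc[te_idx] = fold
    rows = []
    for gene, idx in genes.groupby(genes).groups.items():
        if len(idx) < 3:
            rho = np.nan
        else:
            rho = spearmanr(y.loc[idx], preds.loc[idx]).statistic
        rows.append({"gene_id": gene, "n_guides": len(idx), "rho": rho})
    per_gene = pd.DataFrame(rows)
    return CVReport(
        per_gene=per_gene,
        predictions=preds,
        mean_rho=float(per_gene["rho"].mean(skipna=True)),
        folds=folds,
    )
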