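"""Single-view framework: concatenated multi-omics pathway scores fed to a
pluggable predictor.

The omics blocks are column-concatenated (each already unit-variance
scaled, so the pathway transform itself is the cross-omics harmonizer) and
ssPA is fitted on the concatenation: a pathway's submatrix may then mix,
say, metabolite and protein columns. A predictor conforming to a small
fit / predict_score / feature_importance contract is trained on the
resulting sample-by-pathway matrix. Default predictors: PLS (k = 1
multi-block model), random forest, logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import multiview
from .pathways import PathwayCollection, filter_coverage
from .preprocess import OmicsBlock, OutcomeVector, apply_standardizer, fit_standardizer
from .sspa import PathwayScoreMatrix, SspaTransformer, fit_sspa, transform_sspa

__all__ = [
    "PredictorSpec",
    "SingleViewModel",
    "PLSPredictor",
    "RandomForestPredictor",
    "LogisticPredictor",
    "make_predictor",
    "fit_singleview",
    "predict_singleview",
    "importance",
    "rfe_select",
]


class PLSPredictor:
    """Single-block PLS predictor (the k = 1 multi-block model)."""

    def __init__(self, R: int = 1, **kwargs):
        self.R = R
        self.kwargs = kwargs
        self.model_ = None

    def fit(self, scores: pd.DataFrame, y):
        self.model_ = multiview.fit_mbpls([scores], y, R=self.R, **self.kwargs)
        return self

    def predict_score(self, scores: pd.DataFrame) -> np.ndarray:
        return multiview.predict(self.model_, [scores])

    def feature_importance(self) -> pd.Series:
        v = multiview.vip(self.model_)
        return v.values.droplevel("block")


# Defaults follow a tuned random-forest configuration for pathway-score
# classification; all overridable through PredictorSpec params.
RF_DEFAULTS = dict(
    n_estimators=200,
    min_samples_split=2,
    min_samples_leaf=4,
    max_features="sqrt",
    max_depth=10,
    bootstrap=True,
    oob_score=True,
)


class RandomForestPredictor:
    def __init__(self, random_state: int | None = None, **kwargs):
        params = {**RF_DEFAULTS, **kwargs}
        self.clf = RandomForestClassifier(random_state=random_state, **params)
        self.columns_ = None

    def fit(self, scores: pd.DataFrame, y):
        self.columns_ = list(scores.columns)
        yv = y.encoded() if isinstance(y, OutcomeVector) else np.asarray(y)
        self.clf.fit(scores.to_numpy(), yv)
        return self

    def predict_score(self, scores: pd.DataFrame) -> np.ndarray:
        return self.clf.predict_proba(scores[self.columns_].to_numpy())[:, 1]

    def feature_importance(self) -> pd.Series:
        return pd.Series(self.clf.feature_importances_, index=self.columns_)


class LogisticPredictor:
    def __init__(self, **kwargs):
        kwargs.setdefault("max_iter", 1000)
        self.clf = LogisticRegression(**kwargs)
        self.columns_ = None

    def fit(self, scores: pd.DataFrame, y):
        self.columns_ = list(scores.columns)
        yv = y.encoded() if isinstance(y, OutcomeVector) else np.asarray(y)
        self.clf.fit(scores.to_numpy(), yv)
        return self

    def predict_score(self, scores: pd.DataFrame) -> np.ndarray:
        return self.clf.predict_proba(scores[self.columns_].to_numpy())[:, 1]

    def feature_importance(self) -> pd.Series:
        return pd.Series(np.abs(self.clf.coef_[0]), index=self.columns_)


@dataclass
class PredictorSpec:
    """Declarative predictor choice: kind tag + hyperparameters."""

    kind: str = "pls"
    params: dict = field(default_factory=dict)


def make_predictor(spec: PredictorSpec):
    if spec.kind == "pls":
        return PLSPredictor(**spec.params)
    if spec.kind == "random_forest":
        return RandomForestPredictor(**spec.params)
    if spec.kind == "logistic":
        return LogisticPredictor(**spec.params)
    if spec.kind == "custom":
        obj = spec.params.get("instance")
        for meth in ("fit", "predict_score"):
            if not callable(getattr(obj, meth, None)):
                raise TypeError(f"custom predictor lacks required method {meth!r}")
        return obj
    raise ValueError(f"unknown predictor kind {spec.kind!r}")


@dataclass
class SingleViewModel:
    transformer: SspaTransformer
    predictor: object
    predictor_kind: str
    pathway_ids: list[str]
    pathway_names: dict[str, str]
    standardizers: list
    block_labels: list[str]
    importance_table: pd.DataFrame | None = None


def _concat_standardized(
    blocks: list[OmicsBlock], standardizers=None
) -> tuple[OmicsBlock, list]:
    if standardizers is None:
        standardizers = [fit_standardizer(b) for b in blocks]
    std_blocks = [apply_standardizer(s, b) for s, b in zip(standardizers, blocks)]
    data = pd.concat([b.data for b in std_blocks], axis=1)
    if data.columns.has_duplicates:
        raise ValueError("feature ids collide across blocks")
    cat = OmicsBlock(
        data=data, omics_label="concat", is_log_scale=True, is_standardized=True
    )
    return cat, standardizers


def fit_singleview(
    blocks: list[OmicsBlock],
    y: OutcomeVector,
    pathways: PathwayCollection,
    sspa_method: str = "svd",
    predictor: PredictorSpec | None = None,
    min_coverage: int = 2,
) -> SingleViewModel:
    """Standardize, concatenate, score pathways on the concatenation, and
    fit the predictor on the multi-omics score matrix."""
    predictor = predictor or PredictorSpec("pls")
    cat, standardizers = _concat_standardized(blocks)
    filtered, _ = filter_coverage(pathways, set(cat.feature_ids), min_coverage)
    transformer = fit_sspa(cat, filtered, method=sspa_method, min_coverage=min_coverage)
    A = transform_sspa(transformer, cat)
    clf = make_predictor(predictor)
    clf.fit(A.scores, y)
    model = SingleViewModel(
        transformer=transformer,
        predictor=clf,
        predictor_kind=predictor.kind,
        pathway_ids=list(A.pathway_ids),
        pathway_names={p.id: p.name for p in filtered},
        standardizers=standardizers,
        block_labels=[b.omics_label for b in blocks],
    )
    model.importance_table = importance(model)
    return model


def predict_singleview(model: SingleViewModel, blocks: list[OmicsBlock]) -> np.ndarray:
    cat, _ = _concat_standardized(blocks, model.standardizers)
    A = transform_sspa(model.transformer, cat)
    return model.predictor.predict_score(A.scores)


def importance(model: SingleViewModel) -> pd.DataFrame:
    """Ranked pathway table; the metric depends on the predictor kind
    (pls -> VIP, random_forest -> impurity importance, logistic -> |beta|).
    Ties are broken by pathway id for determinism."""
    fi = getattr(model.predictor, "feature_importance", None)
    if not callable(fi):
        raise ValueError(
            "predictor exposes no feature_importance; use permutation p-values "
            "(inference.permutation_pvalues) instead"
        )
    imp = fi()
    df = pd.DataFrame(
        {
            "pathway_id": imp.index,
            "name": [model.pathway_names.get(p, "") for p in imp.index],
            "importance": imp.to_numpy(),
        }
    )
    df = df.sort_values(
        ["importance", "pathway_id"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def rfe_select(
    scores: PathwayScoreMatrix,
    y: OutcomeVector,
    predictor: PredictorSpec | None = None,
    cv_folds: int = 5,
    seed: int | None = None,
    drop_frac: float = 0.1,
) -> tuple[list[str], pd.DataFrame]:
    """Recursive feature elimination with cross-validated scoring.

    Iteratively drops the lowest-importance `drop_frac` of remaining
    pathways (at least one per step), recording the stratified
    `cv_folds`-fold AUROC at each feature count. Returns the subset at
    the count maximizing CV score (smallest count on ties) and the curve.
    """
    predictor = predictor or PredictorSpec("pls")
    X = scores.scores
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features for elimination")
    yv = y.encoded()
    if len(yv) < cv_folds:
        raise ValueError("fewer samples than folds")

    remaining = list(X.columns)
    curve_rows = []
    subsets: dict[int, list[str]] = {}
    rng = np.random.default_rng(seed)
    while True:
        Xr = X[remaining]
        skf = StratifiedKFold(
            n_splits=cv_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        aucs = []
        for tr, te in skf.split(Xr, yv):
            clf = make_predictor(predictor)
            clf.fit(Xr.iloc[tr], yv[tr])
            aucs.append(roc_auc_score(yv[te], clf.predict_score(Xr.iloc[te])))
        curve_rows.append({"n_features": len(remaining), "cv_auc": float(np.mean(aucs))})
        subsets[len(remaining)] = list(remaining)
        if len(remaining) == 1:
            break
        clf = make_predictor(predictor)
        clf.fit(Xr, yv)
        imp = clf.feature_importance().sort_values(
            ascending=True, kind="stable"
        )
        n_drop = max(1, int(np.floor(len(remaining) * drop_frac)))
        drop = set(imp.index[:n_drop])
        remaining = [f for f in remaining if f not in drop]
    curve = pd.DataFrame(curve_rows)
    best = curve["cv_auc"].max()
    at_max = curve[curve["cv_auc"] >= best - 1e-12]["n_features"]
    n_sel = int(at_max.min())  # parsimony on ties
    return subsets[n_sel], curve
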