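"""Rank knockout targets: binary feature matrix, random-forest importance
(IncNodePurity), knockout frequencies, co-occurrence and PCA summaries.

The feature matrix has one row per mutant design and one binary column per
candidate reaction (1 = knocked).  Regression forests predict succinate
flux, growth, or MOMA distance from the knockout pattern; per-feature
importance is the total decrease in node impurity (squared error) summed
over all splits on that feature across all trees — the IncNodePurity
measure of the R randomForest package — computed here by walking the
fitted trees, unnormalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import train_test_split

from .design_enum import MutantDesign
from .mutant_eval import EvaluationRecord

RESPONSES = ("product", "growth", "distance")

__all__ = [
    "KnockoutFeatureMatrix",
    "ImportanceReport",
    "FrequencyReport",
    "PCAResult",
    "build_feature_matrix",
    "fit_rf",
    "predict_phenotype",
    "knockout_frequency",
    "cooccurrence_correlation",
    "frequency_pca",
]


@dataclass
class KnockoutFeatureMatrix:
    features: np.ndarray                # m x n binary
    candidates: list[str]
    responses: dict[str, np.ndarray]
    design_labels: list[str] = field(default_factory=list)
    source_models: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=int)
        if not np.isin(self.features, (0, 1)).all():
            raise ValueError("feature matrix entries must be binary")
        m = self.features.shape[0]
        for name, y in self.responses.items():
            if len(y) != m:
                raise ValueError(f"response {name!r} length {len(y)} != {m} rows")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.candidates)
        for name, y in self.responses.items():
            df[f"response_{name}"] = y
        if self.source_models:
            df["source_model"] = self.source_models
        return df


@dataclass
class ImportanceReport:
    response: str
    importances: dict[str, float]       # IncNodePurity per feature used
    rank: list[str]                     # features, most important first
    train_mse: float
    test_mse: float
    split_fraction: float
    seed: int
    n_features_used: int
    dropped_features: list[str]
    model: RandomForestRegressor = field(repr=False, default=None)
    feature_order: list[str] = field(default_factory=list, repr=False)


def build_feature_matrix(
    designs: list[MutantDesign],
    candidates: list[str],
    eval_records: list[EvaluationRecord],
) -> KnockoutFeatureMatrix:
    """Binary designs-by-candidates matrix with aligned FBA/MOMA responses."""
    by_design = {id(r.design): r for r in eval_records}
    rec_by_ko = {r.design.knockouts: r for r in eval_records}
    rows, prod, growth, dist, labels, sources = [], [], [], [], [], []
    cand_set = set(candidates)
    for d in designs:
        outside = d.knockouts - cand_set
        if outside:
            raise ValueError(
                f"design {sorted(d.knockouts)} knocks reactions outside the "
                f"candidate set: {sorted(outside)}"
            )
        rec = by_design.get(id(d)) or rec_by_ko.get(d.knockouts)
        if rec is None:
            raise ValueError(f"no evaluation record for design {sorted(d.knockouts)}")
        rows.append([1 if c in d.knockouts else 0 for c in candidates])
        prod.append(rec.fba_product)
        growth.append(rec.fba_growth)
        dist.append(rec.moma_distance)
        labels.append(";".join(sorted(d.knockouts)))
        sources.append(d.source_model)
    return KnockoutFeatureMatrix(
        np.array(rows, dtype=int),
        list(candidates),
        {
            "product": np.array(prod, float),
            "growth": np.array(growth, float),
            "distance": np.array(dist, float),
        },
        labels,
        sources,
    )


def _inc_node_purity(model: RandomForestRegressor, n_features: int) -> np.ndarray:
    """Total impurity (squared-error) decrease per feature, summed over all
    splits of all trees; the forest-level analogue of IncNodePurity."""
    total = np.zeros(n_features)
    for est in model.estimators_:
        t = est.tree_
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:
                continue
            dec = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[left] * t.impurity[left]
                - t.weighted_n_node_samples[right] * t.impurity[right]
            )
            total[t.feature[node]] += dec
    return total


def fit_rf(
    matrix: KnockoutFeatureMatrix,
    response: str = "product",
    split_fraction: float = 0.7,
    seed: int = 42,
    n_trees: int = 500,
    max_features: float = 1.0,
) -> ImportanceReport:
    """Train/test a regression forest on the knockout matrix.

    Zero-variance columns (never- or always-knocked reactions) are dropped
    before training; the train/test split is stratified by source model
    when more than one model contributed designs.  Fully reproducible for
    a fixed seed.

    ``max_features`` defaults to all features per split: knockout matrices
    have few, binary, sparse-signal columns, and per-split feature
    subsampling both inflates held-out error and makes tree structure
    depend on column order.  Set it to 1/3 for the classic regression-
    forest mtry = p/3 behaviour.
    """
    if response not in matrix.responses:
        raise ValueError(f"unknown response {response!r}; have {list(matrix.responses)}")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie in (0, 1)")
    X = matrix.features
    if X.shape[0] < 10:
        raise ValueError("need at least 10 designs to fit a forest")
    y = matrix.responses[response]

    variances = X.var(axis=0)
    used = np.nonzero(variances > 0)[0]
    dropped = [matrix.candidates[j] for j in np.nonzero(variances == 0)[0]]
    feature_names = [matrix.candidates[j] for j in used]
    Xu = X[:, used]

    strat = None
    if matrix.source_models and len(set(matrix.source_models)) > 1:
        counts = pd.Series(matrix.source_models).value_counts()
        if counts.min() >= 2:
            strat = matrix.source_models
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xu, y, train_size=split_fraction, random_state=seed, stratify=strat
    )

    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        bootstrap=True,
    )
    model.fit(X_tr, y_tr)
    train_mse = float(mean_squared_error(y_tr, model.predict(X_tr)))
    test_mse = float(mean_squared_error(y_te, model.predict(X_te)))

    if np.ptp(y) == 0:
        warnings.warn("constant response; importances are all zero", stacklevel=2)
        purity = np.zeros(len(used))
    else:
        purity = _inc_node_purity(model, len(used))
    importances = dict(zip(feature_names, purity.astype(float)))
    rank = sorted(feature_names, key=lambda f: (-importances[f], f))
    return ImportanceReport(
        response, importances, rank, train_mse, test_mse,
        split_fraction, seed, len(used), dropped, model, feature_names,
    )


def predict_phenotype(report: ImportanceReport, design_vector: np.ndarray) -> float:
    """Ensemble-mean prediction for one knockout pattern (over the features
    the report was trained on)."""
    x = np.asarray(design_vector, dtype=float).ravel()
    if x.size != report.n_features_used:
        raise ValueError(
            f"design vector length {x.size} != {report.n_features_used} features"
        )
    return float(report.model.predict(x.reshape(1, -1))[0])


@dataclass
class FrequencyReport:
    counts: pd.Series                   # reaction -> total knockout count
    fractions: pd.Series                # reaction -> fraction of designs
    per_model: pd.DataFrame             # reaction x source_model counts
    per_k: pd.DataFrame                 # reaction x k counts
    above_average: pd.Series            # reaction -> bool (count > mean)


def knockout_frequency(designs: list[MutantDesign]) -> FrequencyReport:
    """Knockout counts per reaction, overall, per source model and per k."""
    if not designs:
        raise ValueError("no designs")
    rows = []
    for d in designs:
        for r in d.knockouts:
            rows.append((r, d.source_model, d.k))
    df = pd.DataFrame(rows, columns=["reaction", "model", "k"])
    counts = df["reaction"].value_counts().sort_index()
    fractions = counts / len(designs)
    per_model = df.pivot_table(
        index="reaction", columns="model", aggfunc="size", fill_value=0
    )
    per_k = df.pivot_table(index="reaction", columns="k", aggfunc="size", fill_value=0)
    above = counts > counts.mean()
    return FrequencyReport(counts, fractions, per_model, per_k, above)


def cooccurrence_correlation(per_k: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between reactions' frequency-by-k vectors.

    Needs at least two k levels; a reaction with zero variance across k has
    undefined correlations (NaN off-diagonal, 1 on the diagonal).
    """
    if per_k.shape[1] < 2:
        raise ValueError("need frequencies at >= 2 knockout sizes")
    corr = per_k.T.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class PCAResult:
    scores: np.ndarray                  # rows x 2
    loadings: np.ndarray                # columns x 2
    explained_variance: np.ndarray      # fractions, length 2
    row_labels: list[str]
    column_labels: list[str]


def frequency_pca(freq: pd.DataFrame) -> PCAResult:
    """First two principal components of the (centered) frequency matrix.

    Deterministic sign convention: the largest-magnitude loading of each
    component is made positive.
    """
    if freq.shape[0] < 2 or freq.shape[1] < 2:
        raise ValueError("frequency matrix must be at least 2 x 2")
    X = freq.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("frequency matrix has rank 0 after centering")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    k = min(2, len(s))
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    for comp in range(k):
        lead = np.argmax(np.abs(loadings[:, comp]))
        if loadings[lead, comp] < 0:
            loadings[:, comp] = -loadings[:, comp]
            scores[:, comp] = -scores[:, comp]
    if k == 1:  # degenerate rank-1 input: pad a zero second component
        scores = np.hstack([scores, np.zeros_like(scores)])
        loadings = np.hstack([loadings, np.zeros_like(loadings)])
        explained = np.array([explained[0], 0.0])
    return PCAResult(
        scores, loadings, explained[:2],
        [str(i) for i in freq.index],
        [str(c) for c in freq.columns],
    )
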