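"""Supervised fine-tuning of a two-cluster split on a molecular continuum.

Weakly separated neighboring clusters (a venous plexus population and the
arterial plexus emerging from it) are re-resolved by combining unsupervised
hierarchical clustering with random-forest vote-probability filtering:

1. differential expression between the two provisional clusters defines the
   working gene space;
2. average-linkage hierarchical clustering on Pearson-correlation distance,
   cut at the root, gives the initial two-way split;
3. per-fold random-forest importances over stratified folds select feature
   genes;
4. cells whose out-of-bag vote probability for their current class exceeds
   ``train_vote_min`` train a classifier that re-labels the remaining cells;
5. repeated stratified cross-validation measures each cell's held-out vote
   probability for its label, and cells below ``keep_vote_min`` are
   discarded as ambiguous.

The vote probability of a cell is the fraction of ensemble trees voting its
current class label, measured out-of-bag in step 4 and held-out in step 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .dataset import ExpressionDataset, ValidationError
from .diffexpr import wilcoxon_deg

__all__ = [
    "RefinementConfig",
    "RefinementResult",
    "initial_split",
    "rf_feature_select",
    "refine_labels",
    "cv_filter",
    "fine_tune_clusters",
]

DISCARDED = "discarded"


@dataclass
class RefinementConfig:
    """Knobs of the refinement procedure.

    ``train_vote_min`` (default 0.6) gates the confident training set in the
    reclassification step; ``keep_vote_min`` (default 0.55) is the ambiguity
    cutoff applied to the mean cross-validated vote probability over
    ``n_runs`` repetitions of ``n_folds``-fold CV.
    """

    n_folds: int = 10
    n_runs: int = 100
    train_vote_min: float = 0.6
    keep_vote_min: float = 0.55
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 <= self.keep_vote_min <= self.train_vote_min < 1.0):
            raise ValidationError(
                "require 0.5 <= keep_vote_min <= train_vote_min < 1"
            )
        if self.n_folds < 2 or self.n_runs < 1 or self.n_trees < 1:
            raise ValidationError("n_folds >= 2, n_runs >= 1, n_trees >= 1")


@dataclass
class RefinementResult:
    """Final labels (including ``"discarded"``), vote diagnostics and features."""

    labels: pd.Series
    mean_vote: pd.Series
    features: list[str]
    aborted: bool = False
    vote_runs: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def discarded(self) -> list[str]:
        return list(self.labels.index[self.labels == DISCARDED])


def _norm_matrix(dataset: ExpressionDataset, cells: list[str], genes: list[str]) -> np.ndarray:
    """cells × genes normalized expression."""
    norm = dataset.require_norm()
    return norm[np.ix_(dataset.gene_index(genes), dataset.cell_index(cells))].T


def initial_split(
    dataset: ExpressionDataset, cells: list[str], genes: list[str]
) -> pd.Series:
    """Two-way split by average-linkage clustering on correlation distance.

    Distance between cells is ``1 - Pearson r`` of their normalized profiles
    over ``genes``; the dendrogram is cut at its root into exactly two
    clusters labeled ``"A"`` and ``"B"``.  Cells with a constant profile
    (undefined correlation) are assigned the label of their nearest
    non-degenerate neighbor by Euclidean distance, with a warning.
    """
    if len(cells) < 3:
        raise ValidationError("initial_split needs at least 3 cells")
    if len(genes) < 2:
        raise ValidationError("initial_split needs at least 2 genes")
    x = _norm_matrix(dataset, cells, genes)
    sd = x.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    ok = np.flatnonzero(sd > 0)
    if ok.size < 3:
        raise ValidationError("fewer than 3 cells with non-constant profiles")
    corr = np.corrcoef(x[ok])
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(z, t=2, criterion="maxclust")
    labels = np.empty(len(cells), dtype=object)
    labels[ok] = np.where(assign == 1, "A", "B")
    if degenerate.size:
        warnings.warn(
            f"{degenerate.size} cell(s) with constant profiles assigned by "
            "nearest neighbor",
            stacklevel=2,
        )
        for i in degenerate:
            d = np.linalg.norm(x[ok] - x[i], axis=1)
            labels[i] = labels[ok[np.argmin(d)]]
    return pd.Series(labels, index=pd.Index(cells, name="cell"), name="cluster")


def _check_two_classes(labels: pd.Series) -> list[str]:
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValidationError(f"expected exactly 2 classes, got {classes}")
    return classes


def rf_feature_select(
    dataset: ExpressionDataset,
    labels: pd.Series,
    genes: list[str],
    config: RefinementConfig | None = None,
) -> pd.DataFrame:
    """Rank genes by mean random-forest importance across stratified folds.

    Per fold, a forest is fit on the training portion and its impurity-based
    importances accumulated; genes are returned ranked by mean importance
    with ``selected`` marking those above the mean importance.
    """
    config = config or RefinementConfig()
    classes = _check_two_classes(labels)
    cells = list(labels.index)
    x = _norm_matrix(dataset, cells, genes)
    y = labels.to_numpy()
    min_class = min((y == c).sum() for c in classes)
    n_folds = config.n_folds
    if min_class < n_folds:
        n_folds = max(2, min_class)
        warnings.warn(
            f"smallest class has {min_class} cells; reducing folds to {n_folds}",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    importances = np.zeros((n_folds, len(genes)))
    for i, (train, _) in enumerate(skf.split(x, y)):
        forest = RandomForestClassifier(
            n_estimators=config.n_trees, random_state=config.seed + i, n_jobs=1
        )
        forest.fit(x[train], y[train])
        importances[i] = forest.feature_importances_
    mean_imp = importances.mean(axis=0)
    table = pd.DataFrame({"gene": genes, "importance": mean_imp})
    table["selected"] = table["importance"] > mean_imp.mean()
    return table.sort_values("importance", ascending=False, kind="stable").reset_index(
        drop=True
    )


def refine_labels(
    dataset: ExpressionDataset,
    labels: pd.Series,
    features: list[str],
    config: RefinementConfig | None = None,
) -> pd.Series:
    """Re-classify cells using a forest trained on vote-confident cells.

    A forest fit on all cells yields out-of-bag vote probabilities; cells
    voting their own class above ``train_vote_min`` form the training set of
    a second forest that predicts the remaining cells.  If either class has
    no confident cell the refinement aborts and the input labels are
    returned unchanged, with a warning.
    """
    config = config or RefinementConfig()
    if not features:
        raise ValidationError("features must be non-empty")
    classes = _check_two_classes(labels)
    cells = list(labels.index)
    x = _norm_matrix(dataset, cells, features)
    y = labels.to_numpy()
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        forest.fit(x, y)
    class_col = {c: i for i, c in enumerate(forest.classes_)}
    oob = forest.oob_decision_function_
    own_vote = np.array([oob[i, class_col[y[i]]] for i in range(len(y))])
    own_vote = np.nan_to_num(own_vote, nan=0.0)
    confident = own_vote > config.train_vote_min
    for c in classes:
        if not np.any(confident & (y == c)):
            warnings.warn(
                f"no confident training cells for class {c!r}; refinement aborted",
                stacklevel=2,
            )
            return labels.copy()
    clf = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.seed + 1, n_jobs=1
    )
    clf.fit(x[confident], y[confident])
    out = y.copy()
    rest = ~confident
    if np.any(rest):
        out[rest] = clf.predict(x[rest])
    return pd.Series(out, index=labels.index, name="cluster")


def cv_filter(
    dataset: ExpressionDataset,
    labels: pd.Series,
    features: list[str],
    config: RefinementConfig | None = None,
    keep_diagnostics: bool = False,
) -> RefinementResult:
    """Discard ambiguous cells by repeated cross-validated vote probability.

    Over ``n_runs`` repetitions of stratified ``n_folds``-fold CV, each
    cell's held-out vote probability for its current label is recorded;
    cells whose mean falls below ``keep_vote_min`` are discarded, the rest
    keep their labels.
    """
    config = config or RefinementConfig()
    if not features:
        raise ValidationError("features must be non-empty")
    _check_two_classes(labels)
    cells = list(labels.index)
    x = _norm_matrix(dataset, cells, features)
    y = labels.to_numpy()
    min_class = min(pd.Series(y).value_counts())
    n_folds = min(config.n_folds, max(2, min_class))
    votes = np.zeros((config.n_runs, len(y)))
    for run in range(config.n_runs):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=config.seed + 1000 + run
        )
        for fold, (train, test) in enumerate(skf.split(x, y)):
            forest = RandomForestClassifier(
                n_estimators=config.n_trees,
                random_state=config.seed + 7919 * run + fold,
                n_jobs=1,
            )
            forest.fit(x[train], y[train])
            proba = forest.predict_proba(x[test])
            col = {c: i for i, c in enumerate(forest.classes_)}
            for j, idx in enumerate(test):
                votes[run, idx] = proba[j, col[y[idx]]] if y[idx] in col else 0.0
    mean_vote = votes.mean(axis=0)
    final = np.where(mean_vote < config.keep_vote_min, DISCARDED, y)
    index = pd.Index(cells, name="cell")
    return RefinementResult(
        labels=pd.Series(final, index=index, name="cluster"),
        mean_vote=pd.Series(mean_vote, index=index, name="mean_vote"),
        features=list(features),
        vote_runs=pd.DataFrame(votes.T, index=index) if keep_diagnostics else None,
    )


def fine_tune_clusters(
    dataset: ExpressionDataset,
    labels: pd.Series,
    config: RefinementConfig | None = None,
    deg_fc_min: float = 1.5,
    keep_diagnostics: bool = False,
) -> RefinementResult:
    """Full fine-tuning of a provisional two-cluster split.

    Orchestrates DEG selection between the provisional clusters, the
    hierarchical re-split on DEGs, random-forest feature selection,
    vote-guided re-labeling and the cross-validated ambiguity filter, all
    seeded from ``config.seed``.
    """
    config = config or RefinementConfig()
    classes = _check_two_classes(labels)
    cells = list(labels.index)
    g1 = list(labels.index[labels == classes[0]])
    g2 = list(labels.index[labels == classes[1]])
    degs = wilcoxon_deg(dataset, g1, g2, fc_min=deg_fc_min)
    genes = list(degs["gene"])
    if len(genes) < 2:
        # no differential signal between the provisional clusters: refining
        # on arbitrary genes would merely re-learn a noise partition
        warnings.warn(
            "fewer than 2 DEGs between the provisional clusters; "
            "refinement aborted",
            stacklevel=2,
        )
        return RefinementResult(
            labels=labels.copy(),
            mean_vote=pd.Series(np.nan, index=labels.index, name="mean_vote"),
            features=[],
            aborted=True,
        )
    split = initial_split(dataset, cells, genes)
    ranked = rf_feature_select(dataset, split, genes, config)
    features = list(ranked.loc[ranked["selected"], "gene"])
    if not features:
        features = list(ranked["gene"].head(10))
    adjusted = refine_labels(dataset, split, features, config)
    if adjusted.equals(split) and len(set(adjusted)) < 2:
        return RefinementResult(adjusted, pd.Series(np.nan, index=adjusted.index),
                                features, aborted=True)
    result = cv_filter(dataset, adjusted, features, config, keep_diagnostics)
    return result
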