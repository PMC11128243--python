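"""Random-forest co-occurrence between eukaryote clades and virus families.

Each eukaryote clade becomes a binary target ("rare" vs "abundant" relative
to the clade's mean count over all samples) predicted from per-sample virus
family abundances (family-level sums of the 25%-cutoff normalized coverage
table). The number of features tried per split (mtry) is tuned with a
tuneRF-style doubling/halving search (step factor 1.5, required relative
OOB improvement 0.01, 1000 trees). Clades are reported only if they reach
1% relative abundance in at least one lake and their final forest's
out-of-bag error is strictly below 25%. Edges of the association network
are the top mean-decrease-Gini family per clade plus up to three more
families whose importance is within 80% of the top one.

Co-occurrence is not infection: an edge is a statistical statement about
shared distribution patterns, nothing more.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .coverage import AbundanceTable
from .io import SampleMetadata, ValidationError


@dataclass
class CladeLabeling:
    """Per-(sample, clade) rare/abundant labels and the mean thresholds."""

    labels: pd.DataFrame  # samples x clades of {"rare", "abundant"}
    thresholds: pd.Series  # clade -> mean count


def binarize_clades(euk_counts: pd.DataFrame) -> CladeLabeling:
    """Categorize counts as abundant (> clade mean) or rare (<= mean).

    A count exactly at the mean is "rare": the rule is stated as strictly
    above/below, so the boundary needs a fixed convention.
    """
    if euk_counts.shape[0] < 2:
        raise ValidationError("need at least two samples to binarize")
    means = euk_counts.mean(axis=0)
    zero = means[euk_counts.sum(axis=0) == 0]
    if len(zero):
        warnings.warn(
            f"clades with zero total counts are all-rare: {list(zero.index)}",
            stacklevel=2,
        )
    labels = euk_counts.gt(means, axis=1).replace({True: "abundant", False: "rare"})
    return CladeLabeling(labels=labels, thresholds=means)


@dataclass
class RfModelReport:
    clade: str
    oob_error: float
    mtry_selected: int
    n_trees: int
    importances: pd.Series  # family -> mean decrease Gini
    seed: int | None
    degenerate: bool = False


@dataclass
class Edge:
    clade: str
    family: str
    weight: float
    is_top: bool


class TunedRandomForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest with a tuneRF-style search for ``max_features`` (mtry).

    Starting from floor(sqrt(p)), candidate mtry values are generated by
    multiplying / dividing by ``step_factor``; a step in either direction is
    taken only while the out-of-bag error improves by more than ``improve``
    (relative). The final forest is refit at the best mtry with ``n_trees``
    trees, and its OOB error and Gini (mean decrease impurity) importances
    are what downstream filters and edge selection consume.

    Parameters follow the conventions of the R randomForest/tuneRF pair:
    ``n_tree_try`` trees during the search, ``step_factor`` 1.5,
    ``improve`` 0.01.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        n_tree_try: int = 1000,
        step_factor: float = 1.5,
        improve: float = 0.01,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.n_tree_try = n_tree_try
        self.step_factor = step_factor
        self.improve = improve
        self.random_state = random_state

    def _oob_error(self, X, y, mtry: int, n_trees: int) -> tuple[float, RandomForestClassifier]:
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=mtry,
            criterion="gini",
            oob_score=True,
            bootstrap=True,
            random_state=self.random_state,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            forest.fit(X, y)
        return 1.0 - float(forest.oob_score_), forest

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValidationError("single-class target: degenerate model")
        p = X.shape[1]
        m0 = max(1, int(math.floor(math.sqrt(p))))
        errors: dict[int, float] = {}
        forests: dict[int, RandomForestClassifier] = {}
        errors[m0], forests[m0] = self._oob_error(X, y, m0, self.n_tree_try)
        for direction in (-1, 1):
            prev_err = errors[m0]
            m = m0
            while True:
                if direction < 0:
                    m_new = max(1, int(math.floor(m / self.step_factor)))
                else:
                    m_new = min(p, int(math.ceil(m * self.step_factor)))
                if m_new == m or m_new in errors:
                    break
                err, forests[m_new] = self._oob_error(X, y, m_new, self.n_tree_try)
                errors[m_new] = err
                rel_improve = (prev_err - err) / prev_err if prev_err > 0 else 0.0
                if rel_improve <= self.improve:
                    break
                prev_err = err
                m = m_new
        best = min(errors, key=lambda m: (errors[m], m))
        if self.n_trees == self.n_tree_try:
            final_err, forest = errors[best], forests[best]
        else:
            final_err, forest = self._oob_error(X, y, best, self.n_trees)
        self.mtry_ = best
        self.tuning_errors_ = errors
        self.oob_error_ = final_err
        self.estimator_ = forest
        self.classes_ = forest.classes_
        self.feature_importances_ = forest.feature_importances_
        self.n_features_in_ = p
        return self

    def predict(self, X):
        return self.estimator_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.estimator_.predict_proba(np.asarray(X, dtype=float))


def family_features(table: AbundanceTable, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Per-sample virus-family abundances: column sums of normalized
    coverage within each family (25%-cutoff table)."""
    fam = taxonomy["family"].reindex(table.values.columns).fillna("undetermined")
    return table.values.T.groupby(fam.to_numpy()).sum().T


def tune_and_fit(
    features: pd.DataFrame,
    target: pd.Series,
    clade: str,
    n_tree_try: int = 1000,
    step_factor: float = 1.5,
    improve: float = 0.01,
    n_trees: int = 1000,
    seed: int | None = None,
) -> RfModelReport:
    """Tune mtry and fit the final forest for one clade's rare/abundant
    target; a single-class target yields a degenerate report."""
    y = target.reindex(features.index)
    if y.nunique() < 2:
        return RfModelReport(
            clade=clade,
            oob_error=float("nan"),
            mtry_selected=0,
            n_trees=0,
            importances=pd.Series(0.0, index=features.columns),
            seed=seed,
            degenerate=True,
        )
    est = TunedRandomForestClassifier(
        n_trees=n_trees,
        n_tree_try=n_tree_try,
        step_factor=step_factor,
        improve=improve,
        random_state=seed,
    )
    est.fit(features.to_numpy(dtype=float), y.to_numpy())
    return RfModelReport(
        clade=clade,
        oob_error=est.oob_error_,
        mtry_selected=est.mtry_,
        n_trees=n_trees,
        importances=pd.Series(est.feature_importances_, index=features.columns),
        seed=seed,
    )


def filter_clades(
    euk_counts: pd.DataFrame,
    metadata: SampleMetadata,
    reports: dict[str, RfModelReport],
    min_rel_abund: float = 0.01,
    max_error: float = 0.25,
) -> set[str]:
    """Clades worth reporting: >=1% relative abundance in at least one lake
    and final-forest OOB error strictly below 25%."""
    lake = metadata.lake_of().reindex(euk_counts.index)
    by_lake = euk_counts.groupby(lake.to_numpy()).sum()
    rel = by_lake.div(by_lake.sum(axis=1).where(lambda s: s > 0), axis=0)
    abundant_somewhere = (rel >= min_rel_abund).any(axis=0)
    keep = set()
    for clade, report in reports.items():
        if report.degenerate:
            continue
        if not bool(abundant_somewhere.get(clade, False)):
            continue
        if report.oob_error < max_error:
            keep.add(clade)
    return keep


def select_edges(
    report: RfModelReport, window: float = 0.8, max_extra: int = 3
) -> list[Edge]:
    """Top-Gini family plus up to ``max_extra`` families within ``window``
    of the top importance; ties break lexicographically by family name."""
    imp = report.importances
    if len(imp) == 0:
        raise ValidationError("report has no feature importances")
    if (imp <= 0).all():
        warnings.warn(f"all-zero importances for clade {report.clade}", stacklevel=2)
        return []
    ranked = imp.sort_values(ascending=False, kind="stable")
    ranked = ranked.loc[
        sorted(ranked.index, key=lambda f: (-ranked[f], f))
    ]
    top_family = ranked.index[0]
    top_weight = float(ranked.iloc[0])
    edges = [Edge(report.clade, top_family, top_weight, True)]
    for fam in ranked.index[1:]:
        if len(edges) - 1 >= max_extra:
            break
        w = float(ranked[fam])
        if w >= window * top_weight:
            edges.append(Edge(report.clade, fam, w, False))
        else:
            break
    return edges


@dataclass
class AssociationNetwork:
    """Bipartite clade-family network with Gini-importance edge weights."""

    edges: list[Edge]
    reports: dict[str, RfModelReport] = field(default_factory=dict)
    eligible_clades: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "clade": e.clade,
                    "family": e.family,
                    "gini": e.weight,
                    "is_top": e.is_top,
                }
                for e in self.edges
            ],
            columns=["clade", "family", "gini", "is_top"],
        )

    def to_sif(self) -> str:
        return "\n".join(f"{e.clade}\tco_occurs_with\t{e.family}" for e in self.edges)

    def top_edge(self, clade: str) -> Edge | None:
        for e in self.edges:
            if e.clade == clade and e.is_top:
                return e
        return None


def build_network(
    euk_counts: pd.DataFrame,
    abundance: AbundanceTable,
    taxonomy: pd.DataFrame,
    metadata: SampleMetadata,
    seed: int = 0,
    n_tree_try: int = 1000,
    step_factor: float = 1.5,
    improve: float = 0.01,
    n_trees: int = 1000,
    window: float = 0.8,
    max_extra: int = 3,
    min_rel_abund: float = 0.01,
    max_error: float = 0.25,
) -> AssociationNetwork:
    """Run the full association procedure over every detected clade."""
    features = family_features(abundance, taxonomy)
    features = features.reindex(sorted(set(features.index) & set(euk_counts.index)))
    euk = euk_counts.reindex(features.index)
    labeling = binarize_clades(euk)
    reports: dict[str, RfModelReport] = {}
    for i, clade in enumerate(sorted(euk.columns)):
        clade_seed = (seed + 7919 * (i + 1)) % (2**31)
        reports[clade] = tune_and_fit(
            features,
            labeling.labels[clade],
            clade,
            n_tree_try=n_tree_try,
            step_factor=step_factor,
            improve=improve,
            n_trees=n_trees,
            seed=clade_seed,
        )
    eligible = filter_clades(
        euk, metadata, reports, min_rel_abund=min_rel_abund, max_error=max_error
    )
    edges: list[Edge] = []
    for clade in sorted(eligible):
        edges.extend(select_edges(reports[clade], window=window, max_extra=max_extra))
    return AssociationNetwork(edges=edges, reports=reports, eligible_clades=eligible)
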