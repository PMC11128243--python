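"""Distance-based community structure of GVMAG assemblages.

The quantitative route is: Hellinger-transform the breadth-filtered
abundance matrix, compute Bray-Curtis dissimilarities, ordinate with
non-metric multidimensional scaling, and test the region effect with a
one-way PERMANOVA (999 label permutations by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import MDS

from .coverage import AbundanceTable
from .io import SampleMetadata, ValidationError


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with labelled samples."""

    data: pd.DataFrame
    metric: str = ""

    def __post_init__(self) -> None:
        a = self.data.to_numpy(dtype=float)
        if a.shape[0] != a.shape[1] or not (self.data.index == self.data.columns).all():
            raise ValidationError("distance matrix must be square with matching labels")
        if not np.allclose(a, a.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(a), 0):
            raise ValidationError("distance matrix must have a zero diagonal")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def condensed(self) -> np.ndarray:
        return squareform(self.data.to_numpy(dtype=float), checks=False)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    n_starts: int
    converged: bool
    seed: int | None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# NMDS stress-1 = {self.stress:.6g}, n_starts = {self.n_starts}\n")
            self.coordinates.to_csv(fh, sep="\t", index_label="sample_id")


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "pseudo_F": [self.pseudo_F],
                "R2": [self.R2],
                "p_value": [self.p_value],
                "n_permutations": [self.n_permutations],
            }
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transforms and distances
# ---------------------------------------------------------------------------


def hellinger(table: pd.DataFrame | AbundanceTable) -> pd.DataFrame:
    """Hellinger transform: per-sample square root of relative abundances.

    y_ij = sqrt(x_ij / sum_j x_ij). All-zero rows stay all-zero (warning).
    """
    df = table.values if isinstance(table, AbundanceTable) else table
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("Hellinger transform requires non-negative entries")
    totals = x.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        warnings.warn("all-zero sample rows map to all-zero rows", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.sqrt(np.where(totals > 0, x / np.where(totals > 0, totals, 1.0), 0.0))
    return pd.DataFrame(y, index=df.index, columns=df.columns)


class HellingerTransformer(TransformerMixin, BaseEstimator):
    """Stateless scikit-learn transformer wrapping :func:`hellinger`."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return hellinger(X).to_numpy()
        return hellinger(pd.DataFrame(np.asarray(X, dtype=float))).to_numpy()


def bray_curtis(table: pd.DataFrame | AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample rows.

    d_jk = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik); a pair of all-zero
    rows is assigned distance 0 with a warning.
    """
    df = table.values if isinstance(table, AbundanceTable) else table
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative entries")
    if x.shape[0] < 2:
        raise ValidationError("Bray-Curtis needs at least two samples")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"), checks=False)
    if np.isnan(d).any():
        warnings.warn("all-zero row pairs assigned distance 0", stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        pd.DataFrame(d, index=df.index, columns=df.index), metric="bray_curtis"
    )


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling on a precomputed dissimilarity.

    Minimizes Kruskal stress-1 by monotone regression over ``n_starts``
    random initializations and keeps the best solution; deterministic for a
    fixed ``random_state``.

    Parameters
    ----------
    n_components : target dimensionality (2 matches the usual ordination
        figures).
    n_starts : random restarts of the SMACOF iteration.
    max_iter, eps : per-start iteration cap and relative stress-improvement
        convergence threshold.
    """

    def __init__(self, n_components=2, n_starts=20, max_iter=300, eps=1e-6,
                 random_state=None):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.eps = eps
        self.random_state = random_state

    def fit(self, d: DistanceMatrix | pd.DataFrame | np.ndarray, y=None):
        self.fit_transform(d)
        return self

    def fit_transform(self, d: DistanceMatrix | pd.DataFrame | np.ndarray, y=None):
        if isinstance(d, DistanceMatrix):
            ids, mat = d.ids, d.data.to_numpy(dtype=float)
        elif isinstance(d, pd.DataFrame):
            ids, mat = list(d.index), d.to_numpy(dtype=float)
        else:
            mat = np.asarray(d, dtype=float)
            ids = [f"s{i}" for i in range(mat.shape[0])]
        if self.n_components >= mat.shape[0]:
            raise ValidationError("n_components must be smaller than the sample count")
        mds = MDS(
            n_components=self.n_components,
            metric_mds=False,
            metric="precomputed",
            n_init=self.n_starts,
            init="random",
            max_iter=self.max_iter,
            eps=self.eps,
            normalized_stress=True,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = mds.fit_transform(mat)
        self.embedding_ = coords
        self.stress_ = float(mds.stress_)
        self.n_iter_ = int(mds.n_iter_)
        self.converged_ = self.n_iter_ < self.max_iter
        self.ids_ = ids
        return coords

    def result(self) -> OrdinationResult:
        cols = [f"NMDS{i + 1}" for i in range(self.n_components)]
        return OrdinationResult(
            coordinates=pd.DataFrame(self.embedding_, index=self.ids_, columns=cols),
            stress=self.stress_,
            n_starts=self.n_starts,
            converged=self.converged_,
            seed=self.random_state,
        )


def nmds(
    d: DistanceMatrix, k: int = 2, n_starts: int = 20, seed: int | None = None
) -> OrdinationResult:
    est = NMDS(n_components=k, n_starts=n_starts, random_state=seed)
    est.fit(d)
    return est.result()


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _ss_within(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> float:
    # sum over groups g of (1/n_g) * sum_{j<k in g} d^2_{jk}
    q = np.einsum("ig,ij,jg->g", onehot, d2, onehot)
    return float((q / (2.0 * sizes)).sum())


def permanova(
    d: DistanceMatrix,
    groups: pd.Series | dict,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix (adonis-style).

    Partitions the squared-distance sums into among- and within-group
    components, forms the pseudo-F ratio, and permutes sample labels freely;
    permuted statistics tied with the observed one count toward the p-value.
    With zero within-group dispersion the statistic is +inf by convention.
    """
    labels = pd.Series(groups).reindex(d.ids)
    if labels.isna().any():
        raise ValidationError("every sample needs a group label")
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    n = len(codes)
    if a < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    d2 = d.data.to_numpy(dtype=float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    eye = np.eye(a)

    def f_and_ssw(code_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # code_mat: (m, n) label codes; returns per-row F and SS_within
        onehot = eye[code_mat]  # (m, n, a)
        sizes = onehot.sum(axis=1)  # (m, a)
        q = np.einsum("mig,ij,mjg->mg", onehot, d2, onehot)
        ssw = (q / (2.0 * np.where(sizes > 0, sizes, 1.0))).sum(axis=1)
        ssa = ss_total - ssw
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssa / (a - 1)) / (ssw / (n - a))
        f = np.where(ssw == 0, np.inf, f)
        return f, ssw

    f_obs_arr, ssw_obs_arr = f_and_ssw(codes[None, :])
    f_obs, ssw_obs = float(f_obs_arr[0]), float(ssw_obs_arr[0])
    r2 = float((ss_total - ssw_obs) / ss_total) if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    f_perm, _ = f_and_ssw(codes[perms])
    p = (1 + int((f_perm >= f_obs).sum())) / (1 + n_perm)
    return PermanovaResult(
        pseudo_F=float(f_obs), R2=r2, p_value=float(p), n_permutations=n_perm
    )


# ---------------------------------------------------------------------------
# composition summaries
# ---------------------------------------------------------------------------


def taxon_composition(
    table: AbundanceTable | pd.DataFrame,
    taxonomy: pd.DataFrame,
    metadata: SampleMetadata,
    group_by: str = "region",
    rank: str = "order",
) -> pd.DataFrame:
    """Average per-sample relative abundance by taxonomic rank and group.

    Relative abundances are computed within each sample, then averaged over
    the samples of each lake or region (mean of proportions, robust to
    library-size differences). Missing rank labels appear as their own
    "undetermined" category. Rows sum to 1.
    """
    if group_by not in ("lake", "region"):
        raise ValidationError("group_by must be 'lake' or 'region'")
    if rank not in ("order", "family"):
        raise ValidationError("rank must be 'order' or 'family'")
    df = table.values if isinstance(table, AbundanceTable) else table
    labels = taxonomy[rank].reindex(df.columns).fillna("undetermined")
    by_rank = df.T.groupby(labels.to_numpy()).sum().T
    totals = by_rank.sum(axis=1)
    nonzero = totals > 0
    if (~nonzero).any():
        warnings.warn("samples with zero total abundance dropped", stacklevel=2)
    rel = by_rank.loc[nonzero].div(totals[nonzero], axis=0)
    unit = (metadata.lake_of() if group_by == "lake" else metadata.region_of()).reindex(
        rel.index
    )
    return rel.groupby(unit.to_numpy()).mean()
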