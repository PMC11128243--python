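"""Phylogeny-aware community comparison.

Unweighted UniFrac measures, for a sample pair, the fraction of tree branch
length leading exclusively to GVMAGs seen in only one of the two samples,
relative to all branch length leading to GVMAGs seen in either. It is
presence/absence only: the source table is the 25%-breadth-cutoff abundance
matrix, and coverage magnitudes play no role. Sample relationships are then
summarized with a WPGMA ("mcquitty") dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from skbio import TreeNode
from skbio.diversity import beta_diversity

from .ecology import DistanceMatrix
from .io import ValidationError


def unweighted_unifrac(presence: pd.DataFrame, tree: TreeNode) -> DistanceMatrix:
    """Pairwise unweighted UniFrac over sample rows of a presence matrix.

    ``presence`` is samples x GVMAGs; any nonzero entry counts as present.
    Every GVMAG present in at least one sample must be a tip of ``tree``;
    columns never present anywhere are ignored. The tree root is used
    as-is (a basal branch above the root does not contribute).
    """
    counts = (presence.to_numpy() > 0).astype(int)
    observed = counts.any(axis=0)
    obs_ids = list(presence.columns[observed])
    tips = {t.name for t in tree.tips()}
    missing = [g for g in obs_ids if g not in tips]
    if missing:
        raise ValidationError(
            f"GVMAGs present but missing from tree: {', '.join(missing[:10])}"
        )
    empty = [s for s, row in zip(presence.index, counts) if not row.any()]
    if len(empty) >= 2:
        raise ValidationError(
            f"sample pairs with no GVMAGs have undefined UniFrac: {empty}"
        )
    if len(tree.children) > 2:
        # multifurcating root (e.g. a star tree): insert zero-length nodes;
        # branch lengths, and hence UniFrac, are unchanged
        tree = tree.copy()
        tree.bifurcate()
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
    dm = beta_diversity(
        "unweighted_unifrac",
        counts[:, observed],
        ids=list(presence.index),
        taxa=obs_ids,
        tree=tree,
        validate=True,
    )
    df = pd.DataFrame(dm.data, index=presence.index, columns=presence.index)
    return DistanceMatrix(df, metric="unweighted_unifrac")


@dataclass
class Dendrogram:
    """WPGMA merge tree over samples (scipy linkage encoding)."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: list[str]
    method: str = "wpgma"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> pd.Series:
        assign = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick with branch lengths = parent merge height - child height."""
        root, _ = hierarchy.to_tree(self.linkage, rd=True)

        def render(node, parent_height) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            inner = ",".join(render(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:.10g}"

        inner = ",".join(render(c, root.dist) for c in (root.left, root.right))
        return f"({inner});"


def wpgma(d: DistanceMatrix) -> Dendrogram:
    """WPGMA agglomeration (hclust's "mcquitty").

    Repeatedly merges the closest pair; the merged cluster's distance to any
    other cluster is the simple mean of the two members' distances. Samples
    are processed in lexicographic label order, so equidistant merge
    candidates resolve to the lexicographically first pair.
    """
    order = sorted(d.ids)
    if len(order) < 2:
        raise ValidationError("WPGMA needs at least two samples")
    mat = d.data.loc[order, order].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValidationError("distance matrix contains NaN")
    from scipy.spatial.distance import squareform

    z = hierarchy.linkage(squareform(mat, checks=False), method="weighted")
    return Dendrogram(linkage=z, labels=order)
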