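"""Endemism and sharing of GVMAGs and their gene content across units.

All set algebra runs on the strict (70% breadth) presence matrix: a GVMAG
is present in a lake or region if it is present in at least one of the
unit's samples. Exact-subset intersection counts feed UpSet-style plots;
pairwise sharing is reported directionally (denominator = the focal unit's
total), which is what makes asymmetric shared percentages possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import POLAR_REGIONS, SampleMetadata, ValidationError


def collapse_presence(
    presence_by_sample: pd.DataFrame, metadata: SampleMetadata, unit: str
) -> pd.DataFrame:
    """OR sample-level presence up to lakes or regions."""
    if unit not in ("lake", "region"):
        raise ValidationError("unit must be 'lake' or 'region'")
    mapping = (metadata.lake_of() if unit == "lake" else metadata.region_of()).reindex(
        presence_by_sample.index
    )
    if mapping.isna().any():
        missing = list(presence_by_sample.index[mapping.isna()])
        raise ValidationError(f"samples missing from metadata: {missing}")
    all_units = (
        metadata.data["lake"] if unit == "lake" else metadata.data["region"]
    ).unique()
    unused = set(all_units) - set(mapping)
    if unused:
        warnings.warn(f"units with no samples dropped: {sorted(unused)}", stacklevel=2)
    out = (presence_by_sample > 0).groupby(mapping.to_numpy()).any().astype(int)
    out.index.name = unit
    return out


@dataclass
class IntersectionCounts:
    """Exact-subset intersection counts plus per-unit sharing summaries."""

    exact_subsets: dict[frozenset, int]
    unit_totals: pd.Series  # GVMAGs present in each unit
    unique_counts: pd.Series  # GVMAGs present in exactly that unit
    uniqueness_fraction: pd.Series
    pairwise_shared: pd.DataFrame  # directional |u ∩ v| / |present in u|
    display_threshold: float = 0.001

    def shared_below_threshold(self) -> pd.DataFrame:
        """Flags for pairwise percentages under the display threshold."""
        off_diag = self.pairwise_shared.copy()
        for u in off_diag.index:
            off_diag.loc[u, u] = float("nan")
        return off_diag < self.display_threshold

    def to_tsv(self, path) -> None:
        rows = [
            {"subset": "|".join(sorted(k)), "n_gvmags": v}
            for k, v in sorted(
                self.exact_subsets.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
            )
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def upset_counts(p: pd.DataFrame, display_threshold: float = 0.001) -> IntersectionCounts:
    """Exact-subset membership counts over a units x GVMAGs binary matrix.

    Each GVMAG present in >=1 unit contributes to exactly one subset: the
    set of units it occurs in. Pairwise shared fractions are directional.
    """
    if p.shape[0] < 1:
        raise ValidationError("need at least one unit")
    b = p > 0
    detected = b.any(axis=0)
    subsets: dict[frozenset, int] = {}
    sigs = b.loc[:, detected]
    units = list(p.index)
    for _, col in sigs.items():
        key = frozenset(col.index[col])
        subsets[key] = subsets.get(key, 0) + 1
    totals = b.sum(axis=1)
    unique = pd.Series(
        {u: subsets.get(frozenset([u]), 0) for u in units}, dtype=int
    ).reindex(units)
    uniq_frac = (unique / totals.where(totals > 0)).astype(float)
    bm = b.to_numpy(dtype=int)
    inter = bm @ bm.T
    denom = totals.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        shared = pd.DataFrame(
            inter / denom[:, None], index=units, columns=units
        )
    return IntersectionCounts(
        exact_subsets=subsets,
        unit_totals=totals,
        unique_counts=unique,
        uniqueness_fraction=uniq_frac,
        pairwise_shared=shared,
        display_threshold=display_threshold,
    )


@dataclass
class ClusterDistribution:
    """Region distribution of protein clusters."""

    cluster_regions: pd.Series  # cluster_id -> frozenset of regions
    counts: IntersectionCounts
    specificity_fraction: pd.Series  # region -> |only in r| / |found in r|
    polar_specific_fraction: float  # clusters found only in polar regions

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "cluster_id": self.cluster_regions.index,
                "regions": ["|".join(sorted(r)) for r in self.cluster_regions],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def protein_cluster_distribution(
    clusters: pd.DataFrame,
    region_of_gvmag: pd.Series,
    polar_regions: tuple[str, ...] = POLAR_REGIONS,
) -> ClusterDistribution:
    """Map each protein cluster to the regions of its member GVMAGs.

    ``region_of_gvmag`` is typically origin-based (the region of the lake
    each GVMAG was assembled from). A cluster is specific to region r if
    every member's GVMAG maps to r; polar-specific if its region set is a
    subset of the polar regions.
    """
    regions = region_of_gvmag.reindex(clusters["gvmag_id"].unique())
    if regions.isna().any():
        bad = list(regions.index[regions.isna()])[:5]
        raise ValidationError(f"cluster members from GVMAGs without a region: {bad}")
    merged = clusters.merge(
        region_of_gvmag.rename("region"), left_on="gvmag_id", right_index=True
    )
    cluster_regions = merged.groupby("cluster_id")["region"].agg(frozenset)
    all_regions = sorted(set(region_of_gvmag))
    binary = pd.DataFrame(
        [[r in s for s in cluster_regions] for r in all_regions],
        index=all_regions,
        columns=cluster_regions.index,
    ).astype(int)
    counts = upset_counts(binary)
    only = pd.Series(
        {r: counts.exact_subsets.get(frozenset([r]), 0) for r in all_regions}
    )
    found = counts.unit_totals
    specificity = (only / found.where(found > 0)).astype(float)
    polar = set(polar_regions)
    n_polar_specific = sum(1 for s in cluster_regions if set(s) <= polar)
    return ClusterDistribution(
        cluster_regions=cluster_regions,
        counts=counts,
        specificity_fraction=specificity,
        polar_specific_fraction=n_polar_specific / len(cluster_regions),
    )
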