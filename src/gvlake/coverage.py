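"""GVMAG abundance quantification from per-contig depth tables.

A GVMAG's read-depth coverage in a sample is the length-weighted mean of its
member contigs' average depths::

    coverage = sum(contig_len * contig_avg_depth) / gvmag_total_length

and its horizontal (breadth) fraction is the covered-base total over the
genome length. Coverage is normalized by library size and scaled by 1e9 so
values are comparable across samples of very different sequencing depth.
A GVMAG counts as present in a sample only if at least a cutoff fraction of
its bases is covered: 25% for distance-based analyses, 70% for the stricter
presence/absence (endemism) analyses. Both comparisons are inclusive (>=).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    MIN_GVMAG_LENGTH,
    ContigDepthTable,
    GvmagCatalog,
    SampleMetadata,
    ValidationError,
)

NORMALIZATION_CONSTANT = 1e9
"""Scale applied after dividing by library size (coverage per 1e9 reads)."""


@dataclass
class AbundanceTable:
    """Samples × GVMAGs matrix of breadth-filtered normalized coverage.

    ``values`` holds normalized coverage, exactly zero wherever the
    horizontal fraction fell below ``breadth_cutoff``; ``breadths`` retains
    the unfiltered horizontal fractions for threshold diagnostics.
    """

    values: pd.DataFrame
    breadth_cutoff: float
    breadths: pd.DataFrame | None = None

    def presence(self) -> pd.DataFrame:
        """Binary presence matrix (1 where the filtered coverage is > 0)."""
        return (self.values > 0).astype(int)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# normalized GVMAG coverage (per {NORMALIZATION_CONSTANT:.0e} reads), "
                f"breadth cutoff {self.breadth_cutoff}\n"
            )
            self.values.to_csv(fh, sep="\t", index_label="sample_id")


def _per_gvmag_stats(
    depth: ContigDepthTable, catalog: GvmagCatalog
) -> tuple[pd.Series, pd.Series]:
    """Length-weighted depth and breadth for every GVMAG in one sample.

    Contigs absent from the sample's depth table contribute zero depth and
    zero covered bases (sparse depth exports are common).
    """
    merged = catalog.contigs.merge(
        depth.data[["contig_id", "total_avg_depth", "covered_bases"]],
        on="contig_id",
        how="left",
    ).fillna({"total_avg_depth": 0.0, "covered_bases": 0})
    merged["weighted"] = merged["contig_len"] * merged["total_avg_depth"]
    g = merged.groupby("gvmag_id")
    total_len = g["contig_len"].sum()
    depths = g["weighted"].sum() / total_len
    breadths = g["covered_bases"].sum() / total_len
    return depths, breadths


def gvmag_depth(depth: ContigDepthTable, catalog: GvmagCatalog, gvmag_id: str) -> float:
    """Length-weighted mean read depth of one GVMAG in one sample."""
    members = catalog.members(gvmag_id)
    merged = members.merge(
        depth.data[["contig_id", "total_avg_depth"]], on="contig_id", how="left"
    ).fillna({"total_avg_depth": 0.0})
    total = int(members["contig_len"].sum())
    return float((merged["contig_len"] * merged["total_avg_depth"]).sum() / total)


def gvmag_breadth(depth: ContigDepthTable, catalog: GvmagCatalog, gvmag_id: str) -> float:
    """Fraction of the GVMAG's bases covered by at least one read."""
    members = catalog.members(gvmag_id)
    merged = members.merge(
        depth.data[["contig_id", "covered_bases"]], on="contig_id", how="left"
    ).fillna({"covered_bases": 0})
    total = int(members["contig_len"].sum())
    return float(merged["covered_bases"].sum() / total)


def normalize(
    depth_value: float, library_size: int, constant: float = NORMALIZATION_CONSTANT
) -> float:
    """Library-size normalization: depth / reads × constant (default 1e9)."""
    if library_size <= 0:
        raise ValidationError("library_size must be positive")
    return depth_value / library_size * constant


def build_abundance_table(
    depths: dict[str, ContigDepthTable],
    catalog: GvmagCatalog,
    metadata: SampleMetadata,
    breadth_cutoff: float,
    constant: float = NORMALIZATION_CONSTANT,
) -> AbundanceTable:
    """Normalized, breadth-filtered abundance matrix over all samples.

    Entries whose horizontal fraction is below ``breadth_cutoff`` are set to
    exactly zero; the comparison is inclusive (>= keeps the entry).
    """
    if not 0 < breadth_cutoff <= 1:
        raise ValidationError("breadth_cutoff must be in (0, 1]")
    lib = metadata.library_sizes()
    missing = [s for s in depths if s not in lib.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    gvmags = catalog.gvmag_ids
    rows, brows = [], []
    sample_ids = sorted(depths)
    for sample_id in sample_ids:
        d, b = _per_gvmag_stats(depths[sample_id], catalog)
        d = d.reindex(gvmags, fill_value=0.0)
        b = b.reindex(gvmags, fill_value=0.0)
        norm = d / lib[sample_id] * constant
        rows.append(norm.where(b >= breadth_cutoff, 0.0))
        brows.append(b)
    values = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    breadths = pd.DataFrame(brows, index=values.index)
    return AbundanceTable(values=values, breadth_cutoff=breadth_cutoff, breadths=breadths)


def marker_filter(
    markers: pd.DataFrame, min_markers: int = 4, max_copies: int = 4
) -> set[str]:
    """GVMAGs eligible for the species tree by GVOG7 marker content.

    Keeps genomes with at least ``min_markers`` of the seven markers present
    (copy count >= 1) and no marker exceeding ``max_copies`` copies.
    """
    if markers.shape[1] != 7:
        raise ValidationError(f"expected 7 marker columns, got {markers.shape[1]}")
    counts = markers.to_numpy()
    keep = ((counts >= 1).sum(axis=1) >= min_markers) & (counts <= max_copies).all(axis=1)
    return set(markers.index[keep])


def restrict_to_viral(catalog: GvmagCatalog, viral_flags: pd.Series) -> GvmagCatalog:
    """Drop contigs not predicted viral; re-apply the genome-length floor.

    GVMAGs whose viral contigs total less than the minimum assembly length
    are removed entirely. Flags for contigs absent from the catalog are
    ignored with a warning.
    """
    known = set(catalog.contigs["contig_id"])
    unknown = [c for c in viral_flags.index if c not in known]
    if unknown:
        warnings.warn(
            f"viral flags for {len(unknown)} contigs not in catalog; ignored",
            stacklevel=2,
        )
    flags = viral_flags.reindex(catalog.contigs["contig_id"])
    if flags.isna().any():
        raise ValidationError("viral flags must cover every catalog contig")
    kept = catalog.contigs[flags.to_numpy(dtype=bool)]
    totals = kept.groupby("gvmag_id")["contig_len"].sum()
    surviving = set(totals[totals >= MIN_GVMAG_LENGTH].index)
    kept = kept[kept["gvmag_id"].isin(surviving)].reset_index(drop=True)
    if kept.empty:
        warnings.warn("no GVMAG survives the viral-contig restriction", stacklevel=2)
    tax = catalog.taxonomy.loc[sorted(surviving)] if catalog.taxonomy is not None else None
    markers = catalog.markers
    if markers is not None:
        markers = markers.loc[markers.index.isin(surviving)]
    origin = catalog.origin_lake
    if origin is not None:
        origin = origin[origin.index.isin(surviving)]
    return GvmagCatalog(kept, tax, markers, None, origin)
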