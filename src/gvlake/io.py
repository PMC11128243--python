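"""Readers and writers for the pipeline's tabular inputs and outputs.

All tables are UTF-8 TSV; lines starting with ``#`` are comments. The depth
table follows the ``jgi_summarize_bam_contig_depths`` dialect (columns
``contigName``, ``contigLen``, ``totalAvgDepth`` plus per-sample depth /
variance pairs) extended with a ``coveredBases`` column carrying breadth
information, which the stock depth file does not contain but the presence
rules require. Real-data users derive ``coveredBases`` upstream from
pileups; the synthetic generator emits it directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from skbio import TreeNode

MIN_GVMAG_LENGTH = 75_000
"""Minimum total assembly length (bp) for a GVMAG to enter the catalog."""

REGIONS = ("LIM", "Arctic_subarctic", "Temperate", "Antarctic")
POLAR_REGIONS = ("LIM", "Arctic_subarctic", "Antarctic")

GVOG7 = (
    "GVOGm0013",
    "GVOGm0022",
    "GVOGm0054",
    "GVOGm0172",
    "GVOGm0461",
    "GVOGm0760",
    "GVOGm0890",
)
"""The seven core giant-virus orthologous groups used for tree inclusion."""


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


class ValidationError(ValueError):
    """A parsed table violates a domain invariant."""


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


# ---------------------------------------------------------------------------
# depth tables
# ---------------------------------------------------------------------------


@dataclass
class ContigDepthTable:
    """Per-contig mean depth and covered bases for one sample."""

    sample_id: str
    data: pd.DataFrame  # contig_id, contig_len, total_avg_depth, covered_bases

    def __post_init__(self) -> None:
        d = self.data
        if (d["total_avg_depth"] < 0).any():
            bad = d.loc[d["total_avg_depth"] < 0, "contig_id"].iloc[0]
            raise ValidationError(f"negative depth for contig {bad!r}")
        if ((d["covered_bases"] < 0) | (d["covered_bases"] > d["contig_len"])).any():
            bad = d.loc[d["covered_bases"] > d["contig_len"], "contig_id"]
            raise ValidationError(
                "covered_bases outside [0, contig_len] for contigs: "
                + ", ".join(bad.astype(str).head(5))
            )
        zero_depth = d["total_avg_depth"] == 0
        if (d.loc[zero_depth, "covered_bases"] != 0).any():
            raise ValidationError("contig with zero depth but nonzero covered bases")
        if d["contig_id"].duplicated().any():
            raise ValidationError("duplicate contig ids in depth table")

    def depth_of(self, contig_id: str) -> float:
        row = self.data.loc[self.data["contig_id"] == contig_id]
        return 0.0 if row.empty else float(row["total_avg_depth"].iloc[0])


def read_depth_table(path: str | Path, sample_id: str) -> ContigDepthTable:
    """Read one sample's jgi-style depth table (with ``coveredBases``).

    Unknown columns (e.g. per-sample ``.bam`` / ``.bam-var`` pairs) are
    ignored; column order beyond the header names is irrelevant.
    """
    df = _read_tsv(path)
    _require_columns(df, ("contigName", "contigLen", "totalAvgDepth", "coveredBases"), path)
    out = pd.DataFrame(
        {
            "contig_id": df["contigName"].astype(str),
            "contig_len": df["contigLen"].astype(int),
            "total_avg_depth": df["totalAvgDepth"].astype(float),
            "covered_bases": df["coveredBases"].astype(int),
        }
    )
    return ContigDepthTable(sample_id=sample_id, data=out)


def write_depth_table(table: ContigDepthTable, path: str | Path) -> None:
    d = table.data
    out = pd.DataFrame(
        {
            "contigName": d["contig_id"],
            "contigLen": d["contig_len"],
            "totalAvgDepth": d["total_avg_depth"],
            f"{table.sample_id}.bam": d["total_avg_depth"],
            f"{table.sample_id}.bam-var": 0.0,
            "coveredBases": d["covered_bases"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Sample → lake → region mapping plus library size and conductivity.

    ``library_size`` is total reads; ``conductivity`` is mS/cm and optional.
    """

    data: pd.DataFrame  # sample_id, lake, region, library_size, conductivity

    def __post_init__(self) -> None:
        d = self.data
        if d["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        lake_regions = d.groupby("lake")["region"].nunique()
        if (lake_regions > 1).any():
            bad = lake_regions[lake_regions > 1].index[0]
            raise ValidationError(f"lake {bad!r} maps to more than one region")
        if (d["library_size"] <= 0).any():
            raise ValidationError("library_size must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def lake_of(self) -> pd.Series:
        return self.data.set_index("sample_id")["lake"]

    def region_of(self) -> pd.Series:
        return self.data.set_index("sample_id")["region"]

    def region_of_lake(self) -> pd.Series:
        return self.data.drop_duplicates("lake").set_index("lake")["region"]

    def library_sizes(self) -> pd.Series:
        return self.data.set_index("sample_id")["library_size"]


def read_metadata(path: str | Path) -> SampleMetadata:
    df = _read_tsv(path)
    _require_columns(df, ("sample_id", "lake", "region", "library_size"), path)
    if "conductivity" not in df.columns:
        df["conductivity"] = float("nan")
    df = df[["sample_id", "lake", "region", "library_size", "conductivity"]].copy()
    df["library_size"] = df["library_size"].astype(int)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GVMAG catalog
# ---------------------------------------------------------------------------


@dataclass
class GvmagCatalog:
    """GVMAG → contig membership with optional taxonomy, markers and flags.

    Contig membership is a partition: a contig belongs to at most one GVMAG,
    and every GVMAG totals at least ``MIN_GVMAG_LENGTH`` bp.
    """

    contigs: pd.DataFrame  # gvmag_id, contig_id, contig_len
    taxonomy: pd.DataFrame | None = None  # index gvmag_id; columns order, family
    markers: pd.DataFrame | None = None  # index gvmag_id; GVOG7 copy counts
    viral_flags: pd.Series | None = None  # index contig_id -> bool
    origin_lake: pd.Series | None = None  # index gvmag_id -> lake of assembly

    def __post_init__(self) -> None:
        c = self.contigs
        if c["contig_id"].duplicated().any():
            bad = c.loc[c["contig_id"].duplicated(), "contig_id"].iloc[0]
            raise ValidationError(f"contig {bad!r} assigned to more than one GVMAG")
        short = self.total_lengths()
        short = short[short < MIN_GVMAG_LENGTH]
        if len(short):
            raise ValidationError(
                f"GVMAGs below the {MIN_GVMAG_LENGTH} bp minimum length: "
                + ", ".join(short.index.astype(str)[:5])
            )
        if self.taxonomy is not None:
            for rank in ("order", "family"):
                self.taxonomy[rank] = self.taxonomy[rank].fillna("undetermined")

    @property
    def gvmag_ids(self) -> list[str]:
        return sorted(self.contigs["gvmag_id"].unique())

    def total_lengths(self) -> pd.Series:
        return self.contigs.groupby("gvmag_id")["contig_len"].sum()

    def members(self, gvmag_id: str) -> pd.DataFrame:
        sub = self.contigs[self.contigs["gvmag_id"] == gvmag_id]
        if sub.empty:
            raise ValidationError(f"unknown or empty GVMAG {gvmag_id!r}")
        return sub

    def family_of(self) -> pd.Series:
        if self.taxonomy is None:
            raise ValidationError("catalog has no taxonomy")
        return self.taxonomy["family"]

    def order_of(self) -> pd.Series:
        if self.taxonomy is None:
            raise ValidationError("catalog has no taxonomy")
        return self.taxonomy["order"]


def read_catalog(
    path: str | Path,
    taxonomy_path: str | Path | None = None,
    markers_path: str | Path | None = None,
    viral_flags_path: str | Path | None = None,
    origin_path: str | Path | None = None,
) -> GvmagCatalog:
    """Load the GVMAG membership table and optional side tables."""
    df = _read_tsv(path)
    _require_columns(df, ("gvmag_id", "contig_id", "contig_len"), path)
    contigs = df[["gvmag_id", "contig_id", "contig_len"]].copy()
    contigs["contig_len"] = contigs["contig_len"].astype(int)
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else None
    markers = read_markers(markers_path) if markers_path else None
    flags = read_viral_flags(viral_flags_path) if viral_flags_path else None
    origin = None
    if origin_path:
        odf = _read_tsv(origin_path)
        _require_columns(odf, ("gvmag_id", "origin_lake"), origin_path)
        origin = odf.set_index("gvmag_id")["origin_lake"]
    return GvmagCatalog(contigs, taxonomy, markers, flags, origin)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ("gvmag_id",), path)
    for rank in ("order", "family"):
        if rank not in df.columns:
            df[rank] = "undetermined"
    return df.set_index("gvmag_id")[["order", "family"]]


def read_markers(path: str | Path) -> pd.DataFrame:
    """GVOG7 copy-count table: one row per GVMAG, seven marker columns."""
    df = _read_tsv(path)
    _require_columns(df, ("gvmag_id",) + GVOG7, path)
    return df.set_index("gvmag_id")[list(GVOG7)].astype(int)


def read_viral_flags(path: str | Path) -> pd.Series:
    df = _read_tsv(path)
    _require_columns(df, ("contig_id", "is_viral"), path)
    flags = df.set_index("contig_id")["is_viral"]
    if flags.dtype == object:
        flags = flags.map({"True": True, "False": False, "true": True, "false": False})
    return flags.astype(bool)


def write_catalog(catalog: GvmagCatalog, path: str | Path) -> None:
    catalog.contigs.to_csv(path, sep="\t", index=False)


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    taxonomy.to_csv(path, sep="\t", index=True, index_label="gvmag_id")


def write_markers(markers: pd.DataFrame, path: str | Path) -> None:
    markers.to_csv(path, sep="\t", index=True, index_label="gvmag_id")


def write_viral_flags(flags: pd.Series, path: str | Path) -> None:
    flags.rename("is_viral").to_csv(path, sep="\t", index_label="contig_id")


# ---------------------------------------------------------------------------
# eukaryote counts and protein clusters
# ---------------------------------------------------------------------------


def read_euk_counts(path: str | Path) -> pd.DataFrame:
    """18S clade read counts per sample, long form → samples × clades."""
    df = _read_tsv(path)
    _require_columns(df, ("sample_id", "clade", "read_count"), path)
    wide = df.pivot_table(
        index="sample_id", columns="clade", values="read_count", aggfunc="sum", fill_value=0
    )
    return wide.astype(int)


def write_euk_counts(counts: pd.DataFrame, path: str | Path) -> None:
    long = counts.stack().rename("read_count").reset_index()
    long.columns = ["sample_id", "clade", "read_count"]
    long.to_csv(path, sep="\t", index=False)


def read_protein_clusters(path: str | Path) -> pd.DataFrame:
    """MMseqs2-style membership: cluster_id, gvmag_id, protein_id."""
    df = _read_tsv(path)
    _require_columns(df, ("cluster_id", "gvmag_id", "protein_id"), path)
    return df[["cluster_id", "gvmag_id", "protein_id"]]


def write_protein_clusters(clusters: pd.DataFrame, path: str | Path) -> None:
    clusters.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> TreeNode:
    """Read a single rooted newick tree; tip labels are kept verbatim.

    Branches without a length are treated as zero-length (with a warning);
    duplicate tip labels are rejected because tips index GVMAGs.
    """
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    missing = False
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            missing = True
    if missing:
        warnings.warn("tree has branches without lengths; treated as 0", stacklevel=2)
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValidationError("duplicate tip labels in tree")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative run configuration; CLI flags override these values."""

    paths: dict = field(default_factory=dict)
    breadth_cutoff_quant: float = 0.25
    breadth_cutoff_presence: float = 0.70
    normalization_constant: float = 1e9
    n_permutations: int = 999
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    cfg.paths = raw.get("paths", {})
    cutoffs = raw.get("cutoffs", {})
    cfg.breadth_cutoff_quant = float(cutoffs.get("quantification", 0.25))
    cfg.breadth_cutoff_presence = float(cutoffs.get("presence", 0.70))
    cfg.normalization_constant = float(raw.get("normalization_constant", 1e9))
    cfg.n_permutations = int(raw.get("n_permutations", 999))
    cfg.seed = int(raw.get("seed", 0))
    return cfg
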