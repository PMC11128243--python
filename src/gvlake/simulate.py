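"""Synthetic lake-metagenome inputs with known biogeographic structure.

The generator emulates the data layout of a multi-lake giant-virus survey:
region-structured communities built from per-lake endemic GVMAG pools plus
within-region and between-region shared pools, per-contig depth tables with
covered-base (breadth) counts, a species tree over all GVMAGs, eukaryote
clade counts with planted virus-family associations, and protein clusters
with a planted polar-specific fraction. Every random draw flows from a
single seeded generator, so a fixed seed gives byte-identical outputs.

Generative model, in brief:

* A GVMAG present in a sample gets a genome-wide log-normal depth and a
  covered fraction drawn as ``0.75 + 0.25 * Beta(a, b)`` — present genomes
  always clear the 70% presence rule, so true presence is recoverable.
* An absent GVMAG receives cross-mapping noise (reads hitting genes shared
  with present relatives) on a single contig, capped at 20% of the genome,
  so absent genomes never reach the 25% breadth rule.
* Eukaryote clade counts are Poisson; for planted (clade, family) pairs the
  rate is modulated by ``exp(effect * z)`` where ``z`` is the standardized
  per-sample normalized abundance of the paired virus family.
* Protein clusters: a planted fraction draws members only from GVMAGs of
  polar-origin; the rest always include at least one temperate-origin
  member, so the planted polar-specific fraction is identifiable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .io import (
    GVOG7,
    POLAR_REGIONS,
    REGIONS,
    ContigDepthTable,
    GvmagCatalog,
    SampleMetadata,
    ValidationError,
    write_catalog,
    write_depth_table,
    write_euk_counts,
    write_markers,
    write_metadata,
    write_newick,
    write_protein_clusters,
    write_taxonomy,
    write_viral_flags,
)

_ORDER_FAMILIES = {
    "Imitervirales": ["IM-01", "IM-04", "IM-05", "IM-12", "IM-13"],
    "Algavirales": ["AG-01", "AG-02"],
    "Pandoravirales": ["PV-01", "PV-incertae-sedis"],
    "Pimascovirales": ["PM-01"],
    "Asfuvirales": ["AF-01"],
}
_ORDER_WEIGHTS = {
    "Imitervirales": 0.60,
    "Algavirales": 0.15,
    "Pandoravirales": 0.10,
    "Pimascovirales": 0.08,
    "Asfuvirales": 0.04,
    "undetermined": 0.03,
}
_EUK_CLADES = (
    "Haptophyta",
    "Chlorophyta",
    "Fungi",
    "Ciliophora",
    "Chrysophyceae",
    "Dinoflagellata",
    "Cercozoa",
    "Katablepharidophyta",
    "Bacillariophyta",
    "Cryptophyta",
)


def _default_between() -> dict[tuple[str, str], int]:
    """Polar regions exchange more genomes than polar-temperate pairs."""
    out: dict[tuple[str, str], int] = {}
    for i, r1 in enumerate(REGIONS):
        for r2 in REGIONS[i + 1 :]:
            polar = r1 in POLAR_REGIONS and r2 in POLAR_REGIONS
            out[(r1, r2)] = 4 if polar else 1
    return out


@dataclass
class SimulationConfig:
    """Knobs of the synthetic survey; defaults give the integration-scale
    community: 4 regions x 5 lakes x 2 samples, ~475 GVMAGs."""

    n_regions: int = 4
    lakes_per_region: int = 5
    samples_per_lake: int = 2
    n_gvmags_endemic_per_lake: int = 20
    n_gvmags_shared_within_region: int = 15
    n_gvmags_shared_between_regions: dict[tuple[str, str], int] = field(
        default_factory=_default_between
    )
    contigs_per_gvmag: tuple[int, int] = (1, 8)
    gvmag_length: tuple[int, int] = (75_000, 2_126_000)
    depth_lognormal: tuple[float, float] = (1.0, 1.0)  # (mu, sigma) of ln depth
    breadth_given_present: tuple[float, float] = (6.0, 2.0)  # Beta(a, b) on [0.75, 1]
    library_size: tuple[int, int] = (5_000_000, 50_000_000)
    n_euk_clades: int = 8
    planted_associations: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("Haptophyta", "IM-12", 1.5),
            ("Chlorophyta", "IM-01", 1.5),
            ("Fungi", "IM-13", 1.5),
        ]
    )
    n_protein_clusters: int = 300
    polar_specific_cluster_fraction: float = 0.30
    detection_prob: float = 0.85
    cross_mapping_prob: float = 0.20
    non_viral_contig_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_regions <= len(REGIONS):
            raise ValidationError(f"n_regions must be in [1, {len(REGIONS)}]")
        if self.gvmag_length[0] < 75_000:
            raise ValidationError("gvmag_length must respect the 75 kb floor")
        total = self.n_gvmags_endemic_per_lake + self.n_gvmags_shared_within_region + sum(
            self.n_gvmags_shared_between_regions.values()
        )
        if total == 0:
            raise ValidationError("config generates no community at all")
        if any(e <= 0 for _, _, e in self.planted_associations):
            raise ValidationError("planted association effect sizes must be > 0")

    @property
    def regions(self) -> tuple[str, ...]:
        return REGIONS[: self.n_regions]


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery checks."""

    endemic: dict[str, set[str]]  # lake -> GVMAG ids
    shared_within: dict[str, set[str]]  # region -> GVMAG ids
    shared_between: dict[tuple[str, str], set[str]]
    home_lakes: dict[str, set[str]]
    true_presence: pd.DataFrame  # samples x GVMAGs, {0,1}
    planted_edges: list[tuple[str, str]]  # (clade, family)
    polar_specific_clusters: set[str]

    def lake_presence(self, metadata: SampleMetadata) -> pd.DataFrame:
        lake = metadata.lake_of().reindex(self.true_presence.index)
        return self.true_presence.groupby(lake.to_numpy()).max()

    def lake_uniqueness(self, metadata: SampleMetadata) -> pd.Series:
        """Fraction of each lake's detected GVMAGs found in no other lake."""
        byl = self.lake_presence(metadata)
        n_lakes_with = byl.sum(axis=0)
        unique = ((byl == 1) & (n_lakes_with == 1)).sum(axis=1)
        total = byl.sum(axis=1)
        return (unique / total).astype(float)


@dataclass
class SimulatedCommunity:
    config: SimulationConfig
    depths: dict[str, ContigDepthTable]
    catalog: GvmagCatalog
    metadata: SampleMetadata
    euk_counts: pd.DataFrame
    protein_clusters: pd.DataFrame
    viral_flags: pd.Series
    tree: TreeNode
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------


def random_coalescent_tree(tip_names: list[str], rng: np.random.Generator) -> TreeNode:
    """Random sequential coalescence with exponential waiting times.

    Lineages merge in random pairs; branch lengths are strictly positive,
    which is all UniFrac needs of a tree.
    """
    nodes = [TreeNode(name=n) for n in tip_names]
    heights = [0.0] * len(nodes)
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += float(rng.exponential(2.0 / (k * (k - 1))) + 1e-6)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        right, h_r = nodes.pop(j), heights.pop(j)
        left, h_l = nodes.pop(i), heights.pop(i)
        left.length = height - h_l
        right.length = height - h_r
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
        heights.append(height)
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# community simulation
# ---------------------------------------------------------------------------


def _make_lakes(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for region in config.regions:
        for il in range(config.lakes_per_region):
            lake = f"{region}_L{il + 1:02d}"
            for isamp in range(config.samples_per_lake):
                rows.append((f"{lake}_s{isamp + 1}", lake, region))
    return pd.DataFrame(rows, columns=["sample_id", "lake", "region"])


def _assign_taxonomy(gvmag_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    orders = list(_ORDER_WEIGHTS)
    probs = np.array(list(_ORDER_WEIGHTS.values()))
    probs = probs / probs.sum()
    chosen_orders = rng.choice(orders, size=len(gvmag_ids), p=probs)
    families = [
        rng.choice(_ORDER_FAMILIES[o]) if o in _ORDER_FAMILIES else "undetermined"
        for o in chosen_orders
    ]
    return pd.DataFrame(
        {"order": chosen_orders, "family": families},
        index=pd.Index(gvmag_ids, name="gvmag_id"),
    )


def _split_length(total: int, n_contigs: int, rng: np.random.Generator) -> np.ndarray:
    w = rng.uniform(0.5, 1.5, size=n_contigs)
    lens = np.floor(w / w.sum() * total).astype(int)
    lens[-1] += total - lens.sum()
    return lens


def simulate_community(config: SimulationConfig) -> SimulatedCommunity:
    """Generate all pipeline inputs plus the ground truth they encode."""
    rng = np.random.default_rng(config.seed)
    samples = _make_lakes(config)
    lakes_of_region = samples.drop_duplicates("lake").groupby("region")["lake"].apply(list)

    # --- GVMAG pools -------------------------------------------------------
    home_lakes: dict[str, set[str]] = {}
    endemic: dict[str, set[str]] = {lake: set() for lake in samples["lake"].unique()}
    shared_within: dict[str, set[str]] = {r: set() for r in config.regions}
    shared_between: dict[tuple[str, str], set[str]] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"GVMAG{counter:05d}"

    for lake in samples["lake"].unique():
        for _ in range(config.n_gvmags_endemic_per_lake):
            g = new_id()
            endemic[lake].add(g)
            home_lakes[g] = {lake}
    for region in config.regions:
        for _ in range(config.n_gvmags_shared_within_region):
            g = new_id()
            shared_within[region].add(g)
            home_lakes[g] = set(lakes_of_region[region])
    for (r1, r2), n in config.n_gvmags_shared_between_regions.items():
        if r1 not in config.regions or r2 not in config.regions:
            continue
        shared_between[(r1, r2)] = set()
        for _ in range(n):
            g = new_id()
            shared_between[(r1, r2)].add(g)
            home_lakes[g] = set(lakes_of_region[r1]) | set(lakes_of_region[r2])
    gvmag_ids = sorted(home_lakes)
    if not gvmag_ids:
        raise ValidationError("config generates no community at all")

    # --- catalog -----------------------------------------------------------
    lo, hi = config.gvmag_length
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(gvmag_ids))).astype(int)
    lengths = np.clip(lengths, lo, hi)
    rows = []
    contig_slices: dict[str, list[str]] = {}
    for g, total in zip(gvmag_ids, lengths):
        n_contigs = int(rng.integers(config.contigs_per_gvmag[0], config.contigs_per_gvmag[1] + 1))
        clens = _split_length(int(total), n_contigs, rng)
        ids = [f"{g}_c{i + 1}" for i in range(n_contigs)]
        contig_slices[g] = ids
        rows.extend(zip([g] * n_contigs, ids, clens.tolist()))
    contigs = pd.DataFrame(rows, columns=["gvmag_id", "contig_id", "contig_len"])
    taxonomy = _assign_taxonomy(gvmag_ids, rng)
    # planted families must exist in the community for the association to
    # be realisable at any community size
    fam_to_order = {f: o for o, fams in _ORDER_FAMILIES.items() for f in fams}
    for _, fam, _ in config.planted_associations:
        if fam not in set(taxonomy["family"]):
            g = gvmag_ids[int(rng.integers(len(gvmag_ids)))]
            taxonomy.loc[g, ["order", "family"]] = [fam_to_order.get(fam, "undetermined"), fam]
    markers = pd.DataFrame(
        rng.choice([0, 1, 2, 5], size=(len(gvmag_ids), 7), p=[0.12, 0.72, 0.12, 0.04]),
        index=pd.Index(gvmag_ids, name="gvmag_id"),
        columns=list(GVOG7),
    )
    origin = pd.Series(
        {g: sorted(home)[int(rng.integers(len(home)))] for g, home in
         ((g, home_lakes[g]) for g in gvmag_ids)},
        name="origin_lake",
    ).sort_index()
    viral_flags = pd.Series(
        rng.random(len(contigs)) >= config.non_viral_contig_prob,
        index=pd.Index(contigs["contig_id"], name="contig_id"),
        name="is_viral",
    )
    catalog = GvmagCatalog(contigs, taxonomy, markers, viral_flags, origin)

    # --- metadata ----------------------------------------------------------
    lib = rng.integers(config.library_size[0], config.library_size[1] + 1, len(samples))
    lake_cond = {
        lake: float(np.exp(rng.normal(0.5, 1.2)))
        for lake in samples["lake"].unique()
    }
    meta = samples.copy()
    meta["library_size"] = lib
    meta["conductivity"] = [
        round(lake_cond[lk] * float(rng.uniform(0.9, 1.1)), 4) for lk in meta["lake"]
    ]
    metadata = SampleMetadata(meta)

    # --- presence ----------------------------------------------------------
    sample_ids = list(samples["sample_id"])
    lake_of_sample = samples.set_index("sample_id")["lake"]
    presence = pd.DataFrame(0, index=pd.Index(sample_ids, name="sample_id"), columns=gvmag_ids)
    for g in gvmag_ids:
        eligible = [s for s in sample_ids if lake_of_sample[s] in home_lakes[g]]
        draws = rng.random(len(eligible)) < config.detection_prob
        if not draws.any():
            draws[int(rng.integers(len(eligible)))] = True
        for s, hit in zip(eligible, draws):
            if hit:
                presence.loc[s, g] = 1

    # --- depth tables ------------------------------------------------------
    contig_index = {c: i for i, c in enumerate(contigs["contig_id"])}
    clen = contigs["contig_len"].to_numpy()
    mu, sigma = config.depth_lognormal
    a_b, b_b = config.breadth_given_present
    depths: dict[str, ContigDepthTable] = {}
    true_norm_depth = pd.DataFrame(
        0.0, index=presence.index, columns=gvmag_ids
    )  # per-1e9-read family aggregation source for planted associations
    lib_of = metadata.library_sizes()
    for s in sample_ids:
        depth_arr = np.zeros(len(contigs))
        covered_arr = np.zeros(len(contigs), dtype=int)
        for g in gvmag_ids:
            idx = np.array([contig_index[c] for c in contig_slices[g]])
            total = int(clen[idx].sum())
            if presence.loc[s, g]:
                gdepth = float(rng.lognormal(mu, sigma))
                jitter = rng.lognormal(0.0, 0.25, size=len(idx))
                depth_arr[idx] = gdepth * jitter
                frac = 0.75 + 0.25 * float(rng.beta(a_b, b_b))
                covered_arr[idx] = np.ceil(frac * clen[idx]).astype(int)
                covered_arr[idx] = np.minimum(covered_arr[idx], clen[idx])
                true_norm_depth.loc[s, g] = (
                    float((clen[idx] * depth_arr[idx]).sum() / total) / lib_of[s] * 1e9
                )
            elif rng.random() < config.cross_mapping_prob:
                # cross-mapping noise: one contig, bounded well below the
                # 25% breadth rule
                j = idx[int(rng.integers(len(idx)))]
                u = float(rng.uniform(0.02, 0.6))
                covered = min(
                    int(clen[j]), int(np.floor(u * clen[j])), int(np.floor(0.20 * total))
                )
                if covered > 0:
                    covered_arr[j] = covered
                    depth_arr[j] = float(rng.lognormal(mu - 2.0, 0.5)) * covered / clen[j]
        data = pd.DataFrame(
            {
                "contig_id": contigs["contig_id"],
                "contig_len": clen,
                "total_avg_depth": depth_arr,
                "covered_bases": covered_arr,
            }
        )
        depths[s] = ContigDepthTable(sample_id=s, data=data)

    # --- eukaryote counts --------------------------------------------------
    clades = list(_EUK_CLADES[: config.n_euk_clades])
    planted = {c: (f, e) for c, f, e in config.planted_associations}
    fam_abund = true_norm_depth.T.groupby(taxonomy["family"].to_numpy()).sum().T
    euk = pd.DataFrame(0, index=presence.index, columns=clades)
    for clade in clades:
        lam = float(np.exp(rng.uniform(np.log(200), np.log(2000))))
        if clade in planted:
            fam, eff = planted[clade]
            if fam not in fam_abund.columns:
                raise ValidationError(f"planted family {fam!r} not in simulated taxonomy")
            x = fam_abund[fam].to_numpy(dtype=float)
            # monotone in family abundance via the rank transform: robust to
            # the heavy tail of coverage and yields balanced rare/abundant
            # classes for the downstream forest
            ranks = pd.Series(x).rank(method="average").to_numpy()
            z = 2.0 * (ranks - ranks.min()) / max(ranks.max() - ranks.min(), 1.0) - 1.0
            rate = lam * np.exp(eff * z)
        else:
            rate = np.full(len(presence), lam)
        euk[clade] = rng.poisson(rate)

    # --- protein clusters --------------------------------------------------
    region_of_lake = metadata.region_of_lake()
    origin_region = origin.map(region_of_lake)
    polar_pool = [g for g in gvmag_ids if origin_region[g] in POLAR_REGIONS]
    temperate_pool = [g for g in gvmag_ids if origin_region[g] not in POLAR_REGIONS]
    n_polar = int(round(config.polar_specific_cluster_fraction * config.n_protein_clusters))
    if n_polar and not polar_pool:
        raise ValidationError("no polar-origin GVMAGs to plant polar clusters in")
    cluster_rows = []
    polar_specific: set[str] = set()
    prot = 0
    for i in range(config.n_protein_clusters):
        cid = f"PC{i + 1:05d}"
        k = int(rng.integers(2, 7))
        if i < n_polar:
            members = rng.choice(polar_pool, size=min(k, len(polar_pool)), replace=False)
            polar_specific.add(cid)
        else:
            # force >= 1 temperate member so only planted clusters are
            # polar-specific
            members = list(rng.choice(gvmag_ids, size=k, replace=False))
            if temperate_pool and not any(g in temperate_pool for g in members):
                members[0] = temperate_pool[int(rng.integers(len(temperate_pool)))]
        for g in members:
            prot += 1
            cluster_rows.append((cid, g, f"P{prot:06d}"))
    clusters = pd.DataFrame(cluster_rows, columns=["cluster_id", "gvmag_id", "protein_id"])

    tree = random_coalescent_tree(gvmag_ids, rng)

    truth = GroundTruth(
        endemic=endemic,
        shared_within=shared_within,
        shared_between=shared_between,
        home_lakes=home_lakes,
        true_presence=presence,
        planted_edges=[(c, f) for c, f, _ in config.planted_associations],
        polar_specific_clusters=polar_specific,
    )
    return SimulatedCommunity(
        config=config,
        depths=depths,
        catalog=catalog,
        metadata=metadata,
        euk_counts=euk,
        protein_clusters=clusters,
        viral_flags=viral_flags,
        tree=tree,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

FIXTURE_PRESETS: dict[str, dict] = {
    "tiny": dict(
        n_regions=2,
        lakes_per_region=1,
        samples_per_lake=2,
        n_gvmags_endemic_per_lake=5,
        n_gvmags_shared_within_region=0,
        n_gvmags_shared_between_regions={("LIM", "Arctic_subarctic"): 2},
        contigs_per_gvmag=(1, 4),
        n_euk_clades=4,
        n_protein_clusters=30,
    ),
    "small": dict(
        n_regions=3,
        lakes_per_region=2,
        samples_per_lake=2,
        n_gvmags_endemic_per_lake=6,
        n_gvmags_shared_within_region=3,
        n_protein_clusters=80,
    ),
    "medium": dict(),  # the SimulationConfig defaults
}


def config_for(size: str, seed: int = 0, **overrides) -> SimulationConfig:
    if size not in FIXTURE_PRESETS:
        raise ValidationError(f"unknown fixture size {size!r}")
    kwargs = dict(FIXTURE_PRESETS[size])
    kwargs.update(overrides)
    return SimulationConfig(seed=seed, **kwargs)


def emit_fixture(size: str, out_dir: str | Path, seed: int = 0) -> Path:
    """Write a self-contained fixture directory loadable by every reader."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config_for(size, seed=seed)
    sim = simulate_community(config)
    write_fixture(sim, out)
    return out


def write_fixture(sim: SimulatedCommunity, out: str | Path) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    depth_dir = out / "depth"
    depth_dir.mkdir(exist_ok=True)
    for s, table in sim.depths.items():
        write_depth_table(table, depth_dir / f"{s}.depth.tsv")
    write_catalog(sim.catalog, out / "catalog.tsv")
    write_taxonomy(sim.catalog.taxonomy, out / "taxonomy.tsv")
    write_markers(sim.catalog.markers, out / "markers.tsv")
    write_viral_flags(sim.viral_flags, out / "viral_flags.tsv")
    sim.catalog.origin_lake.rename("origin_lake").to_csv(
        out / "origin.tsv", sep="\t", index_label="gvmag_id"
    )
    write_metadata(sim.metadata, out / "metadata.tsv")
    write_euk_counts(sim.euk_counts, out / "euk_counts.tsv")
    write_protein_clusters(sim.protein_clusters, out / "protein_clusters.tsv")
    write_newick(sim.tree, out / "species_tree.nwk")
    manifest = dataclasses.asdict(sim.config)
    manifest["n_gvmags"] = len(sim.catalog.gvmag_ids)
    manifest["n_samples"] = len(sim.metadata.sample_ids)
    manifest["n_gvmags_shared_between_regions"] = {
        f"{a}|{b}": v for (a, b), v in sim.config.n_gvmags_shared_between_regions.items()
    }
    with open(out / "MANIFEST.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_fixture(path: str | Path):
    """Read a fixture directory back into in-memory pipeline inputs."""
    from .io import read_catalog, read_depth_table, read_euk_counts, read_metadata
    from .io import read_newick, read_protein_clusters

    path = Path(path)
    metadata = read_metadata(path / "metadata.tsv")
    catalog = read_catalog(
        path / "catalog.tsv",
        taxonomy_path=path / "taxonomy.tsv",
        markers_path=path / "markers.tsv",
        viral_flags_path=path / "viral_flags.tsv",
        origin_path=path / "origin.tsv",
    )
    depths = {
        s: read_depth_table(path / "depth" / f"{s}.depth.tsv", s)
        for s in metadata.sample_ids
    }
    euk = read_euk_counts(path / "euk_counts.tsv")
    clusters = read_protein_clusters(path / "protein_clusters.tsv")
    tree = read_newick(path / "species_tree.nwk")
    return metadata, catalog, depths, euk, clusters, tree
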