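import numpy as np
import pandas as pd
import pytest

from gvlake.io import ContigDepthTable, GvmagCatalog, SampleMetadata
from gvlake.coverage import build_abundance_table
from gvlake.simulate import config_for, simulate_community


@pytest.fixture(scope="session")
def tiny_sim():
    return simulate_community(config_for("tiny", seed=11))


@pytest.fixture(scope="session")
def medium_sim():
    return simulate_community(config_for("medium", seed=7))


@pytest.fixture(scope="session")
def medium_tables(medium_sim):
    s = medium_sim
    t25 = build_abundance_table(s.depths, s.catalog, s.metadata, 0.25)
    t70 = build_abundance_table(s.depths, s.catalog, s.metadata, 0.70)
    return t25, t70


def make_depth_table(sample_id, rows):
    """rows: list of (contig_id, contig_len, depth, covered_bases)."""
    return ContigDepthTable(
        sample_id=sample_id,
        data=pd.DataFrame(
            rows, columns=["contig_id", "contig_len", "total_avg_depth", "covered_bases"]
        ),
    )


def make_catalog(memberships, taxonomy=None):
    """memberships: list of (gvmag_id, contig_id, contig_len)."""
    contigs = pd.DataFrame(memberships, columns=["gvmag_id", "contig_id", "contig_len"])
    tax = None
    if taxonomy is not None:
        tax = pd.DataFrame(taxonomy).set_index("gvmag_id")
    return GvmagCatalog(contigs, tax)


def make_metadata(rows):
    """rows: list of (sample_id, lake, region, library_size)."""
    df = pd.DataFrame(rows, columns=["sample_id", "lake", "region", "library_size"])
    df["conductivity"] = np.nan
    return SampleMetadata(df)
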