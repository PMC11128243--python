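import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
import hypothesis.extra.numpy as hnp

from gvlake.ecology import (
    NMDS,
    DistanceMatrix,
    HellingerTransformer,
    bray_curtis,
    hellinger,
    nmds,
    permanova,
    taxon_composition,
)
from gvlake.io import ValidationError
from .conftest import make_metadata


def dm_from(array, ids):
    df = pd.DataFrame(array, index=ids, columns=ids)
    return DistanceMatrix(df)


# ---------------------------------------------------------------------------
# Hellinger
# ---------------------------------------------------------------------------


def test_hellinger_hand_values():
    df = pd.DataFrame([[1.0, 3.0]], index=["s1"], columns=["a", "b"])
    out = hellinger(df)
    np.testing.assert_allclose(out.loc["s1"], [0.5, np.sqrt(0.75)], atol=1e-12)
    df = pd.DataFrame([[5.0, 0.0, 0.0]], index=["s1"], columns=list("abc"))
    np.testing.assert_allclose(hellinger(df).loc["s1"], [1.0, 0.0, 0.0], atol=1e-15)


def test_hellinger_rejects_negative_and_warns_on_zero_rows():
    with pytest.raises(ValidationError):
        hellinger(pd.DataFrame([[-1.0, 2.0]]))
    with pytest.warns(UserWarning, match="all-zero"):
        out = hellinger(pd.DataFrame([[0.0, 0.0], [1.0, 1.0]]))
    np.testing.assert_array_equal(out.iloc[0], [0.0, 0.0])


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    hnp.arrays(
        float,
        st.tuples(st.integers(1, 6), st.integers(1, 8)),
        elements=st.floats(0, 1e6, allow_nan=False),
    )
)
def test_hellinger_rows_have_unit_sum_of_squares(x):
    out = hellinger(pd.DataFrame(x)).to_numpy()
    nonzero = x.sum(axis=1) > 0
    np.testing.assert_allclose((out[nonzero] ** 2).sum(axis=1), 1.0, atol=1e-9)


def test_hellinger_transformer_composes_with_sklearn():
    from sklearn.pipeline import make_pipeline

    pipe = make_pipeline(HellingerTransformer())
    out = pipe.fit_transform(np.array([[1.0, 3.0], [2.0, 2.0]]))
    np.testing.assert_allclose(out[0], [0.5, np.sqrt(0.75)], atol=1e-12)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def test_bray_curtis_hand_values():
    df = pd.DataFrame(
        [[1.0, 1.0], [0.0, 2.0], [1.0, 1.0], [2.0, 0.0]], index=list("abcd")
    )
    d = bray_curtis(df)
    assert d.data.loc["a", "c"] == 0.0  # identical rows
    assert d.data.loc["b", "d"] == pytest.approx(1.0)  # disjoint supports
    assert d.data.loc["a", "b"] == pytest.approx(0.5)  # (1+1)/(1+3)


def test_bray_curtis_single_sample_and_zero_rows():
    with pytest.raises(ValidationError, match="two samples"):
        bray_curtis(pd.DataFrame([[1.0, 2.0]]))
    with pytest.warns(UserWarning, match="all-zero"):
        d = bray_curtis(pd.DataFrame([[0.0, 0.0], [0.0, 0.0]], index=["a", "b"]))
    assert d.data.loc["a", "b"] == 0.0


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    hnp.arrays(
        float,
        st.tuples(st.integers(2, 6), st.integers(1, 8)),
        elements=st.floats(0.001, 1e3, allow_nan=False),
    )
)
def test_bray_curtis_is_a_bounded_symmetric_dissimilarity(x):
    d = bray_curtis(pd.DataFrame(x)).data.to_numpy()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0)
    assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


def test_nmds_recovers_planar_configuration():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    res = nmds(dm_from(d, list("abc")), k=2, n_starts=10, seed=0)
    assert res.stress < 1e-3


def test_nmds_is_deterministic_given_seed(medium_tables):
    t25, _ = medium_tables
    d = bray_curtis(hellinger(t25))
    r1 = nmds(d, seed=42)
    r2 = nmds(d, seed=42)
    pd.testing.assert_frame_equal(r1.coordinates, r2.coordinates)
    assert r1.stress == r2.stress


def test_nmds_separates_constructed_regions(medium_sim, medium_tables):
    t25, _ = medium_tables
    d = bray_curtis(hellinger(t25))
    res = nmds(d, seed=0)
    coords = res.coordinates
    regions = medium_sim.metadata.region_of().reindex(coords.index)
    from scipy.spatial.distance import pdist, squareform

    dd = squareform(pdist(coords.to_numpy()))
    same = regions.to_numpy()[:, None] == regions.to_numpy()[None, :]
    iu = np.triu_indices_from(dd, k=1)
    within = dd[iu][same[iu]]
    between = dd[iu][~same[iu]]
    assert within.mean() < between.mean()


def test_nmds_dimension_must_be_below_sample_count():
    d = dm_from(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])
    with pytest.raises(ValidationError):
        nmds(d, k=2)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def test_permanova_perfect_separation_gives_min_p():
    # two groups of 6 duplicated samples each: within-group distance 0,
    # so SS_within = 0 and the statistic is +inf; no permutation happens
    # to rebuild the split, so p hits its floor 1/(n_perm+1)
    n = 12
    d = np.ones((n, n))
    d[:6, :6] = 0.0
    d[6:, 6:] = 0.0
    ids = [f"s{i}" for i in range(n)]
    groups = {s: ("g1" if i < 6 else "g2") for i, s in enumerate(ids)}
    res = permanova(dm_from(d, ids), groups, n_perm=99, seed=0)
    assert np.isinf(res.pseudo_F)
    assert res.p_value == pytest.approx(1 / 100)


def test_permanova_uninformative_distances_give_p_one():
    d = np.ones((6, 6)) - np.eye(6)
    ids = list("abcdef")
    groups = dict(zip(ids, ["g1"] * 3 + ["g2"] * 3))
    res = permanova(dm_from(d, ids), groups, n_perm=99, seed=0)
    assert res.p_value == 1.0


def test_permanova_requires_two_groups():
    d = dm_from(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])
    with pytest.raises(ValidationError, match="two groups"):
        permanova(d, {"a": "g", "b": "g"})


def test_permanova_statistic_matches_reference_implementation():
    """Pseudo-F must agree with scikit-bio's PERMANOVA on random data."""
    import skbio

    rng = np.random.default_rng(0)
    x = rng.gamma(2.0, size=(12, 30))
    ids = [f"s{i}" for i in range(12)]
    d = bray_curtis(pd.DataFrame(x, index=ids))
    groups = pd.Series(["g1"] * 4 + ["g2"] * 4 + ["g3"] * 4, index=ids)
    ours = permanova(d, groups, n_perm=99, seed=0)
    ref = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(d.data.to_numpy(), ids=ids), groups.to_numpy(),
        permutations=99,
    )
    assert ours.pseudo_F == pytest.approx(float(ref["test statistic"]), rel=1e-10)


def test_permanova_is_deterministic_given_seed(medium_sim, medium_tables):
    t25, _ = medium_tables
    d = bray_curtis(hellinger(t25))
    r1 = permanova(d, medium_sim.metadata.region_of(), seed=9)
    r2 = permanova(d, medium_sim.metadata.region_of(), seed=9)
    assert (r1.pseudo_F, r1.p_value) == (r2.pseudo_F, r2.p_value)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def test_taxon_composition_averages_per_sample_proportions():
    table = pd.DataFrame(
        [[10.0, 0.0], [0.0, 1.0]],
        index=["s1", "s2"],
        columns=["g1", "g2"],
    )
    tax = pd.DataFrame(
        {"order": ["X", "Y"], "family": ["fx", "fy"]},
        index=pd.Index(["g1", "g2"], name="gvmag_id"),
    )
    meta = make_metadata([("s1", "L1", "LIM", 10), ("s2", "L1", "LIM", 10)])
    comp = taxon_composition(table, tax, meta, group_by="lake", rank="order")
    # 100%/0% and 0%/100% average to 50/50 regardless of magnitudes
    assert comp.loc["L1", "X"] == pytest.approx(0.5)
    assert comp.loc["L1", "Y"] == pytest.approx(0.5)


def test_taxon_composition_rows_sum_to_one(medium_sim, medium_tables):
    t25, _ = medium_tables
    comp = taxon_composition(
        t25, medium_sim.catalog.taxonomy, medium_sim.metadata, "region", "order"
    )
    np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-12)
    assert "undetermined" in comp.columns  # unassigned taxa form a category
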