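import numpy as np
import pandas as pd
import pytest

from gvlake.association import (
    Edge,
    RfModelReport,
    TunedRandomForestClassifier,
    binarize_clades,
    build_network,
    family_features,
    filter_clades,
    select_edges,
    tune_and_fit,
)
from gvlake.io import ValidationError
from .conftest import make_metadata


def counts_df(values, samples=None, clades=None):
    values = np.atleast_2d(values)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    clades = clades or [f"c{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=samples, columns=clades)


def report(clade, importances, oob=0.1):
    return RfModelReport(
        clade=clade,
        oob_error=oob,
        mtry_selected=2,
        n_trees=100,
        importances=pd.Series(importances),
        seed=0,
    )


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def test_binarize_splits_at_the_clade_mean():
    lab = binarize_clades(counts_df([[0], [10]], clades=["c"]))
    assert list(lab.labels["c"]) == ["rare", "abundant"]
    assert lab.thresholds["c"] == 5.0

    lab = binarize_clades(counts_df([[1], [2], [9]], clades=["c"]))
    assert list(lab.labels["c"]) == ["rare", "rare", "abundant"]


def test_binarize_tie_at_mean_is_rare():
    lab = binarize_clades(counts_df([[5], [5], [5]], clades=["c"]))
    assert (lab.labels["c"] == "rare").all()


def test_binarize_zero_clade_warns_and_scale_invariance():
    with pytest.warns(UserWarning, match="zero total"):
        lab = binarize_clades(counts_df([[0, 1], [0, 3]], clades=["z", "c"]))
    assert (lab.labels["z"] == "rare").all()
    a = binarize_clades(counts_df([[1, 7], [4, 2], [9, 9]]))
    b = binarize_clades(counts_df(3 * np.array([[1, 7], [4, 2], [9, 9]])))
    pd.testing.assert_frame_equal(a.labels, b.labels)


# ---------------------------------------------------------------------------
# clade filter
# ---------------------------------------------------------------------------


def test_filter_clades_applies_both_rules():
    meta = make_metadata([("s1", "L1", "LIM", 10), ("s2", "L2", "LIM", 10)])
    # c_low is 0.9% everywhere; c_ok reaches 50% in L1
    counts = pd.DataFrame(
        {"c_low": [9, 9], "c_ok": [500, 100], "rest": [491, 891]},
        index=["s1", "s2"],
    )
    reports = {
        "c_low": report("c_low", {"f": 1.0}, oob=0.01),
        "c_ok": report("c_ok", {"f": 1.0}, oob=0.24),
    }
    keep = filter_clades(counts, meta, reports)
    assert keep == {"c_ok"}

    reports["c_ok"].oob_error = 0.25  # boundary: "below 25%" is strict
    assert filter_clades(counts, meta, reports) == set()


def test_filter_clades_skips_degenerate_models():
    meta = make_metadata([("s1", "L1", "LIM", 10), ("s2", "L1", "LIM", 10)])
    counts = pd.DataFrame({"c": [50, 50]}, index=["s1", "s2"])
    rep = report("c", {"f": 1.0}, oob=float("nan"))
    rep.degenerate = True
    assert filter_clades(counts, meta, {"c": rep}) == set()


# ---------------------------------------------------------------------------
# edge selection
# ---------------------------------------------------------------------------


def test_select_edges_applies_the_importance_window():
    edges = select_edges(report("c", {"F1": 10.0, "F2": 8.5, "F3": 7.9}))
    assert [(e.family, e.is_top) for e in edges] == [("F1", True), ("F2", False)]


def test_select_edges_caps_extra_edges_with_lexicographic_ties():
    imp = {"F1": 10.0, "F2": 9.0, "F3": 9.0, "F4": 9.0, "F5": 9.0, "F6": 9.0}
    edges = select_edges(report("c", imp))
    assert len(edges) == 4
    assert edges[0].family == "F1" and edges[0].is_top
    assert [e.family for e in edges[1:]] == ["F2", "F3", "F4"]


def test_select_edges_single_feature_and_all_zero():
    edges = select_edges(report("c", {"F1": 3.0}))
    assert len(edges) == 1 and edges[0].is_top
    with pytest.warns(UserWarning, match="all-zero"):
        assert select_edges(report("c", {"F1": 0.0, "F2": 0.0})) == []


def test_select_edges_invariant_to_importance_rescaling():
    imp = {"F1": 10.0, "F2": 8.5, "F3": 7.9, "F4": 1.0}
    a = select_edges(report("c", imp))
    b = select_edges(report("c", {k: v * 0.037 for k, v in imp.items()}))
    assert [e.family for e in a] == [e.family for e in b]
    assert [e.is_top for e in a] == [e.is_top for e in b]


# ---------------------------------------------------------------------------
# forest tuning
# ---------------------------------------------------------------------------


def separable_data(n=60, p=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.lognormal(1.0, 1.0, size=(n, p))
    y = np.where(X[:, 3] > np.median(X[:, 3]), "abundant", "rare")
    return X, y


def test_tuned_forest_learns_a_separable_signal():
    X, y = separable_data()
    est = TunedRandomForestClassifier(n_trees=300, n_tree_try=300, random_state=0)
    est.fit(X, y)
    assert est.oob_error_ < 0.05
    assert int(np.argmax(est.feature_importances_)) == 3
    assert (est.predict(X) == y).mean() > 0.95


def test_tuned_forest_is_deterministic():
    X, y = separable_data(seed=3)
    r1 = TunedRandomForestClassifier(n_trees=200, n_tree_try=200, random_state=7).fit(X, y)
    r2 = TunedRandomForestClassifier(n_trees=200, n_tree_try=200, random_state=7).fit(X, y)
    assert r1.mtry_ == r2.mtry_
    assert r1.oob_error_ == r2.oob_error_
    np.testing.assert_array_equal(r1.feature_importances_, r2.feature_importances_)


def test_tuned_forest_rejects_single_class_targets():
    X = np.random.default_rng(0).random((10, 3))
    with pytest.raises(ValidationError, match="single-class"):
        TunedRandomForestClassifier().fit(X, ["rare"] * 10)


def test_pure_noise_targets_have_chance_level_oob_error():
    """A label with no relationship to the features should sit near 50%
    OOB error on average."""
    errors = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.lognormal(0.0, 1.0, size=(50, 10))
        y = rng.choice(["rare", "abundant"], size=50)
        est = TunedRandomForestClassifier(n_trees=200, n_tree_try=200, random_state=seed)
        est.fit(X, y)
        errors.append(est.oob_error_)
    assert 0.35 <= float(np.mean(errors)) <= 0.65


def test_tune_and_fit_degenerate_target_reports_without_model():
    feats = pd.DataFrame(np.random.default_rng(0).random((6, 3)), columns=list("abc"))
    rep = tune_and_fit(feats, pd.Series(["rare"] * 6, index=feats.index), "c")
    assert rep.degenerate and rep.mtry_selected == 0


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def test_build_network_recovers_planted_edges_small_scale():
    from gvlake.coverage import build_abundance_table
    from gvlake.simulate import config_for, simulate_community

    s = simulate_community(config_for("small", seed=11))
    t = build_abundance_table(s.depths, s.catalog, s.metadata, 0.25)
    planted = dict(s.ground_truth.planted_edges)
    net = build_network(
        s.euk_counts[list(planted)], t, s.catalog.taxonomy, s.metadata,
        seed=0, n_trees=300, n_tree_try=300,
    )
    df = net.to_frame()
    assert set(df.columns) == {"clade", "family", "gini", "is_top"}
    assert net.eligible_clades  # the planted signals survive the filters
    for clade in net.eligible_clades:
        sub = df[df["clade"] == clade]
        assert sub["is_top"].sum() == 1  # exactly one top edge per clade
        assert len(sub) <= 4
        assert net.top_edge(clade).family == planted[clade]


def test_network_export_formats(tiny_sim):
    net_edges = [
        Edge("Haptophyta", "IM-12", 1.0, True),
        Edge("Haptophyta", "AG-01", 0.9, False),
    ]
    from gvlake.association import AssociationNetwork

    net = AssociationNetwork(edges=net_edges)
    sif = net.to_sif()
    assert "Haptophyta\tco_occurs_with\tIM-12" in sif
    empty = AssociationNetwork(edges=[])
    assert empty.to_frame().empty and empty.to_sif() == ""


def test_family_features_sum_normalized_coverage(tiny_sim):
    from gvlake.coverage import build_abundance_table

    s = tiny_sim
    t = build_abundance_table(s.depths, s.catalog, s.metadata, 0.25)
    feats = family_features(t, s.catalog.taxonomy)
    np.testing.assert_allclose(
        feats.sum(axis=1).to_numpy(), t.values.sum(axis=1).to_numpy(), rtol=1e-12
    )
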