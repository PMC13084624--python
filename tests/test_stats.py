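"""Hydrolysis pairs, site tables, Ward clustering, volcanoes, detection calls."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from adductomics.cohort import IntensityMatrix
from adductomics.selection import PreprocessConfig, preprocess
from adductomics.stats import (
    anonymize_adducts,
    detection_call,
    detection_grid,
    enrichment_volcano,
    find_hydrolysis_pairs,
    site_distribution,
    three_way_volcano,
    ward_cluster,
)


def _features(rows):
    return pd.DataFrame(rows).set_index("feature_id")


def test_hydrolysis_pairs_basic():
    feats = _features(
        [
            {"feature_id": "a", "protein": "HSA", "position": 34, "residue": "C", "adduct": "HETETE"},
            {"feature_id": "b", "protein": "HSA", "position": 34, "residue": "C", "adduct": "HETE"},
            {"feature_id": "c", "protein": "HSA", "position": 100, "residue": "E", "adduct": "HETETE"},
            {"feature_id": "d", "protein": "APOA1", "position": 34, "residue": "C", "adduct": "HETE"},
        ]
    )
    pairs = find_hydrolysis_pairs(feats)
    assert len(pairs) == 1
    assert pairs.iloc[0]["hetete_feature"] == "a"
    assert pairs.iloc[0]["hete_feature"] == "b"
    no_hete = find_hydrolysis_pairs(feats[feats["adduct"] == "HETETE"])
    assert len(no_hete) == 0


def test_site_distribution_counts_unique_sites():
    feats = _features(
        [
            {"feature_id": "a", "protein": "HSA", "position": 34, "residue": "C", "adduct": "HETETE"},
            {"feature_id": "b", "protein": "HSA", "position": 34, "residue": "C", "adduct": "HETE"},
            {"feature_id": "c", "protein": "HSA", "position": 7, "residue": "E", "adduct": "HETETE"},
            {"feature_id": "d", "protein": "APOA1", "position": 9, "residue": "E", "adduct": "HETETE"},
            {"feature_id": "e", "protein": "X", "position": 1, "residue": "", "adduct": ""},
        ]
    )
    table = site_distribution(feats)
    assert table.loc["HSA"].sum() == 2  # Cys34 counted once despite two adducts
    assert int(table.to_numpy().sum()) == 3
    assert site_distribution(feats[feats["adduct"] == ""]).empty


def test_site_distribution_matches_planted_truth(high_exposure_cohort):
    matrix, truth = high_exposure_cohort
    table = site_distribution(matrix.features)
    n_sites = truth.features.drop_duplicates(subset=["protein", "position"]).shape[0]
    assert int(table.to_numpy().sum()) == n_sites


def test_anonymize_merges_adduct_forms():
    values = pd.DataFrame(
        {
            "s1_HETETE": [20.0, np.nan],
            "s1_HETE": [np.nan, 20.0],
            "bg": [15.0, 15.0],
        },
        index=["x", "y"],
    )
    feats = _features(
        [
            {"feature_id": "s1_HETETE", "kind": "adduct", "protein": "HSA", "position": 34,
             "residue": "C", "adduct": "HETETE", "agent": "Q", "site": "s1", "sequence": "CPFK"},
            {"feature_id": "s1_HETE", "kind": "adduct", "protein": "HSA", "position": 34,
             "residue": "C", "adduct": "HETE", "agent": "HD", "site": "s1", "sequence": "CPFK"},
            {"feature_id": "bg", "kind": "background", "protein": "X", "position": 1,
             "residue": "", "adduct": "", "agent": "", "site": "", "sequence": "AAK"},
        ]
    )
    samples = pd.DataFrame({"agent": ["Q", "HD"]}, index=["x", "y"])
    m = IntensityMatrix(values=values, samples=samples, features=feats)
    merged = anonymize_adducts(m)
    assert merged.values.shape[1] == 2  # one anonymized row + background
    anon = [c for c in merged.values.columns if c.endswith("_anon")][0]
    # each sample keeps its own agent's adduct intensity
    np.testing.assert_allclose(merged.values[anon].to_numpy(), [20.0, 20.0])


def test_ward_separates_planted_agent_profiles(three_agent_cohort):
    matrix, _ = three_agent_cohort
    merged = anonymize_adducts(matrix)
    exposed = (merged.samples["agent"] != "control").to_numpy()
    panel = merged.features.index[merged.features["adduct"] == "anonymized"]
    sub = IntensityMatrix(
        values=merged.values.loc[exposed, panel],
        samples=merged.samples[exposed],
        features=merged.features.loc[panel],
    )
    X = preprocess(sub)
    labels, Z, purity = ward_cluster(X, 3, sub.samples["agent"].to_numpy())
    assert purity == 1.0
    # k = n is trivially pure
    _, _, trivially = ward_cluster(X, X.shape[0], sub.samples["agent"].to_numpy())
    assert trivially == 1.0
    with pytest.raises(ValueError):
        ward_cluster(X, X.shape[0] + 1)


def test_three_way_volcano_null_and_errors():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(0, 1e-9, size=(9, 4)))
    labels = np.repeat(["HD", "Q", "T"], 3)
    out = three_way_volcano(X, labels)
    assert (out["volcano_class"] == "none").all()
    fc_cols = [c for c in out.columns if c.startswith("log2fc")]
    assert out[fc_cols].sum(axis=1).abs().max() < 1e-9
    with pytest.raises(ValueError):
        three_way_volcano(X, np.repeat(["HD", "Q"], [5, 4]))
    with pytest.raises(ValueError):
        three_way_volcano(X.iloc[:7], np.array(["HD"] * 3 + ["Q"] * 3 + ["T"]))


def test_three_way_volcano_classifies_planted_feature():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(0, 0.3, size=(9, 60)))
    labels = np.repeat(["HD", "Q", "T"], 3)
    X.iloc[labels == "Q", 0] += 5.0
    out = three_way_volcano(X, labels)
    assert out.iloc[0]["volcano_class"] == "Q_primary"
    # projection lives on the zero-sum plane: origin maps to the origin
    null_row = out.iloc[1]
    assert abs(null_row["proj_x"]) < 5 and abs(null_row["proj_y"]) < 5


def test_bh_adjustment_is_monotone():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=200)
    adj = multipletests(p, method="fdr_bh")[1]
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_enrichment_volcano_identity_and_absence():
    rng = np.random.default_rng(3)
    base = rng.normal(20, 1, size=(10, 3))
    proteins = pd.Index([f"P{i}" for i in range(10)], name="protein")
    binding = pd.DataFrame(base, index=proteins)
    table, reduction = enrichment_volcano(binding.copy(), binding.copy())
    assert reduction == 0.0
    assert (table["call"] == "unchanged").all()
    eluate = binding.copy()
    eluate.iloc[:4] = np.nan
    table, reduction = enrichment_volcano(eluate, binding)
    assert reduction == pytest.approx(0.4)
    assert (table["call"] == "lost_in_eluate").sum() == 4


def test_detection_call_rules():
    blank = np.array([10.0, 10.5, 9.5])
    assert not detection_call(blank, blank)
    assert detection_call(blank + 10 * blank.std(ddof=1), blank)
    assert not detection_call(np.array([np.nan]), blank)
    with pytest.raises(ValueError):
        detection_call(np.array([12.0]), np.array([10.0, 10.0]))


def test_detection_grid_monotone_over_doses():
    import warnings

    from adductomics.cohort import CohortParams, StudyDesign, simulate_cohort

    design = StudyDesign(
        agents=("Q",), exposure_levels=(5e-3, 5e-5, 5e-6), replicates=3,
        control_replicates=3, seed=9,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m, truth = simulate_cohort(
            design, CohortParams(n_background_features=50, n_adduct_sites=40)
        )
    grid = detection_grid(m, truth.true_features["Q"])
    frac = grid.groupby("dose_m")["detected"].mean()
    assert frac[5e-3] >= frac[5e-5] >= frac[5e-6]
    assert frac[5e-3] > 0.9
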