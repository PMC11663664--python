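"""Descriptive statistics, correlation, PCA biplot, K-means and grading."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from peachem import (
    cluster_and_type,
    correlation_matrix,
    descriptive_stats,
    grade_samples,
    grading_summary,
    pca_biplot,
)
from peachem.stats_grading import kmeans


# -------------------------------------------------------- descriptive


def test_descriptive_basics():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0], "b": [2.0] * 5})
    out = descriptive_stats(df)
    assert out.loc["a", "mean"] == 3.0
    assert out.loc["a", "sd"] == pytest.approx(np.sqrt(2.5))  # 1.5811
    assert out.loc["a", "median"] == 3.0
    assert out.loc["a", "se"] == pytest.approx(np.sqrt(2.5) / np.sqrt(5))
    assert out.loc["b", "sd"] == 0.0
    assert out.loc["b", "cv"] == 0.0
    assert out.loc["a", "q1"] == 2.0 and out.loc["a", "q3"] == 4.0


def test_descriptive_order_invariants(comp2000):
    out = descriptive_stats(comp2000)
    assert (out["min"] <= out["q1"]).all()
    assert (out["q1"] <= out["median"]).all()
    assert (out["median"] <= out["q3"]).all()
    assert (out["q3"] <= out["max"]).all()


def test_descriptive_starch_mean(comp2000):
    out = descriptive_stats(comp2000)
    assert out.loc["starch", "mean"] == pytest.approx(51.41, abs=0.5)


def test_descriptive_needs_two_samples():
    with pytest.raises(ValueError):
        descriptive_stats(pd.DataFrame({"a": [1.0]}))


# -------------------------------------------------------- correlation


def test_perfect_correlation():
    x = np.arange(10.0)
    res = correlation_matrix(pd.DataFrame({"a": x, "b": 2 * x + 1}))
    assert res.r.loc["a", "b"] == pytest.approx(1.0)
    assert res.p.loc["a", "b"] < 1e-10


def test_orthogonal_design_vectors():
    a = np.array([1.0, 1.0, -1.0, -1.0])
    b = np.array([1.0, -1.0, 1.0, -1.0])
    res = correlation_matrix(pd.DataFrame({"a": a, "b": b}))
    assert res.r.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
    assert res.p.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)


def test_p_value_matches_t_oracle():
    # construct two columns with sample correlation exactly 0.5 at n=30
    rng = np.random.default_rng(3)
    u = rng.normal(size=30)
    v = rng.normal(size=30)
    v -= u * (u @ v) / (u @ u)  # orthogonalize
    u = (u - u.mean()) / u.std(ddof=1)
    v = (v - v.mean()) / v.std(ddof=1)
    v -= u * (u @ v) / (u @ u)
    v /= v.std(ddof=1)
    y = 0.5 * u + np.sqrt(0.75) * v
    res = correlation_matrix(pd.DataFrame({"x": u, "y": y}))
    r = res.r.loc["x", "y"]
    assert r == pytest.approx(0.5, abs=1e-10)
    t = 0.5 * np.sqrt(28 / 0.75)
    assert t == pytest.approx(3.0550, abs=1e-3)
    expected_p = 2 * sps.t.sf(t, df=28)
    assert res.p.loc["x", "y"] == pytest.approx(expected_p, rel=1e-10)
    # independent scipy oracle on the same data
    r_sp, p_sp = sps.pearsonr(u, y)
    assert res.p.loc["x", "y"] == pytest.approx(p_sp, rel=1e-6)


def test_zero_variance_column_reported_missing():
    df = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
    res = correlation_matrix(df)
    assert np.isnan(res.r.loc["a", "b"])
    assert np.isnan(res.p.loc["a", "b"])


def test_significance_stars():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    df = pd.DataFrame({"a": x, "b": x + 0.1 * rng.normal(size=50)})
    res = correlation_matrix(df)
    assert res.stars().loc["a", "b"] == "**"


def test_generator_pairs_recovered_via_correlation_matrix(comp2000):
    from peachem.synthetic_data import CORRELATION_PAIRS

    res = correlation_matrix(comp2000)
    for (a, b), target in CORRELATION_PAIRS.items():
        assert res.r.loc[a, b] == pytest.approx(target, abs=0.07), (a, b)
        assert res.p.loc[a, b] < 0.01  # all strongly significant at n=2000


# ------------------------------------------------------------- biplot


def test_correlated_variables_have_zero_angle():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    df = pd.DataFrame(
        {"a": x, "b": 2 * x + 0.001 * rng.normal(size=200),
         "c": rng.normal(size=200)}
    )
    res = pca_biplot(df)
    assert res.loading_angle("a", "b") < 2.0


def test_explained_ratios_sum_to_one(comp2000):
    res = pca_biplot(comp2000.head(200))
    assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)


def test_independent_variables_share_variance():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(rng.normal(size=(5000, 11)),
                      columns=[f"v{i}" for i in range(11)])
    res = pca_biplot(df)
    assert res.explained_variance_ratio[0] == pytest.approx(1 / 11, abs=0.015)


# ------------------------------------------------------------- kmeans


def _blob_table(rng, n_per=20):
    """Three archetypes: low fat / high starch / high protein."""
    rows, labels = [], []
    archetypes = {
        "low_fat": dict(starch=50.0, crude_protein=22.0, moisture=12.0,
                        crude_fiber=6.5, crude_fat=3.05),
        "high_starch": dict(starch=57.0, crude_protein=21.0, moisture=11.5,
                            crude_fiber=5.8, crude_fat=3.6),
        "high_protein": dict(starch=45.0, crude_protein=28.0, moisture=12.5,
                             crude_fiber=7.5, crude_fat=3.9),
    }
    for name, arch in archetypes.items():
        for _ in range(n_per):
            rows.append({k: v + 0.05 * rng.normal() for k, v in arch.items()})
            labels.append(name)
    df = pd.DataFrame(rows, index=[f"S{i}" for i in range(len(rows))])
    return df, pd.Series(labels, index=df.index)


def test_planted_blobs_recovered(rng):
    df, truth = _blob_table(rng)
    labels, mapping = cluster_and_type(df, seed=0)
    assert set(mapping.values()) == {"low_fat", "high_starch", "high_protein"}
    predicted = labels.map(mapping)
    assert (predicted == truth).all()


def test_kmeans_single_cluster_inertia(rng):
    x = rng.normal(size=(30, 4))
    labels, centers, inertia = kmeans(x, k=1, seed=0)
    assert np.all(labels == 0)
    assert inertia == pytest.approx(((x - x.mean(axis=0)) ** 2).sum(), rel=1e-10)


def test_kmeans_matches_sklearn_on_blobs(rng):
    sk = pytest.importorskip("sklearn.cluster")
    df, _ = _blob_table(rng)
    x = df.to_numpy()
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    _, _, inertia = kmeans(z, k=3, seed=0, n_init=10)
    ref = sk.KMeans(n_clusters=3, n_init=10, random_state=0).fit(z)
    assert inertia == pytest.approx(ref.inertia_, rel=1e-6)


def test_labels_invariant_to_sample_order(rng):
    df, _ = _blob_table(rng)
    labels1, map1 = cluster_and_type(df, seed=0)
    perm = rng.permutation(len(df))
    df2 = df.iloc[perm]
    labels2, map2 = cluster_and_type(df2, seed=0)
    classes1 = labels1.map(map1)
    classes2 = labels2.map(map2).reindex(classes1.index)
    assert (classes1 == classes2).all()


def test_kmeans_k_larger_than_n_rejected(rng):
    with pytest.raises(ValueError):
        kmeans(rng.normal(size=(3, 2)), k=5)


# ------------------------------------------------------------- grading


def test_table_mean_composition_grades():
    df = pd.DataFrame(
        {"crude_fat": [3.53], "starch": [51.41], "crude_protein": [23.80]},
        index=["mean_pea"],
    )
    g = grade_samples(df)
    assert g.loc["mean_pea", "fat_level"] == 1
    assert g.loc["mean_pea", "starch_level"] == 2
    assert g.loc["mean_pea", "protein_level"] == 2


@pytest.mark.parametrize(
    "col,value,expected",
    [
        ("crude_fat", 5.0, 1),  # shared endpoint -> better grade
        ("crude_fat", 5.01, 2),
        ("crude_fat", 9.0, 3),
        ("starch", 55.0, 1),
        ("starch", 45.0, 2),
        ("starch", 44.99, 3),
        ("crude_protein", 25.0, 1),
        ("crude_protein", 20.0, 2),
        ("crude_protein", 19.99, 3),
    ],
)
def test_grading_boundaries(col, value, expected):
    base = {"crude_fat": 3.5, "starch": 50.0, "crude_protein": 22.0}
    base[col] = value
    g = grade_samples(pd.DataFrame([base]))
    level_col = {"crude_fat": "fat_level", "starch": "starch_level",
                 "crude_protein": "protein_level"}[col]
    assert g.iloc[0][level_col] == expected


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    fat=st.floats(0, 50, allow_nan=False),
    starch=st.floats(0, 100, allow_nan=False),
    protein=st.floats(0, 50, allow_nan=False),
)
def test_grading_total_and_deterministic(fat, starch, protein):
    df = pd.DataFrame(
        [{"crude_fat": fat, "starch": starch, "crude_protein": protein}]
    )
    g1, g2 = grade_samples(df), grade_samples(df)
    for col in ("fat_level", "starch_level", "protein_level"):
        assert g1.iloc[0][col] in (1, 2, 3)
        assert g1.iloc[0][col] == g2.iloc[0][col]


def test_negative_composition_rejected():
    df = pd.DataFrame([{"crude_fat": -1.0, "starch": 50.0, "crude_protein": 22.0}])
    with pytest.raises(ValueError):
        grade_samples(df)


def test_grading_summary_with_classes(rng):
    df, _ = _blob_table(rng)
    labels, mapping = cluster_and_type(df, seed=0)
    g = grade_samples(df, variety_class=labels.map(mapping))
    summary = grading_summary(g)
    assert sum(summary["variety_class"].values()) == len(df)
    assert set(g["recommended_use"].dropna()) <= {
        "Low-Fat Functional Foods",
        "Used in canned goods, dried fruit, and other products, or processed "
        "into pea flour for bread, biscuits, and other products",
        "Pea protein powder or pea protein meat substitute",
    }
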