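import numpy as np
import pandas as pd
import pytest

from conftest import random_table, toy_metadata
from relicdna.community_stats import (
    DistanceMatrix,
    bray_curtis,
    chao1,
    clr_transform,
    differential_abundance,
    euclidean_clr,
    holm_adjust,
    jaccard,
    pcoa,
    permanova,
    procrustes,
    richness,
    variance_partition,
)
from relicdna.io_tables import AsvCountTable, ParameterError


def small_table(data, samples=None):
    df = pd.DataFrame(
        np.asarray(data).T,
        index=[f"A{i}" for i in range(np.asarray(data).shape[1])],
        columns=samples or [f"s{j}" for j in range(np.asarray(data).shape[0])],
    )
    return AsvCountTable(df)


# ---------------------------------------------------------------- distances


def test_bray_curtis_hand_example():
    t = small_table([[1, 2, 3], [3, 2, 1]])
    d = bray_curtis(t).matrix
    assert d[0, 1] == pytest.approx(1 / 3)  # sum|x-y|=4, sum(x+y)=12
    assert d[0, 0] == 0


def test_jaccard_hand_example():
    t = small_table([[1, 5, 0], [0, 2, 7]])  # A={a,b}, B={b,c}
    d = jaccard(t).matrix
    assert d[0, 1] == pytest.approx(2 / 3)


def test_identical_samples_zero_distance():
    t = small_table([[4, 1, 0], [4, 1, 0]])
    assert bray_curtis(t).matrix[0, 1] == 0
    assert jaccard(t).matrix[0, 1] == 0


def test_distances_bounded_and_symmetric_on_random_tables():
    meta = toy_metadata()
    rng = np.random.default_rng(0)
    for _ in range(10):
        t = random_table(meta, 25, rng)
        for dm in (bray_curtis(t), jaccard(t)):
            m = dm.matrix
            assert (m >= 0).all() and (m <= 1 + 1e-12).all()
            np.testing.assert_allclose(m, m.T)
            assert np.abs(np.diag(m)).max() == 0


def test_distances_match_scipy():
    from scipy.spatial.distance import pdist, squareform

    meta = toy_metadata()
    t = random_table(meta, 30, np.random.default_rng(1))
    X = t.counts.to_numpy(float).T
    np.testing.assert_allclose(
        bray_curtis(t).matrix, squareform(pdist(X, "braycurtis")), atol=1e-12
    )
    np.testing.assert_allclose(
        jaccard(t).matrix, squareform(pdist(X > 0, "jaccard")), atol=1e-12
    )


# ---------------------------------------------------------------- CLR


def test_clr_identities():
    t = small_table([[1, 1, 1, 1]])
    np.testing.assert_allclose(clr_transform(t, 0.0).to_numpy(), 0.0, atol=1e-12)
    t2 = small_table([[1, 4]])
    z = clr_transform(t2, 0.0).to_numpy()[:, 0]
    np.testing.assert_allclose(z, [-np.log(2), np.log(2)])


def test_clr_columns_sum_to_zero_and_pseudocount_contract():
    meta = toy_metadata()
    t = random_table(meta, 20, np.random.default_rng(2))
    z = clr_transform(t, 0.5)
    np.testing.assert_allclose(z.sum(axis=0), 0.0, atol=1e-9)
    with pytest.raises(ParameterError):
        clr_transform(t, -1.0)
    with pytest.raises(ParameterError):
        clr_transform(t, 0.0)  # zeros present


# ---------------------------------------------------------------- PERMANOVA


WORKED_D = np.array(
    [[0, 1, 3, 3], [1, 0, 3, 3], [3, 3, 0, 1], [3, 3, 1, 0]], float
)


def test_permanova_worked_example_exact():
    dm = DistanceMatrix(list("wxyz"), WORKED_D, "euclidean")
    res = permanova(dm, {"g": ["A", "A", "B", "B"]}, exhaustive=True)
    assert res.ss_total == pytest.approx(9.5)
    assert res.table["SS"].iloc[0] == pytest.approx(8.5)
    assert res.table["pseudo_F"].iloc[0] == pytest.approx(17.0)
    assert res.table["R2"].iloc[0] == pytest.approx(8.5 / 9.5)
    assert res.table["p"].iloc[0] == pytest.approx(1 / 3)


def test_permanova_matches_scikit_bio():
    from skbio.stats.distance import DistanceMatrix as SkbioDM
    from skbio.stats.distance import permanova as skbio_permanova

    rng = np.random.default_rng(3)
    X = rng.standard_normal((12, 4))
    X[:6] += 1.5
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    ids = [f"s{i}" for i in range(12)]
    labels = ["a"] * 6 + ["b"] * 6
    ours = permanova(DistanceMatrix(ids, d, "euclidean"), {"g": labels},
                     n_perm=999, seed=0)
    theirs = skbio_permanova(SkbioDM(d, ids), grouping=labels, permutations=999)
    assert ours.table["pseudo_F"].iloc[0] == pytest.approx(
        theirs["test statistic"], rel=1e-9
    )


def test_permanova_two_factor_partition_sums(small_dataset):
    table, meta, _, _ = small_dataset
    from relicdna.filtering import filter_table

    filtered, _ = filter_table(table, meta)
    dm = jaccard(filtered)
    res = permanova(
        dm,
        {"stage": meta.table["stage"].astype(str),
         "dna_type": meta.table["dna_type"]},
        interaction=True, n_perm=99, seed=1,
    )
    total = res.table["SS"].sum() + res.ss_residual
    assert total == pytest.approx(res.ss_total, abs=1e-9)
    assert ((res.table["R2"] >= 0) & (res.table["R2"] <= 1)).all()
    assert (res.table["p"] > 0).all()


def test_permanova_reproducible_and_contract_errors():
    dm = DistanceMatrix(list("wxyz"), WORKED_D, "euclidean")
    a = permanova(dm, {"g": ["A", "A", "B", "B"]}, n_perm=99, seed=5)
    b = permanova(dm, {"g": ["A", "A", "B", "B"]}, n_perm=99, seed=5)
    assert a.table["p"].iloc[0] == b.table["p"].iloc[0]
    with pytest.raises(ValueError, match="single level"):
        permanova(dm, {"g": ["A", "A", "A", "A"]})
    with pytest.raises(ValueError, match="aliased"):
        permanova(dm, {"g": ["A", "A", "B", "B"], "h": ["A", "A", "B", "B"]},
                  n_perm=9)


def test_permanova_null_calibration_small():
    """Type-I error at alpha = 0.05 under permuted labels (lighter replica
    of the full calibration: 300 datasets)."""
    rng = np.random.default_rng(123)
    labels = np.repeat(["a", "b", "c"], 9)
    hits = 0
    N = 300
    for _ in range(N):
        X = rng.standard_normal((27, 5))
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{j}" for j in range(27)], d, "euclidean")
        res = permanova(dm, {"g": rng.permutation(labels)}, n_perm=99,
                        seed=int(rng.integers(2**31)))
        hits += res.table["p"].iloc[0] <= 0.05
    assert 0.02 <= hits / N <= 0.09


# ---------------------------------------------------------------- variance partition


def test_variance_partition_identities():
    rng = np.random.default_rng(4)
    fa = np.repeat(["I", "III", "V"], 9)
    fb = np.tile(np.repeat(["x", "y", "z"], 3), 3)
    # response equal to factor A group means -> R2_A = 1
    means = {"I": 1.0, "III": 5.0, "V": -2.0}
    Y = pd.DataFrame(np.tile([means[v] for v in fa], (4, 1)))
    vp = variance_partition(Y, fa, fb)
    assert vp.table.loc["A", "R2"] == pytest.approx(1.0)
    # nested-model identity on noisy data
    Y2 = pd.DataFrame(rng.standard_normal((10, 27)))
    vp2 = variance_partition(Y2, fa, fb)
    lhs = vp2.table.loc["A+B", "R2"]
    rhs = (
        vp2.table.loc["unique_A", "R2"]
        + vp2.table.loc["unique_B", "R2"]
        + vp2.table.loc["shared", "R2"]
    )
    assert lhs == pytest.approx(rhs, abs=1e-9)


def test_variance_partition_null_adjusted_r2_near_zero():
    rng = np.random.default_rng(5)
    fa = np.repeat(["I", "III", "V"], 9)
    fb = np.tile(np.repeat(["x", "y", "z"], 3), 3)
    vals = [
        variance_partition(
            pd.DataFrame(rng.standard_normal((20, 27))), fa, fb
        ).table.loc["A+B", "adjusted_R2"]
        for _ in range(300)
    ]
    assert abs(np.mean(vals)) < 0.02


# ---------------------------------------------------------------- Procrustes


def test_procrustes_identity_and_similarity_invariance():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((15, 2))
    r = procrustes(X, X, n_perm=99, seed=0)
    assert r.m2 == pytest.approx(0.0, abs=1e-9)
    assert r.correlation == pytest.approx(1.0, abs=1e-9)
    theta = np.pi / 2
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    Y = X @ R.T + np.array([5.0, -3.0])
    r2 = procrustes(X, Y, n_perm=99, seed=0)
    assert r2.m2 == pytest.approx(0.0, abs=1e-9)


def test_procrustes_matches_scipy_m2():
    from scipy.spatial import procrustes as scipy_procrustes

    rng = np.random.default_rng(7)
    X, Y = rng.standard_normal((10, 3)), rng.standard_normal((10, 3))
    _, _, disparity = scipy_procrustes(X, Y)
    r = procrustes(X, Y, n_perm=9, seed=0)
    assert r.m2 == pytest.approx(disparity, rel=1e-9)


def test_protest_null_calibration_small():
    rng = np.random.default_rng(8)
    hits, N = 0, 300
    for _ in range(N):
        r = procrustes(
            rng.standard_normal((20, 3)), rng.standard_normal((20, 3)),
            n_perm=99, seed=int(rng.integers(2**31)),
        )
        hits += r.p <= 0.05
    assert 0.02 <= hits / N <= 0.09


# ---------------------------------------------------------------- PCoA


def test_pcoa_equilateral_and_collinear_configurations():
    # 3 equidistant points: two equal positive eigenvalues
    d = np.ones((3, 3)) - np.eye(3)
    res = pcoa(DistanceMatrix(list("abc"), d, "euclidean"))
    ev = res.eigenvalues
    assert ev[0] == pytest.approx(ev[1])
    assert ev[0] > 0
    # collinear points: one dominant positive eigenvalue
    x = np.array([0.0, 1.0, 2.5, 4.0])
    d2 = np.abs(x[:, None] - x[None, :])
    res2 = pcoa(DistanceMatrix(list("abcd"), d2, "euclidean"))
    assert res2.eigenvalues[0] > 0
    assert np.abs(res2.eigenvalues[1:]).max() <= 1e-9 * res2.eigenvalues[0] + 1e-9


def test_pcoa_reproduces_euclidean_embeddable_distances():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((10, 3))
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    res = pcoa(DistanceMatrix([f"s{i}" for i in range(10)], d, "euclidean"))
    C = res.coordinates.to_numpy()
    d2 = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
    np.testing.assert_allclose(d2, d, atol=1e-6)


def test_pcoa_matches_scikit_bio(small_dataset):
    from skbio.stats.ordination import pcoa as skbio_pcoa

    table, meta, _, _ = small_dataset
    from relicdna.filtering import filter_table

    filtered, _ = filter_table(table, meta)
    dm = bray_curtis(filtered)
    ours = pcoa(dm)
    theirs = skbio_pcoa(dm.matrix, number_of_dimensions=3)
    np.testing.assert_allclose(
        np.sort(ours.eigenvalues)[::-1][:3], theirs.eigvals.values[:3], atol=1e-8
    )


# ---------------------------------------------------------------- richness


def test_chao1_hand_example_and_invariants():
    # S_obs = 10, f1 = 4, f2 = 2 -> 10 + 4*3/(2*3) = 12
    pooled = [1, 1, 1, 1, 2, 2, 3, 5, 9, 20]
    est, se = chao1(pooled)
    assert est == pytest.approx(12.0)
    assert se > 0
    est2, _ = chao1([3, 4, 5])  # no singletons/doubletons
    assert est2 == 3.0
    assert chao1([0, 0, 5])[0] == 1.0


def test_chao1_never_below_observed_on_subsamples():
    rng = np.random.default_rng(10)
    props = rng.dirichlet(np.full(200, 0.3))
    for depth in (100, 500, 2000):
        pooled = rng.multinomial(depth, props)
        est, _ = chao1(pooled)
        assert est >= (pooled > 0).sum()


def test_richness_per_group(small_dataset):
    table, meta, _, _ = small_dataset
    from relicdna.filtering import filter_table

    filtered, _ = filter_table(table, meta)
    r = richness(filtered, meta)
    assert set(r.index) == set(meta.group_ids)
    assert (r["chao1"] >= r["s_obs"]).all()


# ---------------------------------------------------------------- differential abundance


def test_holm_hand_example_and_monotonicity():
    adj = holm_adjust([0.01, 0.03, 0.04])
    np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])
    rng = np.random.default_rng(11)
    p = rng.random(50)
    a = holm_adjust(p)
    assert (a >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(a[order]) >= -1e-15).all()


def test_differential_abundance_recovers_planted_effect():
    rng = np.random.default_rng(12)
    S, reps, depth = 200, 4, 8000
    base = np.exp(rng.standard_normal(S))
    base /= base.sum()
    planted = rng.choice(np.where(base >= np.median(base))[0], 5, replace=False)
    cols, labels = {}, []
    for s in ("I", "III", "V"):
        p = base.copy()
        if s == "V":
            p[planted] *= 4.0
        p /= p.sum()
        for r in range(reps):
            cols[f"{s}_r{r}"] = rng.multinomial(depth, p)
            labels.append(s)
    t = AsvCountTable(pd.DataFrame(cols, index=[f"A{i}" for i in range(S)]))
    res = differential_abundance(clr_transform(t), np.array(labels))
    hit = {f"A{i}" for i in planted} & set(res.significant_asvs)
    assert len(hit) >= 4
    assert (res.effects["p_holm"] >= res.effects["p_raw"] - 1e-15).all()


def test_differential_abundance_zero_variance_and_contracts():
    y = pd.DataFrame(
        np.vstack([np.zeros(6), np.random.default_rng(13).standard_normal(6)]),
        index=["flat", "noisy"],
        columns=[f"s{j}" for j in range(6)],
    )
    res = differential_abundance(y, np.repeat(["I", "V"], 3))
    assert (res.effects.loc["flat"]["p_raw"] == 1.0).all()
    with pytest.raises(ValueError, match="two stages"):
        differential_abundance(y, np.repeat(["I"], 6))


def test_euclidean_clr_matches_direct_computation():
    meta = toy_metadata()
    t = random_table(meta, 15, np.random.default_rng(14))
    d = euclidean_clr(t).matrix
    z = clr_transform(t).to_numpy().T
    i, j = 3, 17
    assert d[i, j] == pytest.approx(np.linalg.norm(z[i] - z[j]))


# hypothesis property: Holm adjustment is monotone and never below raw p
from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    p=st.lists(
        st.floats(min_value=1e-9, max_value=1.0, allow_nan=False),
        min_size=1, max_size=30,
    )
)
def test_holm_property(p):
    p = np.asarray(p)
    adj = holm_adjust(p)
    assert (adj <= 1.0 + 1e-12).all()
    assert (adj >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
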