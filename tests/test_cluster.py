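import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

import mircohort as mc


def brute_force_wpgma(D):
    """Independent dict-based WPGMA with the same node-index tie-break."""
    n = D.shape[0]
    dist = {frozenset((i, j)): float(D[i, j])
            for i in range(n) for j in range(i + 1, n)}
    alive = set(range(n))
    merges = []
    nxt = n
    while len(alive) > 1:
        best = min(dist.items(),
                   key=lambda kv: (kv[1], tuple(sorted(kv[0]))))
        pair, h = best
        a, b = sorted(pair)
        new = nxt
        nxt += 1
        for c in alive - {a, b}:
            dist[frozenset((new, c))] = (
                dist.pop(frozenset((a, c))) +
                dist.pop(frozenset((b, c)))) / 2
        del dist[pair]
        alive -= {a, b}
        alive.add(new)
        merges.append((a, b, h, new))
    return merges


def dmat(values, labels):
    return pd.DataFrame(np.asarray(values, dtype=float), index=labels,
                        columns=labels)


def test_euclidean_distance_cases():
    m = pd.DataFrame([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0]],
                     index=list("abc"))
    D = mc.euclidean_distances(m, "rows")
    assert D.loc["a", "c"] == 0.0
    assert D.loc["a", "b"] == 5.0
    assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)


def test_euclidean_triangle_inequality():
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.normal(size=(5, 7)))
    D = mc.euclidean_distances(m, "rows").to_numpy()
    for i in range(5):
        for j in range(5):
            for k in range(5):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


def test_wpgma_three_leaf_hand_case():
    D = dmat([[0, 1, 4], [1, 0, 4], [4, 4, 0]], list("ABC"))
    dend = mc.wpgma_cluster(D)
    assert dend.merges == [(0, 1, 1.0, 3), (2, 3, 4.0, 4)]
    assert dend.to_newick() == "(C:4,(A:1,B:1):3);"


def test_wpgma_equal_distances_tie_break():
    D = dmat(np.ones((4, 4)) - np.eye(4), list("abcd"))
    dend = mc.wpgma_cluster(D)
    # smallest node-index pairs first; all heights equal
    assert [m[:2] for m in dend.merges] == [(0, 1), (2, 3), (4, 5)]
    assert all(m[2] == 1.0 for m in dend.merges)


def test_wpgma_matches_bruteforce_oracle():
    rng = np.random.default_rng(1)
    for trial in range(20):
        n = 6
        M = rng.random((n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"L{i}" for i in range(n)]
        got = mc.wpgma_cluster(dmat(D, labels)).merges
        want = brute_force_wpgma(D)
        assert len(got) == len(want)
        for (a, b, h, new), (a2, b2, h2, new2) in zip(got, want):
            assert (a, b, new) == (a2, b2, new2)
            assert abs(h - h2) < 1e-12


def test_wpgma_matches_scipy_weighted_linkage():
    from scipy.spatial.distance import squareform
    rng = np.random.default_rng(2)
    for trial in range(10):
        m = rng.normal(size=(8, 5))
        D = mc.euclidean_distances(pd.DataFrame(m), "rows")
        Z = mc.wpgma_cluster(D).to_scipy_linkage()
        ref = linkage(squareform(D.to_numpy()), method="weighted")
        np.testing.assert_allclose(Z[:, 2], ref[:, 2], atol=1e-10)
        np.testing.assert_allclose(Z[:, 3], ref[:, 3])


def test_wpgma_row_order_invariance():
    rng = np.random.default_rng(3)
    m = pd.DataFrame(rng.normal(size=(7, 4)),
                     index=[f"r{i}" for i in range(7)])
    D1 = mc.euclidean_distances(m, "rows")
    heights1 = sorted(h for _, _, h, _ in mc.wpgma_cluster(D1).merges)
    perm = rng.permutation(m.index)
    D2 = mc.euclidean_distances(m.loc[perm], "rows")
    heights2 = sorted(h for _, _, h, _ in mc.wpgma_cluster(D2).merges)
    np.testing.assert_allclose(heights1, heights2)


def test_wpgma_rejects_asymmetric_input():
    D = dmat([[0, 1], [2, 0]], list("ab"))
    with pytest.raises(ValueError, match="symmetric"):
        mc.wpgma_cluster(D)


def test_two_way_cluster_shapes(small_quant):
    logged = mc.log2_transform(small_quant.counts.iloc[:30])
    rows, cols = mc.two_way_cluster(logged)
    assert rows.n_leaves == 30 and cols.n_leaves == logged.shape[1]
    assert rows.to_newick().endswith(";")


# -- concordance ------------------------------------------------------------

def test_replicate_identity():
    x = pd.Series(np.linspace(1, 12, 40))
    out = mc.replicate_concordance(x, x.copy())
    assert out == {"slope": 1.0, "intercept": 0.0, "r_squared": 1.0}


def test_replicate_global_doubling_shifts_intercept():
    """run2 = 2 x run1 before logging: slope 1, intercept 1 on log2."""
    raw = np.linspace(10, 5000, 50)
    out = mc.replicate_concordance(pd.Series(np.log2(raw)),
                                   pd.Series(np.log2(2 * raw)))
    assert abs(out["slope"] - 1.0) < 1e-9
    assert abs(out["intercept"] - 1.0) < 1e-9
    assert out["r_squared"] > 0.999999


def test_replicate_independent_noise_has_no_fit():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        out = mc.replicate_concordance(pd.Series(rng.normal(size=500)),
                                       pd.Series(rng.normal(size=500)))
        hits += out["r_squared"] < 0.05
    assert hits >= 19


def test_replicate_too_few_points():
    with pytest.raises(ValueError):
        mc.replicate_concordance(pd.Series([1.0, 2.0]),
                                 pd.Series([1.0, 2.0]))


def test_technical_replicates_concord(default_cohort, default_quant):
    """Re-sequenced libraries give near-identity per-miRNA totals at the
    default cohort depth."""
    cfg, ann, cohort = default_cohort
    rep = mc.generate_cohort(ann, cfg, run_id=1)
    quant2 = mc.build_count_matrix(rep.alignments, ann)
    out = {}
    for run, quant in (("run1", default_quant), ("run2", quant2)):
        f = mc.factors_from_table(quant.factors, "mirna_mapped")
        norm = mc.normalize(quant.counts, f)
        out[run] = mc.log2_transform(norm).sum(axis=1)
    fit = mc.replicate_concordance(out["run1"], out["run2"])
    assert fit["r_squared"] > 0.95
    assert 0.9 < fit["slope"] < 1.1


@pytest.mark.parametrize("ct, ref, expected", [
    (25.0, 20.0, 0.03125), (20.0, 20.0, 1.0), (18.0, 20.0, 4.0),
])
def test_delta_ct_formula(ct, ref, expected):
    assert mc.delta_ct_expression(ct, ref) == expected


def test_delta_ct_missing_propagates():
    out = mc.delta_ct_expression(np.array([np.nan, 25.0]),
                                 np.array([20.0, 20.0]))
    assert np.isnan(out[0]) and out[1] == 0.03125


def test_platform_regression_cases():
    samples = [f"s{i}" for i in range(20)]
    x = np.linspace(1, 5, 20)
    qpcr = pd.DataFrame({"perfect": x, "flat": x,
                         "sparse": [np.nan] * 18 + [1.0, 2.0]},
                        index=samples)
    seq = pd.DataFrame({"perfect": 2 * x + 1,
                        "flat": np.ones(20),
                        "sparse": x}, index=samples)
    out = mc.platform_regression(qpcr, seq)
    assert out.loc["perfect", "r_squared"] == 1.0
    assert out.loc["flat", "r_squared"] == 0.0
    assert np.isnan(out.loc["sparse", "r_squared"])


def test_platform_regression_recovers_known_r2():
    """Pairs built with true R^2 = 0.5 are estimated within +/-0.08."""
    rng = np.random.default_rng(8)
    n = 500
    x = rng.normal(size=n)
    y = x + rng.normal(size=n)   # var explained = 1 / (1 + 1)
    out = mc.platform_regression(
        pd.DataFrame({"a": x}), pd.DataFrame({"a": y}))
    assert abs(out.loc["a", "r_squared"] - 0.5) < 0.08
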