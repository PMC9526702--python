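"""Statistics contracts: S0 volcano, BH, chi-squared, PCA, clustering, Spearman."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import nichedeconv as nd
from nichedeconv.stats import VolcanoParams, _pearson_chi2

from conftest import make_matrix


# -- S0-moderated volcano ----------------------------------------------------


def test_s0_zero_reduces_to_textbook_pooled_t():
    a = np.array([[1.0, 2.0, 3.0, 4.0], [10.0, 11.0, 12.0, 13.0]])
    b = np.array([[2.0, 2.5, 3.5, 5.0], [20.0, 22.0, 21.0, 19.0]])
    m = make_matrix(np.hstack([a, b]))
    groups_a = [f"S{j:03d}" for j in range(4)]
    groups_b = [f"S{j:03d}" for j in range(4, 8)]
    res = nd.sam_test(m, groups_a, groups_b, VolcanoParams(s0=0.0, n_perm=10, fdr=0.5))
    for i in range(2):
        na = nb = 4
        sp2 = ((na - 1) * a[i].var(ddof=1) + (nb - 1) * b[i].var(ddof=1)) / (na + nb - 2)
        t_hand = (a[i].mean() - b[i].mean()) / (np.sqrt(sp2) * np.sqrt(1 / na + 1 / nb))
        assert abs(res.table["t_s0"].iloc[i] - t_hand) < 1e-12
    # cross-check against scipy's pooled t-test
    t_scipy = sps.ttest_ind(a, b, axis=1, equal_var=True).statistic
    np.testing.assert_allclose(res.table["t_s0"].to_numpy(), t_scipy, atol=1e-12)


def test_null_data_yields_few_significant_calls():
    rng = np.random.default_rng(0)
    counts = []
    for seed in range(3):
        vals = rng.normal(0, 1, size=(2000, 40))
        m = make_matrix(vals)
        ga = [f"S{j:03d}" for j in range(20)]
        gb = [f"S{j:03d}" for j in range(20, 40)]
        res = nd.sam_test(m, ga, gb, VolcanoParams(s0=0.1, fdr=0.05, n_perm=100, seed=seed))
        counts.append(int(res.table["significant"].sum()))
    bound = 0.05 * 2000 + 3 * np.sqrt(0.05 * 2000)
    assert all(c <= bound for c in counts)


def test_spiked_proteins_are_recovered():
    """delta=2 spikes against unit-free noise are flagged at FDR 0.05, s0 0.1."""
    rng = np.random.default_rng(1)
    baseline = rng.normal(25, 2, size=500)
    vals = baseline[:, None] + rng.normal(0, 0.5, size=(500, 40))
    m = make_matrix(vals)
    ga = [f"S{j:03d}" for j in range(20)]
    gb = [f"S{j:03d}" for j in range(20, 40)]
    spiked_ids = list(m.protein_ids[:50])
    spiked, rec = nd.spike_differential(m, ga, spiked_ids, 2.0)
    res = nd.sam_test(spiked, ga, gb, VolcanoParams(s0=0.1, fdr=0.05, n_perm=100, seed=3))
    recovered = res.table.loc[rec.proteins, "significant"].mean()
    assert recovered >= 0.8
    false_calls = res.table.drop(index=rec.proteins)["significant"].sum()
    assert false_calls <= 0.05 * 450 + 3 * np.sqrt(0.05 * 450)


def test_sam_test_rejects_overlapping_or_tiny_groups(small_bulk):
    m = make_matrix(np.random.default_rng(0).normal(size=(10, 6)))
    ids = list(m.sample_ids)
    with pytest.raises(ValueError, match="disjoint"):
        nd.sam_test(m, ids[:3], ids[2:], VolcanoParams(n_perm=10))
    with pytest.raises(ValueError, match="2 samples"):
        nd.sam_test(m, ids[:1], ids[1:], VolcanoParams(n_perm=10))


# -- one-tailed marker contrasts with BH -------------------------------------


def test_null_one_tailed_contrast_centers_at_half():
    rng = np.random.default_rng(4)
    vals = np.tile(rng.normal(20, 1, size=100)[:, None], (1, 10)) + rng.normal(
        0, 0.01, size=(100, 10)
    )
    m = make_matrix(vals)
    res = nd.marker_contrast(m, [f"S{j:03d}" for j in range(5)],
                             [f"S{j:03d}" for j in range(5, 10)], "greater")
    assert abs(res["p"].mean() - 0.5) < 0.1
    assert res["q"].median() > 0.8


def _hand_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH with min-accumulation, written out explicitly."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def test_bh_q_values_match_hand_computation():
    rng = np.random.default_rng(6)
    vals = rng.normal(20, 1, size=(100, 12))
    vals[:10, :6] += 3.0  # strong one-sided signal in 10 proteins
    m = make_matrix(vals)
    res = nd.marker_contrast(m, [f"S{j:03d}" for j in range(6)],
                             [f"S{j:03d}" for j in range(6, 12)], "greater")
    np.testing.assert_allclose(res["q"], _hand_bh(res["p"].to_numpy()), atol=1e-12)
    # unmonotonized value at the 10th smallest p equals p_(10) * m / 10 when
    # it is the running minimum
    p_sorted = np.sort(res["p"].to_numpy())
    assert _hand_bh(res["p"].to_numpy()).min() <= p_sorted[9] * 100 / 10 + 1e-12


def test_bh_is_monotone_and_order_invariant():
    rng = np.random.default_rng(7)
    vals = rng.normal(20, 1, size=(60, 8))
    m = make_matrix(vals)
    ga, gb = [f"S{j:03d}" for j in range(4)], [f"S{j:03d}" for j in range(4, 8)]
    res = nd.marker_contrast(m, ga, gb, "less")
    srt = res.sort_values("p")
    assert (np.diff(srt["q"].to_numpy()) >= -1e-15).all()
    perm = list(rng.permutation(m.protein_ids))
    res2 = nd.marker_contrast(m.subset_proteins(perm), ga, gb, "less")
    np.testing.assert_allclose(res2.loc[res.index, "q"], res["q"], atol=1e-15)


def test_degenerate_zero_variance_gets_continuity_p():
    vals = np.vstack([np.full(8, 5.0), np.random.default_rng(0).normal(size=8)])
    m = make_matrix(vals)
    res = nd.marker_contrast(m, [f"S{j:03d}" for j in range(4)],
                             [f"S{j:03d}" for j in range(4, 8)], "greater")
    assert res["p"].iloc[0] == 0.5


# -- chi-squared enrichment --------------------------------------------------


def _label_series(counts: dict[tuple[str, str], int]):
    dom, sub = {}, {}
    k = 0
    for (s, n), c in counts.items():
        for _ in range(c):
            dom[f"x{k}"] = n
            sub[f"x{k}"] = s
            k += 1
    return pd.Series(dom), pd.Series(sub)


def test_chi2_zero_when_observed_equals_expected():
    dom, sub = _label_series({
        ("proneural", "IT"): 10, ("proneural", "CT"): 10,
        ("mesenchymal", "IT"): 10, ("mesenchymal", "CT"): 10,
    })
    res = nd.chi_squared_niche_enrichment(dom, sub)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    # margins of observed and expected agree
    np.testing.assert_allclose(res.observed.sum(axis=1), res.expected.sum(axis=1), atol=1e-9)
    np.testing.assert_allclose(res.observed.sum(axis=0), res.expected.sum(axis=0), atol=1e-9)


def test_chi2_matches_hand_formula_on_2x2():
    obs = np.array([[10.0, 5.0], [2.0, 13.0]])
    chi2, df, p = _pearson_chi2(obs)
    row, col, tot = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True), obs.sum()
    exp = row @ col / tot
    assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-9)
    assert df == 1
    chi2_sp, p_sp, df_sp, _ = sps.chi2_contingency(obs, correction=False)
    assert chi2 == pytest.approx(chi2_sp, abs=1e-9)
    assert p == pytest.approx(p_sp, abs=1e-9)


def test_chi2_matches_closed_form_on_3x5():
    rng = np.random.default_rng(11)
    obs = rng.integers(1, 30, size=(3, 5)).astype(float)
    chi2, df, p = _pearson_chi2(obs)
    exp = obs.sum(1, keepdims=True) @ obs.sum(0, keepdims=True) / obs.sum()
    assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-9)
    assert df == 8
    chi2_sp, p_sp, _, _ = sps.chi2_contingency(obs, correction=False)
    assert chi2 == pytest.approx(chi2_sp, abs=1e-9) and p == pytest.approx(p_sp, abs=1e-9)


def test_focus_collapse_builds_correct_2x2():
    dom, sub = _label_series({
        ("proneural", "IT"): 10, ("proneural", "CT"): 5,
        ("mesenchymal", "IT"): 2, ("mesenchymal", "CT"): 13,
    })
    res = nd.chi_squared_niche_enrichment(dom, sub, focus=("proneural", "IT"))
    np.testing.assert_array_equal(
        res.focus_observed.to_numpy(), [[10, 5], [2, 13]]
    )
    chi2_hand, _, p_hand = _pearson_chi2(np.array([[10.0, 5.0], [2.0, 13.0]]))
    assert res.focus_chi2 == pytest.approx(chi2_hand, abs=1e-12)
    assert res.focus_p == pytest.approx(p_hand, abs=1e-12)


def test_small_expected_cells_warn():
    dom, sub = _label_series({
        ("proneural", "IT"): 1, ("proneural", "CT"): 30,
        ("mesenchymal", "CT"): 30,
    })
    with pytest.warns(UserWarning, match="expected cell"):
        nd.chi_squared_niche_enrichment(dom, sub)


# -- PCA ---------------------------------------------------------------------


def test_pca_separates_two_point_clusters():
    rng = np.random.default_rng(13)
    base = rng.normal(0, 1, size=50)
    cluster_a = np.tile(base[:, None], (1, 6))
    cluster_b = np.tile((base + 4)[:, None], (1, 6))
    m = make_matrix(np.hstack([cluster_a, cluster_b]), scale_tag="log2")
    scores, evr = nd.pca_embedding(m, 2)
    pc1 = scores["PC1"].to_numpy()
    assert (pc1[:6] * pc1[6:] < 0).all()  # clusters on opposite sides
    assert evr[0] > 0.999  # all variance is between clusters
    assert evr.sum() <= 1 + 1e-12


def test_pca_duplicate_sample_gets_identical_scores(processed_pair):
    _, bulk_p = processed_pair
    m = bulk_p.matrix
    dup = m.values.copy()
    dup["DUP"] = dup[m.sample_ids[0]]
    mm = nd.ProteinMatrix(values=dup, scale_tag="zscored")
    scores, _ = nd.pca_embedding(mm, 2)
    np.testing.assert_allclose(
        scores.loc["DUP"].to_numpy(), scores.iloc[0].to_numpy(), atol=1e-9
    )


def test_pca_rejects_too_many_components():
    m = make_matrix(np.random.default_rng(0).normal(size=(10, 4)), scale_tag="log2")
    with pytest.raises(ValueError):
        nd.pca_embedding(m, 5)


# -- Pearson hierarchical clustering -----------------------------------------


def test_identical_samples_merge_first_at_zero_distance():
    rng = np.random.default_rng(14)
    x = rng.normal(size=30)
    vals = np.column_stack([x, x, rng.normal(size=30)])
    m = make_matrix(vals, scale_tag="log2")
    res = nd.pearson_hierarchical_clustering(m)
    assert res.distance.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert set(res.linkage[0, :2].astype(int)) == {0, 1}
    assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_distance_matrix_symmetric_zero_diagonal(processed_pair):
    _, bulk_p = processed_pair
    res = nd.pearson_hierarchical_clustering(bulk_p.matrix)
    d = res.distance.to_numpy()
    np.testing.assert_allclose(d, d.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-12)


def test_three_sample_average_linkage_matches_hand_computation():
    rng = np.random.default_rng(15)
    vals = rng.normal(size=(40, 3))
    vals[:, 1] = vals[:, 0] + rng.normal(0, 0.2, size=40)  # samples 0,1 similar
    m = make_matrix(vals, scale_tag="log2")
    res = nd.pearson_hierarchical_clustering(m)
    d = res.distance.to_numpy()
    assert set(res.linkage[0, :2].astype(int)) == {0, 1}
    assert res.linkage[0, 2] == pytest.approx(d[0, 1], abs=1e-12)
    assert res.linkage[1, 2] == pytest.approx((d[0, 2] + d[1, 2]) / 2, abs=1e-12)


def test_constant_column_rejected():
    vals = np.column_stack([np.ones(10), np.random.default_rng(0).normal(size=10)])
    with pytest.raises(ValueError, match="constant"):
        nd.pearson_hierarchical_clustering(make_matrix(vals, scale_tag="log2"))


# -- Spearman group correlation ----------------------------------------------


def _pair(values_a, values_b, group):
    a = make_matrix(values_a, scale_tag="log2")
    b = nd.ProteinMatrix(
        values=pd.DataFrame(values_b, index=a.protein_ids,
                            columns=[f"T{j}" for j in range(values_b.shape[1])]),
        scale_tag="log2",
    )
    groups = pd.Series({**{s: group for s in a.sample_ids},
                        **{s: group for s in b.values.columns}})
    return a, b, groups


def test_spearman_monotone_transform_gives_one():
    x = np.random.default_rng(16).normal(size=(20, 1))
    a, b, groups = _pair(x, np.exp(x * 0.5), "g")
    rho = nd.spearman_group_correlation(a, b, groups)
    assert rho["g"] == pytest.approx(1.0)


def test_spearman_reversed_ranks_give_minus_one():
    x = np.random.default_rng(17).normal(size=(15, 1))
    a, b, groups = _pair(x, -x, "g")
    assert nd.spearman_group_correlation(a, b, groups)["g"] == pytest.approx(-1.0)


def test_spearman_with_ties_matches_hand_rank_computation():
    xa = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
    xb = np.array([2.0, 1.0, 4.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0, 9.0])
    a, b, groups = _pair(xa[:, None], xb[:, None], "g")
    rho = nd.spearman_group_correlation(a, b, groups)["g"]

    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        srt = v[order]
        while i < len(v):
            j = i
            while j < len(v) and srt[j] == srt[i]:
                j += 1
            ranks[order[i:j]] = np.mean(np.arange(i, j) + 1)
            i = j
        return ranks

    ra, rb = avg_ranks(xa), avg_ranks(xb)
    hand = np.sum((ra - ra.mean()) * (rb - rb.mean())) / np.sqrt(
        np.sum((ra - ra.mean()) ** 2) * np.sum((rb - rb.mean()) ** 2)
    )
    assert rho == pytest.approx(hand, abs=1e-12)


def test_spearman_missing_group_errors():
    x = np.random.default_rng(18).normal(size=(10, 2))
    a, b, _ = _pair(x, x, "g")
    groups = pd.Series({**{s: "g" for s in a.sample_ids},
                        **{s: "h" for s in b.values.columns}})
    with pytest.raises(ValueError, match="absent"):
        nd.spearman_group_correlation(a, b, groups)
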