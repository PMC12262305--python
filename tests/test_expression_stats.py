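import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from stic_atlas import expression_stats as es


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_single_pvalue_is_identity():
    np.testing.assert_allclose(es.bh_adjust([0.04]), [0.04])


def test_bh_step_up_arithmetic():
    np.testing.assert_allclose(es.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_matches_statsmodels_on_uniform_draws():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=100)
    ours = es.bh_adjust(p)
    theirs = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, theirs, atol=1e-12)


def test_bh_invariant_to_permutation():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=50)
    perm = rng.permutation(50)
    np.testing.assert_allclose(es.bh_adjust(p)[perm], es.bh_adjust(p[perm]))


def test_bh_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        es.bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        es.bh_adjust([-0.1])


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _expr_frame(values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                        columns=[f"a{j}" for j in range(values.shape[1])])


def test_identical_groups_have_zero_logfc():
    rng = np.random.default_rng(2)
    half = rng.normal(5, 1, size=(30, 4))
    m = _expr_frame(np.hstack([half, half]))
    res = es.fit_de(m, [f"a{j}" for j in range(4)], [f"a{j}" for j in range(4, 8)])
    np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-12)


def test_true_shift_recovered_and_significant():
    rng = np.random.default_rng(3)
    vals = rng.normal(5, 0.5, size=(200, 40))
    vals[0, :20] += 2.0
    m = _expr_frame(vals)
    res = es.fit_de(m, [f"a{j}" for j in range(20)], [f"a{j}" for j in range(20, 40)])
    assert res.table.iloc[0]["adj_p"] < 0.05
    assert abs(res.table.iloc[0]["log2fc"] - 2.0) < 0.3


def test_infinite_prior_df_matches_pooled_variance_oracle():
    """With prior df forced to infinity the moderated t collapses to an
    ordinary z with the common pooled variance — checked in closed form."""
    rng = np.random.default_rng(4)
    vals = rng.normal(0, 1, size=(50, 12))
    m = _expr_frame(vals)
    a = [f"a{j}" for j in range(6)]
    b = [f"a{j}" for j in range(6, 12)]
    v0 = 1.7
    res = es.fit_de(m, a, b, prior_df=np.inf, prior_var=v0)
    logfc = vals[:, :6].mean(axis=1) - vals[:, 6:].mean(axis=1)
    t_expected = logfc / np.sqrt(v0 * (1 / 6 + 1 / 6))
    np.testing.assert_allclose(res.table["t"], t_expected, atol=1e-12)
    np.testing.assert_allclose(res.table["p"], 2 * stats.norm.sf(np.abs(t_expected)),
                               atol=1e-12)


def test_groups_smaller_than_two_rejected():
    m = _expr_frame(np.ones((5, 4)))
    with pytest.raises(ValueError, match=">= 2"):
        es.fit_de(m, ["a0"], ["a1", "a2", "a3"])


def test_variance_moderation_shrinks_toward_prior():
    """Genes with extreme sample variances get pulled toward the pooled
    prior, so moderated |t| is less extreme than the ordinary |t| for
    low-variance genes."""
    rng = np.random.default_rng(5)
    vals = rng.normal(0, 1, size=(300, 10))
    vals[0] = np.concatenate([np.full(5, 0.01), np.full(5, -0.01)])  # ~zero variance
    vals[0, 0] += 1e-4
    m = _expr_frame(vals)
    a = [f"a{j}" for j in range(5)]
    b = [f"a{j}" for j in range(5, 10)]
    res = es.fit_de(m, a, b)
    g0 = res.table.iloc[0]
    s2 = (np.var(vals[0, :5], ddof=1) * 4 + np.var(vals[0, 5:], ddof=1) * 4) / 8
    t_ord = g0["log2fc"] / np.sqrt(s2 * (1 / 5 + 1 / 5))
    assert abs(g0["t"]) < abs(t_ord)


# ---------------------------------------------------------------------------
# unique upregulated signatures
# ---------------------------------------------------------------------------

def _fake_de(genes, t, logfc, sig):
    tab = pd.DataFrame({"log2fc": logfc, "t": t, "p": 0.001, "adj_p": 0.001,
                        "mean_expr": 1.0, "significant": sig}, index=genes)
    return es.DEResult(tab)


def test_shared_upregulated_gene_excluded_everywhere():
    genes = ["g1", "g2", "g3"]
    a = _fake_de(genes, [5.0, 4.0, 1.0], [1.0, 1.0, 0.1], [True, True, False])
    b = _fake_de(genes, [4.5, 0.5, 6.0], [1.0, 0.2, 2.0], [True, False, True])
    sigs = es.top_upregulated_unique({"A": a, "B": b}, n=10)
    assert "g1" not in sigs["A"] and "g1" not in sigs["B"]
    assert sigs["A"] == ["g2"]
    assert sigs["B"] == ["g3"]


def test_zero_length_request_gives_empty_lists():
    genes = ["g1"]
    a = _fake_de(genes, [5.0], [1.0], [True])
    sigs = es.top_upregulated_unique({"A": a}, n=0)
    assert sigs["A"] == []


def test_short_list_warns():
    genes = ["g1", "g2"]
    a = _fake_de(genes, [5.0, 3.0], [1.0, 1.0], [True, True])
    with pytest.warns(UserWarning, match="only"):
        es.top_upregulated_unique({"A": a}, n=10)


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _toy_ranking(n=20, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(size=n))[::-1]
    return pd.Series(scores, index=[f"g{i}" for i in range(n)])


def _brute_force_es(ranking, members, weight):
    """Independent running-sum oracle."""
    genes = list(ranking.index)
    scores = ranking.to_numpy()
    hits = np.array([g in members for g in genes])
    w = np.abs(scores) ** weight
    p_hit = np.cumsum(np.where(hits, w, 0.0))
    p_hit = p_hit / p_hit[-1]
    n_miss = (~hits).sum()
    p_miss = np.cumsum(~hits) / n_miss
    running = p_hit - p_miss
    return running[np.argmax(np.abs(running))]


def test_top_k_set_es_matches_brute_force():
    ranking = _toy_ranking()
    members = set(ranking.index[:5])
    res = es.gsea_preranked(ranking, {"top5": sorted(members)}, weight=0.0,
                            n_perm=50, seed=0)
    expected = _brute_force_es(ranking, members, 0.0)
    assert res.table.loc["top5", "es"] == pytest.approx(expected, abs=1e-12)
    # closed form: every hit precedes every miss, so the running sum reaches
    # p_hit - p_miss = 1 - 0 at position k
    assert expected == pytest.approx(1.0)


def test_random_set_es_matches_brute_force_oracle():
    ranking = _toy_ranking(seed=3)
    rng = np.random.default_rng(7)
    members = sorted(rng.choice(ranking.index, size=6, replace=False))
    res = es.gsea_preranked(ranking, {"s": members}, weight=1.0, n_perm=20, seed=1)
    assert res.table.loc["s", "es"] == pytest.approx(
        _brute_force_es(ranking, set(members), 1.0), abs=1e-12
    )


def test_entire_universe_set_has_zero_es():
    ranking = _toy_ranking()
    res = es.gsea_preranked(ranking, {"all": list(ranking.index)}, n_perm=20, seed=0)
    assert res.table.loc["all", "es"] == 0.0


def test_permutation_p_floor():
    ranking = pd.Series(np.linspace(5, -5, 40), index=[f"g{i}" for i in range(40)])
    res = es.gsea_preranked(ranking, {"top": [f"g{i}" for i in range(8)]},
                            weight=0.0, n_perm=200, seed=0)
    assert res.table.loc["top", "p"] == pytest.approx(1 / 201)


def test_es_antisymmetric_under_ranking_negation():
    # members sit at both extremes but with unequal mass so the running-sum
    # extremum is unique (an exactly symmetric set would tie at +/-ES)
    ranking = _toy_ranking(seed=5)
    members = [f"g{i}" for i in (0, 1, 2, 3, 18, 19)]
    es_pos = es.gsea_preranked(ranking, {"s": members}, weight=0.0,
                               n_perm=20, seed=0).table.loc["s", "es"]
    neg = (-ranking).sort_values(ascending=False)
    es_neg = es.gsea_preranked(neg, {"s": members}, weight=0.0,
                               n_perm=20, seed=0).table.loc["s", "es"]
    assert es_neg == pytest.approx(-es_pos, abs=1e-9)


def test_empty_intersection_rejected():
    ranking = _toy_ranking()
    with pytest.raises(ValueError, match="no genes"):
        es.gsea_preranked(ranking, {"ghost": ["zz1", "zz2"]}, n_perm=10)


def test_gmt_round_trip(tmp_path):
    sets = {"alpha": ["g1", "g2", "g3"], "beta": ["g9"]}
    path = tmp_path / "sets.gmt"
    es.write_gmt(sets, path)
    assert es.read_gmt(path) == sets
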