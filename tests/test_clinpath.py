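import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stic_atlas import clinpath as cp
from stic_atlas.cohorts import LESION_COHORT, N_PATIENTS, SUBTYPES


def _records_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for level in counts.index:
        for subtype in counts.columns:
            rows += [{"level": level, "subtype": subtype}] * int(counts.loc[level, subtype])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def test_two_by_two_from_records():
    rec = pd.DataFrame({"level": ["x", "x", "y", "y"], "subtype": ["A", "B", "A", "B"]})
    t = cp.contingency_table(rec, "level", "subtype")
    assert (t.counts.to_numpy() == 1).all()


def test_lymphocyte_table_reconstructed_from_records():
    counts = LESION_COHORT["stromal_lymphocytes"]
    rec = _records_from_counts(counts)
    t = cp.contingency_table(rec, "level", "subtype",
                             row_levels=list(counts.index),
                             col_levels=list(counts.columns))
    assert t.counts.to_numpy().tolist() == [[39, 42, 19, 43], [2, 10, 7, 4]]


def test_record_order_does_not_matter():
    rec = _records_from_counts(LESION_COHORT["architecture"])
    shuffled = rec.sample(frac=1.0, random_state=0)
    t1 = cp.contingency_table(rec, "level", "subtype",
                              row_levels=["Flat", "BLAD"], col_levels=SUBTYPES)
    t2 = cp.contingency_table(shuffled, "level", "subtype",
                              row_levels=["Flat", "BLAD"], col_levels=SUBTYPES)
    pd.testing.assert_frame_equal(t1.counts, t2.counts)


def test_missing_values_excluded_and_counted():
    rec = pd.DataFrame({"level": ["x", None, "y"], "subtype": ["A", "B", None]})
    t = cp.contingency_table(rec, "level", "subtype")
    assert t.n_excluded == 2
    assert t.grand_total == 1


# ---------------------------------------------------------------------------
# expected counts and test choice
# ---------------------------------------------------------------------------

def test_expected_counts_uniform_and_conserving():
    t = cp.ContingencyTable(pd.DataFrame([[5, 5], [5, 5]]))
    np.testing.assert_allclose(cp.expected_counts(t), 5.0)
    t2 = cp.ContingencyTable(pd.DataFrame([[3, 9], [2, 14]]))
    assert cp.expected_counts(t2).to_numpy().sum() == pytest.approx(t2.grand_total)


def test_lymphocyte_minimum_expected_count():
    t = cp.ContingencyTable(LESION_COHORT["stromal_lymphocytes"])
    exp = cp.expected_counts(t)
    assert exp.to_numpy().min() == pytest.approx(26 * 23 / 166, abs=0.01)


def test_choose_test_rule():
    big = cp.ContingencyTable(pd.DataFrame([[100, 100], [100, 100]]))
    assert cp.choose_test(big) == "chi_square"
    borderline = cp.ContingencyTable(LESION_COHORT["stromal_lymphocytes"])
    assert cp.choose_test(borderline) == "fisher_exact"  # min expected 3.6 < 5


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def test_table_equal_to_expectation_scores_zero():
    t = cp.ContingencyTable(pd.DataFrame([[10, 20], [20, 40]]))
    res = cp.chi_square_test(t)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)
    assert res.df == 1


def test_chi_square_matches_direct_summation_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        shape = (rng.integers(2, 4), rng.integers(2, 5))
        counts = rng.integers(1, 40, size=shape)
        t = cp.ContingencyTable(pd.DataFrame(counts))
        res = cp.chi_square_test(t)
        exp = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
        stat = ((counts - exp) ** 2 / exp).sum()
        assert res.statistic == pytest.approx(stat, abs=1e-9)
        assert res.p == pytest.approx(stats.chi2.sf(stat, res.df), abs=1e-12)


def test_zero_margin_directed_to_fisher():
    t = cp.ContingencyTable(pd.DataFrame([[0, 0], [5, 5]]))
    with pytest.raises(ValueError, match="Fisher"):
        cp.chi_square_test(t)


def test_published_lymphocyte_chi_square_pvalue():
    t = cp.ContingencyTable(LESION_COHORT["stromal_lymphocytes"])
    assert cp.chi_square_test(t).p == pytest.approx(0.031, abs=0.0005)


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def _hypergeom_oracle_2x2(a, b, c, d):
    """Two-sided probability-ordering p over all tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    probs = []
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs.append((x, stats.hypergeom.pmf(x, n, r1, c1)))
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return sum(p for _, p in probs if p <= p_obs * (1 + 1e-7))


def test_fisher_2x2_matches_hypergeometric_enumeration():
    t = cp.ContingencyTable(pd.DataFrame([[3, 1], [1, 3]]))
    res = cp.fisher_exact_rxc(t)
    assert res.p == pytest.approx(_hypergeom_oracle_2x2(3, 1, 1, 3), abs=1e-12)
    # and scipy's two-sided Fisher agrees on 2x2
    assert res.p == pytest.approx(stats.fisher_exact([[3, 1], [1, 3]])[1], abs=1e-9)


def test_degenerate_single_row_table_has_p_one():
    t = cp.ContingencyTable(pd.DataFrame([[4, 2, 6]]))
    assert cp.fisher_exact_rxc(t).p == 1.0


def test_fisher_rxc_matches_r_reference_values():
    """Frozen oracle values computed with R 4.3 fisher.test on the bundled
    cohort's gain tables."""
    ccne1 = cp.ContingencyTable(LESION_COHORT["ccne1_gain"])
    myc = cp.ContingencyTable(LESION_COHORT["myc_gain"])
    lymph = cp.ContingencyTable(LESION_COHORT["stromal_lymphocytes"])
    assert cp.fisher_exact_rxc(ccne1).p == pytest.approx(0.01256734, abs=1e-6)
    assert cp.fisher_exact_rxc(myc).p == pytest.approx(0.275094, abs=1e-5)
    assert cp.fisher_exact_rxc(lymph).p == pytest.approx(0.02943929, abs=1e-5)


def test_enumerated_probabilities_sum_to_one():
    counts = np.array([[2, 3, 1], [4, 1, 2]])
    from scipy.special import gammaln

    rows, cols = counts.sum(1), counts.sum(0)
    log_margin = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                  - gammaln(counts.sum() + 1))
    total = sum(
        np.exp(cp._log_table_prob(tab[None].astype(float), log_margin)[0])
        for tab in cp._enumerate_tables(rows, cols)
    )
    assert total == pytest.approx(1.0, abs=1e-9)


def test_monte_carlo_agrees_with_enumeration():
    t = cp.ContingencyTable(LESION_COHORT["ccne1_gain"])
    p_enum = cp.fisher_exact_rxc(t).p
    p_mc = cp.fisher_exact_rxc(t, max_enum_total=1, n_mc=200_000, seed=0)
    assert "monte_carlo" in p_mc.note
    assert abs(p_enum - p_mc.p) < 0.002


def test_associate_reports_both_tests_when_borderline():
    t = cp.ContingencyTable(LESION_COHORT["ccne1_gain"])
    out = cp.associate(t)
    assert out["selected"].method == "fisher_exact"
    assert out["chi_square"].method == "chi_square"
    assert out["chi_square"].p == pytest.approx(0.017, abs=0.001)


# ---------------------------------------------------------------------------
# summaries and scores
# ---------------------------------------------------------------------------

def test_percent_summary_reproduces_published_percentages():
    atypia = cp.ContingencyTable(LESION_COHORT["nuclear_atypia"])
    pct = cp.percent_summary(atypia)
    assert pct.loc["High-grade", "Proliferative"] == 91.5
    assert pct.loc["High-grade", "Immunoreactive"] == 84.6
    arch = cp.percent_summary(cp.ContingencyTable(LESION_COHORT["architecture"]))
    assert arch.loc["BLAD", "Proliferative"] == 44.7
    assert arch.loc["BLAD", "Dormant"] == 4.9


def test_percent_summary_columns_sum_to_100():
    for var, counts in LESION_COHORT.items():
        pct = cp.percent_summary(cp.ContingencyTable(counts))
        assert np.allclose(pct.sum(axis=0), 100.0, atol=0.1)


def test_percent_summary_zero_cell_and_zero_column():
    t = cp.ContingencyTable(pd.DataFrame([[0, 5], [10, 5]]))
    assert cp.percent_summary(t).iloc[0, 0] == 0.0
    empty = cp.ContingencyTable(pd.DataFrame([[0, 5], [0, 5]]))
    with pytest.raises(ValueError, match="zero column"):
        cp.percent_summary(empty)


def test_h_score_arithmetic_and_linearity():
    assert cp.h_score([0, 0, 0, 100]) == 300
    assert cp.h_score([100, 0, 0, 0]) == 0
    assert cp.h_score([50, 0, 50, 0]) == 100
    a = cp.h_score([25, 25, 25, 25])
    b = cp.h_score([35, 15, 25, 25])
    assert a - b == pytest.approx(1 * 10 - 0 * 10)
    with pytest.raises(ValueError, match="sum"):
        cp.h_score([50, 0, 0, 0])


def test_ki67_categories():
    assert cp.ki67_category(51.9) == "High"
    assert cp.ki67_category(4.5) == "Low"
    assert cp.ki67_category(5.0) == "Intermediate"
    assert cp.ki67_category(20.0) == "Intermediate"
    assert cp.ki67_category(20.1) == "High"
    with pytest.raises(ValueError):
        cp.ki67_category(101)


def test_patient_totals_sum_to_cohort_size():
    assert int(N_PATIENTS.sum()) == 166
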