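"""Clinicopathological association statistics for subtype cross-tabulations.

Cross-tabulates categorical lesion covariates against molecular subtype and
tests independence with the Pearson chi-square test (no continuity
correction) or an r x c Fisher exact test chosen by the textbook
expected-count rule (any expected cell < 5).  The Fisher test uses the
probability-ordering two-sided definition, with full enumeration of the
conditional table space for small grand totals and a seeded Monte Carlo
estimate (sequential multivariate hypergeometric sampling) otherwise.

Also includes the immunohistochemistry H-score arithmetic and the Ki67
labelling-index categorisation used in lesion grading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

EXPECTED_COUNT_CUTOFF = 5.0


@dataclass
class ContingencyTable:
    """Nonnegative integer cross-tabulation with margins."""

    counts: pd.DataFrame  # rows x columns
    n_excluded: int = 0

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative cell counts")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("cell counts must be integers")
        self.counts = self.counts.astype(int)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class TestResult:
    """Outcome of an independence test on a contingency table."""

    method: str  # "chi_square" | "fisher_exact"
    p: float
    statistic: float | None = None
    df: int | None = None
    note: str = ""


def contingency_table(
    table: pd.DataFrame, row_var: str, col_var: str,
    row_levels=None, col_levels=None,
) -> ContingencyTable:
    """Cross-tabulate two categorical columns of a sample table.

    Rows with a missing value in either variable are excluded and counted in
    ``n_excluded``.  Level order is the order of first appearance unless an
    explicit level list is given.
    """
    sub = table[[row_var, col_var]]
    ok = sub.notna().all(axis=1)
    n_excluded = int((~ok).sum())
    sub = sub[ok]
    if len(sub) == 0:
        raise ValueError("no complete records to tabulate")
    rl = list(row_levels) if row_levels is not None else list(pd.unique(sub[row_var]))
    cl = list(col_levels) if col_levels is not None else list(pd.unique(sub[col_var]))
    ct = pd.crosstab(sub[row_var], sub[col_var]).reindex(index=rl, columns=cl, fill_value=0)
    return ContingencyTable(ct, n_excluded)


def expected_counts(t: ContingencyTable) -> pd.DataFrame:
    """Expected cell counts under independence: row_i * col_j / N."""
    if t.grand_total <= 0:
        raise ValueError("empty table")
    exp = np.outer(t.row_totals, t.col_totals) / t.grand_total
    return pd.DataFrame(exp, index=t.counts.index, columns=t.counts.columns)


def choose_test(t: ContingencyTable) -> str:
    """Textbook rule: Fisher exact if any expected count < 5, else chi-square."""
    return (
        "fisher_exact"
        if (expected_counts(t).to_numpy() < EXPECTED_COUNT_CUTOFF).any()
        else "chi_square"
    )


def chi_square_test(t: ContingencyTable) -> TestResult:
    """Pearson chi-square independence test, no continuity correction."""
    arr = t.counts.to_numpy()
    if t.grand_total <= 0:
        raise ValueError("empty table")
    if (t.row_totals == 0).any() or (t.col_totals == 0).any():
        raise ValueError("zero margin: use the Fisher exact test")
    res = stats.chi2_contingency(arr, correction=False)
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    return TestResult("chi_square", float(res.pvalue), float(res.statistic), df)


# ---------------------------------------------------------------------------
# r x c Fisher exact test
# ---------------------------------------------------------------------------

def _log_table_prob(cells: np.ndarray, log_margin_term: float) -> np.ndarray:
    """log conditional probability of tables given fixed margins."""
    return log_margin_term - gammaln(cells + 1.0).sum(axis=tuple(range(1, cells.ndim)))


def _enumerate_tables(row_totals: np.ndarray, col_totals: np.ndarray):
    """Yield every nonnegative integer table with the given margins."""
    r, c = len(row_totals), len(col_totals)
    table = np.zeros((r, c), dtype=int)

    def fill_row(i: int, remaining_cols: np.ndarray):
        if i == r - 1:
            if (remaining_cols >= 0).all():
                table[i] = remaining_cols
                yield table
            return
        def fill_cell(j: int, left: int, cols: np.ndarray):
            if j == c - 1:
                if 0 <= left <= cols[j]:
                    table[i, j] = left
                    new_cols = cols.copy()
                    new_cols[: c - 1] = cols[: c - 1] - table[i, : c - 1]
                    new_cols[c - 1] = cols[c - 1] - left
                    yield from fill_row(i + 1, new_cols)
                return
            for v in range(min(left, cols[j]) + 1):
                table[i, j] = v
                yield from fill_cell(j + 1, left - v, cols)
        yield from fill_cell(0, int(row_totals[i]), remaining_cols)

    yield from fill_row(0, col_totals.astype(int).copy())


def _mc_tables(
    row_totals: np.ndarray, col_totals: np.ndarray, n_mc: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample tables from the fixed-margin null by sequential hypergeometrics."""
    r, c = len(row_totals), len(col_totals)
    out = np.zeros((n_mc, r, c), dtype=np.int64)
    remaining_cols = np.broadcast_to(col_totals, (n_mc, c)).copy()
    remaining_total = np.full(n_mc, int(col_totals.sum()), dtype=np.int64)
    for i in range(r - 1):
        left = np.full(n_mc, int(row_totals[i]), dtype=np.int64)
        rest = remaining_total.copy()
        for j in range(c - 1):
            rest = rest - remaining_cols[:, j]
            draw = rng.hypergeometric(remaining_cols[:, j], rest, left)
            out[:, i, j] = draw
            left -= draw
        out[:, i, c - 1] = left
        remaining_cols = remaining_cols - out[:, i, :]
        remaining_total -= int(row_totals[i])
    out[:, r - 1, :] = remaining_cols
    return out


def fisher_exact_rxc(
    t: ContingencyTable,
    max_enum_total: int = 500,
    n_mc: int = 1_000_000,
    seed: int = 0,
) -> TestResult:
    """Two-sided r x c Fisher exact test (probability-ordering definition).

    p is the total conditional probability of tables (same margins) no more
    probable than the observed one.  Full enumeration when the grand total
    is at most ``max_enum_total``; otherwise a seeded Monte Carlo estimate,
    flagged in the result note.
    """
    obs = t.counts.to_numpy()
    rows = t.row_totals.to_numpy()
    cols = t.col_totals.to_numpy()
    # degenerate margins fix the table entirely
    if (rows > 0).sum() <= 1 or (cols > 0).sum() <= 1:
        return TestResult("fisher_exact", 1.0, note="margins determine the table")
    log_margin = (
        gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum() - gammaln(t.grand_total + 1.0)
    )
    log_p_obs = float(_log_table_prob(obs[None], log_margin)[0])
    tol = 1e-7
    if t.grand_total <= max_enum_total:
        total = 0.0
        for tab in _enumerate_tables(rows, cols):
            lp = float(_log_table_prob(tab[None].astype(float), log_margin)[0])
            if lp <= log_p_obs + tol:
                total += np.exp(lp)
        return TestResult("fisher_exact", min(float(total), 1.0))
    rng = np.random.default_rng(seed)
    sims = _mc_tables(rows, cols, int(n_mc), rng)
    lp = _log_table_prob(sims.astype(float), log_margin)
    hits = int((lp <= log_p_obs + tol).sum())
    p = (1 + hits) / (n_mc + 1)
    return TestResult(
        "fisher_exact", float(p), note=f"monte_carlo n={int(n_mc)} seed={seed}"
    )


def associate(
    t: ContingencyTable,
    max_enum_total: int = 500,
    n_mc: int = 1_000_000,
    seed: int = 0,
) -> dict[str, TestResult]:
    """Run the rule-selected test; report both when the rule is borderline.

    Always returns the selected test under ``"selected"``; when any expected
    count is below the cutoff (Fisher selected) the chi-square value is also
    reported under ``"chi_square"`` since published tables do not always
    honour the cutoff.
    """
    method = choose_test(t)
    out: dict[str, TestResult] = {}
    if method == "chi_square":
        out["selected"] = chi_square_test(t)
    else:
        out["selected"] = fisher_exact_rxc(t, max_enum_total, n_mc, seed)
        try:
            out["chi_square"] = chi_square_test(t)
        except ValueError:
            pass
    return out


# ---------------------------------------------------------------------------
# summaries and scores
# ---------------------------------------------------------------------------

def percent_summary(t: ContingencyTable) -> pd.DataFrame:
    """Column percentages (100 * count / column total), rounded to 1 decimal."""
    totals = t.col_totals
    if (totals == 0).any():
        raise ValueError(f"zero column totals: {totals.index[totals == 0].tolist()}")
    return (100.0 * t.counts / totals).round(1)


def h_score(pct_by_intensity) -> float:
    """Immunohistochemistry H-score: sum of intensity (0-3) x percent cells.

    ``pct_by_intensity`` holds the percentages of epithelial cells at
    intensities 0..3; they must sum to 100.  Range 0-300.
    """
    pct = np.asarray(pct_by_intensity, dtype=float)
    if len(pct) != 4:
        raise ValueError("expected percentages for intensities 0..3")
    if (pct < 0).any():
        raise ValueError("percentages must be nonnegative")
    if abs(pct.sum() - 100.0) > 0.01:
        raise ValueError(f"percentages sum to {pct.sum()}, expected 100")
    return float(np.dot(np.arange(4), pct))


def ki67_category(index_pct: float) -> str:
    """Ki67 labelling-index category: Low (<5), Intermediate (5-20), High (>20)."""
    if not (0 <= index_pct <= 100):
        raise ValueError(f"Ki67 index {index_pct} outside [0, 100]")
    if index_pct < 5:
        return "Low"
    if index_pct <= 20:
        return "Intermediate"
    return "High"
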