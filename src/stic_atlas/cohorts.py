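"""Bundled clinicopathological summary of a published 166-lesion STIC cohort.

Counts are the per-subtype cross-tabulations of a reference cohort of 166
tubal precancerous lesions profiled across four molecular subtypes
(Dormant, Mixed, Immunoreactive, Proliferative).  They serve two purposes:
as the default subtype-conditional probabilities for the synthetic cohort
generator, and as a worked example for the association statistics.

Rows are variable levels, columns are molecular subtypes.  The Ki67 column
total for the Dormant subtype is 40 (one lesion unscored); copy-number gain
calls were available for a 39-sample subset.
"""

from __future__ import annotations

import pandas as pd

SUBTYPES = ["Dormant", "Mixed", "Immunoreactive", "Proliferative"]

N_PATIENTS = pd.Series([41, 52, 26, 47], index=SUBTYPES, name="n_patients")


def _table(rows: dict[str, list[int]]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=SUBTYPES).T


LESION_COHORT: dict[str, pd.DataFrame] = {
    "age": _table(
        {
            "30-39": [0, 0, 1, 0],
            "40-49": [3, 0, 5, 0],
            "50-59": [28, 15, 9, 9],
            "60-69": [9, 9, 4, 20],
            "70-79": [1, 28, 7, 13],
        }
    ),
    "brca_status": _table(
        {
            "Negative": [30, 36, 12, 41],
            "BRCA1": [0, 6, 8, 2],
            "BRCA2": [6, 6, 5, 2],
            "Other": [5, 4, 1, 2],
        }
    ),
    "nuclear_atypia": _table(
        {
            "Low-grade": [32, 24, 4, 4],
            "High-grade": [9, 28, 22, 43],
        }
    ),
    "architecture": _table(
        {
            "Flat": [39, 39, 19, 26],
            "BLAD": [2, 13, 7, 21],
        }
    ),
    "stromal_lymphocytes": _table(
        {
            "Non-enriched": [39, 42, 19, 43],
            "Enriched": [2, 10, 7, 4],
        }
    ),
    "ki67": _table(
        {
            "Low": [13, 19, 5, 3],
            "Intermediate": [22, 16, 8, 15],
            "High": [5, 17, 13, 29],
        }
    ),
    "p53_pattern": _table(
        {
            "Missense": [32, 44, 24, 35],
            "Loss/null": [8, 8, 2, 11],
            "Wildtype": [1, 0, 0, 1],
        }
    ),
    "ccne1_gain": _table(
        {
            "Gain": [0, 2, 1, 10],
            "No gain": [9, 6, 4, 7],
        }
    ),
    "myc_gain": _table(
        {
            "Gain": [1, 3, 3, 7],
            "No gain": [8, 5, 2, 10],
        }
    ),
}


def cohort_proportions(variable: str) -> pd.DataFrame:
    """Per-subtype level proportions for ``variable`` (columns sum to 1)."""
    t = LESION_COHORT[variable]
    return t / t.sum(axis=0)


def default_clinpath_probs() -> dict[str, pd.DataFrame]:
    """Default subtype-conditional covariate distributions for the generator.

    Keyed by covariate; each value is a levels x subtypes proportion table
    whose columns sum to 1.  Subtype column labels are the cohort's
    capitalised names; the generator matches them case-insensitively.
    """
    return {
        v: cohort_proportions(v)
        for v in ("brca_status", "nuclear_atypia", "architecture",
                  "stromal_lymphocytes", "ki67")
    }
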