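"""AOI expression preprocessing: variance stabilisation, batch removal, mixing QC.

The expression substrate is an :class:`AOIMatrix` — a genes x AOIs count (or
transformed-expression) matrix with per-AOI metadata (compartment, diagnosis,
batch/run, patient).  Preprocessing follows the usual digital-spatial-profiler
recipe: upper-quartile size-factor normalisation with a log2(x+1) transform,
least-squares removal of per-run batch shifts, and a kBET-style chi-square
rejection rate to quantify residual batch structure in a PCA embedding.

``VarianceStabilizer`` and ``BatchCorrector`` are scikit-learn style
transformers over plain samples x genes arrays; the module-level functions
wrap them for :class:`AOIMatrix` inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA
from sklearn.neighbors import NearestNeighbors
from scipy import stats


@dataclass
class AOIMatrix:
    """Genes x AOIs expression matrix with per-AOI metadata.

    ``values`` is indexed by gene id with AOI ids as columns; ``meta`` is
    indexed by AOI id and carries at least ``compartment``, ``diagnosis``,
    ``batch`` and ``patient``.  ``transformed`` distinguishes raw counts from
    variance-stabilised expression.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate AOI ids")
        missing = self.values.columns.difference(self.meta.index)
        if len(missing):
            raise ValueError(f"AOIs missing from metadata: {list(missing)[:5]}")
        if not self.transformed and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be nonnegative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def aoi_ids(self) -> pd.Index:
        return self.values.columns

    def subset_aois(self, aoi_ids) -> "AOIMatrix":
        return AOIMatrix(
            self.values.loc[:, aoi_ids], self.meta.loc[aoi_ids], self.transformed
        )


@dataclass
class Embedding:
    """AOIs x k coordinates with per-component explained-variance fractions."""

    coordinates: pd.DataFrame
    explained_variance: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        ev = np.asarray(self.explained_variance, dtype=float)
        if len(ev) and (np.any(ev < -1e-12) or np.any(ev > 1 + 1e-12)):
            raise ValueError("explained_variance fractions must lie in [0, 1]")
        if len(ev) > 1 and np.any(np.diff(ev) > 1e-9):
            raise ValueError("explained_variance must be nonincreasing")


class VarianceStabilizer(BaseEstimator, TransformerMixin):
    """Upper-quartile size normalisation followed by log2(x + 1).

    Per sample (AOI), counts are divided by a size factor equal to the
    sample's upper quartile of nonzero counts over the geometric mean of the
    *other* samples' quartiles.  Identical samples get factor 1, and scaling
    one sample's counts scales only its own factor, so the transform cancels
    per-sample depth exactly.
    """

    def __init__(self, quantile: float = 0.75):
        self.quantile = quantile

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if (X < 0).any():
            raise ValueError("counts must be nonnegative")
        totals = X.sum(axis=1)
        if np.any(totals == 0):
            raise ValueError(f"all-zero samples at rows {np.where(totals == 0)[0].tolist()}")
        q = np.array([np.quantile(row[row > 0], self.quantile) for row in X])
        logq = np.log(q)
        n = len(q)
        if n == 1:
            ref = q.copy()
        else:
            ref = np.exp((logq.sum() - logq) / (n - 1))  # leave-one-out geomean
        self.size_factors_ = q / ref
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.log2(X / self.size_factors_[:, None] + 1.0)


class BatchCorrector(BaseEstimator, TransformerMixin):
    """Least-squares removal of per-batch mean shifts, per feature.

    For each feature, every sample's value is reduced by its batch mean's
    deviation from the overall (grand) mean, so all batch means coincide at
    the grand mean and the per-feature grand mean is preserved exactly.
    Assumes roughly additive errors, i.e. variance-stabilised input.
    """

    def fit(self, X, y=None, *, batches=None):
        X = np.asarray(X, dtype=float)
        batches = np.asarray(batches)
        if batches is None or len(batches) != X.shape[0]:
            raise ValueError("one batch label per sample is required")
        labels, inverse = np.unique(batches, return_inverse=True)
        if len(labels) < 2:
            warnings.warn("single batch: correction is the identity")
            self.offsets_ = np.zeros((1, X.shape[1]))
            self.batch_labels_, self.batch_index_ = labels, inverse
            return self
        counts = np.bincount(inverse)
        if np.any(counts < 2):
            bad = labels[counts < 2].tolist()
            raise ValueError(f"batches with fewer than 2 samples: {bad}")
        grand = X.mean(axis=0)
        sums = np.zeros((len(labels), X.shape[1]))
        np.add.at(sums, inverse, X)
        batch_means = sums / counts[:, None]
        self.offsets_ = batch_means - grand
        self.batch_labels_, self.batch_index_ = labels, inverse
        return self

    def transform(self, X, *, batches=None):
        X = np.asarray(X, dtype=float)
        if batches is None:
            idx = self.batch_index_
        else:
            lookup = {b: i for i, b in enumerate(self.batch_labels_)}
            idx = np.array([lookup[b] for b in np.asarray(batches)])
        return X - self.offsets_[idx]

    def fit_transform(self, X, y=None, *, batches=None):
        return self.fit(X, batches=batches).transform(X)


# ---------------------------------------------------------------------------
# AOIMatrix-level wrappers
# ---------------------------------------------------------------------------

def variance_stabilize(m: AOIMatrix) -> AOIMatrix:
    """Q3-normalise and log2(x+1)-transform a raw-count :class:`AOIMatrix`."""
    if m.transformed:
        raise ValueError("matrix is already variance-stabilized")
    totals = m.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"AOIs with all-zero counts: {zero.index.tolist()}")
    vs = VarianceStabilizer().fit(m.values.to_numpy().T)
    out = vs.transform(m.values.to_numpy().T).T
    return AOIMatrix(
        pd.DataFrame(out, index=m.gene_ids, columns=m.aoi_ids), m.meta, transformed=True
    )


def remove_batch_effects(m: AOIMatrix, batch_key: str = "batch") -> AOIMatrix:
    """Remove per-run batch shifts from transformed expression."""
    if not m.transformed:
        raise ValueError("batch removal expects variance-stabilized expression")
    batches = m.meta.loc[m.aoi_ids, batch_key].to_numpy()
    bc = BatchCorrector()
    out = bc.fit_transform(m.values.to_numpy().T, batches=batches).T
    return AOIMatrix(
        pd.DataFrame(out, index=m.gene_ids, columns=m.aoi_ids), m.meta, transformed=True
    )


def pca(m: AOIMatrix, k: int) -> Embedding:
    """Centered PCA of AOIs with deterministic component signs.

    Each loading vector is flipped so that its largest-magnitude entry is
    positive, making coordinates reproducible across runs.
    """
    if k == 0:
        raise ValueError("k must be >= 1")
    X = m.values.to_numpy().T  # AOIs x genes
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(genes, AOIs)={min(X.shape)}")
    model = _SkPCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(X)
    for j in range(k):
        comp = model.components_[j]
        if comp[np.argmax(np.abs(comp))] < 0:
            coords[:, j] = -coords[:, j]
    return Embedding(
        pd.DataFrame(coords, index=m.aoi_ids, columns=[f"PC{i+1}" for i in range(k)]),
        model.explained_variance_ratio_.copy(),
    )


def batch_mixing_score(
    e: Embedding,
    batches,
    k: int = 25,
    alpha: float = 0.05,
    n_draws: int = 100,
    seed: int = 0,
) -> float:
    """kBET-style rejection rate: chi-square GOF of k-NN batch composition.

    For ``n_draws`` seeded anchor AOIs, the batch composition of the anchor's
    k nearest neighbours is tested against the global batch frequencies; the
    fraction of rejections at ``alpha`` is returned.  0 means perfectly
    mixed; 1 means complete batch separation.
    """
    coords = e.coordinates.to_numpy()
    batches = np.asarray(batches)
    labels, inverse = np.unique(batches, return_inverse=True)
    n, n_batches = len(batches), len(labels)
    if n_batches < 2:
        raise ValueError("batch mixing needs at least 2 batches")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of AOIs ({n})")
    if k <= n_batches:
        raise ValueError(f"k={k} must exceed the number of batches ({n_batches})")
    global_freq = np.bincount(inverse, minlength=n_batches) / n
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    rng = np.random.default_rng(seed)
    anchors = rng.choice(n, size=min(n_draws, n), replace=n_draws > n)
    _, idx = nn.kneighbors(coords[anchors])
    rejected = 0
    expected = k * global_freq
    for row in idx:
        observed = np.bincount(inverse[row], minlength=n_batches)
        stat = np.sum((observed - expected) ** 2 / expected)
        p = stats.chi2.sf(stat, df=n_batches - 1)
        rejected += p < alpha
    return rejected / len(anchors)


def ensure_nonnegative(values: pd.DataFrame) -> pd.DataFrame:
    """Shift by the global minimum (if negative) and clip at zero.

    Batch-corrected expression can dip below zero; NMF requires nonnegative
    input, so the matrix is translated and clipped before factorisation.
    """
    arr = values.to_numpy()
    lo = arr.min()
    if lo < 0:
        arr = arr - lo
    return pd.DataFrame(np.clip(arr, 0, None), index=values.index, columns=values.columns)
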