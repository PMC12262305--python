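"""Consensus non-negative matrix factorisation subtyping of epithelial AOIs.

Molecular subtypes are discovered by repeated NMF of the nonnegative
expression matrix: each seeded run clusters AOIs by the dominant metagene
(argmax of the coefficient matrix H), runs are aggregated into a consensus
co-clustering matrix, and the factorisation rank is chosen by cophenetic
correlation (ties broken by silhouette width, then by the smaller rank).

The multiplicative-update factorisation is implemented here so that the loss
trajectory, tie-breaking and seeding are fully specified; scikit-learn's NMF
serves as an independent cross-check in the test-suite only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

_EPS = 1e-12


@dataclass
class NMFFactors:
    """Result of one multiplicative-update NMF run."""

    W: np.ndarray  # features x r
    H: np.ndarray  # r x samples
    loss: float
    loss_history: np.ndarray
    n_iter: int
    seed: int
    kept_rows: np.ndarray  # indices of non-zero input rows that were factorised

    def __post_init__(self) -> None:
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("NMF factors must be nonnegative")


@dataclass
class ConsensusResult:
    """Consensus co-clustering of AOIs at one rank."""

    rank: int
    consensus: np.ndarray  # samples x samples, co-assignment frequencies
    cophenetic: float
    dispersion: float
    silhouette: float
    labels: np.ndarray  # 1..rank per sample
    n_runs: int
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        C = self.consensus
        if not np.allclose(C, C.T, atol=1e-9):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-9):
            raise ValueError("consensus diagonal must be 1")
        if C.min() < -1e-9 or C.max() > 1 + 1e-9:
            raise ValueError("consensus entries must lie in [0, 1]")


def nmf_factorize(
    X: np.ndarray,
    r: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    loss_every: int = 1,
) -> NMFFactors:
    """Frobenius-loss NMF by multiplicative updates, deterministic given seed.

    Zero rows (features) are dropped with a warning before factorisation;
    zero columns are an error because sample clustering would be undefined.
    Stops when the relative loss change falls below ``tol`` or at
    ``max_iter``; the loss sequence is monotone nonincreasing.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("NMF input must be nonnegative")
    if r < 1:
        raise ValueError("rank must be >= 1")
    col_zero = np.where(X.sum(axis=0) == 0)[0]
    if len(col_zero):
        raise ValueError(f"zero columns (samples) at {col_zero.tolist()}")
    kept = np.where(X.sum(axis=1) > 0)[0]
    if len(kept) < X.shape[0]:
        warnings.warn(f"dropping {X.shape[0] - len(kept)} all-zero rows before NMF")
        X = X[kept]

    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / r)
    W = rng.uniform(0.1, 1.0, size=(X.shape[0], r)) * scale
    H = rng.uniform(0.1, 1.0, size=(r, X.shape[1])) * scale

    norm_X = np.linalg.norm(X)
    losses = []
    prev = None
    n_iter = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        n_iter = it
        if it % loss_every == 0 or it == max_iter:
            loss = np.linalg.norm(X - W @ H)
            losses.append(loss)
            if prev is not None and abs(prev - loss) <= tol * max(norm_X, _EPS):
                break
            prev = loss
    return NMFFactors(W, H, losses[-1], np.array(losses), n_iter, seed, kept)


def _run_labels(H: np.ndarray) -> np.ndarray:
    """Cluster samples by dominant metagene; ties go to the lower index."""
    return np.argmax(H, axis=0)


def dispersion(consensus: np.ndarray) -> float:
    """Mean of 4*(c - 0.5)^2; equals 1 exactly when all entries are 0 or 1."""
    return float(np.mean(4.0 * (consensus - 0.5) ** 2))


def cophenetic_correlation(consensus: np.ndarray) -> float:
    """Correlation between (1 - consensus) and its average-linkage dendrogram.

    A constant distance matrix (e.g. a perfectly stable consensus) has no
    variance to correlate, so 1.0 is returned by convention with a warning.
    """
    D = 1.0 - np.asarray(consensus, dtype=float)
    np.fill_diagonal(D, 0.0)
    d = squareform(D, checks=False)
    if np.allclose(d, d[0]):
        warnings.warn("constant consensus distances; cophenetic set to 1.0 by convention")
        return 1.0
    Z = average(d)
    coph_d = cophenet(Z)
    if np.allclose(coph_d, coph_d[0]):
        warnings.warn("constant dendrogram distances; cophenetic set to 1.0 by convention")
        return 1.0
    return float(pearsonr(d, coph_d)[0])


def consensus_nmf(
    X: np.ndarray,
    r: int,
    n_runs: int = 100,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
    sample_ids=None,
) -> ConsensusResult:
    """Aggregate ``n_runs`` seeded NMF runs into a consensus clustering.

    Run ``i`` uses ``seed + i``.  Final labels come from average-linkage
    hierarchical clustering of 1 - consensus cut into ``r`` groups; the
    cophenetic correlation, dispersion and mean silhouette width (on
    1 - consensus distances) quantify stability at this rank.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if r >= n:
        raise ValueError(f"rank {r} must be smaller than the number of samples {n}")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    co = np.zeros((n, n))
    for i in range(n_runs):
        fac = nmf_factorize(X, r, seed=seed + i, max_iter=max_iter, tol=tol,
                            loss_every=10)
        lab = _run_labels(fac.H)
        co += lab[:, None] == lab[None, :]
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)

    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    labels = fcluster(Z, t=r, criterion="maxclust")
    coph = cophenetic_correlation(consensus)
    disp = dispersion(consensus)
    if len(np.unique(labels)) < 2:
        sil = float("nan")
    else:
        sil = float(silhouette_score(D, labels, metric="precomputed"))
    return ConsensusResult(
        rank=r, consensus=consensus, cophenetic=coph, dispersion=disp,
        silhouette=sil, labels=labels, n_runs=n_runs,
        sample_ids=list(sample_ids) if sample_ids is not None else [],
    )


def select_rank(
    results: dict[int, ConsensusResult], tie_tol: float | None = None
) -> tuple[int, pd.DataFrame]:
    """Choose the factorisation rank by cophenetic correlation.

    Returns ``(r*, metric_table)`` where r* maximises cophenetic correlation;
    ties are broken by higher silhouette, then by smaller rank.  Consensus
    entries are quantised at 1/n_runs, so cophenetic values closer than the
    quantisation step are not meaningfully ordered; ``tie_tol`` (default
    1/min(n_runs)) treats them as tied and lets the silhouette decide.
    """
    if len(results) < 2:
        raise ValueError("rank selection needs >= 2 candidate ranks")
    if tie_tol is None:
        tie_tol = 1.0 / min(res.n_runs for res in results.values())
    table = pd.DataFrame(
        {
            r: {"cophenetic": res.cophenetic, "dispersion": res.dispersion,
                "silhouette": res.silhouette}
            for r, res in results.items()
        }
    ).T.sort_index()
    coph = table["cophenetic"].to_numpy()
    best = np.nanmax(coph)
    tied = table.index[coph >= best - tie_tol]
    sils = table.loc[tied, "silhouette"].fillna(-np.inf).to_numpy()
    best_sil = sils.max()
    tied2 = tied[np.isclose(sils, best_sil, atol=1e-9)]
    return int(tied2.min()), table


class ConsensusNMF(BaseEstimator, ClusterMixin):
    """Consensus-NMF clusterer over a samples x features nonnegative matrix.

    Parameters follow the functional API; after :meth:`fit`, ``labels_``,
    ``consensus_``, ``cophenetic_``, ``dispersion_`` and ``silhouette_``
    are available.  ``rank=None`` performs rank selection over
    ``rank_candidates`` and stores the metric table in ``rank_metrics_``.
    """

    def __init__(self, rank=4, rank_candidates=(2, 3, 4, 5, 6), n_runs=100,
                 seed=0, max_iter=300, tol=1e-5):
        self.rank = rank
        self.rank_candidates = rank_candidates
        self.n_runs = n_runs
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples x features matrix")
        Xt = X.T  # features x samples, matching the functional API
        if self.rank is None:
            results = {
                r: consensus_nmf(Xt, r, self.n_runs, self.seed, self.max_iter, self.tol)
                for r in self.rank_candidates
            }
            best, table = select_rank(results)
            self.rank_ = best
            self.rank_metrics_ = table
            res = results[best]
            self.all_results_ = results
        else:
            self.rank_ = int(self.rank)
            res = consensus_nmf(Xt, self.rank_, self.n_runs, self.seed,
                                self.max_iter, self.tol)
        self.labels_ = res.labels
        self.consensus_ = res.consensus
        self.cophenetic_ = res.cophenetic
        self.dispersion_ = res.dispersion
        self.silhouette_ = res.silhouette
        self.result_ = res
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
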