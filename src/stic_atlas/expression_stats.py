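"""Moderated differential expression and preranked gene-set enrichment.

Differential expression uses a two-group linear model per gene with
empirical-Bayes variance moderation: residual variances are shrunk toward a
pooled prior whose degrees of freedom and scale are estimated from the
distribution of log sample variances by method of moments (digamma/trigamma
matching), giving a moderated t with augmented degrees of freedom.
Significance follows the conventional thresholds: Benjamini-Hochberg
adjusted p < 0.05 and |log2 fold change| > 0.5.

Gene-set enrichment is the weighted Kolmogorov-Smirnov running-sum statistic
on a preranked gene list, with a seeded gene-set-resampling null (suited to
subtype-vs-rest contrasts with small groups), NES normalisation by the mean
same-sign null ES, and BH correction across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

DEFAULT_ALPHA = 0.05
DEFAULT_LFC = 0.5


@dataclass
class DEResult:
    """Per-gene moderated-t differential expression summary."""

    table: pd.DataFrame  # index gene; log2fc, mean_expr, t, p, adj_p, significant
    prior_df: float = np.nan
    prior_var: float = np.nan
    group_sizes: tuple = (0, 0)

    def significant_genes(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


@dataclass
class EnrichmentResult:
    """Per-set preranked GSEA summary."""

    table: pd.DataFrame  # index set; es, nes, p, q, size
    leading_edge: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def _fit_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of log(s2) against the theoretical moments
    of log variances under the hierarchical model; returns (d0, s0_sq) with
    d0 = inf when the observed spread is no wider than sampling alone.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e_bar = z.mean()
    var_e = z.var(ddof=1)
    excess = var_e - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        log_s0 = e_bar - special.digamma(df / 2.0) + np.log(df / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (
            e_bar
            - special.digamma(df / 2.0) + np.log(df / 2.0)
            + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        )
    return d0, float(np.exp(log_s0))


def fit_de(
    m,
    group_a,
    group_b,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> DEResult:
    """Two-group moderated-t differential expression (group_a vs group_b).

    ``m`` is a transformed :class:`~stic_atlas.preprocess.AOIMatrix` or a
    genes x samples DataFrame of log2 expression; ``group_a``/``group_b``
    are AOI/column id lists.  log2fc is mean(a) - mean(b).  ``prior_df`` and
    ``prior_var`` override the estimated prior (``prior_df=np.inf`` forces
    full shrinkage to the pooled prior variance).
    """
    values = m.values if hasattr(m, "transformed") else m
    if hasattr(m, "transformed") and not m.transformed:
        raise ValueError("differential expression expects transformed expression")
    A = values.loc[:, list(group_a)].to_numpy(dtype=float)
    B = values.loc[:, list(group_b)].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 AOIs")
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    logfc = mean_a - mean_b
    df_resid = na + nb - 2
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + ((B - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    est_d0, est_s0 = _fit_prior(s2, df_resid)
    d0 = est_d0 if prior_df is None else prior_df
    s0 = est_s0 if prior_var is None else prior_var
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2fc": logfc,
            "mean_expr": (A.sum(axis=1) + B.sum(axis=1)) / (na + nb),
            "t": t,
            "p": p,
            "adj_p": adj,
            "significant": (adj < alpha) & (np.abs(logfc) > lfc_min),
        },
        index=values.index,
    )
    return DEResult(table, d0, s0, (na, nb))


def top_upregulated_unique(
    de_per_subtype: dict[str, DEResult], n: int = 50
) -> dict[str, list[str]]:
    """Top-n uniquely upregulated signature genes per subtype.

    Eligible genes are significant and upregulated in the subtype-vs-rest
    contrast, ranked by moderated t descending; genes significant-up in two
    or more subtypes are removed from every list before truncation.
    """
    up: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {}
    for s, res in de_per_subtype.items():
        t = res.table
        sel = t[t["significant"] & (t["log2fc"] > 0)]
        up[s] = sel.sort_values("t", ascending=False)
        for g in sel.index:
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, c in counts.items() if c >= 2}
    out: dict[str, list[str]] = {}
    for s, sel in up.items():
        genes = [g for g in sel.index if g not in shared][:n]
        if len(genes) < n:
            warnings.warn(
                f"subtype {s}: only {len(genes)} unique upregulated genes (asked {n})"
            )
        out[s] = genes
    return out


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _running_es(scores: np.ndarray, in_set: np.ndarray, weight: float):
    """Signed max-deviation running sum; returns (ES, extremum index)."""
    n = len(scores)
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0, -1
    w = np.abs(scores) ** weight
    hit = np.where(in_set, w, 0.0)
    denom = hit.sum()
    if denom == 0:  # all hit scores are exactly 0 under positive weight
        hit = in_set.astype(float)
        denom = hit.sum()
    p_hit = np.cumsum(hit) / denom
    p_miss = np.cumsum(~in_set) / (n - n_hit)
    running = p_hit - p_miss
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def gsea_preranked(
    ranking: pd.Series,
    gene_sets: dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked GSEA with a seeded gene-set-resampling null.

    ``ranking`` maps gene -> score (larger = more associated with the
    phenotype of interest); genes are walked in descending score order.
    For each set, p = (1 + #{same-sign null |ES| >= |ES|}) / (n_perm + 1)
    and NES = ES / mean |same-sign null ES|; q is BH across sets.
    """
    ranking = ranking.sort_values(ascending=False)
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(dtype=float)
    n = len(genes)
    index_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    leading: dict[str, list[str]] = {}
    for name, members in gene_sets.items():
        idx = np.array(sorted({index_of[g] for g in members if g in index_of}), dtype=int)
        if len(idx) == 0:
            raise ValueError(f"gene set {name!r} has no genes in the ranking")
        in_set = np.zeros(n, dtype=bool)
        in_set[idx] = True
        es, peak = _running_es(scores, in_set, weight)
        k = len(idx)
        null = np.empty(n_perm)
        for b in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=k, replace=False)] = True
            null[b], _ = _running_es(scores, mask, weight)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        n_same = len(same)
        p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (n_perm + 1)
        mean_same = np.mean(np.abs(same)) if n_same else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else 0.0
        if es >= 0:
            le = [g for g in genes[: peak + 1] if in_set[index_of[g]]] if peak >= 0 else []
        else:
            le = [g for g in genes[peak:] if in_set[index_of[g]]] if peak >= 0 else []
        leading[name] = le
        rows.append((name, es, nes, p, k))
    table = pd.DataFrame(rows, columns=["set", "es", "nes", "p", "size"]).set_index("set")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return EnrichmentResult(table[["es", "nes", "p", "q", "size"]], leading)


# ---------------------------------------------------------------------------
# GMT files
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (set name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
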