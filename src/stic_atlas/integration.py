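"""RNA-DNA integration: molecular distances and cytoband-level correlation.

Molecular distance places each lesion relative to reference expression
centroids (normal tube epithelium, carcinoma, mesothelium) by Euclidean
distance over the union of the subtype signature genes.  Cytoband
integration annotates genes with the band containing their start
coordinate and correlates each gene's expression with the log2 ratio of
the DNA segment covering it across matched samples (Pearson, BH-corrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from stic_atlas.expression_stats import bh_adjust
from stic_atlas.genome import GenomeModel
from stic_atlas.preprocess import AOIMatrix


@dataclass
class CytobandMap:
    """Gene -> cytoband assignment plus the reverse band -> genes index."""

    genes: pd.DataFrame  # index gene; chrom, start, end, band
    unmapped: list[str] = field(default_factory=list)

    def genes_in_band(self, band: str) -> list[str]:
        return self.genes.index[self.genes["band"] == band].tolist()


def reference_centroids(
    m: AOIMatrix,
    groups=("NFT", "HGSC", "mesothelium"),
    group_key: str = "diagnosis",
    genes=None,
) -> pd.DataFrame:
    """Per-gene mean expression centroid for each reference group.

    Returns a genes x groups DataFrame, restricted to ``genes`` (e.g. the
    signature union) when given.
    """
    cols = {}
    for g in groups:
        aois = m.meta.index[m.meta[group_key] == g]
        aois = aois.intersection(m.aoi_ids)
        if len(aois) == 0:
            raise ValueError(f"no AOIs for reference group {g!r}")
        cols[g] = m.values.loc[:, aois].mean(axis=1)
    out = pd.DataFrame(cols)
    if genes is not None:
        out = out.loc[list(genes)]
    return out


def molecular_distance(sample_expr: pd.Series, centroid: pd.Series, signature_genes) -> float:
    """Euclidean distance over the signature gene subspace."""
    sig = list(signature_genes)
    if len(sig) == 0:
        raise ValueError("empty signature gene set")
    a = sample_expr.loc[sig].to_numpy(dtype=float)
    b = centroid.loc[sig].to_numpy(dtype=float)
    return float(np.linalg.norm(a - b))


def map_genes_to_cytobands(gene_coords: pd.DataFrame, genome: GenomeModel) -> CytobandMap:
    """Assign each gene to the band containing its start (half-open)."""
    if (gene_coords["start"] < 0).any() or (gene_coords["end"] <= gene_coords["start"]).any():
        bad = gene_coords.index[
            (gene_coords["start"] < 0) | (gene_coords["end"] <= gene_coords["start"])
        ].tolist()
        raise ValueError(f"malformed gene coordinates: {bad[:5]}")
    bands = genome.cytobands
    rows, unmapped = [], []
    for chrom, sub in gene_coords.groupby("chrom", sort=False):
        cband = bands[bands["chrom"] == chrom].sort_values("start")
        starts = cband["start"].to_numpy()
        ends = cband["end"].to_numpy()
        names = cband["name"].to_numpy()
        pos = sub["start"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        for g, p, e, i in zip(sub.index, pos, sub["end"].to_numpy(), idx):
            if i >= 0 and p < ends[i]:
                rows.append((g, chrom, int(p), int(e), names[i]))
            else:
                unmapped.append(g)
    mapped = pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "band"]
    ).set_index("gene")
    return CytobandMap(mapped.loc[gene_coords.index.intersection(mapped.index)], unmapped)


def _segment_value(segments: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """seg_log2 of the segment overlapping [start, end); longest overlap wins."""
    over = segments[
        (segments["chrom"] == chrom)
        & (segments["start"] < end)
        & (segments["end"] > start)
    ]
    if len(over) == 0:
        return np.nan
    overlap = np.minimum(over["end"], end) - np.maximum(over["start"], start)
    return float(over["seg_log2"].to_numpy()[np.argmax(overlap.to_numpy())])


@dataclass
class CorrelationResult:
    """Per-gene expression vs DNA segment log2 Pearson correlations."""

    table: pd.DataFrame  # index gene; r, p, q, n, band
    excluded: list[str] = field(default_factory=list)


def expression_cn_correlation(
    expr: AOIMatrix,
    segs: dict[str, pd.DataFrame],
    cytoband_map: CytobandMap,
    min_n: int = 3,
    sample_key: str = "patient",
    compartment: str = "epithelial",
) -> CorrelationResult:
    """Correlate gene expression with DNA segment log2 across matched samples.

    ``segs`` maps sample (patient) id -> CBS segment table.  Epithelial AOIs
    sharing a DNA sample are averaged first.  Genes covered by no segment or
    with constant DNA values across samples are excluded with a warning.
    """
    meta = expr.meta.loc[expr.aoi_ids]
    keep = meta.index[(meta["compartment"] == compartment) & meta[sample_key].isin(segs)]
    if len(keep) == 0:
        raise ValueError("no AOIs with matched DNA profiles")
    by_sample = expr.values.loc[:, keep].T.groupby(meta.loc[keep, sample_key]).mean().T
    samples = [s for s in by_sample.columns if s in segs]
    if len(samples) < min_n:
        raise ValueError(f"need >= {min_n} matched samples, have {len(samples)}")

    gmap = cytoband_map.genes
    genes = [g for g in expr.gene_ids if g in gmap.index]
    dna = np.full((len(genes), len(samples)), np.nan)
    for j, s in enumerate(samples):
        seg = segs[s]
        for i, g in enumerate(genes):
            row = gmap.loc[g]
            dna[i, j] = _segment_value(seg, str(row["chrom"]), int(row["start"]), int(row["end"]))

    rows, excluded = [], []
    for i, g in enumerate(genes):
        y = dna[i]
        ok = np.isfinite(y)
        if ok.sum() < min_n:
            excluded.append(g)
            continue
        x = by_sample.loc[g, [samples[j] for j in np.where(ok)[0]]].to_numpy(dtype=float)
        yv = y[ok]
        if np.allclose(yv, yv[0]) or np.allclose(x, x[0]):
            excluded.append(g)
            continue
        r, p = stats.pearsonr(x, yv)
        rows.append((g, r, p, int(ok.sum()), gmap.loc[g, "band"]))
    if excluded:
        warnings.warn(
            f"{len(excluded)} genes excluded (no covering segment or constant values)"
        )
    table = pd.DataFrame(rows, columns=["gene", "r", "p", "n", "band"]).set_index("gene")
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return CorrelationResult(table[["r", "p", "q", "n", "band"]], excluded)
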