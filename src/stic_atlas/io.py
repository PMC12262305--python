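"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (genes x AOIs) or MatrixMarket MTX with
row/column name sidecars; locus counts as 4-column TSV (locus_id, chrom,
pos0, count); reference panels as one TSV per member in a directory;
genomes as BED-like arm and cytoband tables; gene sets as GMT.  All TSV
paths may be gzip-compressed (by extension).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from stic_atlas.genome import GenomeModel, ACROCENTRIC_P_ARMS
from stic_atlas.preprocess import AOIMatrix
from stic_atlas.synthetic import LocusCounts, ReferencePanel


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def write_aoi_matrix(m: AOIMatrix, counts_path, meta_path) -> None:
    m.values.to_csv(counts_path, sep="\t", index_label="gene")
    m.meta.to_csv(meta_path, sep="\t", index_label="aoi")


def read_aoi_matrix(counts_path, meta_path, transformed: bool = False) -> AOIMatrix:
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    values.index.name = None
    meta.index.name = None
    return AOIMatrix(values, meta, transformed=transformed)


def write_mtx(m: AOIMatrix, prefix) -> None:
    """Write counts as MatrixMarket plus gene/AOI name sidecars."""
    prefix = Path(prefix)
    scipy_io.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(m.values.to_numpy()))
    Path(str(prefix) + ".genes.txt").write_text("\n".join(m.gene_ids) + "\n")
    Path(str(prefix) + ".aois.txt").write_text("\n".join(m.aoi_ids) + "\n")


def read_mtx(prefix, meta_path, transformed: bool = False) -> AOIMatrix:
    prefix = Path(prefix)
    mat = scipy_io.mmread(str(prefix) + ".mtx").toarray()
    genes = Path(str(prefix) + ".genes.txt").read_text().splitlines()
    aois = Path(str(prefix) + ".aois.txt").read_text().splitlines()
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return AOIMatrix(pd.DataFrame(mat, index=genes, columns=aois), meta, transformed)


# ---------------------------------------------------------------------------
# DNA
# ---------------------------------------------------------------------------

def write_locus_counts(s: LocusCounts, path) -> None:
    df = s.loci.copy()
    df["count"] = s.counts
    df.to_csv(path, sep="\t", index=False)


def read_locus_counts(path, sample_id: str | None = None) -> LocusCounts:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    loci = df[["locus_id", "chrom", "pos0"]].reset_index(drop=True)
    if sample_id is None:
        sample_id = Path(path).name.split(".")[0]
    return LocusCounts(sample_id, loci, df["count"].to_numpy())


def write_panel(panel: ReferencePanel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, mid in enumerate(panel.member_ids):
        write_locus_counts(panel.member(i), directory / f"{mid}.tsv")


def read_panel(directory) -> ReferencePanel:
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no panel member TSVs in {directory}")
    members = [read_locus_counts(p) for p in paths]
    loci = members[0].loci
    for m in members[1:]:
        if not (m.loci["locus_id"].to_numpy() == loci["locus_id"].to_numpy()).all():
            raise ValueError(f"panel member {m.sample_id} has mismatched loci")
    return ReferencePanel(loci, np.array([m.counts for m in members]),
                          [m.sample_id for m in members])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def write_genome(genome: GenomeModel, arms_path, cytobands_path) -> None:
    genome.to_bed().to_csv(arms_path, sep="\t", index=False)
    genome.cytobands.to_csv(cytobands_path, sep="\t", index=False)


def read_genome(arms_path, cytobands_path) -> GenomeModel:
    arms = pd.read_csv(arms_path, sep="\t", dtype={"chrom": str})
    bands = pd.read_csv(cytobands_path, sep="\t", dtype={"chrom": str})
    chroms: dict[str, int] = {}
    cens: dict[str, int] = {}
    for chrom, sub in arms.groupby("chrom", sort=False):
        chroms[chrom] = int(sub["end"].max())
        p = sub[sub["name"].str.endswith("p")]
        cens[chrom] = int(p["end"].iloc[0]) if len(p) else int(sub["start"].min())
    return GenomeModel(chroms, cens, ACROCENTRIC_P_ARMS, bands)


def write_gene_coords(coords: pd.DataFrame, path) -> None:
    coords.reset_index().rename(columns={"index": "gene"}).to_csv(
        path, sep="\t", index=False
    )


def read_gene_coords(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df.set_index("gene")


# ---------------------------------------------------------------------------
# misc tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
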