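"""Genome models: chromosome arms and cytobands for aneuploidy scoring.

Two bundled models are provided.  The *toy* genome is a miniature 22-autosome
genome (10 Mb per chromosome) built for fast simulation; it preserves the
structural facts the aneuploidy machinery relies on: a p/q split per
chromosome, five acrocentric p-arms excluded from scoring (so exactly 39
scoreable arms remain), and named cytobands including the focal-amplification
targets 19q12, 19q13.2 and 8q24.  The *hg* genome uses real GRCh37 autosome
lengths with approximate centromere and target-band coordinates; generic
filler bands tile the remaining arms.

Coordinates are 0-based, intervals half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# p-arms of the acrocentric autosomes carry no scoreable sequence
ACROCENTRIC_P_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p"})

# GRCh37 autosome lengths (bp)
_HG_LENGTHS = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}

# approximate GRCh37 centromere midpoints (bp)
_HG_CENTROMERES = {
    "1": 125_000_000, "2": 93_300_000, "3": 91_000_000, "4": 50_400_000,
    "5": 48_400_000, "6": 61_000_000, "7": 59_900_000, "8": 45_600_000,
    "9": 49_000_000, "10": 40_200_000, "11": 53_700_000, "12": 35_800_000,
    "13": 17_900_000, "14": 17_600_000, "15": 19_000_000, "16": 36_600_000,
    "17": 24_000_000, "18": 17_200_000, "19": 26_500_000, "20": 27_500_000,
    "21": 13_200_000, "22": 14_700_000,
}


@dataclass
class Arm:
    """A chromosome arm interval [start, end)."""

    chrom: str
    name: str  # e.g. "17p"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeModel:
    """Ordered autosomes with arm boundaries and named cytobands.

    Parameters
    ----------
    chromosomes
        Ordered mapping chromosome name -> length in bp.
    centromeres
        Chromosome name -> p/q boundary in bp.
    acrocentric_p_arms
        Arm names (e.g. ``"13p"``) excluded from arm-level scoring.
    cytobands
        DataFrame with columns ``chrom, start, end, name`` (half-open,
        0-based, non-overlapping within a chromosome).
    """

    chromosomes: dict[str, int]
    centromeres: dict[str, int]
    acrocentric_p_arms: frozenset[str] = field(default_factory=frozenset)
    cytobands: pd.DataFrame = None

    def __post_init__(self) -> None:
        for chrom, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            cen = self.centromeres.get(chrom)
            if cen is None or not (0 < cen < length):
                raise ValueError(f"centromere of chromosome {chrom} outside [0, length]")
        if self.cytobands is not None:
            bad = self.cytobands[
                (self.cytobands["start"] < 0)
                | (self.cytobands["end"] <= self.cytobands["start"])
            ]
            if len(bad):
                raise ValueError(f"malformed cytoband intervals: {bad['name'].tolist()}")
            for _, row in self.cytobands.iterrows():
                if row["end"] > self.chromosomes[str(row["chrom"])]:
                    raise ValueError(f"cytoband {row['name']} exceeds chromosome length")

    # ---- arms -----------------------------------------------------------
    def all_arms(self) -> list[Arm]:
        arms: list[Arm] = []
        for chrom, length in self.chromosomes.items():
            cen = self.centromeres[chrom]
            arms.append(Arm(chrom, f"{chrom}p", 0, cen))
            arms.append(Arm(chrom, f"{chrom}q", cen, length))
        return arms

    def scoreable_arms(self) -> list[Arm]:
        """Arms entering arm-level Z-scoring (non-acrocentric autosome arms)."""
        return [a for a in self.all_arms() if a.name not in self.acrocentric_p_arms]

    def arm_by_name(self, name: str) -> Arm:
        for a in self.all_arms():
            if a.name == name:
                return a
        raise KeyError(f"unknown arm {name!r}")

    def arm_of(self, chrom: str, pos: int) -> str:
        cen = self.centromeres[chrom]
        return f"{chrom}p" if pos < cen else f"{chrom}q"

    # ---- cytobands ------------------------------------------------------
    def band_by_name(self, name: str) -> pd.Series:
        hit = self.cytobands[self.cytobands["name"] == name]
        if len(hit) == 0:
            raise KeyError(f"unknown cytoband {name!r}")
        return hit.iloc[0]

    def band_of(self, chrom: str, pos: int) -> str | None:
        """Name of the band containing position ``pos`` (half-open), or None."""
        sub = self.cytobands[self.cytobands["chrom"] == chrom]
        hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
        return None if len(hit) == 0 else str(hit.iloc[0]["name"])

    @property
    def total_length(self) -> int:
        return int(sum(self.chromosomes.values()))

    def to_bed(self) -> pd.DataFrame:
        """Arms as a BED-like frame (chrom, start, end, name)."""
        return pd.DataFrame(
            [(a.chrom, a.start, a.end, a.name) for a in self.all_arms()],
            columns=["chrom", "start", "end", "name"],
        )


def _split_bands(chrom: str, arm: str, start: int, end: int, n: int) -> list[tuple]:
    edges = np.linspace(start, end, n + 1).astype(int)
    return [
        (chrom, int(edges[i]), int(edges[i + 1]), f"{chrom}{arm}{i + 1}")
        for i in range(n)
    ]


def toy_genome() -> GenomeModel:
    """Miniature 22-autosome genome: 10 Mb chromosomes, p/q split at 4 Mb.

    Acrocentric p-arms (13p, 14p, 15p, 21p, 22p) are excluded from scoring,
    leaving 39 scoreable arms.  Chromosome 19q carries named bands including
    19q12 and 19q13.2; chromosome 8q carries 8q24.
    """
    chroms = {str(i): 10_000_000 for i in range(1, 23)}
    cens = {str(i): 4_000_000 for i in range(1, 23)}
    rows: list[tuple] = []
    for c in chroms:
        if c == "19":
            rows += _split_bands("19", "p", 0, 4_000_000, 2)
            rows += [
                ("19", 4_000_000, 5_000_000, "19q11"),
                ("19", 5_000_000, 6_500_000, "19q12"),
                ("19", 6_500_000, 7_500_000, "19q13.1"),
                ("19", 7_500_000, 9_000_000, "19q13.2"),
                ("19", 9_000_000, 10_000_000, "19q13.3"),
            ]
        elif c == "8":
            rows += _split_bands("8", "p", 0, 4_000_000, 2)
            rows += [
                ("8", 4_000_000, 6_000_000, "8q21"),
                ("8", 6_000_000, 7_000_000, "8q22"),
                ("8", 7_000_000, 8_000_000, "8q23"),
                ("8", 8_000_000, 10_000_000, "8q24"),
            ]
        else:
            rows += _split_bands(c, "p", 0, 4_000_000, 2)
            rows += _split_bands(c, "q", 4_000_000, 10_000_000, 3)
    bands = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return GenomeModel(chroms, cens, ACROCENTRIC_P_ARMS, bands)


def hg_genome() -> GenomeModel:
    """GRCh37-scaled genome from the bundled static table (no download).

    Chromosome lengths are exact GRCh37 values; centromeres and the target
    bands 19q12, 19q13.2 and 8q24 use approximate literature coordinates.
    Remaining arms are tiled with three generic filler bands each.
    """
    rows: list[tuple] = []
    for c, length in _HG_LENGTHS.items():
        cen = _HG_CENTROMERES[c]
        if c == "19":
            rows += _split_bands("19", "p", 0, cen, 3)
            rows += [
                ("19", cen, 28_500_000, "19q11"),
                ("19", 28_500_000, 30_800_000, "19q12"),
                ("19", 30_800_000, 37_800_000, "19q13.1"),
                ("19", 37_800_000, 43_100_000, "19q13.2"),
                ("19", 43_100_000, 51_100_000, "19q13.3"),
                ("19", 51_100_000, length, "19q13.4"),
            ]
        elif c == "8":
            rows += _split_bands("8", "p", 0, cen, 3)
            rows += [
                ("8", cen, 52_000_000, "8q11"),
                ("8", 52_000_000, 57_000_000, "8q12"),
                ("8", 57_000_000, 66_000_000, "8q13"),
                ("8", 66_000_000, 84_000_000, "8q21"),
                ("8", 84_000_000, 97_000_000, "8q22"),
                ("8", 97_000_000, 117_700_000, "8q23"),
                ("8", 117_700_000, length, "8q24"),
            ]
        else:
            rows += _split_bands(c, "p", 0, cen, 3)
            rows += _split_bands(c, "q", cen, length, 3)
    bands = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return GenomeModel(dict(_HG_LENGTHS), dict(_HG_CENTROMERES), ACROCENTRIC_P_ARMS, bands)


def get_genome(mode: str = "toy") -> GenomeModel:
    if mode == "toy":
        return toy_genome()
    if mode == "hg":
        return hg_genome()
    raise ValueError(f"unknown genome_mode {mode!r} (expected 'toy' or 'hg')")
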