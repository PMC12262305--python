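"""Synthetic STIC cohort generator.

Emulates the data structure of a spatial precancer atlas so that every
downstream stage is testable without external downloads:

* a genes x AOIs negative-binomial count matrix with four epithelial STIC
  subtypes (dormant, mixed, immunoreactive, proliferative), reference
  normal fallopian-tube (NFT), carcinoma (HGSC) and mesothelium profiles,
  per-run batch shifts, and per-AOI depth variation;
* per-patient genome-wide locus counts with arm-level gains/losses and
  focal amplifications at designated cytobands, plus a euploid reference
  panel over the same loci;
* subtype-conditional clinicopathological covariates.

Subtype geometry is built to mirror the biology by construction: subtype
signature amplitudes grow from dormant to proliferative (so dormant sits
closest to NFT), and the HGSC centroid loads most heavily on the
proliferative signature (so proliferative sits closest to HGSC).

Every output is a pure function of the configuration and its seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from stic_atlas import cohorts
from stic_atlas.genome import GenomeModel, get_genome
from stic_atlas.preprocess import AOIMatrix

SUBTYPES = ("dormant", "mixed", "immunoreactive", "proliferative")
REFERENCE_GROUPS = ("NFT", "HGSC", "mesothelium")


def _default_patients() -> dict[str, int]:
    return {s: 10 for s in SUBTYPES}


def _default_amplitude() -> dict[str, float]:
    # equal signature amplitudes: the four subtypes are symmetric, well-
    # separated clusters, which is what makes consensus rank selection behave
    return {s: 1.0 for s in SUBTYPES}


def _default_hgsc_loadings() -> dict[str, float]:
    # how strongly the carcinoma centroid expresses each subtype signature;
    # the proliferative program dominates, so proliferative lesions sit
    # molecularly closest to carcinoma
    return {"dormant": 0.1, "mixed": 0.3, "immunoreactive": 0.5, "proliferative": 1.0}


def _default_nft_loadings() -> dict[str, float]:
    # normal tube epithelium shares the dormant program (tubal
    # differentiation markers), placing dormant lesions nearest to NFT
    return {"dormant": 0.4}


def _default_cn_events() -> dict[str, list[tuple[str, float]]]:
    """Per-subtype copy-number events (arm or cytoband name, log2 shift).

    Losses of chromosomes 13/17/22 material recur across subtypes while the
    proliferative subtype carries the focal 19q12/8q24 amplifications, so
    every event region except 17p varies across the cohort.  Magnitudes
    reflect laser-capture purity of roughly 80%: a clonal single-copy loss
    appears as log2(1 - 0.8/2) ~ -0.7, a single-copy gain as log2(3/2) ~
    +0.58, and multi-copy focal amplifications around +1.
    """
    return {
        "dormant": [("13q", -0.7), ("17p", -0.7), ("17q", -0.7)],
        "mixed": [("13q", -0.7), ("17p", -0.7), ("22q", -0.7)],
        "immunoreactive": [("13q", -0.7), ("17p", -0.7), ("17q", -0.7), ("22q", -0.7)],
        "proliferative": [("17p", -0.7), ("3q", 0.58), ("19q12", 1.0), ("8q24", 1.0)],
    }


@dataclass
class SynthConfig:
    """Cohort-level simulation parameters.

    The defaults give 40 epithelial AOIs per subtype (10 patients x 4 AOIs),
    2,000 genes with 50 uniquely upregulated signature genes per subtype at a
    mean log2 fold change of 2, four simulated runs as batches, a 20,000-locus
    toy genome at 500k reads per DNA sample, and clinicopathological
    distributions taken from the bundled 166-lesion reference cohort.
    """

    n_patients_per_subtype: dict[str, int] = field(default_factory=_default_patients)
    n_aois_per_patient: int = 4
    n_nft: int = 20
    n_hgsc: int = 10
    n_meso: int = 10
    n_stromal: int = 20
    n_genes: int = 2000
    n_signature_per_subtype: int = 50
    signature_log2fc: float = 2.0
    subtype_amplitude: dict[str, float] = field(default_factory=_default_amplitude)
    hgsc_loadings: dict[str, float] = field(default_factory=_default_hgsc_loadings)
    nft_loadings: dict[str, float] = field(default_factory=_default_nft_loadings)
    n_hgsc_extra: int = 50
    n_meso_signature: int = 50
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    dispersion_meanlog: float = math.log(0.25)
    dispersion_sdlog: float = 0.5
    aoi_depth_sdlog: float = 0.3
    batch_count: int = 4
    batch_sd: float = 0.3
    genome_mode: str = "toy"
    n_loci: int = 20_000
    depth: int = 500_000
    locus_noise_sd: float = 0.1
    cn_events: dict[str, list[tuple[str, float]]] = field(default_factory=_default_cn_events)
    cn_jitter: float = 0.15
    cn_expression_coupling: float = 1.0
    clinpath_probs: dict[str, pd.DataFrame] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for s, n in self.n_patients_per_subtype.items():
            if s not in SUBTYPES:
                raise ValueError(f"unknown subtype {s!r}")
            if n <= 0:
                raise ValueError(f"n_patients_per_subtype[{s!r}] must be > 0")
        for name in ("n_aois_per_patient", "n_nft", "n_hgsc", "n_meso", "n_genes",
                     "n_loci", "depth", "batch_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        demand = (
            len(SUBTYPES) * self.n_signature_per_subtype
            + self.n_hgsc_extra
            + self.n_meso_signature
            + (50 if self.n_stromal else 0)
        )
        if demand > self.n_genes:
            raise ValueError(
                f"signature gene demand ({demand}) exceeds n_genes ({self.n_genes})"
            )
        if self.clinpath_probs is not None:
            for var, tab in self.clinpath_probs.items():
                sums = tab.sum(axis=0)
                if not np.allclose(sums, 1.0, atol=1e-6):
                    raise ValueError(f"clinpath probabilities for {var!r} do not sum to 1")


@dataclass
class LocusCounts:
    """Genome-wide locus read counts for one DNA sample."""

    sample_id: str
    loci: pd.DataFrame  # columns: locus_id, chrom, pos0 (sorted)
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.loci):
            raise ValueError("counts and loci length mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative locus counts")
        if self.total == 0:
            raise ValueError(f"sample {self.sample_id}: zero total reads")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ReferencePanel:
    """Euploid reference samples sharing one locus list."""

    loci: pd.DataFrame
    counts: np.ndarray  # members x loci
    member_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if self.counts.shape != (len(self.member_ids), len(self.loci)):
            raise ValueError("panel shape mismatch")
        if self.size < 8:
            raise ValueError(
                f"reference panel needs >= 8 members for subset matching, got {self.size}"
            )

    @property
    def size(self) -> int:
        return self.counts.shape[0]

    def member(self, i: int) -> LocusCounts:
        return LocusCounts(self.member_ids[i], self.loci, self.counts[i])

    def fractions(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def subset(self, idx) -> "ReferencePanel":
        """Panel restricted to members ``idx`` (validation relaxed for n < 8)."""
        sub = object.__new__(ReferencePanel)
        sub.loci = self.loci
        sub.counts = self.counts[np.asarray(idx)]
        sub.member_ids = [self.member_ids[i] for i in idx]
        return sub


@dataclass
class CohortBundle:
    """Everything the downstream pipeline consumes, plus truth labels."""

    expression: AOIMatrix
    samples: pd.DataFrame
    locus_counts: dict[str, LocusCounts]
    panel: ReferencePanel
    genome: GenomeModel
    gene_coords: pd.DataFrame
    truth: dict

    @property
    def config(self) -> SynthConfig:
        return self.truth["config"]


# ---------------------------------------------------------------------------
# genome loci
# ---------------------------------------------------------------------------

def generate_loci(genome: GenomeModel, n_loci: int, seed) -> pd.DataFrame:
    """Place ``n_loci`` amplicon-style loci uniformly over the genome (seeded)."""
    rng = np.random.default_rng(seed)
    chroms = list(genome.chromosomes)
    lengths = np.array([genome.chromosomes[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_loci, p=lengths / lengths.sum())
    pos = (rng.random(n_loci) * lengths[chrom_idx]).astype(np.int64)
    df = pd.DataFrame(
        {"chrom": [chroms[i] for i in chrom_idx], "pos0": pos}
    )
    order = np.lexsort((df["pos0"].to_numpy(),
                        df["chrom"].map({c: i for i, c in enumerate(chroms)}).to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    df.insert(0, "locus_id", [f"L{i:06d}" for i in range(n_loci)])
    return df


def _region_interval(genome: GenomeModel, name: str) -> tuple[str, int, int]:
    """Resolve an arm name (e.g. ``17p``) or cytoband name to an interval."""
    try:
        arm = genome.arm_by_name(name)
        return arm.chrom, arm.start, arm.end
    except KeyError:
        band = genome.band_by_name(name)
        return str(band["chrom"]), int(band["start"]), int(band["end"])


def _locus_multiplier(
    loci: pd.DataFrame, genome: GenomeModel, events: list[tuple[str, float]]
) -> np.ndarray:
    mult = np.ones(len(loci))
    for name, log2 in events:
        chrom, start, end = _region_interval(genome, name)
        mask = (
            (loci["chrom"].to_numpy() == chrom)
            & (loci["pos0"].to_numpy() >= start)
            & (loci["pos0"].to_numpy() < end)
        )
        mult[mask] *= 2.0 ** log2
    return mult


def generate_dna_sample(
    sample_id: str,
    loci: pd.DataFrame,
    weights: np.ndarray,
    genome: GenomeModel,
    events: list[tuple[str, float]],
    depth: int,
    seed,
    locus_noise_sd: float = 0.1,
) -> LocusCounts:
    """Simulate one DNA sample: multinomial reads over noisy weighted loci.

    Per-locus amplification propensities ``weights`` are shared with the
    reference panel; the sample adds a log-normal per-locus perturbation
    (``locus_noise_sd``) and copy-number multipliers ``2**log2`` over the
    event regions before multinomial read sampling at the given depth.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    noisy = weights * np.exp(rng.normal(0.0, locus_noise_sd, size=len(loci)))
    noisy *= _locus_multiplier(loci, genome, events)
    counts = rng.multinomial(depth, noisy / noisy.sum())
    return LocusCounts(sample_id, loci, counts)


def generate_reference_panel(
    genome: GenomeModel,
    n: int = 30,
    depth: int = 500_000,
    seed: int = 0,
    loci: pd.DataFrame | None = None,
    weights: np.ndarray | None = None,
    n_loci: int = 20_000,
    locus_noise_sd: float = 0.1,
) -> ReferencePanel:
    """Generate ``n`` euploid reference samples over shared loci."""
    if n < 8:
        raise ValueError(f"panel size must be >= 8 (subset matching uses 7), got {n}")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_loci, s_w, *s_members = ss.spawn(2 + n)
    if loci is None:
        loci = generate_loci(genome, n_loci, s_loci)
    if weights is None:
        weights = np.exp(np.random.default_rng(s_w).normal(0.0, 1.0, size=len(loci)))
    rows = [
        generate_dna_sample(
            f"REF{i:02d}", loci, weights, genome, [], depth, s_members[i], locus_noise_sd
        ).counts
        for i in range(n)
    ]
    return ReferencePanel(loci, np.array(rows), [f"REF{i:02d}" for i in range(n)])


# ---------------------------------------------------------------------------
# clinicopathological covariates
# ---------------------------------------------------------------------------

def generate_clinpath(
    subtype_labels: pd.Series,
    clinpath_probs: dict[str, pd.DataFrame] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-patient covariates from subtype-conditional multinomials.

    ``subtype_labels`` maps patient id -> subtype.  ``clinpath_probs`` maps
    covariate -> (levels x subtypes) probability table; columns must cover
    every subtype present (matched case-insensitively).  Defaults to the
    bundled reference-cohort proportions.
    """
    if clinpath_probs is None:
        clinpath_probs = cohorts.default_clinpath_probs()
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=subtype_labels.index)
    out["subtype"] = subtype_labels
    for var, tab in clinpath_probs.items():
        colmap = {c.lower(): c for c in tab.columns}
        levels = list(tab.index)
        draws = []
        for pid in subtype_labels.index:
            s = str(subtype_labels.loc[pid]).lower()
            if s not in colmap:
                raise ValueError(f"unknown subtype label {subtype_labels.loc[pid]!r}")
            p = tab[colmap[s]].to_numpy(dtype=float)
            if not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ValueError(f"probabilities for {var!r}/{s!r} do not sum to 1")
            draws.append(levels[rng.choice(len(levels), p=p / p.sum())])
        out[var] = draws
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Negative binomial with var = mu + disp * mu^2 (gamma-Poisson)."""
    shape = 1.0 / disp
    lam = rng.gamma(shape, mean * disp)
    return rng.poisson(lam)


def generate_cohort(config: SynthConfig) -> CohortBundle:
    """Generate the full synthetic cohort bundle from one configuration."""
    ss = np.random.SeedSequence(config.seed)
    s_genes, s_expr, s_dna, s_clin, s_coords = ss.spawn(5)
    genome = get_genome(config.genome_mode)
    rng_g = np.random.default_rng(s_genes)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    baseline = rng_g.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                            size=config.n_genes)
    dispersion = np.exp(rng_g.normal(config.dispersion_meanlog, config.dispersion_sdlog,
                                     size=config.n_genes))

    # disjoint signature blocks
    pool = rng_g.permutation(config.n_genes)
    cursor = 0
    signatures: dict[str, np.ndarray] = {}
    for s in SUBTYPES:
        signatures[s] = pool[cursor:cursor + config.n_signature_per_subtype]
        cursor += config.n_signature_per_subtype
    hgsc_extra = pool[cursor:cursor + config.n_hgsc_extra]
    cursor += config.n_hgsc_extra
    meso_sig = pool[cursor:cursor + config.n_meso_signature]
    cursor += config.n_meso_signature
    stromal_sig = pool[cursor:cursor + (50 if config.n_stromal else 0)]

    lfc = config.signature_log2fc

    def group_shift(group: str) -> np.ndarray:
        """Log2 deviation of a group centroid from the NFT baseline."""
        shift = np.zeros(config.n_genes)
        if group in SUBTYPES:
            shift[signatures[group]] += config.subtype_amplitude[group] * lfc
        elif group == "NFT":
            for s, w in config.nft_loadings.items():
                shift[signatures[s]] += w * config.subtype_amplitude[s] * lfc
        elif group == "HGSC":
            for s in SUBTYPES:
                shift[signatures[s]] += (
                    config.hgsc_loadings[s] * config.subtype_amplitude[s] * lfc
                )
            shift[hgsc_extra] += lfc
        elif group == "mesothelium":
            shift[meso_sig] += 1.25 * lfc
        elif group == "stroma":
            shift[stromal_sig] += 1.25 * lfc
        return shift

    # ---- patients and AOIs ---------------------------------------------
    patients: list[tuple[str, str]] = []  # (patient_id, group)
    for s in SUBTYPES:
        for i in range(config.n_patients_per_subtype[s]):
            patients.append((f"{s[:4].upper()}{i:02d}", s))
    ref_aois: list[tuple[str, str, str]] = []  # (aoi, patient, group)
    for group, count, tag in (
        ("NFT", config.n_nft, "NFT"),
        ("HGSC", config.n_hgsc, "HGSC"),
        ("mesothelium", config.n_meso, "MESO"),
    ):
        for i in range(count):
            ref_aois.append((f"{tag}{i:02d}_A0", f"{tag}{i:02d}", group))
    stromal_aois = [(f"STRO{i:02d}_A0", f"STRO{i:02d}", "stroma")
                    for i in range(config.n_stromal)]

    aoi_rows: list[dict] = []
    for pid, group in patients:
        for j in range(config.n_aois_per_patient):
            aoi_rows.append(
                {"aoi": f"{pid}_A{j}", "patient": pid, "group": group,
                 "compartment": "epithelial", "diagnosis": "STIC"}
            )
    for aoi, pid, group in ref_aois:
        aoi_rows.append({"aoi": aoi, "patient": pid, "group": group,
                         "compartment": "epithelial", "diagnosis": group})
    for aoi, pid, group in stromal_aois:
        aoi_rows.append({"aoi": aoi, "patient": pid, "group": group,
                         "compartment": "stromal", "diagnosis": "STIC"})
    meta = pd.DataFrame(aoi_rows).set_index("aoi")

    # batches: whole patients assigned round-robin to runs
    patient_order = meta["patient"].drop_duplicates().tolist()
    batch_of = {p: f"run{i % config.batch_count + 1}" for i, p in enumerate(patient_order)}
    meta["batch"] = meta["patient"].map(batch_of)

    # ---- gene coordinates ----------------------------------------------
    rng_c = np.random.default_rng(s_coords)
    chroms = list(genome.chromosomes)
    lens = np.array([genome.chromosomes[c] for c in chroms], dtype=float)
    gidx = rng_c.choice(len(chroms), size=config.n_genes, p=lens / lens.sum())
    gene_len = max(1000, int(genome.total_length / (200 * config.n_genes)) * 10)
    starts = (rng_c.random(config.n_genes) * (lens[gidx] - gene_len)).astype(np.int64)
    gene_coords = pd.DataFrame(
        {"gene": genes, "chrom": [chroms[i] for i in gidx],
         "start": starts, "end": starts + gene_len}
    ).set_index("gene")

    # ---- copy-number events per patient --------------------------------
    rng_d = np.random.default_rng(s_dna)
    patient_events: dict[str, list[tuple[str, float]]] = {}
    for pid, group in patients:
        evs = []
        for name, log2 in config.cn_events.get(group, []):
            jit = 1.0 + rng_d.uniform(-config.cn_jitter, config.cn_jitter)
            evs.append((name, log2 * jit))
        patient_events[pid] = evs

    def gene_cn_shift(pid: str) -> np.ndarray:
        shift = np.zeros(config.n_genes)
        for name, log2 in patient_events.get(pid, []):
            chrom, start, end = _region_interval(genome, name)
            mask = (
                (gene_coords["chrom"].to_numpy() == chrom)
                & (gene_coords["start"].to_numpy() >= start)
                & (gene_coords["start"].to_numpy() < end)
            )
            shift[mask] += config.cn_expression_coupling * log2
        return shift

    # ---- expression counts ---------------------------------------------
    rng_e = np.random.default_rng(s_expr)
    batch_names = sorted(meta["batch"].unique())
    batch_shift = {
        b: rng_e.normal(0.0, config.batch_sd, size=config.n_genes) for b in batch_names
    }
    counts = np.empty((config.n_genes, len(meta)), dtype=np.int64)
    group_shifts = {g: group_shift(g) for g in
                    list(SUBTYPES) + ["NFT", "HGSC", "mesothelium", "stroma"]}
    for j, (aoi, row) in enumerate(meta.iterrows()):
        log2_mu = baseline + group_shifts[row["group"]] + batch_shift[row["batch"]]
        if row["group"] in SUBTYPES and row["compartment"] == "epithelial":
            log2_mu = log2_mu + gene_cn_shift(row["patient"])
        log2_mu = log2_mu + rng_e.normal(0.0, config.aoi_depth_sdlog)
        counts[:, j] = _nb_sample(rng_e, 2.0 ** log2_mu, dispersion)
    expression = AOIMatrix(
        pd.DataFrame(counts, index=genes, columns=meta.index), meta, transformed=False
    )

    # ---- DNA samples and panel -----------------------------------------
    s_loci, s_w, s_panel, s_samples = s_dna.spawn(4)
    loci = generate_loci(genome, config.n_loci, s_loci)
    weights = np.exp(np.random.default_rng(s_w).normal(0.0, 1.0, size=len(loci)))
    panel = generate_reference_panel(
        genome, n=30, depth=config.depth, seed=s_panel,
        loci=loci, weights=weights, locus_noise_sd=config.locus_noise_sd,
    )
    sample_seeds = s_samples.spawn(len(patients))
    locus_counts = {}
    for (pid, group), seed_i in zip(patients, sample_seeds):
        locus_counts[pid] = generate_dna_sample(
            pid, loci, weights, genome, patient_events[pid],
            config.depth, seed_i, config.locus_noise_sd,
        )

    # ---- clinicopathological covariates --------------------------------
    subtype_series = pd.Series({pid: g for pid, g in patients}, name="subtype")
    samples = generate_clinpath(subtype_series, config.clinpath_probs, seed=s_clin)

    # ---- truth ----------------------------------------------------------
    truth_log2 = pd.DataFrame(0.0, index=genes,
                              columns=[pid for pid, _ in patients])
    for pid, _ in patients:
        truth_log2[pid] = gene_cn_shift(pid) / max(config.cn_expression_coupling, 1e-12)
    cn_driven = truth_log2.index[truth_log2.std(axis=1) > 0.15].tolist()
    truth = {
        "config": config,
        "aoi_group": meta["group"].copy(),
        "signatures": {s: [genes[i] for i in signatures[s]] for s in SUBTYPES},
        "hgsc_extra": [genes[i] for i in hgsc_extra],
        "meso_signature": [genes[i] for i in meso_sig],
        "patient_events": patient_events,
        "gene_cn_log2": truth_log2,
        "cn_driven_genes": cn_driven,
        "batch_of": batch_of,
    }
    return CohortBundle(expression, samples, locus_counts, panel, genome,
                        gene_coords, truth)
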