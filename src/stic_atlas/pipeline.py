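"""End-to-end pipeline: simulate -> preprocess -> subtype -> aneuploidy ->
differential expression / enrichment -> integration -> clinicopathological
statistics, driven by a single configuration with one global seed.

Each enabled stage writes its outputs under the run directory and records
parameters, derived seeds and output checksums in ``manifest.json``; rerun
with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from stic_atlas import aneuploidy as an
from stic_atlas import clinpath as cp
from stic_atlas import expression_stats as es
from stic_atlas import integration as integ
from stic_atlas import io as sio
from stic_atlas import preprocess as pp
from stic_atlas import subtyping as st
from stic_atlas.synthetic import SynthConfig, generate_cohort

log = logging.getLogger("stic_atlas")

ALL_STAGES = ("simulate", "preprocess", "subtype", "aneuploidy", "de", "gsea",
              "integrate", "clinpath")


@dataclass
class PipelineConfig:
    """Run directory, global seed, stage switches and per-stage parameters."""

    out: str = "stic_run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in ALL_STAGES}
    )
    simulate: dict = field(default_factory=dict)     # SynthConfig overrides
    preprocess: dict = field(default_factory=dict)   # order, kbet params
    subtype: dict = field(default_factory=lambda: {"ranks": [2, 3, 4, 5, 6], "n_runs": 30})
    aneuploidy: dict = field(default_factory=dict)   # n_perm, alpha, ...
    de: dict = field(default_factory=dict)
    gsea: dict = field(default_factory=lambda: {"n_perm": 200})
    integrate: dict = field(default_factory=dict)
    clinpath: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed offset, kept below 2**31."""
    return (seed * 1000 + ALL_STAGES.index(stage)) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; returns the manifest."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    state: dict = {}

    def record(stage: str, files: list[Path], params: dict, t0: float) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "seed": _stage_seed(config.seed, stage),
            "outputs": {str(f.relative_to(out)): _sha256(f) for f in files},
            "runtime_s": round(time.time() - t0, 2),
        }

    def need(stage: str, key: str):
        if key not in state:
            raise RuntimeError(
                f"stage '{stage}' requires output of a disabled or failed "
                f"upstream stage providing '{key}'"
            )
        return state[key]

    # ---- simulate -------------------------------------------------------
    if config.stages.get("simulate", True):
        t0 = time.time()
        log.info("stage simulate")
        params = dict(config.simulate)
        params.pop("seed", None)
        synth = SynthConfig(**params, seed=_stage_seed(config.seed, "simulate"))
        bundle = generate_cohort(synth)
        d = out / "sim"
        d.mkdir(exist_ok=True)
        sio.write_aoi_matrix(bundle.expression, d / "counts.tsv", d / "meta.tsv")
        bundle.samples.to_csv(d / "samples.tsv", sep="\t", index_label="patient")
        sio.write_genome(bundle.genome, d / "arms.bed", d / "cytobands.bed")
        sio.write_gene_coords(bundle.gene_coords, d / "gene_coords.tsv")
        sio.write_panel(bundle.panel, d / "panel")
        dna = d / "dna"
        dna.mkdir(exist_ok=True)
        for pid, lc in bundle.locus_counts.items():
            sio.write_locus_counts(lc, dna / f"{pid}.tsv")
        es.write_gmt(bundle.truth["signatures"], d / "true_signatures.gmt")
        bundle.truth["aoi_group"].to_csv(d / "truth_groups.tsv", sep="\t",
                                         header=["group"])
        state["bundle"] = bundle
        files = [p for p in d.rglob("*") if p.is_file()]
        record("simulate", files, params, t0)

    # ---- preprocess -----------------------------------------------------
    if config.stages.get("preprocess", True):
        t0 = time.time()
        log.info("stage preprocess")
        bundle = need("preprocess", "bundle")
        order = config.preprocess.get("order", "vst-first")
        raw = bundle.expression
        if order == "vst-first":
            norm = pp.remove_batch_effects(pp.variance_stabilize(raw))
        elif order == "batch-first":
            shifted = pp.remove_batch_effects(
                pp.AOIMatrix(raw.values.astype(float), raw.meta, transformed=True)
            )
            clipped = pp.AOIMatrix(
                shifted.values.clip(lower=0), shifted.meta, transformed=False
            )
            norm = pp.variance_stabilize(clipped)
        else:
            raise ValueError(f"unknown preprocess order {order!r}")
        emb = pp.pca(norm, k=min(10, len(norm.aoi_ids) - 1))
        kbet_seed = _stage_seed(config.seed, "preprocess")
        batches = norm.meta.loc[norm.aoi_ids, "batch"].to_numpy()
        k = int(config.preprocess.get("kbet_k", 25))
        raw_vst = pp.variance_stabilize(raw)
        emb_raw = pp.pca(raw_vst, k=min(10, len(raw_vst.aoi_ids) - 1))
        qc = {
            "kbet_before": pp.batch_mixing_score(emb_raw, batches, k=k, seed=kbet_seed),
            "kbet_after": pp.batch_mixing_score(emb, batches, k=k, seed=kbet_seed),
            "pca_explained_variance": emb.explained_variance.tolist(),
        }
        d = out / "preprocess"
        d.mkdir(exist_ok=True)
        sio.write_aoi_matrix(norm, d / "norm.tsv", d / "meta.tsv")
        (d / "qc.json").write_text(json.dumps(qc, indent=2))
        state["norm"] = norm
        record("preprocess", [d / "norm.tsv", d / "meta.tsv", d / "qc.json"],
               {"order": order, "kbet_k": k}, t0)

    # ---- subtype --------------------------------------------------------
    if config.stages.get("subtype", True):
        t0 = time.time()
        log.info("stage subtype")
        norm = need("subtype", "norm")
        epi = norm.subset_aois(
            norm.meta.index[
                (norm.meta["compartment"] == "epithelial")
                & (norm.meta["diagnosis"] == "STIC")
            ].intersection(norm.aoi_ids)
        )
        X = pp.ensure_nonnegative(epi.values)
        ranks = list(config.subtype.get("ranks", [2, 3, 4, 5, 6]))
        n_runs = int(config.subtype.get("n_runs", 30))
        sseed = _stage_seed(config.seed, "subtype")
        model = st.ConsensusNMF(rank=None, rank_candidates=ranks, n_runs=n_runs,
                                seed=sseed)
        model.fit(X.to_numpy().T)
        labels = pd.Series(model.labels_, index=epi.aoi_ids, name="cluster")
        d = out / "subtype"
        d.mkdir(exist_ok=True)
        labels.to_csv(d / "labels.tsv", sep="\t", index_label="aoi")
        model.rank_metrics_.to_csv(d / "metrics.tsv", sep="\t", index_label="rank")
        pd.DataFrame(model.consensus_, index=epi.aoi_ids, columns=epi.aoi_ids).to_csv(
            d / "consensus.tsv", sep="\t", index_label="aoi"
        )
        state["labels"] = labels
        state["selected_rank"] = model.rank_
        record("subtype", [d / "labels.tsv", d / "metrics.tsv", d / "consensus.tsv"],
               {"ranks": ranks, "n_runs": n_runs, "selected_rank": model.rank_}, t0)

    # ---- aneuploidy -----------------------------------------------------
    if config.stages.get("aneuploidy", True):
        t0 = time.time()
        log.info("stage aneuploidy")
        bundle = need("aneuploidy", "bundle")
        params = {
            "n_perm": int(config.aneuploidy.get("n_perm", 1000)),
            "alpha": float(config.aneuploidy.get("alpha", 0.01)),
        }
        aseed = _stage_seed(config.seed, "aneuploidy")
        arm_rows, seg_frames, focal_rows, idx_rows = [], {}, [], []
        for i, (pid, lc) in enumerate(sorted(bundle.locus_counts.items())):
            arms, segs = an.analyze_dna_sample(
                lc, bundle.panel, bundle.genome,
                n_perm=params["n_perm"], alpha=params["alpha"], seed=aseed + i,
            )
            t = arms.table.copy()
            t.insert(0, "sample", pid)
            arm_rows.append(t.reset_index(names="arm"))
            sf = segs.segments.copy()
            sf.insert(0, "sample", pid)
            seg_frames[pid] = segs.segments
            focal_rows += [
                {"sample": pid, "target": k, **v} for k, v in segs.focal_calls.items()
            ]
            idx_rows.append({"sample": pid, "aneuploidy_index_bp": segs.aneuploidy_index})
            state.setdefault("seg_long", []).append(sf)
        d = out / "aneuploidy"
        d.mkdir(exist_ok=True)
        pd.concat(arm_rows).to_csv(d / "arm_z.tsv", sep="\t", index=False)
        pd.concat(state["seg_long"]).to_csv(d / "segments.tsv", sep="\t", index=False)
        pd.DataFrame(focal_rows).to_csv(d / "focal_calls.tsv", sep="\t", index=False)
        pd.DataFrame(idx_rows).to_csv(d / "aneuploidy_index.tsv", sep="\t", index=False)
        state["segments"] = seg_frames
        record("aneuploidy",
               [d / "arm_z.tsv", d / "segments.tsv", d / "focal_calls.tsv",
                d / "aneuploidy_index.tsv"], params, t0)

    # ---- differential expression ---------------------------------------
    if config.stages.get("de", True):
        t0 = time.time()
        log.info("stage de")
        norm = need("de", "norm")
        labels = need("de", "labels")
        d = out / "de"
        d.mkdir(exist_ok=True)
        de_results = {}
        files = []
        for cluster in sorted(labels.unique()):
            in_c = labels.index[labels == cluster]
            rest = labels.index[labels != cluster]
            res = es.fit_de(norm, in_c, rest)
            de_results[f"cluster{cluster}"] = res
            f = d / f"de_cluster{cluster}.tsv"
            res.table.to_csv(f, sep="\t", index_label="gene")
            files.append(f)
        n_top = int(config.de.get("n_signature", 50))
        sigs = es.top_upregulated_unique(de_results, n=n_top)
        es.write_gmt(sigs, d / "signatures.gmt")
        files.append(d / "signatures.gmt")
        state["de"] = de_results
        state["signatures"] = sigs
        record("de", files, {"n_signature": n_top}, t0)

    # ---- gsea -----------------------------------------------------------
    if config.stages.get("gsea", True):
        t0 = time.time()
        log.info("stage gsea")
        de_results = need("gsea", "de")
        gmt_path = config.gsea.get("gmt")
        sets = es.read_gmt(gmt_path) if gmt_path else need("gsea", "signatures")
        n_perm = int(config.gsea.get("n_perm", 200))
        d = out / "gsea"
        d.mkdir(exist_ok=True)
        files = []
        for name, res in de_results.items():
            ranking = res.table["t"]
            enr = es.gsea_preranked(ranking, sets, n_perm=n_perm,
                                    seed=_stage_seed(config.seed, "gsea"))
            f = d / f"gsea_{name}.tsv"
            enr.table.to_csv(f, sep="\t", index_label="set")
            files.append(f)
        record("gsea", files, {"n_perm": n_perm}, t0)

    # ---- integrate ------------------------------------------------------
    if config.stages.get("integrate", True):
        t0 = time.time()
        log.info("stage integrate")
        bundle = need("integrate", "bundle")
        norm = need("integrate", "norm")
        sigs = need("integrate", "signatures")
        sig_union = sorted({g for genes in sigs.values() for g in genes})
        cents = integ.reference_centroids(norm, genes=sig_union)
        stic = norm.meta.index[
            (norm.meta["diagnosis"] == "STIC")
            & (norm.meta["compartment"] == "epithelial")
        ].intersection(norm.aoi_ids)
        rows = []
        for aoi in stic:
            expr = norm.values[aoi]
            rows.append(
                {"aoi": aoi,
                 **{f"dist_{g}": integ.molecular_distance(expr, cents[g], sig_union)
                    for g in cents.columns}}
            )
        dist = pd.DataFrame(rows).set_index("aoi")
        cmap = integ.map_genes_to_cytobands(bundle.gene_coords, bundle.genome)
        corr_tbl = pd.DataFrame()
        if "segments" in state:
            corr = integ.expression_cn_correlation(norm, state["segments"], cmap)
            corr_tbl = corr.table
        elif config.integrate.get("require_correlation", True):
            raise RuntimeError(
                "stage 'integrate' requires RNA-DNA correlation but the "
                "'aneuploidy' stage is disabled"
            )
        d = out / "integrate"
        d.mkdir(exist_ok=True)
        dist.to_csv(d / "distances.tsv", sep="\t", index_label="aoi")
        corr_tbl.to_csv(d / "expression_cn_correlation.tsv", sep="\t",
                        index_label="gene")
        state["distances"] = dist
        record("integrate", [d / "distances.tsv",
                             d / "expression_cn_correlation.tsv"], {}, t0)

    # ---- clinpath -------------------------------------------------------
    if config.stages.get("clinpath", True):
        t0 = time.time()
        log.info("stage clinpath")
        bundle = need("clinpath", "bundle")
        variables = config.clinpath.get(
            "vars", ["brca_status", "nuclear_atypia", "architecture",
                     "stromal_lymphocytes", "ki67"]
        )
        rows = []
        for var in variables:
            t = cp.contingency_table(bundle.samples, var, "subtype")
            tests = cp.associate(t, seed=_stage_seed(config.seed, "clinpath"))
            sel = tests["selected"]
            rows.append(
                {"variable": var, "method": sel.method, "p": sel.p,
                 "statistic": sel.statistic, "df": sel.df,
                 "chi_square_p": tests.get("chi_square", sel).p
                 if sel.method == "fisher_exact" else sel.p}
            )
        assoc = pd.DataFrame(rows)
        d = out / "clinpath"
        d.mkdir(exist_ok=True)
        assoc.to_csv(d / "associations.tsv", sep="\t", index=False)
        record("clinpath", [d / "associations.tsv"], {"vars": list(variables)}, t0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def validate_inputs(paths: dict[str, str]) -> dict:
    """Check input files for format problems; returns a machine-readable report.

    Recognised keys: ``counts`` + ``meta`` (TSV expression), ``panel``
    (directory), ``sample`` (locus TSV), ``gmt``, ``arms`` + ``cytobands``.
    """
    failures: list[str] = []
    warnings_: list[str] = []
    panel = None
    if "counts" in paths and "meta" in paths:
        try:
            sio.read_aoi_matrix(paths["counts"], paths["meta"])
        except Exception as e:  # noqa: BLE001 - report, don't raise
            failures.append(f"counts/meta: {e}")
    if "panel" in paths:
        try:
            panel = sio.read_panel(paths["panel"])
        except Exception as e:
            failures.append(f"panel: {e}")
    if "sample" in paths:
        try:
            lc = sio.read_locus_counts(paths["sample"])
            if panel is not None:
                if not (lc.loci["locus_id"].to_numpy()
                        == panel.loci["locus_id"].to_numpy()).all():
                    failures.append("sample: locus mismatch with panel")
        except Exception as e:
            failures.append(f"sample: {e}")
    if "gmt" in paths:
        try:
            sets = es.read_gmt(paths["gmt"])
            if not sets:
                failures.append("gmt: no valid gene sets")
            for name, genes in sets.items():
                if len(genes) < 2:
                    warnings_.append(f"gmt: set {name!r} has <2 genes "
                                     "(enrichment unstable)")
        except Exception as e:
            failures.append(f"gmt: {e}")
    if "arms" in paths and "cytobands" in paths:
        try:
            g = sio.read_genome(paths["arms"], paths["cytobands"])
            bed = g.to_bed()
            if not bed.groupby("chrom")["start"].apply(
                lambda s: s.is_monotonic_increasing
            ).all():
                failures.append("arms: BED not sorted by start within chromosome")
        except Exception as e:
            failures.append(f"genome: {e}")
    return {"failures": failures, "warnings": warnings_, "ok": not failures}
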