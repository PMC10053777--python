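"""End-to-end orchestration: config, staged execution, manifest.

A run consumes either real input tables (counts + metadata, GMT, screen and
chemistry TSVs) or generates synthetic ones, then executes: MDS screen ->
common-dispersion NB differential expression -> cross-mixture comparison ->
three-way ORA -> term topology, plus the screen and chemistry summaries
when their tables are present. Every stage writes plain TSV under the
output directory and the manifest records versions, seed, parameters and
per-stage row counts, so a fixed seed reproduces a run byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .diffexpr import (
    LFC_RELAXED,
    LFC_STRICT,
    PADJ_DEFAULT,
    classify_degs,
    estimate_common_dispersion,
    mds_screen,
    nb_wald_contrast,
    size_factors,
    write_contrast_tsv,
)
from .enrichment import filter_terms, hypergeom_enrich, partition_degs
from .mixture_compare import (
    build_lfc_matrix,
    direction_concordance,
    heatmap_structure,
    origin_regression,
    pca_treatments,
)
from .termtopology import build_enrichment_map, reduce_terms

log = logging.getLogger("mixturetox")


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Either the real-input paths (counts/metadata, optionally gmt/tox/chem)
    or ``synthetic=True`` with generator parameters must be given. The
    threshold defaults are the analysis constants: |log2FC| cutoffs 1.0
    (heatmaps/PCA) and 0.5 (GO queries), p_adj 0.05, term-size window
    15-400, overlap-coefficient edge threshold 0.4, Jaccard merge distance
    0.45, top 60 terms per treatment, k-means k=8 with 500 starts.
    """

    outdir: str = "mixturetox_run"
    seed: int = 0
    # real inputs
    counts: str | None = None
    metadata: str | None = None
    gmt: str | None = None
    tox_table: str | None = None
    chem_table: str | None = None
    control_group: str = "control"
    # synthetic mode
    synthetic: bool = False
    n_genes: int = 6000
    samples_per_group: int = 3
    n_terms: int = 120
    n_active_terms: int = 10
    extra_group_scales: dict = field(default_factory=dict)
    beta: float = 0.59
    eps_sd: float = 0.3
    nb_alpha: float = 0.05
    de_fraction: float = 0.1
    # thresholds
    lfc_strict: float = LFC_STRICT
    lfc_relaxed: float = LFC_RELAXED
    padj_max: float = PADJ_DEFAULT
    term_size_min: int = 15
    term_size_max: int = 400
    edge_threshold: float = 0.4
    merge_distance: float = 0.45
    top_n: int = 60
    kmeans_k: int = 8
    kmeans_starts: int = 500
    screen_dilution: float = 0.2
    drop_mds_outliers: bool = False

    def __post_init__(self):
        if not 0 < self.padj_max <= 1:
            raise ValueError("padj_max must be in (0, 1]")
        if self.term_size_min > self.term_size_max:
            raise ValueError("term_size_min > term_size_max")
        if not self.synthetic and (self.counts is None or self.metadata is None):
            raise ValueError("either synthetic mode or counts+metadata paths are required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved in outdir."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }

    state: dict = {}
    stages = [
        ("synthdata", _stage_synthdata),
        ("diffexpr", _stage_diffexpr),
        ("mixture_compare", _stage_compare),
        ("enrichment", _stage_enrichment),
        ("termtopology", _stage_topology),
        ("toxscreen", _stage_toxscreen),
        ("chemistry", _stage_chemistry),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            info = fn(config, state, out)
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            log.error("stage %s failed: %s", name, exc)
            raise StageError(name, exc) from exc
        dt = time.perf_counter() - t0
        if info is None:
            info = {"skipped": True}
        info["wall_s"] = round(dt, 3)
        manifest["stages"][name] = info
        log.info("stage %-16s %6.2fs  %s", name, dt, {k: v for k, v in info.items() if k != "wall_s"})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _setup_logging(logfile: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(sh)
    # one file handler per run
    for h in [h for h in log.handlers if isinstance(h, logging.FileHandler)]:
        log.removeHandler(h)
        h.close()
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    log.addHandler(fh)


def _stage_synthdata(cfg: RunConfig, state: dict, out: Path):
    from . import synthdata as sd

    if not cfg.synthetic:
        state["cm"] = __import__("mixturetox.diffexpr", fromlist=["CountMatrix"]).CountMatrix(
            io.read_counts_tsv(cfg.counts), io.read_metadata_tsv(cfg.metadata)
        )
        state["collection"] = io.read_gmt(cfg.gmt) if cfg.gmt else None
        state["tox"] = pd.read_csv(cfg.tox_table, sep="\t") if cfg.tox_table else None
        state["chem"] = pd.read_csv(cfg.chem_table, sep="\t") if cfg.chem_table else None
        return {"skipped": True, "reason": "real inputs supplied"}

    truth = sd.make_truth(
        cfg.n_genes, de_fraction=cfg.de_fraction, beta=cfg.beta,
        eps_sd=cfg.eps_sd, alpha=cfg.nb_alpha, seed=cfg.seed,
    )
    cm, truth = sd.gen_counts(
        cfg.n_genes, cfg.samples_per_group, truth,
        extra_group_scales=cfg.extra_group_scales or None,
    )
    collection = sd.gen_genesets(
        cfg.n_terms, (cfg.term_size_min, cfg.term_size_max),
        truth=truth, n_active=cfg.n_active_terms,
    )
    tox = sd.gen_toxdata(seed=cfg.seed)
    chem = sd.gen_chemtable(seed=cfg.seed)

    io.write_counts_tsv(cm.counts, out / "counts.tsv")
    io.write_metadata_tsv(cm.groups, out / "metadata.tsv")
    io.write_gmt(collection, out / "genesets.gmt")
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    tox.to_csv(out / "tox_records.tsv", sep="\t", index=False)
    chem.to_csv(out / "chem_table.tsv", sep="\t", index=False)

    state.update(cm=cm, truth=truth, collection=collection, tox=tox, chem=chem)
    return {"n_genes": cm.n_genes, "n_samples": cm.n_samples, "n_terms": len(collection)}


def _stage_diffexpr(cfg: RunConfig, state: dict, out: Path):
    cm = state["cm"]
    mds = mds_screen(cm)
    mds.to_csv(out / "mds_report.tsv", sep="\t")
    n_out = int(mds["outlier_flag"].sum())
    if cfg.drop_mds_outliers and n_out:
        cm = cm.drop_samples(mds.index[mds["outlier_flag"]])
        state["cm"] = cm
    sf = size_factors(cm.counts)
    alpha_hat = estimate_common_dispersion(cm, sf)
    treatments = [g for g in cm.group_names() if g != cfg.control_group]
    contrasts = {}
    for trt in treatments:
        c = nb_wald_contrast(cm, trt, cfg.control_group, alpha_hat, sf)
        contrasts[trt] = c
        write_contrast_tsv(c, out / f"contrast_{trt}.tsv")
    state.update(contrasts=contrasts, alpha_hat=alpha_hat)
    deg_counts = {
        t: len(classify_degs(c, cfg.lfc_strict, cfg.padj_max)) for t, c in contrasts.items()
    }
    return {
        "alpha_hat": round(alpha_hat, 5),
        "mds_outliers": n_out,
        "deg_counts_strict": deg_counts,
    }


def _stage_compare(cfg: RunConfig, state: dict, out: Path):
    contrasts = state["contrasts"]
    if len(contrasts) < 2:
        return {"skipped": True, "reason": "fewer than two treatments"}
    names = list(contrasts)
    a, b = names[0], names[1]
    conc = direction_concordance(
        contrasts[a], contrasts[b], lfc_min=cfg.lfc_strict, padj_max=cfg.padj_max
    )
    pd.DataFrame([{k: v for k, v in conc.items() if k != "discordant_genes"}]).to_csv(
        out / "concordance.tsv", sep="\t", index=False
    )
    lfc = build_lfc_matrix(contrasts, cfg.lfc_strict, cfg.padj_max)
    pair = lfc.values[[a, b]].dropna()
    reg = origin_regression(pair[a], pair[b])
    pd.DataFrame([{**{k: v for k, v in reg.items() if k != "ci95"},
                   "ci_lo": reg["ci95"][0], "ci_hi": reg["ci95"][1],
                   "x": a, "y": b}]).to_csv(out / "origin_regression.tsv", sep="\t", index=False)

    info = {"n_union": conc["n_union"], "n_discordant": conc["n_discordant"],
            "slope": round(reg["slope"], 4), "r2": round(reg["r2"], 4)}
    if lfc.values.shape[0] > cfg.kmeans_k:
        hm = heatmap_structure(lfc, cfg.kmeans_k, cfg.kmeans_starts, seed=cfg.seed)
        hm["gene_cluster_labels"].to_csv(out / "gene_clusters.tsv", sep="\t")
        info["kmeans_best_wss"] = round(hm["best_wss"], 3)
        info["treatment_order"] = hm["treatment_order"]
    if lfc.values.shape[1] >= 3:
        pca = pca_treatments(lfc)
        pca["coordinates"].to_csv(out / "pca_treatments.tsv", sep="\t")
        info["pca_variance_fractions"] = [round(f, 4) for f in pca["variance_fractions"][:3]]
    state["lfc"] = lfc
    return info


def _stage_enrichment(cfg: RunConfig, state: dict, out: Path):
    collection = state.get("collection")
    contrasts = state["contrasts"]
    if collection is None or len(collection) == 0 or len(contrasts) < 2:
        state["enrich"] = None
        return {"skipped": True, "reason": "no gene sets or fewer than two contrasts"}
    names = list(contrasts)
    a, b = names[0], names[1]
    universe = set(contrasts[a].tested_genes()) & set(contrasts[b].tested_genes())
    deg_a = classify_degs(contrasts[a], cfg.lfc_relaxed, cfg.padj_max)
    deg_b = classify_degs(contrasts[b], cfg.lfc_relaxed, cfg.padj_max)
    parts = partition_degs(deg_a, deg_b)
    filtered = filter_terms(collection, cfg.term_size_min, cfg.term_size_max, universe)
    if len(filtered) == 0:
        state["enrich"] = None
        return {"skipped": True, "reason": "no terms within the size window"}

    all_rows = []
    for qid, genes in parts.items():
        if not genes:
            continue
        all_rows.append(hypergeom_enrich(genes, filtered, universe, query_id=qid,
                                         padj_max=cfg.padj_max))
    per_trt = {}
    for trt, deg in zip((a, b), (deg_a, deg_b)):
        per_trt[trt] = hypergeom_enrich(set(deg.genes), filtered, universe, query_id=trt,
                                        padj_max=cfg.padj_max)
    rows = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    if len(rows):
        rows.to_csv(out / "enrichment_threeway.tsv", sep="\t", index=False)
    pd.concat(per_trt.values(), ignore_index=True).to_csv(
        out / "enrichment_per_treatment.tsv", sep="\t", index=False
    )
    state.update(enrich=rows, enrich_per_trt=per_trt, filtered_collection=filtered,
                 universe=universe, partitions=parts)
    n_sig = int(rows["significant"].sum()) if len(rows) else 0
    return {"n_terms_tested": len(filtered),
            "partition_sizes": {k: len(v) for k, v in parts.items()},
            "n_significant_threeway": n_sig}


def _stage_topology(cfg: RunConfig, state: dict, out: Path):
    rows = state.get("enrich")
    if rows is None or not len(rows) or not rows["significant"].any():
        return {"skipped": True, "reason": "no significant enrichment rows"}
    filtered = state["filtered_collection"]
    graph = build_enrichment_map(rows, filtered, cfg.edge_threshold)
    graph.node_table().to_csv(out / "termgraph_nodes.tsv", sep="\t", index=False)
    graph.edge_table().to_csv(out / "termgraph_edges.tsv", sep="\t", index=False)
    graph.write_graphml(out / "termgraph.graphml")
    reduced = reduce_terms(state["enrich_per_trt"], filtered, cfg.top_n, cfg.merge_distance)
    if len(reduced):
        reduced.matrix.to_csv(out / "reduced_terms.tsv", sep="\t")
        reduced.manifest.to_csv(out / "reduced_terms_manifest.tsv", sep="\t", index=False)
    state["termgraph"] = graph
    return {"n_nodes": graph.graph.number_of_nodes(),
            "n_edges": graph.graph.number_of_edges(),
            "n_clusters": graph.n_clusters(),
            "n_reduced_terms": len(reduced)}


def _stage_toxscreen(cfg: RunConfig, state: dict, out: Path):
    from .toxscreen import endpoint_profile, extract_plate_controls, plate_qc

    tox = state.get("tox")
    if tox is None:
        return {"skipped": True, "reason": "no screen table"}
    ctrl = extract_plate_controls(tox)
    qc = plate_qc(ctrl) if len(ctrl) else pd.DataFrame()
    if len(qc):
        qc.to_csv(out / "plate_qc.tsv", sep="\t")
    prof = endpoint_profile(tox, cfg.screen_dilution)
    prof.to_csv(out / "endpoint_profile.tsv", sep="\t")
    return {"n_plates": len(qc), "plates_failed": int((~qc["pass"]).sum()) if len(qc) else 0,
            "n_endpoints": len(prof)}


def _stage_chemistry(cfg: RunConfig, state: dict, out: Path):
    from .chemistry import composition_profile, diagnostic_ratios, sum_pah

    chem = state.get("chem")
    if chem is None:
        return {"skipped": True, "reason": "no chemistry table"}
    samples = sorted(chem["sample"].unique())
    totals = {s: sum_pah(chem, s) for s in samples}
    pd.DataFrame(totals).T.rename_axis("sample").to_csv(out / "pah_totals.tsv", sep="\t")
    ratios = diagnostic_ratios(chem, samples)
    ratios.rename_axis("ratio").to_csv(out / "pah_ratios.tsv", sep="\t")
    for s in samples:
        composition_profile(chem, s).rename_axis("analyte").to_csv(
            out / f"pah_composition_{s}.tsv", sep="\t"
        )
    return {"totals": {s: round(t["total"], 2) for s, t in totals.items()}}


def demo_config(outdir: str = "mixturetox_demo", seed: int = 0) -> RunConfig:
    """Synthetic demonstration run: two mixtures plus one single-chemical arm."""
    return RunConfig(
        outdir=outdir,
        seed=seed,
        synthetic=True,
        n_genes=6000,
        samples_per_group=3,
        extra_group_scales={"singleChem": 0.35},
        kmeans_starts=100,
    )
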