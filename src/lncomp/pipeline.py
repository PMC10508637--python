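"""End-to-end orchestration: simulate -> annotate -> assemble -> network ->
enrich -> hubs, with a machine-readable run manifest recording the filter
funnel (mapped -> classified -> deduplicated -> detected) and per-output
checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import compendium, enrichment, hubs, io, network, probe_annotation
from .config import PipelineConfig
from .synthetic_data import SimulationDesign, simulate_annotation, simulate_expression, simulate_probes
from .types import FinalClass

logger = logging.getLogger("lncomp")

__version__ = "0.1.0"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def funnel_share(numerator: int, denominator: int) -> float:
    """Percentage reported in the funnel (e.g. mapped / platform total)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator outside [0, denominator]")
    return 100.0 * numerator / denominator


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [h for h in logger.handlers if isinstance(h, logging.NullHandler)]
    fmt = logging.Formatter("%(asctime)s [%(stage)s] %(message)s")
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(fmt)
    logger.addHandler(stream)
    fileh = logging.FileHandler(outdir / "run.log")
    fileh.setFormatter(fmt)
    logger.addHandler(fileh)


def _log(stage: str, message: str) -> None:
    logger.info(message, extra={"stage": stage})


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the configured stages in order, writing all stage outputs and a
    JSON manifest under ``outdir``. A stage failure aborts with the failing
    stage named and leaves a FAILED marker next to partial outputs.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    manifest: dict = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": [],
        "funnel": {},
        "outputs": {},
    }
    state: dict = {}
    stage_fns = {
        "simulate": _stage_simulate, "annotate": _stage_annotate,
        "assemble": _stage_assemble, "network": _stage_network,
        "enrich": _stage_enrich, "hubs": _stage_hubs,
    }
    for stage in config.stages:
        _log(stage, "starting")
        try:
            stage_fns[stage](config, out, state, manifest)
        except Exception as exc:  # noqa: BLE001 - rethrown with stage name
            (out / "FAILED").write_text(f"{stage}: {exc}\n")
            raise StageError(stage, exc) from exc
        manifest["stages"].append(stage)
        _log(stage, "done")
    funnel = manifest["funnel"]
    if "n_mapped" in funnel and "n_platform" in funnel:
        funnel["pct_mapped"] = funnel_share(funnel["n_mapped"], funnel["n_platform"])
    for path in sorted(out.iterdir()):
        if path.is_file() and path.name not in ("manifest.json", "run.log"):
            manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ------------------------------------------------------------------- stages

def _design_from_config(config: PipelineConfig) -> SimulationDesign:
    sim = config.simulate
    return SimulationDesign(
        seed=config.seed,
        n_genes=sim.n_genes,
        n_probes_per_class=dict(sim.n_probes_per_class),
        annotation_disagreement_rate=sim.annotation_disagreement_rate,
        tissues=tuple((t[0], int(t[1]), int(t[2])) for t in sim.tissues),
        module_sizes=tuple(sim.module_sizes),
        within_module_cor=sim.within_module_cor,
        noise_sd=sim.noise_sd,
        n_negative_controls=sim.n_negative_controls,
        signal_over_background=sim.signal_over_background,
        tissue_specific_sets=dict(sim.tissue_specific_sets),
        n_never_expressed=sim.n_never_expressed,
    )


def _stage_simulate(config: PipelineConfig, out: Path, state: dict, manifest: dict) -> None:
    design = _design_from_config(config)
    bundle = simulate_annotation(design)
    probes, truth = simulate_probes(bundle, design)
    raw, meta, negctl, truth = simulate_expression(probes, design, truth)

    for source in bundle.sources:
        io.write_gff3(source, bundle.genome, out / f"{source.source_name}.gff3")
    io.write_bed6(probes, out / "probes.bed")
    full = pd.concat([raw, negctl])
    io.write_matrix(full, out / "raw_matrix.tsv")
    io.write_sample_meta(meta, out / "sample_meta.tsv")
    io.write_id_list(list(negctl.index), out / "negative_controls.txt")
    io.write_ground_truth(truth, out / "ground_truth.json")

    # TF / housekeeping lists: deterministic subsets of the planted mRNAs
    mrna = sorted(p for p, c in truth.probe_class.items() if c == "mRNA")
    tf_ids = mrna[::5]
    hkg_ids = mrna[1::4]
    io.write_id_list(tf_ids, out / "tf_list.txt")
    io.write_id_list(hkg_ids, out / "hkg_list.txt")

    # simulated gene sets: one per planted module (its mRNA members) plus
    # deterministic filler sets over the mRNA pool
    sets: dict[str, tuple[str, list[str]]] = {}
    for module in sorted(set(truth.probe_module.values()) - {"grey"}):
        members = sorted(
            p for p, m in truth.probe_module.items()
            if m == module and truth.probe_class.get(p) == "mRNA"
        )
        if members:
            sets[f"SET_{module}"] = (f"planted set for {module}", members)
    for i in range(3):
        sets[f"SET_random{i + 1}"] = ("filler set", mrna[i::3])
    io.write_gmt(sets, out / "gene_sets.gmt")

    state.update(
        bundle=bundle, probes=probes, truth=truth, raw=raw, meta=meta,
        negctl=negctl, tf_ids=set(tf_ids), hkg_ids=set(hkg_ids), gene_sets=sets,
    )
    manifest["funnel"]["n_platform"] = len(probes) + len(negctl)
    manifest["funnel"]["n_mapped"] = len(probes)


def _stage_annotate(config: PipelineConfig, out: Path, state: dict, manifest: dict) -> None:
    bundle, probes = state["bundle"], state["probes"]
    table = probe_annotation.annotate_probes(
        probes, list(bundle.sources), bundle.genome, distance_source=bundle.base
    )
    classified = table[table.final_class != FinalClass.DISCARDED.value]
    # per-gene deduplication: mRNA probes keyed by their same-strand
    # exon-overlap gene in the base annotation; lncRNA probes keep themselves
    probe_by_id = {p.probe_id: p for p in probes}
    probe_to_gene: dict[str, str | None] = {}
    for row in classified.itertuples(index=False):
        probe = probe_by_id[row.probe_id]
        gene_id = None
        if row.final_class == "mRNA":
            for gene in bundle.base.genes_on(probe.chrom):
                if gene.strand == probe.strand and any(
                    probe.start < ee and es < probe.end for es, ee in gene.exons
                ):
                    gene_id = gene.gene_id
                    break
        probe_to_gene[row.probe_id] = gene_id
    kept = probe_annotation.deduplicate_by_mean_signal(probe_to_gene, state["raw"])
    table["kept_after_dedup"] = table.probe_id.isin(kept)
    table.to_csv(out / "annotation.tsv", sep="\t", index=False)

    from .types import ConsensusLabel, Subclass

    labels = [
        ConsensusLabel(probe_id=row.probe_id, final_class=FinalClass(row.final_class),
                       subclass=Subclass(row.subclass))
        for row in classified.itertuples(index=False)
    ]
    density, r, p = (
        probe_annotation.chromosome_density(labels, probe_by_id, bundle.genome)
        if len(bundle.genome.chromosomes) >= 3
        else (None, float("nan"), float("nan"))
    )
    if density is not None:
        density.to_csv(out / "chromosome_density.tsv", sep="\t", index=False)
        manifest["funnel"]["chromosome_density_r"] = None if np.isnan(r) else r
    state.update(annotation=table, kept=kept)
    manifest["funnel"]["n_classified"] = int(len(classified))
    manifest["funnel"]["n_deduplicated"] = int(len(kept))


def _stage_assemble(config: PipelineConfig, out: Path, state: dict, manifest: dict) -> None:
    raw, meta, negctl = state["raw"], state["meta"], state["negctl"]
    kept = state.get("kept", set(raw.index))
    raw_kept = raw.loc[sorted(kept & set(raw.index))]
    thresholds = compendium.detection_threshold(
        negctl, config.assemble.detection_percentile, config.assemble.pooled_controls
    )
    detection = compendium.call_detection(raw_kept, thresholds)
    retained, n_dropped = compendium.drop_never_expressed(detection)
    detection = detection.loc[retained]
    _log("assemble", f"dropped {n_dropped} never-expressed probes")

    normalized = compendium.log2_and_quantile_normalize(raw_kept.loc[retained])
    qc = compendium.compute_qc(normalized)
    qc = compendium.screen_outliers(qc, meta, floor=config.assemble.outlier_floor)
    good = qc.sample_outliers.index[~qc.sample_outliers]
    normalized = normalized[good]
    detection = detection[good]
    meta_kept = meta[meta.sample_id.isin(good)]

    summary = compendium.tissue_expression(detection, meta_kept, config.assemble.tissue_fraction)
    category = state["annotation"].set_index("probe_id")["final_class"].reindex(retained)
    breadth = compendium.expression_breadth_report(summary, category)

    io.write_matrix(normalized, out / "normalized_matrix.tsv")
    detection.astype(int).to_csv(out / "detection.tsv", sep="\t", index_label="probe_id")
    pd.DataFrame({
        "sample_id": qc.median_rho.index,
        "median_spearman": qc.median_rho.values,
        "outlier": qc.sample_outliers.values,
    }).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    summary.expressed.astype(int).to_csv(out / "tissue_expression.tsv", sep="\t",
                                         index_label="probe_id")
    breadth.to_csv(out / "expression_breadth.tsv", sep="\t", index=False)

    state.update(normalized=normalized, detection=detection, meta_kept=meta_kept,
                 summary=summary, category=category)
    manifest["funnel"]["n_detected"] = int(len(retained))
    manifest["funnel"]["n_dropped_never_expressed"] = n_dropped
    manifest["funnel"]["n_outlier_samples"] = int(qc.sample_outliers.sum())


def _stage_network(config: PipelineConfig, out: Path, state: dict, manifest: dict) -> None:
    normalized, meta = state["normalized"], state["meta_kept"]
    cfg = config.network
    if cfg.pick_beta:
        beta, diag = network.pick_soft_threshold(normalized)
        diag.to_csv(out / "soft_threshold.tsv", sep="\t", index=False)
    else:
        beta = cfg.beta
    r = np.corrcoef(normalized.to_numpy(dtype=float))
    adjacency = network.signed_adjacency(r, beta)
    tom = network.topological_overlap(adjacency)
    assignment = network.cut_modules(
        1.0 - tom, list(normalized.index),
        min_module_size=cfg.min_module_size,
        cut_height_quantile=cfg.cut_height_quantile,
    )
    if set(assignment) - {network.GREY}:
        assignment, egs = network.merge_close_modules(
            normalized, assignment, cut=cfg.merge_cut_height
        )
        trait = network.module_trait_correlation(egs.eigengenes, meta)
        egs.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t", index_label="sample_id")
        trait.to_csv(out / "module_trait.tsv", sep="\t", index=False)
        state["eigengenes"] = egs
        state["trait"] = trait
    category = state["category"].map({"mRNA": "mRNA", "lncRNA": "lncRNA"})
    composition, hk_r, hk_p = network.module_composition(
        assignment, category, state.get("tf_ids"), state.get("hkg_ids")
    )
    assignment.to_frame().to_csv(out / "modules.tsv", sep="\t", index_label="probe_id")
    composition.to_csv(out / "module_composition.tsv", sep="\t", index=False)
    state.update(assignment=assignment, composition=composition)
    manifest["funnel"]["n_modules_non_grey"] = int(len(set(assignment) - {network.GREY}))
    manifest["funnel"]["hkg_lncRNA_fraction_r"] = None if np.isnan(hk_r) else hk_r


def _stage_enrich(config: PipelineConfig, out: Path, state: dict, manifest: dict) -> None:
    assignment, category = state["assignment"], state["category"]
    gene_sets = state["gene_sets"]
    universe = sorted(category.index[category == "mRNA"])
    results = {}
    for module in sorted(set(assignment) - {network.GREY}):
        members = assignment.index[assignment == module]
        module_mrna = [p for p in members if category.get(p) == "mRNA"]
        if not module_mrna:
            continue
        results[module] = enrichment.enrich_module(
            module_mrna, gene_sets, universe,
            alpha=config.enrich.alpha, q_cap=config.enrich.q_cap,
        )
    tables = [t.assign(module=m) for m, t in results.items() if len(t)]
    combined = (pd.concat(tables, ignore_index=True) if tables
                else pd.DataFrame(columns=["module", "term_id", "p", "p_adj", "q"]))
    combined.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    enrichment.enrichment_summary(results).to_csv(
        out / "enrichment_summary.tsv", sep="\t", index=False
    )
    state["enrichment"] = results


def _stage_hubs(config: PipelineConfig, out: Path, state: dict, manifest: dict) -> None:
    normalized, assignment, category = state["normalized"], state["assignment"], state["category"]
    tf_ids = state.get("tf_ids", set())
    kinds = pd.Series({
        p: ("TF" if p in tf_ids else ("mRNA" if category.get(p) == "mRNA" else "lncRNA"))
        for p in assignment.index
    })
    edges = hubs.build_edges(
        normalized, assignment, kinds,
        r_min=config.hubs.r_min, alpha=config.hubs.alpha,
        use_absolute=config.hubs.use_absolute,
    )
    for module, table in edges.items():
        if len(table):
            table.to_csv(out / f"edges_{module}.tsv", sep="\t", index=False)
    ht = hubs.hub_table(edges)
    ht.to_csv(out / "hub_table.tsv", sep="\t", index=False)
    state["hub_table"] = ht
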