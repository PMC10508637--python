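"""Synthetic genomes, annotation sources, probe alignments and expression
matrices with planted ground truth.

Geometry: genes are laid out on a fixed grid of non-overlapping slots so
that every classification pathway (exonic, intronic, antisense, intergenic
at <=1 kb / >1 kb / >50 kb) can be planted by construction. Expression uses
a single-factor model per module, x = sqrt(c)*f + sqrt(1-c)*noise, so the
expected within-module correlation equals ``within_module_cor``; the planted
hub gets a strictly larger factor loading. Negative controls and
non-expressed entries are drawn from a log-normal background (normal on the
log2 scale); expressed probes sit ``signal_over_background`` log2 units
above it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import cycle

import numpy as np
import pandas as pd

from .types import (
    AnnotationSource,
    GeneModel,
    GenomeModel,
    GroundTruth,
    ProbeAlignment,
)

#: bp reserved per gene slot; large enough for a > 50 kb intergenic stratum
#: on both sides of a planted probe.
SLOT_BP = 130_000
_CHROM_MARGIN = 1_000

PROBE_CLASSES = ("mRNA", "intronic", "antisense", "lincRNA")
LINC_STRATA = ("utr", "distal", "far")


class SizingError(ValueError):
    """Requested entities do not fit in the simulated genome."""


@dataclass
class SimulationDesign:
    seed: int = 0
    n_genes: int = 30
    n_probes_per_class: dict[str, int] = field(
        default_factory=lambda: {"mRNA": 30, "intronic": 10, "antisense": 10, "lincRNA": 30}
    )
    annotation_disagreement_rate: float = 0.0
    #: (tissue_name, n_samples, n_series)
    tissues: tuple[tuple[str, int, int], ...] = (
        ("oocyte", 10, 2), ("two_cell", 6, 1), ("blastocyst", 12, 2),
        ("cumulus", 8, 1), ("granulosa", 10, 2),
    )
    module_sizes: tuple[int, ...] = ()
    module_tissue_map: dict[str, str] | None = None
    within_module_cor: float = 0.8
    noise_sd: float = 1.0
    n_negative_controls: int = 100
    signal_over_background: float = 4.0
    tissue_specific_sets: dict[str, int] = field(default_factory=dict)
    n_never_expressed: int = 0
    background_mean: float = 6.0
    background_sd: float = 1.0
    #: expressed probes get a per-probe baseline drawn uniformly from
    #: [0, probe_level_spread] log2 units above the detection offset, giving
    #: samples the shared rank structure real arrays have (drives QC).
    probe_level_spread: float = 6.0
    #: weight of the sample-level noise term in each module factor relative
    #: to the tissue indicator; larger values decouple modules that share a
    #: driving tissue
    module_factor_noise: float = 0.5
    probe_length: int = 60
    n_exons_per_gene: int = 4
    exon_length: int = 300
    intron_length: int = 1_000
    n_chromosomes: int = 3
    #: relative share of genes per chromosome (default equal); unequal
    #: weights make per-chromosome probe counts vary
    gene_chrom_weights: tuple[float, ...] | None = None
    chromosome_length: int | None = None
    series_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.annotation_disagreement_rate <= 1.0):
            raise ValueError("annotation_disagreement_rate must be in [0, 1]")
        if not (0.0 <= self.within_module_cor < 1.0):
            raise ValueError("within_module_cor must be in [0, 1)")
        for key, count in self.n_probes_per_class.items():
            if key not in PROBE_CLASSES:
                raise ValueError(f"unknown probe class {key!r}")
            if count < 0:
                raise ValueError("probe counts must be >= 0")
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("need >= 1 gene and >= 1 chromosome")
        if any(n < 0 for n in (self.n_negative_controls, self.n_never_expressed)):
            raise ValueError("counts must be >= 0")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def module_names(self) -> list[str]:
        return [f"M{i + 1}" for i in range(self.n_modules)]

    def resolved_module_tissue_map(self) -> dict[str, str]:
        if self.module_tissue_map is not None:
            return dict(self.module_tissue_map)
        names = [t[0] for t in self.tissues]
        return {m: names[i % len(names)] for i, m in enumerate(self.module_names())}


@dataclass
class AnnotationBundle:
    genome: GenomeModel
    base: AnnotationSource          # unperturbed truth annotation
    sources: tuple[AnnotationSource, ...]
    truth: GroundTruth


def _rng(design: SimulationDesign, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(stage,)))


def _gene_length(design: SimulationDesign) -> int:
    n = design.n_exons_per_gene
    return n * design.exon_length + (n - 1) * design.intron_length


def _make_gene(design: SimulationDesign, gene_id: str, chrom: str, start: int, strand: str) -> GeneModel:
    exons = []
    pos = start
    for _ in range(design.n_exons_per_gene):
        exons.append((pos, pos + design.exon_length))
        pos += design.exon_length + design.intron_length
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=tuple(exons))


def _genes_per_chromosome(design: SimulationDesign) -> list[int]:
    """Largest-remainder allocation of genes to chromosomes by weight."""
    n = design.n_chromosomes
    weights = np.asarray(design.gene_chrom_weights or [1.0] * n, dtype=float)
    if len(weights) != n or np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("gene_chrom_weights must be n_chromosomes non-negative values")
    quota = weights / weights.sum() * design.n_genes
    counts = np.floor(quota).astype(int)
    remainder = design.n_genes - counts.sum()
    for i in np.argsort(-(quota - counts), kind="stable")[:remainder]:
        counts[i] += 1
    return counts.tolist()


def simulate_annotation(design: SimulationDesign) -> AnnotationBundle:
    """Genome + one base annotation + three derived sources where each gene
    is independently perturbed (drop / strand-flip / shift) in one randomly
    chosen source with probability ``annotation_disagreement_rate``.
    """
    rng = _rng(design, stage=0)
    counts = _genes_per_chromosome(design)
    slots_per_chrom = max(counts)
    needed = _CHROM_MARGIN + slots_per_chrom * SLOT_BP
    if design.chromosome_length is not None and design.chromosome_length < needed:
        raise SizingError(
            f"chromosome length {design.chromosome_length} too short for "
            f"{design.n_genes} genes (need >= {needed})"
        )
    chrom_len = design.chromosome_length or needed
    genome = GenomeModel(
        chromosomes=tuple((f"chr{i + 1}", chrom_len) for i in range(design.n_chromosomes))
    )
    genes = []
    g = 0
    for ci, n_on_chrom in enumerate(counts):
        for slot in range(n_on_chrom):
            start = _CHROM_MARGIN + slot * SLOT_BP
            strand = "+" if g % 2 == 0 else "-"
            genes.append(_make_gene(design, f"G{g + 1:04d}", f"chr{ci + 1}", start, strand))
            g += 1
    base = AnnotationSource(source_name="base", genes=tuple(genes))

    source_names = ("ucsc_like", "ensembl_like", "ncbi_like")
    per_source: dict[str, list[GeneModel]] = {s: [] for s in source_names}
    truth = GroundTruth()
    shift = 2 * design.probe_length
    for gene in genes:
        perturb = rng.random() < design.annotation_disagreement_rate
        victim = source_names[rng.integers(len(source_names))] if perturb else None
        kind = ("drop", "flip_strand", "shift")[rng.integers(3)] if perturb else None
        for s in source_names:
            if s != victim:
                per_source[s].append(gene)
                continue
            if kind == "drop":
                continue
            if kind == "flip_strand":
                flipped = "-" if gene.strand == "+" else "+"
                per_source[s].append(
                    GeneModel(gene.gene_id, gene.chrom, flipped, gene.exons, gene.biotype)
                )
            else:  # shift
                moved = tuple((a + shift, b + shift) for a, b in gene.exons)
                per_source[s].append(
                    GeneModel(gene.gene_id, gene.chrom, gene.strand, moved, gene.biotype)
                )
        if victim is not None:
            truth.perturbed_genes[gene.gene_id] = (victim, kind or "")
    sources = tuple(
        AnnotationSource(source_name=s, genes=tuple(per_source[s])) for s in source_names
    )
    return AnnotationBundle(genome=genome, base=base, sources=sources, truth=truth)


def _next_gene_start(base: AnnotationSource, gene: GeneModel) -> int | None:
    after = [g.start for g in base.genes_on(gene.chrom) if g.start > gene.end]
    return min(after) if after else None


def simulate_probes(
    bundle: AnnotationBundle, design: SimulationDesign
) -> tuple[list[ProbeAlignment], GroundTruth]:
    """Place probes so each requested class is true against the unperturbed
    base annotation. lincRNA placements cycle the <=1 kb (same strand),
    >1 kb and >50 kb distance strata.
    """
    rng = _rng(design, stage=1)
    base = bundle.base
    genome_len = bundle.genome.lengths
    plen = design.probe_length
    truth = bundle.truth
    probes: list[ProbeAlignment] = []
    counter = 0

    def add(chrom: str, start: int, strand: str, cls: str, stratum: str | None = None) -> None:
        nonlocal counter
        counter += 1
        pid = f"P{counter:05d}"
        if start < 0 or start + plen > genome_len[chrom]:
            raise SizingError(f"probe {pid} does not fit on {chrom}")
        probes.append(ProbeAlignment(pid, chrom, start, start + plen, strand))
        truth.probe_class[pid] = cls
        if stratum is not None:
            truth.linc_stratum[pid] = stratum

    gene_cycle = cycle(base.genes)
    for _ in range(design.n_probes_per_class.get("mRNA", 0)):
        gene = next(gene_cycle)
        exon = gene.exons[rng.integers(len(gene.exons))]
        if exon[1] - exon[0] < plen:
            raise SizingError("exon shorter than probe length")
        start = int(rng.integers(exon[0], exon[1] - plen + 1))
        add(gene.chrom, start, gene.strand, "mRNA")

    intronic_genes = [g for g in base.genes if g.introns]
    n_intronic = design.n_probes_per_class.get("intronic", 0)
    if n_intronic and not intronic_genes:
        raise SizingError("no introns exist: cannot place intronic probes")
    if n_intronic and any(i[1] - i[0] < plen for g in intronic_genes for i in g.introns):
        raise SizingError("introns shorter than probe length")
    intron_cycle = cycle(intronic_genes) if intronic_genes else None
    for _ in range(n_intronic):
        gene = next(intron_cycle)  # type: ignore[arg-type]
        intron = gene.introns[rng.integers(len(gene.introns))]
        start = int(rng.integers(intron[0], intron[1] - plen + 1))
        add(gene.chrom, start, gene.strand, "intronic")

    for _ in range(design.n_probes_per_class.get("antisense", 0)):
        gene = next(gene_cycle)
        start = int(rng.integers(gene.start, gene.end - plen + 1))
        add(gene.chrom, start, "-" if gene.strand == "+" else "+", "antisense")

    strata = cycle(LINC_STRATA)
    for _ in range(design.n_probes_per_class.get("lincRNA", 0)):
        stratum = next(strata)
        gene = next(gene_cycle)
        nxt = _next_gene_start(base, gene)
        if stratum == "utr":
            d = int(rng.integers(100, 1_000 - plen))
            strand = gene.strand
        elif stratum == "distal":
            d = int(rng.integers(2_000, 40_000))
            strand = "+" if rng.random() < 0.5 else "-"
        else:  # far
            d = int(rng.integers(51_000, 60_000))
            strand = "+" if rng.random() < 0.5 else "-"
        start = gene.end + d
        right_gap = (nxt - (start + plen)) if nxt is not None else None
        limit = 50_000 if stratum == "far" else (1_000 if stratum == "distal" else None)
        if right_gap is not None:
            if right_gap <= d:  # nearest gene would be the wrong one
                raise SizingError("gene slots too tight for lincRNA stratum")
            if limit is not None and right_gap <= limit:
                raise SizingError("gene slots too tight for lincRNA stratum")
        add(gene.chrom, start, strand, "lincRNA", stratum)

    return probes, truth


# --------------------------------------------------------------- expression

def _sample_frame(design: SimulationDesign) -> pd.DataFrame:
    rows = []
    for tissue, n_samples, n_series in design.tissues:
        if n_samples < 1 or n_series < 1:
            raise ValueError(f"tissue {tissue!r}: need >= 1 sample and series")
        for i in range(n_samples):
            rows.append({
                "sample_id": f"{tissue}_{i + 1:03d}",
                "series_id": f"{tissue}_s{i % n_series + 1}",
                "tissue": tissue,
            })
    return pd.DataFrame(rows)


def simulate_expression(
    probes: list[ProbeAlignment],
    design: SimulationDesign,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Raw-scale signal matrix, sample metadata, negative-control matrix and
    updated ground truth (module membership, expressing tissues, hubs).
    """
    if design.noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if not design.tissues:
        raise ValueError("design.tissues must be non-empty")
    truth = truth if truth is not None else GroundTruth()
    rng = _rng(design, stage=2)
    meta = _sample_frame(design)
    samples = meta["sample_id"].tolist()
    tissue_of = meta.set_index("sample_id")["tissue"]
    n_samples = len(samples)

    probe_ids = [p.probe_id for p in probes]
    n_module = sum(design.module_sizes)
    n_specific = sum(design.tissue_specific_sets.values())
    if n_module + n_specific + design.n_never_expressed > len(probe_ids):
        raise SizingError(
            "not enough probes for requested modules, tissue-specific sets "
            "and never-expressed probes"
        )
    pool = list(probe_ids)
    rng.shuffle(pool)

    base_level = design.background_mean + design.signal_over_background
    offsets = {
        pid: float(rng.uniform(0.0, design.probe_level_spread)) for pid in probe_ids
    }
    c = design.within_module_cor
    log2 = np.empty((len(probe_ids), n_samples))
    row_of = {pid: i for i, pid in enumerate(probe_ids)}
    all_tissues = tuple(t[0] for t in design.tissues)

    idx = 0
    tissue_names = [t[0] for t in design.tissues]
    module_tissue = design.resolved_module_tissue_map()
    for module, size in zip(design.module_names(), design.module_sizes):
        members = pool[idx: idx + size]
        idx += size
        driver = module_tissue[module]
        if driver not in tissue_names:
            raise ValueError(f"module {module}: unknown driving tissue {driver!r}")
        indicator = (tissue_of[samples] == driver).to_numpy(dtype=float)
        factor = indicator - indicator.mean()
        if factor.std() > 0:
            factor = factor / factor.std()
        factor = factor + design.module_factor_noise * rng.standard_normal(n_samples)
        factor = (factor - factor.mean()) / factor.std()
        c_hub = c + 0.75 * (1.0 - c)
        for j, pid in enumerate(members):
            load = c_hub if j == 0 else c
            signal = np.sqrt(load) * factor + np.sqrt(1.0 - load) * rng.standard_normal(n_samples)
            log2[row_of[pid]] = base_level + offsets[pid] + design.noise_sd * signal
            truth.probe_module[pid] = module
            truth.probe_tissues[pid] = all_tissues
        truth.module_hub[module] = members[0]

    for tissue, count in design.tissue_specific_sets.items():
        if tissue not in tissue_names:
            raise ValueError(f"unknown tissue {tissue!r} in tissue_specific_sets")
        in_tissue = (tissue_of[samples] == tissue).to_numpy(dtype=bool)
        for pid in pool[idx: idx + count]:
            row = _background(rng, design, n_samples)
            row[in_tissue] = (base_level + offsets[pid]
                              + design.noise_sd * rng.standard_normal(in_tissue.sum()))
            log2[row_of[pid]] = row
            truth.probe_module[pid] = "grey"
            truth.probe_tissues[pid] = (tissue,)
        idx += count

    for pid in pool[idx: idx + design.n_never_expressed]:
        log2[row_of[pid]] = (
            design.background_mean - 5.0 * design.background_sd
            + 0.1 * rng.standard_normal(n_samples)
        )
        truth.probe_module[pid] = "grey"
        truth.probe_tissues[pid] = ()
    idx += design.n_never_expressed

    for pid in pool[idx:]:
        log2[row_of[pid]] = base_level + offsets[pid] + design.noise_sd * rng.standard_normal(n_samples)
        truth.probe_module[pid] = "grey"
        truth.probe_tissues[pid] = all_tissues

    # per-series additive offsets (default none) for outlier-screening tests
    if design.series_offsets:
        series_of = meta.set_index("sample_id")["series_id"]
        for j, s in enumerate(samples):
            log2[:, j] += design.series_offsets.get(series_of[s], 0.0)

    negctl_log2 = _background(rng, design, (design.n_negative_controls, n_samples))
    negctl = pd.DataFrame(
        np.exp2(negctl_log2),
        index=[f"NC{i + 1:04d}" for i in range(design.n_negative_controls)],
        columns=samples,
    )
    raw = pd.DataFrame(np.exp2(log2), index=probe_ids, columns=samples)
    return raw, meta, negctl, truth


def _background(rng: np.random.Generator, design: SimulationDesign, shape) -> np.ndarray:
    return design.background_mean + design.background_sd * rng.standard_normal(shape)
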