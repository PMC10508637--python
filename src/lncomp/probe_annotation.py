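"""Probe classification against gene annotations, multi-source voting,
intergenic distance categories, per-gene deduplication and chromosome
density summaries.

Classification rules (applied independently per annotation source):

* mRNA — the probe overlaps >= 1 bp of an exon of a same-strand gene;
* intronic lncRNA — fully contained in an intron of a same-strand gene and
  not overlapping any same-strand exon;
* antisense lncRNA — overlaps >= 1 bp of an opposite-strand gene body
  (exons + introns);
* lincRNA — overlaps no gene body on either strand;
* ambiguous — qualifies as mRNA AND as some lncRNA category within the same
  source (strictly the mRNA-vs-lncRNA conflict; a probe qualifying as both
  intronic and antisense is reported with the priority antisense > intronic
  and is NOT ambiguous).

Consensus: any ambiguous source discards the probe; one mRNA vote suffices
for mRNA; lncRNA requires all sources to agree on some lncRNA category,
subclass by majority with ties broken antisense > intronic > lincRNA.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AnnotationSource,
    ConsensusLabel,
    FinalClass,
    GeneModel,
    GenomeModel,
    LincDistanceCategory,
    ProbeAlignment,
    ProbeClass,
    Subclass,
)

_SUBCLASS_PRIORITY = (Subclass.ANTISENSE, Subclass.INTRONIC, Subclass.LINCRNA)

_CLASS_TO_SUBCLASS = {
    ProbeClass.INTRONIC: Subclass.INTRONIC,
    ProbeClass.ANTISENSE: Subclass.ANTISENSE,
    ProbeClass.LINCRNA: Subclass.LINCRNA,
}


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _contained(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return b_start <= a_start and a_end <= b_end


def classify_probe_one_source(
    probe: ProbeAlignment, source: AnnotationSource, genome: GenomeModel | None = None
) -> ProbeClass:
    """Classify one probe against one annotation source."""
    if genome is not None and probe.chrom not in genome:
        raise KeyError(f"probe {probe.probe_id}: unknown chromosome {probe.chrom!r}")
    exon_hit = False
    intronic_hit = False
    antisense_hit = False
    any_body_overlap = False
    for gene in source.genes_on(probe.chrom):
        if not _overlaps(probe.start, probe.end, gene.start, gene.end):
            continue
        any_body_overlap = True
        if gene.strand == probe.strand:
            if any(_overlaps(probe.start, probe.end, es, ee) for es, ee in gene.exons):
                exon_hit = True
            elif any(
                _contained(probe.start, probe.end, istart, iend)
                for istart, iend in gene.introns
            ):
                intronic_hit = True
        else:
            antisense_hit = True
    if exon_hit and (intronic_hit or antisense_hit):
        return ProbeClass.AMBIGUOUS
    if exon_hit:
        return ProbeClass.MRNA
    if antisense_hit:
        return ProbeClass.ANTISENSE
    if intronic_hit:
        return ProbeClass.INTRONIC
    if not any_body_overlap:
        return ProbeClass.LINCRNA
    # Overlaps a same-strand gene body without hitting an exon or sitting
    # inside a single intron (possible only with nested/overlapping genes);
    # not intergenic and not cleanly assignable -> discard via ambiguity.
    return ProbeClass.AMBIGUOUS


def classify_consensus(per_source: Mapping[str, ProbeClass], probe_id: str = "") -> ConsensusLabel:
    """Vote per-source classes into a final mRNA / lncRNA / discarded call."""
    if not per_source:
        raise ValueError("per_source mapping is empty")
    classes = list(per_source.values())
    if any(c is ProbeClass.AMBIGUOUS for c in classes):
        return ConsensusLabel(probe_id=probe_id, final_class=FinalClass.DISCARDED)
    if any(c is ProbeClass.MRNA for c in classes):
        if all(c is ProbeClass.MRNA for c in classes):
            return ConsensusLabel(probe_id=probe_id, final_class=FinalClass.MRNA)
        # one mRNA vote suffices
        return ConsensusLabel(probe_id=probe_id, final_class=FinalClass.MRNA)
    # every source assigned some lncRNA category
    subs = [_CLASS_TO_SUBCLASS[c] for c in classes]
    counts = {s: subs.count(s) for s in set(subs)}
    best = max(counts.values())
    winner = next(s for s in _SUBCLASS_PRIORITY if counts.get(s, 0) == best)
    return ConsensusLabel(probe_id=probe_id, final_class=FinalClass.LNCRNA, subclass=winner)


def _gap(probe: ProbeAlignment, gene: GeneModel) -> int:
    if _overlaps(probe.start, probe.end, gene.start, gene.end):
        return 0
    if probe.end <= gene.start:
        return gene.start - probe.end
    return probe.start - gene.end


def lincRNA_distance_category(
    probe: ProbeAlignment, source: AnnotationSource
) -> tuple[str, int, bool, LincDistanceCategory]:
    """Nearest gene, gap distance, strand flag and distance stratum.

    The <= 1 kb boundary is inclusive; the > 50 kb boundary is strict.
    Nearest-gene ties break toward the lexicographically smaller gene_id.
    """
    candidates = source.genes_on(probe.chrom)
    if not candidates:
        candidates = list(source.genes)
    if not candidates:
        raise ValueError("annotation source has no genes; distance undefined")
    nearest = min(candidates, key=lambda g: (_gap(probe, g), g.gene_id))
    distance = _gap(probe, nearest)
    same_strand = nearest.strand == probe.strand
    if distance <= 1_000 and same_strand:
        category = LincDistanceCategory.UTR_EXTENSION_CANDIDATE
    elif distance > 50_000:
        category = LincDistanceCategory.FAR
    else:
        category = LincDistanceCategory.DISTAL
    return nearest.gene_id, distance, same_strand, category


def deduplicate_by_mean_signal(
    probe_to_gene: Mapping[str, Optional[str]], matrix: pd.DataFrame
) -> set[str]:
    """Keep one probe per gene: the one with maximal row mean.

    Ties break toward the lexicographically smallest probe_id. Probes mapped
    to no gene (``None``) are all kept, keyed by their own id.
    """
    missing = [p for p in probe_to_gene if p not in matrix.index]
    if missing:
        raise ValueError(f"probes missing from matrix: {missing[:5]}")
    means = matrix.mean(axis=1)
    kept: set[str] = set()
    by_gene: dict[str, list[str]] = {}
    for probe, gene in probe_to_gene.items():
        if gene is None:
            kept.add(probe)
        else:
            by_gene.setdefault(gene, []).append(probe)
    for gene, probes in by_gene.items():
        kept.add(max(probes, key=lambda p: (means[p], _NegStr(p))))
    return kept


class _NegStr(str):
    """Inverts string ordering so max() prefers the smallest id on ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def chromosome_density(
    labels: Iterable[ConsensusLabel],
    probes: Mapping[str, ProbeAlignment],
    genome: GenomeModel,
) -> tuple[pd.DataFrame, float, float]:
    """Per-chromosome mRNA/lncRNA counts and per-Mb densities, plus the
    Pearson correlation (r, p) between raw per-chromosome counts.
    """
    lengths = genome.lengths
    for name, length in genome.chromosomes:
        if length <= 0:
            raise ValueError(f"zero-length chromosome {name!r}")
    if len(lengths) < 3:
        raise ValueError("need >= 3 chromosomes for a correlation")
    counts = {name: {"n_mRNA": 0, "n_lncRNA": 0} for name in lengths}
    for label in labels:
        if label.final_class is FinalClass.DISCARDED:
            continue
        chrom = probes[label.probe_id].chrom
        key = "n_mRNA" if label.final_class is FinalClass.MRNA else "n_lncRNA"
        counts[chrom][key] += 1
    table = pd.DataFrame(
        [
            {
                "chrom": name,
                "length_bp": lengths[name],
                "n_mRNA": counts[name]["n_mRNA"],
                "n_lncRNA": counts[name]["n_lncRNA"],
                "mRNA_per_Mb": counts[name]["n_mRNA"] / (lengths[name] / 1e6),
                "lncRNA_per_Mb": counts[name]["n_lncRNA"] / (lengths[name] / 1e6),
            }
            for name in lengths
        ]
    )
    x = table["n_mRNA"].to_numpy(dtype=float)
    y = table["n_lncRNA"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant per-chromosome counts: correlation undefined")
        return table, float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return table, float(r), float(p)


def annotate_probes(
    probes: Iterable[ProbeAlignment],
    sources: list[AnnotationSource],
    genome: GenomeModel | None = None,
    distance_source: AnnotationSource | None = None,
) -> pd.DataFrame:
    """Full per-probe annotation table: per-source classes, consensus,
    nearest-gene distance info for consensus lincRNAs.
    """
    if distance_source is None and sources:
        distance_source = sources[0]
    rows = []
    for probe in probes:
        per_source = {
            s.source_name: classify_probe_one_source(probe, s, genome) for s in sources
        }
        label = classify_consensus(per_source, probe_id=probe.probe_id)
        row: dict = {"probe_id": probe.probe_id,
                     "final_class": label.final_class.value,
                     "subclass": label.subclass.value}
        for s in sources:
            row[f"class_{s.source_name}"] = per_source[s.source_name].value
        if (
            label.final_class is FinalClass.LNCRNA
            and label.subclass is Subclass.LINCRNA
            and distance_source is not None
            and distance_source.genes
        ):
            gid, dist, same, cat = lincRNA_distance_category(probe, distance_source)
            row.update(nearest_gene=gid, nearest_gene_distance=dist,
                       same_strand_as_nearest=same, distance_category=cat.value)
        else:
            row.update(nearest_gene=None, nearest_gene_distance=None,
                       same_strand_as_nearest=None, distance_category=None)
        rows.append(row)
    return pd.DataFrame(rows)


def subclass_shares(n_intergenic: int, n_genic: int) -> dict[str, float]:
    """Bookkeeping for the lncRNA subclass breakdown: total and the
    percentage share of the intergenic and genic fractions.
    """
    if n_intergenic < 0 or n_genic < 0:
        raise ValueError("counts must be non-negative")
    total = n_intergenic + n_genic
    if total == 0:
        return {"total": 0, "pct_intergenic": float("nan"), "pct_genic": float("nan")}
    return {
        "total": total,
        "pct_intergenic": 100.0 * n_intergenic / total,
        "pct_genic": 100.0 * n_genic / total,
    }
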