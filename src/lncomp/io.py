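"""Readers and writers for the plain-text interchange formats.

GFF3 is converted between its native 1-based inclusive coordinates and the
internal 0-based half-open convention here, and nowhere else.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .types import AnnotationSource, GeneModel, GenomeModel, GroundTruth, ProbeAlignment

_GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def write_gff3(source: AnnotationSource, genome: GenomeModel, path: str | Path) -> None:
    """Write one annotation source as GFF3 (gene + exon features)."""
    lines = ["##gff-version 3"]
    for name, length in genome.chromosomes:
        lines.append(f"##sequence-region {name} 1 {length}")
    for gene in source.genes:
        lines.append(
            "\t".join([
                gene.chrom, source.source_name, "gene",
                str(gene.start + 1), str(gene.end), ".", gene.strand, ".",
                f"ID={gene.gene_id};biotype={gene.biotype}",
            ])
        )
        for i, (start, end) in enumerate(gene.exons, start=1):
            lines.append(
                "\t".join([
                    gene.chrom, source.source_name, "exon",
                    str(start + 1), str(end), ".", gene.strand, ".",
                    f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}",
                ])
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, source_name: str | None = None) -> AnnotationSource:
    """Read a gene/exon GFF3 file into an :class:`AnnotationSource`.

    Exons are attached to their ``Parent`` gene; a gene feature with no exon
    children is treated as single-exon spanning the gene body.
    """
    path = Path(path)
    gene_rows: dict[str, dict] = {}
    exon_rows: dict[str, list[tuple[int, int]]] = {}
    inferred_source = source_name
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line[:80]!r}")
            row = dict(zip(_GFF3_COLUMNS, fields))
            attrs = _parse_attributes(row["attributes"])
            start = int(row["start"]) - 1  # to 0-based half-open
            end = int(row["end"])
            if inferred_source is None:
                inferred_source = row["source"]
            if row["type"] == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"{path}: gene feature without ID")
                gene_rows[gid] = {
                    "chrom": row["seqid"], "strand": row["strand"],
                    "span": (start, end),
                    "biotype": attrs.get("biotype", "protein_coding"),
                }
            elif row["type"] == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}: exon feature without Parent")
                exon_rows.setdefault(parent, []).append((start, end))
    genes = []
    for gid, info in gene_rows.items():
        exons = tuple(sorted(exon_rows.get(gid, [info["span"]])))
        genes.append(
            GeneModel(gene_id=gid, chrom=info["chrom"], strand=info["strand"],
                      exons=exons, biotype=info["biotype"])
        )
    return AnnotationSource(source_name=inferred_source or path.stem, genes=tuple(genes))


def write_bed6(probes: Iterable[ProbeAlignment], path: str | Path) -> None:
    lines = [
        f"{p.chrom}\t{p.start}\t{p.end}\t{p.probe_id}\t0\t{p.strand}" for p in probes
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed6(path: str | Path) -> list[ProbeAlignment]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        ProbeAlignment(probe_id=r.name, chrom=r.chrom, start=int(r.start),
                       end=int(r.end), strand=r.strand)
        for r in df.itertuples(index=False)
    ]


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "series_id", "tissue"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in metadata")
    return meta


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(ids) + "\n")


def read_id_list(path: str | Path) -> list[str]:
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]


def write_gmt(sets: Mapping[str, tuple[str, list[str]]], path: str | Path) -> None:
    """``sets`` maps term_id -> (description, member ids)."""
    lines = [
        "\t".join([term, desc, *members]) for term, (desc, members) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    out: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        out[fields[0]] = (fields[1], fields[2:])
    return out


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "probe_class": truth.probe_class,
        "probe_module": truth.probe_module,
        "probe_tissues": {k: list(v) for k, v in truth.probe_tissues.items()},
        "module_hub": truth.module_hub,
        "perturbed_genes": {k: list(v) for k, v in truth.perturbed_genes.items()},
        "linc_stratum": truth.linc_stratum,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        probe_class=payload["probe_class"],
        probe_module=payload["probe_module"],
        probe_tissues={k: tuple(v) for k, v in payload["probe_tissues"].items()},
        module_hub=payload["module_hub"],
        perturbed_genes={k: tuple(v) for k, v in payload.get("perturbed_genes", {}).items()},
        linc_stratum=payload.get("linc_stratum", {}),
    )
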