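"""Readers and writers for the pipeline's external formats.

Variant tables are TSV with columns ``strain_id``, ``token``, ``zygosity``;
a VCF 4.x reader converts left-aligned SNV/indel records to the same token
notation.  Annotation comes from GFF3 (via pyranges) or GenBank flat files
and genomes from FASTA (via Biopython).  Proteomes are FASTA plus optional
localization-class and pathway-tag TSVs; kinetic traces are CSV
(``time_s,signal``) plus an events JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .catalog import (
    Feature,
    GenomeAnnotation,
    MutationCatalog,
    MutationRecord,
    parse_mutation_token,
)
from .composition import ProteinRecord
from .physiology import KineticTrace

__all__ = [
    "load_variant_tsv",
    "write_variant_tsv",
    "load_variant_vcf",
    "load_genome_fasta",
    "load_annotation_gff3",
    "load_annotation_genbank",
    "load_plating_tsv",
    "load_proteome_fasta",
    "load_trace_csv",
    "write_newick",
    "write_distance_tsv",
]

PathLike = Union[str, Path]


def load_variant_tsv(path: PathLike) -> MutationCatalog:
    """Read a ``strain_id / token / zygosity`` variant table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"strain_id", "token"}
    if not required <= set(df.columns):
        raise ValueError(f"variant TSV needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        pos, ref, alt, kind = parse_mutation_token(row.token)
        zyg = getattr(row, "zygosity", "homozygous") or "homozygous"
        records.append(MutationRecord(row.strain_id, pos, ref, alt, kind, zyg))
    return MutationCatalog(records)


def write_variant_tsv(catalog: MutationCatalog, path: PathLike) -> None:
    rows = [
        {"strain_id": r.strain_id, "token": r.token(), "zygosity": r.zygosity}
        for r in catalog.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_variant_vcf(path: PathLike, strain_id: Optional[str] = None) -> MutationCatalog:
    """Read single-sample VCF records into the token-based catalog model.

    Left-aligned indels (shared anchor base) are converted to the pure
    insertion/deletion convention; multi-allelic records are out of scope
    and rejected.
    """
    from cyvcf2 import VCF  # deferred: htslib import is comparatively heavy

    vcf = VCF(str(path))
    if strain_id is None:
        strain_id = vcf.samples[0] if vcf.samples else "sample"
    records = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic record at {v.POS} not supported")
        ref, alt = v.REF, v.ALT[0]
        if len(ref) == 1 and len(alt) == 1:
            records.append(MutationRecord(strain_id, v.POS, ref, alt, "SNP"))
        elif len(ref) > 1 and len(alt) == 1 and ref[0] == alt:
            records.append(
                MutationRecord(strain_id, v.POS + 1, ref[1:], "", "deletion")
            )
        elif len(alt) > 1 and len(ref) == 1 and alt[0] == ref:
            records.append(
                MutationRecord(strain_id, v.POS, "", alt[1:], "insertion")
            )
        else:
            raise ValueError(f"unsupported REF/ALT pair {ref}>{alt} at {v.POS}")
    return MutationCatalog(records)


def load_genome_fasta(path: PathLike) -> str:
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def load_annotation_gff3(gff_path: PathLike, fasta_path: PathLike) -> GenomeAnnotation:
    """Genome FASTA + GFF3 CDS features (1-based inclusive internally)."""
    import pyranges as pr

    sequence = load_genome_fasta(fasta_path)
    df = pr.read_gff3(str(gff_path)).df
    cds = df[df.Feature == "CDS"]
    features = []
    for row in cds.itertuples(index=False):
        tag = getattr(row, "locus_tag", None) or getattr(row, "ID", "")
        # pyranges uses 0-based half-open starts
        features.append(Feature(str(tag), int(row.Start) + 1, int(row.End), str(row.Strand)))
    return GenomeAnnotation(sequence, features)


def load_annotation_genbank(path: PathLike) -> GenomeAnnotation:
    record = next(SeqIO.parse(str(path), "genbank"))
    features = []
    for f in record.features:
        if f.type != "CDS":
            continue
        tag = f.qualifiers.get("locus_tag", [""])[0]
        features.append(
            Feature(
                tag,
                int(f.location.start) + 1,
                int(f.location.end),
                "+" if f.location.strand != -1 else "-",
            )
        )
    return GenomeAnnotation(str(record.seq).upper(), features)


def load_plating_tsv(path: PathLike) -> pd.DataFrame:
    """Plating-count table: strain_id, temperature, light, replicate,
    plated_cells, resistant_colonies."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain_id", "replicate", "plated_cells", "resistant_colonies"}
    if not required <= set(df.columns):
        raise ValueError(f"plating TSV needs columns {sorted(required)}")
    return df


def load_proteome_fasta(
    fasta_path: PathLike,
    classes_tsv: Optional[PathLike] = None,
    tags_tsv: Optional[PathLike] = None,
) -> list[ProteinRecord]:
    """Protein FASTA with optional ``protein_id<TAB>class`` localization and
    multi-row ``protein_id<TAB>tag`` pathway tables."""
    classes: dict[str, str] = {}
    if classes_tsv is not None:
        cdf = pd.read_csv(classes_tsv, sep="\t", names=["protein_id", "cls"], header=None,
                          comment="#", dtype=str)
        classes = dict(zip(cdf.protein_id, cdf.cls))
    tags: dict[str, set] = {}
    if tags_tsv is not None:
        tdf = pd.read_csv(tags_tsv, sep="\t", names=["protein_id", "tag"], header=None,
                          comment="#", dtype=str)
        for pid, tag in zip(tdf.protein_id, tdf.tag):
            tags.setdefault(pid, set()).add(tag)
    proteins = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        loc = classes.get(rec.id, "unknown")
        if loc not in ("membrane", "soluble"):
            loc = "unknown"
        proteins.append(
            ProteinRecord(rec.id, str(rec.seq), localization=loc,
                          pathway_tags=frozenset(tags.get(rec.id, set())))
        )
    return proteins


def load_trace_csv(trace_csv: PathLike, events_json: PathLike) -> KineticTrace:
    df = pd.read_csv(trace_csv)
    if not {"time_s", "signal"} <= set(df.columns):
        raise ValueError("trace CSV needs columns time_s, signal")
    with open(events_json) as fh:
        events = json.load(fh)
    return KineticTrace(df.time_s.to_numpy(), df.signal.to_numpy(), events)


def write_newick(tree, path: PathLike, linkage_method: str = "") -> None:
    """Write a clustering tree as Newick; the linkage method is recorded in a
    comment line above the tree."""
    with open(path, "w") as fh:
        if linkage_method:
            fh.write(f"[&linkage={linkage_method}]\n")
        fh.write(str(tree).strip() + "\n")


def write_distance_tsv(dm, path: PathLike) -> None:
    pd.DataFrame(dm.values, index=dm.strains, columns=dm.strains).to_csv(path, sep="\t")
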