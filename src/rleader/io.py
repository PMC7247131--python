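"""Readers for the genomic input formats of the screening pipeline.

GFF3 and BED parsing is delegated to :mod:`pyranges`, which also
converts GFF3's 1-based closed coordinates to the 0-based half-open
convention used throughout this package.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pyranges as pr

from .gene_context import GeneRecord, MotifOccurrence
from .ligand_inference import GeneProteinMap
from .tss_novelty import KnownRnaInterval, TSSRecord

__all__ = [
    "read_gene_annotations",
    "read_occurrences_bed",
    "read_tss",
    "read_known_rnas_bed",
    "read_contig_lengths",
]


def read_gene_annotations(
    path: str | Path,
    gene_map: GeneProteinMap,
    symbol_attribute: str = "gene",
    feature_types: tuple[str, ...] = ("gene",),
) -> list[GeneRecord]:
    """Read gene features from GFF3 into strand-aware records.

    The gene symbol is taken from the ``symbol_attribute`` GFF3
    attribute (falling back to ``ID``); ``gene_map`` supplies the
    product class and r-protein name for each symbol.
    """
    df = pr.read_gff3(str(path), full=True).df
    if feature_types:
        df = df[df["Feature"].isin(feature_types)]
    genes = []
    for _, row in df.iterrows():
        symbol = row.get(symbol_attribute)
        if symbol is None or (isinstance(symbol, float) and pd.isna(symbol)):
            symbol = row.get("ID", "unknown")
        product_class, protein = gene_map.lookup(str(symbol))
        genes.append(
            GeneRecord(
                contig=str(row["Chromosome"]),
                start=int(row["Start"]),
                end=int(row["End"]),
                strand=str(row["Strand"]),
                symbol=str(symbol),
                product_class=product_class,
                protein=protein,
            )
        )
    return genes


def read_contig_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV (contig, length) → dict."""
    out: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, length = line.split("\t")[:2]
        out[name] = int(length)
    return out


def read_occurrences_bed(
    path: str | Path, contig_lengths: dict[str, int]
) -> list[MotifOccurrence]:
    """BED6 of motif homolog loci (name column = motif id)."""
    df = pr.read_bed(str(path)).df
    occs = []
    for _, row in df.iterrows():
        contig = str(row["Chromosome"])
        if contig not in contig_lengths:
            raise KeyError(f"no contig length known for {contig!r}")
        occs.append(
            MotifOccurrence(
                motif_id=str(row["Name"]),
                contig=contig,
                start=int(row["Start"]),
                end=int(row["End"]),
                strand=str(row["Strand"]),
                contig_length=contig_lengths[contig],
            )
        )
    return occs


def read_tss(path: str | Path) -> list[TSSRecord]:
    """TSS positions from single-position BED or 3-column TSV."""
    text = Path(path).read_text()
    records = []
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        if len(fields) >= 6:  # BED6: single-position feature
            records.append(
                TSSRecord(
                    contig=fields[0], position=int(fields[1]), strand=fields[5]
                )
            )
        elif len(fields) >= 3:  # TSV: contig, pos, strand
            records.append(
                TSSRecord(
                    contig=fields[0], position=int(fields[1]), strand=fields[2]
                )
            )
        else:
            raise ValueError(f"unrecognised TSS line: {line!r}")
    return records


def read_known_rnas_bed(path: str | Path) -> list[KnownRnaInterval]:
    """BED6 of previously published RNA loci."""
    df = pr.read_bed(str(path)).df
    return [
        KnownRnaInterval(
            contig=str(row["Chromosome"]),
            start=int(row["Start"]),
            end=int(row["End"]),
            strand=str(row["Strand"]),
            rna_name=str(row["Name"]),
        )
        for _, row in df.iterrows()
    ]
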