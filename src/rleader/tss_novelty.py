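"""Transcription-start-site consistency and novelty screening.

A genuine cis-regulatory leader must be transcribed together with the
gene it regulates, i.e. lie between a transcription start site (TSS)
and the first gene of the operon.  :func:`tss_consistency` scores each
motif occurrence against experimentally mapped TSS positions.

Independently, a candidate motif is only *novel* if its genomic
homologs do not simply re-find an already published RNA;
:func:`novelty_filter` eliminates motifs whose occurrences overlap
known RNA intervals on the same strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gene_context import GeneRecord, MotifOccurrence

__all__ = [
    "TSSRecord",
    "KnownRnaInterval",
    "NoveltyVerdict",
    "tss_consistency",
    "novelty_filter",
    "DEFAULT_TSS_WINDOW",
    "DEFAULT_MIN_OVERLAP_FRAC",
]

#: Search window (nt) upstream of the first gene for candidate TSSes.
DEFAULT_TSS_WINDOW = 2000
#: Minimum overlap, as a fraction of the shorter interval, for a known
#: RNA to disqualify a motif occurrence.
DEFAULT_MIN_OVERLAP_FRAC = 0.5


@dataclass(frozen=True)
class TSSRecord:
    """One experimentally mapped transcription start site."""

    contig: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("TSS position must be >= 0")
        if self.strand not in "+-":
            raise ValueError("TSS strand must be + or -")


@dataclass(frozen=True)
class KnownRnaInterval:
    """A previously published RNA locus (half-open interval)."""

    contig: str
    start: int
    end: int
    strand: str
    rna_name: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"known RNA {self.rna_name}: start must be < end")


@dataclass
class NoveltyVerdict:
    """Keep/eliminate decision for one motif, with offending overlaps."""

    motif_id: str
    keep: bool
    overlaps: list[tuple[MotifOccurrence, KnownRnaInterval]] = field(
        default_factory=list
    )


def tss_consistency(
    occurrence: MotifOccurrence,
    first_gene: GeneRecord,
    tss_list: list[TSSRecord],
    annotations: list[GeneRecord] = (),
    window: int = DEFAULT_TSS_WINDOW,
) -> str:
    """Classify a motif occurrence against mapped TSS positions.

    Returns ``"consistent"`` when some same-strand TSS lies upstream of
    the motif (in transcription direction) with no annotated same-strand
    gene starting strictly between the TSS and the motif — i.e. the
    motif sits inside the 5' leader of a transcript covering the gene.
    Returns ``"inconsistent"`` when TSSes exist in the locus window but
    every one falls inside the motif or between motif and gene start,
    and ``"no-data"`` when no same-strand TSS lies within ``window`` nt
    upstream of the gene.
    """
    if occurrence.strand != first_gene.strand:
        raise ValueError(
            f"occurrence of {occurrence.motif_id} and gene "
            f"{first_gene.symbol} are on different strands"
        )
    forward = occurrence.strand == "+"
    gene_start = first_gene.start if forward else first_gene.end
    motif_start = occurrence.start if forward else occurrence.end

    def upstream_of(pos: int, ref: int) -> bool:
        return pos < ref if forward else pos > ref

    candidates = [
        t
        for t in tss_list
        if t.contig == occurrence.contig
        and t.strand == occurrence.strand
        and upstream_of(t.position, gene_start)
        and abs(gene_start - t.position) <= window
    ]
    if not candidates:
        return "no-data"

    gene_starts = [
        (g.start if forward else g.end)
        for g in annotations
        if g.contig == occurrence.contig
        and g.strand == occurrence.strand
        and g is not first_gene
    ]
    for tss in candidates:
        if upstream_of(tss.position, motif_start):
            blocked = any(
                upstream_of(tss.position, gs) and upstream_of(gs, motif_start)
                for gs in gene_starts
            )
            if not blocked:
                return "consistent"
    return "inconsistent"


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def novelty_filter(
    occurrences: dict[str, list[MotifOccurrence]],
    known: list[KnownRnaInterval],
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> dict[str, NoveltyVerdict]:
    """Eliminate motifs whose homologs overlap previously published RNAs.

    A motif is eliminated iff any of its occurrences overlaps a
    same-strand known RNA by at least ``min_overlap_frac`` of the
    shorter of the two intervals (set the fraction to a tiny positive
    value, e.g. 1e-9, for strict 1-nt overlap elimination).  Every
    offending (occurrence, known RNA) pair is reported.
    """
    verdicts: dict[str, NoveltyVerdict] = {}
    for motif_id, occs in occurrences.items():
        offending = []
        for occ in occs:
            for rna in known:
                if rna.contig != occ.contig or rna.strand != occ.strand:
                    continue
                ov = _overlap(occ.start, occ.end, rna.start, rna.end)
                shorter = min(occ.end - occ.start, rna.end - rna.start)
                if shorter > 0 and ov / shorter >= min_overlap_frac:
                    offending.append((occ, rna))
        verdicts[motif_id] = NoveltyVerdict(
            motif_id=motif_id, keep=not offending, overlaps=offending
        )
    return verdicts
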