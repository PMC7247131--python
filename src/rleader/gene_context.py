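"""Regulated-operon inference from the gene context of motif occurrences.

A cis-regulatory leader sits in the 5' UTR of the transcript it
regulates, so the genes it controls are the chain of co-transcribed
genes immediately downstream of each genomic occurrence of the motif.
Two heuristics bound that chain:

* co-transcribed genes may be separated by at most 500 nt of intergenic
  sequence (larger gaps, or a strand switch, end the operon);
* an occurrence is only *usable* when at least 8 kb of sequence is
  available downstream of the motif — shorter contigs (common in
  draft/metagenomic assemblies) would truncate the chain and bias the
  consensus.

Per-occurrence chains are then merged into a consensus operon: a gene
is retained when it appears in at least ``min_support`` (default 0.75)
of the usable chains, ordered by the rank at which it most often
appears.  Genes seen in a minority of chains (support in
[0.25, min_support)) are reported separately as "often-extended" genes
rather than silently dropped.

All coordinates are 0-based, half-open, strand-aware.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from statistics import median

__all__ = [
    "GeneRecord",
    "MotifOccurrence",
    "OperonPrediction",
    "UNUSABLE",
    "MAX_INTERGENIC_GAP",
    "MIN_DOWNSTREAM_SEQUENCE",
    "downstream_chain",
    "consensus_operon",
    "ContigNotFoundError",
]

#: Maximum intergenic distance (nt) between co-transcribed genes.
MAX_INTERGENIC_GAP = 500
#: Minimum sequence (nt) required downstream of a motif occurrence.
MIN_DOWNSTREAM_SEQUENCE = 8000


class ContigNotFoundError(KeyError):
    """Occurrence lies on a contig absent from the gene annotations."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: half-open interval, strand, symbol."""

    contig: str
    start: int
    end: int
    strand: str
    symbol: str
    product_class: str = "other"  # "r-protein" | "other"
    protein: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.symbol}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.symbol}: strand must be + or -")
        if (self.product_class == "r-protein") != (self.protein is not None):
            raise ValueError(
                f"gene {self.symbol}: protein must be set iff product_class "
                "is 'r-protein'"
            )


@dataclass(frozen=True)
class MotifOccurrence:
    """One genomic homolog of a motif."""

    motif_id: str
    contig: str
    start: int
    end: int
    strand: str
    contig_length: int

    def __post_init__(self) -> None:
        if not self.start < self.end <= self.contig_length:
            raise ValueError(
                f"occurrence of {self.motif_id} on {self.contig}: "
                "need start < end <= contig_length"
            )


class _Unusable:
    """Sentinel: occurrence has too little downstream sequence."""

    def __repr__(self) -> str:  # pragma: no cover
        return "UNUSABLE"

    def __bool__(self) -> bool:
        return False


UNUSABLE = _Unusable()


@dataclass
class OperonPrediction:
    """Consensus regulated operon for one motif.

    ``genes`` holds retained gene symbols in transcription order;
    ``support`` maps each retained symbol to the fraction of usable
    chains containing it; ``often_extended`` lists minority genes that
    extend the operon in some occurrences only.
    """

    motif_id: str
    genes: list[str]
    support: dict[str, float] = field(default_factory=dict)
    often_extended: list[str] = field(default_factory=list)
    n_usable_chains: int = 0
    note: str | None = None


def downstream_chain(
    occurrence: MotifOccurrence,
    annotations: list[GeneRecord],
    max_gap: int = MAX_INTERGENIC_GAP,
    min_downstream: int = MIN_DOWNSTREAM_SEQUENCE,
):
    """Chain of putatively co-transcribed genes downstream of one occurrence.

    Returns the ordered list of same-strand :class:`GeneRecord` starting
    at the first gene strictly downstream of the motif (genes
    overlapping the motif itself are skipped) and chaining while each
    intergenic gap is <= ``max_gap``; an opposite-strand gene or a
    larger gap ends the chain.  Overlapping same-strand genes count as
    gap 0.  Returns :data:`UNUSABLE` when less than ``min_downstream``
    nt of sequence remains downstream of the motif on the contig.

    Raises
    ------
    ContigNotFoundError
        If no annotation mentions the occurrence's contig.
    """
    if not any(g.contig == occurrence.contig for g in annotations):
        raise ContigNotFoundError(
            f"contig {occurrence.contig!r} absent from gene annotations"
        )
    forward = occurrence.strand == "+"
    available = (
        occurrence.contig_length - occurrence.end if forward else occurrence.start
    )
    if available < min_downstream:
        return UNUSABLE

    on_contig = [g for g in annotations if g.contig == occurrence.contig]
    if forward:
        cand = [g for g in on_contig if g.start >= occurrence.end]
        cand.sort(key=lambda g: g.start)
    else:
        cand = [g for g in on_contig if g.end <= occurrence.start]
        cand.sort(key=lambda g: -g.end)

    chain: list[GeneRecord] = []
    prev: GeneRecord | None = None
    for gene in cand:
        if gene.strand != occurrence.strand:
            break
        if prev is not None:
            gap = gene.start - prev.end if forward else prev.start - gene.end
            if gap > max_gap:
                break
        chain.append(gene)
        prev = gene
    return chain


def consensus_operon(
    motif_id: str,
    chains: list[list[str]],
    min_support: float = 0.75,
    extended_min_support: float = 0.25,
) -> OperonPrediction:
    """Merge per-occurrence gene-symbol chains into a consensus operon.

    A symbol is retained iff it occurs in >= ``min_support`` of the
    chains; retained symbols are ordered by modal rank (ties: median
    rank, then symbol).  Symbols with support in
    [``extended_min_support``, ``min_support``) are reported as
    often-extended.  Chains should already exclude unusable
    occurrences.
    """
    if not chains:
        return OperonPrediction(
            motif_id=motif_id,
            genes=[],
            n_usable_chains=0,
            note="no usable occurrences",
        )
    n = len(chains)
    ranks: dict[str, list[int]] = {}
    for chain in chains:
        for rank, symbol in enumerate(chain):
            ranks.setdefault(symbol, []).append(rank)
    support: dict[str, float] = {}
    for symbol in ranks:
        support[symbol] = sum(symbol in chain for chain in chains) / n

    def order_key(symbol: str):
        r = ranks[symbol]
        counts = Counter(r)
        top = max(counts.values())
        modal = min(rank for rank, c in counts.items() if c == top)
        return (modal, median(r), symbol)

    retained = sorted(
        (s for s in ranks if support[s] >= min_support), key=order_key
    )
    extended = sorted(
        (
            s
            for s in ranks
            if extended_min_support <= support[s] < min_support
        ),
        key=order_key,
    )
    return OperonPrediction(
        motif_id=motif_id,
        genes=retained,
        support={s: support[s] for s in retained},
        often_extended=extended,
        n_usable_chains=n,
    )
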