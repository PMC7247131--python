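"""Synthetic alignments and genome fixtures with known ground truth.

Every stage of the screening pipeline is exercised on simulated data:

* :func:`simulate_alignment` evolves sequences down a random Yule tree
  under a consensus secondary structure.  Substitutions at paired
  columns are compensated (both partners replaced by a new canonical
  pair type) with a configurable probability, producing exactly the
  covariation signal the detectors look for; uncompensated events and
  an explicit per-sequence noise term produce non-canonical pairs.

* :func:`generate_genome_fixture` lays out motif occurrences, gene
  cascades and TSS positions on synthetic contigs and writes them as
  GFF3/BED/TSV, including deliberately pathological cases (intergenic
  gap exactly at the chaining limit, contigs truncated just below the
  required downstream sequence).

Both generators are deterministic given a seed.  The alignment model is
intentionally minimal: a uniform substitution process, no indels, no
base-composition bias and no rate variation across sites — enough to
calibrate detector behaviour, not a portrait of real alignments.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .covariation import CANONICAL_PAIRS
from .stockholm import StructuredAlignment, extract_pairs

__all__ = [
    "EvolutionParams",
    "GeneCascadeSpec",
    "ContigSpec",
    "GenomeLayoutSpec",
    "GenomeFixture",
    "simulate_alignment",
    "generate_genome_fixture",
]

_BASES = "ACGU"


@dataclass
class EvolutionParams:
    """Parameters of the structure-aware alignment simulator.

    Defaults emulate a typical curated motif alignment: a few dozen
    sequences from a moderately deep phylogeny whose paired columns are
    almost always rescued by a compensatory partner change, with a low
    rate of residual non-canonical pairs.

    Attributes
    ----------
    n_sequences
        Number of tip sequences (>= 2).
    tree_depth
        Expected substitutions/site from root to tip; branch lengths of
        the random Yule tree are rescaled to this depth.
    pair_substitution_rate, unpaired_substitution_rate
        Poisson event rates (per unit branch length) for paired-column
        units and unpaired columns.
    compensatory_rate
        Probability that a substitution event at a paired column
        replaces the whole pair with a different canonical type;
        otherwise only one partner changes, usually leaving a
        non-canonical pair.
    noncanonical_noise
        Per-sequence, per-pair-column probability of forcing a
        non-canonical state at the tips (alignment error / biological
        exceptions).
    seed
        Seed for the simulation; identical seeds give identical output.
    """

    n_sequences: int = 24
    tree_depth: float = 0.6
    pair_substitution_rate: float = 1.0
    unpaired_substitution_rate: float = 1.0
    compensatory_rate: float = 0.95
    noncanonical_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ValueError("n_sequences must be >= 2")
        for name in ("compensatory_rate", "noncanonical_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _yule_tree(n: int, depth: float, rng: random.Random) -> dendropy.Tree:
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, rng=rng
    )
    height = tree.max_distance_from_root()
    if height > 0 and depth > 0:
        factor = depth / height
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
    elif depth == 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = 0.0
    return tree


def _mutate_unpaired(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[rng.integers(len(choices))]


def _new_pair_type(current: str, rng: np.random.Generator) -> str:
    choices = [p for p in CANONICAL_PAIRS if p != current]
    return choices[rng.integers(len(choices))]


def _force_noncanonical(pair: str, rng: np.random.Generator) -> str:
    """Replace the 3' partner so the pair is no longer canonical."""
    five = pair[0]
    bad = [b for b in _BASES if five + b not in CANONICAL_PAIRS]
    return five + bad[rng.integers(len(bad))]


def simulate_alignment(
    structure: str, params: EvolutionParams
) -> StructuredAlignment:
    """Simulate an alignment that conserves ``structure``.

    The root draws a random canonical pair type for every base pair of
    the structure and a random base for every unpaired column; the
    sequence then evolves down a Yule tree.  The input structure is
    attached as the alignment's consensus structure.
    """
    table = extract_pairs(structure)
    rng = np.random.default_rng(params.seed)
    tree = _yule_tree(
        params.n_sequences, params.tree_depth, random.Random(params.seed)
    )

    n_pairs = len(table.pairs)
    unpaired = sorted(table.unpaired)
    root_pairs = [
        CANONICAL_PAIRS[rng.integers(len(CANONICAL_PAIRS))] for _ in range(n_pairs)
    ]
    root_unpaired = [_BASES[rng.integers(4)] for _ in unpaired]

    states: dict = {tree.seed_node: (root_pairs, root_unpaired)}
    tip_states: dict[str, tuple[list[str], list[str]]] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        pairs, singles = states[node.parent_node]
        pairs = list(pairs)
        singles = list(singles)
        bl = node.edge.length or 0.0
        if bl > 0:
            for k in range(n_pairs):
                n_events = rng.poisson(params.pair_substitution_rate * bl)
                for _ in range(n_events):
                    if rng.random() < params.compensatory_rate:
                        pairs[k] = _new_pair_type(
                            pairs[k] if pairs[k] in CANONICAL_PAIRS else "GC", rng
                        )
                    else:
                        # one partner drifts on its own
                        side = rng.integers(2)
                        old = pairs[k]
                        new_base = _mutate_unpaired(old[side], rng)
                        pairs[k] = (
                            new_base + old[1] if side == 0 else old[0] + new_base
                        )
            for k in range(len(singles)):
                n_events = rng.poisson(params.unpaired_substitution_rate * bl)
                for _ in range(n_events):
                    singles[k] = _mutate_unpaired(singles[k], rng)
        states[node] = (pairs, singles)
        if node.is_leaf():
            tip_states[node.taxon.label] = (pairs, singles)

    length = len(structure)
    records: list[tuple[str, str]] = []
    for idx, label in enumerate(sorted(tip_states), start=1):
        pairs, singles = tip_states[label]
        pairs = list(pairs)
        for k in range(n_pairs):
            if params.noncanonical_noise > 0 and rng.random() < params.noncanonical_noise:
                if pairs[k] in CANONICAL_PAIRS:
                    pairs[k] = _force_noncanonical(pairs[k], rng)
        row = [""] * length
        for k, (i, j) in enumerate(table.pairs):
            row[i], row[j] = pairs[k][0], pairs[k][1]
        for k, col in enumerate(unpaired):
            row[col] = singles[k]
        records.append((f"synth{idx:03d}/1-{length}", "".join(row)))

    return StructuredAlignment(
        records=records,
        consensus_structure=structure,
        metadata={"ID": "synthetic-motif", "SQ": str(len(records))},
    )


# ---------------------------------------------------------------------------
# Genome layout fixtures


@dataclass
class GeneCascadeSpec:
    """A run of genes downstream of an anchor position.

    ``gaps[k]`` is the intergenic distance preceding gene ``k`` (the
    first gap is measured from the anchor, i.e. the motif end).
    """

    symbols: list[str]
    lengths: list[int]
    gaps: list[int]
    strand: str = "+"

    def __post_init__(self) -> None:
        if not len(self.symbols) == len(self.lengths) == len(self.gaps):
            raise ValueError("symbols, lengths and gaps must have equal length")


@dataclass
class ContigSpec:
    name: str
    length: int
    motifs: list[tuple[str, int, int, str]] = field(default_factory=list)
    cascades: list[tuple[int, GeneCascadeSpec]] = field(default_factory=list)
    #: (position, strand) pairs
    tss: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class GenomeLayoutSpec:
    contigs: list[ContigSpec]


@dataclass
class GenomeFixture:
    """Realised genome fixture: in-memory records plus file contents."""

    genes: list  # GeneRecord
    occurrences: list  # MotifOccurrence
    tss: list  # TSSRecord
    contig_lengths: dict[str, int]
    gff3: str
    occurrences_bed: str
    tss_bed: str
    contig_table: str

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotations.gff3": self.gff3,
            "occurrences.bed": self.occurrences_bed,
            "tss.bed": self.tss_bed,
            "contigs.tsv": self.contig_table,
        }
        out = {}
        for name, content in paths.items():
            p = directory / name
            p.write_text(content)
            out[name] = p
        return out


def generate_genome_fixture(
    spec: GenomeLayoutSpec, seed: int = 0, gene_map=None
) -> GenomeFixture:
    """Realise a genome layout spec as annotation records and files.

    ``gene_map`` (a :class:`~rleader.ligand_inference.GeneProteinMap`)
    classifies the cascade symbols; the packaged map is used by
    default.  Raises ``ValueError`` naming the contig when a feature
    does not fit.
    """
    from .gene_context import GeneRecord, MotifOccurrence
    from .ligand_inference import default_gene_protein_map
    from .tss_novelty import TSSRecord

    gene_map = gene_map or default_gene_protein_map()
    genes: list[GeneRecord] = []
    occurrences: list[MotifOccurrence] = []
    tss: list[TSSRecord] = []
    contig_lengths: dict[str, int] = {}
    gff = ["##gff-version 3"]
    occ_bed: list[str] = []
    tss_bed: list[str] = []

    for contig in spec.contigs:
        contig_lengths[contig.name] = contig.length
        gff.append(f"##sequence-region {contig.name} 1 {contig.length}")
        for motif_id, start, end, strand in contig.motifs:
            if not 0 <= start < end <= contig.length:
                raise ValueError(
                    f"contig {contig.name}: motif {motif_id} [{start},{end}) "
                    "does not fit"
                )
            occurrences.append(
                MotifOccurrence(
                    motif_id=motif_id,
                    contig=contig.name,
                    start=start,
                    end=end,
                    strand=strand,
                    contig_length=contig.length,
                )
            )
            occ_bed.append(
                f"{contig.name}\t{start}\t{end}\t{motif_id}\t0\t{strand}"
            )
        for anchor, cascade in contig.cascades:
            pos = anchor
            for symbol, length, gap in zip(
                cascade.symbols, cascade.lengths, cascade.gaps
            ):
                if cascade.strand == "+":
                    start = pos + gap
                    end = start + length
                    pos = end
                else:
                    end = pos - gap
                    start = end - length
                    pos = start
                if not 0 <= start < end <= contig.length:
                    raise ValueError(
                        f"contig {contig.name}: gene {symbol} [{start},{end}) "
                        "does not fit"
                    )
                product_class, protein = gene_map.lookup(symbol)
                genes.append(
                    GeneRecord(
                        contig=contig.name,
                        start=start,
                        end=end,
                        strand=cascade.strand,
                        symbol=symbol,
                        product_class=product_class,
                        protein=protein,
                    )
                )
                gff.append(
                    "\t".join(
                        [
                            contig.name,
                            "rleader-synthetic",
                            "gene",
                            str(start + 1),
                            str(end),
                            ".",
                            cascade.strand,
                            ".",
                            f"ID={symbol}.{len(genes)};gene={symbol}",
                        ]
                    )
                )
        for position, strand in contig.tss:
            if not 0 <= position < contig.length:
                raise ValueError(
                    f"contig {contig.name}: TSS at {position} does not fit"
                )
            tss.append(
                TSSRecord(contig=contig.name, position=position, strand=strand)
            )
            tss_bed.append(
                f"{contig.name}\t{position}\t{position + 1}\tTSS\t0\t{strand}"
            )

    contig_table = "\n".join(
        f"{name}\t{length}" for name, length in contig_lengths.items()
    )
    return GenomeFixture(
        genes=genes,
        occurrences=occurrences,
        tss=tss,
        contig_lengths=contig_lengths,
        gff3="\n".join(gff) + "\n",
        occurrences_bed="\n".join(occ_bed) + "\n",
        tss_bed="\n".join(tss_bed) + "\n",
        contig_table=contig_table + "\n",
    )
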