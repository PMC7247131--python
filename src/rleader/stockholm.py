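"""Stockholm 1.0 alignment I/O with consensus secondary structure.

Alignments of candidate cis-regulatory RNA motifs are exchanged as
Stockholm files carrying a per-column consensus structure line
(``#=GC SS_cons``).  Everything downstream of the parser — base-pair
classification, covariation statistics, report generation — operates on
the :class:`StructuredAlignment` container defined here and the pair
list extracted from the structure line with :func:`extract_pairs`.

The parser is deliberately strict about the two contracts the pipeline
relies on (every sequence has the alignment length; a consensus
structure line is present) and deliberately tolerant of everything else:
unknown ``#=GF``/``#=GC``/``#=GS``/``#=GR`` annotations are preserved
verbatim so that a read → write → read cycle is content-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "StructuredAlignment",
    "PairTable",
    "StockholmError",
    "StockholmParseError",
    "NoConsensusStructureError",
    "StructureError",
    "read_stockholm",
    "write_stockholm",
    "extract_pairs",
]


class StockholmError(ValueError):
    """Base class for Stockholm-related failures."""


class StockholmParseError(StockholmError):
    """Malformed Stockholm text (ragged rows, missing header, ...)."""


class NoConsensusStructureError(StockholmError):
    """Alignment block lacks a consensus structure (SS_cons) line."""


class StructureError(StockholmError):
    """Unbalanced or ill-formed secondary-structure string."""


@dataclass
class StructuredAlignment:
    """A gapped multiple alignment plus its consensus secondary structure.

    Parameters
    ----------
    records
        Ordered ``(identifier, gapped_sequence)`` pairs.  Identifiers are
        unique; sequences all share the alignment length.  Residues are
        kept verbatim (case and T/U are preserved on output; downstream
        computation normalises them).
    consensus_structure
        Per-column structure string (WUSS or dot-bracket), same length
        as the sequences.
    metadata
        File-level ``#=GF`` annotations, tag → value.
    column_annotations
        Other per-column ``#=GC`` lines (tag → string), e.g. ``RF``.
    sequence_annotations
        Preserved ``#=GS`` / ``#=GR`` lines, verbatim, in input order.
    """

    records: list[tuple[str, str]]
    consensus_structure: str
    metadata: dict[str, str] = field(default_factory=dict)
    column_annotations: dict[str, str] = field(default_factory=dict)
    sequence_annotations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        length = len(self.consensus_structure)
        seen: set[str] = set()
        for name, seq in self.records:
            if len(seq) != length:
                raise StockholmParseError(
                    f"sequence {name!r} has length {len(seq)}, "
                    f"alignment length is {length}"
                )
            if name in seen:
                raise StockholmParseError(f"duplicate sequence identifier {name!r}")
            seen.add(name)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def alignment_length(self) -> int:
        return len(self.consensus_structure)

    @property
    def identifiers(self) -> list[str]:
        return [name for name, _ in self.records]

    def sequence(self, name: str) -> str:
        for rec_name, seq in self.records:
            if rec_name == name:
                return seq
        raise KeyError(name)

    def ungapped_fasta(self) -> str:
        """Ungapped sequences as FASTA text (gaps ``-.~_`` stripped)."""
        out = []
        for name, seq in self.records:
            out.append(f">{name}")
            out.append("".join(c for c in seq if c not in "-.~_"))
        return "\n".join(out) + "\n"


@dataclass(frozen=True)
class PairTable:
    """Base-pair list extracted from a consensus structure string."""

    pairs: tuple[tuple[int, int], ...]
    unpaired: frozenset[int]

    def __len__(self) -> int:
        return len(self.pairs)


# Bracket classes recognised in consensus structure strings.  WUSS uses
# <> for simple stems and (), [], {} for multifurcation context; pairs
# of upper/lower-case letters annotate pseudoknots.
_BRACKET_CLASSES = {"<": ">", "(": ")", "[": "]", "{": "}"}
_PK_OPEN = {c: c.lower() for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}


def extract_pairs(structure: str) -> PairTable:
    """Match brackets in a WUSS/dot-bracket string into a pair table.

    Each bracket class (``<>``, ``()``, ``[]``, ``{}`` and every
    pseudoknot letter pair ``Aa`` .. ``Zz``) is matched LIFO
    independently of the others; all remaining characters are unpaired.

    Raises
    ------
    StructureError
        If any class has an unmatched opening or closing character; the
        message names the class and the 0-based column.
    """
    stacks: dict[str, list[int]] = {}
    pairs: list[tuple[int, int]] = []
    paired_cols: set[int] = set()
    for i, c in enumerate(structure):
        if c in _BRACKET_CLASSES or c in _PK_OPEN:
            stacks.setdefault(c, []).append(i)
        else:
            opener = None
            if c in {")", ">", "]", "}"}:
                opener = {v: k for k, v in _BRACKET_CLASSES.items()}[c]
            elif c.isalpha() and c.islower():
                opener = c.upper()
            if opener is not None:
                stack = stacks.get(opener, [])
                if not stack:
                    raise StructureError(
                        f"unmatched closing {c!r} (class {opener}{c}) at column {i}"
                    )
                j = stack.pop()
                pairs.append((j, i))
                paired_cols.update((i, j))
    for opener, stack in stacks.items():
        if stack:
            closer = _BRACKET_CLASSES.get(opener, opener.lower())
            raise StructureError(
                f"unmatched opening {opener!r} (class {opener}{closer}) "
                f"at column {stack[-1]}"
            )
    unpaired = frozenset(i for i in range(len(structure)) if i not in paired_cols)
    return PairTable(pairs=tuple(sorted(pairs)), unpaired=unpaired)


def _finish_block(
    order: list[str],
    seqs: dict[str, list[str]],
    gf: dict[str, str],
    gc: dict[str, list[str]],
    seq_ann: list[str],
) -> StructuredAlignment:
    gc_joined = {tag: "".join(parts) for tag, parts in gc.items()}
    ss = gc_joined.pop("SS_cons", None)
    if ss is None:
        raise NoConsensusStructureError(
            "alignment block has no consensus structure (#=GC SS_cons) line"
        )
    records = [(name, "".join(seqs[name])) for name in order]
    for name, seq in records:
        if len(seq) != len(ss):
            raise StockholmParseError(
                f"sequence {name!r} has length {len(seq)} but the "
                f"consensus structure line has length {len(ss)}"
            )
    return StructuredAlignment(
        records=records,
        consensus_structure=ss,
        metadata=gf,
        column_annotations=gc_joined,
        sequence_annotations=seq_ann,
    )


def read_stockholm(source: str | Path) -> list[StructuredAlignment]:
    """Parse Stockholm 1.0 text into structured alignments.

    ``source`` may be a path to a file or the Stockholm text itself
    (anything containing a newline is treated as text).  A file may hold
    several alignments separated by ``//``; interleaved (wrapped) blocks
    are joined.  Every block must carry a ``#=GC SS_cons`` line.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif "\n" in source:
        text = source
    else:
        text = Path(source).read_text()

    if "# STOCKHOLM" not in text:
        raise StockholmParseError("missing '# STOCKHOLM 1.0' header")

    alignments: list[StructuredAlignment] = []
    order: list[str] = []
    seqs: dict[str, list[str]] = {}
    gf: dict[str, str] = {}
    gc: dict[str, list[str]] = {}
    seq_ann: list[str] = []
    saw_content = False

    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("# STOCKHOLM"):
            continue
        if line.strip() == "//":
            if saw_content:
                alignments.append(_finish_block(order, seqs, gf, gc, seq_ann))
            order, seqs, gf, gc, seq_ann = [], {}, {}, {}, []
            saw_content = False
            continue
        if line.startswith("#=GF"):
            parts = line.split(None, 2)
            if len(parts) == 3:
                tag, value = parts[1], parts[2]
                gf[tag] = (gf[tag] + " " + value) if tag in gf else value
            saw_content = True
            continue
        if line.startswith("#=GC"):
            parts = line.split(None, 2)
            if len(parts) != 3:
                raise StockholmParseError(f"malformed #=GC line: {line!r}")
            gc.setdefault(parts[1], []).append(parts[2].strip())
            saw_content = True
            continue
        if line.startswith("#=GS") or line.startswith("#=GR"):
            seq_ann.append(line)
            saw_content = True
            continue
        if line.startswith("#"):
            continue  # free comment
        parts = line.split()
        if len(parts) != 2:
            raise StockholmParseError(f"malformed sequence line: {line!r}")
        name, chunk = parts
        if name not in seqs:
            order.append(name)
            seqs[name] = []
        seqs[name].append(chunk)
        saw_content = True

    if saw_content:  # tolerate a missing trailing //
        alignments.append(_finish_block(order, seqs, gf, gc, seq_ann))
    return alignments


def write_stockholm(alignments: list[StructuredAlignment] | StructuredAlignment) -> str:
    """Serialise alignments as single-block Stockholm 1.0 text.

    Residues are written verbatim (no T/U or case normalisation);
    ``read_stockholm(write_stockholm(x)) == x``.
    """
    if isinstance(alignments, StructuredAlignment):
        alignments = [alignments]
    out = ["# STOCKHOLM 1.0"]
    for aln in alignments:
        names = [name for name, _ in aln.records]
        gc_tags = list(aln.column_annotations)
        width = max(
            [len(n) for n in names]
            + [len("#=GC SS_cons")]
            + [len(f"#=GC {t}") for t in gc_tags]
            + [1]
        )
        for tag, value in aln.metadata.items():
            out.append(f"#=GF {tag} {value}")
        out.extend(aln.sequence_annotations)
        for name, seq in aln.records:
            out.append(f"{name:<{width}} {seq}")
        for tag, value in aln.column_annotations.items():
            out.append(f"{'#=GC ' + tag:<{width}} {value}")
        out.append(f"{'#=GC SS_cons':<{width}} {aln.consensus_structure}")
        out.append("//")
    return "\n".join(out) + "\n"
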