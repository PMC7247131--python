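"""Prediction of the r-protein ligand of each candidate r-leader.

An r-leader is bound by an excess copy of one of the r-proteins its
operon encodes — in every experimentally characterised case the ligand
gene is itself under the leader's control.  That observation yields a
three-tier decision procedure over the consensus operon:

``Only``
    The operon encodes exactly one distinct r-protein: that protein is
    the ligand.  (Non-ribosomal genes such as *rimM* or *rpoA* never
    become ligands and do not block this case.)
``Prior``
    Several r-proteins are encoded, but exactly one of them is already
    an established r-leader ligand elsewhere — leaders for the same
    protein recur across unrelated lineages, so the established protein
    is the best guess.  Ligands established by ``Only`` calls within
    the same screening run participate as a second, lower-priority tier
    (such calls are flagged ``this-run``): they are consulted only when
    the literature table yields no hit, so a novel ligand discovered in
    this run never overrides a literature-established one.
``Closest``
    Fallback: the first r-protein gene in transcription order.

Proteins that act as an obligate dimer (e.g. S6 and S18) are declared
as a joint ligand name; when both partner genes are present in an
operon they collapse to the single joint name before the tiers are
applied.

Confidence decreases Only > Prior > Closest; each call carries that
tag plus the supporting evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "GeneProteinMap",
    "KnownLigandTable",
    "LigandCall",
    "predict_ligand",
    "two_pass_inference",
    "default_gene_protein_map",
    "default_known_ligands",
    "default_dimers",
]

logger = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "data"

_CONFIDENCE = {"Only": "high", "Prior": "medium", "Closest": "low"}


@dataclass
class GeneProteinMap:
    """Map from gene symbol to (product class, r-protein name)."""

    entries: dict[str, tuple[str, str | None]]

    def lookup(self, symbol: str) -> tuple[str, str | None]:
        """Classify a symbol; unknown symbols are 'other' with a warning."""
        if symbol not in self.entries:
            logger.warning("unknown gene symbol %r: treated as non-ribosomal", symbol)
            return ("other", None)
        return self.entries[symbol]

    def with_overrides(self, overrides: dict[str, str]) -> "GeneProteinMap":
        """Copy of the map with symbol → r-protein overrides applied."""
        merged = dict(self.entries)
        for symbol, protein in overrides.items():
            merged[symbol] = ("r-protein", protein)
        return GeneProteinMap(entries=merged)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneProteinMap":
        entries: dict[str, tuple[str, str | None]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            symbol, product_class = fields[0], fields[1]
            protein = fields[2] if len(fields) > 2 and fields[2] else None
            entries[symbol] = (product_class, protein)
        return cls(entries=entries)


@dataclass
class KnownLigandTable:
    """R-proteins established as r-leader ligands, with provenance.

    ``entries`` maps a ligand name (joint names such as ``S6:S18``
    allowed) to a provenance tag: ``literature`` for previously
    published leaders, ``this-run`` for ligands established by ``Only``
    calls of the current screening run.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def add(self, ligand: str, provenance: str = "this-run") -> None:
        if provenance not in ("literature", "this-run"):
            raise ValueError(f"unknown provenance {provenance!r}")
        # Literature entries are never downgraded.
        if self.entries.get(ligand) != "literature":
            self.entries[ligand] = provenance

    def hits(self, proteins, provenance: str) -> set[str]:
        return {
            p for p in proteins if self.entries.get(p) == provenance
        }

    def copy(self) -> "KnownLigandTable":
        return KnownLigandTable(entries=dict(self.entries))

    @classmethod
    def from_names(cls, names, provenance: str = "literature") -> "KnownLigandTable":
        return cls(entries={n: provenance for n in names})


@dataclass
class LigandCall:
    """Predicted ligand for one motif."""

    motif_id: str
    ligand: str | None
    basis: str | None  # "Only" | "Prior" | "Closest" | None
    evidence: list[tuple[str, str]] = field(default_factory=list)
    from_this_run: bool = False  # Prior tier resolved via a this-run ligand
    confidence: str | None = None

    def __post_init__(self) -> None:
        if self.basis is not None and self.confidence is None:
            self.confidence = _CONFIDENCE[self.basis]


def _operon_proteins(
    genes: list[str], gene_map: GeneProteinMap, dimers: list[tuple[str, str, str]]
) -> list[tuple[str, str]]:
    """(symbol(s), protein) per r-protein gene in order, dimers collapsed.

    When both members of a declared dimer are present, the pair is
    replaced by one entry carrying the joint ligand name, positioned at
    the first member's rank.
    """
    rproteins: list[tuple[str, str]] = []
    for symbol in genes:
        product_class, protein = gene_map.lookup(symbol)
        if product_class == "r-protein":
            rproteins.append((symbol, protein))
    for first, second, joint in dimers:
        have = {p for _, p in rproteins}
        if first in have and second in have:
            collapsed: list[tuple[str, str]] = []
            done = False
            for symbol, protein in rproteins:
                if protein in (first, second):
                    if not done:
                        members = [s for s, p in rproteins if p in (first, second)]
                        collapsed.append(("+".join(members), joint))
                        done = True
                else:
                    collapsed.append((symbol, protein))
            rproteins = collapsed
    return rproteins


def predict_ligand(
    motif_id: str,
    genes: list[str],
    gene_map: GeneProteinMap,
    known: KnownLigandTable,
    dimers: list[tuple[str, str, str]] | None = None,
) -> LigandCall:
    """Apply the Only/Prior/Closest decision procedure to one operon.

    ``genes`` is the consensus operon's retained gene symbols in
    transcription order.  An operon without any r-protein gene yields a
    call with ``ligand`` and ``basis`` both ``None``.
    """
    if not genes:
        raise ValueError(f"motif {motif_id}: empty operon gene list")
    dimers = default_dimers() if dimers is None else dimers
    rproteins = _operon_proteins(genes, gene_map, dimers)
    if not rproteins:
        return LigandCall(
            motif_id=motif_id,
            ligand=None,
            basis=None,
            evidence=[(s, "non-ribosomal") for s in genes],
        )
    distinct = []
    for _, protein in rproteins:
        if protein not in distinct:
            distinct.append(protein)

    if len(distinct) == 1:
        symbols = [s for s, _ in rproteins]
        return LigandCall(
            motif_id=motif_id,
            ligand=distinct[0],
            basis="Only",
            evidence=[(s, "sole regulated r-protein") for s in symbols],
        )

    for provenance in ("literature", "this-run"):
        hit = known.hits(distinct, provenance)
        if len(hit) == 1:
            ligand = next(iter(hit))
            symbols = [s for s, p in rproteins if p == ligand]
            return LigandCall(
                motif_id=motif_id,
                ligand=ligand,
                basis="Prior",
                evidence=[(s, f"established ligand ({provenance})") for s in symbols],
                from_this_run=(provenance == "this-run"),
            )
        if hit:
            break  # >1 literature hits: ambiguous, fall through to Closest

    symbol, ligand = rproteins[0]
    return LigandCall(
        motif_id=motif_id,
        ligand=ligand,
        basis="Closest",
        evidence=[(symbol, "first r-protein gene downstream")],
    )


def two_pass_inference(
    operons: dict[str, list[str]],
    gene_map: GeneProteinMap,
    known_literature: KnownLigandTable,
    dimers: list[tuple[str, str, str]] | None = None,
    overrides: dict[str, dict[str, str]] | None = None,
) -> dict[str, LigandCall]:
    """Resolve a whole batch of motifs, feeding ``Only`` calls forward.

    Pass 1 resolves every motif against the literature table alone;
    ligands of ``Only`` calls are then added with provenance
    ``this-run`` and the motifs not resolved as ``Only`` are
    re-evaluated against the augmented table.  The result is
    deterministic and independent of the input ordering of ``operons``.

    ``overrides`` optionally maps motif_id → {gene symbol → r-protein}
    for per-motif corrections of the gene→protein map.  Per-motif
    failures (e.g. empty operons) are recorded as calls with a
    ``None`` basis rather than aborting the batch.
    """
    overrides = overrides or {}

    def map_for(motif_id: str) -> GeneProteinMap:
        if motif_id in overrides:
            return gene_map.with_overrides(overrides[motif_id])
        return gene_map

    calls: dict[str, LigandCall] = {}
    working = known_literature.copy()
    for motif_id in sorted(operons):
        try:
            calls[motif_id] = predict_ligand(
                motif_id, operons[motif_id], map_for(motif_id), working, dimers
            )
        except ValueError as exc:
            logger.warning("motif %s: %s", motif_id, exc)
            calls[motif_id] = LigandCall(
                motif_id=motif_id,
                ligand=None,
                basis=None,
                evidence=[("", str(exc))],
            )
    for call in calls.values():
        if call.basis == "Only" and call.ligand is not None:
            working.add(call.ligand, provenance="this-run")
    for motif_id in sorted(operons):
        if calls[motif_id].basis != "Only":
            try:
                calls[motif_id] = predict_ligand(
                    motif_id, operons[motif_id], map_for(motif_id), working, dimers
                )
            except ValueError:
                pass  # keep the pass-1 error record
    return calls


def default_gene_protein_map() -> GeneProteinMap:
    """Packaged gene symbol → r-protein table (editable TSV)."""
    return GeneProteinMap.from_tsv(_DATA_DIR / "gene_protein_map.tsv")


def _ligand_config() -> dict:
    with open(_DATA_DIR / "ligand_config.yaml") as fh:
        return yaml.safe_load(fh)


def default_known_ligands() -> KnownLigandTable:
    """Packaged literature table of established r-leader ligands."""
    return KnownLigandTable.from_names(_ligand_config()["known_ligands"])


def default_dimers() -> list[tuple[str, str, str]]:
    """Packaged dimer declarations, e.g. (S6, S18) → joint ligand S6:S18."""
    return [tuple(d) for d in _ligand_config()["dimers"]]
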