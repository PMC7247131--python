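"""Packaged reference set of candidate r-leader motifs.

The package ships a curated table of 20 novel candidate r-leaders
(ligand, ligand basis, regulated genes, lineage, rating, rRNA-similarity
flag).  :func:`replay_ligand_inference` re-runs the two-pass
Only/Prior/Closest procedure on the table's operon gene lists with the
packaged literature known-ligand table and compares the computed calls
against the curated ligand and basis columns — the package's primary
end-to-end validation surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .ligand_inference import (
    LigandCall,
    default_gene_protein_map,
    default_known_ligands,
    two_pass_inference,
)

__all__ = [
    "load_reference_motifs",
    "replay_ligand_inference",
    "reference_counts",
    "relative_increase_pct",
    "ReplayResult",
    "N_PRIOR_RLEADERS",
]

#: Number of r-leader types validated or predicted before this screen.
N_PRIOR_RLEADERS = 35

_TABLE = Path(__file__).parent / "data" / "reference_motifs.tsv"


def load_reference_motifs() -> pd.DataFrame:
    """Load the packaged reference motif table as a DataFrame.

    List-valued columns (``regulated_genes``, ``often_extended``) are
    split into Python lists; ``overrides`` becomes a symbol → protein
    dict; flag columns become booleans.
    """
    df = pd.read_csv(_TABLE, sep="\t", comment="#", dtype=str)
    df["regulated_genes"] = df["regulated_genes"].map(lambda s: s.split(","))
    df["often_extended"] = df["often_extended"].map(
        lambda s: [] if pd.isna(s) else s.split(",")
    )
    for flag in ("at_sign", "rrna_similarity", "extendable"):
        df[flag] = df[flag].map(lambda v: (not pd.isna(v)) and v == "1")

    def parse_overrides(s):
        if pd.isna(s) or not s:
            return {}
        return dict(item.split("=", 1) for item in s.split(","))

    df["overrides"] = df["overrides"].map(parse_overrides)
    return df


@dataclass
class ReplayResult:
    """Outcome of re-deriving the reference table's ligand columns."""

    calls: dict[str, LigandCall]
    table: pd.DataFrame
    mismatches: list[str]

    @property
    def all_match(self) -> bool:
        return not self.mismatches


def replay_ligand_inference(table: pd.DataFrame | None = None) -> ReplayResult:
    """Recompute ligand and basis for every reference motif.

    Runs :func:`~rleader.ligand_inference.two_pass_inference` on the
    reference operon gene lists with the packaged gene→protein map and
    literature known-ligand table, then diffs the computed (ligand,
    basis) against the curated columns.
    """
    table = load_reference_motifs() if table is None else table
    operons = dict(zip(table["motif_id"], table["regulated_genes"]))
    overrides = {
        m: o for m, o in zip(table["motif_id"], table["overrides"]) if o
    }
    calls = two_pass_inference(
        operons,
        default_gene_protein_map(),
        default_known_ligands(),
        overrides=overrides,
    )
    mismatches = []
    for _, row in table.iterrows():
        call = calls[row["motif_id"]]
        if call.ligand != row["ligand"] or call.basis != row["basis"]:
            mismatches.append(
                f"{row['motif_id']}: computed {call.ligand}/{call.basis}, "
                f"curated {row['ligand']}/{row['basis']}"
            )
    return ReplayResult(calls=calls, table=table, mismatches=mismatches)


def reference_counts(result: ReplayResult | None = None) -> dict[str, float]:
    """Summary counts over the reference set, from recomputed calls.

    Keys: total motifs, calls per basis, single-gene ``Only`` calls,
    multi-r-protein motifs, L31 motifs, archaeal motifs, and the
    percentage of motifs flagged as plausibly resembling the ligand's
    rRNA binding site.
    """
    result = replay_ligand_inference() if result is None else result
    table = result.table
    calls = result.calls
    basis = pd.Series({m: c.basis for m, c in calls.items()})
    n_genes = {m: len(g) for m, g in zip(table["motif_id"], table["regulated_genes"])}
    counts = {
        "n_motifs": len(table),
        "n_only": int((basis == "Only").sum()),
        "n_prior": int((basis == "Prior").sum()),
        "n_closest": int((basis == "Closest").sum()),
        "n_only_single_gene": sum(
            1 for m, c in calls.items() if c.basis == "Only" and n_genes[m] == 1
        ),
        "n_l31": int(sum(c.ligand == "L31" for c in calls.values())),
        "n_archaeal": int((table["domain"] == "archaea").sum()),
        "pct_rrna_similarity": float(100.0 * table["rrna_similarity"].mean()),
    }
    counts["n_multi_rgene"] = counts["n_motifs"] - counts["n_only_single_gene"] - sum(
        1
        for m, c in calls.items()
        if c.basis == "Only" and n_genes[m] > 1
    )
    return counts


def relative_increase_pct(n_new: int, n_prior: int = N_PRIOR_RLEADERS) -> float:
    """Percentage growth of the known r-leader catalogue: 100·new/prior."""
    if n_prior <= 0:
        raise ValueError("n_prior must be positive")
    return 100.0 * n_new / n_prior
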