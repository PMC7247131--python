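"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rleader.stockholm import StructuredAlignment


def make_pair_alignment(pair_contents: list[str], structure: str = "<.>") -> StructuredAlignment:
    """Alignment whose columns 0 and 2 hold the given 2-char pair contents.

    ``pair_contents`` like ["GC", "AU", "-U"]; column 1 is a constant A.
    """
    records = [
        (f"seq{i}", f"{duo[0]}A{duo[1]}") for i, duo in enumerate(pair_contents)
    ]
    return StructuredAlignment(records=records, consensus_structure=structure)


def random_iid_alignment(
    n_sequences: int, n_columns: int, rng: np.random.Generator
) -> StructuredAlignment:
    """Alignment of iid uniform ACGU columns (no association anywhere)."""
    bases = np.array(list("ACGU"))
    mat = bases[rng.integers(0, 4, size=(n_sequences, n_columns))]
    records = [(f"seq{i}", "".join(row)) for i, row in enumerate(mat)]
    return StructuredAlignment(
        records=records, consensus_structure="." * n_columns
    )


@pytest.fixture
def pair_alignment_builder():
    return make_pair_alignment


@pytest.fixture
def iid_alignment_builder():
    return random_iid_alignment
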