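"""Base-pair covariation analysis of structure-annotated alignments.

Compensatory double substitutions that preserve Watson-Crick/wobble
pairing are the classic evidence that an alignment encodes a conserved
RNA secondary structure.  This module evaluates each annotated pair of
columns in two complementary ways:

* a simple combinatorial covariation rule (the rule used by the R2R
  drawing package): a pair column "covaries" when at least two observed
  canonical pair types differ at both positions and fewer than 10% of
  the sequences carry a non-canonical pair;

* a statistical association test: the G statistic (log-likelihood-ratio
  chi-square) on the joint dinucleotide table of the two columns, with
  a permutation null obtained by shuffling each column independently
  across sequences.  The null preserves per-column base composition but
  destroys the pairing association.  It is *not* phylogenetically
  corrected — shared ancestry inflates apparent covariation, so
  p-values here are optimistic compared to a phylogeny-aware method
  such as R-scape and should be read as a screening signal only.

Per-motif significance is controlled with Benjamini-Hochberg across the
motif's annotated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .stockholm import PairTable, StructuredAlignment

__all__ = [
    "PairColumnStats",
    "MotifCovariationSummary",
    "CANONICAL_PAIRS",
    "classify_pair",
    "r2r_rule",
    "pair_association_score",
    "permutation_test",
    "summarize_motif",
    "UndefinedScoreError",
]

#: Watson-Crick and G-U wobble pair types (RNA alphabet; T is read as U).
CANONICAL_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")

_GAP_CHARS = set("-.~_")


class UndefinedScoreError(ValueError):
    """Association score requested for <2 ungapped sequence pairs."""


@dataclass
class PairColumnStats:
    """Classification and association statistics for one pair column."""

    pair: tuple[int, int]
    n_sequences: int
    canonical_counts: dict[str, int]
    n_noncanonical: int
    n_gapped: int
    covarying_variant_count: int
    r2r_covarying: bool = False
    score: float | None = None
    p_value: float | None = None
    p_adjusted: float | None = None

    @property
    def noncanonical_fraction(self) -> float:
        return self.n_noncanonical / self.n_sequences


@dataclass
class MotifCovariationSummary:
    """Motif-level roll-up of per-pair covariation evidence.

    ``rating`` is "Y" (likely a structured RNA) when the motif shows at
    least one significant pair after FDR control *and* at least two
    pairs passing the combinatorial rule; otherwise "?" (borderline).
    Both thresholds are configurable in :func:`summarize_motif`.
    """

    n_pairs: int
    n_r2r_covarying: int
    n_significant: int
    rating: str
    pair_stats: list[PairColumnStats] = field(default_factory=list)


def _normalize(residue: str) -> str:
    r = residue.upper()
    return "U" if r == "T" else r


def _pair_strings(alignment: StructuredAlignment, pair: tuple[int, int]):
    i, j = pair
    length = alignment.alignment_length
    if not (0 <= i < j < length):
        raise IndexError(f"pair columns {pair} out of range for length {length}")
    for _, seq in alignment.records:
        yield seq[i], seq[j]


def classify_pair(
    alignment: StructuredAlignment, pair: tuple[int, int]
) -> PairColumnStats:
    """Classify every sequence at a pair of columns.

    Each sequence is counted exactly once: as a specific canonical pair
    type (AU/UA/GC/CG/GU/UG, with T≡U and case ignored), as
    non-canonical, or as gapped (a gap character in either column).

    ``covarying_variant_count`` counts observed canonical types for
    which some *other* observed canonical type differs at both columns
    (GC vs AU: both differ; GC vs GU: only the 3' position differs).
    """
    canonical: dict[str, int] = {}
    n_noncanonical = 0
    n_gapped = 0
    for a, b in _pair_strings(alignment, pair):
        if a in _GAP_CHARS or b in _GAP_CHARS:
            n_gapped += 1
            continue
        duo = _normalize(a) + _normalize(b)
        if duo in CANONICAL_PAIRS:
            canonical[duo] = canonical.get(duo, 0) + 1
        else:
            n_noncanonical += 1
    variants = [
        t
        for t in canonical
        if any(s[0] != t[0] and s[1] != t[1] for s in canonical if s != t)
    ]
    return PairColumnStats(
        pair=pair,
        n_sequences=len(alignment),
        canonical_counts=canonical,
        n_noncanonical=n_noncanonical,
        n_gapped=n_gapped,
        covarying_variant_count=len(variants),
    )


def r2r_rule(
    stats: PairColumnStats,
    min_variants: int = 2,
    max_noncanonical_fraction: float = 0.10,
) -> bool:
    """Combinatorial covariation call for one pair column.

    True iff at least ``min_variants`` observed canonical pair types
    mutually differ at both positions and *fewer than*
    ``max_noncanonical_fraction`` of the sequences are non-canonical
    (strict inequality; 10% exactly fails).  The denominator is all
    sequences, including gapped ones.
    """
    return (
        stats.covarying_variant_count >= min_variants
        and stats.noncanonical_fraction < max_noncanonical_fraction
    )


def _column_codes(
    alignment: StructuredAlignment, pair: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Integer-coded residues at both columns for ungapped sequences."""
    xs: list[str] = []
    ys: list[str] = []
    for a, b in _pair_strings(alignment, pair):
        if a in _GAP_CHARS or b in _GAP_CHARS:
            continue
        xs.append(_normalize(a))
        ys.append(_normalize(b))
    ux = {c: k for k, c in enumerate(sorted(set(xs)))}
    uy = {c: k for k, c in enumerate(sorted(set(ys)))}
    x = np.array([ux[c] for c in xs], dtype=np.intp)
    y = np.array([uy[c] for c in ys], dtype=np.intp)
    return x, y


def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """G = 2 Σ O ln(O/E) on the joint table of two coded columns."""
    n = x.size
    kx = int(x.max()) + 1
    ky = int(y.max()) + 1
    obs = np.bincount(x * ky + y, minlength=kx * ky).reshape(kx, ky).astype(float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / n
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))


def pair_association_score(
    alignment: StructuredAlignment, pair: tuple[int, int]
) -> float:
    """G statistic measuring association between two alignment columns.

    Sequences gapped at either column are excluded.  Returns 0 when
    either column is constant (no variation, hence no association).

    Raises
    ------
    UndefinedScoreError
        If fewer than 2 sequences are ungapped at both columns.
    """
    x, y = _column_codes(alignment, pair)
    if x.size < 2:
        raise UndefinedScoreError(
            f"pair {pair}: fewer than 2 ungapped sequences ({x.size})"
        )
    if x.max() == 0 or y.max() == 0:
        return 0.0
    return _g_statistic(x, y)


def permutation_test(
    alignment: StructuredAlignment,
    pair: tuple[int, int],
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for the column-association G statistic.

    The null is generated by independently permuting the residues of
    each column across sequences, preserving the marginal base
    composition while destroying any pairing association.  Shared
    phylogeny is *not* modelled, so covariation driven purely by
    related sequences can look significant.  The add-one estimator
    ``p = (1 + #{null >= observed}) / (1 + N)`` is used, so p is never 0.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x, y = _column_codes(alignment, pair)
    if x.size < 2:
        raise UndefinedScoreError(
            f"pair {pair}: fewer than 2 ungapped sequences ({x.size})"
        )
    if x.max() == 0 or y.max() == 0:
        observed = 0.0
    else:
        observed = _g_statistic(x, y)
    exceed = 0
    # Shuffle from a sorted copy so the p-value depends only on the
    # multiset of residues, not on the row order of the alignment.
    xp = np.sort(x)
    yp = np.sort(y)
    for _ in range(n_permutations):
        rng.shuffle(xp)
        rng.shuffle(yp)
        if xp.max() == 0 or yp.max() == 0:
            null = 0.0
        else:
            null = _g_statistic(xp, yp)
        if null >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_permutations)


def summarize_motif(
    alignment: StructuredAlignment,
    pair_table: PairTable,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    min_significant: int = 1,
    min_r2r: int = 2,
) -> MotifCovariationSummary:
    """Evaluate all annotated pairs of one motif and rate the motif.

    Per-pair permutation p-values are adjusted with Benjamini-Hochberg
    across the motif's pairs; ``n_significant`` counts rejections at
    level ``alpha``.  Rating is "Y" iff ``n_significant >=
    min_significant`` and the combinatorial rule fires on at least
    ``min_r2r`` pairs, else "?".
    """
    pairs = list(pair_table.pairs)
    if not pairs:
        return MotifCovariationSummary(
            n_pairs=0, n_r2r_covarying=0, n_significant=0, rating="?"
        )
    rng = np.random.default_rng(seed)
    stats: list[PairColumnStats] = []
    for pair in pairs:
        st = classify_pair(alignment, pair)
        st.r2r_covarying = r2r_rule(st)
        try:
            st.score = pair_association_score(alignment, pair)
            st.p_value = permutation_test(
                alignment, pair, n_permutations=n_permutations, seed=rng
            )
        except UndefinedScoreError:
            st.score = None
            st.p_value = None
        stats.append(st)
    pvals = [st.p_value for st in stats if st.p_value is not None]
    n_significant = 0
    if pvals:
        rejected, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        it = iter(zip(rejected, p_adj))
        for st in stats:
            if st.p_value is not None:
                rej, adj = next(it)
                st.p_adjusted = float(adj)
                n_significant += bool(rej)
    n_r2r = sum(st.r2r_covarying for st in stats)
    rating = "Y" if (n_significant >= min_significant and n_r2r >= min_r2r) else "?"
    return MotifCovariationSummary(
        n_pairs=len(pairs),
        n_r2r_covarying=n_r2r,
        n_significant=n_significant,
        rating=rating,
        pair_stats=stats,
    )
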