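"""Downstream gene chaining and consensus-operon construction."""

import pytest

from rleader.gene_context import (
    UNUSABLE,
    ContigNotFoundError,
    GeneRecord,
    MotifOccurrence,
    consensus_operon,
    downstream_chain,
)


def gene(start, end, strand="+", symbol="gene", contig="ctg"):
    return GeneRecord(
        contig=contig, start=start, end=end, strand=strand, symbol=symbol
    )


def occ(start, end, strand="+", contig="ctg", contig_length=20000):
    return MotifOccurrence(
        motif_id="m",
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        contig_length=contig_length,
    )


class TestDownstreamChain:
    def test_large_gap_breaks_chain(self):
        genes = [
            gene(300, 900, symbol="a"),
            gene(1000, 1600, symbol="b"),
            gene(2300, 2900, symbol="c"),  # 700 nt after b
        ]
        chain = downstream_chain(occ(100, 180), genes)
        assert [g.symbol for g in chain] == ["a", "b"]

    @pytest.mark.parametrize("gap, expected", [(500, ["a", "b"]), (501, ["a"])])
    def test_gap_boundary_at_500(self, gap, expected):
        genes = [gene(300, 900, symbol="a"), gene(900 + gap, 1500 + gap, symbol="b")]
        chain = downstream_chain(occ(100, 180), genes)
        assert [g.symbol for g in chain] == expected

    @pytest.mark.parametrize(
        "contig_length, usable", [(8180, True), (8179, False), (5000, False)]
    )
    def test_downstream_sequence_boundary_at_8kb(self, contig_length, usable):
        genes = [gene(300, 900, symbol="a")]
        chain = downstream_chain(
            occ(100, 180, contig_length=contig_length), genes
        )
        if usable:
            assert chain is not UNUSABLE
        else:
            assert chain is UNUSABLE

    def test_strand_switch_breaks_chain(self):
        genes = [
            gene(300, 900, symbol="a"),
            gene(1000, 1600, strand="-", symbol="x"),
            gene(1700, 2300, symbol="b"),
        ]
        chain = downstream_chain(occ(100, 180), genes)
        assert [g.symbol for g in chain] == ["a"]

    def test_opposite_strand_first_gene_gives_empty_chain(self):
        genes = [gene(300, 900, strand="-", symbol="x")]
        assert downstream_chain(occ(100, 180), genes) == []

    def test_overlapping_same_strand_genes_chain_with_gap_zero(self):
        genes = [gene(300, 900, symbol="a"), gene(880, 1400, symbol="b")]
        chain = downstream_chain(occ(100, 180), genes)
        assert [g.symbol for g in chain] == ["a", "b"]

    def test_gene_overlapping_motif_is_skipped(self):
        genes = [gene(150, 400, symbol="in_motif"), gene(450, 900, symbol="a")]
        chain = downstream_chain(occ(100, 180), genes)
        assert [g.symbol for g in chain] == ["a"]

    def test_missing_contig_raises(self):
        with pytest.raises(ContigNotFoundError):
            downstream_chain(occ(100, 180, contig="nope"), [gene(1, 2)])

    def _reflect(self, genes, occurrence, total):
        """Coordinate reflection oracle: mirror the locus, flip strands."""
        flip = {"+": "-", "-": "+"}
        r_genes = [
            GeneRecord(
                contig=g.contig,
                start=total - g.end,
                end=total - g.start,
                strand=flip[g.strand],
                symbol=g.symbol,
            )
            for g in genes
        ]
        r_occ = MotifOccurrence(
            motif_id=occurrence.motif_id,
            contig=occurrence.contig,
            start=total - occurrence.end,
            end=total - occurrence.start,
            strand=flip[occurrence.strand],
            contig_length=total,
        )
        return r_genes, r_occ

    @pytest.mark.parametrize("seed", range(10))
    def test_strand_reflection_symmetry(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        total = 20000
        pos = 400
        genes = []
        for k in range(6):
            pos += int(rng.integers(0, 900))
            length = int(rng.integers(150, 1200))
            strand = "+" if rng.random() < 0.8 else "-"
            genes.append(gene(pos, pos + length, strand=strand, symbol=f"g{k}"))
            pos += length
        forward = downstream_chain(occ(100, 180), genes)
        r_genes, r_occ = self._reflect(genes, occ(100, 180), total)
        mirrored = downstream_chain(r_occ, r_genes)
        assert [g.symbol for g in forward] == [g.symbol for g in mirrored]


class TestConsensusOperon:
    def test_unanimous_chains(self):
        chains = [["rpsD", "rpoA", "rplQ"]] * 10
        op = consensus_operon("m", chains)
        assert op.genes == ["rpsD", "rpoA", "rplQ"]
        assert all(op.support[s] == 1.0 for s in op.genes)

    def test_minority_extension_reported_separately(self):
        chains = [["rplM", "rpsI"]] * 5 + [["rplM", "rpsI", "rpsB"]] * 4 + [[]]
        op = consensus_operon("m", chains)
        assert op.genes == ["rplM", "rpsI"]
        assert op.often_extended == ["rpsB"]
        assert op.support["rplM"] == pytest.approx(0.9)

    def test_modal_rank_ordering_brute_force(self):
        # b most often at rank 1, c most often at rank 2, despite one swap
        chains = [["a", "b", "c"], ["a", "b", "c"], ["a", "c", "b"], ["a", "b", "c"]]
        op = consensus_operon("m", chains, min_support=0.5)
        assert op.genes == ["a", "b", "c"]

    def test_no_usable_chains_flagged(self):
        op = consensus_operon("m", [])
        assert op.genes == []
        assert op.note == "no usable occurrences"

    def test_monotone_in_min_support(self):
        chains = [["a", "b"], ["a"], ["a", "b", "c"], ["a", "b"]]
        sizes = [
            len(consensus_operon("m", chains, min_support=t).genes)
            for t in (0.25, 0.5, 0.75, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_output_subset_of_inputs(self):
        chains = [["a", "b"], ["b", "c"], ["c", "d"]]
        op = consensus_operon("m", chains, min_support=0.3)
        assert set(op.genes) <= {"a", "b", "c", "d"}
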