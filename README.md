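# rleader

Screening pipeline for candidate **ribosomal leaders (r-leaders)** —
structured RNA elements in the 5′ UTRs of mRNAs encoding ribosomal
proteins (r-proteins). When one of the encoded r-proteins is in excess,
it binds the leader in its own mRNA and represses the downstream
operon, closing a feedback loop on ribosome assembly. The package is
aimed at comparative-genomics work: given structure-annotated multiple
sequence alignments of conserved RNA motifs and the genomic context of
their homologs, it decides which motifs behave like r-leaders and which
r-protein each one most likely binds.

## What it computes

**Covariation evaluation.** For each base pair (i, j) annotated in the
alignment's consensus structure (`#=GC SS_cons`, WUSS notation), every
sequence is classified as a canonical pair type (AU, UA, GC, CG, GU,
UG), non-canonical, or gapped. Two detectors run per pair:

* the combinatorial rule used by the R2R drawing package: the pair
  *covaries* when ≥ 2 observed canonical types differ at **both**
  positions (GC↔AU counts, GC↔GU does not) and fewer than 10 % of
  sequences are non-canonical;
* a permutation test on the G statistic
  `G = 2 Σ O_ab ln(O_ab / E_ab)` over the joint dinucleotide table of
  the two columns, with the null obtained by independently shuffling
  each column across sequences. The null preserves base composition
  but is **not** phylogenetically corrected, so p-values are a
  screening signal, not a substitute for a phylogeny-aware method such
  as R-scape. Per-motif FDR control is Benjamini–Hochberg.

**Operon inference.** Around each genomic occurrence of a motif, genes
on the same strand are chained downstream while consecutive intergenic
gaps are ≤ 500 nt; occurrences with < 8 kb of sequence downstream
(truncated contigs) are discarded as unusable. Chains from all usable
occurrences are merged into a consensus operon (gene kept at support
≥ 0.75, minority genes reported as "often extended").

**Ligand prediction (Only / Prior / Closest).** The ligand is assumed
to be encoded by a regulated gene. If the operon encodes exactly one
distinct r-protein → that protein (**Only**). Otherwise, if exactly
one encoded r-protein is an already-established r-leader ligand →
that protein (**Prior**); ligands established by Only calls within the
same run form a second, lower-priority tier. Otherwise the first
r-protein gene downstream (**Closest**). Obligate dimers (S6:S18)
collapse to a joint ligand name.

**TSS and novelty checks.** An occurrence is consistent with mapped
transcription start sites when a same-strand TSS lies upstream of the
motif with no intervening gene start; motifs whose homologs overlap
previously published RNAs (≥ 50 % of the shorter interval, same
strand) are eliminated as not novel.

A synthetic-data module generates structure-conserving alignments
(compensatory substitutions on a Yule tree, tunable non-canonical
noise) and genome/TSS layouts so the whole pipeline is testable without
external downloads.

## Worked example

The package ships a curated reference set of 20 candidate r-leaders
(operon gene lists, lineages, covariation ratings). Re-deriving the
ligand calls:

```bash
$ rleader ligand
motif_id	ligand	basis	this_run
L2-Alphaproteobacteria	L2	Closest
L4-Archaeoglobi	L4	Prior
L13-Bacteroidia	L13	Prior
eL15-Euryarchaeota	eL15	Only
...
L31-Corynebacteriaceae	L31	Prior	@
...
S16-Flavobacteria	S16	Only
```

Reading the output: the L2 motif regulates *rplB, rpsS, rplV, rpsC*,
none an established ligand, so the immediately downstream r-protein
(L2) is the best guess (`Closest`). The Corynebacteriaceae motif
regulates *rpmE, rpmF* (L31, L32); L31 is not a literature ligand but
was established by the four single-gene *rpmE* motifs in the same run,
hence `Prior` with the `@` (this-run) flag. Across the set: 8 motifs
resolve from a single regulated r-protein gene, 10 via a unique prior
ligand, 1 by the closest-gene fallback; 5 motifs point to L31, 4 are
archaeal, and 25 % carry plausible similarity to the ligand's rRNA
binding site.

A full synthetic screen (simulate an alignment, lay out a genome, run
all stages):

```bash
rleader simulate "<<<<....>>>>" --n-sequences 24 --seed 2 -o demo.sto
rleader screen config.yaml -o out/     # see tests/test_pipeline.py for a config
```

The consolidated report has one row per motif: covariation counts and
rating (Y/?), consensus operon with support, ligand call, TSS tallies,
novelty verdict and the final candidate label.

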