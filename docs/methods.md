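# Methods

## Scope and model

The package screens conserved RNA motifs — each given as a multiple
sequence alignment with a consensus secondary structure — for the
hallmarks of ribosomal leaders: a covariation-supported structure,
consistent placement upstream of r-protein operons, a plausible
r-protein ligand, agreement with transcription start sites (TSS), and
novelty relative to published RNAs. It does not discover motifs de
novo (a CMfinder-class job), build covariance models, or judge
structural mimicry of rRNA binding sites; those remain upstream or
manual steps. Coordinates are 0-based half-open throughout; GFF3
boundaries are converted on read (via pyranges).

## Covariation

Each sequence at an annotated pair of columns is classified exactly
once: canonical (AU/UA/GC/CG/GU/UG; T≡U, case ignored), non-canonical,
or gapped (gap character in either column). The combinatorial rule
calls a pair covarying when at least two observed canonical *types*
differ at both positions and strictly fewer than 10 % of sequences are
non-canonical. Two deliberate readings of that rule:

* the denominator of the 10 % criterion is **all** sequences — a
  half-gapped sequence is neither canonical nor non-canonical but
  still counts in the denominator, the literal reading of "fewer than
  10 % of the sequences";
* "differ at both positions" is evaluated over distinct canonical pair
  types, not over pairs of sequences — the only reading under which a
  pure GC→GU wobble shift is not covariation, consistent with standard
  usage.

Statistical support is a permutation test on the G statistic (the
log-likelihood-ratio chi-square) of the two columns' joint
dinucleotide table, computed on sequences ungapped at both columns and
defined as 0 when either column is constant. The null shuffles each
column independently (add-one p-value estimator, `p = (1+k)/(1+N)`, so
p is never 0 and constant columns give p = 1). The shuffle starts
from a sorted copy of the column so the p-value is invariant to the
row order of the alignment. **Limitation:** this null preserves base
composition but not phylogeny; clades of near-identical sequences can
make a pair look significant with no independent substitution events.
A phylogeny-aware test (R-scape's class) is strictly stronger; our
p-values are a screening signal. Per motif, Benjamini–Hochberg
controls the FDR across annotated pairs (default α = 0.05,
1000 permutations). A motif is rated "Y" when ≥ 1 pair is significant
after correction and ≥ 2 pairs pass the combinatorial rule, else "?";
both thresholds are configurable and deliberately modest, since the
rating feeds a candidate label rather than a final claim.

## Operon inference

Genes are chained strictly downstream of the motif in transcription
direction (genes overlapping the motif are skipped — the leader sits
in the 5′ UTR), while each intergenic gap is ≤ 500 nt; an
opposite-strand gene or a larger gap ends the chain. Overlapping
same-strand genes chain with gap 0 (operonic overlap from
translational coupling is common). Occurrences with < 8000 nt of
sequence between motif end and contig end are unusable; the distance
is measured to the contig end regardless of gene content, since the
rule guards against truncated contigs. The consensus keeps a gene at
support ≥ 0.75 of usable chains (no published number exists for
"consistently located"; 0.75 is a configurable default), orders genes
by modal rank (ties: median rank, then symbol) and reports genes at
support in [0.25, 0.75) as "often extended".

## Ligand inference

The ligand is assumed to be encoded by a regulated gene. With the
operon's r-proteins collected in transcription order (declared dimers
such as S6+S18 collapsing to one joint name first):

1. **Only** — exactly one distinct r-protein: it is the ligand.
   Non-ribosomal genes (e.g. *rimM*, *rpoA*) never block this case.
2. **Prior** — exactly one encoded r-protein is an established
   ligand. Matching is tiered: the literature table is consulted
   first; ligands established by Only calls of the same run
   ("this-run" provenance) are consulted only when the literature
   yields zero hits. The tiering matters: a run that itself
   establishes, say, L17 as a ligand must not disturb an operon in
   which S4 — a literature ligand — co-occurs with L17. Calls resolved
   through the this-run tier are flagged (`@`).
3. **Closest** — fallback to the first r-protein gene downstream
   (also used when several established ligands tie, which is
   genuinely ambiguous).

Batch inference is two-pass: pass 1 resolves everything against the
literature table; Only ligands are added with this-run provenance;
non-Only motifs are re-resolved. The result is independent of motif
input order. Confidence is ordinal only (Only > Prior > Closest) — no
probabilities are attached, because the decisive evidence (which gene
lists are complete, which prior table is current) is not modelled.

The packaged literature ligand table (L1, L4, L10, L13, L19, L20, L25,
S2, S4, S6:S18, S7, S8, S10, S15) is a best-effort transcription of
the published record and is user-replaceable; the packaged reference
motif set records one per-motif gene→protein override (its L20 row
lists *rpsT*, conventionally S20, yet assigns L20 — the override
reproduces the table as printed rather than guessing the intent).

## TSS consistency and novelty

An occurrence is *consistent* when some same-strand TSS lies upstream
of the motif with no annotated same-strand gene start strictly between
TSS and motif (the motif then sits in a 5′ leader of a transcript that
covers the gene); *inconsistent* when TSSes exist in the locus window
(default 2000 nt upstream of the first gene — an artifact default, as
published per-study matching criteria vary) but all fall inside the
motif or between motif and gene; *no-data* otherwise. Novelty is
coordinate overlap only: a motif is eliminated when any occurrence
overlaps a same-strand published RNA by ≥ 50 % of the shorter interval
(a tolerance for sloppy boundary annotation; pass a tiny fraction for
strict 1-nt elimination). Similarity-based redundancy judgments are
out of scope.

## Synthetic data

`simulate_alignment` draws a Yule topology (dendropy; branch lengths
rescaled to a root-to-tip depth in expected substitutions/site — the
simplest tunable-depth model, as no specific tree model is implied by
the problem), assigns random canonical types to paired columns and
random bases elsewhere, and evolves the sequence down the tree with
Poisson substitution events. A paired-column event is compensated —
both partners replaced by a different canonical type, an instantaneous
double substitution rather than a two-step rate model, which suffices
to produce the covariation signal the detectors consume — with
probability `compensatory_rate`; otherwise one partner drifts alone.
At the tips, each pair is independently forced non-canonical with
probability `noncanonical_noise`. Defaults: 24 sequences, depth 0.6,
compensatory rate 0.95, noise 0.02 — a moderately deep, mostly
structure-conserving alignment of the size typical for curated motif
seeds. The simulator has no indels, no base-composition bias, no
rate variation across sites and no alignment error, so passing tests
show detector calibration under a clean compensatory signal, not
performance on real alignments.

`generate_genome_fixture` realises declarative contig layouts (motif
placements, gene cascades with explicit intergenic gaps, TSS
positions) as GFF3/BED/TSV text, including the boundary cases the
operon rules hinge on (gap exactly 500 vs 501; 7999 vs 8000 nt of
downstream sequence).

## Validation surface and problem sizes

The packaged reference set of 20 candidate motifs is the end-to-end
check for ligand inference: the two-pass procedure reproduces all 20
curated (ligand, basis) pairs, giving 8 single-gene Only calls,
10 Prior calls among the 11 multi-r-gene motifs, and 1 Closest call;
5 L31 motifs; 4 archaeal motifs; 25 % of motifs flagged for rRNA
similarity; and a 20/35 ≈ 57 % growth of the known catalogue.
Statistical properties run at desk scale: permutation-test type-I
error is checked over 100 seeds × 25 independent column pairs of 30
sequences (199 permutations each) against α + 3 SE; detection of
planted compensatory pairs (≥ 3 observed canonical variants, default
2 % noise) over 100 simulator seeds at ≥ 95 %; simulator noise
recovery at 200 sequences within 3 binomial SE. These sizes were
chosen to give stable Monte-Carlo estimates at interactive runtimes.

## Known limitations

* The permutation null ignores phylogeny (see above) — the main
  statistical gap relative to the state of the art.
* Operon support is a per-gene frequency; "consistently located far
  away" has no distance statistic, so a gene at wildly varying
  distances but high frequency is still retained.
* The gene→protein map is table-driven; unknown symbols degrade to
  "other" with a warning rather than being classified from sequence.
* Ligand predictions inherit the decision procedure's blind spots: an
  RNA that regulates r-protein genes without binding any r-protein
  will still receive a ligand call.
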