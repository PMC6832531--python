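# Methods

## Problem setting

Venom-gland transcriptomes of pit vipers contain tandem arrays of paralogous
multi-exon toxin genes. Long cDNA reads span whole transcripts, so each read
is direct evidence for one isoform. The pipeline classifies such reads
against annotated gene models, names the splice events that distinguish each
isoform from the canonical ("original") transcript, re-derives the protein
consequence of each isoform, and aggregates variants per gene and family.
All stages operate on standard text formats (GFF3, FASTA, BED12, TSV).

## Coordinate model

Genomic intervals are 0-based half-open; GFF3 I/O converts to/from 1-based
inclusive. All splice logic runs on a *transcription axis*: the scaffold
coordinate for plus-strand genes, its mirror image for minus-strand genes,
so exon 1 is always leftmost and "downstream" always means "larger". This
makes event calling strand-symmetric by construction (verified by a
mirror-image property test). Exon indices are the gene's 5′→3′ transcription
order; optional sub-exons share index 1 with letters b, c, … and are not
part of the canonical transcript.

## Gene models and the GFF3 dialect

A gene model carries exons, the transcript-coordinate CDS of the original
transcript, domain blocks as exon ranges, motif patterns (uppercase amino
acids, `X` = any), catalytic residues with reference protein positions, and
the genomic positions of AATAAA polyA signals. These annotations ride as
attributes on the mRNA feature (`domain_blocks=`, `motifs=`, `catalytic=`,
`polyA=`, `cds_start=`, `cds_end=`), keeping one file authoritative; CDS
features are also emitted for standard browsers. Clusters are stored as
`##cluster` directives and otherwise re-derived by single-linkage grouping
of gene spans (default gap 50 kb — clusters in the data motivating this
package span tens of kilobases, and no explicit gap rule exists, so the
default is deliberately generous and configurable).

`derive_model` applies exon gain/loss events (the gene-family evolution
operator): losses drop the named exons and any domain blocks that reference
them, re-indexing the survivors; the parent's terminal exon survives unless
explicitly removed. Gains need genomic intervals that no annotation
provides, so new exons get deterministic synthetic intervals (120 nt,
placed in the 3′ flank or splitting the target intron); `derive_model` is a
structural operator — sequence-level validity is the synthetic-locus
builder's job, and the CDS coordinates are adjusted arithmetically and
clamped.

## Full-length filter

A read is full-length iff it has (a) a translation start and (b) a polyA
signal. The start is the model's canonical start Met when the chain covers
it. When the chain lacks the canonical-start *exon* entirely **and** begins
exactly at an annotated (sub-)exon boundary — the signature of an
alternative first exon or start-exon skip — the first ATG in the read is
accepted as a new start; a chain that merely starts inside an exon
(5′-truncated fragment) is rejected. The polyA check requires a terminal
tail of ≥ 10 A's with an AATAAA hexamer starting 10–46 nt upstream of the
tail. The tail/window geometry is a package decision (no published rule):
the generator places signals exactly 20 nt upstream of the cleavage point
and appends 30-nt tails, well inside the window.

## Splice-event vocabulary and calling rules

Deviations of an exon chain from its model are classified as:

| event | rule |
|---|---|
| `EXON_SKIP` | model exon uncovered, flanked by covered exons |
| `INTRON_RETENTION` | one block spans two consecutive exons across their intron |
| `PARTIAL_INTRON_RETENTION` | block extends ≥ 10 nt *into* an intron without reaching the next exon (side recorded: donor/acceptor) |
| `ALT_DONOR` / `ALT_ACCEPTOR` | exon boundary moved *into* the exon at an annotated junction |
| `ALT_FIRST_EXON` | first block off exon 1, or any sub-exon used |
| `ALT_POLYA` | terminal block ends > 8 nt from the model end; matched to the nearest annotated cleavage point |
| `NOVEL_EXON` | block overlapping no exon and attached to no intron edge |

The extension-vs-truncation asymmetry (extensions = partial retention,
truncations = alternative donor/acceptor) is a deliberate disambiguation:
the two descriptions otherwise overlap, and a ≥ 10 nt threshold separates
real extensions from alignment jitter. Junction matching is exact by
default (`junction_tol=0`; synthetic data is exact) with a configurable
tolerance for noisy alignments. Assignment requires ≥ 1 shared junction and
≥ 50% of the read's junctions matching; ties break by exonic overlap, then
lexicographic gene id. Chains overlapping two or more genes bypass
per-gene calling and go to chimera detection.

## ORF re-projection and protein consequences

Translation runs from the located start to the first in-frame stop
(standard genetic code, ATG starts only); the stop's transcript position is
mapped back through the chain to the genome and classified as
annotated-exon, retained-intron or downstream (3′-extension) sequence. The
frameshift flag is set when the chain changes the cumulative coding length
upstream of the stop by a non-multiple of 3. A per-read "first deviating
codon" is also recorded: catalytic residues downstream of it (or beyond the
protein, or in proteins from non-canonical starts) are reported *absent*;
aligned positions with a different residue are *substituted* (e.g. a
catalytic His→Arg). This prefix-alignment is intentionally conservative: a
variant that restores the reference frame after an internal in-frame
deletion is still scored absent downstream, because residue numbering can
no longer be trusted.

MP structural typing counts a domain block as covered only when every exon
in its range is present with exact boundaries, translated in the original
frame, and entirely upstream of the stop: P-III = MP + disintegrin +
Cys-rich; P-II = MP + disintegrin; P-I = MP only; an uncovered MP domain
makes the transcript non-functional (reported, not typed). P-IV requires
protein-complex evidence and is out of scope. This strict rule means a
variant with a *shortened* disintegrin exon types as P-I even though a
curator might call it P-II — exact-boundary coverage was preferred because
it is deterministic and monotone (moving the stop 5′ never increases the
type, a tested invariant).

## Variant collapsing and chimeras

The variant key is purely structural: exact junction chain + polyA-site
class (nearest annotated cleavage within ± 8 nt) + start class. Single
nucleotide (allelic) substitutions therefore never split a variant — an
allelic pair such as a Glu/Lys site in one svMP gene collapses to one
record, a documented divergence from curated catalogs that count such pairs
separately. Names are `gene-vN` with v1 the original when present, then
descending read support (ties: 5′ coordinate, then key hash). The catalog
reports both inclusive and "structural" counts (the latter ignoring
3′UTR-length-only distinctions).

Multi-gene chains are segmented at donor switches; a chimera is accepted
when its ≥ 2 donor genes belong to one cluster in strictly increasing
genomic order. Strict rank-adjacency is optional (off by default): observed
trans-spliced transcripts include donors that skip the middle gene of a
three-gene cluster, so membership + colinearity is the faithful rule.
Chimeric reads are cataloged separately and never counted into per-gene
variant totals; a conservation check enforces that per-gene variant
supports sum exactly to the assigned full-length reads.

## Synthetic data: what it emulates, and what it does not

Templates: MP-like 17/15/13-exon loci (signal 1, prepro 2–6, MP 7–12 with
the zinc motif placed wholly in exon 11, disintegrin 13–14, Cys-rich 15–16),
SP-like 6/8-exon loci (exon 1 untranslated, triad at positions 57/102/195,
242-aa protein), 6-exon VEGF-like and 4-exon PLA2-like/generic loci, with
2–3 AATAAA signals spaced 60 nt apart past the terminal exon. Three design
guarantees make ground truth computable rather than asserted: introns open
with GT plus a 12-nt block carrying stops in all three frames; every coding
exon after the first carries a 9-nt cassette encoding stops in both shifted
frames (ordinary residues in frame); the 3′UTR opens with the all-frame
stop block. Consequently any retention or frameshift terminates within a
few codons, deterministically. SP exon 5 carries an in-frame AAT-AAA
(Asn-Lys) near its 3′ end so that chimeras ending there still present a
polyA signal. The truth table's protein consequences are recomputed per
read by a direct positional scan of the planned blocks, independent of the
caller/ORF modules, and the test suite re-verifies them with a third,
set/list-based oracle.

Scenario bundles encode the described variant suites: an 18-variant MP
locus with sub-exons 1b–1e (original supported by 10 reads, variants by
1–4), a 15-exon MP suite, the 8-variant VEGF suite (four intron-3-retention
structures sharing one protein), two 3-gene SP clusters with six chimera
plans, a no-splicing control locus, and an 18-family simulation with events
injected only in MP/SP/VEGF. Read supports and sub-seeds are fixed
functions of the scenario seed; identical seeds give byte-identical output.

Not emulated: base-level sequencing error (an option deliberately left off
by default — all acceptance properties assume exact alignments), expression
levels calibrated to real FPKM, allelic variation, intron splice-site
motifs beyond GT/AG, and genuinely novel (unannotated) exonization. Passing
tests therefore demonstrate coordinate/classification correctness, not
robustness to alignment noise; the `junction_tol` knob exists for the
latter but is untuned.

## Numerical and tie-break choices

* polyA geometry: signal start → cleavage = 20 nt (generator), accepted
  window 10–46 nt (filter), site-class tolerance ± 8 nt (catalog).
* partial retention threshold 10 nt; smaller extensions are jitter.
* assignment: ≥ 1 shared junction and ≥ 50% of read junctions.
* variant naming ties: support desc → 5′ coordinate → MD5 of the key.
* degenerate inputs: empty GFF3 → empty lists; empty read → error; chains
  ending before the terminal exon are not given skip calls for the missing
  3′ exons (they cannot be distinguished from cleavage without a tail).

## Problem sizes

The test suite runs six scenario bundles (8–55 reads each, loci of 2–5 kb),
1000 random chain/model pairs against the set-algebra oracle, and 300 more
in the unit suite; the whole suite completes in a few seconds on one CPU.
These sizes were chosen to keep every truth table exhaustively checkable.

## Known limitations

* Assignment ignores reads whose chains match no model junction (reported
  as unassigned, mirroring reads that real catalogs drop as non-matching).
* The catalytic-residue prefix alignment cannot credit residues that
  survive downstream of an in-frame structural change.
* Chimera detection requires annotated clusters; chimeras across
  un-clustered genes are rejected by design.
* `derive_model` gains invent exon intervals; they are placeholders for
  structure-level reasoning, not sequence-validated exons.
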