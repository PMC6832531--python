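# venomiso

Isoform classification for venom-gland long-read transcriptomes.

Snake-venom protein families — metalloproteinases (svMP), serine proteases
(svSP), vascular endothelial growth factors (svVEGF), phospholipases A2
(svPLA2) and others — are encoded by tandem arrays of paralogous multi-exon
genes. Full-length cDNA reads (one molecule per read, 5′ cap to polyA tail)
make it possible to catalog, per gene, every transcript variant produced by
alternative splicing, and even trans-spliced chimeras joining exons of
neighboring genes in a cluster. `venomiso` implements that analysis as a
tested, reusable pipeline:

* **gene models** (`venomiso.models`) — annotated multi-exon genes with
  lettered sub-exons, domain blocks (signal / prepro / MP / disintegrin /
  Cys-rich), amino-acid motifs (e.g. the zinc-binding `HEXGHNLGXXHD` of
  exon 11), catalytic residues (His57/Asp102/Ser195) and AATAAA polyA
  signals; a documented GFF3 dialect with exact round trips; single-linkage
  gene clustering; and `derive_model`, an exon gain/loss operator for
  gene-family evolution (e.g. the two-round deletion 17 → 15 → 13 exons of
  the svMP family, or the 6 → 8-exon 3′UTR gain of one svSP paralog).
* **read filter** (`venomiso.readfilter`) — full-length = start Met codon
  **and** AATAAA signal upstream of a polyA tail; alternative-start variants
  (e.g. exon-2 skip with a new start in exon 3) still pass, 5′-truncated
  fragments do not.
* **splice caller** (`venomiso.splicing`) — assigns each exon chain (BED12)
  to the gene sharing the most exact splice junctions, then classifies every
  deviation: exon skipping, full/partial intron retention, alternative
  donor/acceptor, alternative first exon (sub-exons 1b–1e), alternative
  polyadenylation, novel exons.
* **ORF re-projection** (`venomiso.orf`) — translates each variant from its
  (re-)located start, maps the stop codon back to exon/retained-intron
  coordinates, flags frameshifts, locates motifs, scores catalytic residues
  (present / absent / substituted) and assigns the MP structural class:
  P-I (MP domain only), P-II (+disintegrin), P-III (+Cys-rich).
* **catalog** (`venomiso.catalog`) — collapses reads into named variants
  (structural key: junction chain + polyA site + start class; allelic SNVs
  never split a variant), detects trans-spliced chimeras over clusters, and
  summarizes per gene and per family.
* **synthetic data** (`venomiso.simulate`) — seeded generator for loci,
  clusters and reads with injected events and a computed ground-truth table,
  so every stage is testable without any download.

## Worked example

Simulate the VEGF variant suite (one 6-exon gene, eight planned transcript
structures) and run the full pipeline:

```sh
venomiso simulate --scenario svVEGF_suite --seed 1 --outdir sim
venomiso catalog --reads sim/reads.fasta --alignments sim/alignments.bed \
    --models sim/models.gff3 --outdir out
```

which prints `8 variants, 0 chimeras, AS families: VEGF` and writes
`out/variants.tsv`:

```text
gene_id   variant      support  is_original  events                                 polya_site  protein_length  stop_class
svVEGF01  svVEGF01-v1  4        True                                                pA0         174             annotated_exon
svVEGF01  svVEGF01-v2  2        False        INTRON_RETENTION:5                     pA0         158             retained_intron
svVEGF01  svVEGF01-v3  2        False        INTRON_RETENTION:3                     pA0         95              retained_intron
svVEGF01  svVEGF01-v4  1        False        EXON_SKIP:5;INTRON_RETENTION:3         pA0         95              retained_intron
svVEGF01  svVEGF01-v5  1        False        ALT_POLYA:1;INTRON_RETENTION:3         pA1         95              retained_intron
svVEGF01  svVEGF01-v6  1        False        EXON_SKIP:2                            pA0         31              annotated_exon
svVEGF01  svVEGF01-v7  1        False        INTRON_RETENTION:3;INTRON_RETENTION:5  pA0         95              retained_intron
svVEGF01  svVEGF01-v8  1        False        INTRON_RETENTION:1                     pA0         32              retained_intron
```

Reading this: the original transcript (v1, 4 reads) encodes the full 174-aa
protein; four structurally distinct variants all retain intron 3 and gain
the same premature stop there, so they translate one identical 95-aa
product; the exon-2 skip (v6) shifts frame and stops almost immediately in
exon 3 (31 aa); the intron-1 retention (v8) truncates hardest. Only the
VEGF family is flagged as alternatively spliced. The same pipeline on the
serine-protease cluster scenario (`svSP_clusters`) additionally reports six
trans-spliced chimeras grouped into two cluster regions, with up to three
donor genes per transcript.

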