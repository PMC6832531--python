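"""Annotated multigene venom gene models.

A :class:`GeneModel` describes one multi-exon venom gene: its exons (with
optional lettered sub-exons such as 1b..1e), the transcript-coordinate CDS of
the canonical ("original") transcript, protein domain blocks mapped to exon
ranges (signal peptide, prepro region, metalloproteinase domain, disintegrin,
Cys-rich), amino-acid motifs with their expected exon (e.g. the zinc-binding
motif HEXGHNLGXXHD of exon 11), catalytic residues (e.g. the serine-protease
triad His57/Asp102/Ser195), and the genomic positions of AATAAA
polyadenylation signals.  Tandem paralogs on one scaffold are grouped into
:class:`GeneCluster` objects.

Coordinates are 0-based half-open on the scaffold; exon order is always the
gene's 5'->3' transcription order regardless of strand.  GFF3 I/O converts
to/from the standard 1-based inclusive convention.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from ._coords import (
    Interval,
    gbase,
    genomic_of,
    giv,
    junctions_of,
    obase,
    oiv,
    transcript_of,
)

VALID_STRANDS = ("+", "-")
DOMAIN_NAMES = ("signal", "preprosequence", "MP", "disintegrin", "cys_rich", "other")

#: distance (nt) from the 5' end of an AATAAA hexamer to the expected
#: cleavage/polyadenylation point of transcripts using that signal.
SIGNAL_TO_CLEAVAGE = 20

#: default single-linkage gap for grouping tandem genes into clusters.
DEFAULT_CLUSTER_GAP = 50_000


class ModelError(ValueError):
    """A gene model violates a structural invariant."""


class Gff3ParseError(ValueError):
    """Malformed GFF3 input; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ModelError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}"
            )
        if self.strand not in VALID_STRANDS:
            raise ModelError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def oriented(self) -> Interval:
        return oiv(self.start, self.end, self.strand)

    def overlap_len(self, other: "GenomicInterval | Interval") -> int:
        if isinstance(other, GenomicInterval):
            if other.scaffold != self.scaffold:
                return 0
            s, e = other.start, other.end
        else:
            s, e = other
        return max(0, min(self.end, e) - max(self.start, s))


@dataclass(frozen=True)
class ExonModel:
    index: int
    sublabel: str | None
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ModelError(f"exon index must be >= 1, got {self.index}")

    @property
    def is_primary(self) -> bool:
        """Part of the canonical transcript (sub-exons b..e are optional)."""
        return self.sublabel in (None, "a")

    @property
    def label(self) -> str:
        return f"{self.index}{self.sublabel or ''}"


@dataclass(frozen=True)
class DomainBlock:
    name: str
    first_exon: int
    last_exon: int

    def __post_init__(self) -> None:
        if self.name not in DOMAIN_NAMES:
            raise ModelError(f"unknown domain name {self.name!r}")
        if not (1 <= self.first_exon <= self.last_exon):
            raise ModelError(f"bad exon range for domain {self.name}")


@dataclass(frozen=True)
class MotifAnnotation:
    name: str
    pattern: str  # uppercase amino acids; X matches any residue
    expected_exon: int | None = None

    def __post_init__(self) -> None:
        if not self.pattern or not all(
            c.isupper() and c.isalpha() for c in self.pattern
        ):
            raise ModelError(f"bad motif pattern {self.pattern!r}")


@dataclass(frozen=True)
class CatalyticResidue:
    label: str
    expected_residue: str
    protein_position: int  # 1-based ordinal in the reference protein

    def __post_init__(self) -> None:
        if self.protein_position < 1:
            raise ModelError("protein_position must be >= 1")


@dataclass
class GeneModel:
    gene_id: str
    family: str
    exons: list[ExonModel]
    cds_start: int  # transcript coord of first base of the start codon
    cds_end: int  # transcript coord just past the stop codon
    domain_blocks: list[DomainBlock] = field(default_factory=list)
    motifs: list[MotifAnnotation] = field(default_factory=list)
    catalytic_residues: list[CatalyticResidue] = field(default_factory=list)
    polya_signals: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if not self.exons:
            raise ModelError(f"{self.gene_id}: no exons")
        scaffolds = {e.interval.scaffold for e in self.exons}
        strands = {e.interval.strand for e in self.exons}
        if len(scaffolds) > 1 or len(strands) > 1:
            raise ModelError(f"{self.gene_id}: exons span scaffolds/strands")
        ordered = [e.interval.oriented() for e in self.exons]
        for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
            if a2 < b1:
                raise ModelError(
                    f"{self.gene_id}: exons overlap or are not in 5'->3' order"
                )
        prim = [e.index for e in self.exons if e.is_primary]
        if prim != list(range(1, len(prim) + 1)):
            raise ModelError(f"{self.gene_id}: primary exon indices not 1..n")
        if not (0 <= self.cds_start < self.cds_end):
            raise ModelError(f"{self.gene_id}: cds_start must precede cds_end")
        n = len(prim)
        for blk in self.domain_blocks:
            if blk.last_exon > n:
                raise ModelError(
                    f"{self.gene_id}: domain {blk.name} exceeds exon count {n}"
                )
        spans = sorted((b.first_exon, b.last_exon) for b in self.domain_blocks)
        for (f1, l1), (f2, l2) in zip(spans, spans[1:]):
            if f2 <= l1:
                raise ModelError(f"{self.gene_id}: domain blocks overlap")
        if not self.polya_signals:
            raise ModelError(f"{self.gene_id}: at least one polyA signal required")

    # -- basic accessors --------------------------------------------------
    @property
    def scaffold(self) -> str:
        return self.exons[0].interval.scaffold

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def primary_exons(self) -> list[ExonModel]:
        return [e for e in self.exons if e.is_primary]

    @property
    def sub_exons(self) -> list[ExonModel]:
        return [e for e in self.exons if not e.is_primary]

    @property
    def span(self) -> GenomicInterval:
        start = min(e.interval.start for e in self.exons)
        end = max(e.interval.end for e in self.exons)
        return GenomicInterval(self.scaffold, start, end, self.strand)

    def oriented_primary(self) -> list[Interval]:
        return [e.interval.oriented() for e in self.primary_exons]

    @property
    def transcript_length(self) -> int:
        return sum(b - a for a, b in self.oriented_primary())

    def junctions(self) -> tuple[Interval, ...]:
        """Oriented (donor_end, acceptor_start) pairs of the original transcript."""
        return junctions_of(self.oriented_primary())

    # -- coordinate maps (canonical transcript <-> genome) ---------------
    def genomic_to_transcript(self, gpos: int) -> int | None:
        return transcript_of(self.oriented_primary(), obase(gpos, self.strand))

    def transcript_to_genomic(self, tpos: int) -> int:
        return gbase(genomic_of(self.oriented_primary(), tpos), self.strand)

    @property
    def start_codon_genomic(self) -> int:
        return self.transcript_to_genomic(self.cds_start)

    @property
    def stop_codon_genomic(self) -> int:
        return self.transcript_to_genomic(self.cds_end - 3)

    def exon_containing(self, gpos: int, include_sub: bool = True) -> ExonModel | None:
        for e in self.exons:
            if not include_sub and not e.is_primary:
                continue
            if e.interval.start <= gpos < e.interval.end:
                return e
        return None

    def intron_containing(self, gpos: int) -> int | None:
        """1-based index i of the intron between primary exons i and i+1."""
        p = obase(gpos, self.strand)
        po = self.oriented_primary()
        for i in range(len(po) - 1):
            if po[i][1] <= p < po[i + 1][0]:
                return i + 1
        return None

    def intron_interval(self, i: int) -> Interval:
        """Oriented half-open interval of intron i (between primaries i, i+1)."""
        po = self.oriented_primary()
        if not (1 <= i < len(po)):
            raise ModelError(f"{self.gene_id}: no intron {i}")
        return (po[i - 1][1], po[i][0])

    def cleavage_oriented(self, k: int, dist: int = SIGNAL_TO_CLEAVAGE) -> int:
        """Oriented coordinate where transcripts using polyA signal k end."""
        s = self.polya_signals[k]
        a, _ = oiv(s, s + 6, self.strand)
        return a + dist

    @property
    def terminal_end_oriented(self) -> int:
        return self.oriented_primary()[-1][1]


@dataclass
class GeneCluster:
    cluster_id: str
    region: GenomicInterval
    genes: list[str]  # gene_ids in tandem genomic order

    def rank(self, gene_id: str) -> int:
        return self.genes.index(gene_id)


@dataclass(frozen=True)
class ExonEditEvent:
    """One exon gain/loss step in a gene-family evolution model."""

    kind: str  # "loss" | "gain"
    exon_indices: tuple[int, ...] = ()  # contiguous primary indices removed
    after: int | None = None  # gain: insert after this primary index (0..n)
    count: int = 0  # gain: number of exons inserted

    def __post_init__(self) -> None:
        if self.kind not in ("loss", "gain"):
            raise ModelError(f"unknown edit kind {self.kind!r}")
        if self.kind == "gain" and (self.count < 1 or self.after is None):
            raise ModelError("gain requires after-index and count >= 1")
        if self.kind == "loss" and not self.exon_indices:
            raise ModelError("loss requires exon indices")


def derive_model(
    parent: GeneModel,
    events: Sequence[ExonEditEvent],
    child_id: str | None = None,
    gain_exon_length: int = 120,
    gain_intron_length: int = 150,
) -> GeneModel:
    """Apply exon gain/loss events to a parent model, re-indexing the child.

    Losses remove the named primary exons (the parent's terminal exon is
    retained unless explicitly removed); gains insert deterministic synthetic
    exons after the given index.  Domain blocks referencing removed exons are
    dropped; surviving annotations are re-indexed.  The CDS transcript
    coordinates are adjusted by the removed/gained coding lengths and
    clamped -- sequence-level validity is the synthetic-locus builder's job.
    """
    model = parent
    for ev in events:
        model = _apply_edit(model, ev, gain_exon_length, gain_intron_length)
    if child_id is not None:
        model = replace_gene_id(model, child_id)
    return model


def replace_gene_id(model: GeneModel, gene_id: str) -> GeneModel:
    return GeneModel(
        gene_id=gene_id,
        family=model.family,
        exons=list(model.exons),
        cds_start=model.cds_start,
        cds_end=model.cds_end,
        domain_blocks=list(model.domain_blocks),
        motifs=list(model.motifs),
        catalytic_residues=list(model.catalytic_residues),
        polya_signals=list(model.polya_signals),
    )


def _apply_edit(
    model: GeneModel, ev: ExonEditEvent, gain_len: int, gain_gap: int
) -> GeneModel:
    prim = model.primary_exons
    n = len(prim)
    strand = model.strand
    scaffold = model.scaffold
    if ev.kind == "loss":
        missing = set(ev.exon_indices) - {e.index for e in prim}
        if missing:
            raise ModelError(
                f"{model.gene_id}: cannot remove nonexistent exon(s) {sorted(missing)}"
            )
        removed = set(ev.exon_indices)
        # coding length removed upstream of / inside the CDS
        t = 0
        shift_start = removed_cds = 0
        for e in prim:
            ln = e.interval.length
            if e.index in removed:
                lo, hi = t, t + ln
                shift_start += max(0, min(hi, model.cds_start) - lo)
                removed_cds += max(
                    0, min(hi, model.cds_end) - max(lo, model.cds_start)
                )
            t += ln
        keep = [e for e in model.exons if e.index not in removed]
        old_order = [e.index for e in prim if e.index not in removed]
        remap = {old: new for new, old in enumerate(old_order, start=1)}
        new_exons = [
            ExonModel(remap[e.index], e.sublabel, e.interval) for e in keep
        ]
        new_blocks = [
            DomainBlock(b.name, remap[b.first_exon], remap[b.last_exon])
            for b in model.domain_blocks
            if not (set(range(b.first_exon, b.last_exon + 1)) & removed)
        ]
        new_motifs = [
            MotifAnnotation(
                m.name,
                m.pattern,
                remap.get(m.expected_exon) if m.expected_exon else None,
            )
            for m in model.motifs
            if m.expected_exon is None or m.expected_exon in remap
        ]
        cds_start = model.cds_start - shift_start
        cds_end = model.cds_end - shift_start - removed_cds
        total = sum(e.interval.length for e in new_exons if e.is_primary)
        cds_start = max(0, min(cds_start, total - 3))
        cds_end = max(cds_start + 3, min(cds_end, total))
        return GeneModel(
            gene_id=model.gene_id,
            family=model.family,
            exons=new_exons,
            cds_start=cds_start,
            cds_end=cds_end,
            domain_blocks=new_blocks,
            motifs=new_motifs,
            catalytic_residues=list(model.catalytic_residues),
            polya_signals=list(model.polya_signals),
        )
    # gain
    if not (0 <= ev.after <= n):
        raise ModelError(f"{model.gene_id}: gain insertion point {ev.after} invalid")
    po = [e.interval.oriented() for e in prim]
    if ev.after == n:
        cursor = po[-1][1] + gain_gap
        room = None
    else:
        left = po[ev.after - 1][1] if ev.after >= 1 else None
        right = po[ev.after][0]
        if left is None:
            cursor = right - (gain_len + gain_gap) * ev.count
        else:
            need = ev.count * gain_len + (ev.count + 1) * 20
            room = right - left
            if room < need:
                raise ModelError(
                    f"{model.gene_id}: intron {ev.after} too small for gain"
                )
            cursor = left + 20
    new_ivs = []
    for _ in range(ev.count):
        a, b = cursor, cursor + gain_len
        new_ivs.append(GenomicInterval(scaffold, *giv(a, b, strand), strand))
        cursor = b + (gain_gap if ev.after == n or ev.after == 0 else 20)
    # rebuild exon list in transcription order
    out: list[ExonModel] = []
    new_index = itertools.count(1)
    idx_map: dict[int, int] = {}
    for e in prim:
        if e.index == ev.after + 1:
            for iv in new_ivs:
                out.append(ExonModel(next(new_index), None, iv))
        idx_map[e.index] = next(new_index)
        out.append(ExonModel(idx_map[e.index], e.sublabel, e.interval))
    if ev.after == n:
        for iv in new_ivs:
            out.append(ExonModel(next(new_index), None, iv))
    for e in model.sub_exons:
        out.append(ExonModel(idx_map.get(e.index, e.index), e.sublabel, e.interval))
    out.sort(key=lambda e: e.interval.oriented()[0])
    new_blocks = [
        DomainBlock(b.name, idx_map[b.first_exon], idx_map[b.last_exon])
        for b in model.domain_blocks
    ]
    new_motifs = [
        MotifAnnotation(
            m.name, m.pattern, idx_map.get(m.expected_exon) if m.expected_exon else None
        )
        for m in model.motifs
    ]
    return GeneModel(
        gene_id=model.gene_id,
        family=model.family,
        exons=out,
        cds_start=model.cds_start,
        cds_end=model.cds_end,
        domain_blocks=new_blocks,
        motifs=new_motifs,
        catalytic_residues=list(model.catalytic_residues),
        polya_signals=list(model.polya_signals),
    )


# ---------------------------------------------------------------------------
# clustering


def build_clusters(
    models: Sequence[GeneModel], gap: int = DEFAULT_CLUSTER_GAP
) -> list[GeneCluster]:
    """Single-linkage grouping of gene spans per scaffold at the given gap."""
    clusters: list[GeneCluster] = []
    by_scaffold: dict[str, list[GeneModel]] = {}
    for m in models:
        by_scaffold.setdefault(m.scaffold, []).append(m)
    for scaffold in sorted(by_scaffold):
        genes = sorted(by_scaffold[scaffold], key=lambda m: (m.span.start, m.gene_id))
        current: list[GeneModel] = []
        groups: list[list[GeneModel]] = []
        for m in genes:
            if current and m.span.start - max(g.span.end for g in current) > gap:
                groups.append(current)
                current = []
            current.append(m)
        if current:
            groups.append(current)
        for i, grp in enumerate(groups, start=1):
            region = GenomicInterval(
                scaffold,
                min(g.span.start for g in grp),
                max(g.span.end for g in grp),
                grp[0].strand,
            )
            clusters.append(
                GeneCluster(
                    cluster_id=f"cluster_{scaffold}_{i}",
                    region=region,
                    genes=[g.gene_id for g in grp],
                )
            )
    return clusters


# ---------------------------------------------------------------------------
# GFF3 dialect I/O

_SOURCE = "venomiso"


def write_gene_models(
    models: Sequence[GeneModel], clusters: Sequence[GeneCluster] = ()
) -> str:
    """Serialize models (and optional clusters) to GFF3 text.

    Dialect: gene/mRNA/exon/CDS features; mRNA attributes carry family,
    transcript-coordinate CDS, domain blocks, motifs, catalytic residues and
    1-based polyA signal positions.  Clusters are emitted as ``##cluster``
    directives.  Output is byte-stable for a fixed model ordering.
    """
    out = io.StringIO()
    out.write("##gff-version 3\n")
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        out.write(
            "##cluster\t{}\t{}\t{}\t{}\t{}\n".format(
                c.cluster_id,
                c.region.scaffold,
                c.region.start + 1,
                c.region.end,
                ",".join(c.genes),
            )
        )
    for m in sorted(models, key=lambda m: (m.scaffold, m.span.start, m.gene_id)):
        sp = m.span
        gid, tid = m.gene_id, f"{m.gene_id}.t1"
        out.write(
            f"{m.scaffold}\t{_SOURCE}\tgene\t{sp.start + 1}\t{sp.end}\t.\t"
            f"{m.strand}\t.\tID={gid};family={m.family}\n"
        )
        attrs = [f"ID={tid}", f"Parent={gid}", f"family={m.family}"]
        attrs.append(f"cds_start={m.cds_start}")
        attrs.append(f"cds_end={m.cds_end}")
        if m.domain_blocks:
            attrs.append(
                "domain_blocks="
                + ",".join(f"{b.name}:{b.first_exon}-{b.last_exon}" for b in m.domain_blocks)
            )
        if m.motifs:
            attrs.append(
                "motifs="
                + ",".join(
                    f"{mo.name}:{mo.pattern}:{mo.expected_exon if mo.expected_exon else '.'}"
                    for mo in m.motifs
                )
            )
        if m.catalytic_residues:
            attrs.append(
                "catalytic="
                + ",".join(
                    f"{r.label}:{r.expected_residue}:{r.protein_position}"
                    for r in m.catalytic_residues
                )
            )
        attrs.append("polyA=" + ",".join(str(p + 1) for p in m.polya_signals))
        out.write(
            f"{m.scaffold}\t{_SOURCE}\tmRNA\t{sp.start + 1}\t{sp.end}\t.\t"
            f"{m.strand}\t.\t{';'.join(attrs)}\n"
        )
        for e in sorted(m.exons, key=lambda e: e.interval.start):
            iv = e.interval
            ex_attrs = [
                f"ID={tid}.exon{e.label}",
                f"Parent={tid}",
                f"exon_index={e.index}",
            ]
            if e.sublabel:
                ex_attrs.append(f"sublabel={e.sublabel}")
            out.write(
                f"{m.scaffold}\t{_SOURCE}\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{m.strand}\t.\t{';'.join(ex_attrs)}\n"
            )
        for k, (s, e) in enumerate(_cds_segments(m), start=1):
            out.write(
                f"{m.scaffold}\t{_SOURCE}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                f"ID={tid}.cds{k};Parent={tid}\n"
            )
    return out.getvalue()


def _cds_segments(m: GeneModel) -> list[Interval]:
    """Genomic (scaffold-ascending) CDS segments of the canonical transcript."""
    segs = []
    t = 0
    for e in m.primary_exons:
        a, b = e.interval.oriented()
        lo, hi = max(t, m.cds_start), min(t + (b - a), m.cds_end)
        if lo < hi:
            oa, ob = a + (lo - t), a + (hi - t)
            segs.append(giv(oa, ob, m.strand))
        t += b - a
    return sorted(segs)


def read_gene_models(
    gff3_source: str | Path,
    fasta_source: str | Path | None = None,
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
) -> tuple[list[GeneModel], list[GeneCluster]]:
    """Parse the GFF3 dialect into models and clusters.

    ``gff3_source`` may be GFF3 text or a path.  Clusters come from
    ``##cluster`` directives when present, otherwise from single-linkage
    grouping of gene spans at ``cluster_gap``.  ``fasta_source`` is accepted
    for interface symmetry; models carry coordinates only.
    """
    import gffutils

    if isinstance(gff3_source, Path) or (
        "\n" not in str(gff3_source) and Path(str(gff3_source)).exists()
    ):
        text = Path(gff3_source).read_text()
    else:
        text = str(gff3_source)

    cluster_directives: list[GeneCluster] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("##cluster\t"):
            parts = line.split("\t")
            if len(parts) != 6:
                raise Gff3ParseError(f"line {lineno}: malformed ##cluster directive")
            _, cid, scaffold, s1, e1, genes = parts
            cluster_directives.append(
                GeneCluster(
                    cluster_id=cid,
                    region=GenomicInterval(scaffold, int(s1) - 1, int(e1)),
                    genes=genes.split(","),
                )
            )
            continue
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise Gff3ParseError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        try:
            int(fields[3]), int(fields[4])
        except ValueError:
            raise Gff3ParseError(f"line {lineno}: non-integer coordinates") from None

    body = "\n".join(
        ln for ln in text.splitlines() if not ln.startswith("##cluster\t")
    )
    if not any(ln and not ln.startswith("#") for ln in body.splitlines()):
        return [], []
    db = gffutils.create_db(
        body, dbfn=":memory:", from_string=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        for mrna in db.children(gene, featuretype="mRNA"):
            at = mrna.attributes
            exons = []
            for fe in db.children(mrna, featuretype="exon"):
                idx = int(fe.attributes["exon_index"][0])
                sub = fe.attributes["sublabel"][0] if "sublabel" in fe.attributes else None
                exons.append(
                    ExonModel(
                        idx,
                        sub,
                        GenomicInterval(fe.seqid, fe.start - 1, fe.end, fe.strand),
                    )
                )
            exons.sort(key=lambda e: e.interval.oriented()[0])
            blocks = []
            for spec in at.get("domain_blocks", []):
                name, rng = spec.split(":")
                first, last = rng.split("-")
                blocks.append(DomainBlock(name, int(first), int(last)))
            motifs = []
            for spec in at.get("motifs", []):
                name, pattern, exon = spec.split(":")
                motifs.append(
                    MotifAnnotation(name, pattern, None if exon == "." else int(exon))
                )
            catalytic = []
            for spec in at.get("catalytic", []):
                label, res, pos = spec.split(":")
                catalytic.append(CatalyticResidue(label, res, int(pos)))
            polya = [int(p) - 1 for p in at.get("polyA", [])]
            try:
                models.append(
                    GeneModel(
                        gene_id=gene.id,
                        family=at.get("family", ["other"])[0],
                        exons=exons,
                        cds_start=int(at["cds_start"][0]),
                        cds_end=int(at["cds_end"][0]),
                        domain_blocks=blocks,
                        motifs=motifs,
                        catalytic_residues=catalytic,
                        polya_signals=polya,
                    )
                )
            except ModelError as err:
                raise ModelError(f"validation failed for {gene.id}: {err}") from err
    clusters = cluster_directives or build_clusters(models, gap=cluster_gap)
    return models, clusters
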