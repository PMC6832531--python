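"""ORF re-projection and protein-consequence analysis of isoform reads.

Given a full-length read, its exon chain and its gene model, this module
re-derives the open reading frame (canonical start when the chain retains it,
first downstream ATG when an alternative first exon or exon skip removed the
canonical start exon), maps the stop codon back to the genome (annotated
exon / retained intron / downstream 3' extension), flags frameshifts, and
derives protein-level annotations: motif presence (wildcard patterns such as
the zinc-binding HEXGHNLGXXHD), catalytic-residue status, and snake-venom
metalloproteinase structural typing (P-I: MP domain only; P-II: +disintegrin;
P-III: +Cys-rich).  P-IV typing needs protein-complex evidence and is out of
scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from Bio.Seq import Seq

from ._coords import obase
from .models import GeneModel
from .splicing import ExonChain

MP_TYPE_ORDER = {"P-I": 1, "P-II": 2, "P-III": 3}


class OrfError(ValueError):
    pass


def locate_start(body: str, chain: ExonChain, model: GeneModel) -> tuple[int, str] | None:
    """Find the translation start of a read.

    Returns (transcript position, kind) with kind 'canonical' or 'internal',
    or None when no acceptable start exists.  The canonical start is used
    whenever the chain covers it.  If the chain lacks the canonical-start
    exon entirely *and* begins at an annotated (sub-)exon boundary — the
    signature of an alternative first exon or start-exon skip, as opposed to
    a 5'-truncated read — the first ATG in the read is accepted as a new
    start.
    """
    cs_g = model.start_codon_genomic
    if chain.covers(cs_g):
        t = chain.genomic_to_transcript(cs_g)
        if t is not None and body[t : t + 3] == "ATG":
            return (t, "canonical")
        return None
    start_exon = model.exon_containing(cs_g, include_sub=False)
    if start_exon is not None:
        iv = start_exon.interval
        if any(min(e, iv.end) > max(s, iv.start) for s, e in chain.blocks):
            return None  # truncated within the start exon
    first_a = chain.oriented()[0][0]
    boundary_starts = {e.interval.oriented()[0] for e in model.exons}
    if first_a not in boundary_starts:
        return None
    i = body.find("ATG")
    if i >= 0:
        return (i, "internal")
    return None


@dataclass
class OrfResult:
    read_id: str
    start_tpos: int
    start_kind: str  # 'canonical' | 'internal'
    start_exon: str | None  # exon label containing the start codon
    stop_tpos: int | None  # transcript coord of first base of the stop codon
    stop_class: str  # 'annotated_exon' | 'retained_intron' | 'downstream_exon' | 'runthrough'
    stop_exon: str | None  # exon label, when stop_class == 'annotated_exon'
    stop_intron: int | None  # intron index, when stop_class == 'retained_intron'
    protein: str
    frameshift: bool
    premature: bool
    deviation_aa: int | None  # first codon (canonical numbering) built from a non-model path
    chain: ExonChain


def project_orf(
    transcript_sequence: str, chain: ExonChain, model: GeneModel, read_id: str | None = None
) -> OrfResult:
    """Translate a full-length variant transcript and classify its stop.

    ``transcript_sequence`` is the read; any 3' polyA tail beyond the aligned
    blocks is ignored.  Raises :class:`OrfError` when no start can be
    located.  A missing in-frame stop is reported as a run-through with the
    protein translated to the end of the aligned sequence.
    """
    if not transcript_sequence:
        raise OrfError("empty transcript sequence")
    body = transcript_sequence[: chain.length]
    rid = read_id or chain.read_id
    st = locate_start(body, chain, model)
    if st is None:
        raise OrfError(f"{rid}: no translation start located")
    start_t, start_kind = st
    coding = body[start_t:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    cut = aa.find("*")
    if cut >= 0:
        protein = aa[:cut]
        stop_t = start_t + 3 * cut
        runthrough = False
    else:
        protein = aa
        stop_t = None
        runthrough = True

    start_g = chain.transcript_to_genomic(start_t)
    se = model.exon_containing(start_g)
    start_exon = se.label if se else None

    stop_class, stop_exon, stop_intron = "runthrough", None, None
    premature = runthrough
    if stop_t is not None:
        g = chain.transcript_to_genomic(stop_t)
        ex = model.exon_containing(g)
        if ex is not None:
            stop_class, stop_exon = "annotated_exon", ex.label
        else:
            intron = model.intron_containing(g)
            if intron is not None:
                stop_class, stop_intron = "retained_intron", intron
            else:
                stop_class = "downstream_exon"
        premature = g != model.stop_codon_genomic

    deviation_aa, frameshift = _deviation(chain, model, start_t, start_kind, stop_t)
    return OrfResult(
        read_id=rid,
        start_tpos=start_t,
        start_kind=start_kind,
        start_exon=start_exon,
        stop_tpos=stop_t,
        stop_class=stop_class,
        stop_exon=stop_exon,
        stop_intron=stop_intron,
        protein=protein,
        frameshift=frameshift,
        premature=premature,
        deviation_aa=deviation_aa,
        chain=chain,
    )


def _model_projection(model: GeneModel, g: int) -> int | None:
    """Model-transcript coordinate of genomic base g, projecting intronic
    positions onto the upstream exon end; None when g is in a sub-exon or
    outside the gene body."""
    t = model.genomic_to_transcript(g)
    if t is not None:
        return t
    intron = model.intron_containing(g)
    if intron is not None:
        po = model.oriented_primary()
        return sum(b - a for a, b in po[:intron])
    p = obase(g, model.strand)
    if p >= model.terminal_end_oriented:
        return model.transcript_length
    return None


def _deviation(
    chain: ExonChain,
    model: GeneModel,
    start_t: int,
    start_kind: str,
    stop_t: int | None,
) -> tuple[int | None, bool]:
    """(first deviating codon in canonical numbering, frameshift flag).

    Walks the chain base-by-base from the start codon and finds the first
    base drawn from outside the canonical transcript path; the frameshift
    flag is set when the cumulative coding-length change upstream of the
    stop is not a multiple of three.
    """
    ob = chain.oriented()
    positions: list[int] = []
    for a, b in ob:
        positions.extend(range(a, b))
    if start_kind == "internal":
        return 1, False
    start_p = positions[start_t]
    m_start = _model_projection_base(model, start_p)
    if m_start is None:
        return 1, False
    end_t = stop_t if stop_t is not None else len(positions)
    deviation_aa = None
    mp = model.oriented_primary()
    model_positions: list[int] = []
    for a, b in mp:
        model_positions.extend(range(a, b))
    mi = model_positions.index(start_p)
    for k, t in enumerate(range(start_t, min(end_t + 3, len(positions)))):
        j = mi + k
        if j >= len(model_positions) or positions[t] != model_positions[j]:
            deviation_aa = k // 3 + 1
            break
    frameshift = False
    if deviation_aa is not None and stop_t is not None:
        g_stop = chain.transcript_to_genomic(stop_t)
        m_proj = _model_projection(model, g_stop)
        if m_proj is None:
            frameshift = True
        else:
            delta = (stop_t - start_t) - (m_proj - model.cds_start)
            frameshift = delta % 3 != 0
    elif deviation_aa is not None:
        frameshift = True
    return deviation_aa, frameshift


def _model_projection_base(model: GeneModel, p_oriented: int) -> int | None:
    from ._coords import gbase

    return model.genomic_to_transcript(gbase(p_oriented, model.strand))


@dataclass(frozen=True)
class MotifStatus:
    name: str
    found: bool
    protein_span: tuple[int, int] | None  # 1-based inclusive span in the protein
    exon_index: int | None  # exon containing the majority of the motif codons


def locate_motifs(orf: OrfResult, model: GeneModel, chain: ExonChain | None = None) -> list[MotifStatus]:
    """Match each annotated motif (X = any residue) and back-map it to its exon."""
    chain = chain or orf.chain
    out = []
    for motif in model.motifs:
        rx = re.compile(motif.pattern.replace("X", "."))
        m = rx.search(orf.protein)
        if not m:
            out.append(MotifStatus(motif.name, False, None, None))
            continue
        counts: dict[int, int] = {}
        for k in range(m.start(), m.end()):
            t_mid = orf.start_tpos + 3 * k + 1  # middle base of codon k
            g = chain.transcript_to_genomic(t_mid)
            ex = model.exon_containing(g)
            if ex is not None:
                counts[ex.index] = counts.get(ex.index, 0) + 1
        exon = max(counts, key=lambda i: (counts[i], -i)) if counts else None
        out.append(MotifStatus(motif.name, True, (m.start() + 1, m.end()), exon))
    return out


@dataclass(frozen=True)
class CatalyticStatus:
    label: str
    state: str  # 'present' | 'absent' | 'substituted'
    observed: str | None


def check_catalytic(orf: OrfResult, model: GeneModel) -> list[CatalyticStatus]:
    """Status of each annotated catalytic residue in the variant protein.

    Residue numbering follows the reference (canonical) protein; positions
    beyond the variant protein, downstream of a structural deviation, or in
    proteins translated from a non-canonical start are reported absent.  A
    position that aligns but carries a different residue is 'substituted'
    (e.g. a catalytic His replaced by Arg).
    """
    out = []
    for r in model.catalytic_residues:
        p = r.protein_position
        if orf.start_kind != "canonical":
            out.append(CatalyticStatus(r.label, "absent", None))
        elif p > len(orf.protein):
            out.append(CatalyticStatus(r.label, "absent", None))
        elif orf.deviation_aa is not None and p >= orf.deviation_aa:
            out.append(CatalyticStatus(r.label, "absent", orf.protein[p - 1]))
        elif orf.protein[p - 1] == r.expected_residue:
            out.append(CatalyticStatus(r.label, "present", orf.protein[p - 1]))
        else:
            out.append(CatalyticStatus(r.label, "substituted", orf.protein[p - 1]))
    return out


@dataclass(frozen=True)
class MpType:
    type_: str | None  # 'P-I' | 'P-II' | 'P-III' | None when non-functional
    domains_covered: frozenset[str]
    functional: bool

    @property
    def rank(self) -> int:
        return MP_TYPE_ORDER.get(self.type_, 0)


def type_mp(orf: OrfResult, model: GeneModel) -> MpType:
    """Assign the metalloproteinase structural class of a variant transcript.

    A domain block counts as covered only when every exon of its range is
    present in the chain with exact boundaries, translated in the original
    reading frame, and entirely upstream of the stop codon.  A transcript
    whose MP domain itself is not covered is reported non-functional rather
    than typed.
    """
    chain = orf.chain
    covered: set[str] = set()
    blocks = {b.name: b for b in model.domain_blocks}
    po = model.oriented_primary()
    ob = chain.oriented()
    stop_t = orf.stop_tpos if orf.stop_tpos is not None else chain.length
    for name in ("MP", "disintegrin", "cys_rich"):
        blk = blocks.get(name)
        if blk is None:
            continue
        ok = True
        for i in range(blk.first_exon, blk.last_exon + 1):
            ea, eb = po[i - 1]
            block = next((b for b in ob if b[0] <= ea and b[1] >= eb), None)
            if block is None:
                ok = False
                break
            # original frame at the exon start, relative to the located start
            t_here = chain.genomic_to_transcript(_gb(ea, model.strand))
            m_here = model.genomic_to_transcript(_gb(ea, model.strand))
            if t_here is None or m_here is None or orf.start_kind != "canonical":
                ok = False
                break
            if ((t_here - orf.start_tpos) - (m_here - model.cds_start)) % 3 != 0:
                ok = False
                break
            # fully translated: stop strictly downstream of the exon end
            t_end = chain.genomic_to_transcript(_gb(eb - 1, model.strand))
            if t_end is None or stop_t <= t_end:
                ok = False
                break
        if ok:
            covered.add(name)
    if "MP" not in covered:
        return MpType(None, frozenset(covered), False)
    if "cys_rich" in covered and "disintegrin" in covered:
        return MpType("P-III", frozenset(covered), True)
    if "disintegrin" in covered:
        return MpType("P-II", frozenset(covered), True)
    return MpType("P-I", frozenset(covered), True)


def _gb(p_oriented: int, strand: str) -> int:
    from ._coords import gbase

    return gbase(p_oriented, strand)
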