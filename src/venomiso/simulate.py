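"""Synthetic venom-gland loci, gene clusters and long cDNA reads.

The generator emulates the structure of venom-gland Iso-Seq data over tandem
multigene families: multi-exon metalloproteinase-like loci (17/15/13 exons,
zinc-binding motif in exon 11, domain blocks signal/prepro/MP/disintegrin/
Cys-rich), six-exon serine-protease-like loci (exon 1 untranslated, catalytic
triad His57/Asp102/Ser195), six-exon VEGF-like and four-exon PLA2-like loci.
Reads are full-length cDNAs (start Met .. AATAAA signal .. polyA tail) or
deliberately truncated fragments; splice events of every class and
trans-spliced chimeras over clustered genes can be injected, and every read
is recorded in a ground-truth table whose protein consequences are computed
by a direct positional scan of the planned read (never asserted by fiat).

Design guarantees that make ground truth deterministic:

* every intron begins GT + a block carrying stop codons in all three frames
  within its first 14 nt, so any (partial) intron retention terminates
  translation almost immediately;
* every coding exon (except exon 1) carries a 9-nt cassette encoding stop
  codons in the two shifted frames but ordinary residues in frame, so any
  frameshift entering an exon terminates inside that exon;
* the 3' UTR begins with an all-frame stop block, so frameshifts reaching
  the terminal exon also terminate;
* AATAAA hexamers start exactly 20 nt upstream of their cleavage point and
  polyA tails are 30 nt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._coords import giv, obase, oriented_blocks
from .models import (
    SIGNAL_TO_CLEAVAGE,
    CatalyticResidue,
    DomainBlock,
    ExonModel,
    GeneCluster,
    GeneModel,
    GenomicInterval,
    ModelError,
    MotifAnnotation,
    build_clusters,
    write_gene_models,
)
from .splicing import (
    ALT_ACCEPTOR,
    ALT_DONOR,
    ALT_FIRST_EXON,
    ALT_POLYA,
    EXON_SKIP,
    INTRON_RETENTION,
    PARTIAL_INTRON_RETENTION,
    ExonChain,
    write_bed12,
)

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
#: stops in all three frames within the first 12 nt.
STOP_BLOCK = "TTAATTAATTAA"
#: in-frame Leu-Ile-Glu, but stop codons in both shifted frames.
FRAMESHIFT_CASSETTE = "TTAATTGAG"
POLYA_TAIL = 30
SIGNAL = "AATAAA"

_AA2CODON = {
    "A": "GCT", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGC", "H": "CAC", "I": "ATT", "L": "CTG", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCA", "S": "TCT", "T": "ACA", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}
_NON_STOP = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
]


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# templates


@dataclass(frozen=True)
class LocusTemplate:
    name: str
    family: str
    utr5_len: int
    coding_lens: tuple[int, ...]  # CDS nt per exon; terminal exon may be 0
    utr3_len: int
    n_polya: int
    domain_blocks: tuple[tuple[str, int, int], ...] = ()
    zinc_motif_exon: int | None = None
    catalytic: tuple[tuple[str, str, int], ...] = ()
    sub_exon_count: int = 0
    exon5_signal: bool = False  # plant an in-frame AATAAA near the end of exon 5

    @property
    def n_exons(self) -> int:
        return len(self.coding_lens)


_MP_DOMAINS_17 = (
    ("signal", 1, 1),
    ("preprosequence", 2, 6),
    ("MP", 7, 12),
    ("disintegrin", 13, 14),
    ("cys_rich", 15, 16),
)
_SP_CATALYTIC = (("His57", "H", 57), ("Asp102", "D", 102), ("Ser195", "S", 195))

TEMPLATES: dict[str, LocusTemplate] = {
    "MP17": LocusTemplate(
        "MP17", "MP", 40,
        (99, 130, 130, 130, 130, 130, 160, 160, 160, 160, 160, 160, 130, 130, 130, 130, 0),
        150, 3, _MP_DOMAINS_17, zinc_motif_exon=11,
    ),
    "MP15": LocusTemplate(
        "MP15", "MP", 40,
        (99, 131, 131, 130, 130, 130, 160, 160, 160, 160, 160, 160, 130, 130, 0),
        150, 3,
        (("signal", 1, 1), ("preprosequence", 2, 6), ("MP", 7, 12), ("disintegrin", 13, 14)),
        zinc_motif_exon=11,
    ),
    "MP13": LocusTemplate(
        "MP13", "MP", 40,
        (99, 133, 131, 130, 130, 130, 160, 160, 160, 160, 160, 160, 0),
        150, 3,
        (("signal", 1, 1), ("preprosequence", 2, 6), ("MP", 7, 12)),
        zinc_motif_exon=11,
    ),
    "SP6": LocusTemplate(
        "SP6", "SP", 60, (0, 145, 146, 145, 146, 144), 150, 3,
        catalytic=_SP_CATALYTIC, exon5_signal=True,
    ),
    "SP8": LocusTemplate(
        "SP8", "SP", 60, (0, 145, 146, 145, 146, 144, 0, 0), 150, 3,
        catalytic=_SP_CATALYTIC,
    ),
    "VEGF6": LocusTemplate(
        "VEGF6", "VEGF", 35, (85, 94, 95, 94, 95, 59), 140, 2,
    ),
    "PLA2_4": LocusTemplate("PLA2_4", "PLA2", 30, (70, 70, 70, 36), 120, 2),
    "GEN4": LocusTemplate("GEN4", "other", 30, (70, 70, 70, 36), 120, 2),
}

FLANK = 200
EXTENSION = 160  # room past the terminal exon for alternative polyA signals
ALT_POLYA_SPACING = 60
SUB_EXON_LEN = 50
MINI_INTRON = 42


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _scrub(seq: str, word: str, repl: str) -> str:
    """Destroy every occurrence of `word` by swapping its middle base."""
    s = list(seq)
    i = "".join(s).find(word)
    while i >= 0:
        mid = i + len(word) // 2
        s[mid] = repl if s[mid] != repl else ("C" if repl != "C" else "G")
        i = "".join(s).find(word)
    return "".join(s)


def _rand_utr(rng: np.random.Generator, n: int) -> str:
    return _scrub(_scrub(_rand_seq(rng, n), "ATG", "C"), SIGNAL, "G")


def _mini_intron(rng: np.random.Generator) -> str:
    filler = _rand_seq(rng, MINI_INTRON - 4 - len(STOP_BLOCK))
    return "GT" + STOP_BLOCK + filler + "AG"


def _intron(rng: np.random.Generator) -> str:
    filler = _rand_seq(rng, int(rng.integers(64, 104)))
    return "GT" + STOP_BLOCK + filler + "AG"


def build_locus(
    family_template: str,
    seed: int,
    scaffold: str | None = None,
    gene_id: str | None = None,
    origin: int = 0,
    sub_exons: int | None = None,
) -> tuple[GeneModel, str]:
    """Build one synthetic locus: an annotated gene model plus its sequence.

    The returned sequence is the locus only (5' flank .. 3' flank); exon
    coordinates are offset by ``origin`` so loci can be concatenated into a
    scaffold.  Identical arguments give byte-identical results.
    """
    if family_template not in TEMPLATES:
        raise SimulationError(f"unknown locus template {family_template!r}")
    tpl = TEMPLATES[family_template]
    rng = np.random.default_rng(seed)
    n_sub = tpl.sub_exon_count if sub_exons is None else sub_exons
    gid = gene_id or f"{tpl.name.lower()}_{seed}"
    scaffold = scaffold or f"sc_{gid}"

    total_coding = sum(tpl.coding_lens)
    if total_coding % 3:
        raise SimulationError(f"{tpl.name}: coding length not a multiple of 3")
    n_cod = total_coding // 3
    codons = [str(_NON_STOP[i]) for i in rng.integers(0, len(_NON_STOP), size=n_cod)]
    codons[0] = "ATG"

    # per-exon CDS offsets
    offsets = []
    c = 0
    for ln in tpl.coding_lens:
        offsets.append(c)
        c += ln

    def place(codon_idx: int, codon: str) -> None:
        codons[codon_idx] = codon

    # frameshift cassettes: early in every coding exon after the first
    for k, (off, ln) in enumerate(zip(offsets, tpl.coding_lens), start=1):
        if k == 1 or ln < 36:
            continue
        i0 = math.ceil(off / 3)
        for j, cod in enumerate(("TTA", "ATT", "GAG")):
            place(i0 + 2 + j, cod)

    # zinc-binding motif, fully inside its exon, on the codon grid
    motifs: list[MotifAnnotation] = []
    if tpl.zinc_motif_exon is not None:
        ex = tpl.zinc_motif_exon
        i0 = math.ceil(offsets[ex - 1] / 3)
        pattern = "HEXGHNLGXXHD"
        for j, aa in enumerate(pattern):
            cod = (
                _NON_STOP[int(rng.integers(0, len(_NON_STOP)))]
                if aa == "X"
                else _AA2CODON[aa]
            )
            place(i0 + 6 + j, cod)
        motifs.append(MotifAnnotation("zinc_binding", pattern, ex))

    catalytic: list[CatalyticResidue] = []
    for label, aa, pos in tpl.catalytic:
        place(pos - 1, _AA2CODON[aa])
        catalytic.append(CatalyticResidue(label, aa, pos))

    if tpl.exon5_signal and tpl.n_exons >= 5:
        # in-frame Asn-Lys (AAT AAA) ~21 nt before the end of exon 5, so
        # chimeric reads ending at exon 5 still carry a polyA signal
        end5 = offsets[4] + tpl.coding_lens[4]
        j = (end5 - 21) // 3
        place(j, "AAT")
        place(j + 1, "AAA")

    cds = "".join(codons)
    stop = "TAA"

    utr3 = STOP_BLOCK + _rand_utr(rng, tpl.utr3_len - len(STOP_BLOCK))
    sig_off = tpl.utr3_len - SIGNAL_TO_CLEAVAGE
    utr3 = utr3[:sig_off] + SIGNAL + utr3[sig_off + 6 :]

    # assemble the locus left to right, tracking exon coordinates
    parts: list[str] = []
    pos = origin
    exons: list[ExonModel] = []

    def emit(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    emit(_rand_utr(rng, FLANK))
    for k, ln in enumerate(tpl.coding_lens, start=1):
        chunk = ""
        if k == 1:
            chunk += _rand_utr(rng, tpl.utr5_len)
        chunk += cds[offsets[k - 1] : offsets[k - 1] + ln]
        if k == tpl.n_exons:
            chunk += stop + utr3
        start_here = pos
        emit(chunk)
        exons.append(
            ExonModel(
                k,
                "a" if (k == 1 and n_sub) else None,
                GenomicInterval(scaffold, start_here, pos, "+"),
            )
        )
        if k == tpl.n_exons:
            break
        if k == 1 and n_sub:
            for s_i in range(n_sub):
                emit(_mini_intron(rng))
                sub_start = pos
                body = _rand_utr(rng, 6) + "ATG" + _rand_seq(rng, SUB_EXON_LEN - 9)
                emit(body)
                exons.append(
                    ExonModel(
                        1,
                        chr(ord("b") + s_i),
                        GenomicInterval(scaffold, sub_start, pos, "+"),
                    )
                )
            emit(_mini_intron(rng))
        else:
            emit(_intron(rng))

    term_end = pos
    ext = _rand_utr(rng, EXTENSION)
    polya = [term_end - SIGNAL_TO_CLEAVAGE - origin]
    for k in range(1, tpl.n_polya):
        off = k * ALT_POLYA_SPACING - SIGNAL_TO_CLEAVAGE
        ext = ext[:off] + SIGNAL + ext[off + 6 :]
        polya.append(term_end + off - origin)
    emit(ext)
    emit(_rand_utr(rng, FLANK))

    seq = "".join(parts)
    model = GeneModel(
        gene_id=gid,
        family=tpl.family,
        exons=exons,
        cds_start=tpl.utr5_len,
        cds_end=tpl.utr5_len + total_coding + 3,
        domain_blocks=[DomainBlock(n, f, l) for n, f, l in tpl.domain_blocks],
        motifs=motifs,
        catalytic_residues=catalytic,
        polya_signals=[p + origin for p in polya],
    )
    return model, seq


def build_cluster(
    templates: Sequence[str],
    seed: int,
    scaffold: str = "scaf1",
    gene_ids: Sequence[str] | None = None,
    intergenic_gap: int = 1500,
) -> tuple[GeneCluster, list[GeneModel], str]:
    """Tandem same-strand loci on one scaffold, grouped into a cluster."""
    if not templates:
        raise SimulationError("cluster needs at least one template")
    ids = list(gene_ids) if gene_ids else [f"g{i+1}" for i in range(len(templates))]
    models: list[GeneModel] = []
    seq = ""
    for i, tpl in enumerate(templates):
        m, s = build_locus(
            tpl, seed * 1000 + i, scaffold=scaffold, gene_id=ids[i], origin=len(seq)
        )
        models.append(m)
        seq += s
        if i < len(templates) - 1:
            rng = np.random.default_rng(seed * 1000 + 500 + i)
            seq += _rand_utr(rng, intergenic_gap)
    cluster = build_clusters(models, gap=50_000)[0]
    return cluster, models, seq


def mirror_locus(model: GeneModel, seq: str) -> tuple[GeneModel, str]:
    """Reverse-complement a locus, flipping the model to the minus strand."""
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    exons = [
        ExonModel(
            e.index,
            e.sublabel,
            GenomicInterval(
                e.interval.scaffold,
                L - e.interval.end,
                L - e.interval.start,
                "-" if e.interval.strand == "+" else "+",
            ),
        )
        for e in model.exons
    ]
    exons.sort(key=lambda e: e.interval.oriented()[0])
    return (
        GeneModel(
            gene_id=model.gene_id,
            family=model.family,
            exons=exons,
            cds_start=model.cds_start,
            cds_end=model.cds_end,
            domain_blocks=list(model.domain_blocks),
            motifs=list(model.motifs),
            catalytic_residues=list(model.catalytic_residues),
            polya_signals=[L - p - 6 for p in model.polya_signals],
        ),
        rc,
    )


# ---------------------------------------------------------------------------
# read plans


@dataclass(frozen=True)
class EventSpec:
    kind: str  # splice-event kind, or "NONE"
    exons: tuple[int, ...] = ()
    intron: int | None = None
    offset: int = 0
    side: str | None = None
    polya_index: int | None = None
    sublabels: tuple[str, ...] = ()
    keep_first: bool = True  # ALT_FIRST_EXON: retain exon 1a before the sub-exon

    def token(self) -> str:
        if self.kind == EXON_SKIP:
            return f"{self.kind}:{','.join(map(str, self.exons))}"
        if self.kind == INTRON_RETENTION:
            return f"{self.kind}:{self.intron}"
        if self.kind == PARTIAL_INTRON_RETENTION:
            return f"{self.kind}:{self.intron}:{self.side}"
        if self.kind in (ALT_DONOR, ALT_ACCEPTOR):
            return f"{self.kind}:{self.exons[0]}"
        if self.kind == ALT_FIRST_EXON:
            return f"{self.kind}:{','.join(self.sublabels) or '.'}"
        if self.kind == ALT_POLYA:
            return f"{self.kind}:{self.polya_index}"
        raise SimulationError(f"token undefined for kind {self.kind}")


NONE_EVENT = EventSpec("NONE")

ChimeraSegment = tuple[str, int, int]  # gene_id, first exon, last exon


@dataclass(frozen=True)
class ReadPlan:
    label: str
    gene_id: str | None = None
    events: tuple[EventSpec, ...] = ()
    chimera: tuple[ChimeraSegment, ...] | None = None
    support: int = 1
    full_length: bool = True
    truncation: str | None = None  # 'no_start' | 'no_polya' | 'both'

    def __post_init__(self) -> None:
        if self.support < 1:
            raise SimulationError(f"{self.label}: support must be >= 1")
        if (self.gene_id is None) == (self.chimera is None):
            raise SimulationError(f"{self.label}: exactly one of gene/chimera")

    def token_string(self) -> str:
        return ";".join(
            sorted(ev.token() for ev in self.events if ev.kind != "NONE")
        )


def plan_blocks(model: GeneModel, events: Sequence[EventSpec]) -> list[tuple[int, int]]:
    """Genomic (scaffold-ascending) blocks of a planned variant transcript."""
    po = model.oriented_primary()
    n = len(po)
    blocks: dict[int, list[int]] = {i + 1: list(iv) for i, iv in enumerate(po)}
    extras: list[list[int]] = []
    subs = {e.sublabel: list(e.interval.oriented()) for e in model.sub_exons}
    for ev in events:
        if ev.kind == "NONE":
            continue
        if ev.kind == EXON_SKIP:
            for i in ev.exons:
                if i not in blocks or i in (1, n):
                    raise SimulationError(f"cannot skip exon {i}")
                del blocks[i]
        elif ev.kind == INTRON_RETENTION:
            i = ev.intron
            if not (i and 1 <= i < n) or i not in blocks or i + 1 not in blocks:
                raise SimulationError(f"cannot retain intron {ev.intron}")
            extras.append(list(model.intron_interval(i)))
        elif ev.kind == PARTIAL_INTRON_RETENTION:
            i = ev.intron
            a, b = model.intron_interval(i)
            if not (0 < ev.offset < b - a):
                raise SimulationError(f"partial retention offset {ev.offset} invalid")
            if ev.side == "donor":
                if i not in blocks:
                    raise SimulationError(f"donor exon {i} missing")
                extras.append([a, a + ev.offset])
            elif ev.side == "acceptor":
                if i + 1 not in blocks:
                    raise SimulationError(f"acceptor exon {i+1} missing")
                extras.append([b - ev.offset, b])
            else:
                raise SimulationError(f"bad side {ev.side!r}")
        elif ev.kind == ALT_DONOR:
            i = ev.exons[0]
            if i not in blocks or i == n:
                raise SimulationError(f"alt donor on exon {i} invalid")
            if not (0 < ev.offset < blocks[i][1] - blocks[i][0]):
                raise SimulationError(f"alt donor offset {ev.offset} invalid")
            blocks[i][1] -= ev.offset
        elif ev.kind == ALT_ACCEPTOR:
            i = ev.exons[0]
            if i not in blocks or i == 1:
                raise SimulationError(f"alt acceptor on exon {i} invalid")
            if not (0 < ev.offset < blocks[i][1] - blocks[i][0]):
                raise SimulationError(f"alt acceptor offset {ev.offset} invalid")
            blocks[i][0] += ev.offset
        elif ev.kind == ALT_POLYA:
            k = ev.polya_index
            if k is None or not (0 <= k < len(model.polya_signals)):
                raise SimulationError(f"no polyA signal {ev.polya_index}")
            blocks[n][1] = model.cleavage_oriented(k)
        elif ev.kind == ALT_FIRST_EXON:
            for s in ev.sublabels:
                if s not in subs:
                    raise SimulationError(f"no sub-exon {s!r}")
                extras.append(list(subs[s]))
            if not ev.keep_first:
                if 1 not in blocks:
                    raise SimulationError("exon 1 already removed")
                del blocks[1]
        else:
            raise SimulationError(f"unknown event kind {ev.kind!r}")
    ivs = sorted(list(blocks.values()) + extras)
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return sorted(giv(a, b, model.strand) for a, b in merged)


def chimera_blocks(
    segments: Sequence[ChimeraSegment], models: Mapping[str, GeneModel]
) -> list[tuple[int, int]]:
    ivs: list[tuple[int, int]] = []
    for gid, lo, hi in segments:
        m = models[gid]
        po = m.oriented_primary()
        if not (1 <= lo <= hi <= len(po)):
            raise SimulationError(f"chimera exon range {lo}-{hi} invalid for {gid}")
        for a, b in po[lo - 1 : hi]:
            ivs.append(giv(a, b, m.strand))
    out = sorted(ivs)
    for (s1, e1), (s2, e2) in zip(out, out[1:]):
        if e1 > s2:
            raise SimulationError("chimera segments not colinear")
    return out


def _splice(seq: str, blocks: Sequence[tuple[int, int]], strand: str) -> str:
    body = "".join(seq[s:e] for s, e in blocks)
    return body if strand == "+" else str(Seq(body).reverse_complement())


def _trim_transcript_prefix(
    blocks: Sequence[tuple[int, int]], strand: str, cut: int
) -> list[tuple[int, int]]:
    ob = oriented_blocks(blocks, strand)
    out = []
    for a, b in ob:
        ln = b - a
        if cut >= ln:
            cut -= ln
            continue
        out.append((a + cut, b))
        cut = 0
    return sorted(giv(a, b, strand) for a, b in out)


def _trim_transcript_suffix(
    blocks: Sequence[tuple[int, int]], strand: str, cut: int
) -> list[tuple[int, int]]:
    ob = oriented_blocks(blocks, strand)
    out = []
    for a, b in reversed(ob):
        ln = b - a
        if cut >= ln:
            cut -= ln
            continue
        out.append((a, b - cut))
        cut = 0
    return sorted(giv(a, b, strand) for a, b in out)


# ---------------------------------------------------------------------------
# ground truth (direct positional scans, independent of the caller modules)


def _truth_translate(body: str, start: int) -> tuple[str, int | None]:
    prot = []
    i = start
    while i + 3 <= len(body):
        cod = body[i : i + 3]
        if cod in STOP_CODONS:
            return "".join(prot), i
        prot.append(str(Seq(cod).translate()))
        i += 3
    return "".join(prot), None


def _truth_start(body: str, blocks, model: GeneModel) -> tuple[int, str] | None:
    ob = oriented_blocks(blocks, model.strand)
    positions: list[int] = []
    for a, b in ob:
        positions.extend(range(a, b))
    p = obase(model.start_codon_genomic, model.strand)
    if p in positions:
        t = positions.index(p)
        return (t, "canonical") if body[t : t + 3] == "ATG" else None
    i = body.find("ATG")
    return (i, "internal") if i >= 0 else None


def _truth_mp_type(
    model: GeneModel, blocks, stop_t: int | None, start: tuple[int, str]
) -> str:
    ob = oriented_blocks(blocks, model.strand)
    positions: list[int] = []
    for a, b in ob:
        positions.extend(range(a, b))
    mpos: list[int] = []
    for a, b in model.oriented_primary():
        mpos.extend(range(a, b))
    stop_t = stop_t if stop_t is not None else len(positions)
    covered: set[str] = set()
    for blk in model.domain_blocks:
        if blk.name not in ("MP", "disintegrin", "cys_rich"):
            continue
        ok = start[1] == "canonical"
        po = model.oriented_primary()
        for i in range(blk.first_exon, blk.last_exon + 1):
            if not ok:
                break
            ea, eb = po[i - 1]
            if ea not in positions or (eb - 1) not in positions:
                ok = False
                break
            t0 = positions.index(ea)
            if positions[t0 : t0 + (eb - ea)] != list(range(ea, eb)):
                ok = False
                break
            frame = (t0 - start[0]) - (mpos.index(ea) - model.cds_start)
            if frame % 3 != 0 or stop_t <= t0 + (eb - ea) - 1:
                ok = False
        if ok:
            covered.add(blk.name)
    if "MP" not in covered:
        return "non-functional"
    if {"disintegrin", "cys_rich"} <= covered:
        return "P-III"
    if "disintegrin" in covered:
        return "P-II"
    return "P-I"


# ---------------------------------------------------------------------------
# read emission


@dataclass
class ScenarioBundle:
    name: str
    seed: int
    models: list[GeneModel]
    clusters: list[GeneCluster]
    sequences: dict[str, str]
    reads: list[tuple[str, str]]
    chains: list[ExonChain]
    truth: pd.DataFrame
    plans: list[ReadPlan]

    def reads_dict(self) -> dict[str, str]:
        return dict(self.reads)

    def chains_dict(self) -> dict[str, ExonChain]:
        return {c.read_id: c for c in self.chains}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fasta", "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n")
                s = self.sequences[name]
                for i in range(0, len(s), 70):
                    fh.write(s[i : i + 70] + "\n")
        (outdir / "models.gff3").write_text(
            write_gene_models(self.models, self.clusters)
        )
        with open(outdir / "reads.fasta", "w") as fh:
            for rid, seq in self.reads:
                fh.write(f">{rid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        (outdir / "alignments.bed").write_text(write_bed12(self.chains))
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def emit_reads(
    models: Sequence[GeneModel],
    sequences: Mapping[str, str],
    plans: Sequence[ReadPlan],
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[ExonChain], pd.DataFrame]:
    """Materialize read plans into sequences, BED12-style chains and truth.

    Each full-length read is the spliced concatenation of its planned blocks
    plus a 30-nt polyA tail; truncated reads lose their 5' start region
    and/or their polyA signal+tail.  The truth table has one row per read,
    with protein consequences recomputed from the planned read by a direct
    positional scan.
    """
    by_id = {m.gene_id: m for m in models}
    reads: list[tuple[str, str]] = []
    chains: list[ExonChain] = []
    rows: list[dict] = []
    for plan in plans:
        try:
            if plan.chimera is not None:
                segs = plan.chimera
                first = by_id[segs[0][0]]
                scaffold, strand = first.scaffold, first.strand
                blocks = chimera_blocks(segs, by_id)
                model_for_truth = first
                gene_label = "+".join(g for g, _, _ in segs)
            else:
                model_for_truth = by_id[plan.gene_id]
                scaffold, strand = model_for_truth.scaffold, model_for_truth.strand
                blocks = plan_blocks(model_for_truth, plan.events)
                gene_label = plan.gene_id
        except (SimulationError, ModelError) as err:
            raise SimulationError(f"plan {plan.label!r}: {err}") from err
        seq = sequences[scaffold]
        body = _splice(seq, blocks, strand)

        status = "full_length"
        if plan.truncation in ("no_start", "both"):
            st = _truth_start(body, blocks, model_for_truth)
            cut = (st[0] if st else 0) + 30
            blocks = _trim_transcript_prefix(blocks, strand, cut)
            body = _splice(seq, blocks, strand)
            status = "missing_start"
        if plan.truncation in ("no_polya", "both"):
            blocks = _trim_transcript_suffix(blocks, strand, 30)
            body = _splice(seq, blocks, strand)
            status = "missing_both" if status == "missing_start" else "missing_polya"
        tail = "A" * POLYA_TAIL if (plan.full_length and plan.truncation in (None, "no_start")) else ""
        if plan.truncation is None and not plan.full_length:
            status = "missing_both"

        protein, stop_class, mp_type = "", "", ""
        if status == "full_length":
            st = _truth_start(body, blocks, model_for_truth)
            if st is None:
                raise SimulationError(f"plan {plan.label!r}: no start in planned read")
            protein, stop_i = _truth_translate(body, st[0])
            if plan.chimera is None:
                stop_class = _truth_stop_class(model_for_truth, blocks, stop_i)
                if model_for_truth.family == "MP":
                    mp_type = _truth_mp_type(model_for_truth, blocks, stop_i, st)

        for r in range(plan.support):
            rid = f"{plan.label}.r{r + 1}"
            reads.append((rid, body + tail))
            chains.append(ExonChain(rid, scaffold, strand, tuple(blocks)))
            rows.append(
                {
                    "read_id": rid,
                    "gene_id": gene_label,
                    "variant_label": plan.label,
                    "events": plan.token_string(),
                    "chimera": plan.chimera is not None,
                    "expected_status": status,
                    "protein": protein,
                    "protein_length": len(protein),
                    "stop_class": stop_class,
                    "mp_type": mp_type,
                }
            )
    return reads, chains, pd.DataFrame(rows)


def _truth_stop_class(model: GeneModel, blocks, stop_t: int | None) -> str:
    if stop_t is None:
        return "runthrough"
    ob = oriented_blocks(blocks, model.strand)
    positions: list[int] = []
    for a, b in ob:
        positions.extend(range(a, b))
    p = positions[stop_t]
    from ._coords import gbase

    g = gbase(p, model.strand)
    ex = model.exon_containing(g)
    if ex is not None:
        return f"annotated_exon:{ex.label}"
    intron = model.intron_containing(g)
    if intron is not None:
        return f"retained_intron:{intron}"
    return "downstream_exon"


# ---------------------------------------------------------------------------
# scenarios

SCENARIO_NAMES = (
    "svMP05_suite",
    "svMP08_suite",
    "svVEGF_suite",
    "svSP_clusters",
    "family18",
    "svMP11_noAS",
)

FAMILY18 = (
    "MP", "SP", "CTLP", "PLA2", "3FTX", "APaseN", "CRISP", "Vespryn", "5Nase",
    "DDPase", "Hyal", "NGF", "VEGF", "LAAO", "PDE", "PLB", "BNP", "GPCase",
)


def _sup(i: int) -> int:
    """Deterministic 1..4 read-support pattern for variant plans."""
    return 1 + (i % 4)


def scenario(name: str, seed: int = 0) -> ScenarioBundle:
    """Deterministic scenario bundles mirroring the described variant suites."""
    if name not in SCENARIO_NAMES:
        raise SimulationError(f"unknown scenario {name!r}")
    builder = {
        "svMP05_suite": _scn_mp05,
        "svMP08_suite": _scn_mp08,
        "svVEGF_suite": _scn_vegf,
        "svSP_clusters": _scn_sp_clusters,
        "family18": _scn_family18,
        "svMP11_noAS": _scn_mp11,
    }[name]
    models, clusters, sequences, plans = builder(seed)
    reads, chains, truth = emit_reads(models, sequences, plans, seed=seed)
    return ScenarioBundle(
        name=name,
        seed=seed,
        models=models,
        clusters=clusters,
        sequences=sequences,
        reads=reads,
        chains=chains,
        truth=truth,
        plans=list(plans),
    )


def _scn_mp11(seed: int):
    m, s = build_locus("MP17", seed * 31 + 11, scaffold="sc_mp11", gene_id="svMP11")
    plans = [
        ReadPlan("svMP11-v1", gene_id="svMP11", support=5),
        ReadPlan("svMP11-frag5p", gene_id="svMP11", support=2, truncation="no_start"),
        ReadPlan("svMP11-frag3p", gene_id="svMP11", support=1, truncation="no_polya"),
    ]
    return [m], build_clusters([m]), {m.scaffold: s}, plans


def _scn_mp05(seed: int):
    m, s = build_locus(
        "MP17", seed * 31 + 5, scaffold="sc_mp05", gene_id="svMP05", sub_exons=4
    )
    E = EventSpec
    variant_events: list[tuple[EventSpec, ...]] = [
        (),  # v1 original
        (E(ALT_FIRST_EXON, sublabels=("b",), keep_first=True),),
        (E(ALT_FIRST_EXON, sublabels=("c",), keep_first=False),),
        (E(ALT_FIRST_EXON, sublabels=("d",), keep_first=False),),
        (E(ALT_FIRST_EXON, sublabels=("e",), keep_first=False),),
        (E(ALT_FIRST_EXON, sublabels=("b",), keep_first=False), E(EXON_SKIP, exons=(3,))),
        (E(ALT_POLYA, polya_index=1),),
        (E(ALT_POLYA, polya_index=2),),
        (E(INTRON_RETENTION, intron=14),),
        (E(ALT_DONOR, exons=(14,), offset=31),),
        (E(INTRON_RETENTION, intron=16),),
        (E(INTRON_RETENTION, intron=12),),
        (E(EXON_SKIP, exons=(15,)),),
        (E(INTRON_RETENTION, intron=12), E(ALT_POLYA, polya_index=1)),
        (E(INTRON_RETENTION, intron=12), E(EXON_SKIP, exons=(15,))),
        (E(INTRON_RETENTION, intron=12), E(INTRON_RETENTION, intron=14)),
        (E(PARTIAL_INTRON_RETENTION, intron=7, side="donor", offset=21),),
        (E(INTRON_RETENTION, intron=7),),
    ]
    plans = [
        ReadPlan(
            f"svMP05-v{i + 1}",
            gene_id="svMP05",
            events=evs,
            support=10 if i == 0 else _sup(i),
        )
        for i, evs in enumerate(variant_events)
    ]
    plans.append(
        ReadPlan("svMP05-frag5p", gene_id="svMP05", support=3, truncation="no_start")
    )
    return [m], build_clusters([m]), {m.scaffold: s}, plans


def _scn_mp08(seed: int):
    m, s = build_locus("MP15", seed * 31 + 8, scaffold="sc_mp08", gene_id="svMP08")
    E = EventSpec
    plans = [
        ReadPlan("svMP08-v1", gene_id="svMP08", support=3),
        ReadPlan(
            "svMP08-v3",
            gene_id="svMP08",
            events=(E(INTRON_RETENTION, intron=14),),
            support=2,
        ),
        ReadPlan(
            "svMP08-v4",
            gene_id="svMP08",
            events=(E(INTRON_RETENTION, intron=13),),
            support=1,
        ),
        ReadPlan(
            "svMP08-v5", gene_id="svMP08", events=(E(EXON_SKIP, exons=(14,)),), support=1
        ),
        ReadPlan(
            "svMP08-v6",
            gene_id="svMP08",
            events=(E(EXON_SKIP, exons=(13, 14)),),
            support=1,
        ),
        ReadPlan(
            "svMP08-v7",
            gene_id="svMP08",
            events=(E(ALT_POLYA, polya_index=1),),
            support=2,
        ),
        ReadPlan(
            "svMP08-v8",
            gene_id="svMP08",
            events=(E(ALT_ACCEPTOR, exons=(12,), offset=12),),
            support=1,
        ),
    ]
    return [m], build_clusters([m]), {m.scaffold: s}, plans


def _scn_vegf(seed: int):
    m, s = build_locus("VEGF6", seed * 31 + 3, scaffold="sc_vegf", gene_id="svVEGF01")
    E = EventSpec
    variant_events: list[tuple[EventSpec, ...]] = [
        (),
        (E(INTRON_RETENTION, intron=5),),
        (E(INTRON_RETENTION, intron=3),),
        (E(INTRON_RETENTION, intron=3), E(EXON_SKIP, exons=(5,))),
        (E(INTRON_RETENTION, intron=3), E(INTRON_RETENTION, intron=5)),
        (E(INTRON_RETENTION, intron=3), E(ALT_POLYA, polya_index=1)),
        (E(INTRON_RETENTION, intron=1),),
        (E(EXON_SKIP, exons=(2,)),),
    ]
    supports = [4, 2, 2, 1, 1, 1, 1, 1]
    plans = [
        ReadPlan(f"svVEGF-v{i + 1}", gene_id="svVEGF01", events=evs, support=supports[i])
        for i, evs in enumerate(variant_events)
    ]
    return [m], build_clusters([m]), {m.scaffold: s}, plans


def _scn_sp_clusters(seed: int):
    cl_a, models_a, seq_a = build_cluster(
        ["SP6", "SP6", "SP6"],
        seed * 31 + 21,
        scaffold="sc_sp_a",
        gene_ids=["svSP03", "svSP01", "svSP09"],
    )
    cl_b, models_b, seq_b = build_cluster(
        ["SP6", "SP6", "SP6"],
        seed * 31 + 22,
        scaffold="sc_sp_b",
        gene_ids=["svSP04", "svSP05", "svSP08"],
    )
    models = models_a + models_b
    E = EventSpec
    plans = [
        ReadPlan(f"{m.gene_id}-v1", gene_id=m.gene_id, support=2) for m in models
    ]
    plans += [
        ReadPlan(
            "svSP04-v2", gene_id="svSP04", events=(E(EXON_SKIP, exons=(2,)),), support=2
        ),
        ReadPlan(
            "svSP01-v2",
            gene_id="svSP01",
            events=(E(INTRON_RETENTION, intron=4),),
            support=1,
        ),
    ]
    chimeras = [
        ("chimA1", (("svSP03", 1, 5), ("svSP01", 6, 6))),
        ("chimA2", (("svSP01", 1, 3), ("svSP09", 4, 6))),
        ("chimB1", (("svSP04", 1, 3), ("svSP05", 4, 5), ("svSP08", 6, 6))),
        ("chimB2", (("svSP04", 1, 3), ("svSP05", 4, 5))),
        ("chimB3", (("svSP04", 1, 2), ("svSP05", 3, 6))),
        ("chimB4", (("svSP04", 1, 3), ("svSP08", 4, 6))),
    ]
    plans += [
        ReadPlan(label, chimera=segs, support=2) for label, segs in chimeras
    ]
    sequences = {"sc_sp_a": seq_a, "sc_sp_b": seq_b}
    return models, [cl_a, cl_b], sequences, plans


_FAMILY_TEMPLATE = {"MP": "MP17", "SP": "SP6", "VEGF": "VEGF6", "PLA2": "PLA2_4"}


def _scn_family18(seed: int):
    models: list[GeneModel] = []
    sequences: dict[str, str] = {}
    plans: list[ReadPlan] = []
    E = EventSpec
    for i, fam in enumerate(FAMILY18):
        tpl = _FAMILY_TEMPLATE.get(fam, "GEN4")
        gid = f"sv{fam}01"
        m, s = build_locus(
            tpl, seed * 97 + i, scaffold=f"sc_{fam.lower()}", gene_id=gid
        )
        if m.family != fam:
            m = GeneModel(
                gene_id=m.gene_id,
                family=fam,
                exons=list(m.exons),
                cds_start=m.cds_start,
                cds_end=m.cds_end,
                domain_blocks=list(m.domain_blocks),
                motifs=list(m.motifs),
                catalytic_residues=list(m.catalytic_residues),
                polya_signals=list(m.polya_signals),
            )
        models.append(m)
        sequences[m.scaffold] = s
        plans.append(ReadPlan(f"{gid}-v1", gene_id=gid, support=2))
        if fam == "MP":
            plans.append(
                ReadPlan(
                    f"{gid}-v2", gene_id=gid, events=(E(EXON_SKIP, exons=(15,)),)
                )
            )
        elif fam == "SP":
            plans.append(
                ReadPlan(
                    f"{gid}-v2", gene_id=gid, events=(E(INTRON_RETENTION, intron=4),)
                )
            )
        elif fam == "VEGF":
            plans.append(
                ReadPlan(
                    f"{gid}-v2", gene_id=gid, events=(E(INTRON_RETENTION, intron=3),)
                )
            )
    return models, build_clusters(models), sequences, plans
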