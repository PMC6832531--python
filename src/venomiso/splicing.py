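"""Assignment of exon chains to gene models and splice-event classification.

An :class:`ExonChain` is a read's spliced alignment: ordered genomic blocks on
one scaffold (BED12 in, BED12 out).  :func:`assign_gene` picks the model
sharing the most exact splice junctions; :func:`call_events` classifies every
deviation of a chain from its model into the event vocabulary observed in
venom-gland isoform catalogs: exon skipping, full and partial intron
retention, alternative donor/acceptor usage, alternative first exons
(including lettered sub-exons), alternative polyadenylation, and novel exons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._coords import (
    Interval,
    blocks_length,
    gbase,
    genomic_of,
    junctions_of,
    obase,
    oriented_blocks,
    transcript_of,
)
from .models import GeneModel, ModelError

# event kinds
EXON_SKIP = "EXON_SKIP"
INTRON_RETENTION = "INTRON_RETENTION"
PARTIAL_INTRON_RETENTION = "PARTIAL_INTRON_RETENTION"
ALT_DONOR = "ALT_DONOR"
ALT_ACCEPTOR = "ALT_ACCEPTOR"
ALT_FIRST_EXON = "ALT_FIRST_EXON"
ALT_POLYA = "ALT_POLYA"
NOVEL_EXON = "NOVEL_EXON"

EVENT_KINDS = (
    EXON_SKIP,
    INTRON_RETENTION,
    PARTIAL_INTRON_RETENTION,
    ALT_DONOR,
    ALT_ACCEPTOR,
    ALT_FIRST_EXON,
    ALT_POLYA,
    NOVEL_EXON,
)

#: minimum extension into an intron (nt) to call partial retention rather
#: than treat the boundary shift as alignment jitter.
MIN_PARTIAL_RETENTION = 10

#: tolerance (nt) for matching a chain 3' end to an annotated polyA cleavage.
POLYA_TOLERANCE = 8


@dataclass(frozen=True)
class ExonChain:
    """A read's ordered aligned genomic blocks (scaffold-ascending)."""

    read_id: str
    scaffold: str
    strand: str
    blocks: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"{self.read_id}: empty chain")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if not (s1 < e1 and e1 <= s2):
                raise ValueError(f"{self.read_id}: blocks unsorted or overlapping")

    @property
    def length(self) -> int:
        return blocks_length(self.blocks)

    def oriented(self) -> list[Interval]:
        return oriented_blocks(self.blocks, self.strand)

    def junctions(self) -> tuple[Interval, ...]:
        return junctions_of(self.oriented())

    def covers(self, gpos: int) -> bool:
        return any(s <= gpos < e for s, e in self.blocks)

    def genomic_to_transcript(self, gpos: int) -> int | None:
        return transcript_of(self.oriented(), obase(gpos, self.strand))

    def transcript_to_genomic(self, tpos: int) -> int:
        return gbase(genomic_of(self.oriented(), tpos), self.strand)


# ---------------------------------------------------------------------------
# BED12


def chain_to_bed12(chain: ExonChain) -> str:
    start = chain.blocks[0][0]
    end = chain.blocks[-1][1]
    sizes = ",".join(str(e - s) for s, e in chain.blocks) + ","
    starts = ",".join(str(s - start) for s, e in chain.blocks) + ","
    return "\t".join(
        [
            chain.scaffold,
            str(start),
            str(end),
            chain.read_id,
            "0",
            chain.strand,
            str(start),
            str(end),
            "0",
            str(len(chain.blocks)),
            sizes,
            starts,
        ]
    )


def write_bed12(chains: Iterable[ExonChain]) -> str:
    return "".join(chain_to_bed12(c) + "\n" for c in chains)


def read_bed12(text: str) -> list[ExonChain]:
    chains = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"BED12 line {lineno}: expected 12 fields")
        start = int(f[1])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        blocks = tuple(
            (start + o, start + o + sz) for o, sz in zip(offsets, sizes)
        )
        chains.append(ExonChain(f[3], f[0], f[5], blocks))
    return chains


# ---------------------------------------------------------------------------
# assignment


@dataclass(frozen=True)
class AssignmentResult:
    read_id: str
    gene_id: str | None
    shared_junctions: int
    fraction: float  # fraction of the read's junctions matching the model


def _exonic_overlap(chain: ExonChain, model: GeneModel) -> int:
    total = 0
    for s, e in chain.blocks:
        for ex in model.exons:
            total += ex.interval.overlap_len((s, e))
    return total


def _junction_match(j1: Interval, j2: Interval, tol: int) -> bool:
    return abs(j1[0] - j2[0]) <= tol and abs(j1[1] - j2[1]) <= tol


def assign_gene(
    chain: ExonChain,
    models: Sequence[GeneModel],
    min_fraction: float = 0.5,
    junction_tol: int = 0,
) -> AssignmentResult:
    """Assign a chain to the model maximizing shared exact splice junctions.

    Requires >=1 shared junction and >= ``min_fraction`` of the read's
    junctions matching; ties break by larger exonic overlap, then gene_id.
    Single-exon chains are assigned by maximal exonic overlap.
    """
    cjunc = chain.junctions()
    best: tuple[int, int, str] | None = None
    best_model: GeneModel | None = None
    for m in sorted(models, key=lambda m: m.gene_id):
        if m.scaffold != chain.scaffold or m.strand != chain.strand:
            continue
        shared = sum(
            1
            for j in cjunc
            if any(_junction_match(j, mj, junction_tol) for mj in m.junctions())
        )
        overlap = _exonic_overlap(chain, m)
        # models are visited in gene_id order, so strict > keeps the
        # lexicographically first gene on ties
        if best is None or (shared, overlap) > (best[0], best[1]):
            best = (shared, overlap, m.gene_id)
            best_model = m
    if best_model is None:
        return AssignmentResult(chain.read_id, None, 0, 0.0)
    shared, overlap, gid = best
    if not cjunc:
        if overlap > 0:
            return AssignmentResult(chain.read_id, gid, 0, 1.0)
        return AssignmentResult(chain.read_id, None, 0, 0.0)
    fraction = shared / len(cjunc)
    if shared >= 1 and fraction >= min_fraction:
        return AssignmentResult(chain.read_id, gid, shared, fraction)
    return AssignmentResult(chain.read_id, None, shared, fraction)


def genes_touched(
    chain: ExonChain, models: Sequence[GeneModel], min_overlap: int = 10
) -> list[str]:
    """Gene ids whose exons overlap the chain by >= min_overlap nt."""
    out = []
    for m in models:
        if m.scaffold != chain.scaffold:
            continue
        if _exonic_overlap(chain, m) >= min_overlap:
            out.append(m.gene_id)
    return out


def is_multigene(chain: ExonChain, models: Sequence[GeneModel]) -> bool:
    return len(genes_touched(chain, models)) > 1


# ---------------------------------------------------------------------------
# event calling


@dataclass(frozen=True)
class SpliceEvent:
    kind: str
    exons: tuple[int, ...] = ()
    intron: int | None = None
    side: str | None = None  # 'donor' | 'acceptor' for partial retention
    shift: int = 0  # boundary offset in nt, where applicable
    polya_index: int | None = None
    sublabels: tuple[str, ...] = ()
    span: Interval | None = None  # genomic scaffold coords

    def signature(self) -> tuple:
        return (
            self.kind,
            self.exons,
            self.intron,
            self.side,
            self.polya_index,
            self.sublabels,
        )

    def token(self) -> str:
        """Canonical compact encoding, shared with the simulator's truth table."""
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
            return f"{self.kind}:{self.polya_index if self.polya_index is not None else '?'}"
        return f"{self.kind}:{self.span[0] if self.span else '?'}"


def encode_events(events: Sequence[SpliceEvent]) -> str:
    return ";".join(sorted(e.token() for e in events))


def call_events(
    chain: ExonChain,
    model: GeneModel,
    junction_tol: int = 0,
    min_partial: int = MIN_PARTIAL_RETENTION,
    polya_tol: int = POLYA_TOLERANCE,
) -> list[SpliceEvent]:
    """Classify all deviations of a chain from its assigned model.

    A perfect match yields an empty list.  Boundary differences of
    ``junction_tol`` nt or less are treated as alignment jitter; intronic
    extensions shorter than ``min_partial`` likewise.  The chain must lie on
    the model's scaffold and strand.
    """
    if chain.scaffold != model.scaffold:
        raise ModelError(
            f"{chain.read_id}: scaffold {chain.scaffold} != model {model.scaffold}"
        )
    if chain.strand != model.strand:
        raise ModelError(f"{chain.read_id}: strand mismatch with {model.gene_id}")
    po = model.oriented_primary()
    n = len(po)
    strand = model.strand
    subs = [(e, e.interval.oriented()) for e in model.sub_exons]
    B = chain.oriented()
    events: list[SpliceEvent] = []
    covered: set[int] = set()
    sub_hits: list[str] = []

    def gspan(a: int, b: int) -> Interval:
        s1, e1 = (a, b) if strand == "+" else (-b, -a)
        return (s1, e1)

    for bi, (a, b) in enumerate(B):
        hits = [i for i, (ea, eb) in enumerate(po, start=1) if min(b, eb) > max(a, ea)]
        shere = [e.sublabel for e, (sa, sb) in subs if min(b, sb) > max(a, sa)]
        if shere:
            sub_hits.extend(s for s in shere if s not in sub_hits)
        if not hits:
            if shere:
                continue
            if a >= po[-1][1]:
                continue  # 3' extension past the terminal exon: polyA territory
            events.append(SpliceEvent(NOVEL_EXON, span=gspan(a, b)))
            continue
        covered.update(hits)
        i, j = hits[0], hits[-1]
        for k in range(i, j):
            events.append(
                SpliceEvent(
                    INTRON_RETENTION, exons=(k, k + 1), intron=k,
                    span=gspan(*model.intron_interval(k)),
                )
            )
        ea, eb = po[i - 1][0], po[j - 1][1]
        # 5' edge of the block
        if a < ea - junction_tol and i > 1:
            ext = ea - a
            intron_len = ea - po[i - 2][1]
            if ext < intron_len and ext >= min_partial:
                events.append(
                    SpliceEvent(
                        PARTIAL_INTRON_RETENTION, intron=i - 1, side="acceptor",
                        shift=ext, span=gspan(a, ea),
                    )
                )
        elif a > ea + junction_tol and bi > 0:
            events.append(
                SpliceEvent(ALT_ACCEPTOR, exons=(i,), shift=a - ea, span=gspan(ea, a))
            )
        # 3' edge of the block
        if b > eb + junction_tol and j < n:
            ext = b - eb
            intron_len = po[j][0] - eb
            if ext < intron_len and ext >= min_partial:
                events.append(
                    SpliceEvent(
                        PARTIAL_INTRON_RETENTION, intron=j, side="donor",
                        shift=ext, span=gspan(eb, b),
                    )
                )
        elif b < eb - junction_tol and bi < len(B) - 1:
            events.append(
                SpliceEvent(ALT_DONOR, exons=(j,), shift=eb - b, span=gspan(b, eb))
            )

    # exon skipping: uncovered exons strictly inside the covered range
    if covered:
        lo, hi = min(covered), max(covered)
        run: list[int] = []
        for i in range(lo, hi + 2):
            if i <= hi and i not in covered:
                run.append(i)
            elif run:
                events.append(
                    SpliceEvent(
                        EXON_SKIP, exons=tuple(run),
                        span=gspan(po[run[0] - 1][0], po[run[-1] - 1][1]),
                    )
                )
                run = []
    # alternative first exon: sub-exon usage, or exon 1 absent from the chain
    first_overlaps_e1 = bool(B) and min(B[0][1], po[0][1]) > max(B[0][0], po[0][0])
    if sub_hits or (covered and min(covered) > 1) or not first_overlaps_e1:
        start_exon = min(covered) if covered else None
        events.append(
            SpliceEvent(
                ALT_FIRST_EXON,
                exons=(start_exon,) if start_exon else (),
                sublabels=tuple(sub_hits),
                span=gspan(*B[0]),
            )
        )
    # alternative polyadenylation: chain 3' end off the model terminal end
    end = B[-1][1]
    if abs(end - po[-1][1]) > polya_tol:
        idx = None
        for k in range(len(model.polya_signals)):
            if abs(model.cleavage_oriented(k) - end) <= polya_tol:
                idx = k
                break
        events.append(
            SpliceEvent(ALT_POLYA, polya_index=idx, span=gspan(po[-1][1], max(end, po[-1][1] + 1)))
        )
    uniq: dict[tuple, SpliceEvent] = {}
    for ev in events:
        uniq.setdefault(ev.signature(), ev)
    return sorted(uniq.values(), key=lambda e: (e.span or (0, 0), e.kind))
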