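"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the interval-walking implementation under test:
the splice oracle works on per-base coverage *sets*, and the translation
oracle uses a literal codon dictionary and positional lists.
"""

from __future__ import annotations

import numpy as np

from venomiso._coords import obase
from venomiso.models import GeneModel
from venomiso.simulate import EventSpec
from venomiso.splicing import (
    ALT_ACCEPTOR,
    ALT_DONOR,
    ALT_FIRST_EXON,
    ALT_POLYA,
    EXON_SKIP,
    INTRON_RETENTION,
    PARTIAL_INTRON_RETENTION,
    ExonChain,
)

# --------------------------------------------------------------------------
# splice-event oracle (per-base set algebra)


def oracle_event_tokens(
    chain: ExonChain, model: GeneModel, min_partial: int = 10, polya_tol: int = 8
) -> set[str]:
    cov: set[int] = set()
    for a, b in chain.oriented():
        cov.update(range(a, b))
    po = model.oriented_primary()
    n = len(po)
    toks: set[str] = set()

    covered = {i for i in range(1, n + 1) if cov & set(range(*po[i - 1]))}
    if not covered:
        return toks
    lo, hi = min(covered), max(covered)

    # exon skipping: maximal uncovered runs strictly inside the covered range
    run: list[int] = []
    for i in range(lo, hi + 2):
        if i <= hi and i not in covered:
            run.append(i)
        elif run:
            toks.add(f"{EXON_SKIP}:{','.join(map(str, run))}")
            run = []

    # intron retention, partial retention
    for i in range(1, n):
        ia, ib = po[i - 1][1], po[i][0]
        iset = set(range(ia, ib))
        if iset <= cov:
            toks.add(f"{INTRON_RETENTION}:{i}")
            continue
        k = 0
        while ia + k in cov:
            k += 1
        if (ia - 1) in cov and min_partial <= k < ib - ia:
            toks.add(f"{PARTIAL_INTRON_RETENTION}:{i}:donor")
        j = 0
        while ib - 1 - j in cov:
            j += 1
        if ib in cov and min_partial <= j < ib - ia:
            toks.add(f"{PARTIAL_INTRON_RETENTION}:{i}:acceptor")

    # inward boundary shifts at annotated junctions
    for i in sorted(covered):
        ea, eb = po[i - 1]
        exon_cov = cov & set(range(ea, eb))
        if (eb - 1) not in exon_cov and any(p >= eb for p in cov):
            if i < n:
                toks.add(f"{ALT_DONOR}:{i}")
        if ea not in exon_cov and any(p < ea for p in cov):
            toks.add(f"{ALT_ACCEPTOR}:{i}")

    # alternative first exon (sub-exon usage or exon 1 absent)
    sub_hits = [
        e.sublabel
        for e in sorted(model.sub_exons, key=lambda e: e.interval.oriented()[0])
        if cov & set(range(*e.interval.oriented()))
    ]
    if sub_hits or lo > 1:
        toks.add(f"{ALT_FIRST_EXON}:{','.join(sub_hits) or '.'}")

    # alternative polyadenylation
    end = max(cov) + 1
    if abs(end - po[-1][1]) > polya_tol:
        idx = "?"
        for k in range(len(model.polya_signals)):
            if abs(model.cleavage_oriented(k) - end) <= polya_tol:
                idx = k
                break
        toks.add(f"{ALT_POLYA}:{idx}")
    return toks


# --------------------------------------------------------------------------
# translation oracle

_CODE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_BASES):
    for _j, _b in enumerate(_BASES):
        for _k, _c in enumerate(_BASES):
            _CODE[_a + _b + _c] = _AAS[16 * _i + 4 * _j + _k]


def oracle_translate(body: str, start: int) -> str:
    prot = []
    for i in range(start, len(body) - 2, 3):
        aa = _CODE[body[i : i + 3]]
        if aa == "*":
            break
        prot.append(aa)
    return "".join(prot)


def oracle_protein(body: str, chain: ExonChain, model: GeneModel) -> str | None:
    """Start location + single-frame translation via positional lists."""
    positions: list[int] = []
    for a, b in chain.oriented():
        positions.extend(range(a, b))
    p = obase(model.start_codon_genomic, model.strand)
    if p in positions:
        t = positions.index(p)
        if body[t : t + 3] != "ATG":
            return None
        return oracle_translate(body, t)
    i = body.find("ATG")
    return oracle_translate(body, i) if i >= 0 else None


# --------------------------------------------------------------------------
# random event plans for property tests


def random_events(
    rng: np.random.Generator, model: GeneModel, max_events: int = 3
) -> tuple[EventSpec, ...]:
    """A random non-conflicting event combination valid for the model.

    Each event claims a window of exon indices; claimed windows are kept
    disjoint so the injected events compose without interacting.
    """
    n = len(model.primary_exons)
    po = model.oriented_primary()
    subs = sorted({e.sublabel for e in model.sub_exons})
    kinds = [EXON_SKIP, INTRON_RETENTION, PARTIAL_INTRON_RETENTION, ALT_DONOR, ALT_ACCEPTOR, ALT_POLYA]
    if subs:
        kinds.append(ALT_FIRST_EXON)
    claimed: set[int] = set()
    events: list[EventSpec] = []
    for _ in range(int(rng.integers(0, max_events + 1))):
        kind = kinds[int(rng.integers(0, len(kinds)))]
        if kind == EXON_SKIP and n > 3:
            i = int(rng.integers(2, n))
            claim = {i - 1, i, i + 1}
            ev = EventSpec(EXON_SKIP, exons=(i,))
        elif kind == INTRON_RETENTION and n > 2:
            i = int(rng.integers(1, n))
            claim = {i, i + 1}
            ev = EventSpec(INTRON_RETENTION, intron=i)
        elif kind == PARTIAL_INTRON_RETENTION and n > 2:
            i = int(rng.integers(1, n))
            ia, ib = po[i - 1][1], po[i][0]
            if ib - ia <= 12:
                continue
            off = int(rng.integers(10, ib - ia))
            side = "donor" if rng.integers(0, 2) else "acceptor"
            claim = {i, i + 1}
            ev = EventSpec(PARTIAL_INTRON_RETENTION, intron=i, side=side, offset=off)
        elif kind == ALT_DONOR:
            i = int(rng.integers(2, n))
            ln = po[i - 1][1] - po[i - 1][0]
            off = int(rng.integers(1, max(2, ln - 10)))
            claim = {i, i + 1}
            ev = EventSpec(ALT_DONOR, exons=(i,), offset=off)
        elif kind == ALT_ACCEPTOR:
            i = int(rng.integers(2, n))
            ln = po[i - 1][1] - po[i - 1][0]
            off = int(rng.integers(1, max(2, ln - 10)))
            claim = {i - 1, i}
            ev = EventSpec(ALT_ACCEPTOR, exons=(i,), offset=off)
        elif kind == ALT_POLYA and len(model.polya_signals) > 1:
            k = int(rng.integers(1, len(model.polya_signals)))
            claim = {n}
            ev = EventSpec(ALT_POLYA, polya_index=k)
        elif kind == ALT_FIRST_EXON and subs:
            s = subs[int(rng.integers(0, len(subs)))]
            keep = bool(rng.integers(0, 2))
            claim = {1, 2}
            ev = EventSpec(ALT_FIRST_EXON, sublabels=(s,), keep_first=keep)
        else:
            continue
        if claim & claimed:
            continue
        claimed |= claim
        events.append(ev)
    return tuple(events)
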