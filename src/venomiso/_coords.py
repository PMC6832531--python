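"""Strand-oriented coordinate arithmetic.

Internal convention: genomic intervals are 0-based half-open on the scaffold.
All splice logic runs on a *transcription axis*: for a '+' gene the axis is
the scaffold coordinate; for a '-' gene it is the mirrored coordinate ``-x``,
so that 5'->3' order is always ascending and "downstream" always means
"larger".  ``obase``/``gbase`` convert a single base, ``oiv``/``giv`` an
interval.
"""

from __future__ import annotations

from typing import Sequence

Interval = tuple[int, int]


def obase(g: int, strand: str) -> int:
    """Oriented position of the base occupying [g, g+1)."""
    return g if strand == "+" else -(g + 1)


def gbase(p: int, strand: str) -> int:
    """Scaffold coordinate of the base at oriented position p."""
    return p if strand == "+" else -(p + 1)


def oiv(start: int, end: int, strand: str) -> Interval:
    """Oriented half-open interval for scaffold interval [start, end)."""
    return (start, end) if strand == "+" else (-end, -start)


def giv(a: int, b: int, strand: str) -> Interval:
    """Scaffold half-open interval for oriented interval [a, b)."""
    return (a, b) if strand == "+" else (-b, -a)


def oriented_blocks(blocks: Sequence[Interval], strand: str) -> list[Interval]:
    """Blocks (scaffold ascending) re-expressed in transcription order."""
    if strand == "+":
        return [tuple(b) for b in blocks]
    return [oiv(s, e, "-") for s, e in reversed(list(blocks))]


def blocks_length(blocks: Sequence[Interval]) -> int:
    return sum(e - s for s, e in blocks)


def transcript_of(oblocks: Sequence[Interval], p: int) -> int | None:
    """Transcript coordinate of oriented base p, or None if unspliced."""
    t = 0
    for a, b in oblocks:
        if a <= p < b:
            return t + (p - a)
        t += b - a
    return None


def genomic_of(oblocks: Sequence[Interval], tpos: int) -> int:
    """Oriented coordinate of transcript base tpos (raises if off the end)."""
    t = 0
    for a, b in oblocks:
        if t <= tpos < t + (b - a):
            return a + (tpos - t)
        t += b - a
    raise IndexError(f"transcript position {tpos} beyond spliced length {t}")


def junctions_of(oblocks: Sequence[Interval]) -> tuple[Interval, ...]:
    """(donor_end, acceptor_start) oriented pairs between consecutive blocks."""
    return tuple(
        (oblocks[i][1], oblocks[i + 1][0]) for i in range(len(oblocks) - 1)
    )
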