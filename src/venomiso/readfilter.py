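"""Full-length classification of long cDNA reads.

A read counts as full-length only when it carries both a translation start
(the model's canonical start Met, or a legitimate new in-chain start for
alternative-first-exon variants) and a polyadenylation signal: an AATAAA
hexamer a short distance upstream of a terminal polyA tail.  Reads failing
either check are "short" and excluded from isoform cataloging.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from .models import GeneModel
from .orf import locate_start
from .splicing import ExonChain

FULL_LENGTH = "full_length"
MISSING_START = "missing_start"
MISSING_POLYA = "missing_polya"
MISSING_BOTH = "missing_both"

#: minimum run of terminal A's accepted as a polyA tail.
MIN_TAIL = 10

#: allowed distance (nt) from the AATAAA hexamer start to the tail start.
SIGNAL_WINDOW = (10, 46)

#: without a model, a start ATG is searched in this 5' window of the read.
FIVE_PRIME_WINDOW = 100


@dataclass(frozen=True)
class FullLengthStatus:
    read_id: str
    status: str
    start_tpos: int | None
    start_kind: str | None  # 'canonical' | 'internal' | 'window'
    polya_signal_pos: int | None  # read coordinate of the AATAAA hexamer
    tail_length: int


def classify_read(
    read_sequence: str,
    exon_chain: ExonChain | None,
    assigned_model: GeneModel | None,
    min_tail: int = MIN_TAIL,
    signal_window: tuple[int, int] = SIGNAL_WINDOW,
    five_prime_window: int = FIVE_PRIME_WINDOW,
) -> FullLengthStatus:
    """Classify one read as full-length / missing start / missing polyA / both."""
    if not read_sequence:
        raise ValueError("empty read sequence")
    seq = read_sequence.upper()
    rid = exon_chain.read_id if exon_chain else "read"

    if exon_chain is not None and exon_chain.length <= len(seq):
        body = seq[: exon_chain.length]
        tail_len = len(seq) - exon_chain.length
    else:
        stripped = seq.rstrip("A")
        tail_len = len(seq) - len(stripped)
        body = stripped

    sig_pos = None
    lo, hi = signal_window
    if tail_len >= min_tail:
        window_start = max(0, len(body) - hi)
        idx = body.rfind("AATAAA", window_start)
        if idx >= 0 and lo <= len(body) - idx <= hi:
            sig_pos = idx
    polya_ok = sig_pos is not None

    start = None
    if assigned_model is not None and exon_chain is not None:
        start = locate_start(body, exon_chain, assigned_model)
    else:
        i = body[:five_prime_window].find("ATG")
        if i >= 0:
            start = (i, "window")
    start_ok = start is not None

    if start_ok and polya_ok:
        status = FULL_LENGTH
    elif start_ok:
        status = MISSING_POLYA
    elif polya_ok:
        status = MISSING_START
    else:
        status = MISSING_BOTH
    return FullLengthStatus(
        read_id=rid,
        status=status,
        start_tpos=start[0] if start else None,
        start_kind=start[1] if start else None,
        polya_signal_pos=sig_pos,
        tail_length=tail_len,
    )


def filter_batch(
    reads: Mapping[str, str],
    chains: Mapping[str, ExonChain],
    models: Mapping[str, GeneModel | None],
) -> tuple[list[str], list[str], Counter, dict[str, FullLengthStatus]]:
    """Partition reads into kept (full-length) and discarded, with counts.

    ``models`` maps read_id to the model used for the start check (None for
    unassigned reads).  Every read lands in exactly one of kept/discarded.
    """
    kept, discarded = [], []
    counts: Counter = Counter()
    statuses: dict[str, FullLengthStatus] = {}
    for rid in sorted(reads):
        st = classify_read(reads[rid], chains.get(rid), models.get(rid))
        statuses[rid] = st
        counts[st.status] += 1
        (kept if st.status == FULL_LENGTH else discarded).append(rid)
    return kept, discarded, counts, statuses
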