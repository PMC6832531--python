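"""Variant collapsing, trans-splicing chimera detection and summaries.

Full-length reads assigned to one gene are collapsed into named variants by
structural identity (exact junction chain + polyA-site class + start class);
single-nucleotide differences never split a variant.  Reads spanning several
tandem genes are segmented into donor (gene, exon-range) pieces and reported
as trans-spliced chimeras when the donors belong to one gene cluster in
colinear order.  Summaries aggregate per gene and per family, flagging the
families that show alternative splicing at all.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .models import GeneCluster, GeneModel
from .orf import MpType, OrfResult
from .splicing import ExonChain, SpliceEvent, encode_events

#: chain 3' ends within this distance of an annotated cleavage point share
#: a polyA-site class.
POLYA_CLASS_TOLERANCE = 8


class ConservationError(AssertionError):
    """Read support and assigned-read counts disagree."""


@dataclass
class ReadCall:
    """Everything the pipeline knows about one kept, single-gene read."""

    read_id: str
    gene_id: str
    chain: ExonChain
    events: list[SpliceEvent]
    orf: OrfResult
    mp_type: MpType | None


def polya_class(chain: ExonChain, model: GeneModel, tol: int = POLYA_CLASS_TOLERANCE) -> str:
    end = chain.oriented()[-1][1]
    for k in range(len(model.polya_signals)):
        if abs(model.cleavage_oriented(k) - end) <= tol:
            return f"pA{k}"
    return f"pA?{end}"


def start_class(orf: OrfResult, chain: ExonChain) -> str:
    if orf.start_kind == "canonical":
        return "canonical"
    return f"internal@{chain.transcript_to_genomic(orf.start_tpos)}"


@dataclass
class VariantRecord:
    gene_id: str
    name: str
    chain: ExonChain
    events: list[SpliceEvent]
    support: int
    orf: OrfResult
    mp_type: MpType | None
    is_original: bool
    polya_site: str
    read_ids: list[str]

    @property
    def event_string(self) -> str:
        return encode_events(self.events)


def collapse_variants(calls: Sequence[ReadCall], models: Mapping[str, GeneModel]) -> list[VariantRecord]:
    """Collapse reads into named variants per gene.

    Variant key = (exact junction chain, polyA-site class, start class).
    Names are gene-vN with v1 the original when present, then descending
    read support; ties break by 5' genomic coordinate then key hash.
    """
    groups: dict[tuple, list[ReadCall]] = {}
    for call in sorted(calls, key=lambda c: c.read_id):
        model = models[call.gene_id]
        key = (
            call.gene_id,
            call.chain.junctions(),
            polya_class(call.chain, model),
            start_class(call.orf, call.chain),
        )
        groups.setdefault(key, []).append(call)
    records: list[VariantRecord] = []
    per_gene: dict[str, list[tuple]] = {}
    for key, members in groups.items():
        rep = members[0]
        item = (key, rep, len(members))
        per_gene.setdefault(rep.gene_id, []).append(item)
    for gene_id in sorted(per_gene):
        items = per_gene[gene_id]

        def order(item):
            key, rep, support = item
            original = len(rep.events) == 0
            digest = hashlib.md5(repr(key).encode()).hexdigest()
            return (
                0 if original else 1,
                -support,
                rep.chain.oriented()[0][0],
                digest,
            )

        for v, (key, rep, support) in enumerate(sorted(items, key=order), start=1):
            members = groups[key]
            records.append(
                VariantRecord(
                    gene_id=gene_id,
                    name=f"{gene_id}-v{v}",
                    chain=rep.chain,
                    events=rep.events,
                    support=support,
                    orf=rep.orf,
                    mp_type=rep.mp_type,
                    is_original=len(rep.events) == 0,
                    polya_site=polya_class(rep.chain, models[gene_id]),
                    read_ids=[m.read_id for m in members],
                )
            )
    return records


@dataclass
class ChimeraRecord:
    chimera_id: str
    cluster_id: str
    segments: tuple[tuple[str, int, int], ...]  # (gene_id, first_exon, last_exon)
    support: int
    read_ids: list[str]


def _segment_chain(
    chain: ExonChain, models: Sequence[GeneModel]
) -> list[tuple[str, int, int]]:
    """Label each block with its best-overlap (gene, exon) and merge runs."""
    segs: list[tuple[str, int, int]] = []
    for s, e in chain.blocks:
        best = None
        for m in models:
            if m.scaffold != chain.scaffold:
                continue
            for ex in m.primary_exons:
                ov = ex.interval.overlap_len((s, e))
                if ov > 0 and (best is None or ov > best[0]):
                    best = (ov, m.gene_id, ex.index)
        if best is None:
            continue
        _, gid, idx = best
        if segs and segs[-1][0] == gid:
            lo, hi = segs[-1][1], segs[-1][2]
            segs[-1] = (gid, min(lo, idx), max(hi, idx))
        else:
            segs.append((gid, idx, idx))
    return segs


def detect_chimeras(
    chains: Sequence[ExonChain],
    clusters: Sequence[GeneCluster],
    models: Sequence[GeneModel],
    require_adjacent: bool = False,
) -> tuple[list[ChimeraRecord], list[str]]:
    """Detect trans-spliced chimeras among multi-gene chains.

    A chain qualifies when its donor segments come from >=2 distinct genes
    that all belong to one cluster, in strictly increasing cluster order
    (i.e. colinear along the tandem array).  With ``require_adjacent`` the
    donors must additionally be consecutive cluster members.  Returns
    (records, rejected read ids).
    """
    by_cluster: dict[str, GeneCluster] = {c.cluster_id: c for c in clusters}
    gene_to_cluster: dict[str, str] = {}
    for c in clusters:
        for g in c.genes:
            gene_to_cluster[g] = c.cluster_id
    groups: dict[tuple, list[ExonChain]] = {}
    rejected: list[str] = []
    for chain in sorted(chains, key=lambda c: c.read_id):
        segs = tuple(_segment_chain(chain, models))
        donors = [g for g, _, _ in segs]
        if len(segs) < 2 or len(set(donors)) != len(donors):
            rejected.append(chain.read_id)
            continue
        cids = {gene_to_cluster.get(g) for g in donors}
        if len(cids) != 1 or None in cids:
            rejected.append(chain.read_id)
            continue
        cluster = by_cluster[next(iter(cids))]
        ranks = [cluster.rank(g) for g in donors]
        if ranks != sorted(ranks):
            rejected.append(chain.read_id)
            continue
        if require_adjacent and any(b - a != 1 for a, b in zip(ranks, ranks[1:])):
            rejected.append(chain.read_id)
            continue
        groups.setdefault((cluster.cluster_id, segs), []).append(chain)
    records = []
    for k, (key, members) in enumerate(sorted(groups.items()), start=1):
        cid, segs = key
        records.append(
            ChimeraRecord(
                chimera_id=f"chimera{k:02d}",
                cluster_id=cid,
                segments=segs,
                support=len(members),
                read_ids=[c.read_id for c in members],
            )
        )
    return records, rejected


@dataclass
class CatalogSummary:
    per_gene: dict[str, dict]
    per_family: dict[str, dict]
    chimera_cluster_count: int
    chimera_count: int
    unassigned_reads: int
    as_families: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_gene": self.per_gene,
                "per_family": self.per_family,
                "chimera_cluster_count": self.chimera_cluster_count,
                "chimera_count": self.chimera_count,
                "unassigned_reads": self.unassigned_reads,
                "as_families": self.as_families,
            },
            indent=2,
            sort_keys=True,
        )


def summarize(
    variants: Sequence[VariantRecord],
    chimeras: Sequence[ChimeraRecord],
    models: Sequence[GeneModel],
    unassigned_reads: int = 0,
    assigned_counts: Mapping[str, int] | None = None,
) -> CatalogSummary:
    """Aggregate the catalog per gene and per family.

    Enforces the conservation invariant: per-gene variant supports must sum
    to the number of assigned full-length reads of that gene (chimeric reads
    are tallied separately and never double-counted).
    """
    fam_of = {m.gene_id: m.family for m in models}
    per_gene: dict[str, dict] = {}
    for m in sorted(models, key=lambda m: m.gene_id):
        per_gene[m.gene_id] = {
            "family": m.family,
            "variant_count": 0,
            "structural_variant_count": 0,
            "read_support": 0,
            "event_kinds": {},
            "mp_types": {},
        }
    structural_keys: dict[str, set] = {}
    for v in variants:
        g = per_gene.setdefault(
            v.gene_id,
            {
                "family": fam_of.get(v.gene_id, "other"),
                "variant_count": 0,
                "structural_variant_count": 0,
                "read_support": 0,
                "event_kinds": {},
                "mp_types": {},
            },
        )
        g["variant_count"] += 1
        g["read_support"] += v.support
        skey = (v.chain.junctions(), start_class(v.orf, v.chain))
        structural_keys.setdefault(v.gene_id, set()).add(skey)
        for ev in v.events:
            g["event_kinds"][ev.kind] = g["event_kinds"].get(ev.kind, 0) + 1
        if v.mp_type is not None:
            label = v.mp_type.type_ or "non-functional"
            g["mp_types"][label] = g["mp_types"].get(label, 0) + 1
    for gid, keys in structural_keys.items():
        per_gene[gid]["structural_variant_count"] = len(keys)
    if assigned_counts is not None:
        for gid, info in per_gene.items():
            expected = assigned_counts.get(gid, 0)
            if info["read_support"] != expected:
                raise ConservationError(
                    f"{gid}: variant supports sum to {info['read_support']}, "
                    f"but {expected} full-length reads were assigned"
                )
    per_family: dict[str, dict] = {}
    for gid, info in per_gene.items():
        fam = info["family"]
        f = per_family.setdefault(
            fam, {"genes": 0, "variant_count": 0, "alternative_splicing": False}
        )
        f["genes"] += 1
        f["variant_count"] += info["variant_count"]
        non_original = info["variant_count"] - sum(
            1 for v in variants if v.gene_id == gid and v.is_original
        )
        if non_original > 0:
            f["alternative_splicing"] = True
    as_families = sorted(
        fam for fam, info in per_family.items() if info["alternative_splicing"]
    )
    return CatalogSummary(
        per_gene=per_gene,
        per_family=per_family,
        chimera_cluster_count=len({c.cluster_id for c in chimeras}),
        chimera_count=len(chimeras),
        unassigned_reads=unassigned_reads,
        as_families=as_families,
    )


def variants_table(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "gene_id": v.gene_id,
                "variant": v.name,
                "support": v.support,
                "is_original": v.is_original,
                "events": v.event_string,
                "polya_site": v.polya_site,
                "protein_length": len(v.orf.protein),
                "premature_stop": v.orf.premature,
                "frameshift": v.orf.frameshift,
                "stop_class": v.orf.stop_class,
                "mp_type": (v.mp_type.type_ or "non-functional") if v.mp_type else "",
                "reads": ",".join(v.read_ids),
            }
        )
    return pd.DataFrame(rows)


def chimeras_table(chimeras: Sequence[ChimeraRecord]) -> pd.DataFrame:
    rows = []
    for c in chimeras:
        rows.append(
            {
                "chimera_id": c.chimera_id,
                "cluster_id": c.cluster_id,
                "segments": "|".join(f"{g}:{lo}-{hi}" for g, lo, hi in c.segments),
                "donor_count": len(c.segments),
                "support": c.support,
                "reads": ",".join(c.read_ids),
            }
        )
    return pd.DataFrame(rows)
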