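"""End-to-end isoform cataloging: filter -> assign -> call -> project -> collapse.

Ties the stage modules together the way the command-line interface and the
test-bench scenarios use them: reads are classified full-length/short, exon
chains are assigned to gene models (multi-gene chains routed to chimera
detection), splice events are called, ORFs re-projected, variants collapsed
and summarized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .catalog import (
    CatalogSummary,
    ChimeraRecord,
    ReadCall,
    VariantRecord,
    collapse_variants,
    detect_chimeras,
    summarize,
)
from .models import GeneCluster, GeneModel
from .orf import project_orf, type_mp
from .readfilter import FULL_LENGTH, FullLengthStatus, classify_read
from .splicing import ExonChain, assign_gene, call_events, genes_touched


@dataclass
class PipelineResult:
    statuses: dict[str, FullLengthStatus]
    assignments: dict[str, str | None]
    calls: list[ReadCall]
    variants: list[VariantRecord]
    chimeras: list[ChimeraRecord]
    rejected_chimeras: list[str]
    unassigned_reads: list[str]
    summary: CatalogSummary


def run_pipeline(
    models: Sequence[GeneModel],
    clusters: Sequence[GeneCluster],
    reads: Mapping[str, str],
    chains: Mapping[str, ExonChain],
    junction_tol: int = 0,
) -> PipelineResult:
    by_id = {m.gene_id: m for m in models}
    statuses: dict[str, FullLengthStatus] = {}
    assignments: dict[str, str | None] = {}
    calls: list[ReadCall] = []
    multigene_chains: list[ExonChain] = []
    unassigned: list[str] = []
    assigned_counts: dict[str, int] = {}

    for rid in sorted(reads):
        chain = chains.get(rid)
        if chain is None:
            continue
        touched = genes_touched(chain, models)
        if len(touched) > 1:
            # start check against the 5'-most donor gene
            touched.sort(key=lambda g: by_id[g].span.oriented()[0])
            filter_model = by_id[touched[0]]
            st = classify_read(reads[rid], chain, filter_model)
            statuses[rid] = st
            assignments[rid] = "+".join(touched)
            if st.status == FULL_LENGTH:
                multigene_chains.append(chain)
            continue
        res = assign_gene(chain, models, junction_tol=junction_tol)
        model = by_id.get(res.gene_id) if res.gene_id else None
        st = classify_read(reads[rid], chain, model)
        statuses[rid] = st
        assignments[rid] = res.gene_id
        if st.status != FULL_LENGTH:
            continue
        if model is None:
            unassigned.append(rid)
            continue
        events = call_events(chain, model, junction_tol=junction_tol)
        orf = project_orf(reads[rid], chain, model, read_id=rid)
        mp = type_mp(orf, model) if model.family == "MP" else None
        calls.append(
            ReadCall(
                read_id=rid,
                gene_id=model.gene_id,
                chain=chain,
                events=events,
                orf=orf,
                mp_type=mp,
            )
        )
        assigned_counts[model.gene_id] = assigned_counts.get(model.gene_id, 0) + 1

    variants = collapse_variants(calls, by_id)
    chimeras, rejected = detect_chimeras(multigene_chains, clusters, models)
    summary = summarize(
        variants,
        chimeras,
        models,
        unassigned_reads=len(unassigned),
        assigned_counts=assigned_counts,
    )
    return PipelineResult(
        statuses=statuses,
        assignments=assignments,
        calls=calls,
        variants=variants,
        chimeras=chimeras,
        rejected_chimeras=rejected,
        unassigned_reads=unassigned,
        summary=summary,
    )
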