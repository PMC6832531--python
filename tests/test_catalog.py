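"""Variant collapsing, chimera detection, per-gene/per-family summaries."""

from __future__ import annotations

import pytest

from venomiso.catalog import (
    ConservationError,
    chimeras_table,
    detect_chimeras,
    summarize,
    variants_table,
)
from venomiso.pipeline import run_pipeline
from venomiso.simulate import ReadPlan, build_cluster, build_locus, emit_reads, scenario
from venomiso.splicing import ExonChain


class TestCollapse:
    def test_identical_reads_one_variant(self, mp17):
        m, s = mp17
        reads, chains, _ = emit_reads(
            [m], {m.scaffold: s}, [ReadPlan("v1", gene_id=m.gene_id, support=3)]
        )
        res = run_pipeline([m], [], dict(reads), {c.read_id: c for c in chains})
        assert len(res.variants) == 1
        v = res.variants[0]
        assert v.support == 3 and v.is_original and v.name == f"{m.gene_id}-v1"

    def test_polya_only_difference_two_variants_one_protein(self, mp17):
        from venomiso.simulate import EventSpec

        m, s = mp17
        reads, chains, _ = emit_reads(
            [m],
            {m.scaffold: s},
            [
                ReadPlan("a", gene_id=m.gene_id, support=2),
                ReadPlan(
                    "b",
                    gene_id=m.gene_id,
                    events=(EventSpec("ALT_POLYA", polya_index=1),),
                    support=1,
                ),
            ],
        )
        res = run_pipeline([m], [], dict(reads), {c.read_id: c for c in chains})
        assert len(res.variants) == 2
        assert len({v.orf.protein for v in res.variants}) == 1
        assert {v.polya_site for v in res.variants} == {"pA0", "pA1"}

    def test_vegf_suite_eight_variants(self, pipeline_results):
        res = pipeline_results["svVEGF_suite"]
        assert len(res.variants) == 8
        originals = [v for v in res.variants if v.is_original]
        assert len(originals) == 1 and originals[0].name == "svVEGF01-v1"

    def test_naming_deterministic_across_runs(self):
        outs = []
        for _ in range(2):
            b = scenario("svMP05_suite", seed=4)
            res = run_pipeline(b.models, b.clusters, b.reads_dict(), b.chains_dict())
            outs.append(
                [(v.name, v.support, v.event_string, v.read_ids) for v in res.variants]
            )
        assert outs[0] == outs[1]

    def test_variant_counts_match_planned_structures(self, bundles, pipeline_results):
        """100% recovery: one variant per distinct planned structure."""
        for name, b in bundles.items():
            truth = b.truth
            fl = truth[(truth.expected_status == "full_length") & (~truth.chimera)]
            planned = fl.groupby("gene_id")["variant_label"].nunique()
            res = pipeline_results[name]
            got = {}
            for v in res.variants:
                got[v.gene_id] = got.get(v.gene_id, 0) + 1
            assert got == planned.to_dict(), name


class TestChimeras:
    def test_two_and_three_donor_records(self, pipeline_results):
        res = pipeline_results["svSP_clusters"]
        assert len(res.chimeras) == 6
        donors = sorted(len(c.segments) for c in res.chimeras)
        assert donors == [2, 2, 2, 2, 2, 3]
        three = next(c for c in res.chimeras if len(c.segments) == 3)
        assert three.segments == (
            ("svSP04", 1, 3),
            ("svSP05", 4, 5),
            ("svSP08", 6, 6),
        )
        assert all(c.support == 2 for c in res.chimeras)

    def test_single_gene_chain_is_not_a_chimera(self, mp17):
        m, s = mp17
        reads, chains, _ = emit_reads(
            [m], {m.scaffold: s}, [ReadPlan("v1", gene_id=m.gene_id)]
        )
        records, rejected = detect_chimeras(chains, [], [m])
        assert records == [] and rejected == [c.read_id for c in chains]

    def test_cross_cluster_chain_rejected(self):
        from venomiso.models import build_clusters

        c1, (g1, g2), _ = build_cluster(["SP6", "SP6"], 13, gene_ids=["g1", "g2"])
        g3, _ = build_locus(
            "SP6", 14, scaffold=g1.scaffold, gene_id="g3", origin=200_000
        )
        clusters = build_clusters([g1, g2, g3])
        assert len(clusters) == 2
        e = lambda m, i: (
            m.primary_exons[i - 1].interval.start,
            m.primary_exons[i - 1].interval.end,
        )
        chain = ExonChain("bad", g1.scaffold, "+", (e(g1, 1), e(g3, 6)))
        records, rejected = detect_chimeras([chain], clusters, [g1, g2, g3])
        assert records == [] and rejected == ["bad"]

    def test_adjacency_flag_rejects_rank_skips(self, bundles):
        b = bundles["svSP_clusters"]
        multi = [
            c
            for c in b.chains
            if b.truth.set_index("read_id").loc[c.read_id, "chimera"]
        ]
        strict, _ = detect_chimeras(multi, b.clusters, b.models, require_adjacent=True)
        loose, _ = detect_chimeras(multi, b.clusters, b.models)
        skipping = {("svSP04", 1, 3), ("svSP08", 4, 6)}
        assert any(set(c.segments) == skipping for c in loose)
        assert not any(set(c.segments) == skipping for c in strict)


class TestSummarize:
    def test_family18_flags_exactly_three_families(self, pipeline_results):
        res = pipeline_results["family18"]
        assert res.summary.as_families == ["MP", "SP", "VEGF"]
        # negative controls: the 15 other families have exactly one original
        for gid, info in res.summary.per_gene.items():
            if info["family"] not in ("MP", "SP", "VEGF"):
                assert info["variant_count"] == 1, gid
                assert info["event_kinds"] == {}, gid

    def test_all_original_simulation_zero_families(self, pipeline_results):
        res = pipeline_results["svMP11_noAS"]
        assert res.summary.as_families == []
        assert len(res.variants) == 1

    def test_chimera_cluster_count_two(self, pipeline_results):
        res = pipeline_results["svSP_clusters"]
        assert res.summary.chimera_cluster_count == 2

    def test_conservation_enforced(self, pipeline_results, bundles):
        # holds on every scenario by construction...
        for name, res in pipeline_results.items():
            for gid, info in res.summary.per_gene.items():
                support = sum(v.support for v in res.variants if v.gene_id == gid)
                assert support == info["read_support"]
        # ...and a wrong count raises
        res = pipeline_results["svMP11_noAS"]
        with pytest.raises(ConservationError):
            summarize(
                res.variants,
                res.chimeras,
                bundles["svMP11_noAS"].models,
                assigned_counts={"svMP11": 99},
            )

    def test_tables_are_well_formed(self, pipeline_results):
        res = pipeline_results["svSP_clusters"]
        vt = variants_table(res.variants)
        ct = chimeras_table(res.chimeras)
        assert len(vt) == len(res.variants) and len(ct) == len(res.chimeras)
        assert res.summary.to_json().startswith("{")
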