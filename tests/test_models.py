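"""Gene-model invariants, GFF3 round trips, exon gain/loss, clustering."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomiso.models import (
    ExonEditEvent,
    Gff3ParseError,
    GenomicInterval,
    ModelError,
    build_clusters,
    derive_model,
    read_gene_models,
    write_gene_models,
)
from venomiso.simulate import build_locus

# exon counts of the eleven metalloproteinase genes, svMP01..svMP11
MP_EXON_COUNTS = (17, 17, 17, 15, 17, 13, 15, 15, 17, 15, 17)
_TPL = {17: "MP17", 15: "MP15", 13: "MP13"}


def _mp_family_models():
    models, seqs = [], {}
    origin = 0
    for i, n in enumerate(MP_EXON_COUNTS, start=1):
        m, s = build_locus(
            _TPL[n], 100 + i, scaffold="sc_mpfam", gene_id=f"svMP{i:02d}", origin=origin
        )
        models.append(m)
        origin += len(s) + 800
    return models


class TestInterval:
    def test_rejects_degenerate(self):
        with pytest.raises(ModelError):
            GenomicInterval("s", 10, 10)
        with pytest.raises(ModelError):
            GenomicInterval("s", 5, 3)
        with pytest.raises(ModelError):
            GenomicInterval("s", 0, 5, strand="?")

    def test_oriented_is_ascending_on_both_strands(self):
        plus = GenomicInterval("s", 10, 20, "+").oriented()
        minus = GenomicInterval("s", 10, 20, "-").oriented()
        assert plus == (10, 20)
        assert minus == (-20, -10)
        assert plus[0] < plus[1] and minus[0] < minus[1]


class TestGff3RoundTrip:
    def test_mp_family_fixture(self):
        models = _mp_family_models()
        text = write_gene_models(models, build_clusters(models))
        back, clusters = read_gene_models(text)
        assert [len(m.primary_exons) for m in back] == list(MP_EXON_COUNTS)
        for a, b in zip(models, sorted(back, key=lambda m: m.gene_id)):
            assert a.gene_id == b.gene_id
            assert [(e.index, e.sublabel, e.interval) for e in a.exons] == [
                (e.index, e.sublabel, e.interval) for e in b.exons
            ]
            assert (a.cds_start, a.cds_end) == (b.cds_start, b.cds_end)
            assert a.domain_blocks == b.domain_blocks
            assert a.motifs == b.motifs
            assert a.catalytic_residues == b.catalytic_residues
            assert a.polya_signals == b.polya_signals
        assert len(clusters) == 1 and clusters[0].genes == [m.gene_id for m in models]

    def test_sub_exon_labels_preserved(self):
        m, _ = build_locus("MP17", 5, gene_id="g", sub_exons=4)
        back, _ = read_gene_models(write_gene_models([m]))
        assert [e.sublabel for e in back[0].exons if not e.is_primary] == ["b", "c", "d", "e"]

    @pytest.mark.parametrize("seed", range(25))
    def test_random_loci_round_trip_and_byte_stability(self, seed):
        tpl = ["MP17", "MP15", "MP13", "SP6", "VEGF6", "PLA2_4"][seed % 6]
        m, _ = build_locus(tpl, 1000 + seed, gene_id=f"g{seed}")
        text = write_gene_models([m])
        assert text == write_gene_models([m])  # byte-stable
        back, _ = read_gene_models(text)
        assert write_gene_models(back) == text

    def test_empty_input(self):
        models, clusters = read_gene_models("##gff-version 3\n")
        assert models == [] and clusters == []

    def test_malformed_line_names_line_number(self):
        bad = "##gff-version 3\nsc\tsrc\tgene\t1\t100\n"
        with pytest.raises(Gff3ParseError, match="line 2"):
            read_gene_models(bad)


class TestDeriveModel:
    def test_two_round_deletion_17_to_13(self, mp17):
        m, _ = mp17
        c1 = derive_model(m, [ExonEditEvent("loss", exon_indices=(15, 16))])
        assert len(c1.primary_exons) == 15
        assert not any(b.name == "cys_rich" for b in c1.domain_blocks)
        c2 = derive_model(c1, [ExonEditEvent("loss", exon_indices=(13, 14))])
        assert len(c2.primary_exons) == 13
        assert not any(b.name == "disintegrin" for b in c2.domain_blocks)
        # the parent's terminal exon survives both rounds
        assert c2.primary_exons[-1].interval == m.primary_exons[-1].interval

    def test_empty_events_is_identity(self, mp17):
        m, _ = mp17
        child = derive_model(m, [])
        assert [e.interval for e in child.exons] == [e.interval for e in m.exons]

    def test_sp_gains_two_utr_exons(self, sp6):
        m, _ = sp6
        child = derive_model(m, [ExonEditEvent("gain", after=6, count=2)])
        assert len(child.primary_exons) == 8
        # the gained exons are 3' of the stop codon: pure 3' UTR
        stop_t = child.cds_end
        assert child.genomic_to_transcript(
            child.primary_exons[6].interval.start
        ) >= stop_t

    def test_loss_of_missing_exon_is_an_error(self, mp17):
        m, _ = mp17
        with pytest.raises(ModelError, match="nonexistent"):
            derive_model(m, [ExonEditEvent("loss", exon_indices=(99,))])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(data=st.data())
    def test_exon_count_arithmetic(self, data, mp17):
        """count(child) == count(parent) - losses + gains for random sequences."""
        m, _ = mp17
        model = m
        expected = len(model.primary_exons)
        for _ in range(data.draw(st.integers(0, 3))):
            n = len(model.primary_exons)
            if n <= 4 or data.draw(st.booleans()):
                k = data.draw(st.integers(1, 2))
                model = derive_model(model, [ExonEditEvent("gain", after=n, count=k)])
                expected += k
            else:
                i = data.draw(st.integers(2, n - 1))
                model = derive_model(model, [ExonEditEvent("loss", exon_indices=(i,))])
                expected -= 1
        assert len(model.primary_exons) == expected


class TestClustering:
    def _brute_single_linkage(self, models, gap):
        # oracle: transitive closure over all pairs
        ids = [m.gene_id for m in models]
        spans = {m.gene_id: (m.scaffold, m.span.start, m.span.end) for m in models}
        parent = {g: g for g in ids}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a in ids:
            for b in ids:
                sa, s1, e1 = spans[a]
                sb, s2, e2 = spans[b]
                if sa == sb and max(s1, s2) - min(e1, e2) <= gap:
                    parent[find(a)] = find(b)
        groups = {}
        for g in ids:
            groups.setdefault(find(g), set()).add(g)
        return {frozenset(v) for v in groups.values()}

    @pytest.mark.parametrize("gap", [500, 2000, 10_000])
    def test_matches_brute_force(self, gap):
        models = []
        for i, off in enumerate([0, 5000, 6000, 30_000]):
            m, _ = build_locus(
                "PLA2_4", 50 + i, scaffold="scX", gene_id=f"g{i}", origin=off
            )
            models.append(m)
        got = {frozenset(c.genes) for c in build_clusters(models, gap=gap)}
        assert got == self._brute_single_linkage(models, gap)

    def test_two_genes_one_kb_apart_cluster_at_10kb(self):
        m1, s1 = build_locus("PLA2_4", 7, scaffold="scY", gene_id="a")
        m2, _ = build_locus("PLA2_4", 8, scaffold="scY", gene_id="b", origin=len(s1) + 1000)
        clusters = build_clusters([m1, m2], gap=10_000)
        assert len(clusters) == 1 and clusters[0].genes == ["a", "b"]

    def test_cluster_order_follows_genomic_order(self):
        m2, _ = build_locus("PLA2_4", 9, scaffold="scZ", gene_id="late", origin=3000)
        m1, _ = build_locus("PLA2_4", 10, scaffold="scZ", gene_id="early")
        (c,) = build_clusters([m2, m1], gap=50_000)
        assert c.genes == ["early", "late"]
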