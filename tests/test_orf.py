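"""ORF re-projection, motif back-mapping, catalytic status, MP typing."""

from __future__ import annotations

import pytest

from oracles import oracle_protein
from venomiso.models import (
    ExonModel,
    GeneModel,
    GenomicInterval,
    MotifAnnotation,
)
from venomiso.orf import (
    check_catalytic,
    locate_motifs,
    project_orf,
    type_mp,
)
from venomiso.simulate import EventSpec, ReadPlan, emit_reads
from venomiso.splicing import ExonChain


def _one_read(model, seq, events=()):
    reads, chains, _ = emit_reads(
        [model],
        {model.scaffold: seq},
        [ReadPlan("p", gene_id=model.gene_id, events=tuple(events))],
    )
    return reads[0][1], chains[0]


class TestProjectOrf:
    def test_original_equals_canonical_cds(self, mp17):
        m, s = mp17
        seq, chain = _one_read(m, s)
        orf = project_orf(seq, chain, m)
        cds = "".join(s[e.interval.start : e.interval.end] for e in m.primary_exons)[
            m.cds_start : m.cds_end
        ]
        assert orf.protein == oracle_protein(seq[: chain.length], chain, m)
        assert len(orf.protein) == (len(cds) - 3) // 3
        assert not orf.premature and not orf.frameshift
        assert orf.stop_class == "annotated_exon" and orf.stop_exon == "17"

    def test_retained_intron_12_premature_stop(self, mp17):
        m, s = mp17
        seq, chain = _one_read(m, s, [EventSpec("INTRON_RETENTION", intron=12)])
        orf = project_orf(seq, chain, m)
        assert orf.premature
        assert orf.stop_class == "retained_intron" and orf.stop_intron == 12

    def test_alt_polya_same_protein(self, mp17):
        """3'UTR-length variants translate the identical protein."""
        m, s = mp17
        seq0, chain0 = _one_read(m, s)
        seq1, chain1 = _one_read(m, s, [EventSpec("ALT_POLYA", polya_index=2)])
        orf0 = project_orf(seq0, chain0, m)
        orf1 = project_orf(seq1, chain1, m)
        assert orf0.protein == orf1.protein
        assert not orf1.premature and not orf1.frameshift

    def test_exon_skip_frameshift_flag(self, mp17):
        m, s = mp17
        seq, chain = _one_read(m, s, [EventSpec("EXON_SKIP", exons=(15,))])
        orf = project_orf(seq, chain, m)
        assert orf.frameshift and orf.premature
        assert orf.stop_class == "annotated_exon" and orf.stop_exon == "16"

    def test_matches_brute_force_on_every_simulated_read(self, bundles, pipeline_results):
        checked = 0
        for name, res in pipeline_results.items():
            by_id = {m.gene_id: m for m in bundles[name].models}
            reads = bundles[name].reads_dict()
            for call in res.calls:
                body = reads[call.read_id][: call.chain.length]
                assert call.orf.protein == oracle_protein(
                    body, call.chain, by_id[call.gene_id]
                ), (name, call.read_id)
                checked += 1
        assert checked > 100


class TestMotifs:
    def test_zinc_motif_in_exon_11(self, mp17):
        m, s = mp17
        seq, chain = _one_read(m, s)
        (status,) = locate_motifs(project_orf(seq, chain, m), m)
        assert status.found and status.exon_index == 11

    def test_truncated_protein_loses_motif(self, mp17):
        m, s = mp17
        seq, chain = _one_read(m, s, [EventSpec("INTRON_RETENTION", intron=7)])
        (status,) = locate_motifs(project_orf(seq, chain, m), m)
        assert not status.found

    def test_motif_straddling_exons_majority_codon(self):
        """Hand-built two-exon gene with the motif split 2/4 across the
        junction: the majority-codon exon wins (oracle: codon-by-codon map)."""
        # exon1: ATG + 2 motif codons; exon2: 4 motif codons + stop + polyA room
        e1 = "ATG" + "CAC" + "GAA"  # M H E
        e2 = "GGC" + "CAC" + "AAC" + "CTG" + "TAA" + "T" * 40
        seq = e1 + "GTTTAATTAATTAAAG" + e2
        i1 = (0, len(e1))
        i2 = (len(e1) + 16, len(e1) + 16 + len(e2))
        model = GeneModel(
            gene_id="tiny",
            family="other",
            exons=[
                ExonModel(1, None, GenomicInterval("t", *i1)),
                ExonModel(2, None, GenomicInterval("t", *i2)),
            ],
            cds_start=0,
            cds_end=24,
            motifs=[MotifAnnotation("m", "HEGHNL", None)],
            polya_signals=[i2[1] - 20],
        )
        chain = ExonChain("r", "t", "+", (i1, i2))
        body = e1 + e2
        orf = project_orf(body, chain, model)
        (status,) = locate_motifs(orf, model)
        # oracle: codon exon membership, middle base
        exon_of = []
        for k in range(status.protein_span[0] - 1, status.protein_span[1]):
            g = chain.transcript_to_genomic(orf.start_tpos + 3 * k + 1)
            exon_of.append(1 if i1[0] <= g < i1[1] else 2)
        majority = max(set(exon_of), key=exon_of.count)
        assert status.found and status.exon_index == majority == 2


class TestCatalytic:
    def test_intact_triad(self, sp6):
        m, s = sp6
        seq, chain = _one_read(m, s)
        states = {c.label: c.state for c in check_catalytic(project_orf(seq, chain, m), m)}
        assert states == {"His57": "present", "Asp102": "present", "Ser195": "present"}

    def test_early_stop_loses_ser195(self, sp6):
        m, s = sp6
        seq, chain = _one_read(m, s, [EventSpec("INTRON_RETENTION", intron=4)])
        states = {c.label: c.state for c in check_catalytic(project_orf(seq, chain, m), m)}
        assert states["His57"] == "present"
        assert states["Ser195"] == "absent"

    def test_engineered_his_to_arg_substitution(self, sp6):
        """Mutating the His57 codon in the genome reports 'substituted' R."""
        m, s = sp6
        g = m.transcript_to_genomic(m.cds_start + 56 * 3)
        mutated = s[:g] + "CGT" + s[g + 3 :]  # CAC(H) -> CGT(R)
        seq, chain = _one_read(m, mutated)
        states = {c.label: (c.state, c.observed) for c in check_catalytic(project_orf(seq, chain, m), m)}
        assert states["His57"] == ("substituted", "R")
        assert states["Ser195"][0] == "present"


class TestMpTyping:
    @pytest.mark.parametrize(
        "events,expected",
        [
            ((), "P-III"),
            ((EventSpec("INTRON_RETENTION", intron=14),), "P-II"),
            ((EventSpec("INTRON_RETENTION", intron=12),), "P-I"),
            ((EventSpec("INTRON_RETENTION", intron=7),), None),
        ],
    )
    def test_stop_position_determines_type(self, mp17, events, expected):
        m, s = mp17
        seq, chain = _one_read(m, s, events)
        mp = type_mp(project_orf(seq, chain, m), m)
        assert mp.type_ == expected
        assert mp.functional == (expected is not None)

    def test_monotonic_in_stop_position(self, mp17):
        """Moving the stop 5' through successive intron retentions never
        increases the structural type (P-III >= P-II >= P-I ordering)."""
        m, s = mp17
        ranks = []
        for intron in range(16, 6, -1):
            seq, chain = _one_read(m, s, [EventSpec("INTRON_RETENTION", intron=intron)])
            mp = type_mp(project_orf(seq, chain, m), m)
            ranks.append(mp.rank)
        assert ranks == sorted(ranks, reverse=True)

    def test_vegf_identical_protein_quartet(self, bundles, pipeline_results):
        """The four intron-3-retention structures give exactly one protein."""
        res = pipeline_results["svVEGF_suite"]
        quartet = [
            v for v in res.variants if "INTRON_RETENTION:3" in v.event_string
        ]
        assert len(quartet) == 4
        assert len({v.orf.protein for v in quartet}) == 1
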