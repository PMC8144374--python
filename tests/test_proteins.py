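"""Protein effect prediction: matching, splicing edits, translation,
localization, classification, prioritization and end-to-end annotation."""

import numpy as np
import pandas as pd
import pytest

from bbsplice.annotation import TranscriptModel, translate_transcript
from bbsplice.events import Junction, SpliceEvent, make_event_jid
from bbsplice.proteins import (
    PairCandidate,
    SpliceEditError,
    annotate_events,
    apply_splice,
    classify_effect,
    localize_alteration,
    match_transcripts,
    prioritize_pairs,
)
from bbsplice.simulate import SUPPORTED_CATALOG, make_toy_annotation


# ---------------------------------------------------------------------------
# hand-built inclusion/skip fixture: gene with a cassette exon
# ---------------------------------------------------------------------------

def _cassette_fixture(tmp_path):
    """One gene, two annotated transcripts: Tinc includes a 102-nt cassette
    exon that Tskip lacks."""
    utr5, utr3 = "CCTTCC", "TAAGTAAGTAAG"
    exon1_coding = "ATG" + "GAA" * 5          # 18 nt
    cassette = "CAC" * 34                      # 102 nt
    exon3_coding = "GTT" * 5 + "TAA"
    i1 = "GT" + "C" * 50 + "AG"
    i2 = "GT" + "C" * 50 + "AG"
    seq = utr5 + exon1_coding + i1 + cassette + i2 + exon3_coding + utr3
    e1 = (1, 6 + 18)
    c_start = e1[1] + len(i1) + 1
    cas = (c_start, c_start + 101)
    e3_start = cas[1] + len(i2) + 1
    e3 = (e3_start, len(seq))
    cds = (7, e3_start + 17)  # ATG .. TAA inclusive

    gtf = []
    for tid, exons in (("TINC", [e1, cas, e3]), ("TSKIP", [e1, e3])):
        attrs = f'gene_id "GC"; transcript_id "{tid}"; transcript_biotype "protein_coding";'
        gtf.append(f"toy\tx\ttranscript\t{exons[0][0]}\t{exons[-1][1]}\t.\t+\t.\t{attrs}")
        for s, e in exons:
            gtf.append(f"toy\tx\texon\t{s}\t{e}\t.\t+\t.\t{attrs}")
        for s, e in exons:
            cs, ce = max(s, cds[0]), min(e, cds[1] - 3)
            if cs <= ce:
                gtf.append(f"toy\tx\tCDS\t{cs}\t{ce}\t.\t+\t0\t{attrs}")
        gtf.append(f"toy\tx\tstop_codon\t{cds[1] - 2}\t{cds[1]}\t.\t+\t.\t{attrs}")
    (tmp_path / "g.gtf").write_text("\n".join(gtf) + "\n")
    (tmp_path / "g.fa").write_text(">toy\n" + seq + "\n")

    event = SpliceEvent(
        event_id="es", gene_id="GC", contig="toy", strand="+", event_type="ES",
        iso1_junctions=(Junction(e1[1], cas[0]), Junction(cas[1], e3[0])),
        iso2_junctions=(Junction(e1[1], e3[0]),),
    )
    from bbsplice.annotation import Annotation

    return Annotation(tmp_path / "g.gtf", tmp_path / "g.fa"), event


class TestMatchTranscripts:
    def test_cassette_fixture_matches_both_isoforms(self, tmp_path):
        ann, event = _cassette_fixture(tmp_path)
        matches = {m.transcript_id: m.matches for m in match_transcripts(event, ann)}
        assert matches == {"TINC": "iso1", "TSKIP": "iso2"}

    def test_unmatched_junctions_give_neither(self, tmp_path):
        ann, event = _cassette_fixture(tmp_path)
        shifted = SpliceEvent(
            "x", "GC", "toy", "+", "ES",
            iso1_junctions=tuple(Junction(j.donor_base + 6, j.acceptor_base + 6)
                                 for j in event.iso1_junctions),
            iso2_junctions=(Junction(event.iso1_junctions[0].donor_base + 6,
                                     event.iso1_junctions[1].acceptor_base + 6),),
        )
        assert all(m.matches == "neither" for m in match_transcripts(shifted, ann))

    def test_a3_acceptor_shift_matches_iso1_only(self, tmp_path):
        ann, event = _cassette_fixture(tmp_path)
        j = event.iso1_junctions[0]
        a3 = SpliceEvent("a3", "GC", "toy", "+", "A3",
                         iso1_junctions=(j,),
                         iso2_junctions=(Junction(j.donor_base, j.acceptor_base + 14),))
        matches = {m.transcript_id: m.matches for m in match_transcripts(a3, ann)}
        assert matches["TINC"] == "iso1"
        assert matches["TSKIP"] == "neither"

    def test_absent_gene_yields_unknown_effect(self, tmp_path):
        ann, event = _cassette_fixture(tmp_path)
        orphan = SpliceEvent("o", "NOGENE", event.contig, "+", "ES",
                             event.iso1_junctions, event.iso2_junctions)
        effects, _, _ = annotate_events([orphan], ann)
        assert effects.loc[0, "effect_cat"] == "Unknown"
        assert effects.loc[0, "aa_change_type"] == "Unknown"


class TestApplySplice:
    def test_skip_edit_matches_annotated_skip_transcript(self, tmp_path):
        ann, event = _cassette_fixture(tmp_path)
        tinc, tskip = ann.transcripts["TINC"], ann.transcripts["TSKIP"]
        edited = apply_splice(tinc, event, 1, 2)
        assert edited.exons == tskip.exons

    def test_round_trip_identity(self, tmp_path):
        ann, event = _cassette_fixture(tmp_path)
        tinc = ann.transcripts["TINC"]
        assert apply_splice(apply_splice(tinc, event, 1, 2), event, 2, 1).exons == tinc.exons

    def test_ir_retention_merges_exons(self, tmp_path):
        ann, event = _cassette_fixture(tmp_path)
        tskip = ann.transcripts["TSKIP"]
        d, a = tskip.introns[0]
        ir = SpliceEvent("ir", "GC", "toy", "+", "IR",
                         (Junction(d, a),), (), ir_interval=(d + 1, a - 1))
        merged = apply_splice(tskip, ir, 1, 2)
        assert len(merged.exons) == len(tskip.exons) - 1

    def test_mismatched_junctions_rejected(self, tmp_path):
        ann, event = _cassette_fixture(tmp_path)
        with pytest.raises(SpliceEditError):
            apply_splice(ann.transcripts["TSKIP"], event, 1, 2)


class TestTranslate:
    def _model(self, strand, exons, cds, tid="T"):
        return TranscriptModel(tid, "G", "c", strand, tuple(exons), cds)

    def test_forward_strand_standard_code(self, tmp_path):
        (tmp_path / "g.fa").write_text(">c\n" + "ATGAAATAG" + "\n")
        (tmp_path / "g.gtf").write_text(
            'c\tx\ttranscript\t1\t9\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'c\tx\texon\t1\t9\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'c\tx\tCDS\t1\t6\t.\t+\t0\tgene_id "G"; transcript_id "T";\n'
            'c\tx\tstop_codon\t7\t9\t.\t+\t.\tgene_id "G"; transcript_id "T";\n')
        from bbsplice.annotation import Annotation
        ann = Annotation(tmp_path / "g.gtf", tmp_path / "g.fa")
        assert translate_transcript(ann.transcripts["T"], ann) == "MK*"

    def test_reverse_strand_involution(self, tmp_path):
        from Bio.Seq import Seq
        rc = str(Seq("ATGAAATAG").reverse_complement())
        (tmp_path / "g.fa").write_text(">c\n" + rc + "\n")
        (tmp_path / "g.gtf").write_text(
            'c\tx\ttranscript\t1\t9\t.\t-\t.\tgene_id "G"; transcript_id "T";\n'
            'c\tx\texon\t1\t9\t.\t-\t.\tgene_id "G"; transcript_id "T";\n'
            'c\tx\tCDS\t4\t9\t.\t-\t0\tgene_id "G"; transcript_id "T";\n'
            'c\tx\tstop_codon\t1\t3\t.\t-\t.\tgene_id "G"; transcript_id "T";\n')
        from bbsplice.annotation import Annotation
        ann = Annotation(tmp_path / "g.gtf", tmp_path / "g.fa")
        assert translate_transcript(ann.transcripts["T"], ann) == "MK*"


class TestLocalize:
    def test_single_substitution(self):
        ref_pos, alt_pos, rp, ap = localize_alteration("MKLV*", "MKAV*")
        assert ref_pos == (3, 3) and alt_pos == (3, 3)
        assert (rp, ap) == ("L", "A")

    def test_identical_proteins_silent_shape(self):
        assert localize_alteration("MKV*", "MKV*") == (None, None, "", "")

    def test_frameshift_through_stop_keeps_stop_mark(self):
        """Reference runs 210 residues past the divergence, alternative stops
        5 residues after it: altered regions span through the stop marks."""
        prefix = "M" + "A" * 179
        ref = prefix + "R" + "Q" * 209 + "*"
        alt = prefix + "SSFQF*"
        ref_pos, alt_pos, rp, ap = localize_alteration(ref, alt)
        assert ref_pos == (181, 391)
        assert alt_pos == (181, 186)
        assert ap == "SSFQF*"
        assert rp.endswith("*")

    def test_pure_insertion_has_empty_reference_run(self):
        ref_pos, alt_pos, rp, ap = localize_alteration("MKV*", "MKAV*")
        assert rp == "" and ap == "A"
        assert ref_pos == (3, 2)  # insertion point, start > end
        assert alt_pos == (3, 3)


class TestClassify:
    def test_inframe_deletion(self):
        ref = "M" + "A" * 40 + "*"
        alt = "M" + "A" * 6 + "*"
        assert classify_effect(ref, alt, -102) == "Deletion"

    def test_frameshift_dominates(self):
        ref = "M" + "A" * 40 + "*"
        alt = "M" + "A" * 3 + "QRST*"
        assert classify_effect(ref, alt, -103) == "FrameDisruption"

    def test_noncoding_outside_cds(self):
        p = "MAV*"
        assert classify_effect(p, p, 0, event_overlaps_cds=False) == "NonCoding"

    def test_silent_when_identical(self):
        assert classify_effect("MAV*", "MAV*", 0) == "Silent"

    def test_truncation_on_early_stop(self):
        assert classify_effect("MAAAAAAA*", "MAA*", 0) == "Truncation"

    def test_stop_loss(self):
        assert classify_effect("MAV*", "MAVQQQ", 0) == "StopLoss"

    def test_insertion_by_positive_delta(self):
        assert classify_effect("MAV*", "MAQQV*", 6) == "Insertion"


class TestPrioritize:
    def _cand(self, tid, known, alt_pept, ref_protein):
        return PairCandidate(
            transcript=TranscriptModel(tid, "G", "c", "+", ((1, 10),), None),
            from_iso=1, to_iso=2, ref_protein=ref_protein, alt_protein="X",
            known_pair=known, cds_nt_delta=0, event_overlaps_cds=True,
            ref_pos=None, alt_pos=None, ref_pept="", alt_pept=alt_pept,
            effect_cat="Insertion")

    def test_known_pair_wins(self):
        a = self._cand("T1", True, "AB", "M" * 10)
        b = self._cand("T2", False, "ABCDEFGH", "M" * 90)
        assert prioritize_pairs([a, b]) is a

    def test_longest_altered_run_breaks_known_tie(self):
        a = self._cand("T1", True, "ABCDEFGHIJKL", "M" * 10)
        b = self._cand("T2", True, "ABCDE", "M" * 90)
        assert prioritize_pairs([a, b]) is a

    def test_longest_start_isoform_breaks_remaining_tie(self):
        a = self._cand("T1", True, "ABC", "M" * 10)
        b = self._cand("T2", True, "ABC", "M" * 90)
        assert prioritize_pairs([a, b]) is b

    def test_lexicographic_final_tie(self):
        a = self._cand("T2", True, "ABC", "M" * 10)
        b = self._cand("T1", True, "ABC", "M" * 10)
        assert prioritize_pairs([a, b]) is b

    def test_empty_candidates(self):
        assert prioritize_pairs([]) is None


class TestAnnotateEvents:
    def test_toy_catalog_reproduced_exactly(self, toy_fixture, toy_annotation):
        effects, known, novel = annotate_events(toy_fixture["events"], toy_annotation)
        expected = toy_fixture["expected_table"]
        got = effects.set_index("event_jid")
        for _, row in expected.iterrows():
            g = got.loc[row["event_jid"]]
            for col in ("event_cat", "effect_cat", "aa_change_type",
                        "ref_seq_header", "alt_seq_header",
                        "refSeqPos", "altSeqPos", "refPept", "altPept"):
                assert str(g[col]) == str(row[col]), (row["event_jid"], col)

    def test_peptides_refindable_in_fasta(self, toy_fixture, toy_annotation):
        effects, known, novel = annotate_events(toy_fixture["events"], toy_annotation)
        seqs = dict(known) | dict(novel)
        for _, row in effects.iterrows():
            for header_col, pos_col, pept_col in (
                    ("ref_seq_header", "refSeqPos", "refPept"),
                    ("alt_seq_header", "altSeqPos", "altPept")):
                pept = str(row[pept_col]).rstrip("*")
                if not pept:
                    continue
                seq = seqs[row[header_col]]
                start, end = (int(x) for x in str(row[pos_col]).split("-"))
                assert seq[start - 1:start - 1 + len(pept)] == pept

    def test_strand_mirroring_consistent(self, toy_fixture):
        """Every effect category appears correctly on both strands."""
        by_strand = {}
        for event, (_, row) in zip(toy_fixture["events"],
                                   toy_fixture["expected_table"].iterrows()):
            by_strand.setdefault(event.strand, []).append(row["effect_cat"])
        assert set(by_strand) == {"+", "-"}

    def test_novel_increased_filter(self, tmp_path, toy_fixture, toy_annotation):
        from bbsplice.proteins import filter_novel_increased

        jids = [make_event_jid(e) for e in toy_fixture["events"]]
        increased = {jid: {1: "CTRL", 2: "CASE"} for jid in jids}
        effects, _, _ = annotate_events(toy_fixture["events"], toy_annotation, increased)
        kept = filter_novel_increased(effects, "CASE")
        assert set(kept["event_jid"]) == set(
            effects.loc[effects["aa_change_type"] == "Novel", "event_jid"])
        assert len(kept) > 0

    def test_known_alt_when_peptide_in_other_isoform(self, tmp_path):
        """Skipping TINC's cassette gives an alternative protein identical to
        TSKIP's, so the (empty) altered run is known; both known transcripts
        make it the prioritized pair."""
        ann, event = _cassette_fixture(tmp_path)
        effects, known, novel = annotate_events([event], ann)
        assert effects.loc[0, "aa_change_type"] == "Known"
        assert novel == []
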