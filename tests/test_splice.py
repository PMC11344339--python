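"""Splice-event consequences: mRNA deltas, frame, protein HGVS, NMD, amplicons."""

import numpy as np
import pytest

from foundersplice.gene_model import parse_hgvs_c
from foundersplice.simulate import gen_transcript_fixture, naive_translate
from foundersplice.splice import (
    PrimerPair,
    SpliceEvent,
    apply_splice_event,
    apply_variant_to_transcript,
    consequence_report,
    find_ag_dinucleotides,
    frame_consequence,
    gel_match,
    predict_amplicon_sizes,
    predict_nmd,
    translate_consequence,
)


class TestApplySpliceEvent:
    @pytest.mark.parametrize("spec,delta", [
        ({"kind": "exon_skip", "target": 3, "length_nt": 322}, -322),
        ({"kind": "partial_intron_retention_3prime", "target": 4, "length_nt": 18}, +18),
        ({"kind": "exonic_acceptor_truncation", "target": 5, "length_nt": 59}, -59),
        ({"kind": "exon_skip", "target": 4, "length_nt": 138}, -138),
    ])
    def test_deltas_match_event_size(self, spec, delta):
        fx = gen_transcript_fixture(seed=10, n_exons=8, events=[{**spec, "label": "e"}])
        alt = apply_splice_event(fx.model, fx.events[0])
        assert alt.delta_nt == delta
        assert len(alt.mrna) - len(fx.wt_mrna) == delta          # conservation
        assert alt.mrna == fx.truth["e"].altered_mrna            # constructed truth

    def test_minus_strand_retention_uses_transcription_orientation(self):
        fx = gen_transcript_fixture(
            seed=11, n_exons=6, strand="-",
            events=[{"kind": "partial_intron_retention_3prime", "target": 2,
                     "length_nt": 21, "label": "r"}])
        alt = apply_splice_event(fx.model, fx.events[0])
        assert alt.mrna == fx.truth["r"].altered_mrna

    def test_skip_of_nonexistent_exon_raises(self):
        fx = gen_transcript_fixture(seed=12, n_exons=4)
        with pytest.raises(IndexError):
            apply_splice_event(fx.model, SpliceEvent("exon_skip", 9))

    def test_retention_exceeding_intron_raises(self):
        fx = gen_transcript_fixture(seed=12, n_exons=4)
        with pytest.raises(ValueError):
            apply_splice_event(
                fx.model, SpliceEvent("partial_intron_retention_3prime", 1, 10_000))

    def test_declared_exon_length_mismatch_raises(self):
        fx = gen_transcript_fixture(seed=12, n_exons=4)
        with pytest.raises(ValueError):
            apply_splice_event(fx.model, SpliceEvent("exon_skip", 2, 1))


class TestFrameConsequence:
    @pytest.mark.parametrize("delta,frame,aa", [
        (+18, "in_frame", +6),      # 18-nt retention extends the protein by 6 aa
        (-138, "in_frame", -46),    # 138-nt exon skip shortens it by 46 aa
        (-322, "frameshift", None),
        (0, "in_frame", 0),
        (-59, "frameshift", None),
    ])
    def test_frame_law(self, delta, frame, aa):
        got_frame, got_aa = frame_consequence(delta)
        assert got_frame == frame
        assert got_aa == aa


def _expected_kind(truth):
    if truth.frame_class == "frameshift":
        return "frameshift_with_PTC" if truth.stop_found else "no_stop"
    return "inframe_deletion" if truth.delta_nt < 0 else "inframe_insertion"


class TestTranslateConsequence:
    def test_engineered_frameshift_four_novel_residues(self):
        """Out-of-frame 322-nt exon skip terminating after 4 novel residues."""
        fx = gen_transcript_fixture(
            seed=1, n_exons=10,
            events=[{"kind": "exon_skip", "target": 3, "length_nt": 322,
                     "novel_aa": 4, "label": "skip"}])
        cons = translate_consequence(apply_splice_event(fx.model, fx.events[0]), fx.model)
        t = fx.truth["skip"]
        assert cons.kind == "frameshift_with_PTC"
        assert cons.novel_aa_count == 4 == t.novel_aa_count
        assert cons.hgvs_p.endswith("fs*5")                 # stop counted per fs*N
        assert cons.ptc_tx_pos == t.ptc_tx_pos
        assert cons.nmd_predicted == t.nmd_predicted

    def test_engineered_eleven_novel_residues(self):
        """59-nt exonic truncation via an ectopic acceptor: stop after 11 novel aa."""
        fx = gen_transcript_fixture(
            seed=2, n_exons=10,
            events=[{"kind": "exonic_acceptor_truncation", "target": 4,
                     "length_nt": 59, "novel_aa": 11, "label": "tr"}])
        cons = translate_consequence(apply_splice_event(fx.model, fx.events[0]), fx.model)
        assert cons.kind == "frameshift_with_PTC"
        assert cons.novel_aa_count == 11
        assert cons.hgvs_p.endswith("fs*12")

    def test_inframe_retention_plus_six(self):
        fx = gen_transcript_fixture(
            seed=3, n_exons=10,
            events=[{"kind": "partial_intron_retention_3prime", "target": 7,
                     "length_nt": 18, "label": "ret"}])
        cons = translate_consequence(apply_splice_event(fx.model, fx.events[0]), fx.model)
        assert cons.kind == "inframe_insertion"
        assert cons.aa_delta == +6
        assert not cons.nmd_predicted

    def test_nonsense_substitution_arg3885(self):
        """CGA→TGA at codon 3885 via c.11653C>T, as for a classic stop-gain."""
        # enough downstream exons that the new stop sits well upstream of the
        # last junction (so the NMD rule fires)
        fx = gen_transcript_fixture(seed=4, n_exons=34, exon_length_range=(380, 400),
                                    planted_codons={3885: "CGA"})
        assert fx.wt_protein[3884] == "R"
        v = parse_hgvs_c("c.11653C>T")
        cons = translate_consequence(apply_variant_to_transcript(fx.model, v), fx.model)
        assert cons.kind == "nonsense"
        assert cons.hgvs_p == "p.Arg3885*"
        assert cons.nmd_predicted

    def test_single_base_deletion_matches_naive_truth(self):
        """A frameshifting 1-nt deletion agrees with independent naive translation."""
        fx = gen_transcript_fixture(seed=5, n_exons=12, exon_length_range=(150, 250),
                                    planted_codons={300: "CCT"})
        v = parse_hgvs_c("c.900del")      # removes the T of the Pro-300 codon
        alt = apply_variant_to_transcript(fx.model, v)
        cons = translate_consequence(alt, fx.model)
        wt_prot, _ = naive_translate(fx.wt_mrna)
        mut_prot, stop = naive_translate(alt.mrna)
        i = next(k for k in range(len(mut_prot)) if wt_prot[k] != mut_prot[k])
        assert cons.frame_class == "frameshift"
        if stop:
            assert cons.kind == "frameshift_with_PTC"
            assert cons.novel_aa_count == len(mut_prot) - i
            assert cons.hgvs_p.endswith(f"fs*{len(mut_prot) - i + 1}")

    def test_start_codon_loss_reports_no_orf(self):
        fx = gen_transcript_fixture(seed=6, n_exons=4, planted_codons={1: "ATG"})
        v = parse_hgvs_c("c.2T>C")
        cons = translate_consequence(apply_variant_to_transcript(fx.model, v), fx.model)
        assert cons.kind == "no_ORF"

    def test_oracle_equivalence_varied_events(self, rng):
        """Engine output equals the constructed naive-translation truth on a
        varied sample of fixtures (both strands, all event kinds)."""
        kinds = ["exon_skip", "partial_intron_retention_3prime",
                 "partial_intron_retention_5prime", "exonic_acceptor_truncation"]
        for k in range(40):
            n_exons = int(rng.integers(4, 10))
            kind = kinds[k % 4]
            target = int(rng.integers(2, n_exons - 1)) if kind in (
                "exon_skip", "exonic_acceptor_truncation") else int(
                rng.integers(1, n_exons))
            spec = {"kind": kind, "target": target, "label": "e"}
            if kind.startswith("partial"):
                spec["length_nt"] = int(rng.integers(4, 60))
            if kind == "exonic_acceptor_truncation":
                spec["length_nt"] = int(rng.integers(4, 60))
            fx = gen_transcript_fixture(seed=9000 + k, n_exons=n_exons,
                                        strand="-" if k % 2 else "+", events=[spec])
            t = fx.truth["e"]
            alt = apply_splice_event(fx.model, fx.events[0])
            cons = translate_consequence(alt, fx.model)
            assert alt.mrna == t.altered_mrna
            assert cons.frame_class == t.frame_class
            assert cons.kind == _expected_kind(t)
            if t.frame_class == "frameshift":
                assert cons.novel_aa_count == t.novel_aa_count
            else:
                assert cons.aa_delta == t.aa_delta
            assert cons.ptc_tx_pos == t.ptc_tx_pos
            assert cons.nmd_predicted == t.nmd_predicted


class TestNMD:
    def test_ptc_in_early_exon_triggers_nmd(self):
        fx = gen_transcript_fixture(seed=20, n_exons=10,
                                    events=[{"kind": "exon_skip", "target": 2,
                                             "length_nt": 100, "novel_aa": 3,
                                             "label": "s"}])
        cons = translate_consequence(apply_splice_event(fx.model, fx.events[0]), fx.model)
        assert cons.nmd_predicted

    def test_rule_arithmetic(self):
        junctions = [100, 400, 900]
        assert predict_nmd(100, junctions) is True          # 800 nt upstream
        assert predict_nmd(890, junctions) is False         # 10 nt before last junction
        assert predict_nmd(844, junctions) is True          # 56 > 55
        assert predict_nmd(845, junctions) is False         # exactly 55: not beyond
        assert predict_nmd(950, junctions) is False         # in the final exon
        assert predict_nmd(100, []) is False                # single-exon transcript
        assert predict_nmd(None, junctions) is False

    def test_threshold_configurable(self):
        assert predict_nmd(840, [900], threshold=50) is True
        assert predict_nmd(840, [900], threshold=70) is False


class TestAmplicons:
    @pytest.fixture
    def exon13_15_fixture(self):
        """Exons sized so a 472-nt amplicon spans exons 13–15 with exon 14 = 322 nt."""
        fx = gen_transcript_fixture(
            seed=30, n_exons=16, exon_length_range=(75, 76),
            events=[{"kind": "exon_skip", "target": 14, "length_nt": 322,
                     "label": "skip14"}])
        return fx

    def test_wt_472_mutant_150(self, exon13_15_fixture):
        fx = exon13_15_fixture
        lo13 = fx.model.exon_tx_span(13)[0]
        primers = PrimerPair(lo13, lo13 + 471, label="ex13-15")
        calls = predict_amplicon_sizes(fx.model, primers, list(fx.events))
        assert [c.size_nt for c in calls] == [472, 150]     # sorted descending

    def test_no_events_single_wt_band(self, exon13_15_fixture):
        fx = exon13_15_fixture
        calls = predict_amplicon_sizes(fx.model, PrimerPair(10, 389), [])
        assert len(calls) == 1 and calls[0].size_nt == 380

    def test_wt_380_mutant_242_for_138nt_skip(self):
        fx = gen_transcript_fixture(
            seed=31, n_exons=8, exon_length_range=(100, 140),
            events=[{"kind": "exon_skip", "target": 5, "length_nt": 138,
                     "label": "skip5"}])
        lo4 = fx.model.exon_tx_span(4)[0]
        calls = predict_amplicon_sizes(fx.model, PrimerPair(lo4, lo4 + 379),
                                       list(fx.events))
        assert [c.size_nt for c in calls] == [380, 242]
        # gel estimate of ~250 bp reconciles with the exact 242-nt prediction
        assert gel_match(242, 250)
        assert not gel_match(242, 350)

    def test_primer_inside_skipped_exon_reports_lost(self, exon13_15_fixture):
        fx = exon13_15_fixture
        lo14 = fx.model.exon_tx_span(14)[0]
        calls = predict_amplicon_sizes(fx.model,
                                       PrimerPair(lo14 + 5, fx.model.spliced_length),
                                       list(fx.events))
        lost = [c for c in calls if c.allele == "skip14"]
        assert lost and lost[0].primer_lost and lost[0].size_nt is None

    def test_amplicon_additivity_property(self, rng):
        """mutant − WT size equals delta_nt whenever both primers survive."""
        fx = gen_transcript_fixture(
            seed=32, n_exons=9,
            events=[{"kind": "partial_intron_retention_5prime", "target": 4,
                     "length_nt": 25, "label": "r"}])
        wt_len = fx.model.spliced_length
        for _ in range(20):
            a = int(rng.integers(1, fx.model.exon_tx_span(4)[0]))
            b = int(rng.integers(fx.model.exon_tx_span(5)[1], wt_len + 1))
            calls = {c.allele: c for c in predict_amplicon_sizes(
                fx.model, PrimerPair(a, b), list(fx.events))}
            assert calls["r"].size_nt - calls["WT"].size_nt == 25


class TestHelpers:
    def test_find_ag_near_acceptor(self):
        fx = gen_transcript_fixture(
            seed=40, n_exons=5,
            events=[{"kind": "partial_intron_retention_3prime", "target": 2,
                     "length_nt": 18, "label": "r"}])
        hits = find_ag_dinucleotides(fx.model, 2, window=60)
        assert 0 in hits                       # the canonical acceptor AG itself

    def test_consequence_report_frame(self):
        fx = gen_transcript_fixture(
            seed=41, n_exons=8,
            events=[{"kind": "exon_skip", "target": 3, "novel_aa": 4, "label": "s"},
                    {"kind": "partial_intron_retention_3prime", "target": 6,
                     "length_nt": 18, "label": "r"}])
        lo = fx.model.exon_tx_span(2)[0]
        df = consequence_report(fx.model, list(fx.events),
                                PrimerPair(lo, fx.model.spliced_length))
        assert set(df["event"]) == {"s", "r"}
        assert set(df.columns) >= {"delta_nt", "frame_class", "hgvs_p",
                                   "nmd_predicted", "amplicon_nt"}
        row = df[df["event"] == "r"].iloc[0]
        assert row["frame_class"] == "in_frame" and row["aa_delta"] == 6
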