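"""Spliced-EST coverage, junction inference, and PTC/NMD annotation."""

import numpy as np
import pytest

from _oracles import (
    brute_force_coverage,
    brute_force_first_stop,
    brute_force_junctions,
)
from rpgintrons.est import (
    ALT_3SS,
    ALT_5SS,
    CANONICAL,
    CASSETTE_EXON,
    RETAINED_INTRON,
    GeneModel,
    SplicedAlignment,
    UnclassifiableIsoformError,
    annotate_ptc,
    classify_event,
    coverage_per_base,
    filter_spliced_track,
    infer_junctions,
    percentile_lines,
    read_bed12,
    write_bed12,
)
from rpgintrons.simulate import (
    ESTSimConfig,
    build_template_locus,
    simulate_spliced_ests,
)


@pytest.fixture(scope="module")
def template():
    genome, model, canonical, minor = build_template_locus()
    return genome, model, canonical, minor


def make_filter_genome():
    """One chromosome with three gaps: long GT..AG, short GT..AG, GC..AG."""
    seq = list("c" * 500)
    seq[150:152] = "gt"; seq[248:250] = "ag"     # gap A: 100 nt, canonical
    seq[300:302] = "gt"; seq[318:320] = "ag"     # gap B: 20 nt, too short
    seq[330:332] = "gc"; seq[428:430] = "ag"     # gap C: 100 nt, non-GT
    return {"chrF": "".join(seq)}


class TestFilterSplicedTrack:
    GENOME = make_filter_genome()

    def test_long_gt_ag_gap_kept(self):
        aln = SplicedAlignment("a", "chrF", "+", ((100, 150), (250, 290)))
        assert filter_spliced_track([aln], self.GENOME) == [aln]

    def test_short_gap_dropped(self):
        aln = SplicedAlignment("b", "chrF", "+", ((280, 300), (320, 340)))
        assert filter_spliced_track([aln], self.GENOME) == []

    def test_non_gt_ag_gap_dropped(self):
        aln = SplicedAlignment("c", "chrF", "+", ((310, 330), (430, 460)))
        assert filter_spliced_track([aln], self.GENOME) == []

    def test_minus_strand_reads_reverse_complement(self):
        # CT..AC genomically reads GT..AG on the minus strand
        seq = list("c" * 300)
        seq[100:102] = "ct"; seq[198:200] = "ac"
        genome = {"chrM": "".join(seq)}
        aln = SplicedAlignment("m", "chrM", "-", ((50, 100), (200, 250)))
        assert filter_spliced_track([aln], genome) == [aln]
        plus = SplicedAlignment("p", "chrM", "+", ((50, 100), (200, 250)))
        assert filter_spliced_track([plus], genome) == []


class TestCoverage:
    def test_blocks_covered_gap_not(self):
        aln = SplicedAlignment("a", "c", "+", ((10, 20), (30, 40)))
        track = coverage_per_base([aln], (0, 50))
        assert track.counts[10:20].tolist() == [1] * 10
        assert track.counts[20:30].tolist() == [0] * 10
        assert track.max_cov == 1

    def test_empty_set_all_zero(self):
        track = coverage_per_base([], (0, 30))
        assert not track.counts.any()

    def test_matches_bruteforce_on_simulated_ests(self):
        _, _, alignments, _ = simulate_spliced_ests(
            ESTSimConfig(n_ests=50, seed=7))
        region = (0, 1000)
        track = coverage_per_base(alignments, region)
        assert track.counts.tolist() == \
            brute_force_coverage(alignments, region)

    def test_coverage_conservation(self):
        _, _, alignments, _ = simulate_spliced_ests(
            ESTSimConfig(n_ests=80, seed=3))
        track = coverage_per_base(alignments, (0, 1000))
        block_total = sum(e - s for a in alignments for s, e in a.blocks)
        assert int(track.counts.sum()) == block_total


class TestPercentileLines:
    def test_fraction_of_maximum(self):
        track = coverage_per_base(
            [SplicedAlignment(f"r{i}", "c", "+", ((0, 10),))
             for i in range(200)], (0, 10))
        assert percentile_lines(track) == (10.0, 190.0)

    def test_unit_maximum(self):
        track = coverage_per_base(
            [SplicedAlignment("r", "c", "+", ((0, 10),))], (0, 10))
        assert percentile_lines(track) == (0.05, 0.95)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            percentile_lines(coverage_per_base([], (0, 10)))

    def test_rare_isoform_sits_below_low_line(self, template):
        genome, model, canonical, minor = template
        _, _, alignments, truth = simulate_spliced_ests(
            ESTSimConfig(n_ests=600, minor_isoform_freq=0.02, seed=5))
        track = coverage_per_base(alignments, (0, 1000))
        low, _ = percentile_lines(track)
        # coverage unique to the minor isoform: the exon-2 extension
        minor_only = track.counts[560:610].max()
        assert minor_only < low


class TestJunctions:
    def test_shared_junction_counted_once_with_support(self, template):
        genome, *_ = template
        alns = [SplicedAlignment(f"r{i}", "chrT", "+",
                                 ((200, 250), (350, 400)))
                for i in range(3)]
        calls = infer_junctions(alns, genome)
        assert len(calls) == 1
        assert (calls[0].donor_end, calls[0].acceptor_start) == (250, 350)
        assert calls[0].count == 3
        assert (calls[0].donor_dinuc, calls[0].acceptor_dinuc) == ("GT", "AG")

    def test_two_donors_one_acceptor_two_calls(self, template):
        genome, *_ = template
        alns = [SplicedAlignment("r1", "chrT", "+", ((500, 550), (700, 750))),
                SplicedAlignment("r2", "chrT", "+", ((560, 610), (700, 750)))]
        calls = infer_junctions(alns, genome)
        assert {(c.donor_end, c.acceptor_start) for c in calls} == \
            {(550, 700), (610, 700)}

    def test_matches_bruteforce_enumeration(self, template):
        genome, *_ = template
        _, _, alignments, _ = simulate_spliced_ests(
            ESTSimConfig(n_ests=120, minor_isoform_freq=0.1, seed=9))
        got = {(c.donor_end, c.acceptor_start): c.count
               for c in infer_junctions(alignments, genome)}
        assert got == brute_force_junctions(alignments, genome["chrT"])

    def test_junction_count_bounded_by_spanning_alignments(self, template):
        genome, *_ = template
        _, _, alignments, _ = simulate_spliced_ests(
            ESTSimConfig(n_ests=200, seed=2))
        for call in infer_junctions(alignments, genome):
            spanning = [a for a in alignments
                        if a.span[0] <= call.donor_end
                        and call.acceptor_start <= a.span[1]]
            assert call.count <= len(spanning)


def make_yeast_model():
    """Single-intron yeast-style gene: the retained intron carries an
    in-frame stop three codons into the intron."""
    seq = ("atg" + "gct" * 3             # exon 1 CDS, [0, 12)
           + "gtc" + "taa" + "c" * 40 + "ag"   # intron [12, 60)
           + "gct" * 9 + "taa")          # exon 2 CDS, [60, 90)
    model = GeneModel("yeastRP", "chrY", "+", ((0, 12), (60, 90)), 0, 90)
    return {"chrY": seq}, model


class TestPtcAnnotation:
    def test_canonical_isoform_has_no_ptc(self, template):
        genome, model, canonical, _ = template
        ann = annotate_ptc(model, canonical, genome)
        assert ann.event == CANONICAL
        assert ann.ptc_position is None
        assert not ann.nmd_predicted

    def test_alt_donor_extension_introduces_nmd_ptc(self, template):
        genome, model, _, minor = template
        ann = annotate_ptc(model, minor, genome, "minor")
        assert ann.event == ALT_5SS
        assert ann.ptc_position == 551
        assert ann.nmd_predicted

    def test_retained_intron_in_frame_stop(self):
        genome, model = make_yeast_model()
        ann = annotate_ptc(model, ((0, 90),), genome)
        assert ann.event == RETAINED_INTRON
        assert ann.ptc_position == 15
        assert ann.nmd_predicted

    def test_frameshifting_cassette_exon_ptc_matches_codon_scan(self,
                                                                template):
        genome, model, _, _ = template
        # 19-nt cassette exon inside intron 2 shifts the frame; a stop is
        # planted in the shifted frame of exon 3 (canonical frame unaffected)
        seq = genome["chrT"]
        seq = seq[:708] + "a" + seq[709:]
        local = {"chrT": seq}
        iso = ((100, 250), (350, 550), (560, 579), (700, 900))
        ann = annotate_ptc(model, iso, local)
        assert ann.event == CASSETTE_EXON
        # independent codon-scan oracle over the spliced isoform sequence
        spliced = "".join(seq[s:e] for s, e in iso)
        coords = [p for s, e in iso for p in range(s, e)]
        t0 = coords.index(model.cds_start)
        stop_t = brute_force_first_stop(spliced, t0)
        assert stop_t is not None
        assert ann.ptc_position == coords[stop_t] == 706

    def test_ptc_stable_under_3prime_extension(self):
        genome, model = make_yeast_model()
        a1 = annotate_ptc(model, ((0, 90),), genome)
        # pad the chromosome and extend the terminal exon 3' of the PTC
        padded = {"chrY": genome["chrY"] + "c" * 30}
        a2 = annotate_ptc(model, ((0, 120),), padded)
        assert a1.ptc_position == a2.ptc_position

    def test_isoform_without_start_codon_rejected(self, template):
        genome, model, _, _ = template
        with pytest.raises(ValueError, match="start codon"):
            annotate_ptc(model, ((350, 550), (700, 900)), genome)


class TestClassifyEvent:
    def test_examples(self, template):
        genome, model, canonical, minor = template
        assert classify_event(model, canonical) == CANONICAL
        assert classify_event(model, minor) == ALT_5SS
        assert classify_event(
            model, ((100, 250), (350, 550), (705, 900))) == ALT_3SS
        assert classify_event(
            model, ((100, 250), (350, 550), (560, 580), (700, 900))) \
            == CASSETTE_EXON
        assert classify_event(
            model, ((100, 250), (350, 900))) == RETAINED_INTRON

    def test_strand_aware_donor_acceptor_swap(self):
        model = GeneModel("m", "c", "-", ((0, 100), (200, 300)), 10, 290)
        # moved left (genomic) end of the junction: acceptor on minus strand
        assert classify_event(model, ((0, 90), (200, 300))) == ALT_3SS
        assert classify_event(model, ((0, 100), (210, 300))) == ALT_5SS

    def test_unrelated_junctions_unclassifiable(self, template):
        _, model, _, _ = template
        with pytest.raises(UnclassifiableIsoformError):
            classify_event(model, ((100, 200), (400, 500), (800, 900)))


class TestBed12RoundTrip:
    def test_round_trip(self, tmp_path):
        _, _, alignments, _ = simulate_spliced_ests(
            ESTSimConfig(n_ests=20, seed=4))
        path = tmp_path / "ests.bed"
        write_bed12(alignments, path)
        assert read_bed12(path) == alignments
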