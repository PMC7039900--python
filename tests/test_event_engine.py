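"""Junction classification taxonomy, cryptic-exon pairing, and event naming."""

import pytest

from spliceprofile.event_engine import (
    canonical_junctions,
    classify_junction,
    detect_events,
    frame_status,
    merge_es,
    name_event,
    pair_cryptic_exons,
)
from spliceprofile.synthetic_data import SimulationConfig, simulate_models

from conftest import junction, make_model


class TestCanonicalJunctions:
    def test_counts(self, three_exon_model):
        assert len(canonical_junctions(three_exon_model)) == 2
        two = make_model([50, 50], [100])
        assert len(canonical_junctions(two)) == 1
        one = make_model([50], [])
        assert canonical_junctions(one) == set()

    def test_canonical_classifies_canonical(self, three_exon_model):
        m = three_exon_model
        for _, s, e, _ in canonical_junctions(m):
            assert classify_junction(junction(m, s, e), m).kind == "canonical"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_canonical_identity_random_models(self, seed):
        cfg = SimulationConfig(seed=seed, n_genes=3, exon_count_range=(4, 20))
        for m in simulate_models(cfg):
            for _, s, e, _ in canonical_junctions(m):
                assert classify_junction(junction(m, s, e), m).kind == "canonical"


class TestClassification:
    def test_full_exon_skip(self, three_exon_model):
        m = three_exon_model
        c = classify_junction(junction(m, 1100, 2999), m)
        e = c.event
        assert e.event_type == "ESF"
        assert e.skipped_exon_indices == (2,)
        assert e.deleted_length == 100
        assert len(e.denominator_junctions) == 2
        assert e.name == "r.101_200del"

    def test_multi_exon_skip(self, five_exon_model):
        m = five_exon_model
        # donor of exon 1 to acceptor of exon 4 skips exons 2 and 3
        s = m.exons[0][1] + 1
        e = m.exons[3][0] - 1
        ev = classify_junction(junction(m, s, e), m).event
        assert ev.event_type == "ESF"
        assert ev.skipped_exon_indices == (2, 3)
        assert ev.deleted_length == 120 + 90
        assert len(ev.denominator_junctions) == 3

    def test_intron_retention_8nt_frameshift(self):
        # exon 1 of 80 nt: acceptor of exon 2 sits at transcript position 81
        m = make_model([80, 100], [200], start=1000)
        intron_end = m.exons[1][0] - 1
        ev = classify_junction(junction(m, 1080, intron_end - 8), m).event
        assert ev.event_type == "IP"
        assert ev.inserted_length == 8
        assert ev.frame_status == "frameshift"
        assert ev.name == "r.80_81ins81-8_81-1"

    def test_partial_skip_17nt_frameshift(self):
        # 3060 nt upstream of the truncated exon: deletion at r.3061_3077
        m = make_model([3060, 100], [500], start=1000)
        acceptor = m.exons[1][0]
        ev = classify_junction(junction(m, 3060 + 1000, acceptor + 16), m).event
        assert ev.event_type == "ESP"
        assert ev.deleted_length == 17
        assert ev.frame_status == "frameshift"
        assert ev.name == "r.3061_3077del"

    def test_partial_skip_donor_side(self):
        # last 13 bases of a 23 nt first exon deleted: r.11_23del
        m = make_model([23, 100], [300], start=1000)
        ev = classify_junction(junction(m, 1010, m.exons[1][0] - 1), m).event
        assert ev.event_type == "ESP"
        assert ev.deleted_length == 13
        assert ev.name == "r.11_23del"

    def test_esf_name_from_transcript_span(self):
        m = make_model([5074, 78, 100], [500, 500])
        s = m.exons[0][1] + 1
        e = m.exons[2][0] - 1
        ev = classify_junction(junction(m, s, e), m).event
        assert ev.name == "r.5075_5152del"
        assert ev.frame_status == "in-frame"  # 78 mod 3 == 0

    def test_ip_retention_name_acceptor_side(self):
        m = make_model([576, 100], [400], start=1000)
        intron_start = m.exons[0][1] + 1
        intron_end = m.exons[1][0] - 1
        ev = classify_junction(junction(m, intron_start, intron_end - 4), m).event
        assert ev.event_type == "IP"
        assert ev.inserted_length == 4
        assert ev.name == "r.576_577ins577-4_577-1"

    def test_wrong_strand_unassigned(self, three_exon_model):
        c = classify_junction(junction(three_exon_model, 1100, 2999, strand="-"),
                              three_exon_model)
        assert c.kind == "unassigned"
        assert "strand" in c.reason

    def test_exitron_like_unassigned(self, three_exon_model):
        c = classify_junction(junction(three_exon_model, 1010, 2090),
                              three_exon_model)
        assert c.kind == "unassigned"
        assert "exitron" in c.reason

    def test_boundary_tiebreak_prefers_canonical(self, three_exon_model):
        # both ends coincide with canonical boundaries of adjacent exons:
        # canonical, never a zero-length partial skip
        m = three_exon_model
        assert classify_junction(junction(m, 1100, 1999), m).kind == "canonical"


class TestCrypticExons:
    def test_pairing_63nt_in_frame(self, three_exon_model):
        m = three_exon_model
        ja = junction(m, 1100, 1399)  # cryptic acceptor at 1400
        jb = junction(m, 1463, 1999)  # cryptic donor at 1462
        (ic,) = pair_cryptic_exons([ja, jb], m)
        assert ic.event_type == "IC"
        assert ic.inserted_length == 63
        assert ic.frame_status == "in-frame"
        assert ic.affected_genomic_span == (1400, 1462)
        assert len(ic.supporting_junctions) == 2
        assert ic.name == "r.100_101ins100+301_100+363"

    def test_single_candidate_no_ic(self, three_exon_model):
        m = three_exon_model
        assert pair_cryptic_exons([junction(m, 1100, 1399)], m) == []

    def test_empty_interval_rejected(self, three_exon_model):
        m = three_exon_model
        ja = junction(m, 1100, 1499)
        jb = junction(m, 1500, 1999)  # implied interval (1500, 1499): empty
        assert pair_cryptic_exons([ja, jb], m) == []

    def test_detect_events_consumes_paired_ips(self, three_exon_model):
        m = three_exon_model
        ja = junction(m, 1100, 1399)
        jb = junction(m, 1463, 1999)
        events, _ = detect_events([ja, jb], m)
        assert [e.event_type for e in events] == ["IC"]

    def test_unpaired_candidate_stays_ip(self, three_exon_model):
        m = three_exon_model
        events, _ = detect_events([junction(m, 1100, 1991)], m)
        assert [e.event_type for e in events] == ["IP"]


class TestFrameAndMirror:
    def test_frame_exhaustive(self):
        for delta in range(0, 301):
            assert (frame_status(delta, 0) == "in-frame") == (delta % 3 == 0)
            assert (frame_status(0, delta) == "in-frame") == (delta % 3 == 0)

    def test_strand_mirror_invariance(self):
        plus = make_model([80, 120, 90, 60], [500, 700, 400], start=5000)
        hi = max(e for _, e in plus.exons) + 1000
        mirrored = [(hi - e, hi - s) for s, e in plus.exons]
        minus = make_model(
            [e - s + 1 for s, e in sorted(mirrored)],
            [sorted(mirrored)[i + 1][0] - sorted(mirrored)[i][1] - 1
             for i in range(len(mirrored) - 1)],
            strand="-", start=sorted(mirrored)[0][0],
        )
        probes = [
            (plus.exons[0][1] + 1, plus.exons[2][0] - 1),  # skip exon 2
            (plus.exons[1][1] + 1, plus.exons[2][0] + 16),  # partial skip
            (plus.exons[0][1] + 1, plus.exons[1][0] - 9),  # 8 nt retention
        ]
        for s, e in probes:
            ev_p = classify_junction(junction(plus, s, e), plus).event
            ev_m = classify_junction(junction(minus, hi - e, hi - s), minus).event
            assert ev_p.event_type == ev_m.event_type
            assert ev_p.inserted_length == ev_m.inserted_length
            assert ev_p.deleted_length == ev_m.deleted_length
            assert ev_p.frame_status == ev_m.frame_status


class TestExclusionsAndMerge:
    def test_excluded_exon_events_dropped(self):
        m = make_model([100, 100, 100], [900, 900], start=1000,
                       excluded={2})
        events, _ = detect_events([junction(m, 1100, 2999)], m)
        assert events == []
        events, _ = detect_events([junction(m, 1100, 2999)], m,
                                  drop_excluded=False)
        with pytest.raises(ValueError, match="excluded"):
            name_event(events[0], m)

    def test_merge_es_combines_full_and_partial(self, three_exon_model):
        m = three_exon_model
        esf = classify_junction(junction(m, 1100, 2999), m).event
        esp = classify_junction(junction(m, 1100, 2016), m).event
        assert esp.event_type == "ESP" and esp.skipped_exon_indices == (2,)
        aggregates = merge_es([esf, esp])
        assert len(aggregates) == 1
        assert aggregates[0].exon_indices == (2,)
        assert set(aggregates[0].components) == {esf, esp}

    def test_merge_es_single_component(self, three_exon_model):
        m = three_exon_model
        esf = classify_junction(junction(m, 1100, 2999), m).event
        (agg,) = merge_es([esf])
        assert agg.components == (esf,)

    def test_merge_es_ignores_intronic_events(self, three_exon_model):
        m = three_exon_model
        ip = classify_junction(junction(m, 1100, 1991), m).event
        assert ip.event_type == "IP"
        assert merge_es([ip]) == []
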