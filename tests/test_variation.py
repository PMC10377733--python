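import numpy as np
import pytest

from pstrtool.align import AlignedPair, align_pair
from pstrtool.detect import find_pstrs
from pstrtool.families import generate_family, random_family_spec
from pstrtool.seqio import ProteinRecord
from pstrtool.variation import (
    UnitVariationEvent,
    call_events,
    call_family_events,
    map_to_query,
)


def keys(events):
    return {(e.carrier_id, e.unit, e.carrier_start, e.n_extra_units) for e in events}


class TestCallEvents:
    def test_single_extra_unit(self):
        a, b = ProteinRecord("a", "MKPQPQW"), ProteinRecord("b", "MKPQW")
        events = call_events(align_pair(a, b), find_pstrs(a), find_pstrs(b))
        assert keys(events) == {("a", "PQ", 5, 1)}
        assert events[0].partner_id == "b"

    def test_gap_without_adjacent_conserved_unit_is_silent(self):
        # both PQ units of the carrier oppose gaps: nothing conserved remains
        pair = AlignedPair("a", "b", "MKPQPQW", "MK----W")
        a, b = ProteinRecord("a", "MKPQPQW"), ProteinRecord("b", "MKW")
        assert call_events(pair, find_pstrs(a), find_pstrs(b)) == []

    def test_identical_sequences_produce_no_events(self):
        a = ProteinRecord("a", "MKPQPQW")
        b = ProteinRecord("b", "MKPQPQW")
        assert call_events(align_pair(a, b), find_pstrs(a), find_pstrs(b)) == []

    def test_two_unit_block_counted_as_one_event(self):
        pair = AlignedPair("c", "d", "APQPQPQPQV", "APQPQ----V")
        c, d = ProteinRecord("c", "APQPQPQPQV"), ProteinRecord("d", "APQPQV")
        pq_run = [p for p in find_pstrs(c) if p.unit == "PQ"]
        events = call_events(pair, pq_run, [p for p in find_pstrs(d) if p.unit == "PQ"])
        assert keys(events) == {("c", "PQ", 6, 2)}

    def test_non_primitive_unit_reported_alongside(self):
        pair = AlignedPair("c", "d", "APQPQPQPQV", "APQPQ----V")
        c, d = ProteinRecord("c", "APQPQPQPQV"), ProteinRecord("d", "APQPQV")
        events = call_events(pair, find_pstrs(c), find_pstrs(d))
        assert keys(events) == {("c", "PQ", 6, 2), ("c", "PQPQ", 6, 1)}

    def test_partner_side_carrier_detected_symmetrically(self):
        # the longer sequence is in row b: carrier/partner swap, same event
        pair = AlignedPair("b", "a", "MKPQ--W", "MKPQPQW")
        a, b = ProteinRecord("a", "MKPQPQW"), ProteinRecord("b", "MKPQW")
        events = call_events(pair, find_pstrs(b), find_pstrs(a))
        assert keys(events) == {("a", "PQ", 5, 1)}

    def test_foreign_annotation_rejected(self):
        a, b = ProteinRecord("a", "MKPQPQW"), ProteinRecord("b", "MKPQW")
        wrong = find_pstrs(ProteinRecord("a", "ACDACDAC"))
        with pytest.raises(ValueError, match="not.*from this pair|does not match"):
            call_events(align_pair(a, b), wrong, [])

    def test_left_placed_gap_canonicalized_to_c_terminal_phase(self):
        # same biology as test_single_extra_unit but the gap sits N-terminally,
        # as another aligner might place it
        pair = AlignedPair("a", "b", "MKPQPQW", "MK--PQW")
        a, b = ProteinRecord("a", "MKPQPQW"), ProteinRecord("b", "MKPQW")
        events = call_events(pair, find_pstrs(a), find_pstrs(b))
        assert keys(events) == {("a", "PQ", 5, 1)}


class TestMapToQuery:
    def test_self_mapping_returns_central_position(self):
        ev = UnitVariationEvent("a", "b", "PQ", 5, 1)
        rec = ProteinRecord("a", "MKPQPQW")
        assert map_to_query(ev, rec, rec) == 5

    def test_central_position_formula_for_longer_unit(self):
        ev = UnitVariationEvent("a", "b", "ACD", 10, 1)
        assert ev.central_carrier_pos == 11

    def test_gap_column_falls_back_to_preceding_query_position(self):
        carrier = ProteinRecord("a", "MKPQPQW")
        query = ProteinRecord("b", "MKPQW")
        ev = UnitVariationEvent("a", "b", "PQ", 5, 1)
        assert map_to_query(ev, carrier, query) == 4

    def test_event_before_any_query_residue_maps_to_zero(self):
        pair = AlignedPair("a", "q", "PQPQW", "--PQW")
        ev = UnitVariationEvent("a", "q", "PQ", 1, 1)
        carrier = ProteinRecord("a", "PQPQW")
        query = ProteinRecord("q", "PQW")
        assert map_to_query(ev, carrier, query, _alignment=pair) == 0


class TestCallFamilyEvents:
    def test_shared_extra_unit_deduplicated_with_two_partners(self, pq_family):
        result = call_family_events(pq_family)
        assert len(result.events) == 1
        (event,) = result.events
        assert event.carrier_id == "a"
        assert event.unit == "PQ"
        assert event.n_extra_units == 1
        assert event.partner_ids == ("b", "c")
        assert event.query_pos == event.central_carrier_pos  # query is carrier

    def test_support_matrix_marks_only_variant_pairs(self, pq_family):
        result = call_family_events(pq_family)
        support = result.support
        assert support[0, 1] == support[0, 2] == 1
        assert support[1, 2] == 0
        assert (support == support.T).all() and (np.diag(support) == 0).all()

    def test_identical_family_is_event_free(self):
        records = [ProteinRecord(f"s{i}", "MKVPQPQLW") for i in range(4)]
        result = call_family_events(records)
        assert result.events == [] and not result.support.any()

    def test_two_private_expansions_give_two_events(self):
        records = [
            ProteinRecord("q", "MDVAPQPQIRGHEWLWLSTYN"),
            ProteinRecord("r", "MDVAPQPQPQIRGHEWLWLSTYN"),
            ProteinRecord("s", "MDVAPQPQIRGHEWLWLWLSTYN"),
        ]
        result = call_family_events(records)
        assert keys(result.events) == {("r", "PQ", 9, 1), ("s", "WL", 18, 1)}

    def test_query_override_changes_mapping_reference(self, pq_family):
        by_first = call_family_events(pq_family, query="a")
        by_short = call_family_events(pq_family, query="b")
        assert by_first.query_id == "a" and by_short.query_id == "b"
        # carrier a, block at 12-13; query b lacks the block: previous residue
        assert by_first.events[0].query_pos == 12
        assert by_short.events[0].query_pos == 11

    def test_unknown_query_id_rejected(self, pq_family):
        with pytest.raises(ValueError, match="query"):
            call_family_events(pq_family, query="nope")

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            call_family_events([ProteinRecord("a", "MK")])

    def test_events_frame_schema(self, pq_family):
        frame = call_family_events(pq_family).events_frame()
        assert list(frame.columns) == [
            "carrier_id", "partner_ids", "unit", "carrier_start",
            "n_extra_units", "query_pos",
        ]
        assert frame.iloc[0].partner_ids == "b,c"

    def test_position_track_totals_match_events(self, pq_family):
        result = call_family_events(pq_family)
        track = result.position_track(len(pq_family[0]))
        assert track.n_events.sum() == len(result.events)
        assert track.loc[track.n_events > 0, "query_pos"].tolist() == [
            result.events[0].query_pos
        ]


class TestPlantedRecovery:
    def test_pipeline_reproduces_generator_truth(self):
        for seed in range(12):
            spec = random_family_spec(seed, base_length=150)
            records, truth = generate_family(spec)
            found = call_family_events(records).events
            as_set = lambda evs: {
                (e.carrier_id, e.unit, e.carrier_start, e.n_extra_units,
                 e.query_pos, e.partner_ids)
                for e in evs
            }
            assert as_set(found) == as_set(truth), spec
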