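"""Junction calling: anchoring, indel calls, microhomology, cut distance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drwhite import (
    CallClass,
    EventMixture,
    anchor_read,
    call_junction,
    microhomology_length,
    sample_events,
)
from drwhite.events import EventClass
from drwhite.junctions import distance_to_cut_interval, left_align_deletion
from drwhite.reads import events_to_reads


# ---------------------------------------------------------------------------
# microhomology: brute-force junction-enumeration oracle
# ---------------------------------------------------------------------------


def mh_oracle(seq: str, interval: tuple[int, int]) -> int:
    """Number of distinct placements of an equal-sized deletion producing the
    identical repaired sequence, minus one."""
    s, e = interval
    d = e - s
    junction = seq[:s] + seq[e:]
    placements = [
        s2 for s2 in range(0, len(seq) - d + 1) if seq[:s2] + seq[s2 + d :] == junction
    ]
    assert placements == list(range(placements[0], placements[-1] + 1)), "non-contiguous"
    return len(placements) - 1


@pytest.mark.parametrize(
    "seq, interval, expected",
    [
        # periodic repeat: every placement of the 4-bp deletion yields ACGTAC
        ("ACGTACGTAC", (2, 6), 6),
        # boundary bases all differ -> no junction ambiguity
        ("AACCGGTT", (2, 4), 0),
        ("AAAA", (1, 3), 2),  # homopolymer
    ],
)
def test_microhomology_frozen_examples(seq, interval, expected):
    assert mh_oracle(seq, interval) == expected
    assert microhomology_length(seq, interval) == expected


def test_microhomology_equals_oracle_on_1000_random_cases():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = int(rng.integers(8, 40))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        s = int(rng.integers(0, n - 1))
        e = int(rng.integers(s + 1, n + 1))
        assert microhomology_length(seq, (s, e)) == mh_oracle(seq, (s, e))


def test_microhomology_is_placement_invariant():
    seq = "ACGTACGTAC"
    s, e = left_align_deletion(seq, (2, 6))
    m = microhomology_length(seq, (s, e))
    for shift in range(m + 1):
        assert microhomology_length(seq, (s + shift, e + shift)) == m


def test_interval_out_of_bounds_rejected():
    with pytest.raises(ValueError, match="out of bounds"):
        microhomology_length("ACGT", (2, 9))


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def test_reference_read_anchors_at_annotated_positions(ref):
    left_end, right_start = anchor_read(ref.sequence, ref)
    assert left_end == ref.left_anchor_interval[1]
    assert right_start == ref.right_anchor_interval[0]


def test_hr_product_remains_anchorable(ref):
    hr_read = ref.hr_product()
    anchors = anchor_read(hr_read, ref)
    assert anchors is not None
    left_end, right_start = anchors
    ref_span = ref.right_anchor_interval[0] - ref.left_anchor_interval[1]
    assert (right_start - left_end) == ref_span - 23


def test_random_sequence_is_unalignable(ref):
    rng = np.random.default_rng(0)
    read = "".join(rng.choice(list("ACGT"), size=len(ref)))
    call = call_junction(read, ref)
    assert call.call_class is CallClass.UNALIGNABLE
    assert call.reason == "anchor_not_found"


def test_single_anchor_mismatch_tolerated(ref):
    a0, _ = ref.left_anchor_interval
    seq = list(ref.sequence)
    seq[a0 + 3] = {"A": "C"}.get(seq[a0 + 3], "A")
    assert call_junction("".join(seq), ref).call_class is CallClass.UNMODIFIED


# ---------------------------------------------------------------------------
# junction calls
# ---------------------------------------------------------------------------


def test_hr_read_called_as_23bp_deletion_at_hr_interval(ref):
    call = call_junction(ref.hr_product(), ref)
    assert call.call_class is CallClass.DELETION
    assert call.del_size == 23
    assert call.del_interval == ref.hr_deletion_interval
    assert call.distance_to_cut == 0


def test_one_bp_deletion_left_of_cut(ref):
    c = ref.cut_index
    read = ref.sequence[: c - 1] + ref.sequence[c:]
    call = call_junction(read, ref)
    assert call.call_class is CallClass.DELETION
    assert call.del_size == 1
    assert call.distance_to_cut == 0


def test_insertion_at_cut(ref):
    c = ref.cut_index
    read = ref.sequence[:c] + "GG" + ref.sequence[c:]
    call = call_junction(read, ref)
    assert call.call_class is CallClass.INSERTION
    assert call.insert_seq == "GG"
    assert call.del_size == 0
    assert call.distance_to_cut == 0


def test_deletion_distance_uses_equivalence_region(ref):
    # right flank position 12 ('T' between two 'C's): 1-bp deletion with
    # microhomology 0 whose left-aligned start is 12 bases right of the cut
    c = ref.cut_index
    read = ref.sequence[: c + 12] + ref.sequence[c + 13 :]
    call = call_junction(read, ref)
    assert call.mh_length == 0
    assert call.distance_to_cut == 12
    # deletion spanning the cut -> distance 0
    assert distance_to_cut_interval(ref.sequence, (c - 3, c + 3), c) == 0


def test_unmodified_read(ref):
    call = call_junction(ref.sequence, ref)
    assert call.call_class is CallClass.UNMODIFIED
    assert call.del_size == 0 and call.insert_seq == "" and call.mh_length == 0
    assert call.distance_to_cut == 0


def test_shift_range_length_is_mh_plus_one(ref):
    call = call_junction(ref.hr_product(), ref)
    s0, s1 = call.shift_range
    assert s1 - s0 == call.mh_length + 1


# ---------------------------------------------------------------------------
# round trip: simulator -> caller
# ---------------------------------------------------------------------------

_CLASS_TO_CALL = {
    EventClass.UNCUT: CallClass.UNMODIFIED,
    EventClass.HR: CallClass.DELETION,
    EventClass.NHEJ_DELETION: CallClass.DELETION,
    EventClass.MMEJ_DELETION: CallClass.DELETION,
    EventClass.NHEJ_INSERTION: CallClass.INSERTION,
    EventClass.NHEJ_DEL_WITH_INSERT: CallClass.DEL_WITH_INSERT,
}


def test_zero_error_round_trip_recovers_events(ref, default_mixture):
    events = sample_events(default_mixture, ref, 400, seed=8)
    records, _ = events_to_reads(events, ref, seed=9)
    for event, rec in zip(events, records):
        call = call_junction(str(rec.seq), ref, read_id=rec.id)
        assert call.call_class is _CLASS_TO_CALL[event.event_class]
        if event.del_interval and call.call_class is CallClass.DELETION:
            # recovered interval must be in the same shift-equivalence class
            assert call.del_size == event.del_interval[1] - event.del_interval[0]
            s0 = left_align_deletion(ref.sequence, event.del_interval)[0]
            assert call.del_interval[0] == s0
            assert call.mh_length == microhomology_length(ref.sequence, event.del_interval)
        if event.event_class is EventClass.NHEJ_INSERTION:
            assert len(call.insert_seq) == len(event.insert_seq)


def test_left_alignment_idempotence(ref, default_mixture):
    """Reconstructing a call's read and re-calling returns an identical call."""
    events = sample_events(default_mixture, ref, 200, seed=12)
    records, _ = events_to_reads(events, ref, seed=13)
    for rec in records:
        first = call_junction(str(rec.seq), ref, read_id=rec.id)
        if first.call_class in (CallClass.UNALIGNABLE, CallClass.UNMODIFIED):
            continue
        s, e = first.del_interval if first.del_interval else (ref.cut_index, ref.cut_index)
        rebuilt = ref.sequence[:s] + first.insert_seq + ref.sequence[e:]
        assert call_junction(rebuilt, ref, read_id=rec.id) == first


@settings(deadline=None, max_examples=50, derandomize=True)
@given(size=st.integers(1, 25), offset=st.integers(0, 25), seed=st.integers(0, 100))
def test_constructed_deletions_always_recovered(ref, size, offset, seed):
    """Any cut-proximal deletion is recovered in the right equivalence class."""
    c = ref.cut_index
    s = c - offset
    read = ref.sequence[:s] + ref.sequence[s + size :]
    call = call_junction(read, ref)
    assert call.call_class is CallClass.DELETION
    assert call.del_size == size
    assert call.del_interval[0] == left_align_deletion(ref.sequence, (s, s + size))[0]
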