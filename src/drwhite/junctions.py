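"""Repair-junction calling against the reporter amplicon.

Each read is anchored on two short primer-proximal segments of the
reference chosen *outside* the HR-deleted window (the published target-site
flanks compose the I-SceI site itself, which HR removes, so anchoring on
them would make HR products unalignable; here the printed flanks define
only the cut coordinate).  The inter-anchor segment is then compared with
the corresponding reference segment by longest-common-prefix/suffix
arithmetic, which yields the indel, its full shift-equivalence class
(microhomology), and its distance to the cut.

Conventions
-----------
* Deletions are reported left-aligned: the smallest start index among all
  placements producing the identical repaired sequence.
* Microhomology of a deletion is the deletion-junction ambiguity length:
  the number of equivalent placements minus one.  Insertions get 0.
* Distance to the cut uses the whole shift-equivalence region, not the
  left-aligned point, so that a microhomology-shiftable junction near the
  cut is retained regardless of alignment convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .reference import ReferenceConstruct


class CallClass(str, enum.Enum):
    UNMODIFIED = "unmodified"
    DELETION = "deletion"
    INSERTION = "insertion"
    DEL_WITH_INSERT = "del_with_insert"
    UNALIGNABLE = "unalignable"


@dataclass(frozen=True)
class JunctionCall:
    """One read's parsed repair outcome (coordinates on the reference)."""

    read_id: str
    call_class: CallClass
    del_interval: tuple[int, int] | None = None  # left-aligned, half-open
    del_size: int = 0
    insert_seq: str = ""
    mh_length: int = 0
    # Half-open range of equivalent deletion start positions (deletions) or
    # insertion points (insertions); length == mh_length + 1 for deletions.
    shift_range: tuple[int, int] | None = None
    distance_to_cut: int = 0
    reason: str = ""  # populated for unalignable calls

    @property
    def has_deletion(self) -> bool:
        return self.del_size > 0

    @property
    def is_pure_deletion(self) -> bool:
        return self.call_class is CallClass.DELETION


# ---------------------------------------------------------------------------
# microhomology / left alignment primitives
# ---------------------------------------------------------------------------


def left_align_deletion(seq: str, interval: tuple[int, int]) -> tuple[int, int]:
    """Shift a deletion interval to its leftmost equivalent placement."""
    s, e = _check_interval(seq, interval)
    while s > 0 and seq[s - 1] == seq[e - 1]:
        s -= 1
        e -= 1
    return s, e


def microhomology_length(seq: str, interval: tuple[int, int]) -> int:
    """Junction ambiguity of a deletion: number of equivalent placements - 1.

    Equals the largest ``m`` with ``seq[s:s+m] == seq[e:e+m]`` evaluated at
    the left-aligned placement ``[s, e)``; placement-invariant by
    construction (any equivalent input interval gives the same answer).
    """
    s, e = left_align_deletion(seq, interval)
    m = 0
    while e + m < len(seq) and seq[s + m] == seq[e + m]:
        m += 1
    return m


def _check_interval(seq: str, interval: tuple[int, int]) -> tuple[int, int]:
    s, e = interval
    if not (0 <= s < e <= len(seq)):
        raise ValueError(f"deletion interval {interval} out of bounds for length {len(seq)}")
    return s, e


def distance_to_cut_interval(
    seq: str, interval: tuple[int, int], cut_index: int
) -> int:
    """Minimal gap (bp) between a deletion's shift-equivalence region and the cut.

    0 when the region (union of all equivalent placements) contains or
    touches the inter-base cut index.
    """
    s, e = left_align_deletion(seq, interval)
    m = microhomology_length(seq, (s, e))
    region_start, region_end = s, e + m  # union of deleted bases over placements
    if region_start > cut_index:
        return region_start - cut_index
    if region_end < cut_index:
        return cut_index - region_end
    return 0


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def _find_with_mismatch(read: str, probe: str, rightmost: bool, start: int = 0) -> int:
    """Position of an occurrence of ``probe`` in ``read`` allowing <=1 mismatch.

    Exact occurrences are preferred; returns -1 if absent.
    """
    pos = read.rfind(probe) if rightmost else read.find(probe, start)
    if pos >= 0:
        return pos
    k = len(probe)
    positions = range(len(read) - k, start - 1, -1) if rightmost else range(start, len(read) - k + 1)
    for i in positions:
        mism = 0
        for a, b in zip(read[i : i + k], probe):
            if a != b:
                mism += 1
                if mism > 1:
                    break
        if mism <= 1:
            return i
    return -1


def anchor_read(read: str, ref: ReferenceConstruct) -> tuple[int, int] | None:
    """Locate the two anchor segments in a read.

    Returns ``(left_anchor_end, right_anchor_start)`` in read coordinates
    (the rightmost occurrence of the left anchor and the leftmost occurrence
    of the right anchor beyond it; one mismatch tolerated per anchor), or
    ``None`` if either anchor is absent.
    """
    read = read.upper()
    left_pos = _find_with_mismatch(read, ref.left_anchor, rightmost=True)
    if left_pos < 0:
        return None
    left_end = left_pos + len(ref.left_anchor)
    right_pos = _find_with_mismatch(read, ref.right_anchor, rightmost=False, start=left_end)
    if right_pos < 0:
        return None
    return left_end, right_pos


# ---------------------------------------------------------------------------
# junction calling
# ---------------------------------------------------------------------------


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def call_junction(
    read: str,
    ref: ReferenceConstruct,
    read_id: str = "read",
    substitution_tolerance: int = 2,
) -> JunctionCall:
    """Call the repair junction of one read against the reference.

    Deterministic; deletions are left-aligned.  Equal-length reads with at
    most ``substitution_tolerance`` scattered mismatches are treated as
    unmodified (sequencing substitutions), a single contiguous same-length
    mismatch run as a deletion-with-insert, and anything with more
    non-contiguous differences as unalignable.
    """
    anchors = anchor_read(read, ref)
    if anchors is None:
        return JunctionCall(read_id, CallClass.UNALIGNABLE, reason="anchor_not_found")
    left_end, right_start = anchors
    seg = read.upper()[left_end:right_start]

    ref_lo = ref.left_anchor_interval[1]
    ref_hi = ref.right_anchor_interval[0]
    rseg = ref.sequence[ref_lo:ref_hi]
    cut = ref.cut_index

    len_m, len_r = len(seg), len(rseg)
    L = _common_prefix(rseg, seg)
    S = _common_suffix(rseg, seg)

    if len_m == len_r:
        if L == len_r:
            return JunctionCall(read_id, CallClass.UNMODIFIED)
        diffs = [i for i in range(len_r) if seg[i] != rseg[i]]
        if len(diffs) <= substitution_tolerance:
            return JunctionCall(read_id, CallClass.UNMODIFIED)
        if diffs[-1] - diffs[0] + 1 == len(diffs) or (L + S < len_r and all(
            rseg[i] != seg[i] for i in range(L, len_r - S)
        )):
            # single contiguous replacement run -> deletion with insert
            return _replacement_call(read_id, rseg, seg, L, S, ref_lo, cut)
        return JunctionCall(
            read_id, CallClass.UNALIGNABLE, reason="multiple_noncontiguous_differences"
        )

    if len_m < len_r:  # net deletion
        d = len_r - len_m
        if L + S >= len_m:  # pure deletion
            s_min = max(0, len_r - S - d)
            s_max = min(L, len_r - d)
            mh = s_max - s_min
            s0 = s_min + ref_lo
            interval = (s0, s0 + d)
            return JunctionCall(
                read_id,
                CallClass.DELETION,
                del_interval=interval,
                del_size=d,
                mh_length=mh,
                shift_range=(s0, s0 + mh + 1),
                distance_to_cut=distance_to_cut_interval(ref.sequence, interval, cut),
            )
        return _replacement_call(read_id, rseg, seg, L, S, ref_lo, cut)

    # net insertion
    d = len_m - len_r
    if L + S >= len_r:  # pure insertion
        p_min = max(0, len_r - S)
        p_max = min(L, len_r)
        p0 = p_min + ref_lo
        shift = p_max - p_min
        dist = max(0, p0 - cut, cut - (p0 + shift))
        return JunctionCall(
            read_id,
            CallClass.INSERTION,
            insert_seq=seg[p_min : p_min + d],
            shift_range=(p0, p0 + shift + 1),
            distance_to_cut=dist,
        )
    return _replacement_call(read_id, rseg, seg, L, S, ref_lo, cut)


def _replacement_call(
    read_id: str, rseg: str, seg: str, L: int, S: int, ref_lo: int, cut: int
) -> JunctionCall:
    """Deletion-with-insert: reference run [L, len_r-S) replaced by read run."""
    s, e = L + ref_lo, len(rseg) - S + ref_lo
    insert = seg[L : len(seg) - S]
    dist = 0 if s <= cut <= e else (s - cut if s > cut else cut - e)
    return JunctionCall(
        read_id,
        CallClass.DEL_WITH_INSERT,
        del_interval=(s, e),
        del_size=e - s,
        insert_seq=insert,
        shift_range=(s, s + 1),
        distance_to_cut=dist,
    )


def call_reads(
    reads: "list[tuple[str, str]]", ref: ReferenceConstruct
) -> list[JunctionCall]:
    """Call junctions for an iterable of ``(read_id, sequence)`` pairs."""
    return [call_junction(seq, ref, read_id=rid) for rid, seq in reads]
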