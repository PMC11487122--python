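"""Operating-characteristic scans of the junction caller and classifier.

These scans recover the pipeline's operative thresholds from its observed
behaviour on constructed single-indel products: the HR-signature deletion
length, the largest indel still labelled NHEJ, the cut-proximity retention
boundary, and the smallest microhomology labelled MMEJ.  They serve as
end-to-end checks that the implementation enforces exactly the thresholds
it is configured with.
"""

from __future__ import annotations

import numpy as np

from .classify import ClassifierConfig, Pathway, apply_cut_filter, classify_call
from .events import EventClass, RepairEvent
from .junctions import call_junction, microhomology_length
from .reads import events_to_reads
from .reference import RIGHT_FLANK, ReferenceConstruct, assemble_reference, build_reference


def hr_deletion_size_called(arm_length: int = 50, seed: int = 1) -> int:
    """Deletion size called for a zero-error perfect-HR read."""
    ref = build_reference(arm_length, seed=seed)
    event = RepairEvent(EventClass.HR, del_interval=ref.hr_deletion_interval)
    records, _ = events_to_reads([event], ref, seed=seed)
    call = call_junction(str(records[0].seq), ref)
    return call.del_size


def _nhej_compatible_deletion(
    ref: ReferenceConstruct, size: int
) -> tuple[int, int] | None:
    """A cut-spanning deletion of ``size`` with junction microhomology <= 1
    that is not the HR signature, if the reference offers one."""
    c = ref.cut_index
    for s in range(c - size, c + 1):
        if s < 0 or s + size > len(ref.sequence):
            continue
        if microhomology_length(ref.sequence, (s, s + size)) <= 1:
            if size == 23 and s <= ref.hr_deletion_interval[0] <= s + 1:
                continue
            return (s, s + size)
    return None


def max_nhej_indel_size(
    config: ClassifierConfig | None = None,
    max_scan: int = 30,
    arm_length: int = 50,
    seed: int = 1,
) -> int:
    """Largest indel size (scanning 1..max_scan) the classifier labels NHEJ.

    For each size, both a zero-microhomology deletion at the cut and an
    insertion at the cut are constructed and classified.
    """
    config = config or ClassifierConfig()
    ref = build_reference(arm_length, seed=seed)
    rng = np.random.default_rng(seed)
    c = ref.cut_index
    largest = 0
    for size in range(1, max_scan + 1):
        reads = []
        interval = _nhej_compatible_deletion(ref, size)
        if interval is not None:
            reads.append(ref.sequence[: interval[0]] + ref.sequence[interval[1] :])
        insert = "".join(rng.choice(list("ACGT"), size=size))
        reads.append(ref.sequence[:c] + insert + ref.sequence[c:])
        for read in reads:
            call = call_junction(read, ref)
            if classify_call(call, config, ref) is Pathway.NHEJ:
                largest = max(largest, size)
    return largest


def max_retained_cut_distance(
    config: ClassifierConfig | None = None,
    max_scan: int = 20,
    arm_length: int = 50,
    seed: int = 1,
) -> int:
    """Largest called cut distance surviving the proximity filter.

    Scans 1-bp deletions at offsets 0..max_scan right of the cut (offsets
    within the target-site flank give deterministic microhomology-0 sites).
    """
    config = config or ClassifierConfig()
    ref = build_reference(arm_length, seed=seed)
    c = ref.cut_index
    calls = []
    for off in range(0, max_scan + 1):
        read = ref.sequence[: c + off] + ref.sequence[c + off + 1 :]
        calls.append(call_junction(read, ref, read_id=f"off{off}"))
    retained, _ = apply_cut_filter(calls, config)
    return max(call.distance_to_cut for call in retained)


def reference_with_cut_microhomology(m: int, seed: int = 1) -> tuple[ReferenceConstruct, tuple[int, int]]:
    """An amplicon whose left arm ends with an engineered repeat, plus a
    cut-spanning deletion interval with junction microhomology exactly ``m``.

    The repeat is a copy of the right flank's first ``m`` bases placed at
    the end of the left arm, so deleting [arm_tail_start, cut) (through the
    whole left flank) leaves exactly ``m`` ambiguous bases at the junction.
    The printed flank and primer sequences are untouched.
    """
    if not (0 <= m <= 5):
        raise ValueError("engineered microhomology supported for m in 0..5")
    # at m=5 the right-flank prefix would extend the match ('T' at both
    # positions 0 and 5 of the comparison), so the second copy starts at 1
    e_off = 1 if m == 5 else 0
    tail = RIGHT_FLANK[e_off : e_off + m]
    rng = np.random.default_rng(seed)
    for _ in range(100):
        body = "".join(rng.choice(list("ACGT"), size=50 - 1 - m))
        left_arm = body + "T" + tail  # 'T' guard blocks left-shift of the junction
        right_arm = "".join(rng.choice(list("ACGT"), size=50))
        try:
            ref = assemble_reference(left_arm, right_arm)
        except ValueError:
            continue
        c = ref.cut_index
        interval = (c - len(ref.left_flank) - m, c + e_off)
        if microhomology_length(ref.sequence, interval) == m:
            return ref, interval
    raise RuntimeError(f"could not engineer microhomology {m}")


def min_mmej_microhomology(
    config: ClassifierConfig | None = None, max_scan: int = 5, seed: int = 1
) -> int:
    """Smallest engineered junction microhomology labelled MMEJ (scan 0..max_scan)."""
    config = config or ClassifierConfig()
    for m in range(0, max_scan + 1):
        ref, (s, e) = reference_with_cut_microhomology(m, seed=seed)
        read = ref.sequence[:s] + ref.sequence[e:]
        call = call_junction(read, ref)
        if classify_call(call, config, ref) is Pathway.MMEJ:
            return m
    raise RuntimeError("no scanned microhomology classified MMEJ")
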