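"""Pathway classification of repair-junction calls.

Implements the published filtering and class definitions: reads whose
junction lies more than 10 bp from the expected cut site are excluded;
the fixed 23-nt recognition-site deletion is the HR signature; pure
deletions with >= 2 bp of junction microhomology are MMEJ; the remaining
insertions, deletions and deletions-with-insert up to 25 bp are NHEJ.
Indels above the 25-bp cap are tallied separately ("other") rather than
silently dropped, so totals stay auditable.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field, asdict

from .junctions import CallClass, JunctionCall
from .reference import ReferenceConstruct


@dataclass(frozen=True)
class ClassifierConfig:
    max_cut_distance: int = 10  # bp; retention boundary, inclusive
    hr_deletion_size: int = 23
    nhej_max_indel: int = 25
    mmej_min_mh: int = 2
    tide_indel_window: int = 25

    def __post_init__(self) -> None:
        for name in ("max_cut_distance", "hr_deletion_size", "nhej_max_indel", "mmej_min_mh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a nonnegative integer")


class Pathway(str, enum.Enum):
    UNMODIFIED = "unmodified"
    HR = "hr"
    NHEJ = "nhej"
    MMEJ = "mmej"
    OTHER = "other"  # indel above the NHEJ size cap


def apply_cut_filter(
    calls: list[JunctionCall], config: ClassifierConfig
) -> tuple[list[JunctionCall], dict[str, int]]:
    """Retain unmodified calls and junctions within ``max_cut_distance`` of the cut.

    Unalignable calls are dropped (and counted); returns (retained, drop counts).
    """
    retained: list[JunctionCall] = []
    drops = {"unalignable": 0, "distance": 0}
    for call in calls:
        if call.call_class is CallClass.UNALIGNABLE:
            drops["unalignable"] += 1
        elif call.call_class is CallClass.UNMODIFIED:
            retained.append(call)
        elif call.distance_to_cut <= config.max_cut_distance:
            retained.append(call)
        else:
            drops["distance"] += 1
    return retained, drops


def classify_call(
    call: JunctionCall, config: ClassifierConfig, ref: ReferenceConstruct
) -> Pathway:
    """Assign a retained call to unmodified / hr / nhej / mmej / other.

    The HR signature (a deletion whose shift-equivalence class contains the
    HR interval, with no insert) wins unconditionally, even if its junction
    shows incidental microhomology.
    """
    if call.call_class is CallClass.UNMODIFIED:
        return Pathway.UNMODIFIED
    if call.call_class is CallClass.DELETION and _is_hr_signature(call, config, ref):
        return Pathway.HR
    indel_size = max(call.del_size, len(call.insert_seq))
    if indel_size > config.nhej_max_indel:
        return Pathway.OTHER
    if call.call_class is CallClass.DELETION and call.mh_length >= config.mmej_min_mh:
        return Pathway.MMEJ
    return Pathway.NHEJ


def _is_hr_signature(
    call: JunctionCall, config: ClassifierConfig, ref: ReferenceConstruct
) -> bool:
    if call.del_size != config.hr_deletion_size or call.insert_seq:
        return False
    s0, s1 = call.shift_range  # equivalent start positions, half-open
    return s0 <= ref.hr_deletion_interval[0] < s1


@dataclass
class PathwaySummary:
    """Per-sample repair-product counts, proportions and histograms."""

    n_total: int
    n_retained: int
    n_unalignable: int
    n_dropped_distance: int
    n_unmodified: int
    n_hr: int
    n_nhej: int
    n_mmej: int
    n_other: int
    pct_repaired: float
    pct_hr_of_repaired: float
    pct_nhej_of_repaired: float
    pct_mmej_of_deletions: float
    deletion_size_histogram: dict[int, int] = field(default_factory=dict)
    mh_histogram: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(
    calls: list[JunctionCall], config: ClassifierConfig, ref: ReferenceConstruct
) -> PathwaySummary:
    """Filter, classify and tabulate a sample's junction calls.

    Percentages use the published denominators: repaired products
    (hr+nhej+mmej) over retained reads; HR and NHEJ over repaired products;
    MMEJ over pure-deletion products.
    """
    retained, drops = apply_cut_filter(calls, config)
    counts: Counter[Pathway] = Counter()
    del_sizes: Counter[int] = Counter()
    mh_hist: Counter[int] = Counter()
    n_pure_deletions = 0
    for call in retained:
        pw = classify_call(call, config, ref)
        counts[pw] += 1
        if pw in (Pathway.HR, Pathway.NHEJ, Pathway.MMEJ) and call.has_deletion:
            del_sizes[call.del_size] += 1
        if pw in (Pathway.NHEJ, Pathway.MMEJ) and call.call_class is CallClass.DELETION:
            n_pure_deletions += 1
            mh_hist[call.mh_length] += 1

    n_retained = len(retained)
    n_repaired = counts[Pathway.HR] + counts[Pathway.NHEJ] + counts[Pathway.MMEJ]
    pct = lambda a, b: 100.0 * a / b if b else 0.0
    return PathwaySummary(
        n_total=len(calls),
        n_retained=n_retained,
        n_unalignable=drops["unalignable"],
        n_dropped_distance=drops["distance"],
        n_unmodified=counts[Pathway.UNMODIFIED],
        n_hr=counts[Pathway.HR],
        n_nhej=counts[Pathway.NHEJ],
        n_mmej=counts[Pathway.MMEJ],
        n_other=counts[Pathway.OTHER],
        pct_repaired=pct(n_repaired, n_retained),
        pct_hr_of_repaired=pct(counts[Pathway.HR], n_repaired),
        pct_nhej_of_repaired=pct(counts[Pathway.NHEJ], n_repaired),
        pct_mmej_of_deletions=pct(counts[Pathway.MMEJ], n_pure_deletions),
        deletion_size_histogram=dict(sorted(del_sizes.items())),
        mh_histogram=dict(sorted(mh_hist.items())),
    )
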