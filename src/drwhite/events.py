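"""Ground-truth repair events and the event sampler.

Event classes mirror the assay's readout: perfect HR (fixed 23-nt deletion
of the recognition-site window), NHEJ (small deletions, insertions, and
deletions with non-templated insert, all <= 25 bp), MMEJ (deletions whose
junction carries >= 2 bp of flanking microhomology), and uncut molecules.

Default mixture proportions follow the reporter's published behaviour: HR
around 20% of repair products, NHEJ ~75%, MMEJ a minor ~5%; within NHEJ,
99.3% of products contain a deletion, mostly 1 bp.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .junctions import left_align_deletion, microhomology_length
from .reference import ReferenceConstruct

_BASES = "ACGT"


class EventClass(str, enum.Enum):
    UNCUT = "uncut"
    HR = "hr"
    NHEJ_DELETION = "nhej_deletion"
    NHEJ_INSERTION = "nhej_insertion"
    NHEJ_DEL_WITH_INSERT = "nhej_del_with_insert"
    MMEJ_DELETION = "mmej_deletion"


NHEJ_CLASSES = frozenset(
    {EventClass.NHEJ_DELETION, EventClass.NHEJ_INSERTION, EventClass.NHEJ_DEL_WITH_INSERT}
)


@dataclass(frozen=True)
class RepairEvent:
    event_class: EventClass
    del_interval: tuple[int, int] | None = None
    insert_seq: str = ""
    mh_length: int = 0

    def apply(self, ref: ReferenceConstruct) -> str:
        """Mutated amplicon sequence produced by this event."""
        seq = ref.sequence
        if self.event_class is EventClass.UNCUT:
            return seq
        if self.del_interval is not None:
            s, e = self.del_interval
            return seq[:s] + self.insert_seq + seq[e:]
        c = ref.cut_index
        return seq[:c] + self.insert_seq + seq[c:]


def _truncated_geometric(p_one: float, max_size: int) -> dict[int, float]:
    raw = {k: p_one * (1.0 - p_one) ** (k - 1) for k in range(1, max_size + 1)}
    z = sum(raw.values())
    return {k: v / z for k, v in raw.items()}


#: Deletion-size distribution: geometric-like with P(1 bp) = 0.6, truncated
#: at 25 bp (the published spectra give only summary ranges; 1-bp deletions
#: dominate).
DEFAULT_DELETION_SIZES = _truncated_geometric(0.6, 25)
#: Insertion sizes 1-3 bp, 1 bp most common.
DEFAULT_INSERTION_SIZES = {1: 0.6, 2: 0.25, 3: 0.15}

#: Within-NHEJ composition: 99.3% of NHEJ products contain a deletion
#: (pure deletions plus a small deletion-with-insert fraction).
DEFAULT_DELETION_FRACTION_WITHIN_NHEJ = 0.993
DEFAULT_DEL_WITH_INSERT_FRACTION = 0.005


@dataclass(frozen=True)
class EventMixture:
    """Proportions of repair-event classes plus NHEJ indel-size model."""

    proportions: dict[EventClass, float]
    nhej_deletion_sizes: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DELETION_SIZES)
    )
    nhej_insertion_sizes: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INSERTION_SIZES)
    )

    def __post_init__(self) -> None:
        for name, dist in (
            ("proportions", self.proportions),
            ("nhej_deletion_sizes", self.nhej_deletion_sizes),
            ("nhej_insertion_sizes", self.nhej_insertion_sizes),
        ):
            if any(v < 0 for v in dist.values()):
                raise ValueError(f"{name} must be nonnegative")
            if not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1 (got {sum(dist.values())!r})")

    @property
    def deletion_fraction_within_nhej(self) -> float:
        nhej = sum(self.proportions.get(k, 0.0) for k in NHEJ_CLASSES)
        if nhej == 0:
            return float("nan")
        dels = self.proportions.get(EventClass.NHEJ_DELETION, 0.0) + self.proportions.get(
            EventClass.NHEJ_DEL_WITH_INSERT, 0.0
        )
        return dels / nhej

    @classmethod
    def from_pathway_fractions(
        cls,
        hr: float = 0.20,
        nhej: float = 0.75,
        mmej: float = 0.05,
        uncut: float = 0.0,
        deletion_fraction_within_nhej: float = DEFAULT_DELETION_FRACTION_WITHIN_NHEJ,
        del_with_insert_fraction: float = DEFAULT_DEL_WITH_INSERT_FRACTION,
        **size_dists,
    ) -> "EventMixture":
        """Build a mixture from pathway-level fractions.

        ``deletion_fraction_within_nhej`` is the fraction of NHEJ products
        containing a deletion (pure deletions + deletions-with-insert);
        ``del_with_insert_fraction`` is the deletion-with-insert share of all
        NHEJ products.
        """
        pure_del = deletion_fraction_within_nhej - del_with_insert_fraction
        if pure_del < 0:
            raise ValueError("del_with_insert_fraction exceeds deletion fraction")
        props = {
            EventClass.UNCUT: uncut,
            EventClass.HR: hr,
            EventClass.NHEJ_DELETION: nhej * pure_del,
            EventClass.NHEJ_DEL_WITH_INSERT: nhej * del_with_insert_fraction,
            EventClass.NHEJ_INSERTION: nhej * (1.0 - deletion_fraction_within_nhej),
            EventClass.MMEJ_DELETION: mmej,
        }
        return cls(proportions=props, **size_dists)

    @classmethod
    def default(cls) -> "EventMixture":
        return cls.from_pathway_fractions()


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _random_insert(rng: np.random.Generator, size: int) -> str:
    return "".join(rng.choice(list(_BASES), size=size))


def _sample_size(rng: np.random.Generator, dist: dict[int, float]) -> int:
    sizes = sorted(dist)
    p = np.array([dist[k] for k in sizes], dtype=float)
    return int(rng.choice(sizes, p=p / p.sum()))


def _is_hr_equivalent(ref: ReferenceConstruct, interval: tuple[int, int]) -> bool:
    s, e = interval
    if e - s != ref.hr_deletion_interval[1] - ref.hr_deletion_interval[0]:
        return False
    s0, _ = left_align_deletion(ref.sequence, interval)
    m = microhomology_length(ref.sequence, interval)
    return s0 <= ref.hr_deletion_interval[0] <= s0 + m


def _sample_nhej_deletion(
    rng: np.random.Generator, ref: ReferenceConstruct, dist: dict[int, float]
) -> tuple[tuple[int, int], int]:
    """Deletion spanning/touching the cut with junction microhomology <= 1."""
    c = ref.cut_index
    for _ in range(100):
        k = _sample_size(rng, dist)
        s = int(rng.integers(c - k, c + 1))
        interval = (s, s + k)
        mh = microhomology_length(ref.sequence, interval)
        if mh <= 1 and not _is_hr_equivalent(ref, interval):
            return interval, mh
    # exhaustive fallback: any size with a valid placement
    for k in sorted(dist, key=dist.get, reverse=True):
        for s in range(c - k, c + 1):
            interval = (s, s + k)
            mh = microhomology_length(ref.sequence, interval)
            if mh <= 1 and not _is_hr_equivalent(ref, interval):
                return interval, mh
    raise RuntimeError("no NHEJ-compatible deletion placement near the cut")


def _mmej_candidates(
    ref: ReferenceConstruct, dist: dict[int, float], wiggle: int = 8
) -> tuple[list[tuple[tuple[int, int], int]], np.ndarray]:
    """All cut-touching deletion intervals with >= 2 bp microhomology."""
    c = ref.cut_index
    cands: list[tuple[tuple[int, int], int]] = []
    weights: list[float] = []
    for k in sorted(dist):
        if k < 2:
            continue
        for s in range(c - k - wiggle, c + wiggle + 1):
            if s < 0 or s + k > len(ref.sequence):
                continue
            interval = (s, s + k)
            mh = microhomology_length(ref.sequence, interval)
            if mh < 2 or _is_hr_equivalent(ref, interval):
                continue
            s0, e0 = left_align_deletion(ref.sequence, interval)
            if not (s0 <= c <= e0 + mh):  # equivalence region must touch the cut
                continue
            cands.append((interval, mh))
            weights.append(dist[k])
    return cands, np.asarray(weights, dtype=float)


def sample_events(
    mixture: EventMixture, ref: ReferenceConstruct, n: int, seed: int
) -> list[RepairEvent]:
    """Draw ``n`` ground-truth repair events from a mixture.

    Multinomial over event classes; deletion intervals are placed so their
    shift-equivalence region touches the cut.  MMEJ deletions are drawn from
    the enumerated set of intervals whose flanks share >= 2 identical bases
    in this reference; NHEJ deletions are rejection-sampled to junction
    microhomology <= 1 and are never HR-signature-equivalent.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    classes = sorted(mixture.proportions, key=lambda c: c.value)
    probs = np.array([mixture.proportions[c] for c in classes], dtype=float)
    counts = rng.multinomial(n, probs / probs.sum())

    events: list[RepairEvent] = []
    for cls_, count in zip(classes, counts):
        for _ in range(count):
            events.append(_sample_one(rng, cls_, mixture, ref))
    # interleave classes so truncation of the list is unbiased
    rng.shuffle(events)  # type: ignore[arg-type]
    return events


def _sample_one(
    rng: np.random.Generator,
    cls_: EventClass,
    mixture: EventMixture,
    ref: ReferenceConstruct,
) -> RepairEvent:
    seq, c = ref.sequence, ref.cut_index
    if cls_ is EventClass.UNCUT:
        return RepairEvent(EventClass.UNCUT)
    if cls_ is EventClass.HR:
        return RepairEvent(
            EventClass.HR,
            del_interval=ref.hr_deletion_interval,
            mh_length=microhomology_length(seq, ref.hr_deletion_interval),
        )
    if cls_ is EventClass.NHEJ_DELETION:
        interval, mh = _sample_nhej_deletion(rng, ref, mixture.nhej_deletion_sizes)
        return RepairEvent(EventClass.NHEJ_DELETION, del_interval=interval, mh_length=mh)
    if cls_ is EventClass.NHEJ_INSERTION:
        size = _sample_size(rng, mixture.nhej_insertion_sizes)
        return RepairEvent(EventClass.NHEJ_INSERTION, insert_seq=_random_insert(rng, size))
    if cls_ is EventClass.NHEJ_DEL_WITH_INSERT:
        interval, _ = _sample_nhej_deletion(rng, ref, mixture.nhej_deletion_sizes)
        s, e = interval
        # an equal-length replacement is observationally a substitution, not
        # an indel product, so the insert length must differ from the deletion
        for _ in range(100):
            size = _sample_size(rng, mixture.nhej_insertion_sizes)
            if size != e - s:
                break
        for _ in range(100):
            ins = _random_insert(rng, size)
            # insert must not extend the flank matches, or the product would
            # collapse to a pure (shifted) deletion
            if ins[0] != seq[s] and ins[-1] != seq[e - 1]:
                break
        return RepairEvent(EventClass.NHEJ_DEL_WITH_INSERT, del_interval=interval, insert_seq=ins)
    if cls_ is EventClass.MMEJ_DELETION:
        cands = _mmej_cache(ref, mixture)
        if not cands[0]:
            raise RuntimeError("reference offers no >=2 bp-microhomology deletion near the cut")
        idx = int(rng.choice(len(cands[0]), p=cands[1]))
        interval, mh = cands[0][idx]
        return RepairEvent(EventClass.MMEJ_DELETION, del_interval=interval, mh_length=mh)
    raise ValueError(f"unknown event class {cls_}")


_MMEJ_CACHE: dict[tuple[int, int], tuple[list, np.ndarray]] = {}


def _mmej_cache(ref: ReferenceConstruct, mixture: EventMixture):
    key = (hash(ref.sequence), hash(tuple(sorted(mixture.nhej_deletion_sizes.items()))))
    if key not in _MMEJ_CACHE:
        cands, w = _mmej_candidates(ref, mixture.nhej_deletion_sizes)
        _MMEJ_CACHE[key] = (cands, w / w.sum() if len(w) else w)
    return _MMEJ_CACHE[key]
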