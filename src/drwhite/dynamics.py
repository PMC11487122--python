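"""Focus-trajectory statistics and the ROI relative-enrichment statistic.

Movement out of polycomb bodies is summarized at a query lag after focus
appearance (default 10 minutes, snapped to the nearest imaging timepoint);
kinetics as the median focus lifetime; retention as the fraction of foci
that never leave the domain before resolving.  The ROI statistic compares
mean histone-mark intensity in a small region around the DSB with the whole
polycomb body, per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .tracks import FocusTrack, INSIDE, OUTSIDE, NOT_DETECTABLE, RESOLVED
from . import qpcr


def state_at(track: FocusTrack, lag_minutes: float) -> str:
    """State at the sampled timepoint nearest to appearance + lag.

    Resolved persists beyond the last observation; a never-resolved track
    queried beyond its horizon reports its last observed state.
    """
    t_query = track.appearance_time + lag_minutes
    times = np.array([t for t, _ in track.states])
    last_t, last_s = track.states[-1]
    if t_query > last_t:
        return last_s  # resolved is absorbing; otherwise last observation
    idx = int(np.argmin(np.abs(times - t_query)))
    return track.states[idx][1]


@dataclass(frozen=True)
class MovementSummary:
    n_foci: int
    lag_minutes: float
    n_outside_at_t: int
    n_inside_at_t: int
    n_nd_or_resolved_at_t: int
    pct_outside: float  # denominator: all appeared foci
    pct_outside_of_detected: float  # denominator excluding nd/resolved foci
    median_resolution_time: float | None
    accumulation_pct: float

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def location_counts(self) -> list[int]:
        return [self.n_outside_at_t, self.n_inside_at_t, self.n_nd_or_resolved_at_t]


def fraction_outside_at(
    tracks: list[FocusTrack], lag_minutes: float = 10.0
) -> MovementSummary:
    """Tally focus locations at a lag after appearance.

    ``pct_outside`` uses all appeared foci as denominator (not-detectable
    and already-resolved foci count as a third category of the same pie);
    ``pct_outside_of_detected`` excludes them, since the published
    denominator convention is not stated.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    n_out = n_in = n_other = 0
    for track in tracks:
        s = state_at(track, lag_minutes)
        if s == OUTSIDE:
            n_out += 1
        elif s == INSIDE:
            n_in += 1
        else:
            n_other += 1
    n = len(tracks)
    detected = n_out + n_in
    return MovementSummary(
        n_foci=n,
        lag_minutes=lag_minutes,
        n_outside_at_t=n_out,
        n_inside_at_t=n_in,
        n_nd_or_resolved_at_t=n_other,
        pct_outside=100.0 * n_out / n,
        pct_outside_of_detected=100.0 * n_out / detected if detected else 0.0,
        median_resolution_time=median_resolution_time(tracks),
        accumulation_pct=accumulation_fraction(tracks),
    )


def median_resolution_time(tracks: list[FocusTrack]) -> float | None:
    """Median first-resolution time; ``None`` if <50% resolve within horizon."""
    times = np.array(
        [t if (t := track.resolution_time()) is not None else np.inf for track in tracks]
    )
    med = float(np.median(times))
    return med if np.isfinite(med) else None


def accumulation_fraction(tracks: list[FocusTrack]) -> float:
    """Percentage of foci whose every observed pre-resolution state is inside."""
    n_acc = sum(
        1
        for track in tracks
        if all(s == INSIDE for _, s in track.states if s != RESOLVED)
    )
    return 100.0 * n_acc / len(tracks) if tracks else 0.0


# ---------------------------------------------------------------------------
# ROI relative enrichment (live-imaging H3K27me3 proxy)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiEnrichment:
    ratios: pd.Series  # per-cell dsb/domain intensity ratio
    mean_ratio: float
    pct_drop: float
    n_rejected: int


def roi_relative_enrichment(table: pd.DataFrame) -> RoiEnrichment:
    """Per-cell DSB-region / whole-domain intensity ratios.

    ``table`` needs columns ``cell_id``, ``dsb_mean_intensity`` and
    ``domain_mean_intensity``; rows with nonpositive domain intensity are
    rejected (with a warning) rather than poisoning the mean.
    """
    ok = table["domain_mean_intensity"] > 0
    n_rejected = int((~ok).sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} cells with nonpositive domain intensity")
    sub = table[ok]
    ratios = (sub["dsb_mean_intensity"] / sub["domain_mean_intensity"]).rename("ratio")
    mean_ratio = float(ratios.mean()) if len(ratios) else float("nan")
    return RoiEnrichment(
        ratios=ratios,
        mean_ratio=mean_ratio,
        pct_drop=(1.0 - mean_ratio) * 100.0,
        n_rejected=n_rejected,
    )


def compare_conditions(
    a: MovementSummary, b: MovementSummary
) -> tuple[float, int, float]:
    """Two-sided chi-square on the two conditions' location-category counts."""
    table = np.array([a.location_counts, b.location_counts])
    return qpcr.chi_square_2xk(table)
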