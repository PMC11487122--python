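"""Simulated DSB repair-focus trajectories relative to polycomb bodies.

Each track is one repair focus that appears (t = 0) inside a polycomb body
and is followed on a regular 5-minute imaging grid.  Its location at the
10-minute checkpoint is drawn from a preset categorical distribution
(outside / inside / not-detectable); afterwards a per-interval resolution
hazard, calibrated to the preset's median focus lifetime, retires the
focus.  Foci still inside at 10 minutes either leave later or accumulate
(never leave before resolution), with the accumulating fraction a preset
parameter.

Presets are calibrated to the published movement percentages:
60% of Mu2 foci (single I-SceI DSB) leave the domain within ten minutes,
77% of ATRIP foci in irradiated control cells, 53% under dUtx depletion;
the ATRIP accumulation fractions are 21% (control) and 33% (dUtx RNAi).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

INSIDE = "inside"
OUTSIDE = "outside"
NOT_DETECTABLE = "not_detectable"
RESOLVED = "resolved"
STATES = (INSIDE, OUTSIDE, NOT_DETECTABLE, RESOLVED)


@dataclass(frozen=True)
class FocusTrack:
    """One focus's state sequence; times in minutes from appearance."""

    focus_id: str
    states: tuple[tuple[float, str], ...]
    appearance_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("a track needs at least one observation")
        times = [t for t, _ in self.states]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("observation times must be strictly increasing")
        if self.states[0] != (self.appearance_time, INSIDE):
            raise ValueError("tracks model foci born inside polycomb bodies")
        seen_resolved = False
        for _, s in self.states:
            if s not in STATES:
                raise ValueError(f"unknown state {s!r}")
            if seen_resolved and s != RESOLVED:
                raise ValueError("resolved is absorbing")
            seen_resolved = seen_resolved or s == RESOLVED

    def resolution_time(self) -> float | None:
        for t, s in self.states:
            if s == RESOLVED:
                return t
        return None


@dataclass(frozen=True)
class TrackPreset:
    name: str
    p_out: float  # P(outside at the 10-min checkpoint)
    p_nd: float = 0.0  # P(not detectable at 10 min)
    p_accumulate: float = 0.0  # long-run fraction never leaving before resolution
    median_resolution_min: float = 55.0
    interval_min: float = 5.0
    horizon_min: float = 45.0
    late_exit_p: float = 0.4  # per-interval exit probability after 10 min

    def __post_init__(self) -> None:
        if not (0 <= self.p_out <= 1 and 0 <= self.p_nd <= 1 and 0 <= self.p_accumulate <= 1):
            raise ValueError("preset probabilities must be in [0, 1]")
        if self.p_out + self.p_nd + self.p_accumulate > 1 + 1e-9:
            raise ValueError("p_out + p_nd + p_accumulate must not exceed 1")

    @property
    def resolution_hazard(self) -> float:
        """Per-interval hazard after the 10-min checkpoint matching the median."""
        if self.median_resolution_min <= 10:
            raise ValueError("median resolution must exceed the 10-min checkpoint")
        n_intervals = (self.median_resolution_min - 10.0) / self.interval_min
        return 1.0 - 0.5 ** (1.0 / n_intervals)


PRESETS: dict[str, TrackPreset] = {
    "mu2_isceI_control": TrackPreset("mu2_isceI_control", p_out=0.60, p_accumulate=0.20),
    "atrip_control": TrackPreset("atrip_control", p_out=0.77, p_accumulate=0.21),
    "atrip_dUtx": TrackPreset("atrip_dUtx", p_out=0.53, p_accumulate=0.33),
}


def simulate_focus_tracks(
    preset: str | TrackPreset,
    n: int,
    seed: int,
    horizon_min: float | None = None,
) -> list[FocusTrack]:
    """Draw ``n`` focus tracks from a preset.

    Every track starts inside at t=0; location at the 10-min checkpoint
    follows the preset's categorical distribution; resolution is geometric
    on the imaging grid after the checkpoint.  ``horizon_min`` overrides the
    preset's observation horizon (kinetics analyses need a horizon beyond
    the median lifetime).
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            ) from None
    if horizon_min is not None:
        preset = replace(preset, horizon_min=horizon_min)
    rng = np.random.default_rng(seed)
    p_late = 1.0 - preset.p_out - preset.p_nd - preset.p_accumulate
    fates = rng.choice(
        ["exit_early", "nd", "accumulate", "exit_late"],
        size=n,
        p=[preset.p_out, preset.p_nd, preset.p_accumulate, max(p_late, 0.0)],
    )
    return [_one_track(rng, f"focus_{i:05d}", fate, preset) for i, fate in enumerate(fates)]


def _geometric_time(rng: np.random.Generator, start: float, p: float, dt: float) -> float:
    """First event time on the grid start, start+dt, ... with per-step prob p."""
    if p <= 0:
        return float("inf")
    return start + dt * (rng.geometric(p) - 1)


def _one_track(
    rng: np.random.Generator, focus_id: str, fate: str, preset: TrackPreset
) -> FocusTrack:
    dt, horizon = preset.interval_min, preset.horizon_min
    checkpoint = 10.0
    if fate == "exit_early":
        exit_time = float(rng.choice([5.0, checkpoint]))
        nd_time = float("inf")
    elif fate == "nd":
        exit_time = float("inf")
        nd_time = float(rng.choice([5.0, checkpoint]))
    elif fate == "accumulate":
        exit_time = float("inf")
        nd_time = float("inf")
    else:  # exit_late: leaves after the checkpoint, before resolving
        exit_time = _geometric_time(rng, checkpoint + dt, preset.late_exit_p, dt)
        nd_time = float("inf")

    # resolution hazard starts after the 10-min checkpoint; late exiters
    # resolve only after they have left (their defining behaviour)
    hazard_start = max(checkpoint, exit_time if fate == "exit_late" else checkpoint) + dt
    resolve_time = _geometric_time(rng, hazard_start, preset.resolution_hazard, dt)

    states: list[tuple[float, str]] = []
    t = 0.0
    while t <= horizon + 1e-9:
        if t >= resolve_time:
            states.append((t, RESOLVED))
            break
        elif t >= nd_time:
            states.append((t, NOT_DETECTABLE))
        elif t >= exit_time:
            states.append((t, OUTSIDE))
        else:
            states.append((t, INSIDE))
        t += dt
    return FocusTrack(focus_id=focus_id, states=tuple(states))
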