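"""Aggregate per-position trace profiles downstream of the cut.

A simulated stand-in for Sanger chromatograms: at each read position
downstream of the cut, a 4-channel (A/C/G/T) signal.  A molecule carrying a
net deletion of ``d`` bases upstream shows the reference base shifted by
``+d`` at every downstream position; an insertion of ``d`` bases shows
ambiguous signal over the inserted stretch, then the reference shifted by
``-d``.  An aggregate trace over a molecule population is the
weight-averaged sum of these shifted indicator profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import ReferenceConstruct

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
CHANNELS = ("A", "C", "G", "T")


@dataclass(frozen=True)
class TraceProfile:
    """Per-position 4-channel intensities at offsets 0.. downstream of cut."""

    positions: np.ndarray  # 0-based offsets downstream of the cut
    signal: np.ndarray  # shape (n_positions, 4), channel order A/C/G/T

    def __post_init__(self) -> None:
        if self.signal.shape != (len(self.positions), 4):
            raise ValueError("signal must have shape (n_positions, 4)")


def _onehot(base: str) -> np.ndarray:
    v = np.zeros(4)
    v[_BASE_INDEX[base]] = 1.0
    return v


def candidate_profile(
    ref: ReferenceConstruct, offset: int, n_positions: int
) -> np.ndarray:
    """Indicator profile of the reference carrying a net indel of ``offset`` bp.

    ``offset`` < 0 is a deletion of ``-offset`` bases ending at the cut;
    ``offset`` > 0 an insertion of unknown bases at the cut (ambiguity-
    averaged: 0.25 per channel over the inserted stretch).
    """
    seq, c = ref.sequence, ref.cut_index
    out = np.zeros((n_positions, 4))
    for j in range(n_positions):
        if offset >= 0 and j < offset:
            out[j] = 0.25
        else:
            out[j] = _onehot(seq[c + j - offset])
    return out


def default_trace_length(ref: ReferenceConstruct, window: int) -> int:
    """Longest usable trace: deletion candidates need ``window`` bases of slack."""
    return len(ref) - ref.cut_index - window - 1


def simulate_trace(
    weights: dict[int, float],
    ref: ReferenceConstruct,
    n_positions: int | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    window: int = 25,
) -> TraceProfile:
    """Aggregate trace for a mixture of indel offsets.

    ``weights`` maps indel offset (0 = unedited, negative = deletion,
    positive = insertion) to a nonnegative fraction; fractions must sum to
    at most 1 (a deficit reads as uniformly dimmer signal).
    """
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be nonnegative")
    total = sum(weights.values())
    if total > 1.0 + 1e-9:
        raise ValueError(f"weights must sum to <= 1 (got {total})")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    if n_positions is None:
        n_positions = min(50, default_trace_length(ref, window))
    signal = np.zeros((n_positions, 4))
    for offset, w in weights.items():
        signal += w * candidate_profile(ref, offset, n_positions)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return TraceProfile(positions=np.arange(n_positions), signal=signal)
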