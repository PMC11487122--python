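"""Trace decomposition: estimate an indel spectrum from an aggregate trace.

The trace downstream of the cut is modelled as a nonnegative mixture of
indel-shifted reference indicator profiles (offsets -window..+window).
Weights are recovered by nonnegative least squares; the -23 component is
the HR product, all other nonzero offsets up to the window are NHEJ-type
edits.  Weights below 0.1% are zeroed and the remainder renormalized; no
per-component significance testing is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .reference import ReferenceConstruct, HR_DELETION_SIZE
from .traces import TraceProfile, candidate_profile

PRUNE_THRESHOLD = 1e-3


@dataclass(frozen=True)
class ShiftLibrary:
    """Candidate profiles, one per indel offset in [-window, +window]."""

    offsets: tuple[int, ...]
    profiles: np.ndarray  # shape (n_offsets, n_positions, 4)
    n_positions: int

    @property
    def design_matrix(self) -> np.ndarray:
        return self.profiles.reshape(len(self.offsets), -1).T


@dataclass(frozen=True)
class DecompositionResult:
    weights: dict[int, float]
    r_squared: float
    total_editing: float


@dataclass(frozen=True)
class SpectrumReport:
    pct_hr: float
    pct_nhej: float
    pct_total_edited: float


def build_shift_library(
    ref: ReferenceConstruct, window: int = 25, n_positions: int | None = None
) -> ShiftLibrary:
    """One candidate per offset d in {-window..+window} on a shared grid."""
    if window < 1:
        raise ValueError("window must be >= 1")
    max_pos = len(ref) - ref.cut_index - window - 1
    if n_positions is None:
        n_positions = min(50, max_pos)
    if n_positions < 1 or n_positions > max_pos:
        raise ValueError(
            f"n_positions must be in [1, {max_pos}] for this reference/window"
        )
    offsets = tuple(range(-window, window + 1))
    profiles = np.stack([candidate_profile(ref, d, n_positions) for d in offsets])
    return ShiftLibrary(offsets=offsets, profiles=profiles, n_positions=n_positions)


def decompose(trace: TraceProfile, library: ShiftLibrary) -> DecompositionResult:
    """Nonnegative least-squares fit of the trace onto the shift library.

    Minimizes ``||signal - sum_d w_d candidate_d||^2`` s.t. ``w_d >= 0``;
    weights < 0.1% are zeroed, the rest renormalized to fractions of the
    decomposable signal.  ``r_squared`` is computed from the raw NNLS fit.
    """
    if len(trace.positions) != library.n_positions:
        raise ValueError("trace and library must share the position grid")
    b = trace.signal.reshape(-1)
    if not np.any(b):
        raise ValueError("empty trace")
    A = library.design_matrix
    w, rnorm = nnls(A, b)
    rss = rnorm**2
    tss = float(np.sum((b - b.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0

    w = np.where(w < PRUNE_THRESHOLD, 0.0, w)
    total = w.sum()
    if total > 0:
        w = w / total
    weights = {d: float(x) for d, x in zip(library.offsets, w)}
    return DecompositionResult(
        weights=weights,
        r_squared=float(r2),
        total_editing=float(1.0 - weights.get(0, 0.0)),
    )


def spectrum_report(result: DecompositionResult) -> SpectrumReport:
    """HR / NHEJ split of the edited fraction (HR = the -23 component)."""
    total = result.total_editing
    if total <= 0:
        return SpectrumReport(0.0, 0.0, 0.0)
    w_hr = result.weights.get(-HR_DELETION_SIZE, 0.0)
    return SpectrumReport(
        pct_hr=100.0 * w_hr / total,
        pct_nhej=max(0.0, 100.0 * (total - w_hr) / total),
        pct_total_edited=100.0 * total,
    )
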