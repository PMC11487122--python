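"""Reporter amplicon model for the DR-*white* single-DSB assay.

The reporter is PCR-amplified around an I-SceI recognition site.  The
amplicon is modelled as::

    left_primer + left_arm + left_flank | right_flank + right_arm + rc(right_primer)

where ``|`` is the cut point (an inter-base index).  The last 9 nt of the
left flank and the first 9 nt of the right flank together form the 18-bp
I-SceI recognition site.  Homologous recombination with the internal
*iwhite* donor removes the recognition site, observed as a fixed 23-nt
deletion spanning the cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Assay constants: target-site flanks and amplification primers.
LEFT_FLANK = "TTGAGCTGTAGGGATAA"
RIGHT_FLANK = "CAGGGTAATAGCTCTTTG"
LEFT_PRIMER = "GACTGGACTCATTTACCGCCC"
RIGHT_PRIMER = "TTGGTAGGACACTGGGCAC"
ISCEI_SITE = "TAGGGATAACAGGGTAAT"  # last 9 nt of left flank + first 9 of right

HR_DELETION_SIZE = 23
# The 23-nt HR deletion window is placed as [cut-9, cut+14): any placement
# containing the cut is consistent with the assay readout; this one keeps the
# full 18-nt recognition site inside the deleted window.
HR_LEFT_OF_CUT = 9

# Read-anchoring geometry (see junctions.anchor_read).  Anchors sit outside
# the HR window — and outside the flanks entirely — so that HR products,
# which lose the recognition site, remain anchorable.
ANCHOR_LENGTH = 12
ANCHOR_MARGIN = 18  # bases between flank end and anchor, on each side

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASES = np.array(list("ACGT"))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceConstruct:
    """The unrepaired reporter amplicon and its annotations.

    Coordinates are 0-based, half-open; ``cut_index`` is an inter-base
    index (the boundary between the two cleavage halves).
    """

    sequence: str
    cut_index: int
    hr_deletion_interval: tuple[int, int]
    left_flank: str = LEFT_FLANK
    right_flank: str = RIGHT_FLANK
    left_primer: str = LEFT_PRIMER
    right_primer: str = RIGHT_PRIMER

    def __post_init__(self) -> None:
        seq, c = self.sequence, self.cut_index
        h0, h1 = self.hr_deletion_interval
        if h1 - h0 != HR_DELETION_SIZE or not (h0 <= c <= h1):
            raise ValueError(
                f"HR deletion interval must have length {HR_DELETION_SIZE} "
                f"and contain the cut index; got {self.hr_deletion_interval}"
            )
        if seq.count(self.left_flank) != 1 or not seq[:c].endswith(self.left_flank):
            raise ValueError("left flank must occur exactly once, ending at the cut")
        if seq.count(self.right_flank) != 1 or not seq[c:].startswith(self.right_flank):
            raise ValueError("right flank must occur exactly once, starting at the cut")
        if not seq.startswith(self.left_primer):
            raise ValueError("left primer must be a prefix of the amplicon")
        if not seq.endswith(reverse_complement(self.right_primer)):
            raise ValueError("right primer reverse complement must be a suffix")

    # -- anchor annotations -------------------------------------------------

    @property
    def left_anchor_interval(self) -> tuple[int, int]:
        end = self.cut_index - len(self.left_flank) - ANCHOR_MARGIN
        return (end - ANCHOR_LENGTH, end)

    @property
    def right_anchor_interval(self) -> tuple[int, int]:
        start = self.cut_index + len(self.right_flank) + ANCHOR_MARGIN
        return (start, start + ANCHOR_LENGTH)

    @property
    def left_anchor(self) -> str:
        a, b = self.left_anchor_interval
        return self.sequence[a:b]

    @property
    def right_anchor(self) -> str:
        a, b = self.right_anchor_interval
        return self.sequence[a:b]

    def hr_product(self) -> str:
        """Amplicon sequence after perfect HR (HR window excised)."""
        h0, h1 = self.hr_deletion_interval
        return self.sequence[:h0] + self.sequence[h1:]

    def __len__(self) -> int:
        return len(self.sequence)


def assemble_reference(left_arm: str, right_arm: str) -> ReferenceConstruct:
    """Assemble a reporter amplicon from explicit arm sequences.

    Raises ``ValueError`` if the arms recreate a flank (flank uniqueness is
    what makes the cut coordinate well defined).
    """
    left_arm, right_arm = left_arm.upper(), right_arm.upper()
    seq = (
        LEFT_PRIMER
        + left_arm
        + LEFT_FLANK
        + RIGHT_FLANK
        + right_arm
        + reverse_complement(RIGHT_PRIMER)
    )
    cut = len(LEFT_PRIMER) + len(left_arm) + len(LEFT_FLANK)
    return ReferenceConstruct(
        sequence=seq,
        cut_index=cut,
        hr_deletion_interval=(cut - HR_LEFT_OF_CUT, cut - HR_LEFT_OF_CUT + HR_DELETION_SIZE),
    )


def build_reference(arm_length: int, seed: int) -> ReferenceConstruct:
    """Build a reporter amplicon with random arms of ``arm_length`` bp.

    ``seed`` is mandatory: generated constructs are part of a simulation's
    provenance and must be reproducible.  Arms that recreate a flank (or the
    recognition site) are resampled, erroring after 100 attempts.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if arm_length < 30:
        raise ValueError("arm_length must be >= 30 (anchoring needs 30 bp arms)")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        left_arm = "".join(rng.choice(_BASES, size=arm_length))
        right_arm = "".join(rng.choice(_BASES, size=arm_length))
        try:
            ref = assemble_reference(left_arm, right_arm)
        except ValueError:
            continue
        if ref.sequence.count(ISCEI_SITE) == 1:
            return ref
    raise RuntimeError("could not assemble arms free of flank collisions in 100 attempts")
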