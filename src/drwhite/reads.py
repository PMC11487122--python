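"""Amplicon read simulation from ground-truth repair events.

Reads emulate merged 150-bp paired-end amplicon sequencing: by default each
event yields one full-length read of the mutated amplicon (pair merging is
out of scope), with independent per-base substitution errors and constant
Q30 qualities.  A truth table links every read id to its generating event.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .events import RepairEvent
from .reference import ReferenceConstruct

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

TRUTH_COLUMNS = ["read_id", "event_class", "del_start", "del_end", "insert_seq", "mh_length"]


def events_to_reads(
    events: list[RepairEvent],
    ref: ReferenceConstruct,
    seed: int,
    read_length: int | None = None,
    substitution_rate: float = 0.0,
    quality: int = 30,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Sequence each event's mutated amplicon into FASTQ records + truth table.

    ``read_length`` truncates reads from the 5' end (``None`` keeps the full
    amplicon, emulating merged pairs).  Substitution errors are independent
    per base at ``substitution_rate``; indel sequencing errors are not
    modelled (the assay's signal is itself an indel).
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if not (0.0 <= substitution_rate <= 0.1):
        raise ValueError("substitution_rate must be in [0, 0.1]")
    if read_length is not None and read_length > len(ref):
        raise ValueError("read_length exceeds amplicon length")
    rng = np.random.default_rng(seed)

    records: list[SeqRecord] = []
    truth_rows = []
    for i, event in enumerate(events):
        read_id = f"read_{i:06d}"
        seq = event.apply(ref)
        if read_length is not None:
            seq = seq[:read_length]
        if substitution_rate > 0:
            seq = _substitute(rng, seq, substitution_rate)
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
        s, e = event.del_interval if event.del_interval else (-1, -1)
        truth_rows.append(
            (read_id, event.event_class.value, s, e, event.insert_seq, event.mh_length)
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return records, truth


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for pos in hits:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(3))]
    return "".join(arr)
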