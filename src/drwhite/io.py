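"""File formats: FASTA/FASTQ via Biopython, all tables as headered TSV.

Table schemas
-------------
truth          read_id, event_class, del_start, del_end, insert_seq, mh_length
calls          read_id, call_class, del_start, del_end, del_size, insert_seq,
               mh_length, shift_start, shift_end, distance_to_cut, reason
tracks         focus_id, time_min, state
qPCR plate     locus, channel, assay, condition, replicate, ct
ROI table      cell_id, dsb_mean_intensity, domain_mean_intensity
trace          position, A, C, G, T

Missing intervals are encoded as -1 in TSV (tables stay integer-typed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .junctions import CallClass, JunctionCall
from .tracks import FocusTrack
from .traces import TraceProfile

CALL_COLUMNS = [
    "read_id", "call_class", "del_start", "del_end", "del_size", "insert_seq",
    "mh_length", "shift_start", "shift_end", "distance_to_cut", "reason",
]


# -- sequences --------------------------------------------------------------


def write_fasta(path, records) -> None:
    SeqIO.write(records, str(path), "fasta")


def write_fastq(path, records) -> None:
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# -- tables -----------------------------------------------------------------


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def calls_to_frame(calls: list[JunctionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        s, e = c.del_interval if c.del_interval else (-1, -1)
        ss, se = c.shift_range if c.shift_range else (-1, -1)
        rows.append(
            (c.read_id, c.call_class.value, s, e, c.del_size, c.insert_seq,
             c.mh_length, ss, se, c.distance_to_cut, c.reason)
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def frame_to_calls(df: pd.DataFrame) -> list[JunctionCall]:
    calls = []
    for r in df.fillna({"insert_seq": "", "reason": ""}).itertuples(index=False):
        calls.append(
            JunctionCall(
                read_id=r.read_id,
                call_class=CallClass(r.call_class),
                del_interval=None if r.del_start < 0 else (int(r.del_start), int(r.del_end)),
                del_size=int(r.del_size),
                insert_seq=str(r.insert_seq),
                mh_length=int(r.mh_length),
                shift_range=None if r.shift_start < 0 else (int(r.shift_start), int(r.shift_end)),
                distance_to_cut=int(r.distance_to_cut),
                reason=str(r.reason),
            )
        )
    return calls


def tracks_to_frame(tracks: list[FocusTrack]) -> pd.DataFrame:
    rows = [(t.focus_id, time, state) for t in tracks for time, state in t.states]
    return pd.DataFrame(rows, columns=["focus_id", "time_min", "state"])


def frame_to_tracks(df: pd.DataFrame) -> list[FocusTrack]:
    tracks = []
    for focus_id, group in df.groupby("focus_id", sort=True):
        group = group.sort_values("time_min")
        states = tuple(zip(group["time_min"].astype(float), group["state"]))
        tracks.append(FocusTrack(focus_id=str(focus_id), states=states,
                                 appearance_time=float(group["time_min"].iloc[0])))
    return tracks


def trace_to_frame(trace: TraceProfile) -> pd.DataFrame:
    df = pd.DataFrame(trace.signal, columns=["A", "C", "G", "T"])
    df.insert(0, "position", trace.positions)
    return df


def frame_to_trace(df: pd.DataFrame) -> TraceProfile:
    return TraceProfile(
        positions=df["position"].to_numpy(),
        signal=df[["A", "C", "G", "T"]].to_numpy(dtype=float),
    )


# -- input validation -------------------------------------------------------


@dataclass(frozen=True)
class Diagnostic:
    path: str
    record: str
    message: str
    severity: str = "error"  # "error" or "note"


def validate_inputs(paths: list) -> list[Diagnostic]:
    """Check FASTQ/FASTA/TSV files for structural conformity.

    Returns one diagnostic per problem (empty list = all clean); never
    mutates inputs.  Mixed line endings are accepted with a note.
    """
    diags: list[Diagnostic] = []
    for path in map(Path, paths):
        if not path.exists():
            diags.append(Diagnostic(str(path), "-", "file not found"))
            continue
        raw = path.read_bytes()
        if b"\r\n" in raw and b"\n" != raw[:0]:
            has_unix = raw.replace(b"\r\n", b"").count(b"\n") > 0
            if has_unix:
                diags.append(Diagnostic(str(path), "-", "mixed line endings", "note"))
        text = raw.decode(errors="replace").replace("\r\n", "\n")
        suffix = path.suffix.lower()
        if suffix in (".fastq", ".fq"):
            diags.extend(_validate_fastq(str(path), text))
        elif suffix in (".fasta", ".fa"):
            if not text.lstrip().startswith(">"):
                diags.append(Diagnostic(str(path), "line 1", "FASTA must start with '>'"))
        elif suffix in (".tsv", ".txt"):
            diags.extend(_validate_tsv(str(path), text))
    return diags


def _validate_fastq(path: str, text: str) -> list[Diagnostic]:
    diags = []
    lines = text.rstrip("\n").split("\n") if text.strip() else []
    if len(lines) % 4 != 0:
        last_id = next((l for l in reversed(lines) if l.startswith("@")), "?")
        diags.append(Diagnostic(path, last_id, "truncated FASTQ record"))
        return diags
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        rec = header.split()[0] if header else f"line {i + 1}"
        if not header.startswith("@"):
            diags.append(Diagnostic(path, rec, "record header must start with '@'"))
        elif not plus.startswith("+"):
            diags.append(Diagnostic(path, rec, "separator line must start with '+'"))
        elif len(seq) != len(qual):
            diags.append(Diagnostic(path, rec, "sequence/quality length mismatch"))
    return diags


def _validate_tsv(path: str, text: str) -> list[Diagnostic]:
    lines = [l for l in text.split("\n") if l]
    if not lines:
        return [Diagnostic(path, "-", "empty table")]
    width = lines[0].count("\t")
    for i, line in enumerate(lines[1:], start=2):
        if line.count("\t") != width:
            return [Diagnostic(path, f"line {i}", "inconsistent column count")]
    return []
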