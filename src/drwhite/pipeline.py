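"""End-to-end orchestration: simulate -> call -> classify / decompose /
dynamics / chip, under one explicit-seed configuration.

A run writes every intermediate artifact (FASTA reference, FASTQ reads,
TSV tables) plus a single ``report.json`` / ``report.txt`` pair; identical
configurations produce byte-identical reports (no timestamps; JSON keys
sorted; every stochastic stage carries its own seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, classify, dynamics, io, plates, qpcr, tide, tracks, traces
from .events import EventMixture, sample_events
from .reads import events_to_reads
from .reference import build_reference
from .junctions import call_reads

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Seeds, mixture/preset selections and thresholds for one pipeline run.

    Round-trips through YAML unchanged; every stochastic stage has its own
    seed so stages can be re-run independently.
    """

    seeds: dict = field(
        default_factory=lambda: {
            "reference": 1, "events": 2, "reads": 3, "trace": 4,
            "tracks": 5, "qpcr": 6, "roi": 7,
        }
    )
    arm_length: int = 50
    n_events: int = 2000
    mixture: dict = field(
        default_factory=lambda: {"hr": 0.20, "nhej": 0.75, "mmej": 0.05, "uncut": 0.0}
    )
    substitution_rate: float = 0.0
    classifier: dict = field(default_factory=dict)
    trace: dict = field(default_factory=lambda: {"weights": {"0": 0.7, "-23": 0.2, "-1": 0.1}, "noise_sd": 0.0})
    tracks: dict = field(default_factory=lambda: {"preset": "mu2_isceI_control", "n": 2000, "lag": 10.0})
    qpcr: dict = field(
        default_factory=lambda: {
            "target_locus": "3xp3", "control_locus": "ubx",
            "loss_fraction": 0.28, "replicates": 13, "noise_sd_ct": 0.2,
        }
    )
    roi: dict = field(default_factory=lambda: {"preset": "damaged_control", "n_cells": 300})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def chip_design(target: str, control: str, loss_fraction: float) -> pd.DataFrame:
    """Two-locus, two-condition ChIP design with a mark loss at the target.

    In the DSB condition the target locus keeps ``1 - loss_fraction`` of its
    control-condition IP recovery; the internal-control locus is unchanged.
    """
    return pd.DataFrame(
        [
            (target, "minus_dsb", 1.0, 8.0),
            (target, "plus_dsb", 1.0, 8.0 * (1.0 - loss_fraction)),
            (control, "minus_dsb", 1.0, 8.0),
            (control, "plus_dsb", 1.0, 8.0),
        ],
        columns=["locus", "condition", "input_quantity", "ip_over_input"],
    )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages in dependency order; returns the report dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "drwhite",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seeds": dict(config.seeds),
    }

    # -- sequencing arm: simulate, call, classify ---------------------------
    logger.info("stage reference/events/reads")
    ref = build_reference(config.arm_length, seed=config.seeds["reference"])
    mixture = EventMixture.from_pathway_fractions(**config.mixture)
    events = sample_events(mixture, ref, n=config.n_events, seed=config.seeds["events"])
    records, truth = events_to_reads(
        events, ref, seed=config.seeds["reads"], substitution_rate=config.substitution_rate
    )
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    io.write_fasta(out / "reference.fasta", [SeqRecord(Seq(ref.sequence), id="drwhite_amplicon", description="")])
    io.write_fastq(out / "reads.fastq", records)
    io.write_table(truth, out / "truth.tsv")

    calls = call_reads([(rec.id, str(rec.seq)) for rec in records], ref)
    io.write_table(io.calls_to_frame(calls), out / "calls.tsv")
    cfg = classify.ClassifierConfig(**config.classifier)
    summary = classify.summarize(calls, cfg, ref)
    report["pathway_summary"] = summary.to_dict()

    # -- trace decomposition ------------------------------------------------
    logger.info("stage trace/decompose")
    weights = {int(k): float(v) for k, v in config.trace["weights"].items()}
    trace = traces.simulate_trace(
        weights, ref, noise_sd=config.trace.get("noise_sd", 0.0), seed=config.seeds["trace"]
    )
    io.write_table(io.trace_to_frame(trace), out / "trace.tsv")
    library = tide.build_shift_library(ref, window=cfg.tide_indel_window,
                                       n_positions=len(trace.positions))
    result = tide.decompose(trace, library)
    spectrum = tide.spectrum_report(result)
    report["trace_decomposition"] = {
        "weights": {str(k): v for k, v in sorted(result.weights.items()) if v > 0},
        "r_squared": result.r_squared,
        "pct_hr": spectrum.pct_hr,
        "pct_nhej": spectrum.pct_nhej,
        "pct_total_edited": spectrum.pct_total_edited,
    }

    # -- focus dynamics -----------------------------------------------------
    logger.info("stage tracks/dynamics")
    track_list = tracks.simulate_focus_tracks(
        config.tracks["preset"], n=config.tracks["n"], seed=config.seeds["tracks"]
    )
    io.write_table(io.tracks_to_frame(track_list), out / "tracks.tsv")
    movement = dynamics.fraction_outside_at(track_list, lag_minutes=config.tracks.get("lag", 10.0))
    report["focus_dynamics"] = movement.to_dict()

    # -- ChIP-qPCR ----------------------------------------------------------
    logger.info("stage qpcr/chip")
    qc = config.qpcr
    design = chip_design(qc["target_locus"], qc["control_locus"], qc["loss_fraction"])
    plate = plates.simulate_qpcr(
        design, replicates=qc["replicates"], noise_sd_ct=qc["noise_sd_ct"], seed=config.seeds["qpcr"]
    )
    io.write_table(plate, out / "qpcr_plate.tsv")
    enr = qpcr.ddct_enrichment(plate, qc["target_locus"], qc["control_locus"])
    minus = enr[enr["condition"] == "minus_dsb"].sort_values("replicate")["enrichment"]
    plus = enr[enr["condition"] == "plus_dsb"].sort_values("replicate")["enrichment"]
    chip = qpcr.percent_change(minus.to_numpy(), plus.to_numpy(), paired=True)
    report["chip_enrichment"] = asdict(chip)

    # -- ROI intensities ----------------------------------------------------
    logger.info("stage roi")
    roi_table = plates.simulate_roi_intensities(
        config.roi["preset"], n_cells=config.roi["n_cells"], seed=config.seeds["roi"]
    )
    io.write_table(roi_table, out / "roi.tsv")
    roi = dynamics.roi_relative_enrichment(roi_table)
    report["roi_enrichment"] = {
        "mean_ratio": roi.mean_ratio,
        "pct_drop": roi.pct_drop,
        "n_cells": int(len(roi.ratios)),
        "n_rejected": roi.n_rejected,
    }

    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    (out / "report.txt").write_text(_human_report(report))
    return report


def _human_report(report: dict) -> str:
    ps = report["pathway_summary"]
    td = report["trace_decomposition"]
    fd = report["focus_dynamics"]
    ce = report["chip_enrichment"]
    roi = report["roi_enrichment"]
    lines = [
        f"drwhite {report['version']}  (config {report['config_hash']})",
        "",
        "Repair-product classification (sequencing arm)",
        f"  reads retained        {ps['n_retained']}/{ps['n_total']}",
        f"  repaired              {ps['pct_repaired']:.1f}%",
        f"  HR of repaired        {ps['pct_hr_of_repaired']:.1f}%",
        f"  NHEJ of repaired      {ps['pct_nhej_of_repaired']:.1f}%",
        f"  MMEJ of deletions     {ps['pct_mmej_of_deletions']:.1f}%",
        "",
        "Trace decomposition",
        f"  total edited          {td['pct_total_edited']:.1f}%  (R^2 {td['r_squared']:.4f})",
        f"  HR / NHEJ of edited   {td['pct_hr']:.1f}% / {td['pct_nhej']:.1f}%",
        "",
        "Focus dynamics",
        f"  outside at {fd['lag_minutes']:.0f} min     {fd['pct_outside']:.1f}%  (n={fd['n_foci']})",
        f"  accumulation          {fd['accumulation_pct']:.1f}%",
        "",
        "ChIP-qPCR",
        f"  percent change        {ce['percent_change']:.1f}%  (p={ce['p_value']:.3g}, n={ce['n_pairs']})",
        "",
        "ROI enrichment",
        f"  mean DSB/domain ratio {roi['mean_ratio']:.3f}  (drop {roi['pct_drop']:.1f}%)",
        "",
    ]
    return "\n".join(lines)
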