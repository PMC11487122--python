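"""Synthetic qPCR plates and ROI intensity tables.

The qPCR generator maps true relative quantities to cycle thresholds as
``Ct = base_ct - log2(quantity) + Normal(0, noise_sd_ct)`` — one fresh
noise draw per well.  The ROI generator emulates per-cell mean-intensity
measurements of a histone-mark reporter at the DSB versus the whole
polycomb body; multiplicative lognormal noise is mean-centred so the
expected per-cell ratio equals the preset's true ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qpcr import PLATE_COLUMNS

DEFAULT_BASE_CT = 22.0


def simulate_qpcr(
    design: pd.DataFrame,
    replicates: int,
    noise_sd_ct: float,
    seed: int,
    base_ct: float = DEFAULT_BASE_CT,
    assay: str = "H3K27me3",
) -> pd.DataFrame:
    """Generate an IP/input Ct plate from a design of true quantities.

    ``design`` needs columns ``locus``, ``condition``, ``input_quantity``
    (relative chromatin abundance) and ``ip_over_input`` (true IP recovery
    ratio); every design row yields ``replicates`` IP wells and matched
    input wells.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if noise_sd_ct < 0:
        raise ValueError("noise_sd_ct must be nonnegative")
    required = {"locus", "condition", "input_quantity", "ip_over_input"}
    if not required.issubset(design.columns):
        raise ValueError(f"design must have columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    rows = []
    for row in design.itertuples(index=False):
        for rep in range(1, replicates + 1):
            q_in = row.input_quantity
            q_ip = row.input_quantity * row.ip_over_input
            if q_in <= 0 or q_ip <= 0:
                raise ValueError("true quantities must be positive")
            for channel, q in (("input", q_in), ("IP", q_ip)):
                ct = base_ct - np.log2(q) + (rng.normal(0.0, noise_sd_ct) if noise_sd_ct else 0.0)
                rows.append((row.locus, channel, assay, row.condition, rep, float(ct)))
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def simulate_spikein_rows(
    recoveries: dict[str, float],
    seed: int,
    noise_sd_ct: float = 0.0,
    base_ct: float = DEFAULT_BASE_CT,
) -> pd.DataFrame:
    """Barcoded spike-in nucleosome wells: one IP/input pair per mark.

    ``recoveries`` maps histone-mark name to its true IP/input recovery
    (on-target mark highest, off-target marks lower).
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    rng = np.random.default_rng(seed)
    rows = []
    for mark, rec in recoveries.items():
        if rec <= 0:
            raise ValueError("recoveries must be positive")
        noise = (rng.normal(0.0, noise_sd_ct), rng.normal(0.0, noise_sd_ct)) if noise_sd_ct else (0.0, 0.0)
        rows.append((mark, "input", base_ct + noise[0]))
        rows.append((mark, "IP", base_ct - np.log2(rec) + noise[1]))
    return pd.DataFrame(rows, columns=["barcode_mark", "channel", "ct"])


# ---------------------------------------------------------------------------
# ROI intensities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiPreset:
    name: str
    true_ratio: float  # mean DSB / domain intensity ratio
    domain_mean_log: float = np.log(100.0)  # lognormal location of domain intensity
    domain_sigma: float = 0.3
    ratio_sigma: float = 0.10  # per-cell multiplicative noise on the ratio


ROI_PRESETS: dict[str, RoiPreset] = {
    # ~10% drop in mark intensity at DSBs in untreated (control-RNAi) cells;
    # no drop when the demethylase is depleted
    "damaged_control": RoiPreset("damaged_control", true_ratio=0.90),
    "damaged_dUtx": RoiPreset("damaged_dUtx", true_ratio=1.00),
}


def simulate_roi_intensities(
    preset: str | RoiPreset, n_cells: int, seed: int
) -> pd.DataFrame:
    """Per-cell DSB and whole-domain mean intensities (arbitrary units).

    ``dsb_mean = true_ratio * domain_mean * noise`` with mean-one lognormal
    noise, so the expected per-cell ratio is exactly the preset's
    ``true_ratio``.  ``n_cells = 0`` yields an empty table.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")
    if isinstance(preset, str):
        try:
            preset = ROI_PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(ROI_PRESETS)}"
            ) from None
    rng = np.random.default_rng(seed)
    domain = rng.lognormal(preset.domain_mean_log, preset.domain_sigma, size=n_cells)
    # mean-one multiplicative noise: lognormal(-sigma^2/2, sigma)
    noise = (
        rng.lognormal(-preset.ratio_sigma**2 / 2.0, preset.ratio_sigma, size=n_cells)
        if preset.ratio_sigma > 0
        else np.ones(n_cells)
    )
    dsb = preset.true_ratio * domain * noise
    return pd.DataFrame(
        {
            "cell_id": [f"cell_{i:04d}" for i in range(n_cells)],
            "dsb_mean_intensity": dsb,
            "domain_mean_intensity": domain,
        }
    )
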