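"""qPCR quantification and the study's elementary statistics.

ChIP enrichment is quantified by the delta-delta-Ct scheme: per replicate,
IP/input quantity at a locus is 2**(Ct_input - Ct_IP); the target-locus
quantity is normalized to an internal-control locus with stable levels of
the assayed mark.  Condition comparisons use a ratio paired t-test (a
paired t-test on natural-log ratios), or Welch's t-test when unpaired.
Raw intermediate quantities are convention-dependent (no input-dilution
correction is applied); only ratios of ratios are interpreted, in which
any such factor cancels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ["locus", "channel", "assay", "condition", "replicate", "ct"]


@dataclass(frozen=True)
class EnrichmentResult:
    mean_minus: float
    mean_plus: float
    percent_change: float  # (1 - mean_plus/mean_minus) * 100; positive = loss
    t_statistic: float
    p_value: float
    n_pairs: int
    paired: bool


def _quantities(plate: pd.DataFrame, locus: str, assay: str | None) -> pd.DataFrame:
    sub = plate[plate["locus"] == locus]
    if assay is not None:
        sub = sub[sub["assay"] == assay]
    wide = sub.pivot_table(
        index=["condition", "replicate"], columns="channel", values="ct", aggfunc="mean"
    )
    missing = [ch for ch in ("IP", "input") if ch not in wide.columns]
    if missing:
        raise ValueError(f"locus {locus!r}: no {missing[0]} rows in plate")
    n_bad = int(wide[["IP", "input"]].isna().any(axis=1).sum())
    if n_bad:
        logger.warning("locus %r: dropping %d replicates lacking a matched IP/input row", locus, n_bad)
    wide = wide.dropna(subset=["IP", "input"])
    return (2.0 ** (wide["input"] - wide["IP"])).rename("quantity").reset_index()


def ddct_enrichment(
    plate: pd.DataFrame,
    target_locus: str,
    control_locus: str,
    assay: str | None = None,
) -> pd.DataFrame:
    """Per-replicate target-locus enrichment normalized to a control locus.

    Returns a frame with columns condition, replicate, enrichment; a pure
    function of the plate's Ct columns (invariant to uniform Ct shifts).
    Replicates lacking a matched IP/input row at either locus are dropped
    with a log entry.
    """
    target = _quantities(plate, target_locus, assay)
    control = _quantities(plate, control_locus, assay)
    merged = target.merge(
        control, on=["condition", "replicate"], suffixes=("_target", "_control")
    )
    merged["enrichment"] = merged["quantity_target"] / merged["quantity_control"]
    return merged[["condition", "replicate", "enrichment"]]


def percent_change(
    ratios_minus, ratios_plus, paired: bool = True
) -> EnrichmentResult:
    """Percent change of mean enrichment between conditions, with a t-test.

    The p-value is from a two-sided paired t-test on natural-log ratios
    (the "ratio paired t-test"); with ``paired=False`` a Welch t-test on
    log ratios is used instead.  Identical paired samples give p = 1.
    """
    a = np.asarray(ratios_minus, dtype=float)
    b = np.asarray(ratios_plus, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("enrichment ratios must be positive")
    change = (1.0 - b.mean() / a.mean()) * 100.0
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length samples")
        diffs = np.log(b) - np.log(a)
        if np.std(diffs) < 1e-12:  # degenerate: all pairs shifted identically
            if abs(diffs.mean()) < 1e-12:
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = float(np.sign(diffs.mean()) * np.inf), 0.0
        else:
            t_stat, p = stats.ttest_rel(np.log(b), np.log(a))
    else:
        t_stat, p = stats.ttest_ind(np.log(b), np.log(a), equal_var=False)
    return EnrichmentResult(
        mean_minus=float(a.mean()),
        mean_plus=float(b.mean()),
        percent_change=float(change),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_pairs=min(len(a), len(b)),
        paired=paired,
    )


def spikein_specificity(
    plate: pd.DataFrame, on_target_mark: str
) -> dict[str, float]:
    """Antibody specificity from barcoded spike-in nucleosome recoveries.

    Expects rows with columns ``barcode_mark``, ``channel``, ``ct``.  Each
    mark's IP/input recovery is reported as a percentage of the on-target
    mark's recovery (on-target = 100%).  Marks without both channels are
    reported absent (omitted), not zero.
    """
    if "barcode_mark" not in plate.columns:
        raise ValueError("plate has no spike-in rows (barcode_mark column)")
    wide = plate.pivot_table(
        index="barcode_mark", columns="channel", values="ct", aggfunc="mean"
    )
    recoveries = {}
    for mark, row in wide.iterrows():
        if pd.notna(row.get("IP")) and pd.notna(row.get("input")):
            recoveries[mark] = 2.0 ** (row["input"] - row["IP"])
    if on_target_mark not in recoveries:
        raise ValueError(f"on-target mark {on_target_mark!r} absent from spike-in rows")
    ref = recoveries[on_target_mark]
    return {mark: 100.0 * r / ref for mark, r in recoveries.items()}


def chi_square_2xk(counts) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a 2xk count table.

    Zero-margin categories are pooled out with a warning; a warning is also
    emitted when any expected cell is below 1.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("counts must form a 2 x k table")
    keep = table.sum(axis=0) > 0
    if not keep.all():
        warnings.warn("pooling zero-margin categories out of the chi-square table")
        table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("need at least two non-empty categories")
    if np.allclose(table[0], table[1]):
        return 0.0, table.shape[1] - 1, 1.0
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        warnings.warn("chi-square approximation unreliable: expected cell < 1")
    return float(stat), int(df), float(p)


def relative_viability(
    observed_test: int, observed_reference: int, expected_ratio: float = 1.0
) -> float:
    """Percentage viability from cross offspring counts.

    ``(observed_test / observed_reference) / expected_ratio * 100`` — e.g.
    adult males of the mutant genotype versus wild-type siblings at an
    expected 1:1 Mendelian ratio.
    """
    if observed_reference <= 0:
        raise ValueError("reference count must be positive")
    if expected_ratio <= 0:
        raise ValueError("expected_ratio must be positive")
    return observed_test / observed_reference / expected_ratio * 100.0


def relative_reduction(viability_a: float, viability_b: float) -> float:
    """Relative reduction (1 - vA/vB) x 100 between two viabilities."""
    if viability_b <= 0:
        raise ValueError("reference viability must be positive")
    return (1.0 - viability_a / viability_b) * 100.0


def knockdown_level(
    expression: pd.DataFrame,
    gene: str,
    housekeeping: str,
    condition: str,
    reference_condition: str,
) -> float:
    """2**(-ddCt) relative expression of ``gene`` vs a housekeeping gene.

    ``expression`` needs columns gene, condition, replicate, ct (RT-qPCR,
    no IP/input split).  Returns expression in ``condition`` relative to
    ``reference_condition``; 1.0 means no knockdown.
    """
    wide = expression.pivot_table(
        index=["condition", "replicate"], columns="gene", values="ct", aggfunc="mean"
    )
    for g in (gene, housekeeping):
        if g not in wide.columns:
            raise ValueError(f"gene {g!r} absent from expression table")
    dct = (wide[gene] - wide[housekeeping]).dropna()
    means = dct.groupby("condition").mean()
    for cond in (condition, reference_condition):
        if cond not in means.index:
            raise ValueError(f"condition {cond!r} absent from expression table")
    ddct = means[condition] - means[reference_condition]
    return float(2.0 ** (-ddct))
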