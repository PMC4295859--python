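"""qRT-PCR relative quantification and baseline-relative differences.

The default quantification divides the mean cycle threshold (CT) of the
target gene by the mean CT of the housekeeping gene (GAPDH) in the same
condition x time cell — the CT-ratio convention of the study this pipeline
models.  Because CT is inversely related to transcript abundance, the
CT-ratio moves *opposite* to expression; the conventional ``2**-ddCT``
fold-change is therefore offered side by side as an explicitly labelled
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QpcrPlate", "relative_quantity", "relative_difference_vs_baseline",
           "fold_change_ddct", "compare_conditions"]


class PlateError(ValueError):
    pass


@dataclass
class QpcrPlate:
    """Well records of a qPCR run.

    ``wells`` columns: gene, condition, time_h, replicate, ct.  Triplicates
    are typical but any replicate count >= 1 is accepted.
    """

    wells: pd.DataFrame
    housekeeping: str = "GAPDH"

    def __post_init__(self) -> None:
        required = {"gene", "condition", "time_h", "replicate", "ct"}
        missing = required - set(self.wells.columns)
        if missing:
            raise PlateError(f"plate table missing columns: {sorted(missing)}")
        ct = self.wells["ct"]
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise PlateError("all CT values must be positive and finite")

    def _cell(self, gene: str, condition: str, time_h) -> pd.Series:
        sel = self.wells[
            (self.wells["gene"] == gene)
            & (self.wells["condition"] == condition)
            & (self.wells["time_h"] == time_h)
        ]
        return sel["ct"]


def relative_quantity(plate: QpcrPlate, gene: str, condition: str, time_h) -> float:
    """CT-ratio relative quantity: mean CT(target) / mean CT(housekeeping)."""
    target = plate._cell(gene, condition, time_h)
    hk = plate._cell(plate.housekeeping, condition, time_h)
    if target.empty:
        raise PlateError(f"no wells for {gene} / {condition} / t={time_h}")
    if hk.empty:
        raise PlateError(
            f"no housekeeping ({plate.housekeeping}) wells for {condition} / t={time_h}"
        )
    return float(target.mean() / hk.mean())


def relative_difference_vs_baseline(
    plate: QpcrPlate, gene: str, condition: str, time_h, baseline_time=6
) -> float:
    """Ratio of the CT-ratio quantity at ``time_h`` to the baseline time point."""
    rq_t = relative_quantity(plate, gene, condition, time_h)
    rq_0 = relative_quantity(plate, gene, condition, baseline_time)
    return rq_t / rq_0


def fold_change_ddct(
    plate: QpcrPlate, gene: str, condition: str, time_h, baseline_time=6
) -> float:
    """Conventional ``2**-ddCT`` fold change vs the baseline time point.

    dCT = mean CT(target) - mean CT(housekeeping) per cell; ddCT subtracts
    the baseline cell's dCT.  Higher expression gives fold change > 1,
    unlike the CT-ratio path.
    """
    dct_t = plate._cell(gene, condition, time_h).mean() - plate._cell(
        plate.housekeeping, condition, time_h
    ).mean()
    dct_0 = plate._cell(gene, condition, baseline_time).mean() - plate._cell(
        plate.housekeeping, condition, baseline_time
    ).mean()
    if np.isnan(dct_t) or np.isnan(dct_0):
        raise PlateError(f"missing wells for {gene} / {condition}")
    return float(2.0 ** -(dct_t - dct_0))


def compare_conditions(plate: QpcrPlate, gene: str, time_h, cond_a: str, cond_b: str):
    """Two-sided t-test on replicate-level relative quantities.

    Each replicate's quantity is its target CT divided by the mean
    housekeeping CT of the same cell; conditions are compared with Welch's
    t.  Returns ``(t, p, significant_at_0.05)``.
    """
    out = []
    for cond in (cond_a, cond_b):
        target = plate._cell(gene, cond, time_h)
        hk = plate._cell(plate.housekeeping, cond, time_h)
        if len(target) < 2:
            raise PlateError(f"condition {cond!r} has fewer than 2 replicates")
        if hk.empty:
            raise PlateError(f"no housekeeping wells for {cond!r} / t={time_h}")
        out.append(target.to_numpy() / hk.mean())
    t, p = stats.ttest_ind(out[0], out[1], equal_var=False)
    return float(t), float(p), bool(p < 0.05)
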