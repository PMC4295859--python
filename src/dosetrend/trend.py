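"""Dose-trend ranking statistics.

The acute screen asks, gene by gene, whether expression changes
monotonically along an ordered exposure ladder (untreated control, IC50,
IC90).  The Cuzick rank test for linear trend provides the per-time-point
score: with observations ranked across all dose groups (midranks for ties),
group scores ``l_j`` attached to each observation and ``N`` observations in
total,

    T     = sum_j l_j * r_j
    E[T]  = (N + 1)/2 * sum_j l_j
    Var[T]= (N + 1)/12 * (N * sum_j l_j**2 - (sum_j l_j)**2) * C_ties
    C_ties= 1 - sum_g (t_g**3 - t_g) / (N**3 - N)
    Z     = (T - E[T]) / sqrt(Var[T])

with a two-sided p-value from the standard normal.  The composite score for
a gene is the sum of its per-time-point Z scores (6, 24 and 48 h):
``sigma_z = Z_t6 + Z_t24 + Z_t48``; requiring all three terms to pull the
same way selects genes whose dose response is consistent in direction over
time.  The chronic (day-30, IC10 vs control) screen uses a per-gene
two-sample t-test ranked by p-value instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "CuzickResult",
    "cuzick_trend_test",
    "cuzick_trend_matrix",
    "acute_sigma_z",
    "chronic_ttest_rank",
    "max_sigma_z",
]


class DegenerateInputError(ValueError):
    """All observations tied (or otherwise zero-variance input)."""


@dataclass(frozen=True)
class CuzickResult:
    """Cuzick trend test outcome for one variable."""

    T: float
    expected_T: float
    variance_T: float
    Z: float
    p_two_sided: float
    n_per_group: dict
    scores_used: tuple


def _tie_correction_rows(arr: np.ndarray) -> np.ndarray:
    """Per-row tie-correction factor 1 - sum(t^3 - t)/(N^3 - N)."""
    n = arr.shape[1]
    srt = np.sort(arr, axis=1)
    # run-length encode equal neighbours per row
    boundary = np.ones_like(srt, dtype=bool)
    boundary[:, 1:] = srt[:, 1:] != srt[:, :-1]
    corr = np.empty(arr.shape[0])
    denom = n**3 - n
    for i in range(arr.shape[0]):
        starts = np.flatnonzero(boundary[i])
        sizes = np.diff(np.append(starts, n))
        corr[i] = 1.0 - ((sizes**3 - sizes).sum()) / denom
    return corr


def cuzick_trend_matrix(values: np.ndarray, scores: np.ndarray):
    """Vectorized Cuzick test: one row of ``values`` per gene.

    Returns ``(Z, p, degenerate)`` arrays; degenerate rows (zero variance,
    i.e. all observations tied) get ``Z = 0`` and ``p = 1`` with a flag
    rather than aborting a genome-wide run.
    """
    values = np.asarray(values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != n:
        raise ValueError("scores length must match number of observations")

    ranks = rankdata(values, axis=1)
    sum_l = scores.sum()
    sum_l2 = (scores**2).sum()
    t_stat = ranks @ scores
    expected = (n + 1) / 2.0 * sum_l
    base_var = (n + 1) / 12.0 * (n * sum_l2 - sum_l**2)
    corr = _tie_correction_rows(values)
    var = base_var * corr

    degenerate = var <= 0
    z = np.zeros(values.shape[0])
    ok = ~degenerate
    z[ok] = (t_stat[ok] - expected) / np.sqrt(var[ok])
    p = np.ones(values.shape[0])
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
    return z, p, degenerate, t_stat, expected, var


def cuzick_trend_test(values, group_scores) -> CuzickResult:
    """Cuzick rank test for linear trend across ordered groups.

    Parameters
    ----------
    values
        One measurement per observation.
    group_scores
        Ordered group score ``l_j`` for each observation (e.g. dose rank
        1/2/3 for control/IC50/IC90).
    """
    values = np.asarray(values, dtype=float)
    scores = np.asarray(group_scores, dtype=float)
    if values.size != scores.size:
        raise ValueError("values and group_scores must have equal length")
    if values.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(scores).size < 2:
        raise ValueError("need at least 2 distinct group scores")
    if np.unique(values).size == 1:
        raise DegenerateInputError("all observations are tied; trend undefined")

    z, p, degenerate, t_stat, expected, var = cuzick_trend_matrix(values, scores)
    if degenerate[0]:
        raise DegenerateInputError("zero variance after tie correction; trend undefined")
    uniq, counts = np.unique(scores, return_counts=True)
    return CuzickResult(
        T=float(t_stat[0]),
        expected_T=float(expected),
        variance_T=float(var[0]),
        Z=float(z[0]),
        p_two_sided=float(p[0]),
        n_per_group={float(u): int(c) for u, c in zip(uniq, counts)},
        scores_used=tuple(np.sort(uniq)),
    )


def acute_sigma_z(
    matrix: ExpressionMatrix,
    time_points=(6, 24, 48),
    score_column: str = "dose_score",
    add_bh: bool = True,
) -> pd.DataFrame:
    """Per-gene Cuzick Z at each time point and the summed composite.

    Returns a DataFrame indexed by gene with columns ``z_t{t}`` and
    ``p_t{t}`` per time point, ``sigma_z``, ``direction`` (up/down by the
    sign of the composite), ``rank`` (1 = largest composite), and a
    ``degenerate`` flag set when any time point had zero rank variance.
    An optional Benjamini-Hochberg column per time point is emitted for
    reference only; ranking and selection never use it.
    """
    design = matrix.design
    missing = [t for t in time_points if not (design["time_h"] == t).any()]
    if missing:
        raise ValueError(f"design has no samples at time point(s): {missing}")

    out = pd.DataFrame(index=matrix.values.index)
    degenerate_any = np.zeros(matrix.n_genes, dtype=bool)
    for t in time_points:
        cols = design.index[design["time_h"] == t]
        scores = design.loc[cols, score_column].to_numpy(dtype=float)
        if np.unique(scores).size < 2:
            raise ValueError(f"time point {t}: fewer than 2 dose groups present")
        z, p, degen, *_ = cuzick_trend_matrix(matrix.values[cols].to_numpy(), scores)
        out[f"z_t{t}"] = z
        out[f"p_t{t}"] = p
        if add_bh:
            out[f"bh_q_t{t}"] = multipletests(p, method="fdr_bh")[1]
        degenerate_any |= degen

    z_cols = [f"z_t{t}" for t in time_points]
    out["sigma_z"] = sum(out[c] for c in z_cols)
    out["direction"] = np.where(out["sigma_z"] > 0, "up", np.where(out["sigma_z"] < 0, "down", "flat"))
    out["degenerate"] = degenerate_any
    order = out["sigma_z"].rank(method="first", ascending=False).astype(int)
    out["rank"] = order
    return out.sort_values("sigma_z", ascending=False)


def chronic_ttest_rank(
    matrix: ExpressionMatrix,
    arm_column: str = "arm",
    control_label: str = "control",
    equal_var: bool = False,
    add_bh: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sample t-test (treated vs control), ranked by p-value.

    Welch's unequal-variance t is the default; ``equal_var=True`` gives the
    pooled-variance test.  Direction is the sign of (treated mean - control
    mean).  Zero-variance genes are flagged and given ``t = 0, p = 1``.
    """
    design = matrix.design
    arms = design[arm_column].unique()
    if len(arms) != 2:
        raise ValueError(f"expected exactly 2 arms, found {list(arms)}")
    treated_label = [a for a in arms if a != control_label][0]
    ctrl_cols = design.index[design[arm_column] == control_label]
    trt_cols = design.index[design[arm_column] == treated_label]
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("each arm needs at least 2 replicate columns")

    ctrl = matrix.values[ctrl_cols].to_numpy()
    trt = matrix.values[trt_cols].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(trt, ctrl, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(t_stat)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p = np.where(degenerate, 1.0, p)

    out = pd.DataFrame(
        {
            "t": t_stat,
            "p": p,
            "direction": np.where(trt.mean(axis=1) > ctrl.mean(axis=1), "up", "down"),
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )
    if add_bh:
        out["bh_q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["rank"] = out["p"].rank(method="first").astype(int)
    return out.sort_values(["p", "t"], key=lambda s: s if s.name == "p" else -s.abs())


def max_sigma_z(n_groups: int = 3, replicates_per_group: int = 2, n_time_points: int = 3,
                scores=None) -> float:
    """Largest attainable composite score for a balanced acute design.

    Computed as ``n_time_points`` times the Z of the perfectly dose-ordered
    arrangement (every higher-dose observation exceeding every lower-dose
    one).  Useful as a plausibility bound on reported composite magnitudes.
    """
    if scores is None:
        scores = np.arange(1, n_groups + 1)
    obs_scores = np.repeat(np.asarray(scores, dtype=float), replicates_per_group)
    ordered_values = np.arange(obs_scores.size, dtype=float)
    res = cuzick_trend_test(ordered_values, obs_scores)
    return n_time_points * res.Z
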