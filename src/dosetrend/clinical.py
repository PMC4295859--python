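"""Longitudinal plasma-biomarker statistics.

Implements the analysis battery applied to the treatment-course biomarker
panel (GDF-15, vWF, hsCRP over a BEP chemotherapy schedule): per-time-point
median (range) summaries, paired Wilcoxon signed-rank changes versus the
pre-treatment baseline, Mann-Whitney comparisons between patient groups,
and Spearman correlations between markers.  All tests are two-sided; data
are treated as non-normal throughout.  Missing follow-up samples are
handled pairwise-complete per test, and zero paired differences are
dropped (the Wilcoxon convention).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PlasmaPanel",
    "summarize_timecourse",
    "paired_signed_rank",
    "group_compare",
    "correlate_markers",
    "correlation_track",
]


class PanelError(ValueError):
    pass


@dataclass
class PlasmaPanel:
    """Long-format patient x timepoint x marker measurements.

    ``data`` columns: patient_id, timepoint, marker, value (and optionally
    unit); ``metadata`` one row per patient (age_years, igcccg_group,
    tumor_stage, regimen); ``schedule`` is the ordered timepoint vocabulary,
    whose first label is the baseline.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    schedule: tuple = ("c1d1", "c1d8", "c1d15", "c2d1", "c2d8", "c3d1", "c3d8", "m1post", "y1")

    def __post_init__(self) -> None:
        required = {"patient_id", "timepoint", "marker", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise PanelError(f"panel missing columns: {sorted(missing)}")
        if (self.data["value"] <= 0).any():
            raise PanelError("all marker values must be positive")
        unknown = set(self.data["timepoint"]) - set(self.schedule)
        if unknown:
            raise PanelError(f"timepoint labels outside the declared schedule: {sorted(unknown)}")
        if self.data.duplicated(["patient_id", "timepoint", "marker"]).any():
            raise PanelError("duplicate (patient, timepoint, marker) records")

    @property
    def baseline(self) -> str:
        return self.schedule[0]

    @property
    def markers(self) -> list:
        return sorted(self.data["marker"].unique())

    def pivot(self, marker: str) -> pd.DataFrame:
        """Patients x timepoints value table for one marker."""
        if marker not in set(self.data["marker"]):
            raise PanelError(f"unknown marker {marker!r}")
        wide = self.data[self.data["marker"] == marker].pivot(
            index="patient_id", columns="timepoint", values="value"
        )
        return wide.reindex(columns=[t for t in self.schedule if t in wide.columns])


# ---------------------------------------------------------------------------
# paired signed-rank test
# ---------------------------------------------------------------------------

def paired_signed_rank(x_baseline, x_followup):
    """Wilcoxon signed-rank test for paired changes; two-sided.

    Pairs with a missing member are removed; zero differences are dropped.
    Small samples (<= 14 nonzero differences) use exhaustive sign-flip
    enumeration (exact even under tied magnitudes); up to 25 without ties,
    the exact distribution; beyond that, the normal approximation with tie
    correction.  Returns ``(W_plus, p)`` where ``W_plus`` is the rank sum of
    positive differences.
    """
    x0 = np.asarray(x_baseline, dtype=float)
    x1 = np.asarray(x_followup, dtype=float)
    if x0.size != x1.size:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(x0) & np.isfinite(x1)
    d = (x1 - x0)[keep]
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise PanelError("no nonzero paired differences; signed-rank test undefined")

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mid = ranks.sum() / 2.0

    if n <= 14:
        masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        sums = masks @ ranks
        p = float(np.mean(np.abs(sums - mid) >= np.abs(w_plus - mid) - 1e-12))
    elif n <= 25 and np.unique(ranks).size == n:
        p = float(stats.wilcoxon(d, method="exact").pvalue)
    else:
        p = float(stats.wilcoxon(d, method="approx", correction=False).pvalue)
    return w_plus, min(p, 1.0)


# ---------------------------------------------------------------------------
# summaries and group comparisons
# ---------------------------------------------------------------------------

def summarize_timecourse(panel: PlasmaPanel, marker: str) -> pd.DataFrame:
    """Median (range) per timepoint and paired signed-rank p vs baseline.

    Timepoints with no observations are emitted with ``n = 0`` and tests
    skipped; if all paired differences are zero the change test reports
    p = 1 (no evidence of change).
    """
    wide = panel.pivot(marker)
    rows = []
    for t in panel.schedule:
        if t not in wide.columns or wide[t].notna().sum() == 0:
            rows.append({"timepoint": t, "n": 0, "median": np.nan, "min": np.nan,
                         "max": np.nan, "p_vs_baseline": np.nan})
            continue
        vals = wide[t].dropna()
        row = {"timepoint": t, "n": int(len(vals)), "median": float(vals.median()),
               "min": float(vals.min()), "max": float(vals.max()), "p_vs_baseline": np.nan}
        if t != panel.baseline and panel.baseline in wide.columns:
            paired = wide[[panel.baseline, t]].dropna()
            if len(paired) < 2:
                logger.warning("%s at %s: <2 complete pairs, change test skipped", marker, t)
            else:
                try:
                    _, row["p_vs_baseline"] = paired_signed_rank(
                        paired[panel.baseline], paired[t]
                    )
                except PanelError:  # all differences zero -> no change
                    row["p_vs_baseline"] = 1.0
        rows.append(row)
    return pd.DataFrame(rows)


def group_compare(panel: PlasmaPanel, marker: str, timepoint: str, grouping: str,
                  split=None):
    """Mann-Whitney U between two patient groups at one timepoint.

    ``grouping`` names a metadata column; ``split`` optionally maps its
    values onto two group labels (e.g. merging intermediate and poor
    prognosis).  Returns ``(U, p, summaries)`` with per-group
    "median (range; n)" strings keyed by group label.
    """
    wide = panel.pivot(marker)
    if timepoint not in wide.columns:
        raise PanelError(f"no observations at timepoint {timepoint!r}")
    meta = panel.metadata.set_index("patient_id")
    labels = meta[grouping]
    if split is not None:
        labels = labels.map(split) if callable(split) else labels.map(split)
    values = wide[timepoint].dropna()
    labels = labels.reindex(values.index).dropna()
    values = values.loc[labels.index]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise PanelError(f"grouping must yield exactly 2 groups, got {groups}")
    a = values[labels == groups[0]].to_numpy()
    b = values[labels == groups[1]].to_numpy()
    if a.size == 0 or b.size == 0:
        raise PanelError("one of the comparison groups is empty")

    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    summaries = {
        g: f"{np.median(v):.1f} ({np.min(v):.1f}-{np.max(v):.1f}; n = {v.size})"
        for g, v in ((groups[0], a), (groups[1], b))
    }
    return float(u), float(p), summaries


# ---------------------------------------------------------------------------
# marker correlations
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Exact two-sided permutation p for Spearman's rho (tiny n)."""
    rx, ry = rankdata(x), rankdata(y)
    rs = []
    for perm in itertools.permutations(range(len(ry))):
        rs.append(np.corrcoef(rx, ry[list(perm)])[0, 1])
    rs = np.asarray(rs)
    return float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))


def correlate_markers(panel: PlasmaPanel, marker_a: str, marker_b: str, timepoint: str):
    """Spearman rank correlation between two markers at one timepoint.

    Pairwise-complete observations; at least 4 pairs are required.  The
    p-value uses the t-approximation, replaced by exact permutation
    enumeration for n <= 8.  Returns ``(r_s, p, n)``.
    """
    wa, wb = panel.pivot(marker_a), panel.pivot(marker_b)
    if timepoint not in wa.columns or timepoint not in wb.columns:
        raise PanelError(f"no observations at timepoint {timepoint!r}")
    pairs = pd.concat([wa[timepoint], wb[timepoint]], axis=1, keys=["a", "b"]).dropna()
    n = len(pairs)
    if n < 4:
        raise PanelError(f"need >= 4 complete pairs, found {n}")
    r_s, p = stats.spearmanr(pairs["a"], pairs["b"])
    if n <= 8:
        p = _spearman_exact_p(pairs["a"].to_numpy(), pairs["b"].to_numpy(), r_s)
    return float(r_s), float(p), n


def correlation_track(panel: PlasmaPanel, marker_a: str, marker_b: str,
                      holm: bool = True) -> pd.DataFrame:
    """Per-timepoint Spearman correlation between two markers.

    A Holm-adjusted column is emitted for reference; the per-timepoint
    significance flags use the unadjusted two-sided p at 0.05, matching the
    study's convention of reporting each timepoint on its own.
    """
    rows = []
    for t in panel.schedule:
        try:
            r_s, p, n = correlate_markers(panel, marker_a, marker_b, t)
        except PanelError:
            rows.append({"timepoint": t, "r_s": np.nan, "p": np.nan, "n": 0})
            continue
        rows.append({"timepoint": t, "r_s": r_s, "p": p, "n": n})
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] <= 0.05
    if holm and out["p"].notna().any():
        adj = np.full(len(out), np.nan)
        mask = out["p"].notna().to_numpy()
        adj[mask] = multipletests(out.loc[mask, "p"], method="holm")[1]
        out["holm_p"] = adj
    return out
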