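"""Synthetic microarray, qPCR and plasma-panel generators.

These generators emulate the statistical structure of an endothelial-cell
chemotherapy exposure study so that every downstream stage (normalization,
trend ranking, overlap selection, enrichment, clinical statistics) can be
exercised end to end without any external download:

* an *acute* design — untreated control, IC50 and IC90 dose groups sampled at
  6/24/48 h, with several replicate specimens per dose x time cell and
  (optionally) multiple hybridizations per specimen;
* a *chronic* design — a low-dose (IC10) arm against an untreated arm after a
  month of repeated exposure;
* a longitudinal plasma-biomarker panel (GDF-15, vWF, hsCRP) over a
  bleomycin-etoposide-cisplatin course schedule, with log-scale course
  effects and a Gaussian-copula cross-marker correlation;
* random gene-set catalogs in GMT form, optionally with a planted set.

All generators are pure functions of their design (including its seed): the
same design yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, TruthTable

__all__ = [
    "AcuteDesign",
    "ChronicDesign",
    "PlasmaDesign",
    "GeneSetCollection",
    "generate_acute_experiment",
    "generate_chronic_experiment",
    "generate_plasma_panel",
    "generate_gmt_catalog",
    "BEP_SCHEDULE",
]

#: sampling schedule of a bleomycin-etoposide-cisplatin course:
#: days 1/8/15 of course 1, days 1/8 of courses 2-3, one month after
#: completion and one year after the start of chemotherapy.
BEP_SCHEDULE = ("c1d1", "c1d8", "c1d15", "c2d1", "c2d8", "c3d1", "c3d8", "m1post", "y1")

#: default plasma markers with units and typical baseline medians
DEFAULT_MARKERS = {
    "GDF-15": ("pg/mL", 383.0),
    "vWF": ("%", 100.0),
    "hsCRP": ("mg/L", 2.0),
}


class InvalidDesignError(ValueError):
    """Raised when a synthetic design violates its invariants."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidDesignError(msg)


@dataclass(frozen=True)
class AcuteDesign:
    """Acute-exposure array experiment: ordered dose ladder x time points."""

    n_genes: int = 2000
    n_trend_genes: int = 50
    dose_scores: tuple = (1, 2, 3)  # control, IC50, IC90
    time_points_h: tuple = (6, 24, 48)
    replicates_per_group: int = 2
    hybridizations_per_specimen: int = 4
    effect_size_log2: float = 1.0
    noise_sd_log2: float = 0.5
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 1.5
    drug: str = "bleomycin"
    seed: int = 0
    #: optional separate seed for *which* genes carry the trend (and their
    #: directions); lets several settings share planted candidates while
    #: their noise differs
    spike_seed: int | None = None

    def validate(self) -> None:
        _check(self.n_genes > 0, "n_genes must be positive")
        _check(0 <= self.n_trend_genes <= self.n_genes, "n_trend_genes must be <= n_genes")
        _check(len(self.dose_scores) >= 2, "need at least two dose groups")
        _check(
            all(b > a for a, b in zip(self.dose_scores, self.dose_scores[1:])),
            "dose_scores must be strictly increasing",
        )
        _check(len(self.time_points_h) >= 1, "need at least one time point")
        _check(self.replicates_per_group >= 1, "replicates_per_group must be >= 1")
        _check(self.hybridizations_per_specimen >= 1, "hybridizations_per_specimen must be >= 1")
        _check(np.isfinite(self.effect_size_log2), "effect_size_log2 must be finite")
        _check(self.noise_sd_log2 >= 0, "noise_sd_log2 must be non-negative")


@dataclass(frozen=True)
class ChronicDesign:
    """Chronic low-dose exposure: treated (IC10) vs untreated arm at day 30."""

    n_genes: int = 2000
    n_affected_genes: int = 50
    arms: tuple = ("control", "IC10")
    replicates_per_arm: int = 3
    effect_size_log2: float = 1.0
    noise_sd_log2: float = 0.5
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 1.5
    drug: str = "bleomycin"
    seed: int = 0
    spike_seed: int | None = None

    def validate(self) -> None:
        _check(self.n_genes > 0, "n_genes must be positive")
        _check(0 <= self.n_affected_genes <= self.n_genes, "n_affected_genes must be <= n_genes")
        _check(len(self.arms) == 2, "chronic design has exactly two arms")
        _check(self.replicates_per_arm >= 2, "replicates_per_arm must be >= 2 (t-test needs variance)")
        _check(np.isfinite(self.effect_size_log2), "effect_size_log2 must be finite")


def _default_multipliers() -> dict:
    """Course effects loosely shaped like the published marker trajectories:
    a strong within-course spike for GDF-15, a sustained vWF rise, and an
    oscillating acute-phase hsCRP response."""
    return {
        "GDF-15": {"c1d1": 1.0, "c1d8": 9.0, "c1d15": 4.0, "c2d1": 3.0, "c2d8": 12.0,
                   "c3d1": 5.0, "c3d8": 14.0, "m1post": 2.6, "y1": 1.0},
        "vWF": {"c1d1": 1.0, "c1d8": 1.6, "c1d15": 1.45, "c2d1": 1.4, "c2d8": 2.0,
                "c3d1": 1.9, "c3d8": 2.0, "m1post": 1.35, "y1": 1.15},
        "hsCRP": {"c1d1": 1.0, "c1d8": 0.3, "c1d15": 2.1, "c2d1": 2.5, "c2d8": 0.3,
                  "c3d1": 1.8, "c3d8": 0.3, "m1post": 1.1, "y1": 0.75},
    }


@dataclass(frozen=True)
class PlasmaDesign:
    """Longitudinal plasma panel over a BEP course schedule.

    Values are lognormal: ``log v = log(baseline median) + log(multiplier)
    + patient effect + correlated noise``.  The noise vector across markers
    at each patient x time point follows a Gaussian copula with pairwise
    latent correlation ``cross_marker_rho``, so the rank (Spearman)
    correlation between markers is tunable independently of the marginals.
    """

    n_patients: int = 41
    timepoint_labels: tuple = BEP_SCHEDULE
    markers: tuple = tuple(DEFAULT_MARKERS)
    units: dict = field(default_factory=lambda: {m: u for m, (u, _) in DEFAULT_MARKERS.items()})
    baseline_log_medians: dict = field(
        default_factory=lambda: {m: float(np.log(v)) for m, (_, v) in DEFAULT_MARKERS.items()}
    )
    course_multipliers: dict = field(default_factory=_default_multipliers)
    noise_sd_log: float = 0.5
    patient_sd_log: float = 0.0
    cross_marker_rho: float = 0.35
    missing_rate: float = 0.0
    good_prognosis_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_patients >= 1, "n_patients must be positive")
        _check(len(self.timepoint_labels) >= 2, "need at least two time points")
        for m in self.markers:
            _check(m in self.baseline_log_medians, f"unknown marker label {m!r}: no baseline median")
            _check(m in self.course_multipliers, f"unknown marker label {m!r}: no course multipliers")
            for t in self.timepoint_labels:
                mult = self.course_multipliers[m].get(t, 1.0)
                _check(mult > 0, f"multiplier for {m} at {t} must be > 0")
        _check(abs(self.cross_marker_rho) < 1, "|cross_marker_rho| must be < 1")
        _check(0 <= self.missing_rate < 1, "missing_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# microarray generators
# ---------------------------------------------------------------------------

def _gene_ids(n: int) -> list:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_acute_experiment(design: AcuteDesign) -> tuple[ExpressionMatrix, TruthTable]:
    """Simulate the acute dose-ladder experiment.

    Trend genes shift their mean log2 expression by ``effect_size_log2`` per
    dose step — in the same direction at every time point — while background
    genes have dose-independent means.  One sample column is produced per
    (dose, time, replicate, hybridization); hybridizations of the same
    specimen share the specimen value and differ only by measurement noise.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    genes = _gene_ids(design.n_genes)

    baseline = rng.normal(design.baseline_mean_log2, design.baseline_sd_log2, design.n_genes)
    directions = np.zeros(design.n_genes, dtype=int)
    if design.n_trend_genes:
        spike_rng = np.random.default_rng(
            [17, design.seed if design.spike_seed is None else design.spike_seed]
        )
        spiked = spike_rng.choice(design.n_genes, size=design.n_trend_genes, replace=False)
        directions[spiked] = spike_rng.choice([-1, 1], size=design.n_trend_genes)

    columns, sample_ids = [], []
    for t in design.time_points_h:
        for dose_idx, score in enumerate(design.dose_scores):
            for rep in range(1, design.replicates_per_group + 1):
                specimen_mean = baseline + directions * design.effect_size_log2 * dose_idx
                specimen_noise = rng.normal(0.0, design.noise_sd_log2, design.n_genes)
                for hyb in range(1, design.hybridizations_per_specimen + 1):
                    hyb_noise = (
                        rng.normal(0.0, design.noise_sd_log2, design.n_genes)
                        if design.hybridizations_per_specimen > 1
                        else 0.0
                    )
                    columns.append(specimen_mean + specimen_noise + hyb_noise)
                    sample_ids.append(f"{design.drug}_t{t}_d{score}_r{rep}_h{hyb}")

    values = pd.DataFrame(np.column_stack(columns), index=genes, columns=sample_ids)
    dsgn = pd.DataFrame(
        [
            {
                "drug": design.drug,
                "dose_score": int(s.split("_d")[1].split("_")[0]),
                "time_h": int(s.split("_t")[1].split("_")[0]),
                "replicate": int(s.split("_r")[1].split("_")[0]),
                "hybridization": int(s.split("_h")[1]),
            }
            for s in sample_ids
        ],
        index=sample_ids,
    )
    truth = TruthTable(
        genes=pd.DataFrame(
            {
                "gene": [genes[i] for i in np.flatnonzero(directions)],
                "direction": directions[np.flatnonzero(directions)],
            }
        ).reset_index(drop=True),
        params={"effect_size_log2": design.effect_size_log2},
    )
    if design.n_trend_genes == 0:
        truth.genes = pd.DataFrame(columns=["gene", "direction"])
    return ExpressionMatrix(values=values, design=dsgn, level="gene"), truth


def generate_chronic_experiment(design: ChronicDesign) -> tuple[ExpressionMatrix, TruthTable]:
    """Simulate the chronic two-arm (control vs IC10) experiment."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    genes = _gene_ids(design.n_genes)

    baseline = rng.normal(design.baseline_mean_log2, design.baseline_sd_log2, design.n_genes)
    directions = np.zeros(design.n_genes, dtype=int)
    if design.n_affected_genes:
        spike_rng = np.random.default_rng(
            [17, design.seed if design.spike_seed is None else design.spike_seed]
        )
        affected = spike_rng.choice(design.n_genes, size=design.n_affected_genes, replace=False)
        directions[affected] = spike_rng.choice([-1, 1], size=design.n_affected_genes)

    columns, sample_ids, rows = [], [], []
    for arm_idx, arm in enumerate(design.arms):
        shift = directions * design.effect_size_log2 * arm_idx  # treated arm only
        for rep in range(1, design.replicates_per_arm + 1):
            columns.append(baseline + shift + rng.normal(0.0, design.noise_sd_log2, design.n_genes))
            sid = f"{design.drug}_{arm}_d30_r{rep}"
            sample_ids.append(sid)
            rows.append(
                {"drug": design.drug, "dose_score": arm_idx, "time_h": 720,
                 "replicate": rep, "arm": arm}
            )

    values = pd.DataFrame(np.column_stack(columns), index=genes, columns=sample_ids)
    dsgn = pd.DataFrame(rows, index=sample_ids)
    idx = np.flatnonzero(directions)
    truth = TruthTable(
        genes=pd.DataFrame({"gene": [genes[i] for i in idx], "direction": directions[idx]}),
        params={"effect_size_log2": design.effect_size_log2},
    )
    return ExpressionMatrix(values=values, design=dsgn, level="gene"), truth


# ---------------------------------------------------------------------------
# plasma panel
# ---------------------------------------------------------------------------

def generate_plasma_panel(design: PlasmaDesign):
    """Simulate the longitudinal plasma panel.

    Returns ``(panel, truth)`` where ``panel`` is a
    :class:`~dosetrend.clinical.PlasmaPanel` and the truth table records the
    generating multipliers and the latent cross-marker correlation.
    """
    from .clinical import PlasmaPanel  # local import to avoid a cycle

    design.validate()
    rng = np.random.default_rng(design.seed)
    n_m = len(design.markers)

    corr = np.full((n_m, n_m), design.cross_marker_rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)

    patient_ids = [f"P{i:03d}" for i in range(1, design.n_patients + 1)]
    patient_eff = rng.normal(0.0, design.patient_sd_log, (design.n_patients, n_m))

    records = []
    for p_idx, pid in enumerate(patient_ids):
        for t in design.timepoint_labels:
            z = chol @ rng.standard_normal(n_m)
            missing = design.missing_rate > 0 and rng.random() < design.missing_rate
            if missing:
                continue
            for m_idx, marker in enumerate(design.markers):
                mult = design.course_multipliers[marker].get(t, 1.0)
                logv = (
                    design.baseline_log_medians[marker]
                    + np.log(mult)
                    + patient_eff[p_idx, m_idx]
                    + design.noise_sd_log * z[m_idx]
                )
                records.append(
                    {"patient_id": pid, "timepoint": t, "marker": marker,
                     "value": float(np.exp(logv)), "unit": design.units.get(marker, "")}
                )

    n_good = int(round(design.good_prognosis_fraction * design.n_patients))
    groups = ["good"] * n_good + ["intermediate/poor"] * (design.n_patients - n_good)
    metadata = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "age_years": rng.integers(18, 50, design.n_patients),
            "igcccg_group": groups,
            "tumor_stage": rng.choice(["II", "III", "IV"], design.n_patients, p=[0.7, 0.1, 0.2]),
            "regimen": "BEP",
        }
    )
    panel = PlasmaPanel(
        data=pd.DataFrame(records),
        metadata=metadata,
        schedule=tuple(design.timepoint_labels),
    )
    truth = TruthTable(
        params={
            "course_multipliers": design.course_multipliers,
            "cross_marker_rho": design.cross_marker_rho,
            "baseline_log_medians": design.baseline_log_medians,
        }
    )
    return panel, truth


# ---------------------------------------------------------------------------
# gene-set catalogs
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets (as in a GMT file) with optional descriptions."""

    sets: dict  # name -> tuple of member symbols
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            members = tuple(members)
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")
            self.sets[name] = members

    def __len__(self) -> int:
        return len(self.sets)

    def filtered(self, min_size: int = 5, max_size: int = 500, universe=None) -> "GeneSetCollection":
        """Restrict members to ``universe`` (if given) and drop sets whose
        restricted size falls outside ``[min_size, max_size]``."""
        universe_set = set(universe) if universe is not None else None
        kept, desc = {}, {}
        for name, members in self.sets.items():
            if universe_set is not None:
                members = tuple(g for g in members if g in universe_set)
            if min_size <= len(members) <= max_size:
                kept[name] = members
                if name in self.descriptions:
                    desc[name] = self.descriptions[name]
        return GeneSetCollection(sets=kept, descriptions=desc)


def generate_gmt_catalog(
    n_sets: int,
    size_range: tuple,
    n_genes: int,
    planted_set=None,
    seed: int = 0,
    gene_ids=None,
) -> GeneSetCollection:
    """Random gene-set catalog over ``n_genes`` symbols.

    ``planted_set`` (an iterable of gene ids) is included verbatim as the
    first set, named ``PLANTED``, and counts toward ``n_sets``.
    """
    lo, hi = size_range
    if lo > hi or lo < 2 or hi > n_genes:
        raise InvalidDesignError(f"size_range {size_range} must satisfy 2 <= lo <= hi <= n_genes")
    rng = np.random.default_rng(seed)
    genes = list(gene_ids) if gene_ids is not None else _gene_ids(n_genes)
    if len(genes) != n_genes:
        raise InvalidDesignError("gene_ids length must equal n_genes")

    sets, descriptions = {}, {}
    n_random = n_sets
    if planted_set is not None:
        sets["PLANTED"] = tuple(planted_set)
        descriptions["PLANTED"] = "planted set"
        n_random -= 1
    for i in range(1, n_random + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        name = f"SET_{i:04d}"
        sets[name] = tuple(genes[j] for j in sorted(members))
        descriptions[name] = "random set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
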