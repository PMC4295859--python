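"""Top-k candidate lists per exposure setting and their multi-setting overlap.

Each exposure setting (drug x acute/chronic) yields an ordered candidate
list: the acute screen takes the k/2 genes with the largest composite trend
score (up-regulated) plus the k/2 with the smallest (down-regulated); the
chronic screen takes the k genes with the smallest t-test p-values.  Genes
appearing in at least ``m`` of the settings' lists form the candidate set —
the selection that singled out GDF-15, ATF3 and AREG in the study this
pipeline models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class RankedGeneLists:
    """Ordered candidate list for one exposure setting.

    ``table`` has columns ``gene``, ``direction`` ("up"/"down") and
    ``statistic`` (composite trend score or p-value, as printed).
    """

    setting: str
    table: pd.DataFrame
    k: int

    def __post_init__(self) -> None:
        if self.table["gene"].duplicated().any():
            dup = self.table.loc[self.table["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"{self.setting}: duplicate symbols in list: {dup}")
        if len(self.table) > self.k:
            raise ValueError(f"{self.setting}: list longer than k={self.k}")

    @property
    def genes(self) -> list:
        return self.table["gene"].tolist()

    def direction_of(self, gene: str) -> str:
        row = self.table.loc[self.table["gene"] == gene]
        return row["direction"].iloc[0] if len(row) else ""


@dataclass
class OverlapReport:
    """Membership of every listed gene across settings, plus the selection."""

    membership: pd.DataFrame  # gene x setting boolean + 'count'
    candidates: list
    m: int
    pairwise: dict = field(default_factory=dict)  # (setting_a, setting_b) -> set


def top_k_lists(trend: pd.DataFrame, k: int, mode: str, setting: str = "") -> RankedGeneLists:
    """Build the per-setting top-k list from a trend-ranking table.

    ``mode="acute"`` expects the output of :func:`~dosetrend.trend.acute_sigma_z`
    (columns ``sigma_z``/``direction``) and returns the k/2 largest-composite
    genes as "up" plus the k/2 smallest as "down".  ``mode="chronic"``
    expects :func:`~dosetrend.trend.chronic_ttest_rank` output (columns
    ``p``/``t``/``direction``) and returns the k smallest-p genes.  Ties at
    the list boundary are broken by the statistic and then by symbol, so the
    output is deterministic.
    """
    if k > len(trend):
        raise ValueError(f"k={k} exceeds number of genes ({len(trend)})")
    df = trend.reset_index().rename(columns={trend.index.name or "index": "gene"})
    df["gene"] = df["gene"].astype(str)

    if mode == "acute":
        if k % 2:
            raise ValueError("acute mode needs an even k (k/2 up + k/2 down)")
        up = df.sort_values(["sigma_z", "gene"], ascending=[False, True]).head(k // 2)
        down = df.sort_values(["sigma_z", "gene"], ascending=[True, True]).head(k // 2)
        down = down.iloc[::-1]  # whole table runs from largest to smallest composite
        table = pd.concat(
            [
                pd.DataFrame({"gene": up["gene"], "direction": "up", "statistic": up["sigma_z"]}),
                pd.DataFrame({"gene": down["gene"], "direction": "down", "statistic": down["sigma_z"]}),
            ],
            ignore_index=True,
        )
    elif mode == "chronic":
        sel = df.sort_values(["p", "gene"], ascending=[True, True]).head(k)
        table = pd.DataFrame(
            {"gene": sel["gene"], "direction": sel["direction"], "statistic": sel["p"]}
        ).reset_index(drop=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return RankedGeneLists(setting=setting or mode, table=table.reset_index(drop=True), k=k)


def overlap_select(lists, m: int) -> OverlapReport:
    """Cross-tabulate list membership and select genes present in >= m lists.

    The threshold is a *greater-or-equal* cut: a gene found in all settings
    still belongs to the "at least m" candidate set.
    """
    lists = list(lists)
    if len(lists) < 2:
        raise ValueError("need at least 2 lists to overlap")
    if m > len(lists):
        raise ValueError(f"m={m} exceeds number of lists ({len(lists)})")
    for lst in lists:
        if not lst.genes:
            raise ValueError(f"list {lst.setting!r} is empty")

    settings = [lst.setting for lst in lists]
    if len(set(settings)) != len(settings):
        raise ValueError("duplicate setting labels")

    all_genes = sorted(set(itertools.chain.from_iterable(lst.genes for lst in lists)))
    membership = pd.DataFrame(index=all_genes)
    for lst in lists:
        membership[lst.setting] = membership.index.isin(lst.genes)
    membership["count"] = membership[settings].sum(axis=1).astype(int)
    candidates = sorted(membership.index[membership["count"] >= m])

    pairwise = {
        (a.setting, b.setting): set(a.genes) & set(b.genes)
        for a, b in itertools.combinations(lists, 2)
    }
    return OverlapReport(membership=membership, candidates=candidates, m=m, pairwise=pairwise)


def direction_concordance(report: OverlapReport, lists) -> pd.Series:
    """Whether each candidate's direction agrees across its member lists.

    A gene present in a single list is concordant by convention.
    """
    by_setting = {lst.setting: lst for lst in lists}
    flags = {}
    for gene in report.candidates:
        dirs = {
            by_setting[s].direction_of(gene)
            for s in by_setting
            if report.membership.loc[gene, s]
        }
        flags[gene] = len(dirs) <= 1
    return pd.Series(flags, name="concordant", dtype=bool)
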