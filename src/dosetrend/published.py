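"""Published candidate tables bundled for re-analysis.

The package ships transcriptions of the reported results of the microarray
study it models (bleomycin/cisplatin-exposed HMEC-1 endothelial cells):
the four top-50 differential-expression lists (one per drug x acute/chronic
exposure setting) and the table of KEGG gene sets that passed the
enrichment reporting thresholds.  These are *outputs* of the original
analysis used here as worked-example inputs for the overlap selection and
the enrichment reporting filter; the raw arrays behind them are not
bundled.

Printed p-value bounds such as ``<0.01`` are parsed as their upper bound,
which is conservative for any ``<=`` threshold filter.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .overlap import RankedGeneLists

SETTINGS = ("bleomycin_acute", "bleomycin_chronic", "cisplatin_acute", "cisplatin_chronic")


def _data_path(name: str):
    return resources.files("dosetrend").joinpath("data", name)


def parse_p_bound(token) -> float:
    """Printed p-value or bound ('<0.01') -> numeric upper bound."""
    s = str(token).strip()
    if s.startswith("<"):
        return float(s[1:])
    return float(s)


def load_published_top50(setting: str) -> RankedGeneLists:
    """One of the four published top-50 lists, as a ranked gene list."""
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}; expected one of {SETTINGS}")
    with resources.as_file(_data_path(f"top50_{setting}.tsv")) as path:
        table = pd.read_csv(path, sep="\t")
    return RankedGeneLists(setting=setting, table=table, k=len(table))


def load_all_published_top50() -> list:
    """All four published lists in a fixed setting order."""
    return [load_published_top50(s) for s in SETTINGS]


def load_published_enrichment() -> pd.DataFrame:
    """Reported enriched gene sets with numeric ``fdr_q`` and ``p_nominal``.

    Long format: one row per (set, setting) the original report printed,
    with the direction of enrichment.
    """
    with resources.as_file(_data_path("enrichment_reported.tsv")) as path:
        table = pd.read_csv(path, sep="\t")
    table["p_nominal"] = table["p_nominal"].map(parse_p_bound)
    table["fdr_q"] = table["fdr_q"].astype(float)
    return table
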