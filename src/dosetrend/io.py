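"""Plain-text readers and writers for every pipeline object.

All formats are header-rowed TSV/CSV (gzip accepted transparently by file
extension) plus standard GMT for gene sets.  Parse errors name the
offending line or id.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .clinical import PlasmaPanel
from .matrix import ExpressionMatrix
from .overlap import RankedGeneLists
from .synthetic import GeneSetCollection


class ParseError(ValueError):
    pass


# -- expression matrices -----------------------------------------------------

def write_expression(matrix: ExpressionMatrix, matrix_path, design_path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene" if matrix.level == "gene" else "probe"
    out.to_csv(matrix_path, sep="\t")
    matrix.design.rename_axis("sample").to_csv(design_path, sep="\t")


def _header_fields(path):
    import gzip as _gzip

    opener = _gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return fh.readline().rstrip("\n").split("\t")


def load_expression(matrix_path, design_path, level: str = "gene") -> ExpressionMatrix:
    header = _header_fields(matrix_path)[1:]  # pandas would mangle duplicates
    dupes = pd.Index(header)[pd.Index(header).duplicated()].tolist()
    if dupes:
        raise ParseError(f"{matrix_path}: duplicate sample ids {dupes}")
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    non_numeric = values.columns[
        [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]
    ]
    if len(non_numeric):
        raise ParseError(f"{matrix_path}: non-numeric values in column(s) {list(non_numeric)}")
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, design=design, level=level)


def load_annotation(path) -> pd.Series:
    """Probe annotation TSV: probe_id <tab> symbol."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ParseError(f"{path}: annotation needs two columns (probe_id, symbol)")
    probe_col, symbol_col = table.columns[:2]
    if table[probe_col].duplicated().any():
        dup = table.loc[table[probe_col].duplicated(), probe_col].tolist()
        raise ParseError(f"{path}: annotation maps probe(s) {dup} more than once")
    return table.set_index(probe_col)[symbol_col]


# -- gene sets ---------------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def load_gmt(path) -> GeneSetCollection:
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            if len(set(members)) != len(members):
                raise ParseError(f"{path}:{lineno}: duplicate members in set {name!r}")
            sets[name] = tuple(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# -- plasma panels -----------------------------------------------------------

def write_plasma(panel: PlasmaPanel, data_path, metadata_path=None) -> None:
    panel.data.to_csv(data_path, index=False)
    if metadata_path is not None and not panel.metadata.empty:
        panel.metadata.to_csv(metadata_path, index=False)


def load_plasma(data_path, metadata_path=None, schedule=None) -> PlasmaPanel:
    data = pd.read_csv(data_path)
    metadata = pd.read_csv(metadata_path) if metadata_path is not None else pd.DataFrame()
    kwargs = {"schedule": tuple(schedule)} if schedule is not None else {}
    return PlasmaPanel(data=data, metadata=metadata, **kwargs)


# -- ranked lists and trend tables -------------------------------------------

def write_ranked_list(lst: RankedGeneLists, path) -> None:
    lst.table.to_csv(path, sep="\t", index=False)


def load_gene_list(path, setting: str = "", k: int | None = None) -> RankedGeneLists:
    table = pd.read_csv(path, sep="\t")
    if "gene" not in table.columns:
        raise ParseError(f"{path}: gene-list TSV needs a 'gene' column")
    if "direction" not in table.columns:
        table["direction"] = ""
    return RankedGeneLists(
        setting=setting or Path(path).stem, table=table, k=k if k is not None else len(table)
    )


def load_gene_lists(paths, settings=None) -> list:
    settings = settings or [Path(p).stem for p in paths]
    return [load_gene_list(p, setting=s) for p, s in zip(paths, settings)]


def write_trend_table(trend: pd.DataFrame, path) -> None:
    out = trend.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t")


def load_trend_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# -- manifests ---------------------------------------------------------------

def write_manifest(path, **entries) -> None:
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=str) + "\n")
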