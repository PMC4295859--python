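"""Array preprocessing: log2 transform, quantile normalization, probe
collapsing and hybridization averaging.

The supported path treats each channel of a two-channel array as an
independent sample column labelled by its hybridized specimen, and
normalizes all columns jointly (single-channel analysis of two-channel
data).  Ratio formation and dye-bias modelling are deliberately out of
scope.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


def log2_transform(
    matrix: ExpressionMatrix, *, strict: bool = False, epsilon: float = 1e-6
) -> ExpressionMatrix:
    """Replace every raw intensity by its base-2 logarithm.

    Non-positive intensities are floored at ``epsilon`` with a warning; with
    ``strict=True`` the first offending (row, sample) aborts the run instead.
    """
    vals = matrix.values
    bad = vals.to_numpy() <= 0
    if bad.any():
        if strict:
            r, c = np.argwhere(bad)[0]
            raise PreprocessError(
                f"non-positive intensity at probe {vals.index[r]!r}, sample {vals.columns[c]!r}"
            )
        logger.warning("flooring %d non-positive intensities at %g", int(bad.sum()), epsilon)
        vals = vals.clip(lower=epsilon)
    return replace(matrix, values=np.log2(vals))


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common quantile profile.

    The reference profile is the vector of row-wise means of the
    column-sorted values; each column's values are replaced by the reference
    value at their rank.  Tied values receive the mean of the reference
    values their tie group spans (mean-of-ranks convention), so within-column
    rank order is preserved exactly.
    """
    if matrix.n_samples < 2:
        raise PreprocessError("quantile normalization needs at least 2 sample columns")
    arr = matrix.values.to_numpy(dtype=float)
    n = arr.shape[0]
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    grid = np.arange(n, dtype=float)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")  # midranks for ties
        out[:, j] = np.interp(ranks - 1.0, grid, reference)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=values)


def collapse_probes(matrix: ExpressionMatrix, annotation: pd.Series) -> ExpressionMatrix:
    """Average multiple probes targeting the same gene symbol.

    ``annotation`` maps probe id -> HUGO symbol.  Unmapped probes are dropped
    (and counted in the run log); the result is a gene-level matrix with one
    row per symbol, each value the arithmetic mean of that symbol's probes.
    """
    if matrix.level != "probe":
        raise PreprocessError("collapse_probes expects a probe-level matrix")
    annotation = pd.Series(annotation)
    if annotation.empty:
        raise PreprocessError("empty probe annotation")
    if (annotation.astype(str).str.len() == 0).any():
        raise PreprocessError("annotation contains empty gene symbols")

    symbols = matrix.values.index.map(annotation)
    unmapped = symbols.isna()
    if unmapped.any():
        logger.info("dropping %d unmapped probes", int(unmapped.sum()))
    collapsed = matrix.values.loc[~unmapped].groupby(symbols[~unmapped]).mean()
    collapsed.index.name = matrix.values.index.name
    return ExpressionMatrix(values=collapsed, design=matrix.design, level="gene")


def average_hybridizations(
    matrix: ExpressionMatrix, grouping=("drug", "dose_score", "time_h", "replicate")
) -> ExpressionMatrix:
    """Average repeated hybridizations of the same specimen.

    ``grouping`` names the design columns that identify a specimen; all
    sample columns sharing those labels are averaged into one column.  The
    new design keeps one row per specimen (first label wins for columns
    outside the grouping key).
    """
    grouping = [g for g in grouping if g in matrix.design.columns]
    if not grouping:
        raise PreprocessError("no grouping columns present in the design sheet")
    keys = matrix.design[grouping]
    group_ids = keys.astype(str).agg("|".join, axis=1)

    new_cols, new_rows, new_ids = [], [], []
    for gid, members in group_ids.groupby(group_ids, sort=False).groups.items():
        members = list(members)
        new_cols.append(matrix.values[members].mean(axis=1))
        row = matrix.design.loc[members[0]].copy()
        row = row.drop(labels=[c for c in ("hybridization", "channel") if c in row.index])
        new_rows.append(row)
        new_ids.append(gid.replace("|", "_"))
    values = pd.concat(new_cols, axis=1)
    values.columns = new_ids
    design = pd.DataFrame(new_rows)
    design.index = new_ids
    return ExpressionMatrix(values=values, design=design, level=matrix.level)
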