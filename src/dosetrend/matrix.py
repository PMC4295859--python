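"""Expression-matrix container shared by all array-processing stages.

The matrix holds log2 (or raw) intensities as a genes/probes x samples
:class:`pandas.DataFrame`, together with a per-sample design sheet giving the
exposure labels (drug, dose score, time in hours, replicate, optional
channel).  A ``level`` flag records whether rows are probes or collapsed
HUGO gene symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: design-sheet columns every stage may rely on
DESIGN_COLUMNS = ("drug", "dose_score", "time_h", "replicate")


class DesignError(ValueError):
    """Raised when a sample design sheet is inconsistent with the matrix."""


@dataclass
class ExpressionMatrix:
    """Genes/probes x samples intensity matrix with its sample design.

    Parameters
    ----------
    values
        DataFrame indexed by probe id or gene symbol; one column per sample.
    design
        DataFrame indexed by sample id (matching ``values.columns``) with at
        least the columns in :data:`DESIGN_COLUMNS`; a ``channel`` column is
        optional.
    level
        ``"probe"`` or ``"gene"``; collapsed matrices must have unique rows.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    level: str = "probe"

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError(f"level must be 'probe' or 'gene', got {self.level!r}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DesignError(f"duplicate sample ids: {dupes}")
        if not self.values.columns.equals(pd.Index(self.design.index)):
            missing = set(self.values.columns).symmetric_difference(self.design.index)
            raise DesignError(
                f"design sheet does not match matrix columns; mismatched ids: {sorted(missing)[:5]}"
            )
        if self.level == "gene" and self.values.index.duplicated().any():
            raise DesignError("gene-level matrix has duplicated row ids")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``sample_ids`` (order preserved)."""
        sample_ids = list(sample_ids)
        return replace(
            self,
            values=self.values[sample_ids],
            design=self.design.loc[sample_ids],
        )

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.values.to_numpy()).all())


@dataclass
class TruthTable:
    """Ground truth emitted next to every synthetic dataset.

    ``genes`` lists the spiked/affected gene ids with their planted direction
    (+1 up, -1 down); ``params`` records the generating parameters a test may
    want to recover (e.g. plasma course multipliers, latent correlation).
    """

    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["gene", "direction"]))
    params: dict = field(default_factory=dict)
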