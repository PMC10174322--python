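"""Shared in-memory containers for the pipeline.

The central object is :class:`CountMatrix`: a genes-by-samples table of
non-negative integer read counts with a two-group design (group ``"A"`` is
the reference/control arm, group ``"B"`` the case arm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_A = "A"
GROUP_B = "B"
VALID_GROUPS = (GROUP_A, GROUP_B)


@dataclass
class CountMatrix:
    """Genes x samples count matrix with per-sample group labels.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers; index = gene ids (unique),
        columns = sample ids (unique).
    groups
        Series mapping each sample id to ``"A"`` (reference) or ``"B"``
        (case), in the same order as ``counts.columns``.
    mean_model
        Optional generator bookkeeping: the expected count of every cell
        under the simulation model that produced ``counts``. ``None`` for
        real data; never compared for equality.
    """

    counts: pd.DataFrame
    groups: pd.Series
    mean_model: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, copy=False)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(self.groups) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        mm = None if self.mean_model is None else self.mean_model.loc[gene_ids]
        return CountMatrix(self.counts.loc[gene_ids], self.groups, mm)

    def equals(self, other: "CountMatrix") -> bool:
        return self.counts.equals(other.counts) and self.groups.equals(other.groups)
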