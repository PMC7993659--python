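"""Core data containers shared by every analysis stage.

The common currency is :class:`OmicsMatrix`, a gene (or probe) by sample real
matrix tagged with the omics kind it carries. Missing entries are NaN.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError

#: Recognised omics kinds.
KINDS = ("cnv_logratio", "beta", "fpkm", "counts")


@dataclass
class OmicsMatrix:
    """A feature x sample matrix with an omics kind tag.

    Parameters
    ----------
    kind:
        One of ``cnv_logratio``, ``beta``, ``fpkm``, ``counts``.
    values:
        DataFrame indexed by feature id with sample ids as columns. NaN marks
        missing entries.
    """

    kind: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidInputError(f"unknown omics kind {self.kind!r}; expected one of {KINDS}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        vals = self.values.to_numpy(dtype=float)
        if self.kind == "beta":
            observed = vals[np.isfinite(vals)]
            if observed.size and (observed.min() < 0 or observed.max() > 1):
                raise InvalidInputError("beta values must lie in [0, 1]")
        if self.kind == "counts":
            observed = vals[np.isfinite(vals)]
            if observed.size and (observed.min() < 0 or np.any(observed != np.round(observed))):
                raise InvalidInputError("counts must be non-negative integers")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "OmicsMatrix":
        keep = [g for g in genes if g in self.values.index]
        return OmicsMatrix(self.kind, self.values.loc[keep])

    def subset_samples(self, samples) -> "OmicsMatrix":
        keep = [s for s in samples if s in self.values.columns]
        return OmicsMatrix(self.kind, self.values[keep])

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class SubtypeAssignment:
    """Sample -> cluster labels with method provenance."""

    method: str
    labels: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = dict(self.labels)

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    @property
    def samples(self) -> list[str]:
        return list(self.labels.keys())

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for lab in self.labels.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster")

    def label_array(self, samples) -> np.ndarray:
        missing = [s for s in samples if s not in self.labels]
        if missing:
            raise InvalidInputError(f"samples missing from assignment: {missing[:5]}")
        return np.array([self.labels[s] for s in samples])


def align_samples(*matrices: OmicsMatrix) -> list[OmicsMatrix]:
    """Restrict all matrices to their shared samples, in the first matrix's order."""
    shared = set(matrices[0].samples)
    for m in matrices[1:]:
        shared &= set(m.samples)
    if not shared:
        raise InvalidInputError("matrices share no samples")
    order = [s for s in matrices[0].samples if s in shared]
    return [m.subset_samples(order) for m in matrices]
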