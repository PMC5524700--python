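"""Descriptor matrix assembly and univariate variable selection.

The per-code tensors are flattened into a codes x descriptors matrix.
Reduction is deliberately univariate, in two passes: drop columns that are
constant across codes (they carry no information), then keep only columns
whose absolute Pearson correlation with activity reaches a threshold.
Correlation is computed on the non-external codes only, so the external
validation pair never informs selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import IncompatibleTensorError, GridQSARError
from .grid import GridSpec, IEDTensor, Probe

__all__ = ["DescriptorMatrix", "SelectionReport", "assemble_matrix",
           "drop_invariant", "correlation_filter"]

_VAR_TOL = 1e-12


@dataclass
class DescriptorMatrix:
    """Codes x labelled-descriptors matrix with its grid/probe provenance."""

    data: pd.DataFrame  # index = codes, columns = labels
    grid: GridSpec | None = None
    probe_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            raise GridQSARError("duplicate descriptor labels")
        if not np.isfinite(self.data.values).all():
            raise GridQSARError("non-finite descriptor values")

    @property
    def codes(self) -> list[str]:
        return list(self.data.index)

    @property
    def labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self):
        return self.data.shape

    def subset_columns(self, labels: Sequence[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(self.data.loc[:, list(labels)], self.grid,
                                self.probe_names)

    def rows(self, codes: Sequence[str]) -> pd.DataFrame:
        return self.data.loc[list(codes)]


@dataclass
class SelectionReport:
    """Bookkeeping of one reduction pass."""

    threshold: float | None
    n_input: int
    n_zero_variance: int = 0
    n_zero_r: int = 0
    n_retained: int = 0
    retained_labels: list[str] = field(default_factory=list)
    correlations: pd.Series | None = None  # label -> r (where defined)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_input": self.n_input,
            "n_zero_variance": self.n_zero_variance,
            "n_zero_r": self.n_zero_r,
            "n_retained": self.n_retained,
        }


def assemble_matrix(tensors: Sequence[IEDTensor]) -> DescriptorMatrix:
    """Stack per-code tensors into one codes x descriptors matrix.

    All tensors must share the grid, the probe set and the capping state.
    """
    if not tensors:
        raise GridQSARError("no tensors to assemble")
    first = tensors[0]
    names = tuple(p.name for p in first.probes)
    for t in tensors[1:]:
        if not t.grid.compatible_with(first.grid):
            raise IncompatibleTensorError(
                f"tensor {t.code!r} uses a different grid")
        if tuple(p.name for p in t.probes) != names:
            raise IncompatibleTensorError(
                f"tensor {t.code!r} uses a different probe set")
        if t.capped != first.capped:
            raise IncompatibleTensorError("mixed capped/uncapped tensors")
    codes = [t.code for t in tensors]
    if len(set(codes)) != len(codes):
        raise IncompatibleTensorError("duplicate ensemble codes")
    data = pd.DataFrame(
        np.vstack([t.flat_values() for t in tensors]),
        index=codes, columns=first.labels(),
    )
    return DescriptorMatrix(data, grid=first.grid, probe_names=names)


def drop_invariant(matrix: DescriptorMatrix
                   ) -> tuple[DescriptorMatrix, SelectionReport]:
    """Remove columns with zero variance across codes."""
    if matrix.data.shape[0] < 2:
        raise GridQSARError("need >= 2 codes to assess variance")
    values = matrix.data.values
    var = values.var(axis=0)
    keep = var > _VAR_TOL
    retained = [l for l, k in zip(matrix.labels, keep) if k]
    report = SelectionReport(
        threshold=None,
        n_input=len(matrix.labels),
        n_zero_variance=int((~keep).sum()),
        n_retained=len(retained),
        retained_labels=retained,
    )
    return matrix.subset_columns(retained), report


def correlation_filter(matrix: DescriptorMatrix, y: pd.Series,
                       threshold: float, codes: Sequence[str] | None = None
                       ) -> tuple[DescriptorMatrix, SelectionReport]:
    """Keep descriptors with |Pearson r| >= threshold against activity.

    ``y`` maps codes to activity; ``codes`` restricts the correlation to a
    subset (typically the 10 non-external codes) while all rows of the
    matrix are carried through. Zero-variance columns on that subset have
    undefined r and are eliminated (counted as ``n_zero_r``).
    """
    codes = list(codes) if codes is not None else list(matrix.codes)
    if len(codes) < 3:
        raise GridQSARError("need >= 3 codes to correlate")
    yv = y.loc[codes].to_numpy(dtype=float)
    if yv.std() <= 0:
        raise GridQSARError("activity is constant; correlation undefined")
    X = matrix.rows(codes).to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    yc = yv - yv.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    defined = sx > np.sqrt(_VAR_TOL * len(codes))
    r = np.full(X.shape[1], np.nan)
    r[defined] = (Xc[:, defined] * yc[:, None]).sum(axis=0) / (sx[defined] * sy)
    keep = defined & (np.abs(np.where(defined, r, 0.0)) >= threshold)
    retained = [l for l, k in zip(matrix.labels, keep) if k]
    report = SelectionReport(
        threshold=threshold,
        n_input=len(matrix.labels),
        n_zero_r=int((~defined).sum()),
        n_retained=len(retained),
        retained_labels=retained,
        correlations=pd.Series(r[defined],
                               index=[l for l, d in zip(matrix.labels, defined)
                                      if d]),
    )
    return matrix.subset_columns(retained), report
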