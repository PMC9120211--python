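"""Congruence between indicators: zero-filled matrix, transform, Pearson r.

The indicator matrix has one row per corridor cell and one column per
indicator; cell-indicator combinations with no value (e.g. unselected cells
of a complementarity column) are filled with 0, never dropped.  Columns are
made approximately normal by a log1p transform followed by z-scoring, then
all pairwise Pearson correlations are computed over the full row set and
labeled by conventional strength classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .grid import CellSet
from .metrics import CellValueTable

__all__ = [
    "CorrelationMatrix",
    "build_matrix",
    "transform",
    "pearson_all",
    "classify",
    "STRENGTH_LABELS",
]

STRENGTH_LABELS = (
    "very strong", "strong", "moderate", "weak", "very weak or none",
)


def build_matrix(
    tables: Sequence[CellValueTable],
    cells: CellSet,
) -> pd.DataFrame:
    """Cells x indicators value matrix with zero-filling.

    Every corridor cell appears as a row; indicator values missing for a
    cell become 0.  Duplicate indicator names are rejected.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise InvalidInputError("need at least 2 indicator tables")
    names = [t.name for t in tables]
    if len(set(names)) != len(names):
        raise InvalidInputError("duplicate indicator names")
    index = list(cells.cell_ids)
    data = {
        t.name: [t.get(c, 0.0) for c in index]
        for t in tables
    }
    return pd.DataFrame(data, index=index)


def transform(
    matrix: pd.DataFrame,
    order: str = "log_then_z",
) -> pd.DataFrame:
    """Normalize indicator columns for correlation.

    ``log_then_z`` (default): y = log1p(v) per column, then z-score (mean 0,
    unit sample variance).  log1p is used because zero-filled entries make a
    plain log undefined.  ``z_then_log``: z-score first, then the signed log
    ``sign(z) * log1p(|z|)`` (defined on negatives).  Constant columns cannot
    be scaled; they are set to all-zero and reported via a warning.  The
    order used is recorded in ``result.attrs["transform_order"]``.
    """
    if order not in ("log_then_z", "z_then_log"):
        raise InvalidInputError(f"unknown transform order {order!r}")
    out = {}
    constant: list[str] = []

    def zscore(col: np.ndarray) -> np.ndarray:
        sd = col.std(ddof=1) if len(col) > 1 else 0.0
        if sd == 0:
            return None
        return (col - col.mean()) / sd

    for name in matrix.columns:
        col = matrix[name].to_numpy(dtype=float)
        if order == "log_then_z":
            y = zscore(np.log1p(col))
        else:
            y = zscore(col)
            if y is not None:
                y = np.sign(y) * np.log1p(np.abs(y))
        if y is None:
            constant.append(name)
            y = np.zeros(len(col))
        out[name] = y
    if constant:
        warnings.warn(
            f"constant indicator columns left at zero: {constant}",
            UserWarning,
            stacklevel=2,
        )
    result = pd.DataFrame(out, index=matrix.index)
    result.attrs["transform_order"] = order
    result.attrs["constant_columns"] = constant
    return result


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with p-values and strength labels."""

    r: pd.DataFrame
    p: pd.DataFrame
    labels: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = self.r.map(classify)

    def to_long(self) -> pd.DataFrame:
        """Long-format (indicator_a, indicator_b, r, p, label), upper triangle."""
        rows = []
        cols = list(self.r.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rows.append(
                    (a, b, self.r.at[a, b], self.p.at[a, b], self.labels.at[a, b])
                )
        return pd.DataFrame(
            rows, columns=["indicator_a", "indicator_b", "r", "p", "label"]
        )


def pearson_all(matrix: pd.DataFrame) -> CorrelationMatrix:
    """Pearson r, two-sided p and strength label for every column pair.

    Correlations are computed over the full (zero-filled) row set.  Pairs
    involving a constant column get r = 0, p = 1 (no measurable linear
    association).  The result is exactly symmetric with a unit diagonal.
    """
    n = len(matrix)
    if n < 3:
        raise InvalidInputError("need at least 3 rows for correlation")
    cols = list(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if sd[i] == 0 or sd[j] == 0:
                rij, pij = 0.0, 1.0
            else:
                rij, pij = stats.pearsonr(X[:, i], X[:, j])
                rij = float(np.clip(rij, -1.0, 1.0))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    return CorrelationMatrix(r=rdf, p=pdf)


def classify(r: float) -> str:
    """Conventional strength label for a correlation coefficient.

    |r| >= .8 very strong; .6 <= |r| < .8 strong; .4 <= |r| < .6 moderate;
    .2 <= |r| < .4 weak; below .2 very weak or none.  Boundaries are
    inclusive on the lower bound.
    """
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise InvalidInputError(f"|r| > 1: {r}")
    a = min(a, 1.0)
    if a >= 0.8:
        return "very strong"
    if a >= 0.6:
        return "strong"
    if a >= 0.4:
        return "moderate"
    if a >= 0.2:
        return "weak"
    return "very weak or none"
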