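"""Expert panels and their aggregation into a direct-relation matrix.

Each expert scores the direct influence of every ordered factor pair on an
integer scale (0 = no influence up to ``scale_max``, by default 3 = very
strong influence); the diagonal is zero by convention (a factor does not
influence itself directly). A panel is aggregated by the unweighted
arithmetic mean per cell, yielding the direct-relation matrix A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from dematelkit.catalog import FactorCatalog
from dematelkit.errors import ValidationError

logger = logging.getLogger(__name__)


def _check_square(values: np.ndarray, catalog: FactorCatalog, what: str) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"{what}: expected a square matrix, got shape {values.shape}")
    if values.shape[0] != catalog.n:
        raise ValidationError(
            f"{what}: shape {values.shape} does not match catalog with {catalog.n} factors"
        )


@dataclass(frozen=True)
class ExpertScoreMatrix:
    """One expert's n×n integer influence ratings.

    Row i, column j holds the rated direct influence of factor i on factor j,
    an integer in {0, ..., scale_max}; the diagonal must be zero.
    """

    catalog: FactorCatalog
    scores: np.ndarray
    expert_id: str = "expert"
    scale_max: int = 3

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        _check_square(scores, self.catalog, f"expert {self.expert_id!r}")
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.all(np.isfinite(scores)) or np.any(scores != np.round(scores)):
                raise ValidationError(
                    f"expert {self.expert_id!r}: scores must be integers"
                )
            scores = scores.astype(np.int64)
        bad = (scores < 0) | (scores > self.scale_max)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"expert {self.expert_id!r}: score {scores[i, j]} at cell "
                f"({self.catalog.ids[i]}, {self.catalog.ids[j]}) outside "
                f"[0, {self.scale_max}]"
            )
        diag = np.diagonal(scores)
        if np.any(diag != 0):
            i = int(np.flatnonzero(diag)[0])
            raise ValidationError(
                f"expert {self.expert_id!r}: non-zero diagonal at "
                f"({self.catalog.ids[i]}, {self.catalog.ids[i]})"
            )
        scores = scores.astype(np.int64, copy=True)
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)


@dataclass(frozen=True)
class DirectRelationMatrix:
    """The panel-averaged direct-relation matrix A (non-negative, zero diagonal)."""

    catalog: FactorCatalog
    values: np.ndarray
    m_experts: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        _check_square(values, self.catalog, "direct-relation matrix")
        if not np.all(np.isfinite(values)):
            raise ValidationError("direct-relation matrix: non-finite entry")
        if np.any(values < 0):
            i, j = map(int, np.argwhere(values < 0)[0])
            raise ValidationError(
                f"direct-relation matrix: negative entry at "
                f"({self.catalog.ids[i]}, {self.catalog.ids[j]})"
            )
        if np.any(np.diagonal(values) != 0):
            offenders = [
                self.catalog.ids[int(i)] for i in np.flatnonzero(np.diagonal(values))
            ]
            raise ValidationError(
                f"direct-relation matrix: non-zero diagonal at {offenders}"
            )
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)


def aggregate_panel(panel: Sequence[ExpertScoreMatrix]) -> DirectRelationMatrix:
    """Aggregate a panel by the unweighted arithmetic mean per cell.

    Every member must share one catalog (same ids, same order) and one
    ``scale_max``. Aggregation is permutation-invariant over experts, and
    each aggregated cell lies between the panel's min and max for that cell.

    Raises
    ------
    ValidationError
        If the panel is empty or its members are incompatible.
    """
    if len(panel) == 0:
        raise ValidationError("empty panel")
    first = panel[0]
    for expert in panel[1:]:
        if expert.catalog != first.catalog or expert.scale_max != first.scale_max:
            raise ValidationError(
                f"incompatible panel: expert {expert.expert_id!r} does not match "
                f"expert {first.expert_id!r} (catalog or scale_max differs)"
            )
    stacked = np.stack([e.scores for e in panel])
    return DirectRelationMatrix(
        catalog=first.catalog,
        values=stacked.mean(axis=0),
        m_experts=len(panel),
    )


def validate_direct_matrix(
    values,
    catalog: FactorCatalog,
    *,
    m_experts: int | None = None,
    diagonal: str = "error",
) -> DirectRelationMatrix:
    """Validate raw numbers (e.g. a published matrix) as a DirectRelationMatrix.

    Parameters
    ----------
    values
        Square array-like of non-negative reals, shape (n, n) for the catalog.
    diagonal
        ``"error"`` (default) rejects non-zero diagonal entries;
        ``"coerce"`` zeroes them with a logged warning.
    """
    if diagonal not in ("error", "coerce"):
        raise ValidationError(f"diagonal mode must be 'error' or 'coerce', got {diagonal!r}")
    arr = np.asarray(values, dtype=float)
    _check_square(arr, catalog, "direct-relation matrix")
    if diagonal == "coerce" and np.any(np.diagonal(arr) != 0):
        offenders = [catalog.ids[int(i)] for i in np.flatnonzero(np.diagonal(arr))]
        logger.warning("coercing non-zero diagonal to zero at %s", offenders)
        arr = arr.copy()
        np.fill_diagonal(arr, 0.0)
    return DirectRelationMatrix(catalog=catalog, values=arr, m_experts=m_experts)
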