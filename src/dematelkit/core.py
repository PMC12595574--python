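"""Core DEMATEL computations.

The pipeline is: normalize the direct-relation matrix A by its maximum row
sum to get X; sum the geometric series of direct and indirect influence,
T = X + X² + X³ + ... = X(I−X)⁻¹; then summarise each factor by its
dispatched influence R (row sum of T), received influence C (column sum),
prominence R+C (total engagement in the influence system) and relation R−C
(net influence). A factor with positive relation belongs to the cause
group (it drives the system); a negative relation puts it in the effect
group. The mean of all n² entries of T serves as the threshold below which
influences are treated as negligible when drawing the causal network.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.linalg

from dematelkit.catalog import FactorCatalog
from dematelkit.errors import ComputationError, ValidationError
from dematelkit.panel import DirectRelationMatrix, _check_square

logger = logging.getLogger(__name__)

Group = Literal["Cause", "Effect"]

#: Condition-number ceiling for I−X beyond which the influence system is
#: treated as non-convergent rather than silently regularised.
CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class NormalizedDirectMatrix:
    """The normalized direct-relation matrix X = A / max row sum of A."""

    catalog: FactorCatalog
    values: np.ndarray
    normalizing_constant: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        _check_square(values, self.catalog, "normalized matrix")
        if not self.normalizing_constant > 0:
            raise ValidationError("normalizing_constant must be positive")
        if np.any(values < 0) or np.any(values > 1):
            raise ValidationError("normalized entries must lie in [0, 1]")
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class TotalRelationMatrix:
    """The total-relation matrix T = X(I−X)⁻¹: direct plus all indirect influence."""

    catalog: FactorCatalog
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        _check_square(values, self.catalog, "total-relation matrix")
        if not np.all(np.isfinite(values)):
            raise ValidationError("total-relation matrix: non-finite entry")
        if np.any(values < -1e-12):
            raise ValidationError("total-relation matrix: negative entry")
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def row_sums(self) -> np.ndarray:
        """Dispatched influence R per factor."""
        return self.values.sum(axis=1)

    @property
    def column_sums(self) -> np.ndarray:
        """Received influence C per factor."""
        return self.values.sum(axis=0)


@dataclass(frozen=True)
class FactorInfluenceProfile:
    """Per-factor influence summary: R, C, prominence R+C, relation R−C, group."""

    factor_id: str
    label: str
    R: float
    C: float
    prominence: float
    relation: float
    group: Group


@dataclass(frozen=True)
class AnalysisResult:
    """Bundle of all pipeline stages for one direct-relation matrix."""

    direct: DirectRelationMatrix
    normalized: NormalizedDirectMatrix
    total: TotalRelationMatrix
    profiles: tuple[FactorInfluenceProfile, ...]
    threshold: float
    provenance: dict = field(default_factory=dict)

    @property
    def catalog(self) -> FactorCatalog:
        return self.direct.catalog


def normalize(A: DirectRelationMatrix) -> NormalizedDirectMatrix:
    """Normalize A by the maximum over rows of its row sums.

    After normalization every entry lies in [0, 1] and the row attaining
    the maximum row sum sums to exactly 1.

    Raises
    ------
    ComputationError
        If A is all-zero (no influence to normalize).
    """
    row_sums = A.values.sum(axis=1)
    constant = float(row_sums.max())
    if constant == 0.0:
        raise ComputationError("degenerate matrix (no influence): all entries are zero")
    return NormalizedDirectMatrix(
        catalog=A.catalog,
        values=A.values / constant,
        normalizing_constant=constant,
    )


def total_relation(
    X: NormalizedDirectMatrix, *, condition_limit: float = CONDITION_LIMIT
) -> TotalRelationMatrix:
    """Compute T = X(I−X)⁻¹ via a linear solve.

    Equivalently the limit of the series Σ_{k≥1} X^k, which converges when
    the spectral radius of X is below 1 — guaranteed after max-row-sum
    normalization unless every row of A attains the maximal row sum.

    Raises
    ------
    ComputationError
        If I−X is singular or its condition estimate exceeds
        ``condition_limit`` (a non-convergent influence system).
    """
    n = X.catalog.n
    I_minus_X = np.eye(n) - X.values
    cond = float(np.linalg.cond(I_minus_X))
    if not np.isfinite(cond) or cond > condition_limit:
        raise ComputationError(
            f"non-convergent influence system: condition estimate of I-X is "
            f"{cond:.3g} (limit {condition_limit:.3g})"
        )
    # T(I−X) = X  ⇔  (I−X)ᵀ Tᵀ = Xᵀ
    T = scipy.linalg.solve(I_minus_X.T, X.values.T).T
    T = np.where(np.abs(T) < 1e-15, 0.0, T)  # scrub solver noise at true zeros
    return TotalRelationMatrix(catalog=X.catalog, values=T)


def classify_group(relation: float) -> Group:
    """Classify a factor by the sign of its relation R−C.

    Positive → "Cause" (net driver); negative → "Effect" (net driven).
    An exact zero is classified "Effect" with a logged warning, since the
    cause group is defined strictly by positivity.
    """
    if not np.isfinite(relation):
        raise ValidationError(f"relation must be finite, got {relation!r}")
    if relation > 0:
        return "Cause"
    if relation == 0:
        logger.warning("relation is exactly 0; classifying as Effect (tie rule)")
    return "Effect"


def prominence_relation(T: TotalRelationMatrix) -> tuple[FactorInfluenceProfile, ...]:
    """Per-factor profiles (R, C, R+C, R−C, group) in catalog order."""
    R = T.row_sums
    C = T.column_sums
    profiles = []
    for i, (fid, label) in enumerate(T.catalog.factors):
        relation = float(R[i] - C[i])
        profiles.append(
            FactorInfluenceProfile(
                factor_id=fid,
                label=label,
                R=float(R[i]),
                C=float(C[i]),
                prominence=float(R[i] + C[i]),
                relation=relation,
                group=classify_group(relation),
            )
        )
    return tuple(profiles)


def compute_threshold(T: TotalRelationMatrix) -> float:
    """Arithmetic mean over all n² entries of T, diagonal included."""
    return float(T.values.mean())


def analyze(A: DirectRelationMatrix) -> AnalysisResult:
    """Run the full pipeline A → X → T → profiles + threshold.

    Deterministic for a fixed input; stage failures propagate with the
    stage name prefixed.
    """
    stages = {}

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except (ValidationError, ComputationError) as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    X = _stage("normalize", normalize, A)
    T = _stage("total_relation", total_relation, X)
    profiles = _stage("prominence_relation", prominence_relation, T)
    threshold = _stage("compute_threshold", compute_threshold, T)
    stages["normalizing_constant"] = X.normalizing_constant
    stages["threshold"] = threshold
    stages["n_factors"] = A.catalog.n
    stages["m_experts"] = A.m_experts
    stages["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    return AnalysisResult(
        direct=A,
        normalized=X,
        total=T,
        profiles=profiles,
        threshold=threshold,
        provenance=stages,
    )
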