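"""Factor catalogs: the ordered set of factors every matrix is indexed by."""

from __future__ import annotations

from dataclasses import dataclass, field

from dematelkit.errors import ValidationError


@dataclass(frozen=True)
class FactorCatalog:
    """Ordered collection of (factor_id, label) pairs.

    The order is significant: every matrix in an analysis is indexed by it,
    rows as influencing factors and columns as influenced factors.
    """

    factors: tuple[tuple[str, str], ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        factors = tuple((str(fid), str(label)) for fid, label in self.factors)
        object.__setattr__(self, "factors", factors)
        ids = [fid for fid, _ in factors]
        if len(ids) < 2:
            raise ValidationError("catalog needs at least 2 factors")
        if any(not fid for fid in ids):
            raise ValidationError("empty factor_id in catalog")
        if len(set(ids)) != len(ids):
            dupes = sorted({fid for fid in ids if ids.count(fid) > 1})
            raise ValidationError(f"duplicate factor_ids: {dupes}")
        object.__setattr__(self, "_index", {fid: i for i, fid in enumerate(ids)})

    @property
    def n(self) -> int:
        return len(self.factors)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(fid for fid, _ in self.factors)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for _, label in self.factors)

    def index(self, factor_id: str) -> int:
        try:
            return self._index[factor_id]
        except KeyError:
            raise ValidationError(f"unknown factor_id {factor_id!r}") from None

    def label(self, factor_id: str) -> str:
        return self.factors[self.index(factor_id)][1]

    def __contains__(self, factor_id: object) -> bool:
        return factor_id in self._index

    def __len__(self) -> int:
        return self.n

    @classmethod
    def from_pairs(cls, pairs) -> "FactorCatalog":
        """Build from any iterable of (factor_id, label) pairs."""
        return cls(tuple((fid, label) for fid, label in pairs))

    @classmethod
    def from_ids(cls, ids) -> "FactorCatalog":
        """Build with labels equal to the ids (handy for tests/simulations)."""
        return cls(tuple((fid, fid) for fid in ids))
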