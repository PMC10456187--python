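"""Action-unit catalogs and binary stimulus vectors.

A stimulus is a face rendered with a fixed number of facial action units
(AUs, Facial Action Coding System) switched on.  Everything downstream —
trial schedules, proportion estimators, simulated observers — works on the
binary activation pattern only; rendering is a separate, strictly
downstream concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = ["DEFAULT_AU_IDS", "StimulusCatalog", "StimulusVector"]

#: The 16 action units an AU-conditioned face renderer driven by OpenFace
#: intensity outputs can manipulate.  Overridable everywhere: all
#: computation is catalog-agnostic.
DEFAULT_AU_IDS: tuple[int, ...] = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26)


@dataclass(frozen=True)
class StimulusCatalog:
    """An ordered set of AU ids plus the number of AUs active per stimulus.

    Parameters
    ----------
    au_ids
        Distinct positive FACS AU numbers, sorted ascending.  Defaults to
        the 16-AU set above.
    k_active
        How many AUs each design-generated stimulus activates
        simultaneously (default 3; activating many AUs at once tends to
        produce rendering artifacts).
    """

    au_ids: tuple[int, ...] = DEFAULT_AU_IDS
    k_active: int = 3

    def __post_init__(self) -> None:
        ids = tuple(int(a) for a in self.au_ids)
        if len(ids) == 0:
            raise ValueError("catalog needs at least one AU id")
        if any(a <= 0 for a in ids):
            raise ValueError(f"AU ids must be positive integers, got {ids}")
        if len(set(ids)) != len(ids):
            raise ValueError(f"AU ids must be unique, got {ids}")
        if list(ids) != sorted(ids):
            raise ValueError(f"AU ids must be sorted ascending, got {ids}")
        object.__setattr__(self, "au_ids", ids)
        if not 0 <= self.k_active <= len(ids):
            raise ValueError(
                f"k_active must lie in [0, {len(ids)}], got {self.k_active}"
            )

    def __len__(self) -> int:
        return len(self.au_ids)

    def index(self, au_id: int) -> int:
        """Position of ``au_id`` in the catalog; KeyError if absent."""
        try:
            return self.au_ids.index(au_id)
        except ValueError:
            raise KeyError(f"AU{au_id} is not in the catalog {self.au_ids}") from None

    def __contains__(self, au_id: object) -> bool:
        return au_id in self.au_ids


@dataclass(frozen=True)
class StimulusVector:
    """Binary AU activation pattern over a catalog (0 = off, 1 = on)."""

    catalog: StimulusCatalog
    activations: tuple[int, ...]

    def __post_init__(self) -> None:
        acts = tuple(int(a) for a in self.activations)
        if len(acts) != len(self.catalog):
            raise ValueError(
                f"activation vector has length {len(acts)}, "
                f"catalog has {len(self.catalog)} AUs"
            )
        if any(a not in (0, 1) for a in acts):
            raise ValueError(f"activations must be 0/1, got {acts}")
        object.__setattr__(self, "activations", acts)

    @classmethod
    def from_active_ids(
        cls, catalog: StimulusCatalog, active_ids: Iterable[int]
    ) -> "StimulusVector":
        ids = set(int(a) for a in active_ids)
        for a in ids:
            if a not in catalog:
                raise KeyError(f"AU{a} is not in the catalog {catalog.au_ids}")
        return cls(catalog, tuple(1 if a in ids else 0 for a in catalog.au_ids))

    @property
    def active_ids(self) -> frozenset[int]:
        return frozenset(
            a for a, x in zip(self.catalog.au_ids, self.activations) if x
        )

    @property
    def n_active(self) -> int:
        return sum(self.activations)

    def has(self, au_id: int) -> bool:
        return bool(self.activations[self.catalog.index(au_id)])

    def __str__(self) -> str:  # "4;6;12" style, stable and explicit
        return ";".join(str(a) for a in sorted(self.active_ids))
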