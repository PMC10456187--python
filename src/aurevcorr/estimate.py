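"""Mental-representation estimation from 2AFC responses.

The estimator is a two-stage reverse-correlation analysis.  For each action
unit *i* the trials Ω split into three disjoint subsets by the activation
pattern of *i* in the two stimuli: exactly one bears it (Ω_{i*}), both do
(Ω_i), neither does (Ω_ī).

Stage 1 (dominant AU): over Ω_{i*}, the fraction of trials in which the
*chosen* stimulus bears AU i,

    P(i | Ω_{i*}) = |Z_{Ω_{i*}} ∩ Φ_i| / |Z_{Ω_{i*}}|,

where Z is the set of chosen stimuli and Φ_i the stimuli bearing AU i.  The
dominant AU d is the argmax of these proportions.

Stage 2 (complementary AUs): restrict to Ω_d (both stimuli bear d), split
again by each non-dominant AU j, and compute P(j | Ω_{d,j*}) the same way.
The complementary set is C = { j : P(j | Ω_{d,j*}) ≥ T_q } for a threshold
T_q well above 50% (a proportion of 50% means AU j carries no information
for the task).  The mental prototype activates {d} ∪ C.

Zero-denominator proportions are *undefined*, never silently 0, and are
excluded from the argmax and from thresholding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import StimulusCatalog, StimulusVector
from .design import ResponseSet

__all__ = [
    "AUPartition",
    "SelectionTally",
    "ProportionTable",
    "MentalPrototype",
    "ConvergenceCurve",
    "partition_by_au",
    "selection_proportions",
    "dominant_au",
    "complementary_proportions",
    "complementary_set",
    "build_prototype",
    "convergence_curve",
    "estimate_prototype",
    "dominant_subset_indices",
]

#: Default threshold separating complementary from non-complementary AUs.
DEFAULT_THRESHOLD = 0.8

#: Prototypes in the comparison literature activate 2-5 AUs; sizes outside
#: this band trigger a warning (never an error).
PROTOTYPE_SIZE_RANGE = (2, 5)


@dataclass(frozen=True)
class AUPartition:
    """Trial indices split by one AU's activation pattern across the pair."""

    au_id: int
    exactly_one: tuple[int, ...]
    both: tuple[int, ...]
    neither: tuple[int, ...]


@dataclass(frozen=True)
class SelectionTally:
    au_id: int
    selected_with_au: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.selected_with_au <= self.denominator:
            raise ValueError(
                f"AU{self.au_id}: tally {self.selected_with_au}/{self.denominator} "
                "is out of range"
            )

    @property
    def proportion(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.selected_with_au / self.denominator


@dataclass(frozen=True)
class ProportionTable:
    """Per-AU selection proportions with explicit numerators/denominators.

    ``context`` is ``"dominant_stage"`` or ``"complementary_stage"`` (the
    latter carries the conditioning dominant AU in ``conditioned_on``).
    Entries with a zero denominator have ``proportion is None``.
    """

    context: Literal["dominant_stage", "complementary_stage"]
    tallies: Mapping[int, SelectionTally]
    conditioned_on: int | None = None

    def proportion(self, au_id: int) -> float | None:
        return self.tallies[au_id].proportion

    def defined(self) -> dict[int, float]:
        return {
            a: t.proportion
            for a, t in self.tallies.items()
            if t.proportion is not None
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "au_id": a,
                "numerator": t.selected_with_au,
                "denominator": t.denominator,
                "proportion": t.proportion if t.proportion is not None else float("nan"),
                "defined": t.proportion is not None,
            }
            for a, t in sorted(self.tallies.items())
        ]
        return pd.DataFrame(rows, columns=["au_id", "numerator", "denominator", "proportion", "defined"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class MentalPrototype:
    """Estimated mental representation: dominant AU + complementary AUs.

    The binary control vector activates exactly {dominant} ∪ complementary.
    """

    catalog: StimulusCatalog
    dominant: int
    complementary: frozenset[int]
    threshold: float
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.dominant not in self.catalog:
            raise KeyError(f"dominant AU{self.dominant} is not in the catalog")
        comp = frozenset(int(j) for j in self.complementary)
        for j in comp:
            if j not in self.catalog:
                raise KeyError(f"complementary AU{j} is not in the catalog")
        if self.dominant in comp:
            raise ValueError(
                f"AU{self.dominant} cannot be both dominant and complementary"
            )
        object.__setattr__(self, "complementary", comp)
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")

    @property
    def active_ids(self) -> frozenset[int]:
        return self.complementary | {self.dominant}

    @property
    def vector(self) -> StimulusVector:
        return StimulusVector.from_active_ids(self.catalog, self.active_ids)

    def to_dict(self) -> dict:
        return {
            "catalog": list(self.catalog.au_ids),
            "dominant": self.dominant,
            "complementary": sorted(self.complementary),
            "threshold": self.threshold,
            "vector": list(self.vector.activations),
            "provenance": dict(self.provenance),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "MentalPrototype":
        catalog = StimulusCatalog(tuple(payload["catalog"]), k_active=0)
        return cls(
            catalog=catalog,
            dominant=int(payload["dominant"]),
            complementary=frozenset(int(j) for j in payload["complementary"]),
            threshold=float(payload["threshold"]),
            provenance=dict(payload.get("provenance", {})),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MentalPrototype":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ConvergenceCurve:
    """Correlation of partial-trial histograms with the final histogram."""

    stage: Literal["dominant", "complementary"]
    points: tuple[tuple[int, float | None], ...]

    @property
    def final_r(self) -> float | None:
        return self.points[-1][1] if self.points else None

    def trials_to_reach(self, r_target: float) -> int | None:
        """Smallest n from which r stays ≥ r_target for every later point."""
        best = None
        for n, r in reversed(self.points):
            if r is not None and r >= r_target:
                best = n
            else:
                break
        return best


# ---------------------------------------------------------------------------
# estimation


def partition_by_au(responses: ResponseSet, au_id: int) -> AUPartition:
    """Split trials by whether one, both or neither stimulus bears ``au_id``."""
    col = responses.catalog.index(au_id)  # KeyError on unknown AU
    left, right, _ = responses.matrices()
    l, r = left[:, col], right[:, col]
    idx = np.arange(responses.m)
    return AUPartition(
        au_id=au_id,
        exactly_one=tuple(idx[l ^ r].tolist()),
        both=tuple(idx[l & r].tolist()),
        neither=tuple(idx[~l & ~r].tolist()),
    )


def _stage_tallies(
    left: np.ndarray, right: np.ndarray, chose_left: np.ndarray, au_ids: Sequence[int]
) -> dict[int, SelectionTally]:
    chosen = np.where(chose_left[:, None], left, right)
    exactly_one = left ^ right
    tallies = {}
    for col, au in enumerate(au_ids):
        mask = exactly_one[:, col]
        tallies[au] = SelectionTally(
            au_id=au,
            selected_with_au=int(np.sum(mask & chosen[:, col])),
            denominator=int(np.sum(mask)),
        )
    return tallies


def selection_proportions(responses: ResponseSet) -> ProportionTable:
    """Stage-1 table P(i | Ω_{i*}) for every catalog AU."""
    if responses.m == 0:
        raise ValueError("cannot compute proportions from an empty response set")
    left, right, chose_left = responses.matrices()
    return ProportionTable(
        context="dominant_stage",
        tallies=_stage_tallies(left, right, chose_left, responses.catalog.au_ids),
    )


def dominant_au(table: ProportionTable) -> int:
    """Argmax of the defined proportions; ties go to the smallest AU id."""
    defined = table.defined()
    if not defined:
        raise ValueError("all proportions are undefined; cannot pick a dominant AU")
    best = max(defined.values())
    winners = sorted(a for a, p in defined.items() if p == best)
    if len(winners) > 1:
        warnings.warn(
            f"dominant-AU tie at P={best:.3f} between AUs {winners}; "
            f"returning the smallest id AU{winners[0]}",
            stacklevel=2,
        )
    return winners[0]


def dominant_subset_indices(responses: ResponseSet, d: int) -> tuple[int, ...]:
    """Chronological indices of Ω_d: trials whose two stimuli both bear d."""
    return partition_by_au(responses, d).both


def complementary_proportions(responses: ResponseSet, d: int) -> ProportionTable:
    """Stage-2 table P(j | Ω_{d,j*}) over Ω_d, for every j ≠ d."""
    both_idx = dominant_subset_indices(responses, d)
    au_ids = [a for a in responses.catalog.au_ids if a != d]
    if not both_idx:
        warnings.warn(
            f"no trial has AU{d} active in both stimuli (Ω_d is empty); "
            "all complementary proportions are undefined",
            stacklevel=2,
        )
        tallies = {a: SelectionTally(a, 0, 0) for a in au_ids}
    else:
        sub = responses.subset(both_idx)
        left, right, chose_left = sub.matrices()
        cols = [responses.catalog.index(a) for a in au_ids]
        tallies = _stage_tallies(
            left[:, cols], right[:, cols], chose_left, au_ids
        )
    return ProportionTable(
        context="complementary_stage", tallies=tallies, conditioned_on=d
    )


def complementary_set(table: ProportionTable, threshold: float) -> frozenset[int]:
    """C = { j : P(j | Ω_{d,j*}) defined and ≥ threshold } (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    chosen = frozenset(a for a, p in table.defined().items() if p >= threshold)
    if not chosen:
        warnings.warn("empty complementary set at this threshold", stacklevel=2)
    return chosen


def build_prototype(
    d: int,
    complementary: Sequence[int] | frozenset[int],
    catalog: StimulusCatalog,
    threshold: float,
    provenance: dict | None = None,
) -> MentalPrototype:
    """Assemble the prototype activating {d} ∪ C; warns outside 2-5 AUs."""
    proto = MentalPrototype(
        catalog=catalog,
        dominant=d,
        complementary=frozenset(complementary),
        threshold=threshold,
        provenance=provenance or {},
    )
    lo, hi = PROTOTYPE_SIZE_RANGE
    n = len(proto.active_ids)
    if not lo <= n <= hi:
        warnings.warn(
            f"prototype activates {n} AUs, outside the typical {lo}-{hi} range",
            stacklevel=2,
        )
    return proto


# ---------------------------------------------------------------------------
# convergence diagnostics


def _histogram(table: ProportionTable, au_ids: Sequence[int]) -> np.ndarray:
    return np.array(
        [
            t.proportion if (t := table.tallies[a]).proportion is not None else np.nan
            for a in au_ids
        ]
    )


def _pairwise_r(partial: np.ndarray, final: np.ndarray) -> float | None:
    ok = ~np.isnan(partial) & ~np.isnan(final)
    if ok.sum() < 2:
        return None
    x, y = partial[ok], final[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None  # constant histogram: correlation undefined
    return float(np.corrcoef(x, y)[0, 1])


def convergence_curve(
    responses: ResponseSet,
    stage: Literal["dominant", "complementary"] = "dominant",
    step: int = 10,
    d: int | None = None,
) -> ConvergenceCurve:
    """Pearson correlation between first-n-trial and final-histogram.

    For the dominant stage, n runs over chronological prefixes of Ω; for
    the complementary stage, over prefixes of the chronological subsequence
    Ω_d (which requires ``d``).  Undefined AU bins are dropped pairwise;
    points with fewer than two commonly defined bins, or a constant partial
    histogram, are flagged as undefined (``None``).
    """
    if step < 1:
        raise ValueError("step must be ≥ 1")
    if stage == "dominant":
        base = responses
        def table_of(sub: ResponseSet) -> ProportionTable:
            return selection_proportions(sub)
        au_ids: Sequence[int] = responses.catalog.au_ids
    elif stage == "complementary":
        if d is None:
            raise ValueError("complementary stage requires the dominant AU d")
        base = responses.subset(dominant_subset_indices(responses, d))
        def table_of(sub: ResponseSet) -> ProportionTable:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return complementary_proportions(sub, d)
        au_ids = [a for a in responses.catalog.au_ids if a != d]
    else:
        raise ValueError(f"unknown stage {stage!r}")

    total = base.m
    if total == 0:
        raise ValueError("no trials available for this stage")
    final = _histogram(table_of(base), au_ids)
    ns = list(range(step, total + 1, step))
    if not ns or ns[-1] != total:
        ns.append(total)
    points = []
    for n in ns:
        partial = _histogram(table_of(base.subset(range(n))), au_ids)
        points.append((n, _pairwise_r(partial, final)))
    return ConvergenceCurve(stage=stage, points=tuple(points))


def estimate_prototype(
    responses: ResponseSet,
    threshold: float = DEFAULT_THRESHOLD,
    provenance: dict | None = None,
) -> tuple[MentalPrototype, ProportionTable, ProportionTable]:
    """Full two-stage pipeline: responses → (prototype, stage tables)."""
    dom_table = selection_proportions(responses)
    d = dominant_au(dom_table)
    comp_table = complementary_proportions(responses, d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp = complementary_set(comp_table, threshold)
    prov = dict(provenance or {})
    prov.setdefault("m", responses.m)
    if responses.question_label:
        prov.setdefault("question_label", responses.question_label)
    proto = build_prototype(d, comp, responses.catalog, threshold, provenance=prov)
    return proto, dom_table, comp_table
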