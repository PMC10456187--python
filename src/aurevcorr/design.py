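"""Combinatorial 2AFC stimulus designs and their on-disk formats.

The design space is every way of activating exactly ``k_active`` AUs out of
the catalog (e.g. C(16, 3) = 560 stimuli).  A schedule is a set of
two-alternative forced-choice (2AFC) trials: unordered stimulus pairs drawn
uniformly without replacement, each displayed once, with the left/right
presentation side randomized independently.

File formats (UTF-8, plain CSV, ``#``-prefixed metadata lines allowed):

* schedule:  ``trial_id,left_aus,right_aus`` with AU ids semicolon-joined
  (``"4;6;12"``) — explicit ids, never positional bitmasks.
* responses: schedule columns plus ``choice`` in ``{left, right}``.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .catalog import StimulusCatalog, StimulusVector

__all__ = [
    "TrialPair",
    "ResponseSet",
    "enumerate_stimuli",
    "sample_schedule",
    "write_schedule",
    "read_schedule",
    "write_responses",
    "read_responses",
]

Choice = Literal["left", "right"]


@dataclass(frozen=True)
class TrialPair:
    """One 2AFC trial: two distinct stimuli shown side by side."""

    trial_id: int
    left: StimulusVector
    right: StimulusVector

    def __post_init__(self) -> None:
        if self.left.activations == self.right.activations:
            raise ValueError(f"trial {self.trial_id}: left and right are identical")

    @property
    def unordered_key(self) -> frozenset[tuple[int, ...]]:
        return frozenset((self.left.activations, self.right.activations))


class ResponseSet:
    """All answered trials of one perceptual experiment (the set Ω, |Ω| = m).

    Stores trials in chronological (file) order; exposes cached boolean
    activation matrices for the vectorized estimators.
    """

    def __init__(
        self,
        trials: Sequence[tuple[TrialPair, Choice]],
        question_label: str = "",
        observer_id: str = "",
        catalog: StimulusCatalog | None = None,
    ) -> None:
        trials = list(trials)
        for pair, choice in trials:
            if choice not in ("left", "right"):
                raise ValueError(
                    f"trial {pair.trial_id}: choice must be 'left' or 'right', got {choice!r}"
                )
        if catalog is None:
            if not trials:
                raise ValueError("catalog is required for an empty ResponseSet")
            catalog = trials[0][0].left.catalog
        self.trials: list[tuple[TrialPair, Choice]] = trials
        self.question_label = question_label
        self.observer_id = observer_id
        self.catalog = catalog
        self._matrices: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def m(self) -> int:
        return len(self.trials)

    def __len__(self) -> int:
        return self.m

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(left, right, chose_left): two (m, n_au) bool arrays + (m,) bool."""
        if self._matrices is None:
            m, n = self.m, len(self.catalog)
            left = np.zeros((m, n), dtype=bool)
            right = np.zeros((m, n), dtype=bool)
            chose_left = np.zeros(m, dtype=bool)
            for t, (pair, choice) in enumerate(self.trials):
                left[t] = pair.left.activations
                right[t] = pair.right.activations
                chose_left[t] = choice == "left"
            self._matrices = (left, right, chose_left)
        return self._matrices

    def subset(self, indices: Sequence[int]) -> "ResponseSet":
        """Chronological sub-experiment (order of ``indices`` preserved)."""
        return ResponseSet(
            [self.trials[i] for i in indices],
            question_label=self.question_label,
            observer_id=self.observer_id,
            catalog=self.catalog,
        )


def enumerate_stimuli(catalog: StimulusCatalog) -> list[StimulusVector]:
    """All C(n, k_active) stimuli, in lexicographic order of AU positions."""
    vectors = []
    n = len(catalog)
    for positions in combinations(range(n), catalog.k_active):
        acts = [0] * n
        for p in positions:
            acts[p] = 1
        vectors.append(StimulusVector(catalog, tuple(acts)))
    return vectors


def n_unordered_pairs(n_stimuli: int) -> int:
    """Number of distinct 2AFC trials available, C(n, 2)."""
    return math.comb(n_stimuli, 2)


def sample_schedule(
    stimuli: Sequence[StimulusVector], m: int, seed: int
) -> list[TrialPair]:
    """Draw ``m`` unordered stimulus pairs uniformly without replacement.

    Each pair appears at most once; the side on which each member is shown
    is randomized independently.  Bitwise reproducible from ``seed``.
    """
    n = len(stimuli)
    if len({s.activations for s in stimuli}) != n:
        raise ValueError("stimuli must be distinct")
    total = n_unordered_pairs(n)
    if m < 0:
        raise ValueError("m must be non-negative")
    if m > total:
        raise ValueError(
            f"requested m={m} trials but only C({n},2)={total} distinct "
            f"unordered pairs exist"
        )
    rng = np.random.default_rng(seed)
    pair_idx = rng.choice(total, size=m, replace=False)
    flip = rng.integers(0, 2, size=m).astype(bool)

    # unrank: pairs (i, j), i < j, lexicographic; cum[i] = #pairs with first < i
    firsts = np.arange(n, dtype=np.int64)
    cum = firsts * (n - 1) - firsts * (firsts - 1) // 2
    i = np.searchsorted(cum, pair_idx, side="right") - 1
    j = i + 1 + (pair_idx - cum[i])

    schedule = []
    for t in range(m):
        a, b = stimuli[int(i[t])], stimuli[int(j[t])]
        if flip[t]:
            a, b = b, a
        schedule.append(TrialPair(trial_id=t, left=a, right=b))
    return schedule


# ---------------------------------------------------------------------------
# serialization


def _format_aus(vec: StimulusVector) -> str:
    return ";".join(str(a) for a in sorted(vec.active_ids))


def _parse_aus(
    text: str, catalog: StimulusCatalog, row: int, column: str
) -> StimulusVector:
    if text.strip() == "":
        ids: list[int] = []
    else:
        try:
            ids = [int(tok) for tok in text.split(";")]
        except ValueError:
            raise ValueError(f"row {row}: cannot parse {column}={text!r}") from None
    for a in ids:
        if a not in catalog:
            raise ValueError(
                f"row {row}: AU{a} in {column} is not in the catalog {catalog.au_ids}"
            )
    if len(set(ids)) != len(ids):
        raise ValueError(f"row {row}: duplicated AU id in {column}={text!r}")
    return StimulusVector.from_active_ids(catalog, ids)


def _write_rows(
    path: str | Path,
    header: list[str],
    rows: Iterable[list[str]],
    metadata: dict[str, str],
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key}={value}\n")
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def _read_rows(path: str | Path) -> tuple[dict[str, str], list[str], list[tuple[int, list[str]]]]:
    metadata: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = value.strip()
                continue
            if not line.strip():
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = fields
            else:
                rows.append((lineno, fields))
    if header is None:
        header = []
    return metadata, header, rows


def write_schedule(
    schedule: Sequence[TrialPair],
    path: str | Path,
    metadata: dict[str, str] | None = None,
) -> None:
    _write_rows(
        path,
        ["trial_id", "left_aus", "right_aus"],
        (
            [str(p.trial_id), _format_aus(p.left), _format_aus(p.right)]
            for p in schedule
        ),
        metadata or {},
    )


def _check_schedule_row(
    pair: TrialPair,
    row: int,
    seen_ids: set[int],
    seen_pairs: set[frozenset],
    catalog: StimulusCatalog,
    strict: bool,
) -> None:
    if pair.trial_id in seen_ids:
        raise ValueError(f"row {row}: duplicate trial_id {pair.trial_id}")
    seen_ids.add(pair.trial_id)
    key = pair.unordered_key
    if key in seen_pairs:
        raise ValueError(f"row {row}: duplicated unordered stimulus pair")
    seen_pairs.add(key)
    for side, vec in (("left", pair.left), ("right", pair.right)):
        if vec.n_active != catalog.k_active:
            msg = (
                f"row {row}: {side} stimulus activates {vec.n_active} AUs, "
                f"design expects {catalog.k_active}"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=3)


def read_schedule(
    path: str | Path, catalog: StimulusCatalog, strict: bool = False
) -> list[TrialPair]:
    _, header, rows = _read_rows(path)
    expected = ["trial_id", "left_aus", "right_aus"]
    if header[:3] != expected:
        raise ValueError(f"schedule header must start with {expected}, got {header}")
    schedule: list[TrialPair] = []
    seen_ids: set[int] = set()
    seen_pairs: set[frozenset] = set()
    for lineno, fields in rows:
        if len(fields) < 3:
            raise ValueError(f"row {lineno}: expected 3 columns, got {fields}")
        pair = TrialPair(
            trial_id=int(fields[0]),
            left=_parse_aus(fields[1], catalog, lineno, "left_aus"),
            right=_parse_aus(fields[2], catalog, lineno, "right_aus"),
        )
        _check_schedule_row(pair, lineno, seen_ids, seen_pairs, catalog, strict)
        schedule.append(pair)
    return schedule


def write_responses(
    responses: ResponseSet,
    path: str | Path,
    metadata: dict[str, str] | None = None,
) -> None:
    meta = dict(metadata or {})
    if responses.observer_id:
        meta.setdefault("observer_id", responses.observer_id)
    if responses.question_label:
        meta.setdefault("question_label", responses.question_label)
    _write_rows(
        path,
        ["trial_id", "left_aus", "right_aus", "choice"],
        (
            [str(p.trial_id), _format_aus(p.left), _format_aus(p.right), choice]
            for p, choice in responses.trials
        ),
        meta,
    )


def read_responses(
    path: str | Path, catalog: StimulusCatalog, strict: bool = False
) -> ResponseSet:
    """Parse a 2AFC response log; every row must carry a valid choice."""
    metadata, header, rows = _read_rows(path)
    expected = ["trial_id", "left_aus", "right_aus", "choice"]
    if header[:4] != expected:
        raise ValueError(f"responses header must start with {expected}, got {header}")
    trials: list[tuple[TrialPair, Choice]] = []
    seen_ids: set[int] = set()
    seen_pairs: set[frozenset] = set()
    for lineno, fields in rows:
        if len(fields) < 4 or fields[3].strip() == "":
            raise ValueError(f"row {lineno}: missing choice")
        choice = fields[3].strip()
        if choice not in ("left", "right"):
            raise ValueError(
                f"row {lineno}: choice must be 'left' or 'right', got {choice!r}"
            )
        pair = TrialPair(
            trial_id=int(fields[0]),
            left=_parse_aus(fields[1], catalog, lineno, "left_aus"),
            right=_parse_aus(fields[2], catalog, lineno, "right_aus"),
        )
        _check_schedule_row(pair, lineno, seen_ids, seen_pairs, catalog, strict)
        trials.append((pair, choice))  # type: ignore[arg-type]
    return ResponseSet(
        trials,
        question_label=metadata.get("question_label", ""),
        observer_id=metadata.get("observer_id", ""),
        catalog=catalog,
    )
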