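"""Evaluation of prototype sets: opinion scores and Schulze ranking.

Ranking ballots (complete strict orderings of candidate prototypes) are
aggregated Condorcet-style: count, for each ordered pair (i, j), how many
ballots place i above j; then compute Schulze strongest paths — the widest
(max-min) path strengths over the directed graph whose link i→j exists,
with strength counts(i, j), exactly when counts(i, j) > counts(j, i)
(winning-votes variant).  Candidate i beats j iff p(i, j) > p(j, i); the
Schulze guarantee is that this beats-relation is acyclic even when the raw
pairwise preferences are cyclic.  The final ranking places each candidate
at 1 + (number of candidates that beat it), so exact ties share a position.

Path-strength matrices may also be supplied directly (e.g. published
percentage tables) — they are treated as strengths as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RankBallot",
    "PreferenceCounts",
    "PathStrengthMatrix",
    "SchulzeRanking",
    "OpinionScores",
    "count_pairwise",
    "strongest_paths",
    "schulze_rank",
    "mean_opinion_score",
    "random_rank_baseline",
    "read_ballots",
    "read_ratings",
    "read_strengths",
    "write_strengths",
]

Candidate = Hashable


@dataclass(frozen=True)
class RankBallot:
    """One participant's complete strict ranking, best first."""

    participant_id: str
    task: str
    ranking: tuple[Candidate, ...]

    def __post_init__(self) -> None:
        if len(set(self.ranking)) != len(self.ranking):
            raise ValueError(
                f"ballot {self.participant_id}/{self.task}: repeated candidate "
                f"in ranking {self.ranking}"
            )


@dataclass(frozen=True)
class PreferenceCounts:
    """counts[i, j] = number of ballots ranking candidate i above j."""

    candidates: tuple[Candidate, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        n = len(self.candidates)
        if c.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {c.shape}")
        if np.any(np.diag(c) != 0):
            raise ValueError("counts diagonal must be zero")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    def get(self, i: Candidate, j: Candidate) -> float:
        return float(self.counts[self.candidates.index(i), self.candidates.index(j)])


@dataclass(frozen=True)
class PathStrengthMatrix:
    """Schulze strongest-path strengths p(i, j) (counts or percentages)."""

    candidates: tuple[Candidate, ...]
    strengths: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.strengths, dtype=float)
        n = len(self.candidates)
        if s.shape != (n, n):
            raise ValueError(f"strengths must be {n}x{n}, got {s.shape}")
        if np.any(np.diag(s) != 0):
            raise ValueError("strengths diagonal must be zero")
        if np.any(s < 0):
            raise ValueError("strengths must be non-negative")
        object.__setattr__(self, "strengths", s)

    def get(self, i: Candidate, j: Candidate) -> float:
        return float(self.strengths[self.candidates.index(i), self.candidates.index(j)])

    def beats(self) -> np.ndarray:
        """Boolean matrix: i beats j iff p(i, j) > p(j, i)."""
        return self.strengths > self.strengths.T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.strengths, index=self.candidates, columns=self.candidates
        )


@dataclass(frozen=True)
class SchulzeRanking:
    """Candidate → position (1 = best); exact ties share a position."""

    ranks: Mapping[Candidate, int]

    def ordered(self) -> list[tuple[Candidate, int]]:
        return sorted(self.ranks.items(), key=lambda kv: (kv[1], str(kv[0])))

    def __getitem__(self, candidate: Candidate) -> int:
        return self.ranks[candidate]


def count_pairwise(ballots: Sequence[RankBallot]) -> PreferenceCounts:
    """Tally, for every ordered pair, how many ballots prefer i to j.

    All ballots must be complete strict rankings of the same candidate set;
    an incomplete or duplicated ballot is rejected by participant id.
    """
    if not ballots:
        raise ValueError("no ballots")
    candidates = tuple(sorted(set(ballots[0].ranking), key=str))
    cset = set(candidates)
    n = len(candidates)
    pos_of = {c: k for k, c in enumerate(candidates)}
    counts = np.zeros((n, n))
    for b in ballots:
        if set(b.ranking) != cset or len(b.ranking) != n:
            raise ValueError(
                f"ballot {b.participant_id}/{b.task}: ranking {b.ranking} is not "
                f"a permutation of the candidate set {candidates}"
            )
        for a_idx, above in enumerate(b.ranking):
            for below in b.ranking[a_idx + 1 :]:
                counts[pos_of[above], pos_of[below]] += 1
    return PreferenceCounts(candidates=candidates, counts=counts)


def strongest_paths(counts: PreferenceCounts) -> PathStrengthMatrix:
    """Widest-path (max-min) strengths by Floyd-Warshall relaxation.

    A direct link i→j exists with strength counts(i, j) only when
    counts(i, j) > counts(j, i); the strength of a path is its weakest
    link, and p(i, j) is the strongest such path.
    """
    c = counts.counts
    n = c.shape[0]
    p = np.where(c > c.T, c, 0.0)
    np.fill_diagonal(p, 0.0)
    for k in range(n):
        # widen every i→j through k: min(p[i,k], p[k,j]) can beat p[i,j]
        via = np.minimum.outer(p[:, k], p[k, :])
        p = np.maximum(p, via)
        np.fill_diagonal(p, 0.0)
    return PathStrengthMatrix(candidates=counts.candidates, strengths=p)


def schulze_rank(p: PathStrengthMatrix) -> SchulzeRanking:
    """Derive the final ranking from path strengths by counting wins.

    rank(i) = 1 + number of candidates beating i.  A cyclic beats-relation
    cannot arise from genuine Schulze strengths, so it is rejected as bad
    input rather than silently ranked.
    """
    beats = p.beats()
    graph = nx.from_numpy_array(beats.astype(int), create_using=nx.DiGraph)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError(
            "the beats-relation derived from these strengths is cyclic; "
            "they are not valid strongest-path strengths"
        )
    n = len(p.candidates)
    losses = beats.sum(axis=0)  # column j: how many i beat j
    ranks = {c: 1 + int(losses[j]) for j, c in enumerate(p.candidates)}
    tied = np.where(~beats & ~beats.T & ~np.eye(n, dtype=bool))
    if len(tied[0]) > 0:
        pairs = sorted(
            {tuple(sorted((str(p.candidates[i]), str(p.candidates[j]))))
             for i, j in zip(*tied)}
        )
        warnings.warn(f"exact path-strength ties between {pairs}; positions shared", stacklevel=2)
    return SchulzeRanking(ranks=ranks)


# ---------------------------------------------------------------------------
# opinion scores and baseline


@dataclass(frozen=True)
class OpinionScores:
    """Integer ratings on a bounded scale, keyed by (rater, item)."""

    ratings: Mapping[tuple[str, str], int]
    scale: tuple[int, int] = (1, 5)

    def __post_init__(self) -> None:
        lo, hi = self.scale
        for (rater, item), r in self.ratings.items():
            if not (isinstance(r, (int, np.integer)) and lo <= r <= hi):
                raise ValueError(
                    f"rating {r!r} by {rater} for {item} is outside {lo}..{hi}"
                )

    def items(self) -> list[str]:
        return sorted({item for _, item in self.ratings})


def mean_opinion_score(scores: OpinionScores, item: str) -> float:
    """Arithmetic mean of all ratings given to ``item``."""
    values = [r for (_, it), r in scores.ratings.items() if it == item]
    if not values:
        raise ValueError(f"no ratings for item {item!r}")
    return float(np.mean(values))


def random_rank_baseline(task_sizes: Sequence[int], position: int) -> float:
    """Chance that a uniformly random ranking puts one's own prototype at
    ``position``, averaged over tasks of the given candidate-set sizes."""
    if not task_sizes:
        raise ValueError("task_sizes must be non-empty")
    if position < 1:
        raise ValueError("position must be ≥ 1")
    return float(
        np.mean([1.0 / size if position <= size else 0.0 for size in task_sizes])
    )


# ---------------------------------------------------------------------------
# serialization


def read_ballots(path: str | Path) -> list[RankBallot]:
    """CSV with columns participant_id, task, ranking ("a;b;c", best first)."""
    df = pd.read_csv(path, dtype=str)
    required = ["participant_id", "task", "ranking"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"ballot file must have columns {required}, got {list(df.columns)}")
    return [
        RankBallot(
            participant_id=row.participant_id,
            task=row.task,
            ranking=tuple(tok.strip() for tok in row.ranking.split(";")),
        )
        for row in df.itertuples(index=False)
    ]


def read_ratings(path: str | Path, scale: tuple[int, int] = (1, 5)) -> OpinionScores:
    """CSV with columns rater_id, item_id, rating."""
    df = pd.read_csv(path, comment="#")
    required = ["rater_id", "item_id", "rating"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"ratings file must have columns {required}, got {list(df.columns)}")
    ratings = {
        (str(row.rater_id), str(row.item_id)): int(row.rating)
        for row in df.itertuples(index=False)
    }
    return OpinionScores(ratings=ratings, scale=scale)


def _parse_strength(value: object) -> float:
    if isinstance(value, str):
        value = value.strip().rstrip("%").replace("-", "0") or "0"
    v = float(value)
    return v


def read_strengths(path: str | Path) -> PathStrengthMatrix:
    """Labeled square CSV (first row/column = candidate ids); "%" accepted."""
    # no comment handling: candidate labels such as "#1" legitimately start with '#'
    df = pd.read_csv(path, index_col=0, dtype=str)
    if list(df.index) != list(df.columns):
        raise ValueError(
            f"row labels {list(df.index)} and column labels {list(df.columns)} differ"
        )
    strengths = df.map(_parse_strength).to_numpy(dtype=float)
    np.fill_diagonal(strengths, 0.0)
    return PathStrengthMatrix(candidates=tuple(df.index), strengths=strengths)


def write_strengths(p: PathStrengthMatrix, path: str | Path) -> None:
    p.to_frame().to_csv(path)
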