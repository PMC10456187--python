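"""Rank prototypes with the Schulze method.

First aggregates a toy set of ballots (count pairwise preferences →
strongest paths → rank by wins), then re-derives the final rankings of the
bundled published path-strength matrices for all four emotion tasks.
"""

from aurevcorr import (
    RANKING_TASKS,
    RankBallot,
    count_pairwise,
    load_published_strengths,
    schulze_rank,
    strongest_paths,
)

ballots = [
    RankBallot("p1", "demo", ("a", "b", "c")),
    RankBallot("p2", "demo", ("a", "c", "b")),
    RankBallot("p3", "demo", ("b", "c", "a")),
]
paths = strongest_paths(count_pairwise(ballots))
print("toy ballots →", {c: r for c, r in schulze_rank(paths).ordered()})

for task in RANKING_TASKS:
    ranking = schulze_rank(load_published_strengths(task))
    order = ", ".join(f"{cand} (rank {pos})" for cand, pos in ranking.ordered())
    print(f"{task}: {order}")
# "#k" are the four observers' personalized prototypes; "Ek."/"Yu." are
# comparison prototypes from the expression literature.  Rank 1 = most
# preferred by the crowd of raters.
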