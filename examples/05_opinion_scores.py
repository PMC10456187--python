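"""Mean opinion scores and the random-ranking baseline.

Computes each emotion's mean 1-5 satisfaction score from the bundled
observer ratings, and the chance level that an observer's own prototype
lands at a given rank under uniformly random ranking.
"""

from aurevcorr import load_published_ratings, mean_opinion_score, random_rank_baseline

scores = load_published_ratings()
for item in scores.items():
    print(f"MOS({item}) = {mean_opinion_score(scores, item)}")

sizes = [6, 6, 6, 4]  # three 6-candidate tasks, one 4-candidate task
for position in (1, 5):
    chance = random_rank_baseline(sizes, position)
    print(f"random-ranking chance of position {position}: {chance:.4f} ({chance:.2%})")
# 18.75% at positions 1-4 and 12.5% at 5-6; observers placing their own
# prototype first >= 50% of the time therefore beat chance by far.
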