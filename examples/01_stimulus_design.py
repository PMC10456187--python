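"""Build the combinatorial 2AFC stimulus design.

Enumerates every stimulus that activates exactly 3 of the 16 catalog AUs,
then samples a duplicate-free trial schedule of 840 unordered pairs.
"""

from aurevcorr import StimulusCatalog, enumerate_stimuli, sample_schedule
from aurevcorr.design import n_unordered_pairs

catalog = StimulusCatalog()  # 16 AUs, 3 active per stimulus
stimuli = enumerate_stimuli(catalog)
pairs = n_unordered_pairs(len(stimuli))
schedule = sample_schedule(stimuli, m=840, seed=0)

print(f"AU catalog: {catalog.au_ids}")
print(f"stimuli with exactly {catalog.k_active} active AUs: {len(stimuli)}")
print(f"distinct unordered 2AFC pairs: {pairs}")
print(f"sampled schedule: {len(schedule)} trials, "
      f"{len({p.unordered_key for p in schedule})} unique pairs")
print(f"first trial: left={schedule[0].left} vs right={schedule[0].right}")
# 560 stimuli give ~1.56e5 possible trials; 840 are shown, each pair once.
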