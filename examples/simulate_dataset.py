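"""Generate a synthetic rated-episode dataset and write it to disk.

Each of the participants contributes 25 four-second episodes covering every
combination of five valence and five arousal levels; AU trajectories follow
the planted linear effect model with an onset/hold/offset envelope.
"""

from pathlib import Path

from auaffect import GeneratorSpec, generate_riken_like
from auaffect.synthdata import write_dataset

spec = GeneratorSpec(n_participants=4, seed=42)
data = generate_riken_like(spec)
out = Path("scratch_example_dataset")
write_dataset(data, out)

n_episodes = sum(len(eps) for eps in data.values())
n_frames = len(data["P00"][0].frames)
print(f"participants:        {len(data)}")
print(f"episodes:            {n_episodes} (25 per participant, 5x5 affect grid)")
print(f"frames per episode:  {n_frames} (4 s at {spec.frame_rate:.0f} fps)")
print(f"written under:       {out}/ (OpenFace-dialect AU CSVs + ratings.csv)")
# The ratings.csv index pairs each AU table with its episode-level valence
# and arousal ratings on the 1-5 scale; the AU CSVs can be re-read with
# auaffect.read_au_table or the training commands.
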