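"""Leave-one-participant-out evaluation of the GRU affect models.

Trains separate valence and arousal regressors on all but one participant,
predicts the held-out participant's episodes, and summarizes per-participant
Pearson correlations with a one-sample t-test on the Fisher-z values.
Uses a scaled-down training schedule so the script runs in about a minute.
"""

import numpy as np

from auaffect import GeneratorSpec, generate_riken_like, loocv, to_rated_episodes
from auaffect.estimator import ModelConfig, Target

spec = GeneratorSpec(n_participants=6, seed=7)
episodes = to_rated_episodes(generate_riken_like(spec))

configs = {
    t: ModelConfig.for_target(
        t, epochs=30, learning_rate=1e-2, dropout=0.0, recurrent_dropout=0.0
    )
    for t in Target
}
results, inference = loocv(episodes, configs=configs, seed=7)

print("per-participant correlations (actual vs estimated):")
for r in results:
    print(f"  {r.participant_id}: r_valence={r.r_valence:+.3f}  "
          f"r_arousal={r.r_arousal:+.3f}  (n={r.n_pairs})")
for t in Target:
    gi = inference[t]
    print(f"{t.value}: mean r = {gi.mean_r:.3f}, "
          f"t({gi.df}) = {gi.t_stat:.2f}, p = {gi.p_two_sided:.2g}, d = {gi.cohens_d:.2f}")
print("mean r near 1 and a small p mean the planted AU->affect mapping was "
      "recovered for unseen participants.")
print(f"mean r_valence = {np.mean([r.r_valence for r in results]):.3f}")
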