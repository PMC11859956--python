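"""Category/AU dimensional baseline: valence and arousal without training.

Valence is 'happy' minus the strongest negative category.  Arousal is the
mean of the five highest AU activations after subtracting each AU's rolling
60-second mean, so a sudden activation burst scores high while a static face
scores near zero.
"""

from auaffect import GeneratorSpec, baseline_arousal, baseline_valence, generate_category_series
from auaffect.baseline import CategoryFrame

frame = CategoryFrame(
    timestamp=0.0,
    intensities={
        "happy": 0.8, "sad": 0.2, "angry": 0.0, "scared": 0.3,
        "disgusted": 0.2, "surprised": 0.0, "neutral": 0.0,
    },
)
print(f"valence for happy=0.8 vs strongest negative 0.3: {baseline_valence(frame):.2f}")

# a quiet face with a burst of activation on several AUs at t = 80 s
spec = GeneratorSpec(n_participants=1, seed=5)
steps = [(80.0, k, 0.6) for k in ("AU04", "AU05", "AU07", "AU17", "AU23")]
_, activations = generate_category_series(spec, 120.0, constant=0.1, steps=steps)
for t in (10.0, 79.0, 80.0, 110.0):
    print(f"arousal at t={t:5.1f} s: {baseline_arousal(activations, t):+.3f}")
print("arousal jumps when activations rise above their trailing 60-s mean, "
      "then decays as the mean catches up.")
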