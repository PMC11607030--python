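"""Generate a small labeled synthetic diathermy-like dataset.

Five classes — liver, muscle, fat, fascia (electrosurgical bursts at
class-specific center frequencies) and idle (quiet pink-noise pauses) —
are written as WAV files with a CSV manifest.
"""

from pathlib import Path

from laparosound import make_dataset

out = Path("scratch/example_dataset")
manifest = make_dataset(out, n_per_class=4, seed=0)
print(manifest.to_string(index=False))
print(f"\n{len(manifest)} recordings in {out}; durations are the per-class "
      "draw from the configured range (0.76-5.17 s for tissue, up to 20 s idle).")
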