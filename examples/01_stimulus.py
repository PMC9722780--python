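"""Build one trial's stimulus and inspect the target ramp and noise.

The display is two 16-bar fields of dynamic Gaussian noise (SD 0.1,
30 Hz, 4.5 s).  The target is a contrast ramp 10**min(0.05 t - 3, 0)
added to the two central bars of one field from a random onset frame.
"""

import numpy as np

from rlci import StimulusParams, make_trial_movie, target_contrast

params = StimulusParams()
movie = make_trial_movie(params, 42, cue_mode="schedule")

print(f"frames: {params.n_frames}  ({params.duration_ms:.0f} ms at "
      f"{params.frame_rate_hz:.0f} Hz)")
print(f"target side: {'left' if movie.target_side == 0 else 'right'}, "
      f"onset frame {movie.target_onset_frame}")
if movie.cue:
    print(f"cue: side {'left' if movie.cue.side == 0 else 'right'}, "
          f"onset frame {movie.cue.onset_frame} "
          f"({movie.cue.onset_frame * params.frame_duration_ms:.0f} ms)")
else:
    print("cue: none this trial (6% of trials)")

# the ramp is invisible at onset (0.001) and saturates at frame 60 (2 s)
for t in (0, 15, 30, 45, 60):
    print(f"  target contrast at {t:3d} frames after onset: "
          f"{target_contrast(t, params):.4f}")

print(f"noise sample SD (this movie): {movie.noise.std():.4f}  (nominal 0.1)")
print(f"displayed contrast range: [{movie.contrast.min():.3f}, "
      f"{movie.contrast.max():.3f}]  (clipped to [-1, 1])")
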