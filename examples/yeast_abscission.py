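"""Membrane-peak abscission scoring along the mother-daughter axis.

A single membrane ridge at the bud neck means the cell has yet to abscise;
two distinct intensity peaks mark membrane separation.  Ingression is
detected from the narrowing of the ridge, and time to abscission is
counted from ingression to the first sustained double-peak frame.
"""

import abscission as ab

params = ab.SceneParams.yeast(seed=5, read_noise_sd=15.0, poisson_noise=True)
movie, truth = ab.generate_division_movie(params)

h, w = movie.frame_shape
cy = (h - 1) / 2
axis = ((cy, 2.0), (cy, w - 3.0))  # mother-daughter axis through the neck

profiles = [
    ab.extract_neck_profile(movie.frame(f, "membrane"), axis, movie.pixel_size_um, frame_index=f)
    for f in range(movie.n_frames)
]
calls = [ab.classify_profile(p) for p in profiles]
print("per-frame call:", "".join(c.classification.value[0].upper() for c in calls))

ingression = ab.detect_ingression(profiles)
t_abscission = ab.time_to_abscission(calls, movie.time_min(ingression), movie.frame_interval_min)
print(f"ingression at frame {ingression} (truth {truth.event_frames['t_ingression_min']})")
print(f"time from ingression to abscission: {t_abscission} min "
      f"(truth {params.t_abscission_min - params.t_ingression_min} min)")
# S = single peak (not abscised), D = double peak (membranes separated),
# A = ambiguous.  The S->D transition is the abscission event.
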