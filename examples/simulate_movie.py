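"""Generate a synthetic division movie with ground truth and write it to disk.

The movie has four role-tagged channels (histone, actin, membrane, tubulin)
rendering a cell that enters anaphase, forms a chromatin bridge, ingresses
and abscises its membrane, and accumulates then clears midzone actin
clusters — with every event time known exactly.
"""

import abscission as ab

params = ab.SceneParams(seed=7, read_noise_sd=10.0, poisson_noise=True)
movie, truth = ab.generate_division_movie(params)

ab.write_movie("scratch_movie.ome.tif", movie)

print(f"movie: {movie.n_frames} frames of {movie.frame_shape}, "
      f"{movie.pixel_size_um} um/px, {movie.frame_interval_min} min/frame")
print("ground-truth event frames (frame index at/after the event):")
for event, frame in truth.event_frames.items():
    t = truth.event_times[event]
    print(f"  {event:24s} t = {t!s:>6} min  frame = {frame}")
# Frames at or after each listed frame index show the corresponding scene
# change (nucleus split, ridge narrowing/splitting, cluster appearance...).
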