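# Methods

This note documents the models, conventions and parameter choices behind
the package, what the synthetic-data generator does and does not emulate,
and the numerical decisions a user extending the package should know.

## Conventions

All geometry uses 0-based, row-major `(y, x)` pixel indices with
pixel-centre coordinates; physical units come from multiplying by the
calibration (`pixel_size_um`, `frame_interval_min`).  Connected
components use 8-connectivity everywhere so 1-px diagonal chromatin
bridges stay connected.  A pixel belongs to a rasterized region (midzone
rectangle, measurement ellipse) if its centre lies inside, boundary
inclusive.  Censored events — anything not observed before the end of the
recording — are `None`/`NaN`, never imputed.

## Chromatin segmentation and bridge status

Nuclei are connected components of a thresholded histone channel, at
least `min_area_px` (default 20) pixels, with border-touching components
flagged and excluded from geometry.  Centroids are unweighted mask
centroids: robust to intensity gradients, at the cost of ignoring
sub-pixel brightness structure (an intensity-weighted variant would be a
one-line change; mask centroids were chosen as the more reproducible
default).  Only frames with exactly two interior nuclei feed the midzone
analysis.

Bridge status distinguishes a corridor between the two nuclei:
`CONNECTED` when one positive component touches both nucleus masks,
`FRAGMENTED` when a component of at least `min_object_px` (default 4)
pixels lies in the corridor without connecting them, `RESOLVED`
otherwise.  Fragmented bridges count as unresolved — stretched DNA can
give weak or discontinuous nucleosome signal, so discontinuity is not
evidence of resolution.  The resolution time is the first frame at/after
anaphase onset that is RESOLVED and never relapses.

Anaphase onset is the first frame where the major axis of the whole
chromatin mass (union of positive pixels, so the trace keeps growing
after the mass splits in two) reaches `elongation_factor` (default 1.5)
times its pre-division baseline (median of the first 5 frames), sustained
for 2 frames.  "Rapid elongation" is qualitative in origin; all three
knobs are config-exposed.

RPA-like foci are local maxima inside nucleus masks exceeding the
nucleoplasmic background (median intensity in the masks) by `k` (default
3) times the median absolute deviation, merged within
`min_separation_px`.  A small relative tolerance (1e-4 of the background)
guards the degenerate flat-nucleoplasm case where the MAD is zero and any
infinitesimal gradient would otherwise register.  Focus counts are
monotonically non-increasing in `k` by construction.

## Actin-cluster index

Within the midzone rectangle (height = half the internuclear centroid
distance along the internuclear axis, width = twice the mean nuclear
major axis, centred on the centroid midpoint) the actin-positive pixel
set *P* is everything above threshold; sub-threshold pixels are zeroed
and excluded.  The top set is the `ceil(0.05 |P|)` brightest pixels, ties
broken by intensity then row-major scan order so results are exactly
reproducible.  Enrichment `E = (Int_top − Int_all)/Int_all`; the centre
of mass of the top set is intensity-weighted (unweighted behind a flag);
distances `d_all` and `d_top` are unweighted means of pixel-centre
Euclidean distances; clustering `C = d_all/d_top`; index `E·C`.  Frames
with `|P| < min_positive_px` (default 20) or `d_top ≤ 1e-6` px are
invalid rather than infinite.

Clearance is an automated surrogate for what is traditionally scored by
eye: the first frame at/after anaphase whose index stays below
`tau_rel` (default 0.5) times the median pre-anaphase index for
`k_frames` (default 2) consecutive retained frames.  When no usable
pre-anaphase baseline exists — the common case when pre-anaphase frames
are dropped for not having two nuclei, or their index is ~0 — the
absolute threshold `tau_abs` (default 2.0) is used and a notice logged.
The default was chosen from the structure of the index: a spatially
unstructured field has clustering ≈ 1 and Gaussian-tail enrichment below
~1.5, bounding its index below ~2, while genuine cluster scenes multiply
enrichment ≥ 2 by clustering ≥ 2.  Frames invalidated by a *low positive
count* also count as cleared — no actin-positive signal left in the
midzone is clearance — whereas frames invalidated by degenerate `d_top`
do not.

## Membrane profiles and abscission

Profiles are sampled at ~1 px spacing along a user-annotated
mother–daughter axis (ground truth supplies it for synthetic movies;
automatic neck finding is out of scope), averaged over a perpendicular
band of ±2 px, max-projected over Z first when a stack is supplied
(mean behind a flag), and Gaussian-smoothed along their length (σ = 1 px)
to suppress single-pixel noise peaks.  Peaks with prominence at least
`prominence_rel` (default 0.25) times the profile maximum are accepted;
one peak is SINGLE, two or more spanning at least `min_separation_um`
(default 0.4 µm) are DOUBLE, anything else AMBIGUOUS.  Relative
prominence makes the call invariant under multiplicative intensity
scaling.  Abscission is the first frame at/after ingression with DOUBLE
sustained 2 frames; ingression is the first sustained drop of the main
peak's FWHM below 0.6× its baseline (median of the first 5 frames).

## Midbody quantification

Best focus is the slice maximizing tubulin intensity variance inside the
seed ROI (max integrated intensity behind a flag); ties resolve to the
lowest index.  Five slices centred there are max-projected (edge slices
use the available subset).  The "tight ellipse" is the second-moment
(moments-matched) ellipse of the largest Otsu component — deterministic
and standard, with no iterative fitting.  Total intensity is stored
exactly as area × mean.  A constant-background estimator (median of the
projection outside the seed ROI) is available; note that maximum
projection raises the noise floor by the order statistic of the slice
count, and this floor is *larger* outside a structure than on top of it,
so flat-field subtraction overcorrects at low SNR.  The recovery studies
therefore run at SNR ≈ 20 without subtraction, where the residual bias is
within the stated 5% envelope; at SNR near 10 the max-projection bias
alone approaches that envelope.

## Timing statistics and qPCR

Completion fractions keep censored cells in the denominator — the curves
are raw "fraction of cells" plots, not Kaplan–Meier estimates, matching
how such readouts are reported.  Mann–Whitney uses the exact null
distribution when `n_x + n_y ≤ 12` and the pooled sample is tie-free,
else the normal approximation with mid-rank tie correction and continuity
correction (both via scipy, behind the package's surface).  Fisher's
exact test sums hypergeometric point probabilities ≤ the observed one
with a 1e-7 relative tie tolerance.  Box summaries use linear
interpolation between order statistics and Tukey 1.5×IQR whiskers.
Relative expression is 2^−ΔCt from replicate-mean Cts (per-replicate
averaging behind a flag), normalized to the single control sample;
adding any constant to all Cts of a run cancels.  Primer efficiency is
10^(−1/slope) − 1 from the Ct-vs-log10(dilution) least-squares slope,
passing above 90%.

## The synthetic-data generator

The generator emulates the *observable geometry* of a dividing cell, not
its biology: an isotropic Gaussian nucleus that jumps apart by
`anaphase_jump_um` (default 1.5 µm, emulating fast anaphase A — and
making "rapid elongation" instantaneous at the anaphase frame) and then
separates at `separation_speed_um_per_min`; a Gaussian-profile chromatin
bridge (contiguous, or two disjoint fragments) until `t_bridge_resolve`;
an actin channel with a *flat* cytoplasmic disk plus a furrow ridge from
anaphase and `n_clusters` Gaussian clusters in the midzone from
`t_cluster_start` (default 5 min after anaphase, when checkpoint actin
patches appear at the intercellular bridge) to `t_clear`; a membrane neck
ridge that narrows at ingression and splits into two ridges
`post_abscission_gap_um` apart at abscission; and a filled tubulin
ellipse between midbody formation and severing.  The cytoplasm is a flat
disk deliberately: a smooth (Gaussian) cytoplasm would itself register as
a bright compact cluster, whereas a flat field has enrichment exactly 0
at zero noise, which is what makes the noise-free closed loops exact.

Noise follows the standard camera model — Poisson on the signal if
enabled, then additive Gaussian read noise, then a constant offset,
clipped at zero — with one seeded generator per movie and deterministic
per-channel sub-streams, so identical `(params, seed)` give bit-identical
movies.  Default event times (anaphase 30 min, ingression 40, abscission
60, clusters 35→120, midbody 50→180, bridge resolution 80, at 5-min
frames; the yeast preset images every 2 min) put anaphase past the
detectors' baseline windows and inside the movie horizon.

What the generator does **not** emulate — and what passing closed loops
therefore do not demonstrate about real data: cell crowding and
neighbouring cells, photobleaching and focus drift, 3D point-spread
functions, textured chromatin, moving/dynamic actin clusters, and
midbody arms that deviate from an ellipse.  Real movies additionally need
the manual annotations (cell rectangle, neck axis, seed ROI) that ground
truth supplies automatically here.

## Problem sizes

The default verification studies use 50 seeded movies per recovery
experiment (96×96 px × 48 frames, or 64×64 × 40 for the bud-neck regime),
100 midbody renders at 64×64 × 9 slices, and cohorts of 100 cells per
arm — sizes at which every study runs in seconds while keeping the
recovery rates stable across seeds.

## Known limitations

Thresholds are global per frame; no illumination-gradient correction is
provided.  The clearance rule and the ingression/elongation detectors are
automated stand-ins for judgements originally made by eye — their
defaults are calibrated on the generator's scenes and should be reviewed
against a handful of manually scored real cells before use in anger.
Tracking is nonexistent: the pipeline assumes one dividing cell per
(cropped) field.  Fisher's and Mann–Whitney tests are the only built-in
hypothesis tests; multiple-comparison procedures belong to a general
statistics environment.
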