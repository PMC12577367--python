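"""Actin-cluster index: midzone ROI, brightness enrichment, clustering, clearance.

The index quantifies how strongly bright actin signal accumulates in a
tight cluster near the midzone between the two segregating nuclei:

* *brightness enrichment* ``E = (Int_top5% - Int_all) / Int_all`` over the
  actin-positive pixels P of the midzone ROI, where the top set is the
  ``ceil(0.05 |P|)`` brightest pixels;
* *clustering* ``C = dCOM_all / dCOM_top5%``, the mean distance of all
  positive pixels to the top-set centre of mass divided by the mean
  distance of the top-set pixels to it;
* the actin-cluster index is the product ``E * C``.

A uniform field has E = 0 and hence index 0; a bright, compact cluster
drives both factors up.  The midzone ROI is the rectangle between the two
nucleus centroids with height half the internuclear distance (along the
internuclear axis) and width twice the mean nuclear major axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError
from .movie import Movie
from .segmentation import NucleusRegion, NucleusSet, select_two_nuclei_frames, threshold_positive

logger = logging.getLogger(__name__)

__all__ = [
    "MidzoneROI",
    "build_midzone_roi",
    "ActinFrameScore",
    "score_actin_frame",
    "ActinTrace",
    "actin_trace",
    "score_clearance",
]


@dataclass
class MidzoneROI:
    """Oriented rectangle between two nucleus centroids.

    ``height_px`` extends along the internuclear axis (unit vector from
    nucleus A to nucleus B), ``width_px`` perpendicular to it; the
    rectangle is centred on the centroid midpoint.  A pixel belongs to the
    rasterized ROI if its centre lies inside (boundary inclusive).
    """

    center: tuple[float, float]  # (y, x)
    axis_unit_vector: tuple[float, float]  # (dy, dx), A -> B
    height_px: float
    width_px: float

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise DataError("midzone ROI must have positive height and width")

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        dy = yy - self.center[0]
        dx = xx - self.center[1]
        uy, ux = self.axis_unit_vector
        along = dy * uy + dx * ux
        perp = -dy * ux + dx * uy
        eps = 1e-9
        return (np.abs(along) <= self.height_px / 2.0 + eps) & (
            np.abs(perp) <= self.width_px / 2.0 + eps
        )


def build_midzone_roi(region_a: NucleusRegion, region_b: NucleusRegion) -> MidzoneROI:
    """Rectangle between two nuclei, covering furrow and postanaphase patches."""
    ay, ax = region_a.centroid
    by, bx = region_b.centroid
    dy, dx = by - ay, bx - ax
    dist = math.hypot(dy, dx)
    if dist <= 0:
        raise DataError("nucleus centroids coincide; midzone ROI is undefined")
    return MidzoneROI(
        center=((ay + by) / 2.0, (ax + bx) / 2.0),
        axis_unit_vector=(dy / dist, dx / dist),
        height_px=0.5 * dist,
        width_px=2.0 * 0.5 * (region_a.major_axis_px + region_b.major_axis_px),
    )


@dataclass
class ActinFrameScore:
    """Per-frame components of the actin-cluster index."""

    frame_index: int
    n_positive: int
    int_all: float
    int_top: float
    enrichment: float
    com: tuple[float, float]
    d_all: float
    d_top: float
    clustering: float
    index: float
    valid: bool
    low_signal: bool  # invalid specifically because |P| < min_positive_px

    def as_dict(self) -> dict:
        return {
            "frame_index": self.frame_index,
            "n_positive": self.n_positive,
            "int_all": self.int_all,
            "int_top": self.int_top,
            "enrichment": self.enrichment,
            "com_y": self.com[0],
            "com_x": self.com[1],
            "d_all": self.d_all,
            "d_top": self.d_top,
            "clustering": self.clustering,
            "index": self.index,
            "valid": self.valid,
            "low_signal": self.low_signal,
        }


def score_actin_frame(
    actin: np.ndarray,
    roi: MidzoneROI,
    threshold="otsu",
    positive_mask: np.ndarray | None = None,
    top_fraction: float = 0.05,
    min_positive_px: int = 20,
    epsilon: float = 1e-6,
    weighted_com: bool = True,
    frame_index: int = 0,
) -> ActinFrameScore:
    """Score one frame: enrichment, clustering and their product.

    ``positive_mask`` (precomputed) takes precedence over ``threshold``;
    sub-threshold pixels are excluded from P entirely.  The top set is the
    ``ceil(top_fraction * |P|)`` brightest positive pixels with ties broken
    by intensity then row-major scan order; its centre of mass is
    intensity-weighted by default (unweighted behind the flag).  Distances
    are unweighted means of pixel-centre Euclidean distances.  Frames with
    ``|P| < min_positive_px`` or degenerate top-set spread
    (``d_top <= epsilon``) are flagged invalid and the index is reported
    missing (NaN).
    """
    actin = np.asarray(actin, dtype=float)
    roi_mask = roi.rasterize(actin.shape)
    if not roi_mask.any():
        raise DataError("midzone ROI rasterizes to zero pixels inside the image")
    if positive_mask is None:
        positive_mask = threshold_positive(actin, threshold)
    p_mask = roi_mask & np.asarray(positive_mask, dtype=bool)
    ys, xs = np.nonzero(p_mask)
    vals = actin[ys, xs]
    n = vals.size

    nan = float("nan")
    if n == 0:
        return ActinFrameScore(
            frame_index, 0, nan, nan, nan, (nan, nan), nan, nan, nan, nan, False, True
        )

    m = max(1, math.ceil(top_fraction * n))
    flat = ys * actin.shape[1] + xs
    order = np.lexsort((flat, -vals))  # intensity desc, then row-major asc
    top = order[:m]
    int_all = float(vals.mean())
    int_top = float(vals[top].mean())
    enrichment = (int_top - int_all) / int_all if int_all > 0 else nan

    top_y, top_x, top_v = ys[top].astype(float), xs[top].astype(float), vals[top]
    if weighted_com and top_v.sum() > 0:
        com_y = float(np.average(top_y, weights=top_v))
        com_x = float(np.average(top_x, weights=top_v))
    else:
        com_y, com_x = float(top_y.mean()), float(top_x.mean())
    d_all = float(np.hypot(ys - com_y, xs - com_x).mean())
    d_top = float(np.hypot(top_y - com_y, top_x - com_x).mean())

    low_signal = n < min_positive_px
    degenerate = d_top <= epsilon
    valid = not (low_signal or degenerate) and np.isfinite(enrichment)
    if degenerate or not np.isfinite(enrichment):
        clustering = nan
        index = nan
    else:
        clustering = d_all / d_top
        index = enrichment * clustering
    if not valid:
        index = nan
    return ActinFrameScore(
        frame_index=frame_index,
        n_positive=int(n),
        int_all=int_all,
        int_top=int_top,
        enrichment=float(enrichment),
        com=(com_y, com_x),
        d_all=d_all,
        d_top=d_top,
        clustering=float(clustering) if clustering == clustering else nan,
        index=float(index) if index == index else nan,
        valid=bool(valid),
        low_signal=bool(low_signal),
    )


@dataclass
class ActinTrace:
    """Time-ordered frame scores for one cell plus its clearance time."""

    cell_id: str
    scores: list[ActinFrameScore]
    t_anaphase_min: float
    frame_interval_min: float
    clearance_time_min: float | None = None

    def frame_times(self) -> np.ndarray:
        return np.array([s.frame_index * self.frame_interval_min for s in self.scores])

    def index_trace(self) -> np.ndarray:
        return np.array([s.index for s in self.scores])


def actin_trace(
    movie: Movie,
    nuclei_sets: list[NucleusSet],
    t_anaphase_min: float,
    cell_id: str = "cell",
    threshold="otsu",
    **score_kwargs,
) -> ActinTrace:
    """Score every retained (exactly-two-nuclei) frame, rebuilding the ROI per frame."""
    retained = select_two_nuclei_frames(nuclei_sets)
    if not retained:
        raise DataError("no frames with exactly two interior nuclei")
    actin = movie.channel("actin")
    scores = []
    for ns in retained:
        a, b = ns.interior_regions()
        roi = build_midzone_roi(a, b)
        scores.append(
            score_actin_frame(
                actin[ns.frame_index],
                roi,
                threshold=threshold,
                frame_index=ns.frame_index,
                **score_kwargs,
            )
        )
    return ActinTrace(
        cell_id=cell_id,
        scores=scores,
        t_anaphase_min=t_anaphase_min,
        frame_interval_min=movie.frame_interval_min,
    )


def score_clearance(
    trace: ActinTrace,
    tau_rel: float = 0.5,
    k_frames: int = 2,
    tau_abs: float | None = 2.0,
) -> float | None:
    """Automated surrogate for visual actin-clearance scoring.

    Clearance is the first frame at/after anaphase onset whose index stays
    below ``tau_rel`` times the pre-anaphase baseline (median index over
    valid pre-anaphase frames) for ``k_frames`` consecutive retained
    frames; the returned value is minutes from anaphase onset, or ``None``
    if the clusters never clear.  When no usable pre-anaphase baseline
    exists the absolute threshold ``tau_abs`` is used instead (a notice is
    logged).  Frames invalidated by a low positive-pixel count also count
    as cleared: no actin-positive signal left in the midzone *is*
    clearance.
    """
    pre = [
        s.index
        for s in trace.scores
        if s.valid and s.frame_index * trace.frame_interval_min < trace.t_anaphase_min
    ]
    baseline = float(np.median(pre)) if pre else float("nan")
    if pre and np.isfinite(baseline) and baseline > 0:
        threshold = tau_rel * baseline
    else:
        if tau_abs is None:
            raise DataError("no pre-anaphase baseline and no tau_abs fallback configured")
        logger.info(
            "score_clearance: no usable pre-anaphase baseline for %s; "
            "falling back to absolute threshold %.3g",
            trace.cell_id,
            tau_abs,
        )
        threshold = tau_abs

    post = [s for s in trace.scores if s.frame_index * trace.frame_interval_min >= trace.t_anaphase_min]
    run = 0
    for i, s in enumerate(post):
        cleared = (s.valid and s.index < threshold) or s.low_signal
        run = run + 1 if cleared else 0
        if run >= k_frames:
            first = post[i - k_frames + 1]
            return first.frame_index * trace.frame_interval_min - trace.t_anaphase_min
    return None
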