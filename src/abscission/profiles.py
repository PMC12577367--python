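"""Membrane intensity profiles at the neck and the single/double-peak classifier.

Abscission in the budding-yeast assay is scored from the distribution of
membrane-marker intensity along the mother-daughter axis at the bud neck:
a cell that has yet to abscise shows a single intensity peak; membrane
separation produces two distinct peaks.  Profiles are sampled along a
user-annotated axis segment, averaged over a perpendicular band, and (for
Z-stacks) aggregated by maximum projection before sampling.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks, peak_widths

from .exceptions import DataError

__all__ = [
    "NeckProfile",
    "extract_neck_profile",
    "PeakClass",
    "PeakCall",
    "classify_profile",
    "time_to_abscission",
    "detect_ingression",
]


@dataclass
class NeckProfile:
    positions_um: np.ndarray
    intensities: np.ndarray
    frame_index: int

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions_um.shape != self.intensities.shape:
            raise DataError("positions and intensities must have the same length")
        if self.positions_um.size >= 2 and not np.all(np.diff(self.positions_um) > 0):
            raise DataError("positions must be strictly increasing")


def extract_neck_profile(
    image: np.ndarray,
    axis_endpoints: tuple[tuple[float, float], tuple[float, float]],
    pixel_size_um: float,
    half_width_px: int = 2,
    frame_index: int = 0,
    z_aggregate: str = "max",
    spacing_px: float = 1.0,
    smooth_sigma_px: float = 1.0,
) -> NeckProfile:
    """Intensity profile along the mother-daughter axis through the neck.

    ``image`` is a single 2D frame or a ``(Z, H, W)`` stack (aggregated over
    Z by maximum projection by default, mean behind the flag); endpoints
    are ``(y, x)`` pixel coordinates and must lie inside the image.  Each
    sample averages a perpendicular band of ``+/- half_width_px``; the
    profile is then Gaussian-smoothed along its length
    (``smooth_sigma_px``, 0 disables) to suppress single-pixel noise peaks.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        if z_aggregate == "max":
            image = image.max(axis=0)
        elif z_aggregate == "mean":
            image = image.mean(axis=0)
        else:
            raise DataError(f"unknown z_aggregate {z_aggregate!r}")
    if image.ndim != 2:
        raise DataError("profile extraction expects a 2D frame or (Z, H, W) stack")
    h, w = image.shape
    (y0, x0), (y1, x1) = axis_endpoints
    for y, x in ((y0, x0), (y1, x1)):
        if not (0 <= y <= h - 1 and 0 <= x <= w - 1):
            raise DataError(f"axis endpoint ({y}, {x}) outside image of shape {image.shape}")
    length = math.hypot(y1 - y0, x1 - x0)
    if length <= 0:
        raise DataError("axis endpoints coincide: zero-length axis")
    n_samples = int(math.ceil(length / spacing_px)) + 1
    s = np.linspace(0.0, length, n_samples)
    uy, ux = (y1 - y0) / length, (x1 - x0) / length
    ny, nx = -ux, uy
    profile = np.zeros(n_samples)
    offsets = range(-half_width_px, half_width_px + 1)
    for o in offsets:
        ys = y0 + s * uy + o * ny
        xs = x0 + s * ux + o * nx
        profile += map_coordinates(image, [ys, xs], order=1, mode="nearest")
    profile /= len(list(offsets))
    if smooth_sigma_px > 0:
        from scipy.ndimage import gaussian_filter1d

        profile = gaussian_filter1d(profile, smooth_sigma_px / spacing_px, mode="nearest")
    return NeckProfile(
        positions_um=s * pixel_size_um, intensities=profile, frame_index=frame_index
    )


class PeakClass(enum.Enum):
    SINGLE = "single"
    DOUBLE = "double"
    AMBIGUOUS = "ambiguous"


@dataclass
class PeakCall:
    frame_index: int
    n_peaks: int
    classification: PeakClass
    peak_positions_um: np.ndarray
    peak_separation_um: float | None


def classify_profile(
    profile: NeckProfile,
    prominence_rel: float = 0.25,
    min_separation_um: float = 0.4,
) -> PeakCall:
    """Single vs double membrane peak at the neck.

    Local maxima with prominence at least ``prominence_rel`` times the
    profile maximum are accepted peaks.  One accepted peak is SINGLE;
    two or more whose extreme positions are at least ``min_separation_um``
    apart are DOUBLE (membrane separation); anything else, including an
    all-zero profile, is AMBIGUOUS.  Relative prominence makes the call
    invariant under multiplicative intensity scaling.
    """
    y = profile.intensities
    if y.size < 5:
        raise DataError("profile needs at least 5 samples")
    peak_max = float(y.max())
    if peak_max <= 0:
        return PeakCall(profile.frame_index, 0, PeakClass.AMBIGUOUS, np.array([]), None)
    idx, _ = find_peaks(y, prominence=prominence_rel * peak_max)
    positions = profile.positions_um[idx]
    n = len(idx)
    if n >= 2:
        separation = float(positions.max() - positions.min())
        if separation >= min_separation_um:
            return PeakCall(profile.frame_index, n, PeakClass.DOUBLE, positions, separation)
        return PeakCall(profile.frame_index, n, PeakClass.AMBIGUOUS, positions, None)
    if n == 1:
        return PeakCall(profile.frame_index, 1, PeakClass.SINGLE, positions, None)
    return PeakCall(profile.frame_index, 0, PeakClass.AMBIGUOUS, positions, None)


def time_to_abscission(
    calls: list[PeakCall],
    t_ingression_min: float,
    frame_interval_min: float,
    persistence_frames: int = 2,
) -> float | None:
    """Minutes from membrane ingression to sustained membrane separation.

    Abscission is the first frame at/after ingression whose DOUBLE call is
    sustained for ``persistence_frames`` consecutive frames; ``None`` if
    the membrane never resolves within the recording.
    """
    if not calls:
        raise DataError("empty call list")
    calls = sorted(calls, key=lambda c: c.frame_index)
    eligible = [c for c in calls if c.frame_index * frame_interval_min >= t_ingression_min - 1e-9]
    run = 0
    for i, c in enumerate(eligible):
        run = run + 1 if c.classification is PeakClass.DOUBLE else 0
        if run >= persistence_frames:
            first = eligible[i - persistence_frames + 1]
            return first.frame_index * frame_interval_min - t_ingression_min
    return None


def _main_peak_fwhm(profile: NeckProfile) -> float:
    y = profile.intensities
    if y.max() <= 0:
        return float("nan")
    i_pk = int(np.argmax(y))
    # peak_widths needs a local maximum index; argmax at the border is a plateau edge
    i_pk = min(max(i_pk, 1), y.size - 2)
    try:
        widths, *_ = peak_widths(y, [i_pk], rel_height=0.5)
    except ValueError:
        return float("nan")
    if profile.positions_um.size >= 2:
        spacing = float(profile.positions_um[1] - profile.positions_um[0])
    else:
        spacing = 1.0
    return float(widths[0] * spacing)


def detect_ingression(
    profiles: list[NeckProfile],
    ingression_fraction: float = 0.6,
    baseline_frames: int = 5,
    persistence_frames: int = 2,
) -> int | None:
    """Frame at which the neck ridge narrows (membrane ingression).

    The full width at half maximum of the main profile peak is tracked
    over time; ingression is the first frame where it falls below
    ``ingression_fraction`` times its baseline (median over the first
    ``baseline_frames`` frames), sustained for ``persistence_frames``.
    Returns the frame index of the first qualifying profile, or ``None``
    if the ridge never narrows.
    """
    if len(profiles) < 3:
        raise DataError("need at least 3 profiles")
    profiles = sorted(profiles, key=lambda p: p.frame_index)
    fwhm = np.array([_main_peak_fwhm(p) for p in profiles])
    baseline = float(np.nanmedian(fwhm[:baseline_frames]))
    if not np.isfinite(baseline) or baseline <= 0:
        return None
    below = fwhm < ingression_fraction * baseline
    run = 0
    for i, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run >= persistence_frames:
            return profiles[i - persistence_frames + 1].frame_index
    return None
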