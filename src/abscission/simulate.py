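"""Seeded synthetic cytokinesis movies and ancillary tables with ground truth.

The generator emulates the imaging regimes this package quantifies:

* a chromatin (histone) channel in which one nucleus elongates and splits
  into two at anaphase onset, optionally leaving a chromatin bridge
  (contiguous or fragmented) between the daughters until it resolves;
* an actin channel with a flat cytoplasmic disk, a midzone furrow band
  from anaphase onset, and long-lived bright clusters inside the midzone
  from ``t_cluster_start`` until ``t_clear``;
* a membrane channel whose bud-neck ridge narrows at ingression and splits
  into two parallel ridges separated by ``post_abscission_gap_um`` at
  abscission;
* a tubulin channel with a midbody-like ellipse between midbody formation
  and severing.

Noise follows the standard camera model: Poisson on the signal (optional),
then additive Gaussian read noise, then a constant background offset,
clipped at zero.  All randomness flows through one seeded generator per
movie with per-channel sub-streams, so identical ``(params, seed)`` give
bit-identical movies.

Event times are minutes from the start of the recording; an event set to
``None`` never happens inside the movie (censored).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, ValidationError
from .movie import Movie

EVENT_FIELDS = (
    "t_anaphase_min",
    "t_ingression_min",
    "t_abscission_min",
    "t_midbody_form_min",
    "t_midbody_sever_min",
    "t_bridge_resolve_min",
    "t_cluster_start_min",
    "t_clear_min",
)

# fraction of the channel peak above which a noise-free pixel counts as
# "true signal" when building ground-truth masks
_MASK_LEVEL = 0.05


@dataclass
class SceneParams:
    """Parameters of one synthetic division movie.

    Defaults emulate a HeLa-scale recording (0.25 µm pixels, 5-min frames)
    with anaphase at 10 min, membrane ingression at 20 min, abscission at
    40 min and actin clusters persisting until 100 min.  Use
    :meth:`yeast` for a bud-neck membrane regime sampled every 2 min.
    """

    image_shape_px: tuple[int, int] = (96, 96)
    pixel_size_um: float = 0.25
    frame_interval_min: float = 5.0
    n_frames: int = 48

    # event times (minutes from recording start); None = never occurs.
    # Anaphase sits past the detector baseline window (first ~5 frames).
    t_anaphase_min: float | None = 30.0
    t_ingression_min: float | None = 40.0
    t_abscission_min: float | None = 60.0
    t_midbody_form_min: float | None = 50.0
    t_midbody_sever_min: float | None = 180.0
    t_bridge_resolve_min: float | None = 80.0
    t_cluster_start_min: float | None = 35.0
    t_clear_min: float | None = 120.0

    # chromatin
    nucleus_sigma_px: float = 4.0
    nucleus_peak: float = 200.0
    separation_speed_um_per_min: float = 0.6
    anaphase_jump_um: float = 1.5
    bridge_width_px: float = 1.2
    bridge_peak: float = 80.0
    bridge_fragmented: bool = False

    # actin
    n_clusters: int = 4
    cluster_sigma_px: float = 2.0
    cluster_peak: float = 200.0
    cytoplasm_peak: float = 30.0
    cytoplasm_radius_frac: float = 0.45
    furrow_peak: float = 120.0
    furrow_sigma_px: float = 2.0

    # membrane
    membrane_ridge_sigma_px: float = 3.0
    membrane_peak: float = 200.0
    ingression_narrowing: float = 0.45
    post_abscission_gap_um: float = 1.2

    # tubulin midbody
    midbody_semi_major_px: float = 6.0
    midbody_semi_minor_px: float = 2.5
    midbody_peak: float = 180.0

    # noise
    background_offset: float = 5.0
    read_noise_sd: float = 0.0
    poisson_noise: bool = False
    seed: int = 0

    @classmethod
    def yeast(cls, **overrides) -> "SceneParams":
        """Bud-neck membrane regime: small field, 0.1 µm pixels, 2-min frames."""
        base = dict(
            image_shape_px=(64, 64),
            pixel_size_um=0.1,
            frame_interval_min=2.0,
            n_frames=40,
            t_anaphase_min=12.0,
            t_ingression_min=20.0,
            t_abscission_min=36.0,
            t_midbody_form_min=None,
            t_midbody_sever_min=None,
            t_bridge_resolve_min=26.0,
            t_cluster_start_min=None,
            t_clear_min=None,
            nucleus_sigma_px=3.0,
            separation_speed_um_per_min=0.25,
            anaphase_jump_um=0.9,
            membrane_ridge_sigma_px=2.5,
            post_abscission_gap_um=1.2,
        )
        base.update(overrides)
        return cls(**base)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for name, value in (
            ("pixel_size_um", self.pixel_size_um),
            ("frame_interval_min", self.frame_interval_min),
            ("nucleus_sigma_px", self.nucleus_sigma_px),
            ("nucleus_peak", self.nucleus_peak),
            ("separation_speed_um_per_min", self.separation_speed_um_per_min),
        ):
            if value <= 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        ordered_pairs = (
            ("t_anaphase_min", "t_ingression_min"),
            ("t_ingression_min", "t_abscission_min"),
            ("t_midbody_form_min", "t_midbody_sever_min"),
        )
        for earlier, later in ordered_pairs:
            a, b = getattr(self, earlier), getattr(self, later)
            if a is not None and b is not None and a > b:
                raise ValidationError(f"event ordering violated: {earlier} ({a}) > {later} ({b})")
        for name in EVENT_FIELDS:
            t = getattr(self, name)
            if t is not None and t < 0:
                raise ValidationError(f"{name} must be nonnegative, got {t}")

    @property
    def duration_min(self) -> float:
        return self.n_frames * self.frame_interval_min

    def event_times(self) -> dict[str, float | None]:
        """Event name -> time (minutes), censored at movie end -> None."""
        out: dict[str, float | None] = {}
        for name in EVENT_FIELDS:
            t = getattr(self, name)
            out[name] = t if (t is not None and t < self.duration_min) else None
        return out


@dataclass
class GroundTruth:
    """Everything the generator knows about a movie it produced."""

    params: SceneParams
    centroids_px: np.ndarray  # (T, 2, 2): per frame, nuclei A/B, (y, x)
    major_axes_px: np.ndarray  # (T, 2): FWHM extent of each rendered nucleus
    event_times: dict[str, float | None]
    event_frames: dict[str, int | None]
    masks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "params": _params_to_jsonable(self.params),
            "event_times": self.event_times,
            "event_frames": self.event_frames,
            "centroids_px": self.centroids_px.tolist(),
            "major_axes_px": self.major_axes_px.tolist(),
        }
        return json.dumps(payload, indent=2)

    def event_table(self) -> pd.DataFrame:
        rows = [
            {"event": k, "t_min": v, "frame": self.event_frames[k]}
            for k, v in self.event_times.items()
        ]
        return pd.DataFrame(rows)


def _params_to_jsonable(params: SceneParams) -> dict:
    d = dataclasses.asdict(params)
    d["image_shape_px"] = list(d["image_shape_px"])
    return d


def params_from_dict(d: dict) -> SceneParams:
    d = dict(d)
    if "image_shape_px" in d:
        d["image_shape_px"] = tuple(d["image_shape_px"])
    return SceneParams(**d)


# ---------------------------------------------------------------------------
# scene geometry
# ---------------------------------------------------------------------------

def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return yy.astype(float), xx.astype(float)


def nucleus_centroids(params: SceneParams, t_min: float) -> np.ndarray:
    """True centroids of the two nuclei at time ``t`` as ``[(y, x), (y, x)]``.

    Before anaphase both coincide at the cell centre (one chromatin mass).
    """
    h, w = params.image_shape_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    t_ana = params.t_anaphase_min
    sep_px = 0.0
    if t_ana is not None and t_min >= t_ana:
        sep_um = params.anaphase_jump_um + params.separation_speed_um_per_min * (t_min - t_ana)
        sep_px = sep_um / params.pixel_size_um
        margin = 4.0 * params.nucleus_sigma_px + 2.0
        sep_px = min(sep_px, max(0.0, (w - 1) - 2.0 * margin))
    half = sep_px / 2.0
    return np.array([[cy, cx - half], [cy, cx + half]])


def _gaussian_blob(yy, xx, cy, cx, sigma, peak):
    return peak * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))


def _segment_distance(yy, xx, p0, p1):
    """Euclidean distance from each pixel centre to the segment p0-p1 ((y, x))."""
    d = np.array(p1) - np.array(p0)
    norm2 = float(d @ d)
    if norm2 == 0:
        return np.hypot(yy - p0[0], xx - p0[1])
    t = ((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / norm2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(yy - (p0[0] + t * d[0]), xx - (p0[1] + t * d[1]))


def _active(t_start, t_end, t_min):
    """Event window [t_start, t_end) with None meaning open at that end."""
    if t_start is not None and t_min < t_start:
        return False
    if t_end is not None and t_min >= t_end:
        return False
    return True


def _cluster_positions(params: SceneParams) -> np.ndarray:
    """Cluster centres, fixed for the whole movie, drawn from the seed."""
    rng = np.random.default_rng([int(params.seed) % (2**31), 1715])
    h, w = params.image_shape_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    n = params.n_clusters
    dy = rng.uniform(-6.0, 6.0, size=n)
    dx = rng.uniform(-3.0, 3.0, size=n)
    return np.column_stack([cy + dy, cx + dx])


def render_scene(params: SceneParams, t_min: float) -> dict[str, np.ndarray]:
    """Noise-free analytic scene at time ``t`` for all four channels."""
    h, w = params.image_shape_px
    yy, xx = _grid((h, w))
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    channels: dict[str, np.ndarray] = {}

    # -- histone: nuclei + bridge ----------------------------------------
    (ay, ax), (by, bx) = nucleus_centroids(params, t_min)
    hist = np.zeros((h, w))
    if ax == bx and ay == by:  # pre-anaphase single chromatin mass
        hist += _gaussian_blob(yy, xx, ay, ax, params.nucleus_sigma_px, params.nucleus_peak)
    else:
        hist += _gaussian_blob(yy, xx, ay, ax, params.nucleus_sigma_px, params.nucleus_peak)
        hist += _gaussian_blob(yy, xx, by, bx, params.nucleus_sigma_px, params.nucleus_peak)
        if _active(params.t_anaphase_min, params.t_bridge_resolve_min, t_min):
            if params.bridge_fragmented:
                spans = [(0.25, 0.40), (0.60, 0.75)]
            else:
                spans = [(0.0, 1.0)]
            p0 = np.array([ay, ax])
            p1 = np.array([by, bx])
            for lo, hi in spans:
                q0 = p0 + lo * (p1 - p0)
                q1 = p0 + hi * (p1 - p0)
                dist = _segment_distance(yy, xx, q0, q1)
                hist = np.maximum(
                    hist, params.bridge_peak * np.exp(-(dist**2) / (2.0 * params.bridge_width_px**2))
                )
    channels["histone"] = hist

    # -- actin: flat cytoplasm disk + furrow band + clusters -------------
    radius = params.cytoplasm_radius_frac * min(h, w)
    disk = (np.hypot(yy - cy, xx - cx) <= radius).astype(float)
    actin = params.cytoplasm_peak * disk
    if _active(params.t_anaphase_min, params.t_cluster_start_min, t_min) and params.t_anaphase_min is not None:
        # furrow: ridge across the midzone, perpendicular to the division axis
        band = params.furrow_peak * np.exp(-((xx - cx) ** 2) / (2.0 * params.furrow_sigma_px**2))
        actin = actin + band * disk
    if _active(params.t_cluster_start_min, params.t_clear_min, t_min) and params.t_cluster_start_min is not None:
        for qy, qx in _cluster_positions(params):
            actin = actin + _gaussian_blob(yy, xx, qy, qx, params.cluster_sigma_px, params.cluster_peak)
    channels["actin"] = actin

    # -- membrane: neck ridge, narrowing at ingression, split at abscission
    sigma = params.membrane_ridge_sigma_px
    if params.t_ingression_min is not None and t_min >= params.t_ingression_min:
        sigma = sigma * params.ingression_narrowing
    envelope = np.exp(-((yy - cy) ** 2) / (2.0 * (0.3 * min(h, w)) ** 2))
    if params.t_abscission_min is not None and t_min >= params.t_abscission_min:
        gap_px = params.post_abscission_gap_um / params.pixel_size_um
        ridge = np.exp(-((xx - (cx - gap_px / 2.0)) ** 2) / (2.0 * sigma**2)) + np.exp(
            -((xx - (cx + gap_px / 2.0)) ** 2) / (2.0 * sigma**2)
        )
    else:
        ridge = np.exp(-((xx - cx) ** 2) / (2.0 * sigma**2))
    channels["membrane"] = params.membrane_peak * ridge * envelope

    # -- tubulin: midbody ellipse between formation and severing ---------
    tub = np.zeros((h, w))
    if _active(params.t_midbody_form_min, params.t_midbody_sever_min, t_min) and params.t_midbody_form_min is not None:
        a, b = params.midbody_semi_major_px, params.midbody_semi_minor_px
        inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        tub = params.midbody_peak * inside.astype(float)
    channels["tubulin"] = tub

    return channels


CHANNEL_ORDER = ("histone", "actin", "membrane", "tubulin")


def generate_division_movie(params: SceneParams) -> tuple[Movie, GroundTruth]:
    """Render a synthetic division movie plus its ground truth."""
    params.validate()
    h, w = params.image_shape_px
    n = params.n_frames
    data = np.zeros((n, len(CHANNEL_ORDER), h, w), dtype=np.float32)
    masks = {role: np.zeros((n, h, w), dtype=bool) for role in CHANNEL_ORDER}
    centroids = np.zeros((n, 2, 2))
    majors = np.zeros((n, 2))

    peaks = {
        "histone": params.nucleus_peak,
        "actin": params.cytoplasm_peak,
        "membrane": params.membrane_peak,
        "tubulin": params.midbody_peak,
    }
    root = np.random.default_rng(int(params.seed) % (2**31))
    streams = {role: rng for role, rng in zip(CHANNEL_ORDER, root.spawn(len(CHANNEL_ORDER)))}

    fwhm = 2.0 * params.nucleus_sigma_px * np.sqrt(2.0 * np.log(2.0))
    for f in range(n):
        t = f * params.frame_interval_min
        scene = render_scene(params, t)
        centroids[f] = nucleus_centroids(params, t)
        majors[f] = fwhm
        for c, role in enumerate(CHANNEL_ORDER):
            signal = scene[role]
            masks[role][f] = signal > _MASK_LEVEL * peaks[role]
            out = signal
            if params.poisson_noise:
                out = streams[role].poisson(np.maximum(out, 0.0)).astype(float)
            if params.read_noise_sd > 0:
                out = out + streams[role].normal(0.0, params.read_noise_sd, size=signal.shape)
            out = out + params.background_offset
            data[f, c] = np.clip(out, 0.0, None)

    movie = Movie(
        data=data,
        channel_roles={role: i for i, role in enumerate(CHANNEL_ORDER)},
        pixel_size_um=params.pixel_size_um,
        frame_interval_min=params.frame_interval_min,
    )
    times = params.event_times()
    frames = {
        k: (movie.frame_at(v) if v is not None else None) for k, v in times.items()
    }
    truth = GroundTruth(
        params=params,
        centroids_px=centroids,
        major_axes_px=majors,
        event_times=times,
        event_frames=frames,
        masks=masks,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# midbody immunofluorescence stacks
# ---------------------------------------------------------------------------

@dataclass
class MidbodyTruth:
    z_best: int
    center: tuple[float, float]
    semi_major_px: float
    semi_minor_px: float
    angle_rad: float
    area_px: int           # rendered positive-pixel count
    marker_amplitude: float

    @property
    def total_intensity(self) -> float:
        return self.area_px * self.marker_amplitude


def generate_midbody_stack(
    shape: tuple[int, int] = (48, 48),
    n_z: int = 9,
    z_best: int = 4,
    semi_major_px: float = 9.0,
    semi_minor_px: float = 3.5,
    angle_rad: float = 0.4,
    tubulin_peak: float = 150.0,
    marker_peak: float = 100.0,
    defocus_px_per_slice: float = 1.2,
    read_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, MidbodyTruth]:
    """Render paired tubulin / marker Z-stacks of a midbody ellipse.

    The ellipse is sharp in slice ``z_best`` and progressively Gaussian-blurred
    away from it, emulating defocus.  Returns ``(tubulin_stack, marker_stack,
    truth)`` with both stacks shaped ``(n_z, H, W)``.
    """
    from scipy.ndimage import gaussian_filter

    h, w = shape
    yy, xx = _grid((h, w))
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ct, st = np.cos(angle_rad), np.sin(angle_rad)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    inside = (u / semi_major_px) ** 2 + (v / semi_minor_px) ** 2 <= 1.0
    tub_sharp = tubulin_peak * inside.astype(float)
    marker_sharp = marker_peak * inside.astype(float)

    rng = np.random.default_rng(int(seed) % (2**31))
    tub = np.zeros((n_z, h, w), dtype=np.float32)
    marker = np.zeros((n_z, h, w), dtype=np.float32)
    for z in range(n_z):
        blur = defocus_px_per_slice * abs(z - z_best)
        tz = gaussian_filter(tub_sharp, blur) if blur > 0 else tub_sharp
        mz = gaussian_filter(marker_sharp, blur) if blur > 0 else marker_sharp
        if read_noise_sd > 0:
            tz = tz + rng.normal(0.0, read_noise_sd, size=tz.shape)
            mz = mz + rng.normal(0.0, read_noise_sd, size=mz.shape)
        tub[z] = np.clip(tz, 0.0, None)
        marker[z] = np.clip(mz, 0.0, None)

    truth = MidbodyTruth(
        z_best=z_best,
        center=(cy, cx),
        semi_major_px=semi_major_px,
        semi_minor_px=semi_minor_px,
        angle_rad=angle_rad,
        area_px=int(inside.sum()),
        marker_amplitude=marker_peak,
    )
    return tub, marker, truth


# ---------------------------------------------------------------------------
# event tables and qPCR tables
# ---------------------------------------------------------------------------

EVENT_COLUMNS = (
    "t_anaphase",
    "t_ingression",
    "t_abscission",
    "t_midbody_form",
    "t_midbody_sever",
    "t_bridge_resolve",
)


def _draw(rng: np.random.Generator, spec, size: int) -> np.ndarray:
    """Draw ``size`` samples from a (family, *params) distribution spec."""
    family, *args = spec
    if family == "point":
        return np.full(size, float(args[0]))
    if family == "normal":
        mu, sd = args
        return np.maximum(rng.normal(mu, sd, size), 0.0)
    if family == "lognormal":
        mean_log, sd_log = args
        return rng.lognormal(mean_log, sd_log, size)
    if family == "uniform":
        lo, hi = args
        return rng.uniform(lo, hi, size)
    if family == "exponential":
        (scale,) = args
        return rng.exponential(scale, size)
    raise DataError(f"unknown distribution family {family!r}")


def generate_event_table(
    n_cells: int,
    condition_specs: list[tuple[str, dict]],
    seed: int = 0,
    horizon_min: float | None = None,
) -> pd.DataFrame:
    """One :class:`EventRecord` row per simulated cell.

    ``condition_specs`` maps each condition label to a dict of column ->
    distribution spec.  Event columns (``t_*``) take ``("point", v)``,
    ``("normal", mu, sd)``, ``("lognormal", mean_log, sd_log)``,
    ``("uniform", lo, hi)`` or ``("exponential", scale)``; the boolean
    columns ``has_bridge`` / ``binucleate`` take ``("bernoulli", p)``.
    Events beyond ``horizon_min`` are censored (NaN).
    """
    if not condition_specs:
        raise DataError("condition_specs must not be empty")
    if n_cells < 0:
        raise DataError("n_cells must be nonnegative")
    rng = np.random.default_rng(int(seed) % (2**31))
    frames = []
    for label, spec in condition_specs:
        df = pd.DataFrame(
            {
                "cell_id": [f"{label}_{i:04d}" for i in range(n_cells)],
                "condition": label,
            }
        )
        for col in EVENT_COLUMNS:
            if col in spec:
                values = _draw(rng, spec[col], n_cells)
                if horizon_min is not None:
                    values = np.where(values <= horizon_min, values, np.nan)
                df[col] = values
            else:
                df[col] = np.nan
        for col in ("has_bridge", "binucleate"):
            if col in spec:
                family, p = spec[col]
                if family != "bernoulli":
                    raise DataError(f"{col} expects a ('bernoulli', p) spec")
                df[col] = rng.random(n_cells) < p
            else:
                df[col] = False
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_qpcr_table(
    true_fold_changes: dict[str, float],
    ct_reference: float = 18.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    control_sample: str | None = None,
    target_gene: str = "target",
    reference_gene: str = "reference",
) -> pd.DataFrame:
    """Ct table whose normalized relative expression equals the fold changes.

    For each sample, ``Ct(target) = ct_reference - log2(fold_change)`` plus
    Gaussian replicate noise on both target and reference Cts; the control
    (first key unless ``control_sample`` given) defines the normalization.
    """
    if not true_fold_changes:
        raise DataError("true_fold_changes must not be empty")
    for sample, fc in true_fold_changes.items():
        if fc <= 0:
            raise DataError(f"fold change for {sample!r} must be positive, got {fc}")
    if control_sample is None:
        control_sample = next(iter(true_fold_changes))
    if control_sample not in true_fold_changes:
        raise DataError(f"control sample {control_sample!r} not in fold-change map")
    rng = np.random.default_rng(int(seed) % (2**31))
    rows = []
    for sample, fc in true_fold_changes.items():
        delta_ct = -np.log2(fc / true_fold_changes[control_sample])
        for rep in range(n_replicates):
            rows.append(
                {
                    "sample": sample,
                    "target_gene": target_gene,
                    "reference_gene": reference_gene,
                    "ct_target": ct_reference + delta_ct + rng.normal(0.0, noise_sd),
                    "ct_reference": ct_reference + rng.normal(0.0, noise_sd),
                    "is_control": sample == control_sample,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)
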