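"""Multi-channel time-lapse container and OME-TIFF round trip.

A :class:`Movie` holds a ``(T, C, H, W)`` raster with role-tagged channels
(``histone``, ``actin``, ``membrane``, ``tubulin``, ``focus_marker``) and
physical calibration (micrometres per pixel, minutes per frame).  Geometry
everywhere in the package uses 0-based, row-major ``(y, x)`` pixel indices
with pixel-centre coordinates; physical units are obtained by multiplying
by the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .exceptions import CalibrationError, DataError

KNOWN_ROLES = ("histone", "actin", "membrane", "tubulin", "focus_marker")


@dataclass
class Movie:
    """Role-tagged multi-channel time-lapse raster with calibration."""

    data: np.ndarray  # (T, C, H, W)
    channel_roles: dict[str, int]
    pixel_size_um: float
    frame_interval_min: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DataError(f"movie data must be (T, C, H, W), got shape {self.data.shape}")
        if self.pixel_size_um <= 0:
            raise CalibrationError("pixel_size_um must be positive")
        if self.frame_interval_min <= 0:
            raise CalibrationError("frame_interval_min must be positive")
        n_channels = self.data.shape[1]
        seen: set[int] = set()
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n_channels:
                raise DataError(f"channel role {role!r} maps to index {idx} outside 0..{n_channels - 1}")
            if idx in seen:
                raise DataError(f"channel index {idx} assigned to more than one role")
            seen.add(idx)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """All frames of one role, shape ``(T, H, W)``."""
        if role not in self.channel_roles:
            raise DataError(f"role {role!r} not present; have {sorted(self.channel_roles)}")
        return self.data[:, self.channel_roles[role]]

    def frame(self, index: int, role: str) -> np.ndarray:
        return self.channel(role)[index]

    def time_min(self, index: int) -> float:
        """Acquisition time of a frame in minutes (frame 0 at t = 0)."""
        return index * self.frame_interval_min

    def frame_at(self, t_min: float) -> int:
        """First frame index acquired at or after ``t_min``."""
        return int(np.ceil(t_min / self.frame_interval_min - 1e-9))


def write_movie(path, movie: Movie) -> None:
    """Write a movie as multi-page OME-TIFF with channel names and calibration."""
    order = sorted(movie.channel_roles.items(), key=lambda kv: kv[1])
    names = [role for role, _ in order]
    tifffile.imwrite(
        path,
        movie.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "TCYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": movie.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": movie.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": movie.frame_interval_min,
            "TimeIncrementUnit": "min",
        },
    )


def read_movie(
    path,
    role_map: dict[str, int] | None = None,
    pixel_size_um: float | None = None,
    frame_interval_min: float | None = None,
) -> Movie:
    """Read an OME-TIFF (or plain TIFF with declared roles) into a :class:`Movie`.

    Calibration is taken from OME metadata; explicit arguments override it.
    A plain multi-page TIFF needs ``role_map`` plus both calibration values,
    and is reshaped to ``(T, C, H, W)`` with ``C = len(role_map)``.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta_pixel = None
        meta_interval = None
        meta_roles: dict[str, int] | None = None
        if tf.ome_metadata:
            ome = tifffile.xml2dict(tf.ome_metadata)
            pixels = ome.get("OME", {}).get("Image", {})
            if isinstance(pixels, list):
                pixels = pixels[0]
            pixels = pixels.get("Pixels", {})
            meta_pixel = pixels.get("PhysicalSizeX")
            meta_interval = pixels.get("TimeIncrement")
            channels = pixels.get("Channel", [])
            if isinstance(channels, dict):
                channels = [channels]
            names = [c.get("Name") for c in channels]
            if names and all(n is not None for n in names):
                meta_roles = {str(n): i for i, n in enumerate(names)}

    if data.ndim == 3:
        # plain stack: interpret as (T*C, H, W)
        n_channels = len(role_map) if role_map else 1
        if data.shape[0] % n_channels:
            raise DataError(
                f"page count {data.shape[0]} not divisible by {n_channels} declared channels"
            )
        data = data.reshape(-1, n_channels, *data.shape[1:])
    elif data.ndim == 4:
        if axes == "CTYX":
            data = np.swapaxes(data, 0, 1)
    else:
        raise DataError(f"unsupported TIFF dimensionality {data.ndim} (axes {axes!r})")

    roles = role_map if role_map is not None else meta_roles
    if roles is None:
        raise DataError("channel roles not found in metadata and no role_map given")
    pixel = pixel_size_um if pixel_size_um is not None else meta_pixel
    interval = frame_interval_min if frame_interval_min is not None else meta_interval
    if pixel is None:
        raise CalibrationError("pixel_size_um missing from metadata and no override given")
    if interval is None:
        raise CalibrationError("frame_interval_min missing from metadata and no override given")
    return Movie(
        data=np.asarray(data),
        channel_roles=dict(roles),
        pixel_size_um=float(pixel),
        frame_interval_min=float(interval),
    )
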