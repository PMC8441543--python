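"""Image-stack containers and readers/writers.

A B-mode acquisition is a sequence of 2-D grayscale frames (depth z by
lateral x) with per-frame start times derived from the acquisition timing:
frame k begins at ``k * (a_lines_per_frame / a_line_rate + dead_time)``
relative to the trigger.  Stacks travel as multi-page TIFF plus a JSON
sidecar carrying acquisition, chamber-geometry and driving-waveform
metadata, so a stack file is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .flow_theory import ChamberGeometry, DrivingWaveform

__all__ = ["AcquisitionParams", "ImageStack", "write_stack", "read_stack", "SidecarError"]


class SidecarError(ValueError):
    """Raised when a stack sidecar is missing required metadata."""


@dataclass(frozen=True)
class AcquisitionParams:
    """OCT B-mode acquisition timing and sampling geometry.

    ``a_line_rate`` in Hz, ``dead_time`` (inter-frame) in s, free-space pixel
    sizes in um.  The frame interval is ``a_lines_per_frame / a_line_rate +
    dead_time``; e.g. 250 A-lines at 10 kHz with 2 ms dead time gives 27 ms
    (37 Hz), and 208 A-lines at 69 kHz gives ~5.01 ms (199 Hz).
    """

    a_line_rate: float
    a_lines_per_frame: int
    dead_time: float
    pixel_size_x_free_space: float
    pixel_size_z_free_space: float
    n_frames: int
    n_z_pixels: int

    def __post_init__(self) -> None:
        for name in (
            "a_line_rate",
            "a_lines_per_frame",
            "pixel_size_x_free_space",
            "pixel_size_z_free_space",
            "n_frames",
            "n_z_pixels",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dead_time < 0:
            raise ValueError("dead_time must be non-negative")

    @property
    def frame_interval(self) -> float:
        """Seconds between successive frame starts."""
        return self.a_lines_per_frame / self.a_line_rate + self.dead_time

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_interval

    @property
    def field_of_view(self) -> tuple[float, float]:
        """(lateral, axial) extent in free-space um."""
        return (
            self.a_lines_per_frame * self.pixel_size_x_free_space,
            self.n_z_pixels * self.pixel_size_z_free_space,
        )

    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class ImageStack:
    """Frames with timestamps and calibrated pixel sizes.

    ``frames`` has shape (Q, Z, X).  ``pixel_size_x``/``pixel_size_z`` are
    the *current* free-space pixel sizes in um (lateral size shrinks when a
    stack is upsampled; ``upsample_factor`` records by how much).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size_x: float
    pixel_size_z: float
    acquisition: AcquisitionParams | None = None
    geometry: ChamberGeometry | None = None
    waveform: DrivingWaveform | None = None
    upsample_factor: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (Q, Z, X) array")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_interval(self) -> float:
        if self.acquisition is not None:
            return self.acquisition.frame_interval
        if len(self.timestamps) < 2:
            raise ValueError("cannot infer frame interval from a single frame")
        return float(np.median(np.diff(self.timestamps)))


def _dataclass_dict(obj) -> dict:
    return dataclasses.asdict(obj)


_REQUIRED_SIDECAR = ("acquisition", "pixel_size_x", "pixel_size_z")


def write_stack(stack: ImageStack, path: str | Path, dtype: str = "float32") -> Path:
    """Write a stack as multi-page TIFF with a ``.json`` sidecar.

    ``dtype`` is ``"float32"`` (lossless for simulator output, the default)
    or ``"uint16"`` (values are clipped/rounded into the 16-bit range).
    """
    path = Path(path)
    frames = stack.frames
    if dtype == "uint16":
        frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        frames = frames.astype(np.float32)
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    tifffile.imwrite(path, frames, photometric="minisblack")
    sidecar = {
        "pixel_size_x": stack.pixel_size_x,
        "pixel_size_z": stack.pixel_size_z,
        "upsample_factor": stack.upsample_factor,
        "timestamps": stack.timestamps.tolist(),
        "acquisition": _dataclass_dict(stack.acquisition) if stack.acquisition else None,
        "geometry": _dataclass_dict(stack.geometry) if stack.geometry else None,
        "waveform": _dataclass_dict(stack.waveform) if stack.waveform else None,
        "meta": stack.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF + JSON sidecar written by :func:`write_stack`.

    Timestamps are reconstructed from the acquisition metadata when not
    stored explicitly.  Missing sidecar keys raise :class:`SidecarError`
    listing what is absent.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise SidecarError(f"sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    missing = [k for k in _REQUIRED_SIDECAR if sidecar.get(k) is None]
    if missing:
        raise SidecarError(f"sidecar missing required keys: {missing}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    acq = AcquisitionParams(**sidecar["acquisition"])
    timestamps = (
        np.asarray(sidecar["timestamps"], dtype=float)
        if sidecar.get("timestamps")
        else acq.timestamps()[: frames.shape[0]]
    )
    geometry = (
        ChamberGeometry(**sidecar["geometry"]) if sidecar.get("geometry") else None
    )
    waveform = (
        DrivingWaveform(**sidecar["waveform"]) if sidecar.get("waveform") else None
    )
    return ImageStack(
        frames=frames,
        timestamps=timestamps,
        pixel_size_x=sidecar["pixel_size_x"],
        pixel_size_z=sidecar["pixel_size_z"],
        acquisition=acq,
        geometry=geometry,
        waveform=waveform,
        upsample_factor=int(sidecar.get("upsample_factor", 1)),
        meta=sidecar.get("meta", {}),
    )
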