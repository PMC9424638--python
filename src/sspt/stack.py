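"""The time-lapse video container used throughout the package.

A :class:`FrameStack` is a time-ordered stack of 2-D 8-bit grayscale frames
with temporal (seconds/frame) and spatial (µm/pixel) calibration.  It is the
common currency between the synthetic-video generator and the
polarized-video-microscopy (PVM) analysis pipeline.  Frames use 0-based
(row, col) indexing with row 0 at the top; the first frame is at t = 0
(recording starts at the moment of UV exposure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["FrameStack", "read_stack"]

#: Default spatial calibration, µm per pixel (14 px per µm).
DEFAULT_PIXEL_SIZE_UM = 1.0 / 14.0

# ITU-R BT.601 luma weights, used when a color video must be collapsed
# to a single gray channel.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameStack:
    """A T×H×W stack of 8-bit grayscale frames with calibration.

    Parameters
    ----------
    frames
        Array of shape (T, H, W), dtype uint8.
    frame_interval_s
        Seconds between consecutive frames (> 0).
    pixel_size_um
        Physical size of one pixel in µm.
    meta
        Free-form provenance/quality flags (e.g. ``{"truncated": True}``
        when drift pushed the crystal out of frame).
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a 3-D (T, H, W) array, got shape {self.frames.shape}"
            )
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValueError("frame values must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)
        if self.n_frames < 3:
            raise ValueError(f"a stack needs at least 3 frames, got {self.n_frames}")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, first frame at t = 0."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def with_frames(self, frames: np.ndarray) -> "FrameStack":
        """A new stack sharing this stack's calibration and metadata."""
        return FrameStack(
            frames=frames,
            frame_interval_s=self.frame_interval_s,
            pixel_size_um=self.pixel_size_um,
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------ I/O

    def write_tiff(self, path) -> None:
        """Write as an 8-bit grayscale multi-page TIFF."""
        tifffile.imwrite(
            path,
            self.frames,
            photometric="minisblack",
            metadata={
                "frame_interval_s": self.frame_interval_s,
                "pixel_size_um": self.pixel_size_um,
            },
        )

    def write_avi(self, path, fps: float | None = None) -> None:
        """Write as an AVI video (requires an imageio ffmpeg backend)."""
        import imageio.v3 as iio

        if fps is None:
            fps = 1.0 / self.frame_interval_s
        try:
            iio.imwrite(path, self.frames, fps=fps, codec="rawvideo")
        except (ImportError, ValueError, OSError) as exc:  # no ffmpeg plugin
            raise SSPTAviUnavailable(
                "AVI output needs an imageio ffmpeg backend (imageio-ffmpeg); "
                "none is installed. Use write_tiff instead."
            ) from exc


class SSPTAviUnavailable(RuntimeError):
    """AVI support requested but no video backend is available."""


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse a trailing RGB(A) channel axis to 8-bit luma."""
    if arr.ndim == 4 and arr.shape[-1] in (3, 4):
        warnings.warn("color video converted to grayscale by BT.601 luma")
        gray = arr[..., :3].astype(float) @ _LUMA
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    return arr


def read_stack(
    path,
    frame_interval_s: float,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> FrameStack:
    """Read a multi-page TIFF or AVI video into a :class:`FrameStack`.

    The file's container carries no reliable calibration, so the frame
    interval (and optionally pixel size) must be supplied by the caller.
    """
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        try:
            arr = np.asarray(iio.imread(path))
        except (ImportError, ValueError, OSError) as exc:
            raise SSPTAviUnavailable(
                f"could not read {path!r}: reading non-TIFF video requires an "
                "imageio ffmpeg backend (imageio-ffmpeg)"
            ) from exc
    arr = _to_gray(arr)
    if arr.ndim == 2:
        raise ValueError("file contains a single frame, not a time series")
    return FrameStack(arr, frame_interval_s=frame_interval_s, pixel_size_um=pixel_size_um)
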