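"""Synthetic polarized-video-microscopy (PVM) stacks with known ground truth.

A birefringent crystal between crossed polarizers changes its transmitted
intensity as the lattice converts during a solid-to-solid phase transition.
This module renders such videos from a generative description
(:class:`SyntheticCrystalSpec`) together with the per-pixel ground-truth
transition-time field (:class:`T1Field`), so the analysis pipeline can be
validated end-to-end without real microscopy data.

The temporal intensity profile of each pixel is a two-component mixture of
normal CDFs: a small, early "shoulder" component (the gradual onset driven
by slow ligand release) followed by the primary, Gaussian-like transition
centred on the pixel's transition time T1.  The spatial T1 field is a linear
gradient plus a smooth correlated Gaussian random field, emulating the waves
of transition that propagate across a real crystal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr
from skimage.draw import polygon2mask

from .errors import InvalidSpecError
from .stack import DEFAULT_PIXEL_SIZE_UM, FrameStack

__all__ = [
    "SyntheticCrystalSpec",
    "T1Field",
    "generate_t1_field",
    "pixel_intensity_curve",
    "render_video",
    "write_truth_csv",
    "read_truth_csv",
]


def _default_polygon() -> list[tuple[float, float]]:
    # a rectangular crystal inset in the default 128x128 image
    return [(24.0, 24.0), (24.0, 104.0), (104.0, 104.0), (104.0, 24.0)]


@dataclass
class SyntheticCrystalSpec:
    """Generative description of a crystal video.

    Defaults emulate the study conditions: a ~6 µm crystal imaged at
    14 px/µm, 0.5 s frame interval for 6 min, transitioning around t = 60 s
    with a primary transition of σ = 8 s preceded by a small shoulder,
    2 gray levels of sensor noise, 8-bit quantization.

    All times are seconds, all intensities 8-bit gray levels, all lengths
    pixels unless a ``_um`` suffix says otherwise.
    """

    image_height_px: int = 128
    image_width_px: int = 128
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = 0.5
    duration_s: float = 360.0
    crystal_polygon: list = field(default_factory=_default_polygon)
    baseline_intensity: float = 30.0
    final_intensity: float = 200.0
    background_intensity: float = 10.0
    t1_mean_s: float = 60.0
    t1_gradient_s_per_um: float = 0.0
    t1_gradient_direction_deg: float = 0.0  # 0 = along columns (+x)
    t1_noise_sd_s: float = 0.0
    t1_corr_length_um: float = 1.0
    primary_width_s: float = 8.0
    shoulder_fraction: float = 0.2
    shoulder_lead_s: float = 25.0
    shoulder_width_s: float = 4.0
    noise_sd: float = 2.0
    drift_px_per_frame: tuple = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.image_height_px < 1 or self.image_width_px < 1:
            raise InvalidSpecError("image dimensions must be positive")
        for name in ("pixel_size_um", "frame_interval_s", "duration_s",
                     "primary_width_s", "shoulder_width_s", "t1_corr_length_um"):
            if not getattr(self, name) > 0:
                raise InvalidSpecError(f"{name} must be > 0")
        for name in ("baseline_intensity", "final_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise InvalidSpecError(f"{name} must lie in [0, 255], got {v}")
        if not 0 <= self.shoulder_fraction < 1:
            raise InvalidSpecError("shoulder_fraction must lie in [0, 1)")
        if self.t1_noise_sd_s < 0 or self.shoulder_lead_s < 0:
            raise InvalidSpecError("t1_noise_sd_s and shoulder_lead_s must be >= 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        poly = np.asarray(self.crystal_polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
            raise InvalidSpecError("crystal_polygon needs at least 3 (row, col) vertices")
        if (poly[:, 0].min() < 0 or poly[:, 1].min() < 0
                or poly[:, 0].max() > self.image_height_px
                or poly[:, 1].max() > self.image_width_px):
            raise InvalidSpecError("crystal_polygon lies outside the image")
        if self.duration_s / self.frame_interval_s < 3:
            raise InvalidSpecError("duration must span at least 3 frame intervals")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration_s / self.frame_interval_s)) + 1

    @property
    def delta_intensity(self) -> float:
        """Signed intensity change through the transition (may be negative)."""
        return self.final_intensity - self.baseline_intensity

    def mask(self) -> np.ndarray:
        """Boolean crystal mask (True inside the polygon)."""
        return polygon2mask(
            (self.image_height_px, self.image_width_px),
            np.asarray(self.crystal_polygon, dtype=float),
        )

    def to_json(self, path) -> None:
        d = asdict(self)
        d["drift_px_per_frame"] = list(d["drift_px_per_frame"])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SyntheticCrystalSpec":
        d = dict(mapping)
        if "drift_px_per_frame" in d:
            d["drift_px_per_frame"] = tuple(d["drift_px_per_frame"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SyntheticCrystalSpec":
        with open(path) as fh:
            return cls.from_mapping(json.load(fh))


@dataclass
class T1Field:
    """Per-pixel ground-truth transition times over the crystal mask.

    ``values`` has the same H×W shape as the frames; pixels outside the
    crystal are NaN, pixels inside are finite and >= 0.
    """

    values: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("T1 field must be a 2-D map")
        finite = np.isfinite(self.values)
        if finite.any() and np.nanmin(self.values) < 0:
            raise ValueError("T1 values must be >= 0")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def mean(self) -> float:
        return float(np.nanmean(self.values))

    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1))


def generate_t1_field(spec: SyntheticCrystalSpec) -> T1Field:
    """Ground-truth T1 map: mean + linear gradient + smooth random field.

    The gradient acts along ``t1_gradient_direction_deg`` (0° = along the
    column/x axis), measured in s/µm from the mask centroid so the field
    mean stays near ``t1_mean_s``.  The random component is white noise
    smoothed with a Gaussian kernel of width ``t1_corr_length_um`` and
    rescaled so its standard deviation over the mask equals
    ``t1_noise_sd_s``.  Deterministic for a given spec (seeded).
    """
    spec.validate()
    mask = spec.mask()
    if not mask.any():
        raise InvalidSpecError("crystal_polygon encloses no pixels")
    h, w = mask.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    r0 = rows[mask].mean()
    c0 = cols[mask].mean()
    theta = np.deg2rad(spec.t1_gradient_direction_deg)
    proj_um = ((cols - c0) * np.cos(theta) + (rows - r0) * np.sin(theta)) * spec.pixel_size_um
    t1 = spec.t1_mean_s + spec.t1_gradient_s_per_um * proj_um

    if spec.t1_noise_sd_s > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])
        white = rng.standard_normal((h, w))
        smooth = gaussian_filter(white, sigma=spec.t1_corr_length_um / spec.pixel_size_um)
        vals = smooth[mask]
        sd = vals.std()
        if sd > 0:
            t1 = t1 + (smooth - vals.mean()) / sd * spec.t1_noise_sd_s

    t1 = np.clip(t1, 0.0, None)
    t1[~mask] = np.nan
    return T1Field(t1, pixel_size_um=spec.pixel_size_um)


def pixel_intensity_curve(t, t1, spec: SyntheticCrystalSpec):
    """Noiseless intensity of a crystal pixel at time ``t`` (continuous).

    I(t) = baseline + ΔI·[ f_s·Φ((t − (T1 − lead))/σ_s)
                           + (1 − f_s)·Φ((t − T1)/σ_p) ]

    with Φ the standard normal CDF, f_s the shoulder amplitude fraction,
    σ_s/σ_p the shoulder/primary widths.  Monotone in t whenever ΔI ≠ 0;
    broadcasts over array-valued ``t`` and ``t1``.
    """
    t = np.asarray(t, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    fs = spec.shoulder_fraction
    shoulder = ndtr((t - (t1 - spec.shoulder_lead_s)) / spec.shoulder_width_s)
    primary = ndtr((t - t1) / spec.primary_width_s)
    return spec.baseline_intensity + spec.delta_intensity * (
        fs * shoulder + (1.0 - fs) * primary
    )


def _shift2d(arr: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """Rigid integer translation with constant fill (no wrap-around)."""
    out = np.full_like(arr, fill)
    h, w = arr.shape
    r0_src, r0_dst = max(0, -dr), max(0, dr)
    c0_src, c0_dst = max(0, -dc), max(0, dc)
    nr = max(0, h - abs(dr))
    nc = max(0, w - abs(dc))
    if nr and nc:
        out[r0_dst:r0_dst + nr, c0_dst:c0_dst + nc] = arr[r0_src:r0_src + nr, c0_src:c0_src + nc]
    return out


def render_video(spec: SyntheticCrystalSpec) -> tuple[FrameStack, T1Field]:
    """Render the full synthetic stack and its ground-truth T1 field.

    Frame k is acquired at t = k·frame_interval_s.  Crystal pixels follow
    :func:`pixel_intensity_curve` with their own T1; background pixels sit
    at ``background_intensity``.  Drift is applied as a rigid translation of
    the crystal (mask and field together), rounded to whole pixels per
    frame.  Gaussian sensor noise of sd ``noise_sd`` is added, then values
    are clipped to [0, 255] and quantized to 8 bits.  Bit-deterministic for
    a given spec.

    Returns the stack and the T1 field in frame-0 (undrifted) geometry.
    If drift pushes the crystal entirely out of the frame the stack is
    flagged ``meta["truncated"] = True`` and a warning is issued.
    """
    spec.validate()
    field_ = generate_t1_field(spec)
    mask = field_.mask
    t1_vals = field_.values[mask]
    times = np.arange(spec.n_frames) * spec.frame_interval_s

    # (T, n_mask) noiseless intensities for the crystal pixels
    crystal = pixel_intensity_curve(times[:, None], t1_vals[None, :], spec)

    h, w = mask.shape
    frames = np.empty((spec.n_frames, h, w), dtype=float)
    drift = np.asarray(spec.drift_px_per_frame, dtype=float)
    truncated = False
    base = np.full((h, w), float(spec.background_intensity))
    for k in range(spec.n_frames):
        img = base.copy()
        img[mask] = crystal[k]
        dr, dc = np.rint(k * drift).astype(int)
        if dr or dc:
            img = _shift2d(img, dr, dc, spec.background_intensity)
            if not _shift2d(mask.astype(np.uint8), dr, dc, 0).any():
                truncated = True
        frames[k] = img

    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
        frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)

    frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    meta = {"synthetic": True, "seed": spec.seed}
    if truncated:
        warnings.warn("drift moved the crystal entirely out of frame; stack truncated")
        meta["truncated"] = True
    stack = FrameStack(
        frames,
        frame_interval_s=spec.frame_interval_s,
        pixel_size_um=spec.pixel_size_um,
        meta=meta,
    )
    return stack, field_


def write_truth_csv(field: T1Field, path) -> None:
    """Ground truth as CSV with columns row, col, t1_s (mask pixels only)."""
    rows, cols = np.nonzero(field.mask)
    pd.DataFrame(
        {"row": rows, "col": cols, "t1_s": field.values[rows, cols]}
    ).to_csv(path, index=False)


def read_truth_csv(path, shape: tuple[int, int], pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> T1Field:
    df = pd.read_csv(path)
    vals = np.full(shape, np.nan)
    vals[df["row"].to_numpy(), df["col"].to_numpy()] = df["t1_s"].to_numpy()
    return T1Field(vals, pixel_size_um=pixel_size_um)
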