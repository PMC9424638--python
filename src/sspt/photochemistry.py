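"""Uncaging photochemistry arithmetic.

Quantifies UV photolysis of the photocaged ligand (pcADE → adenine):
an HPLC standard curve calibrates peak area against adenine amount, the
percent released is the observed peak area relative to the area expected
for the amount loaded, and simple beam geometry converts LED power into
power density and the illuminated fraction of the sample drop.  The drop
and beam are treated as circles (the drop's height and shape are ignored),
so the illuminated fraction is just the squared diameter ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .errors import CalibrationError

__all__ = [
    "StandardCurve",
    "UncagingReplicates",
    "BeamGeometry",
    "ReplicateSummary",
    "fit_standard_curve",
    "percent_released",
    "summarize_replicates",
    "power_density",
    "illuminated_fraction",
    "nominal_uncaged_concentration",
]


@dataclass(frozen=True)
class StandardCurve:
    """OLS calibration line: peak area = slope · amount(nmol) + intercept."""

    points: tuple  # ((nmol, area), ...)
    slope: float
    intercept: float
    r_squared: float

    def expected_area(self, amount_nmol: float, through_origin: bool = False) -> float:
        if amount_nmol <= 0:
            raise ValueError("amount_nmol must be > 0")
        return self.slope * amount_nmol + (0.0 if through_origin else self.intercept)


@dataclass(frozen=True)
class UncagingReplicates:
    """Replicate percent-released measurements for one exposure condition."""

    exposure_s: float
    mode: str  # 'direct' or 'microscope'
    yields_percent: tuple

    def __post_init__(self):
        if self.mode not in ("direct", "microscope"):
            raise ValueError("mode must be 'direct' or 'microscope'")
        if len(self.yields_percent) < 1:
            raise ValueError("need at least one replicate")
        if any(not 0 <= y <= 100 for y in self.yields_percent):
            raise ValueError("yields must lie in [0, 100] percent")


@dataclass(frozen=True)
class BeamGeometry:
    """UV beam / sample-drop dimensions and measured power."""

    beam_diameter_mm: float
    power_mW: float
    drop_diameter_mm: float | None = None
    aperture_diameter_mm: float | None = None

    def __post_init__(self):
        for name in ("beam_diameter_mm", "power_mW", "drop_diameter_mm",
                     "aperture_diameter_mm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 when given")


class ReplicateSummary(NamedTuple):
    mean_percent: float
    sd_percent: float
    n: int


def fit_standard_curve(points) -> StandardCurve:
    """Ordinary least-squares line through (amount nmol, peak area) points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise CalibrationError("need at least 3 (amount, area) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise CalibrationError("amounts have zero variance; cannot calibrate")
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise CalibrationError(f"calibration slope must be > 0, got {res.slope:g}")
    return StandardCurve(
        points=tuple(map(tuple, pts)),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def percent_released(
    peak_area: float,
    amount_loaded_nmol: float,
    curve: StandardCurve,
    through_origin: bool = False,
) -> float:
    """Percent of the loaded caged ligand released, from the observed peak area.

    100 × area / expected-area-for-the-loaded-amount, clipped to [0, 120]
    (values above 100% are flagged with a warning — they indicate a
    calibration or loading inconsistency, not extra release).
    """
    if peak_area < 0:
        raise ValueError("peak_area must be >= 0")
    expected = curve.expected_area(amount_loaded_nmol, through_origin=through_origin)
    if expected <= 0:
        raise CalibrationError("expected peak area is not positive")
    pct = 100.0 * peak_area / expected
    if pct > 100.0:
        warnings.warn(f"percent released {pct:.1f}% exceeds 100%; clipped at 120%")
    return float(np.clip(pct, 0.0, 120.0))


def summarize_replicates(reps: UncagingReplicates) -> ReplicateSummary:
    """Arithmetic mean and sample (n−1) sd of replicate yields."""
    y = np.asarray(reps.yields_percent, dtype=float)
    sd = 0.0 if len(y) == 1 else float(y.std(ddof=1))
    return ReplicateSummary(float(y.mean()), sd, len(y))


def power_density(power_mW: float, diameter_mm: float) -> float:
    """Beam power density in W/cm² for a circular spot."""
    if not power_mW > 0 or not diameter_mm > 0:
        raise ValueError("power and diameter must be > 0")
    radius_cm = diameter_mm / 20.0
    return (power_mW / 1000.0) / (np.pi * radius_cm**2)


def illuminated_fraction(beam_diameter_mm: float, drop_diameter_mm: float) -> float:
    """Fraction of the drop cross-section hit by the beam: (d_beam/d_drop)²."""
    if not beam_diameter_mm > 0 or not drop_diameter_mm > 0:
        raise ValueError("diameters must be > 0")
    if beam_diameter_mm > drop_diameter_mm:
        warnings.warn("beam wider than drop; fraction capped at 1")
        return 1.0
    return (beam_diameter_mm / drop_diameter_mm) ** 2


def nominal_uncaged_concentration(c0_mM: float, yield_percent: float) -> float:
    """Nominal free-ligand concentration after uncaging: c0 · yield / 100."""
    if c0_mM < 0 or yield_percent < 0:
        raise ValueError("concentration and yield must be >= 0")
    return c0_mM * yield_percent / 100.0
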