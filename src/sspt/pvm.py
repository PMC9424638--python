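"""Polarized-video-microscopy (PVM) trace analysis.

The pipeline mirrors how birefringence time-lapse videos of crystals
undergoing a solid-to-solid phase transition are quantified: crop regions
of interest, average pixels into superpixel intensity traces, smooth with a
boxcar window, differentiate, and read the transition time T1 (time of the
primary first-derivative peak) and its temporal width HWHM (half-width at
half-maximum of that peak) off each trace.  Two study designs are
implemented on top of the per-trace machinery:

* :func:`analyze_positions` — up to seven 10×10 px ROIs spread over a
  crystal, one mean trace each (positional-uniformity analysis, boxcar 65);
* :func:`roi_size_sweep` — concentric square ROIs of increasing size
  analysed per superpixel (size-dependence analysis, boxcar 39), with
  k-means classification of the resulting T1 distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import DegenerateTraceError, NoTransitionError
from .stack import FrameStack

__all__ = [
    "RegionOfInterest",
    "IntensityTrace",
    "TransitionEvent",
    "ClusterResult",
    "crop_roi",
    "mean_trace",
    "superpixel_traces",
    "boxcar_smooth",
    "normalize_trace",
    "first_derivative",
    "detect_transition",
    "analyze_positions",
    "roi_size_sweep",
    "cluster_t1",
    "choose_k",
    "hwhm_report",
]

log = logging.getLogger(__name__)

POSITIONS_WINDOW = 65  # boxcar length (frames) for the positional analysis
SIZES_WINDOW = 39      # boxcar length (frames) for the ROI-size analysis
ROI_SWEEP_SIZES_PX = (2, 4, 8, 14, 28, 42)  # ~0.1 to ~3 µm at 14 px/µm


@dataclass(frozen=True)
class RegionOfInterest:
    """Square ROI, half-open pixel convention [top, top+side) × [left, left+side)."""

    top_row: int
    left_col: int
    side_px: int
    label: str = ""

    def __post_init__(self):
        if self.side_px < 1:
            raise ValueError("side_px must be >= 1")
        if self.top_row < 0 or self.left_col < 0:
            raise ValueError("ROI origin must be non-negative")


@dataclass
class IntensityTrace:
    """A single intensity-vs-time curve (mean gray level or normalized)."""

    times_s: np.ndarray
    values: np.ndarray
    normalized: bool = False
    source: str = ""

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times_s) >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def replace(self, values, normalized=None, source=None) -> "IntensityTrace":
        return IntensityTrace(
            self.times_s,
            values,
            normalized=self.normalized if normalized is None else normalized,
            source=self.source if source is None else source,
        )


@dataclass
class TransitionEvent:
    """Descriptors of one detected transition.

    ``t1_s`` is the time of the primary first-derivative peak, ``hwhm_s``
    its half-width at half-maximum, ``direction`` +1 for rising intensity
    and −1 for falling, ``shoulder_times_s`` the times of smaller peaks
    preceding T1.  ``flags`` records quality caveats (e.g. a flank that
    never crossed half height).
    """

    t1_s: float
    hwhm_s: float
    peak_height: float
    direction: int
    shoulder_times_s: tuple = ()
    flags: tuple = ()


@dataclass
class ClusterResult:
    labels: np.ndarray
    centroids: np.ndarray
    k: int
    seed: int


# --------------------------------------------------------------- primitives


def crop_roi(stack: FrameStack, roi: RegionOfInterest) -> FrameStack:
    """Crop a square ROI out of every frame; calibration is preserved."""
    _, h, w = stack.shape
    bottom = roi.top_row + roi.side_px
    right = roi.left_col + roi.side_px
    if roi.top_row >= h or bottom > h:
        raise ValueError(f"ROI rows [{roi.top_row}, {bottom}) exceed frame height {h}")
    if roi.left_col >= w or right > w:
        raise ValueError(f"ROI cols [{roi.left_col}, {right}) exceed frame width {w}")
    return stack.with_frames(stack.frames[:, roi.top_row:bottom, roi.left_col:right])


def mean_trace(stack: FrameStack, source: str = "") -> IntensityTrace:
    """Mean gray level of every frame as one trace."""
    return IntensityTrace(
        stack.times_s, stack.frames.mean(axis=(1, 2)), source=source
    )


def _superpixel_array(stack: FrameStack, bin_px: int) -> np.ndarray:
    """(T, H//bin, W//bin) array of bin-mean intensities."""
    if bin_px not in (1, 2):
        raise ValueError("bin_px must be 1 or 2")
    t, h, w = stack.shape
    hb, wb = h // bin_px, w // bin_px
    if hb == 0 or wb == 0:
        raise ValueError(f"frame {h}x{w} too small for bin_px={bin_px}")
    if (h % bin_px) or (w % bin_px):
        log.info("dropping %d row(s) / %d col(s) not filling a %d-px bin",
                 h % bin_px, w % bin_px, bin_px)
    arr = stack.frames[:, : hb * bin_px, : wb * bin_px].astype(float)
    return arr.reshape(t, hb, bin_px, wb, bin_px).mean(axis=(2, 4))


def superpixel_traces(stack: FrameStack, bin_px: int = 1) -> list[IntensityTrace]:
    """One trace per square superpixel of side ``bin_px`` (1 or 2).

    The value of each superpixel is the arithmetic mean of its pixels; any
    trailing rows/columns that do not fill a bin are dropped (logged).
    """
    arr = _superpixel_array(stack, bin_px)
    times = stack.times_s
    return [
        IntensityTrace(times, arr[:, r, c], source=f"r{r}c{c}")
        for r in range(arr.shape[1])
        for c in range(arr.shape[2])
    ]


def boxcar_smooth(trace: IntensityTrace, window: int) -> IntensityTrace:
    """Centered moving average with reflection padding; length preserved."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    n = len(trace)
    if window > n:
        max_w = n if n % 2 == 1 else n - 1
        raise ValueError(
            f"window {window} exceeds trace length {n}; largest usable odd window is {max_w}"
        )
    if window == 1:
        return trace.replace(trace.values.copy())
    return trace.replace(uniform_filter1d(trace.values, size=window, mode="reflect"))


def normalize_trace(trace: IntensityTrace) -> IntensityTrace:
    """Min-max normalize to [0, 1]."""
    lo, hi = trace.values.min(), trace.values.max()
    if hi == lo:
        raise DegenerateTraceError("trace is constant; cannot normalize")
    return trace.replace((trace.values - lo) / (hi - lo), normalized=True)


def first_derivative(trace: IntensityTrace) -> IntensityTrace:
    """dI/dt by central differences (one-sided at the ends), per second."""
    if len(trace) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return trace.replace(np.gradient(trace.values, trace.times_s), normalized=False)


# ---------------------------------------------------------------- detection


def _interp_crossing(t0, v0, t1, v1, level):
    """Time where the segment (t0,v0)->(t1,v1) crosses ``level``."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def _refine_peak_time(t: np.ndarray, s: np.ndarray, peak_idx: int,
                      top_fraction: float = 0.75) -> float:
    """Sub-sample peak time via a quadratic fit over the top of the peak.

    Fits a parabola to the contiguous samples above ``top_fraction`` of the
    peak height.  Exact for symmetric peaks; falls back to the discrete
    argmax when fewer than 3 samples qualify or the fit is not concave.
    """
    h = s[peak_idx]
    lev = top_fraction * h
    lo = peak_idx
    while lo > 0 and s[lo - 1] >= lev:
        lo -= 1
    hi = peak_idx
    while hi < len(s) - 1 and s[hi + 1] >= lev:
        hi += 1
    if hi - lo < 2:
        return float(t[peak_idx])
    a, b, _ = np.polyfit(t[lo:hi + 1], s[lo:hi + 1], 2)
    if a >= 0:
        return float(t[peak_idx])
    return float(np.clip(-b / (2.0 * a), t[lo], t[hi]))


def _robust_tail_sd(values: np.ndarray) -> float:
    """MAD-based sd of the first and last 10% of samples (noise floor)."""
    n = len(values)
    k = max(3, n // 10)
    tails = np.concatenate([values[:k], values[-k:]])
    return 1.4826 * float(np.median(np.abs(tails - np.median(tails))))


def detect_transition(
    deriv: IntensityTrace,
    direction: str = "auto",
    shoulder_fraction: float = 0.2,
    min_shoulder_separation_s: float | None = None,
    noise_floor_factor: float = 3.0,
) -> TransitionEvent:
    """Extract T1, HWHM, and shoulder times from a first-derivative trace.

    The primary peak is the global extremum of the signed derivative in the
    transition direction (``auto`` infers the sign from the net intensity
    change); its time is refined to sub-sample precision by a quadratic fit
    over the top of the peak.  HWHM is half of the full width where the derivative crosses
    half the peak height, found by linear interpolation on each flank; if a
    flank never reaches half height within the trace, the one-sided width
    is used and the event is flagged.  Shoulders are local maxima before T1
    exceeding ``shoulder_fraction`` of the peak height.

    Raises :class:`NoTransitionError` if the peak does not exceed
    ``noise_floor_factor`` robust standard deviations of the derivative's
    tails (or the derivative has no positive excursion at all).
    """
    t = deriv.times_s
    d = deriv.values
    if direction == "auto":
        net = np.trapezoid(d, t)
        sign = 1 if net >= 0 else -1
        # fall back to the largest excursion if the integral is ~0
        if net == 0:
            sign = 1 if d[np.argmax(np.abs(d))] >= 0 else -1
    elif direction == "rise":
        sign = 1
    elif direction == "fall":
        sign = -1
    else:
        raise ValueError("direction must be 'auto', 'rise' or 'fall'")

    s = sign * d
    peak_idx = int(np.argmax(s))
    height = float(s[peak_idx])
    floor = noise_floor_factor * _robust_tail_sd(s)
    if height <= 0 or height <= floor:
        raise NoTransitionError(
            f"primary peak height {height:.4g} does not exceed noise floor {floor:.4g}"
        )

    t1 = _refine_peak_time(t, s, peak_idx)
    half = height / 2.0
    flags: list[str] = []

    left_w = right_w = None
    for i in range(peak_idx, 0, -1):
        if s[i - 1] < half <= s[i]:
            left_w = t1 - _interp_crossing(t[i - 1], s[i - 1], t[i], s[i], half)
            break
    for i in range(peak_idx, len(s) - 1):
        if s[i + 1] < half <= s[i]:
            right_w = _interp_crossing(t[i], s[i], t[i + 1], s[i + 1], half) - t1
            break
    if left_w is None and right_w is None:
        flags.append("no_half_crossing")
        hwhm = (t[-1] - t[0]) / 2.0
    elif left_w is None:
        flags.append("left_flank_missing")
        hwhm = right_w
    elif right_w is None:
        flags.append("right_flank_missing")
        hwhm = left_w
    else:
        hwhm = 0.5 * (left_w + right_w)

    dt = float(np.median(np.diff(t)))
    if min_shoulder_separation_s is None:
        min_sep = 5  # samples
    else:
        min_sep = max(1, round(min_shoulder_separation_s / dt))
    shoulders: tuple = ()
    if peak_idx > 2:
        idx, _ = find_peaks(
            s[:peak_idx], height=shoulder_fraction * height, distance=min_sep
        )
        shoulders = tuple(float(t[i]) for i in idx)

    return TransitionEvent(
        t1_s=t1,
        hwhm_s=float(hwhm),
        peak_height=height,
        direction=sign,
        shoulder_times_s=shoulders,
        flags=tuple(flags),
    )


def _trace_event(trace: IntensityTrace, window: int, **detect_kw) -> TransitionEvent:
    """The standard per-trace pipeline: boxcar -> derivative -> detect."""
    return detect_transition(first_derivative(boxcar_smooth(trace, window)), **detect_kw)


# ------------------------------------------------------------ study designs


def _summary(df: pd.DataFrame) -> dict:
    """Mean ± sample sd of T1 and HWHM over successful detections."""
    ok = df[df["error"].isna()] if "error" in df else df
    n = len(ok)
    out = {"n": n}
    for col, key in (("t1_s", "t1"), ("hwhm_s", "hwhm")):
        if n == 0:
            out[f"mean_{key}_s"] = np.nan
            out[f"sd_{key}_s"] = np.nan
        else:
            out[f"mean_{key}_s"] = float(ok[col].mean())
            out[f"sd_{key}_s"] = 0.0 if n == 1 else float(ok[col].std(ddof=1))
    if n == 1:
        out["n1_flag"] = True
    return out


def analyze_positions(
    stack: FrameStack,
    rois: list[RegionOfInterest],
    window: int = POSITIONS_WINDOW,
    **detect_kw,
) -> tuple[pd.DataFrame, dict]:
    """Positional-uniformity analysis over a set of ROIs.

    Each ROI is cropped, averaged into one trace, boxcar-smoothed
    (window 65 by default), differentiated, and its transition detected.
    Returns a per-ROI event table and a summary (mean T1 ± sd, mean HWHM ±
    sd over the ROIs that yielded a detection; ROI-level failures are
    reported per row, not raised).
    """
    if not rois:
        raise ValueError("need at least one ROI")
    records = []
    for i, roi in enumerate(rois):
        label = roi.label or f"roi{i}"
        rec = {
            "roi_label": label,
            "top_row": roi.top_row,
            "left_col": roi.left_col,
            "side_px": roi.side_px,
            "t1_s": np.nan,
            "hwhm_s": np.nan,
            "peak_height": np.nan,
            "direction": 0,
            "shoulder_times_s": "",
            "flags": "",
            "error": None,
        }
        try:
            ev = _trace_event(mean_trace(crop_roi(stack, roi), source=label),
                              window, **detect_kw)
            rec.update(
                t1_s=ev.t1_s, hwhm_s=ev.hwhm_s, peak_height=ev.peak_height,
                direction=ev.direction,
                shoulder_times_s=";".join(f"{x:g}" for x in ev.shoulder_times_s),
                flags=";".join(ev.flags),
            )
        except (NoTransitionError, ValueError) as exc:
            rec["error"] = str(exc)
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    return df, _summary(df)


def roi_size_sweep(
    stack: FrameStack,
    center: tuple[int, int],
    sizes_px=ROI_SWEEP_SIZES_PX,
    window: int = SIZES_WINDOW,
    bin_px: int = 1,
    **detect_kw,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-superpixel T1 statistics for concentric square ROIs.

    For each requested side length a square ROI centred on ``center`` is
    cropped and analysed superpixel-by-superpixel (boxcar 39 by default).
    ROIs exceeding the frame are clipped with a warning.  Returns
    ``(summary, events)``: one summary row per size (mean/sd of T1 and
    HWHM over superpixels, n=1 cases flagged) and the full per-superpixel
    event table.
    """
    _, h, w = stack.shape
    cr, cc = center
    summaries = []
    all_events = []
    for size in sizes_px:
        top = max(0, cr - size // 2)
        left = max(0, cc - size // 2)
        if top + size > h or left + size > w:
            warnings.warn(f"ROI of side {size} px clipped to frame bounds")
            top = min(top, max(0, h - size))
            left = min(left, max(0, w - size))
            size_eff = min(size, h, w)
        else:
            size_eff = size
        roi = RegionOfInterest(top, left, size_eff, label=f"size{size}")
        sub = crop_roi(stack, roi)
        arr = _superpixel_array(sub, bin_px)
        times = stack.times_s
        recs = []
        for r in range(arr.shape[1]):
            for c in range(arr.shape[2]):
                rec = {
                    "roi_size_px": size,
                    "roi_size_um": size * stack.pixel_size_um,
                    "superpixel_row": top + r * bin_px,
                    "superpixel_col": left + c * bin_px,
                    "t1_s": np.nan, "hwhm_s": np.nan, "peak_height": np.nan,
                    "direction": 0, "flags": "", "error": None,
                }
                try:
                    ev = _trace_event(
                        IntensityTrace(times, arr[:, r, c], source=f"size{size}:r{r}c{c}"),
                        window, **detect_kw,
                    )
                    rec.update(
                        t1_s=ev.t1_s, hwhm_s=ev.hwhm_s,
                        peak_height=ev.peak_height, direction=ev.direction,
                        flags=";".join(ev.flags),
                    )
                except (NoTransitionError, ValueError) as exc:
                    rec["error"] = str(exc)
                recs.append(rec)
        events = pd.DataFrame.from_records(recs)
        all_events.append(events)
        row = {"roi_size_px": size, "roi_size_um": size * stack.pixel_size_um}
        row.update(_summary(events))
        summaries.append(row)
    return pd.DataFrame(summaries), pd.concat(all_events, ignore_index=True)


# ------------------------------------------------------------ classification


def cluster_t1(values, k: int, seed: int = 0) -> ClusterResult:
    """k-means classification of transition times (k-means++, 10 restarts)."""
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(x) < k:
        raise ValueError(f"need at least k={k} values, got {len(x)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    return ClusterResult(
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_.ravel().copy(),
        k=k,
        seed=seed,
    )


def choose_k(values, k_range=(1, 2, 3, 4), seed: int = 0) -> int:
    """Pick k by silhouette score (k=1 only if no k>=2 is admissible)."""
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    best_k, best_score = 1, -np.inf
    for k in k_range:
        if k < 2 or len(x) <= k:
            continue
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(x, labels)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def hwhm_report(events: pd.DataFrame, by=("crystal", "roi_size_px")) -> pd.DataFrame:
    """Mean ± sd of HWHM tabulated per crystal and ROI size.

    ``events`` needs the grouping columns and ``hwhm_s``; rows with a
    non-null ``error`` column are ignored.  Empty input yields an empty
    table.
    """
    cols = [*by, "hwhm_s"]
    if events.empty:
        return pd.DataFrame(columns=[*by, "mean_hwhm_s", "sd_hwhm_s", "n"])
    df = events
    if "error" in df.columns:
        df = df[df["error"].isna()]
    grouped = df[cols].groupby(list(by))["hwhm_s"]
    out = grouped.agg(mean_hwhm_s="mean", sd_hwhm_s=lambda v: 0.0 if len(v) == 1 else v.std(ddof=1), n="count")
    return out.reset_index()
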