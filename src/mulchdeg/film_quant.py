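"""Image-based quantification of biodegradable-film breakdown.

A black polyester film buried in soil loses opacity as microbes eat holes
into it.  Scanning the recovered piece against a light background and
comparing its mean gray value with that of a fresh film and of the bare
background yields a *degradation ratio*:

    ratio(%) = 100 * (gray_residual - gray_fresh) / (gray_background - gray_fresh)

The ratio is 0 for an intact film, 100 for a fully disappeared one, and is
deliberately *not* clamped: scanner noise and film curl produce small
negative values in real series and those are data, not errors.

The weekly ratios of replicate film pieces are summarised as mean +/- SE and
condensed into a per-week degradation *rate* over the early, near-linear
part of the time course (weeks 1-3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FilmImage",
    "GrayCalibration",
    "DegradationMeasurement",
    "DegradationSeries",
    "load_image",
    "to_gray",
    "film_centroid",
    "mean_gray",
    "degradation_ratio",
    "summarize_replicates",
    "degradation_rate",
    "RATE_METHODS",
]

RATE_METHODS = ("endpoint", "mean3", "ols0")


@dataclass
class FilmImage:
    """A scanned film piece as an 8-bit-range grayscale raster.

    ``pixels`` holds gray values on the 0-255 scale (float allowed, e.g.
    after 16-bit rescaling or RGB averaging); ``dpi`` is kept as metadata
    only and ``id`` labels soil/week/replicate.
    """

    pixels: np.ndarray
    dpi: float = 300.0
    id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim == 3:
            arr = to_gray(arr)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("FilmImage requires a non-empty 2-D gray raster")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("gray values must lie in [0, 255]")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class GrayCalibration:
    """Reference gray values: fresh (intact) film and film-free background."""

    gray_fresh: float
    gray_background: float

    def __post_init__(self) -> None:
        for v in (self.gray_fresh, self.gray_background):
            if not 0 <= v <= 255:
                raise ValueError("calibration gray values must lie in [0, 255]")
        if self.gray_background == self.gray_fresh:
            raise ValueError(
                "background and fresh-film gray values coincide; "
                "the degradation ratio is undefined"
            )

    @property
    def threshold(self) -> float:
        """Midpoint gray value separating film from background pixels."""
        return 0.5 * (self.gray_fresh + self.gray_background)


@dataclass
class DegradationMeasurement:
    gray_residual: float
    ratio_percent: float
    week: int
    replicate: int = 0
    soil_id: str = ""


@dataclass
class DegradationSeries:
    """Weekly degradation summary for one soil: (week, mean %, SE %, n)."""

    soil_id: str
    weekly: list[tuple[int, float, float, int]] = field(default_factory=list)
    rate_percent_per_week: float | None = None
    rate_method: str | None = None

    def __post_init__(self) -> None:
        weeks = [w for w, *_ in self.weekly]
        if weeks != sorted(set(weeks)):
            raise ValueError("weeks must be strictly increasing")
        for w, m, se, n in self.weekly:
            if n < 1:
                raise ValueError(f"week {w}: n must be >= 1")
            if not math.isnan(se) and se < 0:
                raise ValueError(f"week {w}: SE must be >= 0")

    def mean_at(self, week: int) -> float:
        for w, m, _, _ in self.weekly:
            if w == week:
                return m
        raise KeyError(f"week {week} not present for soil {self.soil_id!r}")


def load_image(path, id: str = "") -> FilmImage:
    """Read an 8/16-bit grayscale or RGB TIFF/PNG as a :class:`FilmImage`.

    16-bit rasters are rescaled to the 0-255 range; RGB is collapsed to a
    single gray channel with :func:`to_gray`.
    """
    from skimage import io as skio

    arr = np.asarray(skio.imread(str(path)), dtype=float)
    if arr.ndim == 3:
        arr = to_gray(arr)
    if arr.max() > 255:  # 16-bit input
        arr = arr / 65535.0 * 255.0
    return FilmImage(pixels=arr, id=id or str(path))


def to_gray(rgb: np.ndarray, weighting: str = "mean") -> np.ndarray:
    """Collapse an (H, W, 3) array to one gray channel.

    Scanned black film is near-achromatic, so the default is the plain
    channel mean; ``weighting="luminance"`` applies Rec. 601 weights.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim == 2:
        return rgb
    channels = rgb[..., :3]
    if weighting == "luminance":
        return channels @ np.array([0.299, 0.587, 0.114])
    return channels.mean(axis=-1)


def film_centroid(image: FilmImage, threshold: float) -> tuple[int, int]:
    """Row/column centroid of below-threshold (dark, i.e. film) pixels.

    Falls back to the image centre when no pixel is darker than the
    threshold (fully degraded film).
    """
    dark = image.pixels < threshold
    if not dark.any():
        return image.shape[0] // 2, image.shape[1] // 2
    rows, cols = np.nonzero(dark)
    return int(round(rows.mean())), int(round(cols.mean()))


def mean_gray(
    image: FilmImage,
    roi_size: int = 300,
    center: tuple[int, int] | None = None,
    calibration: GrayCalibration | None = None,
) -> float:
    """Mean gray value of a square ROI containing the residual film.

    By default the ROI is centred on the centroid of dark (film) pixels,
    using ``calibration.threshold`` when a calibration is given and the
    image median otherwise; pass ``center=(row, col)`` to override.  The
    ROI is shifted, never cropped, to stay inside the image.
    """
    h, w = image.shape
    if roi_size <= 0:
        raise ValueError("roi_size must be positive")
    if roi_size > h or roi_size > w:
        raise ValueError(
            f"ROI {roi_size}x{roi_size} exceeds image dimensions {h}x{w}"
        )
    if center is None:
        thr = calibration.threshold if calibration is not None else float(
            np.median(image.pixels)
        )
        center = film_centroid(image, thr)
    r0 = int(np.clip(center[0] - roi_size // 2, 0, h - roi_size))
    c0 = int(np.clip(center[1] - roi_size // 2, 0, w - roi_size))
    roi = image.pixels[r0 : r0 + roi_size, c0 : c0 + roi_size]
    return float(roi.mean())


def degradation_ratio(gray_residual: float, cal: GrayCalibration) -> float:
    """Degradation ratio (%) from the residual-film mean gray value.

    Linear interpolation between the fresh-film gray (0 %) and the
    background gray (100 %); values outside [0, 100] pass through
    unclamped.
    """
    denom = cal.gray_background - cal.gray_fresh
    return 100.0 * (gray_residual - cal.gray_fresh) / denom


def summarize_replicates(ratios: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sample SD / sqrt(n)) of replicate ratios.

    With a single replicate the SE is undefined and returned as NaN.
    """
    arr = np.asarray(ratios, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one replicate ratio is required")
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, float("nan")
    se = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, se


def degradation_rate(
    series: DegradationSeries | dict[int, float],
    method: str = "endpoint",
) -> float:
    """Per-week degradation rate over the early (weeks 1-3) time course.

    Methods (all % per week; the early phase is near-linear so they agree
    on exactly linear data):

    - ``endpoint``: week-3 mean ratio / 3 (default; average weekly gain).
    - ``mean3``: arithmetic mean of the week-1..3 ratios.
    - ``ols0``: least-squares slope through the origin on weeks 0-3 with
      the week-0 ratio fixed at 0.
    """
    if method not in RATE_METHODS:
        raise ValueError(f"unknown rate method {method!r}; choose from {RATE_METHODS}")
    if isinstance(series, DegradationSeries):
        means = {w: m for w, m, _, _ in series.weekly}
    else:
        means = dict(series)
    missing = [w for w in (1, 2, 3) if w not in means]
    if missing:
        raise ValueError(f"rate requires weeks 1-3; missing {missing}")
    y1, y2, y3 = means[1], means[2], means[3]
    if method == "endpoint":
        return y3 / 3.0
    if method == "mean3":
        return (y1 + y2 + y3) / 3.0
    # ols0: minimise sum_w (y_w - b*w)^2 over weeks 0..3, y_0 = 0
    return (1 * y1 + 2 * y2 + 3 * y3) / (1 + 4 + 9)


def quantify_series(
    measurements: Sequence[DegradationMeasurement],
    soil_id: str,
    rate_method: str = "endpoint",
) -> DegradationSeries:
    """Aggregate per-replicate measurements into a weekly series + rate."""
    by_week: dict[int, list[float]] = {}
    for m in measurements:
        by_week.setdefault(m.week, []).append(m.ratio_percent)
    weekly = []
    for w in sorted(by_week):
        mean, se = summarize_replicates(by_week[w])
        weekly.append((w, mean, se, len(by_week[w])))
    series = DegradationSeries(soil_id=soil_id, weekly=weekly)
    if all(w in by_week for w in (1, 2, 3)):
        series.rate_percent_per_week = degradation_rate(series, rate_method)
        series.rate_method = rate_method
    return series
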