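"""Quantitative assay computations for trafficking experiments.

Covers the downstream measurements used to characterize surface
localization and proliferation phenotypes of channel constructs:

* two-channel colocalization (Pearson's correlation over a foreground
  mask, and colocalization rate = % of foreground area where both
  channels exceed threshold);
* lane densitometry (per-band signal as a percentage of total declared
  lane signal, non-declared regions excluded);
* growth curves (doubling time from exponential-phase counts, either
  two-point or log-linear regression);
* dead-cell fraction and MTT percent-of-control normalization.

Statistical comparisons across conditions (ANOVA etc.) are out of
scope; outputs are tidy records ready for any stats package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger(__name__)


class AssayError(ValueError):
    """Raised for invalid assay inputs."""


# ---------------------------------------------------------------- imaging

@dataclass
class ChannelPair:
    """Two equal-shape non-negative intensity images with thresholds.

    ``mask_rule`` selects the evaluation mask for both metrics:
    ``"union"`` (default; foreground = above threshold in either
    channel), ``"intersection"``, or ``"whole_image"``.  The rule is
    explicit and recorded in output because acquisition software does
    not publish its masking.
    """

    channel_a: np.ndarray
    channel_b: np.ndarray
    threshold_a: float = 0.0
    threshold_b: float = 0.0
    mask_rule: str = "union"

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        if self.channel_a.shape != self.channel_b.shape:
            raise AssayError(
                f"channel shapes differ: {self.channel_a.shape} vs "
                f"{self.channel_b.shape}")
        if (self.channel_a < 0).any() or (self.channel_b < 0).any():
            raise AssayError("negative intensities")
        if self.threshold_a < 0 or self.threshold_b < 0:
            raise AssayError("thresholds must be >= 0")
        if self.mask_rule not in ("union", "intersection", "whole_image"):
            raise AssayError(f"unknown mask rule {self.mask_rule!r}")


@dataclass(frozen=True)
class ColocResult:
    """Colocalization metrics over the foreground mask.

    ``pearson_r`` is ``None`` when undefined (fewer than two foreground
    pixels or zero variance in a channel) — never silently 0.
    """

    pearson_r: float | None
    coloc_rate_percent: float
    foreground_pixels: int
    coloc_pixels: int
    mask_rule: str
    pearson_undefined_reason: str | None = None
    empty_foreground: bool = False


def pearson_coloc(pair: ChannelPair) -> ColocResult:
    """Pearson correlation and colocalization rate for a channel pair.

    Foreground follows ``pair.mask_rule`` over the per-channel
    threshold masks (strictly above threshold).  Colocalized pixels are
    above threshold in *both* channels; the rate is
    100 * colocalized / foreground (0 with a flag when the foreground
    is empty).
    """
    above_a = pair.channel_a > pair.threshold_a
    above_b = pair.channel_b > pair.threshold_b
    if pair.mask_rule == "union":
        mask = above_a | above_b
    elif pair.mask_rule == "intersection":
        mask = above_a & above_b
    else:
        mask = np.ones_like(above_a, dtype=bool)

    foreground = int(mask.sum())
    coloc = int((above_a & above_b).sum())
    if foreground == 0:
        return ColocResult(pearson_r=None, coloc_rate_percent=0.0,
                           foreground_pixels=0, coloc_pixels=0,
                           mask_rule=pair.mask_rule,
                           pearson_undefined_reason="empty foreground",
                           empty_foreground=True)
    rate = 100.0 * coloc / foreground

    a, b = pair.channel_a[mask], pair.channel_b[mask]
    reason = None
    if foreground < 2:
        r, reason = None, "fewer than 2 foreground pixels"
    elif np.ptp(a) == 0 or np.ptp(b) == 0:
        r, reason = None, "zero variance in a channel"
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return ColocResult(pearson_r=r, coloc_rate_percent=rate,
                       foreground_pixels=foreground, coloc_pixels=coloc,
                       mask_rule=pair.mask_rule,
                       pearson_undefined_reason=reason)


# ----------------------------------------------------------- densitometry

@dataclass
class LaneProfile:
    """A densitometric intensity profile along one gel/blot lane.

    ``band_windows`` are labelled inclusive position intervals declaring
    the bands of interest (e.g. monomer / intermediate / hexamer);
    regions outside them are treated as excluded non-specific signal.
    """

    positions: np.ndarray
    intensity: np.ndarray
    band_windows: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.positions.shape != self.intensity.shape:
            raise AssayError("positions and intensity lengths differ")
        if not np.all(np.diff(self.positions) > 0):
            raise AssayError("positions must be strictly increasing")
        if (self.intensity < 0).any():
            raise AssayError("negative intensities")
        windows = sorted(self.band_windows, key=lambda w: w[1])
        for (_, lo, hi) in windows:
            if lo > hi:
                raise AssayError(f"band window {lo}..{hi} inverted")
        for (_, _, hi_prev), (_, lo_next, _) in zip(windows, windows[1:]):
            if lo_next <= hi_prev:
                raise AssayError("band windows overlap")
        pmin, pmax = self.positions[0], self.positions[-1]
        for (_, lo, hi) in windows:
            if hi < pmin or lo > pmax:
                raise AssayError(
                    f"band window {lo}..{hi} outside profile range "
                    f"{pmin}..{pmax}")


@dataclass(frozen=True)
class BandQuant:
    """Per-band signal and percent of declared lane total."""

    bands: tuple[tuple[str, float, float], ...]  # (label, signal, percent)
    lane_total: float
    baseline: str


def quantify_lane(profile: LaneProfile, baseline: str = "none",
                  baseline_window: int | None = None) -> BandQuant:
    """Quantify each declared band as a percentage of total lane signal.

    The lane total sums baseline-subtracted intensity over the declared
    band windows only — non-specific regions never contribute.
    ``baseline="rolling_min"`` subtracts a rolling-minimum background
    (window in sample points); subtracted values are clipped at zero.
    """
    if not profile.band_windows:
        raise AssayError("at least one band window required")
    signal = profile.intensity
    if baseline == "rolling_min":
        if not baseline_window or baseline_window < 1:
            raise AssayError("rolling_min baseline needs a positive window")
        background = ndimage.minimum_filter1d(signal, size=baseline_window,
                                              mode="nearest")
        signal = np.clip(signal - background, 0.0, None)
    elif baseline != "none":
        raise AssayError(f"unknown baseline mode {baseline!r}")

    per_band = []
    for label, lo, hi in profile.band_windows:
        sel = (profile.positions >= lo) & (profile.positions <= hi)
        if not sel.any():
            logger.warning("band %r window %s..%s contains no samples",
                           label, lo, hi)
        per_band.append((label, float(signal[sel].sum())))
    lane_total = sum(s for _, s in per_band)
    bands = tuple(
        (label, s, 100.0 * s / lane_total if lane_total > 0 else 0.0)
        for label, s in per_band
    )
    return BandQuant(bands=bands, lane_total=lane_total, baseline=baseline)


# ---------------------------------------------------------------- growth

@dataclass
class GrowthSeries:
    """Cell counts over time (hours), with optional MTT optical densities."""

    times: np.ndarray
    live_counts: np.ndarray
    dead_counts: np.ndarray | None = None
    od_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.live_counts = np.asarray(self.live_counts, dtype=float)
        if self.dead_counts is None:
            self.dead_counts = np.zeros_like(self.live_counts)
        self.dead_counts = np.asarray(self.dead_counts, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise AssayError("times must be strictly increasing")
        if self.live_counts.shape != self.times.shape \
                or self.dead_counts.shape != self.times.shape:
            raise AssayError("count vectors must match times in length")
        if (self.live_counts < 0).any() or (self.dead_counts < 0).any():
            raise AssayError("negative counts")

    @classmethod
    def from_csv(cls, path) -> "GrowthSeries":
        """Read a CSV with columns ``time_h, live[, dead]``."""
        df = pd.read_csv(path)
        if "time_h" not in df or "live" not in df:
            raise AssayError(f"{path}: need columns time_h, live")
        return cls(times=df["time_h"].to_numpy(),
                   live_counts=df["live"].to_numpy(),
                   dead_counts=df["dead"].to_numpy() if "dead" in df else None)


@dataclass(frozen=True)
class GrowthResult:
    """Doubling-time estimate over a chosen window of the growth curve."""

    doubling_time_hours: float | None
    window_used: tuple[int, int]
    mode: str
    undefined_reason: str | None = None


def doubling_time(series: GrowthSeries, window: tuple[int, int],
                  mode: str = "two_point") -> GrowthResult:
    """Doubling time from exponential-phase counts.

    Two-point mode: DT = (t_j - t_i) * ln 2 / ln(N_j / N_i), with the
    later count in the numerator so growth gives a positive DT.
    Regression mode fits ln N against t over all points in the window
    (>= 3 required) and returns ln 2 / slope.  Non-increasing or zero
    counts make the estimate undefined, with the reason reported.
    """
    i, j = window
    n = len(series.times)
    if not (0 <= i < j <= n - 1):
        raise AssayError(f"window indices {window} invalid for {n} time points")
    if mode == "two_point":
        ni, nj = series.live_counts[i], series.live_counts[j]
        if ni <= 0 or nj <= 0:
            return GrowthResult(None, window, mode, "zero count in window")
        if nj <= ni:
            return GrowthResult(None, window, mode,
                                "counts not increasing over window")
        dt = (series.times[j] - series.times[i]) * math.log(2) / math.log(nj / ni)
        return GrowthResult(float(dt), window, mode)
    if mode == "regression":
        t = series.times[i:j + 1]
        counts = series.live_counts[i:j + 1]
        if len(t) < 3:
            raise AssayError("regression mode needs >= 3 points in the window")
        if (counts <= 0).any():
            return GrowthResult(None, window, mode, "zero count in window")
        fit = stats.linregress(t, np.log(counts))
        if fit.slope <= 0:
            return GrowthResult(None, window, mode, "non-positive growth slope")
        return GrowthResult(float(math.log(2) / fit.slope), window, mode)
    raise AssayError(f"unknown doubling-time mode {mode!r}")


def dead_fraction(series: GrowthSeries) -> np.ndarray:
    """Dead cells as percent of total (live + dead) per time point.

    Returns NaN where the total is zero (undefined, not 0).
    """
    total = series.live_counts + series.dead_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * series.dead_counts / total, np.nan)
    return pct


def mtt_normalize(values, control_values) -> np.ndarray:
    """Express optical densities as percent of the mean control OD."""
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    mean_control = control.mean()
    if not mean_control > 0:
        raise AssayError("control mean must be positive")
    return 100.0 * values / mean_control
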