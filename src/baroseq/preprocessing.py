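"""Artifact removal and zero-phase low/high-pass band splitting.

Artifact cleaning follows the moving-median scheme used for rat beat series:
a centered moving median of the series (default window 50 beats) defines a
baseline, and any beat whose SAP or PI leaves the band
``baseline * (1 ± p)`` (default p = 0.10, valid range 0.05–0.20) is dropped
from both series.  On stable recordings removals stay well under 1% of
beats; a larger fraction triggers a warning because it usually means the
recording is unstable rather than merely noisy.

Band splitting separates the slow (Mayer-wave, sympathetic) and fast
(respiratory) components of SAP and PI.  Since a Hz-domain cutoff only makes
sense on an evenly sampled signal, the beat series is cubic-spline
interpolated onto a uniform grid (default 10 Hz), filtered with a zero-phase
(forward-backward) Butterworth filter (default 9th order, 0.8 Hz cutoff),
and sampled back at the original beat times.  Zero-phase filtering keeps
ramps aligned with the original beats; its effective magnitude response is
the square of the single-pass response, so the half-power cutoff passes
amplitude 0.5 and the low- plus high-pass outputs reconstruct the input
(Butterworth low/high pairs are power-complementary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .series import BeatSeries

__all__ = [
    "PreprocessConfig",
    "ArtifactReport",
    "moving_median_baseline",
    "remove_artifacts",
    "band_split",
]


@dataclass
class PreprocessConfig:
    """Parameters of artifact cleaning and band splitting.

    median_window : beats in the centered moving-median baseline (>= 3; made
        odd by incrementing when even).
    p : relative artifact threshold; a beat is removed when SAP or PI leaves
        ``baseline * (1 ± p)``.  Values outside 0.05–0.20 require
        ``allow_extreme_p=True``.
    filter_order : Butterworth order for band splitting.
    cutoff_hz : low/high split frequency in Hz.
    resample_fs : uniform-grid rate in Hz used for filtering (cutoff must be
        below its Nyquist frequency).
    """

    median_window: int = 50
    p: float = 0.10
    filter_order: int = 9
    cutoff_hz: float = 0.8
    resample_fs: float = 10.0
    allow_extreme_p: bool = False

    def __post_init__(self) -> None:
        if self.median_window < 3:
            raise ValueError("median_window must be >= 3")
        if self.median_window % 2 == 0:
            self.median_window += 1  # centered window needs odd length
        if not (0.05 <= self.p <= 0.20) and not self.allow_extreme_p:
            raise ValueError(
                f"p={self.p} outside the recommended 0.05–0.20 range; "
                "set allow_extreme_p=True to override"
            )
        if self.p < 0:
            raise ValueError("p must be non-negative")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.resample_fs <= 0:
            raise ValueError("resample_fs must be positive")
        if self.cutoff_hz <= 0 or self.cutoff_hz >= self.resample_fs / 2:
            raise ValueError(
                f"cutoff_hz={self.cutoff_hz} must lie in (0, resample_fs/2)"
            )


@dataclass
class ArtifactReport:
    n_input: int
    removed_indices: np.ndarray
    removed_fraction: float


def moving_median_baseline(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving median, window truncated symmetrically at the edges.

    At index ``i`` the median is taken over ``values[i-k : i+k+1]`` with
    ``k = min(window//2, i, n-1-i)``, so the window shrinks near the edges
    but stays centered.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if window < 1:
        raise ValueError("window must be >= 1")
    if n < window:
        raise ValueError(f"series length {n} shorter than median window {window}")
    half = window // 2
    out = np.empty(n)
    if n >= window and half > 0:
        interior = np.lib.stride_tricks.sliding_window_view(values, 2 * half + 1)
        out[half : n - half] = np.median(interior, axis=1)
    else:
        out[:] = values
    for i in range(min(half, n)):
        k = min(half, i, n - 1 - i)
        out[i] = np.median(values[i - k : i + k + 1])
    for i in range(max(n - half, 0), n):
        k = min(half, i, n - 1 - i)
        out[i] = np.median(values[i - k : i + k + 1])
    return out


def remove_artifacts(
    sap: BeatSeries, pi: BeatSeries, cfg: PreprocessConfig | None = None
) -> tuple[BeatSeries, BeatSeries, ArtifactReport]:
    """Drop beats whose SAP or PI strays more than ``p`` from the moving-median baseline.

    A flagged beat is removed from *both* series so they stay aligned, and
    ``gap_after`` is set on the surviving predecessor of each removal run.
    Thresholds come from the baselines of the original (input) series in a
    single pass; they are not recomputed after removals.
    """
    cfg = cfg or PreprocessConfig()
    if len(sap) == 0 or len(pi) == 0:
        raise ValueError("cannot clean an empty series")
    if len(sap) != len(pi):
        raise ValueError("SAP and PI series must be aligned (equal length)")

    base_sap = moving_median_baseline(sap.values, cfg.median_window)
    base_pi = moving_median_baseline(pi.values, cfg.median_window)
    p = cfg.p
    bad = (
        (sap.values > base_sap * (1 + p))
        | (sap.values < base_sap * (1 - p))
        | (pi.values > base_pi * (1 + p))
        | (pi.values < base_pi * (1 - p))
    )
    removed = np.where(bad)[0]
    keep = np.where(~bad)[0]
    if len(keep) == 0:
        raise ValueError("artifact removal rejected every beat; check p and the input")

    frac = len(removed) / len(sap)
    if frac > 0.01:
        warnings.warn(
            f"artifact removal dropped {frac:.1%} of beats (> 1%); "
            "recording may be unstable",
            stacklevel=2,
        )

    sap_c = sap.take(keep)
    pi_c = pi.take(keep)
    if len(keep) > 1:
        gap_new = np.diff(keep) > 1
        sap_c.gap_after[:-1] |= gap_new
        pi_c.gap_after[:-1] |= gap_new
    return sap_c, pi_c, ArtifactReport(len(sap), removed, frac)


def band_split(
    series: BeatSeries, cfg: PreprocessConfig | None = None, mode: str = "low"
) -> BeatSeries:
    """Zero-phase Butterworth low- or high-pass of a beat series.

    Pipeline: cubic-spline the beat values onto a uniform grid at
    ``cfg.resample_fs``; ``sosfiltfilt`` a zero-phase Butterworth low-pass of
    ``cfg.filter_order`` at ``cfg.cutoff_hz``; spline the filtered grid back
    onto the original beat times.  ``mode="low"`` returns that series;
    ``mode="high"`` returns the residual (input minus the low-pass output),
    which realizes exactly the power-complementary zero-phase high-pass
    response (for Butterworth, 1 − |H_lp|² = |H_hp|², and zero-phase
    responses are real), so low + high reconstructs the input identically.
    """
    cfg = cfg or PreprocessConfig()
    if mode not in ("low", "high"):
        raise ValueError("mode must be 'low' or 'high'")
    n_min = 3 * cfg.filter_order
    if len(series) < n_min:
        raise ValueError(f"need at least {n_min} beats to band-split, got {len(series)}")
    min_duration = 3.0 / cfg.cutoff_hz
    if series.duration < min_duration:
        raise ValueError(
            f"series spans {series.duration:.1f} s; need >= {min_duration:.1f} s "
            f"(a few cutoff periods) for a meaningful {cfg.cutoff_hz} Hz split"
        )

    fs = cfg.resample_fs
    t0, t_end = series.t[0], series.t[-1]
    n_grid = int(np.floor((t_end - t0) * fs)) + 1
    grid = t0 + np.arange(n_grid) / fs
    uniform = CubicSpline(series.t, series.values)(grid)

    sos = butter(cfg.filter_order, cfg.cutoff_hz, btype="low", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, uniform)

    # back to beat times; the last beat may sit < 1/fs past the grid end,
    # where the spline extrapolates smoothly
    low = CubicSpline(grid, filtered)(series.t)
    out = low if mode == "low" else series.values - low
    return series.with_values(out, label=f"{series.label} ({mode}-pass)")
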