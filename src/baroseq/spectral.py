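"""Cross-spectral baroreflex gain: Welch transfer function SAP -> PI with coherence gating.

The beat series are cubic-spline interpolated to an even 10 Hz grid, split
into half-overlapping Hann-windowed segments (default 4096 samples), and the
auto- and cross-spectra are averaged over segments (Welch).  The transfer
gain is ``|S_pi,sap| / S_sap,sap`` (ms/mmHg per frequency bin) and the
magnitude-squared coherence ``|S_pi,sap|^2 / (S_sap S_pi)`` gates which bins
are trusted: the band gain in the low- (0.2–0.8 Hz) and high-frequency
(0.8–3.0 Hz) bands of rat cardiovascular variability is the unweighted mean
of the per-bin gain over bins whose coherence exceeds 0.5.

For short (desk-scale) series the segment length falls back to the largest
power of two allowing at least two half-overlapping segments, with a warning:
averaged coherence needs more than one segment to mean anything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import csd, welch

from .series import BeatSeries, UniformSeries

__all__ = [
    "SpectralParams",
    "TransferResult",
    "interpolate_uniform",
    "welch_transfer",
    "band_gain",
]


def _is_power_of_two(n: int) -> bool:
    return n > 0 and (n & (n - 1)) == 0


@dataclass
class SpectralParams:
    """Welch cross-spectrum parameters.

    fs : interpolation rate (Hz).
    nperseg : samples per Welch segment (power of two); segments overlap by
        half their length and are Hann windowed.
    lf_band / hf_band : Hz intervals; lower edge inclusive, upper exclusive,
        so the 0.8 Hz boundary bin belongs to HF.
    coherence_min : per-bin gate for band gains.
    """

    fs: float = 10.0
    nperseg: int = 4096
    lf_band: tuple[float, float] = (0.2, 0.8)
    hf_band: tuple[float, float] = (0.8, 3.0)
    coherence_min: float = 0.5
    window: str = "hann"
    overlap: float = 0.5  # fixed half-overlap (Welch protocol)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not _is_power_of_two(self.nperseg):
            raise ValueError("nperseg must be a power of two")
        nyq = self.fs / 2
        for name, (lo, hi) in (("lf_band", self.lf_band), ("hf_band", self.hf_band)):
            if not (0 <= lo < hi <= nyq):
                raise ValueError(f"{name}={lo, hi} must satisfy 0 <= lo < hi <= fs/2")
        if not (self.lf_band[1] <= self.hf_band[0] or self.hf_band[1] <= self.lf_band[0]):
            raise ValueError("lf_band and hf_band must be disjoint")
        if not (0 < self.coherence_min < 1):
            raise ValueError("coherence_min must lie in (0, 1)")
        if self.overlap != 0.5:
            raise ValueError("segment overlap is fixed at 0.5")


@dataclass
class TransferResult:
    """Per-bin transfer estimate plus coherence-gated band gains."""

    freqs: np.ndarray
    sap_psd: np.ndarray  # mmHg^2/Hz
    pi_psd: np.ndarray  # ms^2/Hz
    cross: np.ndarray  # complex, conj(SAP)*PI convention
    gain: np.ndarray  # ms/mmHg, |cross|/sap_psd
    phase: np.ndarray  # radians, PI relative to SAP
    coherence: Optional[np.ndarray]  # None when only one segment
    n_segments: int
    nperseg: int
    band_gain_lf: Optional[float] = None
    band_gain_hf: Optional[float] = None


def interpolate_uniform(series: BeatSeries, fs: float = 10.0) -> UniformSeries:
    """Cubic-spline the beat series onto an even grid; no extrapolation.

    The grid starts at the first beat time and steps 1/fs up to (not past)
    the last beat time.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if len(series) < 4:
        raise ValueError("need at least 4 beats for cubic-spline interpolation")
    t0, t_end = series.t[0], series.t[-1]
    n = int(np.floor((t_end - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    vals = CubicSpline(series.t, series.values)(grid)
    return UniformSeries(fs=fs, t0=t0, values=vals)


def _effective_nperseg(n: int, nperseg: int) -> int:
    """Largest usable segment length guaranteeing >= 2 half-overlapping segments."""
    if n >= 2 * nperseg:
        return nperseg
    target = max(n // 2, 4)
    eff = 1 << (target.bit_length() - 1)  # largest power of two <= n//2
    warnings.warn(
        f"series of {n} samples is short for nperseg={nperseg}; "
        f"falling back to nperseg={eff}",
        stacklevel=3,
    )
    return eff


def welch_transfer(
    sap_u: UniformSeries, pi_u: UniformSeries, params: SpectralParams | None = None
) -> TransferResult:
    """Welch-averaged transfer function and coherence between SAP and PI."""
    params = params or SpectralParams()
    if len(sap_u) != len(pi_u):
        raise ValueError("uniform series must have equal length")
    if sap_u.fs != pi_u.fs:
        raise ValueError("uniform series must share the sampling rate")
    n = len(sap_u)
    if n < 8:
        raise ValueError("series too short for spectral estimation")
    nperseg = _effective_nperseg(n, params.nperseg)
    noverlap = nperseg // 2
    kw = dict(
        fs=sap_u.fs,
        window=params.window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
    )
    x, y = sap_u.values, pi_u.values
    freqs, pxx = welch(x, **kw)
    _, pyy = welch(y, **kw)
    _, pxy = csd(x, y, **kw)

    n_segments = (n - nperseg) // (nperseg - noverlap) + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.abs(pxy) / pxx
        coh = np.abs(pxy) ** 2 / (pxx * pyy)
    gain = np.where(pxx > 0, gain, np.nan)
    coherence = None
    if n_segments >= 2:
        coherence = np.clip(np.where((pxx > 0) & (pyy > 0), coh, np.nan), 0.0, 1.0)
    else:
        warnings.warn(
            "single Welch segment: coherence is undefined (identically 1)",
            stacklevel=2,
        )

    result = TransferResult(
        freqs=freqs,
        sap_psd=pxx,
        pi_psd=pyy,
        cross=pxy,
        gain=gain,
        phase=np.angle(pxy),
        coherence=coherence,
        n_segments=n_segments,
        nperseg=nperseg,
    )
    result.band_gain_lf = band_gain(result, params.lf_band, params.coherence_min)
    result.band_gain_hf = band_gain(result, params.hf_band, params.coherence_min)
    return result


def band_gain(
    result: TransferResult,
    band: tuple[float, float],
    coherence_min: float = 0.5,
) -> Optional[float]:
    """Mean transfer gain over band bins with coherence above the gate.

    Band edges: lower inclusive, upper exclusive.  Returns None (with a
    warning) when coherence is unavailable or no bin qualifies.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must be a non-empty interval")
    if hi > result.freqs[-1] or lo < result.freqs[0]:
        raise ValueError(
            f"band {band} outside the frequency grid "
            f"[{result.freqs[0]}, {result.freqs[-1]}]"
        )
    if result.coherence is None:
        warnings.warn("coherence undefined; band gain unavailable", stacklevel=2)
        return None
    in_band = (result.freqs >= lo) & (result.freqs < hi)
    ok = in_band & np.isfinite(result.gain) & (result.coherence > coherence_min)
    if not np.any(ok):
        warnings.warn(
            f"no bin in band {band} with coherence > {coherence_min}", stacklevel=2
        )
        return None
    return float(result.gain[ok].mean())
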