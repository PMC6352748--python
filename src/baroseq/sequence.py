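"""Sequence-method baroreflex analysis: SAP ramps, delayed PI matching, BRS and BEI.

A *ramp* is a maximal run of consecutive beats whose SAP changes all have the
same sign and each exceed the SAP threshold in magnitude (default 0, i.e. any
change counts; ties break a ramp).  A ramp becomes a *baroreflex sequence*
when the PI segment starting ``d`` beats later, of the same length, varies in
the same direction: operationally, when the Pearson correlation between the
ramp's SAP values and the delayed PI values reaches ``r_min`` (default 0.8)
and the regression slope of PI on SAP is positive.  The slope is the
sequence's gain in ms/mmHg; the subject's baroreflex sensitivity (BRS) is the
unweighted mean slope over all accepted sequences (up and down pooled), and
the baroreflex effectiveness index (BEI) is the fraction of evaluable ramps
that were accepted.

Ramps whose delayed PI segment runs off the end of the series or spans a gap
left by artifact removal cannot be evaluated at that delay; they are excluded
from both the numerator and the denominator of BEI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .series import BeatSeries

__all__ = [
    "SequenceParams",
    "Ramp",
    "SequenceMatch",
    "SequenceMethodResult",
    "detect_ramps",
    "find_sequences",
    "delay_sweep",
    "length_sweep",
    "sweep_frame",
    "bei_peak_spacings",
]


@dataclass
class SequenceParams:
    """Knobs of the sequence method.

    n : minimum ramp length in beats (>= 2; values below 3 warn, since the
        method is normally run with at least 3-beat ramps).
    r_min : minimum Pearson correlation between SAP ramp and PI segment.
    delay : offset in beats between ramp start and PI segment start.
    sap_threshold : minimum per-beat SAP change inside a ramp (mmHg; strict).
    pi_threshold : minimum per-beat PI change magnitude in the matched
        segment (ms).  At the default 0 no PI-step constraint is applied at
        all (any PI course may match, provided r and slope qualify).
    """

    n: int = 3
    r_min: float = 0.8
    delay: int = 0
    sap_threshold: float = 0.0
    pi_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("minimum sequence length n must be >= 2")
        if self.n == 2:
            warnings.warn("n=2 is below the recommended minimum of 3", stacklevel=2)
        if not (0 < self.r_min <= 1):
            raise ValueError("r_min must lie in (0, 1]")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.sap_threshold < 0 or self.pi_threshold < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class Ramp:
    """Maximal monotone SAP run: beats ``start .. start+length-1``."""

    start: int
    length: int
    direction: int  # +1 up, -1 down


@dataclass(frozen=True)
class SequenceMatch:
    ramp: Ramp
    delay: int
    slope: float  # ms/mmHg
    pearson_r: float


@dataclass
class SequenceMethodResult:
    """Per-delay sequence-method summary."""

    delay: int
    n_ramps_total: int
    n_ramps_evaluable: int
    n_sequences: int
    bei: float | None
    brs_mean: float | None
    brs_sd: float | None
    matches: list[SequenceMatch] = field(default_factory=list)
    min_len: int = 3


def detect_ramps(
    series: BeatSeries, min_len: int = 3, threshold: float = 0.0
) -> list[Ramp]:
    """All maximal same-direction runs of length >= ``min_len``.

    A step from beat i to i+1 belongs to a run when ``|Δ| > threshold``
    (strict, so equal consecutive values always break a ramp) and no gap
    separates the two beats.  Up and down ramps are both returned, in order
    of their start index.
    """
    v = series.values
    n = len(v)
    if n < min_len:
        return []
    d = np.diff(v)
    sign = np.where(d > threshold, 1, np.where(d < -threshold, -1, 0))
    sign[series.gap_after[:-1]] = 0  # a gap breaks any run

    ramps: list[Ramp] = []
    i = 0
    while i < n - 1:
        s = sign[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j < n - 1 and sign[j] == s:
            j += 1
        length = j - i + 1  # beats, not steps
        if length >= min_len:
            ramps.append(Ramp(start=i, length=length, direction=int(s)))
        i = j
    return ramps


def _evaluate_ramp(
    sap_v: np.ndarray,
    pi_v: np.ndarray,
    gap: np.ndarray,
    ramp: Ramp,
    delay: int,
    params: SequenceParams,
) -> tuple[bool, SequenceMatch | None]:
    """(evaluable, accepted match or None) for one ramp at one delay."""
    n = len(pi_v)
    s, L = ramp.start, ramp.length
    p0 = s + delay
    if p0 + L > n:
        return False, None
    # PI segment must not span a gap (internal transitions gap-free)
    if L > 1 and np.any(gap[p0 : p0 + L - 1]):
        return False, None

    x = sap_v[s : s + L]
    y = pi_v[p0 : p0 + L]

    if params.pi_threshold > 0:
        if np.any(np.abs(np.diff(y)) <= params.pi_threshold):
            return True, None

    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if syy == 0.0:  # flat PI segment: correlation undefined -> no sequence
        return True, None
    r = sxy / math.sqrt(sxx * syy)
    slope = sxy / sxx
    if r >= params.r_min and slope > 0:
        return True, SequenceMatch(ramp=ramp, delay=delay, slope=slope, pearson_r=r)
    return True, None


def _result_for_delay(
    sap: BeatSeries,
    pi: BeatSeries,
    ramps: list[Ramp],
    delay: int,
    params: SequenceParams,
) -> SequenceMethodResult:
    gap = pi.gap_after
    matches: list[SequenceMatch] = []
    n_eval = 0
    for ramp in ramps:
        evaluable, match = _evaluate_ramp(sap.values, pi.values, gap, ramp, delay, params)
        if evaluable:
            n_eval += 1
            if match is not None:
                matches.append(match)
    slopes = np.array([m.slope for m in matches])
    return SequenceMethodResult(
        delay=delay,
        n_ramps_total=len(ramps),
        n_ramps_evaluable=n_eval,
        n_sequences=len(matches),
        bei=(len(matches) / n_eval) if n_eval else None,
        brs_mean=float(slopes.mean()) if len(slopes) else None,
        brs_sd=float(slopes.std(ddof=1)) if len(slopes) > 1 else None,
        matches=matches,
        min_len=params.n,
    )


def find_sequences(
    sap: BeatSeries, pi: BeatSeries, params: SequenceParams | None = None
) -> SequenceMethodResult:
    """Run the sequence method at the single delay in ``params``."""
    params = params or SequenceParams()
    if len(sap) != len(pi):
        raise ValueError("SAP and PI series must be aligned (equal length)")
    ramps = detect_ramps(sap, min_len=params.n, threshold=params.sap_threshold)
    return _result_for_delay(sap, pi, ramps, params.delay, params)


def delay_sweep(
    sap: BeatSeries,
    pi: BeatSeries,
    params: SequenceParams | None = None,
    delays: range | list[int] = range(0, 13),
) -> list[SequenceMethodResult]:
    """Sequence method at each delay (default 0..12); ramps are detected once."""
    params = params or SequenceParams()
    if len(sap) != len(pi):
        raise ValueError("SAP and PI series must be aligned (equal length)")
    ramps = detect_ramps(sap, min_len=params.n, threshold=params.sap_threshold)
    return [_result_for_delay(sap, pi, ramps, int(d), params) for d in delays]


def length_sweep(
    sap: BeatSeries,
    pi: BeatSeries,
    params: SequenceParams | None = None,
    n_values: range | list[int] = range(3, 10),
) -> list[SequenceMethodResult]:
    """Sequence method at the params' delay for each minimum ramp length n.

    Ramp and sequence counts are non-increasing in n (longer minimum length
    only discards ramps).
    """
    params = params or SequenceParams()
    out = []
    for n in n_values:
        out.append(find_sequences(sap, pi, replace(params, n=int(n))))
    return out


def sweep_frame(results: list[SequenceMethodResult], key: str = "delay") -> pd.DataFrame:
    """Tabulate sweep results (key column is 'delay' or 'n')."""
    rows = []
    for r in results:
        rows.append(
            {
                key: r.delay if key == "delay" else r.min_len,
                "n_ramps": r.n_ramps_total,
                "n_ramps_evaluable": r.n_ramps_evaluable,
                "n_sequences": r.n_sequences,
                "bei": np.nan if r.bei is None else r.bei,
                "brs_mean": np.nan if r.brs_mean is None else r.brs_mean,
                "brs_sd": np.nan if r.brs_sd is None else r.brs_sd,
            }
        )
    return pd.DataFrame(rows)


def bei_peak_spacings(bei: np.ndarray | list[float]) -> list[int]:
    """Spacings (in delay steps) between interior local maxima of BEI(d).

    A local maximum is a delay whose BEI strictly exceeds both neighbours
    (NaNs compare false).  Used to expose the respiratory oscillation of BEI
    with delay: with ~4 beats per respiratory cycle the peaks sit 3–4 beats
    apart.
    """
    b = np.asarray(bei, dtype=float)
    peaks = [
        i
        for i in range(1, len(b) - 1)
        if np.isfinite(b[i]) and b[i] > b[i - 1] and b[i] > b[i + 1]
    ]
    return list(np.diff(peaks)) if len(peaks) > 1 else []
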