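"""Beat-indexed series containers and CSV I/O.

The whole toolkit works on *beat-by-beat* series: one value per heart beat
(systolic arterial pressure, SAP, in mmHg, or pulse interval, PI, in ms),
stamped with the beat's occurrence time in seconds.  SAP and PI are kept as
two parallel :class:`BeatSeries` over the same beats, so that a beat removed
as an artifact disappears from both.

Gaps left by artifact removal are recorded on the surviving predecessor via
the per-beat ``gap_after`` flag; downstream stages (ramp detection, sequence
matching) refuse to span a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BeatSeries",
    "UniformSeries",
    "read_beat_series",
    "write_beat_series",
]

#: canonical CSV column names (remappable in read_beat_series)
CSV_COLUMNS = ("time_s", "sap_mmhg", "pi_ms")


@dataclass
class BeatSeries:
    """One measurement per beat, at strictly increasing beat times.

    Parameters
    ----------
    t : array of float
        Beat occurrence times in seconds, strictly increasing.
    values : array of float
        Measurement per beat (SAP in mmHg or PI in ms).  Filtered series
        (e.g. high-pass PI) may be zero-mean; positivity of raw PI is
        enforced at ingestion, not here.
    label : str
        Free-text label, e.g. ``"SAP"`` or ``"PI (high-pass)"``.
    units : str
        ``"mmHg"`` or ``"ms"``.
    gap_after : bool array
        True at beat *i* when one or more beats were removed immediately
        after beat *i*.
    """

    t: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""
    gap_after: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.ndim != 1 or self.values.ndim != 1:
            raise ValueError("t and values must be 1-D")
        if len(self.t) != len(self.values):
            raise ValueError(
                f"t and values length mismatch ({len(self.t)} vs {len(self.values)})"
            )
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            bad = int(np.argmin(np.diff(self.t)))
            raise ValueError(
                f"beat times must be strictly increasing (violation after row {bad})"
            )
        if len(self.t) and not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.values))):
            raise ValueError("beat times and values must be finite")
        if self.gap_after is None:
            self.gap_after = np.zeros(len(self.t), dtype=bool)
        else:
            self.gap_after = np.asarray(self.gap_after, dtype=bool)
            if len(self.gap_after) != len(self.t):
                raise ValueError("gap_after length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Recording span in seconds (0 for <2 beats)."""
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0

    def with_values(self, values: np.ndarray, label: str | None = None) -> "BeatSeries":
        """Same beats, new values (used by the band-split filters)."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            label=self.label if label is None else label,
            gap_after=self.gap_after.copy(),
        )

    def take(self, indices: np.ndarray) -> "BeatSeries":
        return BeatSeries(
            t=self.t[indices],
            values=self.values[indices],
            label=self.label,
            units=self.units,
            gap_after=self.gap_after[indices],
        )


@dataclass
class UniformSeries:
    """Evenly sampled signal: value ``i`` is at time ``t0 + i / fs``."""

    fs: float
    t0: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) and not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs


def read_beat_series(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    require_positive_pi: bool = True,
) -> tuple[BeatSeries, BeatSeries]:
    """Read an aligned (SAP, PI) pair from CSV.

    The file must have a header with columns ``time_s``, ``sap_mmhg`` and
    ``pi_ms`` (names remappable through ``column_map``, which maps canonical
    name -> actual column name).  An optional ``gap_after`` column (0/1) is
    honoured.

    Set ``require_positive_pi=False`` when reading band-split series, whose
    PI column is zero-mean by construction.
    """
    column_map = column_map or {}
    df = pd.read_csv(path)
    cols = {name: column_map.get(name, name) for name in CSV_COLUMNS}
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    t = df[cols["time_s"]].to_numpy(dtype=float)
    sap = df[cols["sap_mmhg"]].to_numpy(dtype=float)
    pi = df[cols["pi_ms"]].to_numpy(dtype=float)

    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"{path}: time_s not strictly increasing at row {row}")
    if require_positive_pi and np.any(pi <= 0):
        row = int(np.argmax(pi <= 0))
        raise ValueError(f"{path}: non-positive pulse interval at row {row}")

    gap_name = column_map.get("gap_after", "gap_after")
    gap = (
        df[gap_name].to_numpy(dtype=float).astype(bool)
        if gap_name in df.columns
        else None
    )
    sap_s = BeatSeries(t, sap, label="SAP", units="mmHg", gap_after=gap)
    pi_s = BeatSeries(t, pi, label="PI", units="ms",
                      gap_after=None if gap is None else gap.copy())
    return sap_s, pi_s


def write_beat_series(
    pair: tuple[BeatSeries, BeatSeries], path: str | Path
) -> None:
    """Write an aligned (SAP, PI) pair as CSV in the dialect read_beat_series accepts.

    Columns: ``beat_index,time_s,sap_mmhg,pi_ms,gap_after`` with gap flags
    encoded 0/1.  Values round-trip to better than 1e-9 relative.
    """
    sap, pi = pair
    if len(sap) != len(pi):
        raise ValueError("SAP and PI series must have equal length")
    gap = sap.gap_after | pi.gap_after
    df = pd.DataFrame(
        {
            "beat_index": np.arange(len(sap), dtype=int),
            "time_s": sap.t,
            "sap_mmhg": sap.values,
            "pi_ms": pi.values,
            "gap_after": gap.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
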