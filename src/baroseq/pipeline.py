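"""Full dual-band protocol: preprocess, band-split, sequence sweeps, transfer function, cohort agreement.

One subject is analyzed as: artifact cleaning -> low- and high-pass versions
of the cleaned SAP/PI pair -> sequence-method delay sweep on the original,
low-pass and high-pass series -> Welch transfer function (original series
only, with coherence-gated LF/HF band gains).  The original series carries
the fast (respiratory) baroreflex arm, the low-pass series the slow
(Mayer-wave) arm — hence the dual-band protocol of reporting both.

A cohort run adds the comparison layer: per-delay OLS of original-series
BRS/BEI on the band-split estimates, Bland–Altman agreement at the reporting
delays, Spearman correlation of sequence BRS against the transfer-function
band gains, and a slow-vs-fast gain summary table.

All outputs are plain CSV/JSON with fixed float formatting, so identical
configs and inputs reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .agreement import bland_altman, ols_r2, spearman_rho
from .preprocessing import PreprocessConfig, band_split, remove_artifacts
from .sequence import SequenceParams, delay_sweep, sweep_frame
from .series import BeatSeries, read_beat_series
from .spectral import SpectralParams, interpolate_uniform, welch_transfer

__all__ = ["PipelineConfig", "SubjectReport", "run_subject", "run_cohort"]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"
SERIES_KINDS = ("original", "lp", "hp")


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from YAML."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sequence: SequenceParams = field(default_factory=SequenceParams)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    delays: tuple[int, ...] = tuple(range(0, 13))
    report_delays: tuple[int, ...] = (1, 3)

    def __post_init__(self) -> None:
        self.delays = tuple(int(d) for d in self.delays)
        self.report_delays = tuple(int(d) for d in self.report_delays)
        missing = [d for d in self.report_delays if d not in self.delays]
        if missing:
            raise ValueError(f"report_delays {missing} not in the computed delays")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "preprocess" in raw:
            kwargs["preprocess"] = PreprocessConfig(**raw["preprocess"])
        if "sequence" in raw:
            kwargs["sequence"] = SequenceParams(**raw["sequence"])
        if "spectral" in raw:
            spec = dict(raw["spectral"])
            for band in ("lf_band", "hf_band"):
                if band in spec:
                    spec[band] = tuple(spec[band])
            kwargs["spectral"] = SpectralParams(**spec)
        for key in ("delays", "report_delays"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        return cls(**kwargs)

    def describe(self) -> dict:
        return {
            "preprocess": dataclasses.asdict(self.preprocess),
            "sequence": dataclasses.asdict(self.sequence),
            "spectral": dataclasses.asdict(self.spectral),
            "delays": list(self.delays),
            "report_delays": list(self.report_delays),
        }


@dataclass
class SubjectReport:
    subject_id: str
    n_beats_in: int
    n_beats_clean: int
    removed_fraction: float
    sequence_tables: dict[str, pd.DataFrame]  # original / lp / hp
    transfer_table: pd.DataFrame
    band_gain_lf: Optional[float]
    band_gain_hf: Optional[float]
    n_segments: int
    nperseg: int
    warnings: list[str] = field(default_factory=list)


def _sequence_table(sap, pi, config: PipelineConfig) -> pd.DataFrame:
    results = delay_sweep(sap, pi, config.sequence, delays=list(config.delays))
    return sweep_frame(results)


def run_subject(
    subject: tuple[BeatSeries, BeatSeries] | str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    subject_id: str = "subject",
) -> SubjectReport:
    """Analyze one subject end to end.

    ``subject`` is either an (SAP, PI) pair or a CSV path readable by
    :func:`baroseq.series.read_beat_series`.  When ``outdir`` is given, the
    sequence tables, the transfer table and a JSON summary are written there.
    """
    config = config or PipelineConfig()
    if isinstance(subject, (str, Path)):
        sap, pi = read_beat_series(subject)
    else:
        sap, pi = subject

    notes: list[str] = []
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")

        sap_c, pi_c, art = remove_artifacts(sap, pi, config.preprocess)
        series = {
            "original": (sap_c, pi_c),
            "lp": (
                band_split(sap_c, config.preprocess, "low"),
                band_split(pi_c, config.preprocess, "low"),
            ),
            "hp": (
                band_split(sap_c, config.preprocess, "high"),
                band_split(pi_c, config.preprocess, "high"),
            ),
        }
        seq_tables = {
            kind: _sequence_table(s, p, config) for kind, (s, p) in series.items()
        }

        # transfer function on the original series only
        fs = config.spectral.fs
        sap_u = interpolate_uniform(sap_c, fs)
        pi_u = interpolate_uniform(pi_c, fs)
        tf = welch_transfer(sap_u, pi_u, config.spectral)

    notes.extend(str(w.message) for w in caught)
    for msg in notes:
        logger.warning("[%s] %s", subject_id, msg)

    tf_table = pd.DataFrame(
        {
            "freq_hz": tf.freqs,
            "sap_psd": tf.sap_psd,
            "pi_psd": tf.pi_psd,
            "gain": tf.gain,
            "phase": tf.phase,
            "coherence": np.full_like(tf.freqs, np.nan)
            if tf.coherence is None
            else tf.coherence,
        }
    )
    report = SubjectReport(
        subject_id=subject_id,
        n_beats_in=art.n_input,
        n_beats_clean=len(sap_c),
        removed_fraction=art.removed_fraction,
        sequence_tables=seq_tables,
        transfer_table=tf_table,
        band_gain_lf=tf.band_gain_lf,
        band_gain_hf=tf.band_gain_hf,
        n_segments=tf.n_segments,
        nperseg=tf.nperseg,
        warnings=notes,
    )

    if outdir is not None:
        out = Path(outdir) / f"subject_{subject_id}"
        out.mkdir(parents=True, exist_ok=True)
        for kind, table in seq_tables.items():
            name = {"original": "orig"}.get(kind, kind)
            table.to_csv(out / f"sequence_{name}.csv", index=False, float_format=FLOAT_FMT)
        tf_table.to_csv(out / "transfer.csv", index=False, float_format=FLOAT_FMT)
        summary = {
            "subject_id": subject_id,
            "n_beats_in": report.n_beats_in,
            "n_beats_clean": report.n_beats_clean,
            "removed_fraction": report.removed_fraction,
            "band_gain_lf": report.band_gain_lf,
            "band_gain_hf": report.band_gain_hf,
            "n_segments": report.n_segments,
            "nperseg": report.nperseg,
            "warnings": notes,
            "parameters": config.describe(),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return report


def _metric_matrix(
    reports: list[SubjectReport], kind: str, metric: str, delays: Sequence[int]
) -> pd.DataFrame:
    """subjects × delays matrix of a sequence metric for one series kind."""
    rows = []
    for rep in reports:
        tab = rep.sequence_tables[kind].set_index("delay")
        rows.append([tab.loc[d, metric] for d in delays])
    return pd.DataFrame(rows, columns=list(delays))


def run_cohort(
    subjects: Sequence[tuple[BeatSeries, BeatSeries] | str | Path],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Subject reports plus the cohort comparison layer.

    Returns a dict with the per-subject reports and DataFrames:

    - ``table1``: per delay and metric (brs/bei), R² of the original-series
      estimate regressed on LP only, HP only, and LP+HP.
    - ``bland_altman``: original vs LP and vs HP BRS at the report delays.
    - ``spearman``: sequence BRS vs transfer-function band gains.
    - ``band_comparison``: cohort mean ± SD of slow vs fast gain estimates.
    """
    config = config or PipelineConfig()
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for cohort statistics")
    reports = [
        run_subject(s, config, outdir=outdir, subject_id=f"{i:03d}")
        for i, s in enumerate(subjects)
    ]
    delays = config.delays

    mats = {
        (kind, metric): _metric_matrix(reports, kind, metric, delays)
        for kind in SERIES_KINDS
        for metric in ("brs_mean", "bei")
    }

    # Table-1-style multiple regression per delay
    t1_rows = []
    for metric, short in (("brs_mean", "brs"), ("bei", "bei")):
        orig = mats[("original", metric)]
        lp = mats[("lp", metric)]
        hp = mats[("hp", metric)]
        for d in delays:
            y = orig[d].to_numpy()
            row = {"metric": short, "delay": d}
            try:
                row["r2_lp"] = ols_r2(y, {"lp": lp[d].to_numpy()}).r2
                row["r2_hp"] = ols_r2(y, {"hp": hp[d].to_numpy()}).r2
                row["r2_lp_hp"] = ols_r2(
                    y, {"lp": lp[d].to_numpy(), "hp": hp[d].to_numpy()}
                ).r2
            except ValueError as exc:
                logger.warning("regression at delay %d (%s) failed: %s", d, short, exc)
                row.update({"r2_lp": np.nan, "r2_hp": np.nan, "r2_lp_hp": np.nan})
            t1_rows.append(row)
    table1 = pd.DataFrame(t1_rows)

    # Bland–Altman at the report delays
    ba_rows = []
    for d in config.report_delays:
        orig = mats[("original", "brs_mean")][d].to_numpy()
        for kind in ("lp", "hp"):
            other = mats[(kind, "brs_mean")][d].to_numpy()
            mask = np.isfinite(orig) & np.isfinite(other)
            if mask.sum() < 3:
                continue
            ba = bland_altman(orig[mask], other[mask])
            ba_rows.append(
                {
                    "delay": d,
                    "comparison": f"original_vs_{kind}",
                    "mean_diff": ba.mean_diff,
                    "sd_diff": ba.sd_diff,
                    "loa_lower": ba.loa_lower,
                    "loa_upper": ba.loa_upper,
                    "prop_bias_slope": ba.proportional_bias_slope,
                    "prop_bias_p": np.nan
                    if ba.proportional_bias_p is None
                    else ba.proportional_bias_p,
                    "n": ba.n,
                }
            )
    ba_table = pd.DataFrame(ba_rows)

    # Spearman: sequence BRS vs transfer band gains
    tf_lf = np.array(
        [np.nan if r.band_gain_lf is None else r.band_gain_lf for r in reports]
    )
    tf_hf = np.array(
        [np.nan if r.band_gain_hf is None else r.band_gain_hf for r in reports]
    )
    sp_rows = []
    for d in config.report_delays:
        for kind, tf_vals, band in (
            ("original", tf_hf, "hf"),
            ("original", tf_lf, "lf"),
            ("hp", tf_hf, "hf"),
            ("lp", tf_lf, "lf"),
        ):
            seq = mats[(kind, "brs_mean")][d].to_numpy()
            mask = np.isfinite(seq) & np.isfinite(tf_vals)
            if mask.sum() < 3:
                continue
            try:
                rho = spearman_rho(seq[mask], tf_vals[mask])
            except ValueError:
                continue
            sp_rows.append(
                {
                    "delay": d,
                    "sequence_series": kind,
                    "tf_band": band,
                    "rho": rho,
                    "n": int(mask.sum()),
                }
            )
    sp_table = pd.DataFrame(sp_rows)

    # slow-vs-fast gain summary
    bc_rows = [
        {
            "estimator": "transfer_lf",
            "mean": float(np.nanmean(tf_lf)),
            "sd": float(np.nanstd(tf_lf, ddof=1)),
            "n": int(np.isfinite(tf_lf).sum()),
        },
        {
            "estimator": "transfer_hf",
            "mean": float(np.nanmean(tf_hf)),
            "sd": float(np.nanstd(tf_hf, ddof=1)),
            "n": int(np.isfinite(tf_hf).sum()),
        },
    ]
    for d in config.report_delays:
        for kind in SERIES_KINDS:
            vals = mats[(kind, "brs_mean")][d].to_numpy()
            bc_rows.append(
                {
                    "estimator": f"sequence_{kind}_d{d}",
                    "mean": float(np.nanmean(vals)),
                    "sd": float(np.nanstd(vals, ddof=1)),
                    "n": int(np.isfinite(vals).sum()),
                }
            )
    band_comparison = pd.DataFrame(bc_rows)

    result = {
        "reports": reports,
        "table1": table1,
        "bland_altman": ba_table,
        "spearman": sp_table,
        "band_comparison": band_comparison,
    }

    if outdir is not None:
        cohort_dir = Path(outdir) / "cohort"
        cohort_dir.mkdir(parents=True, exist_ok=True)
        table1.to_csv(cohort_dir / "table1.csv", index=False, float_format=FLOAT_FMT)
        ba_table.to_csv(
            cohort_dir / "bland_altman.csv", index=False, float_format=FLOAT_FMT
        )
        sp_table.to_csv(cohort_dir / "spearman.csv", index=False, float_format=FLOAT_FMT)
        band_comparison.to_csv(
            cohort_dir / "band_comparison.csv", index=False, float_format=FLOAT_FMT
        )
        with open(Path(outdir) / "run.log", "w") as fh:
            fh.write(json.dumps({"parameters": config.describe()}, indent=2, sort_keys=True))
            fh.write("\n")
            for rep in reports:
                fh.write(
                    f"subject {rep.subject_id}: {rep.n_beats_in} beats in, "
                    f"{rep.n_beats_clean} clean "
                    f"({rep.removed_fraction:.4f} removed); "
                    f"{rep.n_segments} Welch segments (nperseg={rep.nperseg})\n"
                )
                for msg in rep.warnings:
                    fh.write(f"  warning: {msg}\n")
    return result
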