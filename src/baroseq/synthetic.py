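"""Synthetic coupled SAP/PI beat-series generator.

Stands in for rat beat-by-beat recordings: systolic pressure carries a
respiratory oscillation (default 1.5 Hz — about four beats per breath at a
170 ms pulse interval) and a slower Mayer wave (default 0.4 Hz), and the
pulse interval responds to each component through its own linear baroreflex
gain after a fixed delay in beats (fast/vagal arm: high gain, short delay;
slow/sympathetic arm: lower gain, longer delay).

The generator is deliberately open loop (SAP drives PI, never the reverse)
and sinusoidal by default, so every programmed gain and delay is an exact
ground truth that the sequence method and the transfer function should
recover.  A band-limited-noise drive is available for realism checks where
an analytic truth is not needed.

Construction is two-pass: components are evaluated on provisional,
equally-spaced beat times implied by the base pulse interval; the PI series
is then built from beat-delayed components, and the final beat times are the
cumulative sum of the generated PI values (so beat spacing itself fluctuates
with the reflex, as in real tachograms).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .series import BeatSeries

__all__ = ["SyntheticConfig", "generate", "generate_cohort", "study_template", "STUDY_GAIN_SD"]


@dataclass
class SyntheticConfig:
    """Ground-truth parameterization of the coupled SAP/PI generator.

    Defaults emulate a healthy resting rat: ~350 bpm (170 ms PI), 120 mmHg
    SAP, respiration at 1.5 Hz (≈4 beats/cycle) modulating SAP by ±3 mmHg,
    Mayer waves at 0.4 Hz by ±2 mmHg, and a fast baroreflex arm three times
    more sensitive than the slow arm (2.0 vs 0.7 ms/mmHg) with shorter beat
    delay (1 vs 3 beats).  Beat-to-beat Gaussian jitter of 0.5 mmHg / 0.5 ms
    models measurement noise on top of the deterministic oscillations.
    """

    n_beats: int = 5000
    base_pi: float = 170.0  # ms
    base_sap: float = 120.0  # mmHg
    f_resp: float = 1.5  # Hz
    a_resp: float = 3.0  # mmHg
    f_mayer: float = 0.4  # Hz
    a_mayer: float = 2.0  # mmHg
    gain_hf: float = 2.0  # ms/mmHg
    gain_lf: float = 0.7  # ms/mmHg
    delay_hf: int = 1  # beats
    delay_lf: int = 3  # beats
    sap_noise_sd: float = 0.5  # mmHg
    pi_noise_sd: float = 0.5  # ms
    artifact_rate: float = 0.0  # fraction of beats spiked (SAP × 1.3)
    noise_mode: str = "white"  # "white" | "band" (band-limited component noise)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beats < 2:
            raise ValueError("n_beats must be >= 2")
        if self.base_pi <= 0 or self.base_sap <= 0:
            raise ValueError("base_pi and base_sap must be positive")
        beat_rate = 1000.0 / self.base_pi
        for name, f in (("f_resp", self.f_resp), ("f_mayer", self.f_mayer)):
            if not (0 < f < beat_rate / 2):
                raise ValueError(
                    f"{name}={f} Hz must lie below half the mean beat rate "
                    f"({beat_rate / 2:.2f} Hz)"
                )
        if self.gain_hf < 0 or self.gain_lf < 0:
            raise ValueError("gains must be >= 0")
        if self.delay_hf < 0 or self.delay_lf < 0:
            raise ValueError("delays must be >= 0")
        if self.sap_noise_sd < 0 or self.pi_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (0 <= self.artifact_rate < 1):
            raise ValueError("artifact_rate must lie in [0, 1)")
        if self.noise_mode not in ("white", "band"):
            raise ValueError("noise_mode must be 'white' or 'band'")


def _delayed(x: np.ndarray, d: int) -> np.ndarray:
    """x shifted d beats later; indices before the series start contribute 0."""
    if d == 0:
        return x.copy()
    out = np.zeros_like(x)
    out[d:] = x[:-d]
    return out


def _band_noise(rng: np.random.Generator, n: int, f0: float, dt: float, amp: float) -> np.ndarray:
    """Narrow-band Gaussian drive around f0 (for the 'band' realism mode)."""
    from scipy.signal import butter, sosfiltfilt

    white = rng.normal(0.0, 1.0, n)
    lo, hi = 0.7 * f0, 1.3 * f0
    sos = butter(4, [lo, hi], btype="band", fs=1.0 / dt, output="sos")
    shaped = sosfiltfilt(sos, white)
    sd = shaped.std()
    return amp / np.sqrt(2.0) * (shaped / sd if sd > 0 else shaped)


def generate(config: SyntheticConfig | None = None) -> tuple[BeatSeries, BeatSeries, dict]:
    """Generate one (SAP, PI) pair plus the noise-free ground truth.

    Returns ``(sap, pi, truth)`` where ``truth`` holds the component series
    (LF/HF, raw and beat-delayed), the artifact indices, and the config.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_beats
    dt = cfg.base_pi / 1000.0  # provisional beat spacing, s
    t_prov = np.arange(n) * dt

    if cfg.noise_mode == "band":
        lf = _band_noise(rng, n, cfg.f_mayer, dt, cfg.a_mayer)
        hf = _band_noise(rng, n, cfg.f_resp, dt, cfg.a_resp)
    else:
        lf = cfg.a_mayer * np.sin(2 * np.pi * cfg.f_mayer * t_prov)
        hf = cfg.a_resp * np.sin(2 * np.pi * cfg.f_resp * t_prov)

    sap_noise = rng.normal(0.0, cfg.sap_noise_sd, n) if cfg.sap_noise_sd else np.zeros(n)
    pi_noise = rng.normal(0.0, cfg.pi_noise_sd, n) if cfg.pi_noise_sd else np.zeros(n)

    sap = cfg.base_sap + lf + hf + sap_noise
    lf_d = _delayed(lf, cfg.delay_lf)
    hf_d = _delayed(hf, cfg.delay_hf)
    pi = cfg.base_pi + cfg.gain_lf * lf_d + cfg.gain_hf * hf_d + pi_noise
    if np.any(pi <= 0):
        raise ValueError("generated PI non-positive; reduce amplitudes/gains/noise")

    artifact_idx = np.array([], dtype=int)
    if cfg.artifact_rate > 0:
        k = int(round(cfg.artifact_rate * n))
        if k:
            artifact_idx = np.sort(rng.choice(n, size=k, replace=False))
            sap[artifact_idx] *= 1.3

    # final beat times: cumulative PI, anchored so the first beat is at t=0
    t = (np.cumsum(pi) - pi[0]) / 1000.0

    sap_s = BeatSeries(t, sap, label="SAP", units="mmHg")
    pi_s = BeatSeries(t, pi, label="PI", units="ms")
    truth = {
        "config": cfg,
        "lf_component": lf,
        "hf_component": hf,
        "lf_delayed": lf_d,
        "hf_delayed": hf_d,
        "sap_noise_free": cfg.base_sap + lf + hf,
        "pi_noise_free": cfg.base_pi + cfg.gain_lf * lf_d + cfg.gain_hf * hf_d,
        "artifact_indices": artifact_idx,
    }
    return sap_s, pi_s, truth


#: between-subject gain SDs for the study-emulating cohort (~40% CV on the
#: fast gain, matching the wide BRS spread of healthy rat cohorts)
STUDY_GAIN_SD = {"gain_hf": 0.8, "gain_lf": 0.25}


def study_template(n_beats: int = 8000) -> SyntheticConfig:
    """Template emulating a healthy-rat cohort recording for method comparison.

    Differences from the plain defaults, each matching the recorded-data
    setting rather than the analytically convenient one:

    - ``noise_mode="band"``: respiration and Mayer waves as narrow-band noise,
      so the respiratory period drifts over ~3–5.6 beats as in real rats
      instead of repeating exactly.
    - ``delay_hf=0``: the vagal reflex arc in rats is faster than one beat,
      so the fast PI response lands on the same beat as the SAP change.
    - ``n_beats=8000``: the typical length of a ~20-min beat series.

    Use together with :data:`STUDY_GAIN_SD` in :func:`generate_cohort` to
    draw a cohort with realistic between-subject gain spread.
    """
    return SyntheticConfig(
        n_beats=n_beats,
        noise_mode="band",
        delay_hf=0,
        sap_noise_sd=0.2,
        pi_noise_sd=0.2,
    )


def generate_cohort(
    template: SyntheticConfig,
    n_subjects: int,
    between_subject_sd: float | Mapping[str, float] = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[BeatSeries, BeatSeries, dict]], pd.DataFrame]:
    """Cohort of subjects with gains drawn around the template values.

    ``between_subject_sd`` is either a scalar SD applied to both gains or a
    mapping with keys ``gain_hf`` / ``gain_lf``.  Per-subject seeds derive
    deterministically from ``seed``, so the whole cohort is reproducible.
    Negative gain draws are clipped to 0.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if isinstance(between_subject_sd, Mapping):
        sd_hf = float(between_subject_sd.get("gain_hf", 0.0))
        sd_lf = float(between_subject_sd.get("gain_lf", 0.0))
    else:
        sd_hf = sd_lf = float(between_subject_sd)

    rng = np.random.default_rng(seed)
    gains_hf = np.clip(rng.normal(template.gain_hf, sd_hf, n_subjects), 0.0, None)
    gains_lf = np.clip(rng.normal(template.gain_lf, sd_lf, n_subjects), 0.0, None)
    child_seeds = rng.integers(0, 2**31 - 1, n_subjects)

    subjects = []
    rows = []
    for i in range(n_subjects):
        cfg = replace(
            template,
            gain_hf=float(gains_hf[i]),
            gain_lf=float(gains_lf[i]),
            seed=int(child_seeds[i]),
        )
        subjects.append(generate(cfg))
        rows.append(
            {
                "subject": i,
                "seed": int(child_seeds[i]),
                "gain_hf": cfg.gain_hf,
                "gain_lf": cfg.gain_lf,
            }
        )
    return subjects, pd.DataFrame(rows)
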