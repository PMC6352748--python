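# Methods

## Beat series and artifact cleaning

All analyses start from paired beat-by-beat series: systolic arterial
pressure (SAP, mmHg) and pulse interval (PI, ms), one value per beat with
the beat time in seconds. SAP and PI are kept over the same beats; removing
a beat removes it from both series, and the surviving predecessor is
flagged (`gap_after`) so no downstream window spans the hole.

Artifacts are removed in a single pass against a centered moving-median
baseline (default window 50 beats, forced odd; shrunk symmetrically at the
series edges). A beat is dropped when its SAP or PI leaves
`baseline · (1 ± p)`; `p` defaults to 0.10, the midpoint of the accepted
0.05–0.20 range, and values outside that range require an explicit
override. Thresholds come from the original series' baseline and are not
recomputed iteratively — one deterministic pass, no order dependence. A
removal fraction above 1% raises a warning: on stable recordings removals
should stay well below that, so more usually signals an unstable recording
rather than isolated artifacts.

## Band splitting

The slow (Mayer-wave/sympathetic, ≲0.8 Hz) and fast (respiratory/vagal,
≳0.8 Hz) components are separated with a 9th-order Butterworth filter at
0.8 Hz. Because a Hz-domain cutoff is only meaningful on an evenly sampled
signal, the beat series is cubic-spline interpolated onto a uniform grid
(default 10 Hz), filtered, and sampled back at the original beat times.
Filtering is zero-phase (forward–backward, `sosfiltfilt`), so filtered
ramps stay aligned with the original beats; the effective magnitude
response is the square of the single-pass response, hence amplitude 0.5
(not 1/√2) at the cutoff.

Only the low-pass filter is ever run: the high-pass output is the residual
(input minus low-pass) at the beat times. For Butterworth pairs
`1 − |H_lp|² = |H_hp|²` and zero-phase responses are real, so the residual
realizes exactly the zero-phase high-pass response while making
low + high = input an identity rather than an approximation (separately
resampling both bands would re-introduce spline round-trip error of order
`(2πf/fs)⁴/384`, a few 1e-3 for content near the beat-rate Nyquist).

An alternative to the interpolate–filter–resample route would be filtering
in the beat domain with the cutoff converted to cycles/beat via the mean
beat rate; the time-domain route is the default because it keeps the
0.8 Hz cutoff physically meaningful when the heart rate drifts.

## Sequence method

Ramps are maximal runs of same-sign SAP changes, each change strictly
exceeding the SAP threshold (default 0, so equal consecutive values break a
ramp), never spanning a gap, of length ≥ *n* beats (default 3; *n* = 2 is
allowed with a warning). Maximality means a 5-beat run is one ramp, not
three 3-beat sub-ramps, which keeps the BEI denominator unambiguous.

For delay *d*, the candidate PI segment starts *d* beats after the ramp
start and has the ramp's length. Ramps whose segment runs off the series
end or spans a gap are *unevaluable* and excluded from both the numerator
and denominator of BEI — counting them as failures would bias BEI downward
at large delays. A sequence is accepted when the Pearson correlation of PI
on SAP is ≥ `r_min` (default 0.8) and the slope is positive; the PI course
is not required to be monotone, since with a zero PI threshold the
correlation criterion is the operative filter. A zero-variance PI segment
has undefined correlation and counts as a rejection. When a positive PI
threshold is configured, every PI step in the segment must exceed it in
magnitude; at the default 0 no per-step constraint applies.

BRS is the unweighted mean slope over accepted sequences, pooling up- and
down-ramps; BEI is accepted/evaluable. The delay sweep (default d = 0…12)
detects ramps once and re-evaluates the pairing per delay; the length sweep
(n = 3…9) re-detects ramps per *n* at a fixed delay. Ramp and sequence
counts are non-increasing in *n*.

With ~4 beats per respiratory breath, SAP ramps repeat with the breath, so
BEI(d) oscillates with a 3–4 beat period: delays that land one full
respiratory period after the true reflex delay pick up the *next* PI ramp.
`bei_peak_spacings` exposes this by returning the spacing between interior
local maxima of BEI(d).

## Transfer function

SAP and PI are cubic-spline interpolated at 10 Hz (grid from the first to
the last beat time, no extrapolation) and analyzed with the Welch protocol:
half-overlapping Hann-windowed segments (default 4096 samples), per-segment
mean removal, averaged one-sided auto- and cross-spectra with window power
normalization, so PSDs integrate to physical variance. The transfer gain
is `|S_PI,SAP| / S_SAP,SAP` (ms/mmHg per bin) and the magnitude-squared
coherence gates which bins are trusted.

Band gains are the *unweighted mean* of the per-bin gain over bins inside
the band with coherence > 0.5 — the mean rather than an integral keeps
ms/mmHg units. Band edges are lower-inclusive, upper-exclusive, so the
0.8 Hz boundary bin belongs to HF. When no bin passes the gate the band
gain is undefined (reported as missing, with a warning), never zero.

The 4096-sample default assumes ~20-minute recordings. For shorter series
the segment length falls back to the largest power of two ≤ N/2 (with a
warning), guaranteeing at least two segments — averaged coherence over a
single segment is identically 1 and meaningless, so it is reported as
undefined in that case. Desk-scale analyses in the test suite and
acceptance script pass `nperseg=1024` explicitly: with ~5,000-beat series
this yields ~15 averaged segments, keeping the chance rate of the
coherence > 0.5 gate negligible, whereas 4096 would leave only 3 segments
whose null coherence passes the gate in roughly a quarter of noise-only
bins.

## Agreement statistics

Method comparison uses three descriptive tools: OLS regression with
intercept (R² = 1 − SSE/SST; defined as 0 for a constant response;
per-coefficient t-test p-values), Bland–Altman agreement (differences vs
means, limits mean ± 1.96 SD, proportional bias as the OLS slope of
difference on mean), and Spearman rank correlation (Pearson correlation of
mid-ranks). Observations with undefined estimates are dropped pairwise
with a logged count. P-values are reported at the conventional 0.05
reference, never used as gates.

## Synthetic generator

The generator stands in for rat recordings with a known ground truth. SAP
carries a respiratory component (default 1.5 Hz, ±3 mmHg) and a Mayer-wave
component (0.4 Hz, ±2 mmHg) on a 120 mmHg baseline; PI (170 ms baseline,
so ~5.9 beats/s and ~3.9 beats per breath) responds to each component
through its own linear gain after a fixed beat delay — fast arm 2.0
ms/mmHg at 1 beat, slow arm 0.7 ms/mmHg at 3 beats, a >2:1 ratio matching
the vagal-vs-sympathetic sensitivity asymmetry. Construction is two-pass:
components are evaluated on provisional equally spaced beat times, then the
final beat times are the cumulative sum of the generated PI, so beat
spacing itself fluctuates with the reflex as in a real tachogram. Gaussian
beat-to-beat jitter (defaults 0.5 mmHg and 0.5 ms) models measurement
noise; an optional artifact mode multiplies random SAP beats by 1.3.

Two drive modes:

- `white` (default): pure sinusoids — analytic truth, used for exactness
  tests. With zero noise and a single coupling the sequence method must
  recover the programmed gain to machine precision.
- `band`: narrow-band Gaussian drives (4th-order Butterworth bandpass,
  ±30% around each center frequency), so the respiratory period drifts
  over ~3–5.6 beats as in real animals. This is the mode for statistical
  validation: with a pure sinusoidal carrier, the coherence-gated band
  mean also averages frequency-modulation sideband bins created by the
  beat-time warping (whose gain mixes the two arms), biasing the HF band
  mean ~10% low — a property of line spectra, not of the estimator.

The generator is deliberately open-loop (SAP drives PI, never the
reverse) so programmed gains are unambiguous truths. It does *not*
emulate: PI→SAP feedback (present in real data), direct respiratory drive
of PI that bypasses the baroreflex, distributed/latency-jittered reflex
responses, nonstationarity, or ectopy. Passing gain-recovery tests
therefore demonstrates estimator correctness under linear open-loop
coupling, not unbiasedness on real closed-loop recordings.

`generate_cohort` draws per-subject gains around a template (negative
draws clipped at 0) with per-subject seeds derived deterministically from a
master seed. `study_template()` fixes the cohort conditions used for the
method-comparison validations, each chosen to match the recorded-data
setting: band-mode drives; same-beat (delay 0) fast response, since the
rat vagal arc is faster than one beat; 8,000 beats, a typical ~20-minute
series length; and, via `STUDY_GAIN_SD`, a ~40% between-subject CV on the
fast gain, the spread seen across healthy rats. Under these conditions the
original-series BRS at the conventional delays 1 and 3 is explained by the
high-pass-series BRS (R² ≈ 0.9) and not by the low-pass-series BRS
(R² ≲ 0.05), reproducing the band-dominance pattern that motivates the
dual-band protocol. With the sinusoidal drive instead, off-peak delays
yield almost no sequences (the misaligned narrow-band segments are
consistently anti-correlated), so per-subject estimates there are
fluke-dominated — one of the ways a deterministic drive is *less*
forgiving than real variability.

## Pipeline

`run_subject` executes clean → band-split → sequence delay sweep on the
original, low-pass and high-pass series → transfer function on the
original series only (band-split series are analyzed only by the sequence
method, since their band gains are the point of the split). `run_cohort`
adds per-delay regressions of the original-series indices on the
band-split ones, Bland–Altman agreement and sequence-vs-transfer Spearman
correlations at the reporting delays (default 1 and 3), and a slow-vs-fast
gain summary. All outputs are CSV/JSON with fixed `%.10g` float formatting
and deterministic ordering, so identical inputs and configs give
byte-identical files.

## Numerical and edge-case conventions

- Beat indexing is 0-based; times are float seconds.
- Strict inequalities for ramp steps and artifact thresholds; boundary
  values (exactly at threshold) break ramps and survive cleaning.
- Sequence statistics are computed on centered small-window slices, not
  prefix-sum differences, to avoid catastrophic cancellation; exactness
  tests assert slopes to 1e-9.
- `brs_sd` uses ddof=1 and is undefined below 2 sequences; BEI is
  undefined (not 0) when no ramp is evaluable.
- The uniform grid for filtering/interpolation never extrapolates beyond
  the last beat, except that the final beat may sit < 1/fs past the last
  grid point when sampling back, where the spline extrapolates smoothly.

## Problem sizes

Tests and the acceptance script run on synthetic series of 1,000–8,000
beats, cohorts of 5 subjects (gain recovery; ~5,000 beats each) and 61
subjects (band-dominance regression; 8,000 beats each), and 100 random
series of 50–500 beats for brute-force oracle comparison. The full test
suite completes in well under a minute of compute per heavy test; the
acceptance script in ~20 s.

## Known limitations

- The coherence-gated band mean is unweighted; with very narrow-band
  signals it averages few bins and inherits their leakage structure.
- Artifact removal assumes isolated outliers; sustained pressure drifts
  beyond ±p of the median baseline would be (correctly) flagged in bulk,
  triggering the >1% warning.
- Beat-domain delays conflate time and beat count when heart rate varies
  strongly; this matches the sequence-method convention but differs from
  phase-based delay estimates.
- The length sweep's decreasing-BEI behavior requires imperfect slow
  coupling (uncoupled PI variability); with near-deterministic coupling
  BEI is flat in *n*.
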