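# baroseq

Spontaneous baroreflex analysis from beat-by-beat arterial pressure series,
built around the sequence method and its band-split extension.

## The problem

The arterial baroreflex buffers blood-pressure fluctuations by adjusting the
heart period: a rise in systolic arterial pressure (SAP, mmHg) reflexly
lengthens the pulse interval (PI, ms), and vice versa. The *sequence method*
quantifies this from spontaneous variability alone: it finds SAP *ramps*
(runs of ≥ *n* consecutive beats, all rising or all falling) and asks
whether the PI segment starting *d* beats later changes in the same
direction (Pearson *r* ≥ 0.8, positive regression slope). Two indices
follow:

- **BRS** (baroreflex sensitivity, ms/mmHg): the mean regression slope of
  PI on SAP over all accepted sequences;
- **BEI** (baroreflex effectiveness index, 0–1): the fraction of evaluable
  SAP ramps that were accepted as sequences.

In rats (and humans) respiration modulates SAP with a period of ~3–5 beats,
so SAP ramps rarely outlast one breath. As a consequence the sequence
method sees mostly the *fast* (respiratory/vagal) arm of the baroreflex and
is blind to slow oscillations such as Mayer waves — and BEI plotted against
the delay *d* oscillates with the respiratory period. `baroseq` implements
the dual-band protocol that addresses this: analyze the original series
*and* a low-pass filtered version (zero-phase 9th-order Butterworth, 0.8 Hz
cutoff) so the slow arm of the reflex becomes measurable, and cross-check
against the frequency-domain standard, the Welch transfer function
`gain(f) = |S_PI,SAP(f)| / S_SAP(f)` with coherence-gated band averages
(LF 0.2–0.8 Hz, HF 0.8–3.0 Hz).

## What is in the package

- `baroseq.series` — beat-series containers and CSV I/O.
- `baroseq.preprocessing` — moving-median artifact removal; zero-phase
  Butterworth low/high band splitting of unevenly sampled beat series.
- `baroseq.sequence` — ramp detection, delayed sequence matching, BRS/BEI,
  delay (0–12) and minimum-length (3–9) sweeps.
- `baroseq.spectral` — cubic-spline resampling, Welch cross-spectrum,
  transfer gain, coherence, coherence-gated band gains.
- `baroseq.agreement` — OLS R², Bland–Altman limits of agreement, Spearman
  correlation for method comparison.
- `baroseq.synthetic` — an open-loop coupled SAP→PI generator with
  programmable respiratory and Mayer-wave components, band-specific gains
  and beat delays; every estimator can be validated against its ground
  truth.
- `baroseq.pipeline` / `baroseq.cli` — the full protocol as a library call
  or the `baroseq` command.

## Worked example

Generate a synthetic rat recording (respiration 1.5 Hz ≈ 4 beats/cycle,
Mayer waves 0.4 Hz; fast gain 2.0 ms/mmHg at 1-beat delay, slow gain
0.7 ms/mmHg at 3 beats) and run the full protocol:

```python
import baroseq as bq

sap, pi, truth = bq.generate(bq.SyntheticConfig(n_beats=5000, seed=7))
report = bq.run_subject(
    (sap, pi),
    bq.PipelineConfig(spectral=bq.SpectralParams(nperseg=1024)),
)
print(report.sequence_tables["original"].head(6).to_string(index=False))
print("LF band gain %.3f  HF band gain %.3f" %
      (report.band_gain_lf, report.band_gain_hf))
```

```
 delay  n_ramps  n_ramps_evaluable  n_sequences      bei  brs_mean   brs_sd
     0     2275               2275            0 0.000000       NaN      NaN
     1     2275               2274         2274 1.000000  2.002555 0.468927
     2     2275               2274            1 0.000440  1.118353      NaN
     3     2275               2273            0 0.000000       NaN      NaN
     4     2275               2273           15 0.006599  1.578979 0.424953
     5     2275               2272         2272 1.000000  1.984692 0.466378
LF band gain 0.704  HF band gain 1.703
```

Reading the output: BEI peaks at *d* = 1 (the programmed fast delay), where
BRS recovers the programmed 2.0 ms/mmHg, and peaks again at *d* = 5 — one
respiratory period (~4 beats) later — which is the delay-oscillation
artifact the dual-band protocol is designed around. The transfer function
recovers the slow gain in the LF band (0.70); with a pure sinusoidal
respiratory drive the HF band mean (1.70) also averages over
frequency-modulation sideband bins, which is why statistical validation
uses the band-limited-noise drive (`noise_mode="band"`), where both band
gains recover the programmed values (see `docs/methods.md`).

The same protocol runs from the shell:

```sh
baroseq simulate --seed 7 --out subject.csv --truth truth.json
baroseq pipeline --in subject.csv --outdir out/
baroseq sequence --in subject.csv --delays 0:12 --out seq.csv
```

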