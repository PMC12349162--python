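# zskin

Equivalent-circuit modeling of skin–electrode impedance spectra for
wearable bioelectronics.

The impedance of the skin–electrode interface governs the signal
quality of every surface biopotential measurement (ECG, EMG, EOG).
Dry, ultra-thin *tattoo* electrodes (gold, silver, PEDOT:PSS on
polymer nanofilms) and wet pre-gelled Ag/AgCl electrodes behave
differently, and both drift over an hour of wear. `zskin` is a toolkit
for researchers characterizing that interface from impedance sweeps in
the biopotential band (20 Hz – 1 kHz):

- **Circuit algebra** — resistors, capacitors and constant phase
  elements (CPE, `Z = 1/(Q(jω)^α)`) in series/parallel chains, with
  four built-in candidate circuits from the single-time-constant
  baseline `Rs—(R0∥C0)` up to a three-segment CPE-bearing model, plus
  YAML-configurable custom topologies.
- **Fitting** — a weighted magnitude/phase relative residual

  `r = [ w_mod·||Ẑ|−|Z||/|Z| ,  w_phi·|arg Ẑ − arg Z|/|arg Z| ]`

  minimized by bound-constrained trust-region least squares with a
  seeded 300-trial multi-start (log-uniform initial vectors) to escape
  local minima; fit quality scored by separate coefficients of
  determination `R² = 1 − Σ(Z−Ẑ)²/Σ(Z−Z̄)²` for magnitude and phase,
  and model ranking with a parsimony tie-break.
- **Temporal analysis** — independent per-time-point fits over an
  hour-long session, median parameter trajectories across subjects,
  and trend classification (increasing / decreasing / flat).
- **Synthetic campaigns** — a generator that emulates the study
  design (6 subjects × 4 electrode types × 6 sweeps/hour, tens-of-kΩ
  magnitudes at 20 Hz, dry electrodes drifting up and wet drifting
  down) with a ground-truth ledger for end-to-end validation.

## Worked example

Fit the three-segment circuit to a noisy synthetic dry-electrode sweep
(`python examples/fit_spectrum.py`):

```
model: model3   starts converged: 288/300
R^2 magnitude: 0.9998   R^2 phase: 0.9990
 parameter       fitted        truth unit
        Rs         1143         1000 ohm
        R0         1261      3.2e+04 ohm
        C0    3.602e-07    8.289e-08 F
        ...
```

The dual R² scores say the fitted circuit reproduces the sweep to
within the 1 % measurement noise. The parameter columns illustrate a
point the package documents carefully: a near-perfect fit does **not**
mean each of the nine parameters is individually well determined from
1.7 decades of frequency — see `docs/methods.md` for the
identifiability analysis.

Track parameter trends over an hour (`python examples/trend_analysis.py`):

```
 electrode  parameter       trend  change over 60 min
    agagcl         R0  decreasing              -8.1%
      gold         R0  increasing             +26.3%
      gold         C0  decreasing             -22.9%
      ...
```

Dry tattoo electrodes show the drying interface — resistance R0 up,
capacitance C0 down — while the wet Ag/AgCl reference drifts slightly
down, matching the qualitative behavior of such electrodes in vivo.

Other examples: `examples/simulate_cohort.py` (generate and inspect a
campaign), `examples/compare_models.py` (rank the four candidate
circuits).

## Command line

The same pipeline is available as a thin CLI:

```sh
zskin simulate --profile all --subjects 6 --seed 1 --out data/
zskin fit data/S1_gold_t00.csv --model model3 --starts 300 --out fit.json
zskin compare-models data/S1_gold_t00.csv --out ranking.csv
zskin trend data/manifest.csv --out trends/
```

Every command writes a `*_runconfig.json` next to its outputs so any
artifact can be regenerated from its saved configuration alone.

## Layout

```
src/zskin/
  circuits.py   element algebra, built-in and custom topologies
  spectra.py    spectra, sessions, CSV dialect
  fitting.py    residual, multi-start estimator, R², model ranking
  temporal.py   trajectories, cohort medians, trend classification
  synth.py      electrode profiles, drift laws, cohort generator
  cli.py        simulate / fit / compare-models / trend
docs/methods.md  models, estimator, synthetic design, limitations
examples/        narrative scripts, one per capability
```
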