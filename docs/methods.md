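# Methods

`zskin` characterizes the skin–electrode interface of biopotential
electrodes from impedance sweeps recorded over 20 Hz – 1 kHz, the
standard band for surface biosignals (ECG/EMG/EOG). This note
documents the models, the estimator, the synthetic-data design, the
numerical choices, and the limits of what the validation studies show.

## Circuit models

A candidate circuit is an ordered series chain of passive elements and
parallel segments. Element impedances (f in Hz, ω = 2πf explicit
everywhere; no hidden angular frequency):

- resistor: `Z_R = R`
- capacitor: `Z_C = 1/(jωC)`
- constant phase element (CPE): `Z_CPE = 1/(Q·(jω)^α)`, `Q` in S·s^α

The CPE convention matters: rival parameterizations exist (e.g.
`1/(Q(jω))^α`). We use the common electrochemical form above, in which
the CPE phase is exactly −α·90° at every frequency and the element
interpolates continuously between a resistor `R = 1/Q` (α = 0) and a
capacitor `C = Q` (α = 1).

Series entries add as impedances; members of a parallel segment add as
admittances, then invert. For passive R/C/CPE members this guarantees
`Re Z > 0`, `Im Z ≤ 0`, phase in [−90°, 0°], and |Z(f)| non-increasing
in f for the built-in topologies.

Four built-in candidates of increasing detail describe the interface:

| name | chain | parameters |
|---|---|---|
| model0 | Rs — (R0 ∥ C0) | 3 |
| model1 | Rs — (R0 ∥ CPE0) | 4 |
| model2 | Rs — (R0 ∥ C0) — (R1 ∥ CPE1) | 6 |
| model3 | Rs — (R0 ∥ C0) — (R1 ∥ CPE1) — (R2 ∥ CPE2) | 9 |

model0 is the classical single-time-constant circuit. The first
parallel segment (R0 ∥ C0) represents the skin–electrode interface
proper; further CPE-bearing segments absorb the distributed,
frequency-dependent response of deeper epidermal layers. Every model
carries a series resistance Rs because measured magnitude curves
plateau at high frequency. These topologies are package defaults, not
physical law: any alternative chain can be supplied as a small
YAML/`custom` config that round-trips losslessly.

## Data model

Sweeps are recorded in polar form (|Z|, θ) and converted to Cartesian
components when needed via `Z′ = |Z|cosθ`, `Z″ = |Z|sinθ`. Phases are
radians in memory and degrees in files (instrument convention); the
CSV reader/writer is the only conversion point. Validation enforces
strictly increasing frequencies, positive magnitudes, |θ| ≤ 90°, and
warns when θ > 0 (outside the passive band). A session is the ordered
set of sweeps for one subject × electrode type on a shared frequency
grid.

## Estimator

Per frequency point the fit residual holds a magnitude and a phase
component,

    r_mod(f) = w_mod · | |Ẑ(f)| − |Z(f)| | / |Z(f)|
    r_phi(f) = w_phi · | arg Ẑ(f) − arg Z(f) | / max(|arg Z(f)|, θ_floor)

with weights defaulting to 0.5 each for balanced sensitivity. Two
numerical choices:

- `θ_floor` (default 10⁻³ rad) keeps the phase denominator finite
  where the measured phase crosses zero; skin–electrode phase is far
  from zero over most of the band, so the floor is inert on typical
  sweeps.
- The residual is defined elementwise non-negative. The optimizer
  minimizes the *signed* version, which has the identical Euclidean
  norm — hence identical minimizers — but a smooth Jacobian.

A single local fit is a trust-region-reflective bound-constrained
least-squares run. R, C, Q are optimized in log₁₀ space (they span
many decades; conditioning), α in linear space. The Jacobian is
analytic, propagated through the series/parallel admittance algebra,
and is verified against finite differences in the test suite. Step,
function and gradient tolerances are 10⁻¹².

Default bounds: R ∈ [1 Ω, 100 MΩ], C ∈ [0.1 pF, 1 mF],
Q ∈ [10⁻¹², 10⁻²] S·s^α, and α ∈ [0.3, 1] during fitting (evaluation
accepts the full [0, 1]; the fitting floor avoids the resistor
degeneracy at α = 0). All bounds are overridable per parameter.

The cost surface of CPE-bearing circuits is multimodal, so the
estimator is multi-start: `n_starts` (default 300) initial vectors are
drawn log-uniformly within bounds (α uniformly) from one seeded
stream, and the candidate with the smallest residual norm wins, ties
resolved to the lowest start index. Drawing the starts sequentially
from a single stream makes the first k starts of any run a prefix of a
longer run with the same seed, so the best norm is non-increasing in
`n_starts`, and every fit is bit-reproducible given (data, config,
seed). A start that fails to converge is recorded and skipped; only if
every start fails does the fit raise.

Fit quality is scored by two coefficients of determination,

    R² = 1 − Σ(Z − Ẑ)² / Σ(Z − Z̄)²,

computed once on magnitudes and once on phases. Magnitude R² is
computed on the linear Ω scale (the literal form above), not on the
log scale a Bode plot displays; with magnitudes spanning a decade the
linear scale weights the low-frequency end most. Phase R² uses
radians. Model comparison ranks candidates by the mean of the two
R² scores; scores tied within 10⁻³ resolve in favor of fewer
parameters, so a parsimonious model beats an over-parameterized one
that fits no better.

## Temporal analysis

Each time point of a session is fitted independently — no warm
starting — so estimation errors at consecutive sweeps stay
uncorrelated at the cost of repeated multi-starts. Fitted parameters
are strung into per-parameter trajectories; cohorts are summarized by
the pointwise median across subjects (robust to one aberrant subject);
and a trajectory's trend is the sign of a least-squares slope on
(time, value), declared *flat* when the line's first-to-last relative
change is below a configurable floor (default 5 %). The slope-sign
statistic is deliberately minimal: six points per hour support little
more.

## Synthetic data

The generator emulates the measurement campaign the analysis targets:
four electrode types — three dry tattoo electrodes (gold, silver,
PEDOT:PSS) and a wet pre-gelled Ag/AgCl reference — six subjects, six
sweeps over one hour, 50 log-spaced frequencies on 20 Hz – 1 kHz,
magnitudes in the tens of kΩ at 20 Hz, phases in [−90°, 0°].

Each electrode type has a ground-truth model-3 parameter set at t = 0,
a drift law, and an inter-subject spread:

- **Drift** is log-linear in time, `p(t) = p(0)·(1+d)^(t/60 min)`.
  Defaults: dry types `d(R0) = +30 %`, `d(C0) = −25 %` per hour (the
  interface dries out); wet type `d(R0) = −10 %` (gel keeps improving
  contact). Directions are the documented physics; magnitudes are free
  knobs chosen to be clearly visible above the default noise.
- **Noise**: multiplicative log-normal magnitude noise (relative σ
  1 %) and additive Gaussian phase noise (σ 0.009 rad ≈ 0.5°),
  independent across frequencies and time points. No instrument error
  model is available for the campaign; these are documented stand-ins.
- **Inter-subject spread**: log-normal scale factor (σ = 0.3) per
  R/C/Q parameter and a small clipped jitter (σ = 0.02) on the CPE
  exponents.

Ground-truth values follow a *hierarchical* design: the interface
segment R0 ∥ C0 carries most of the impedance with its relaxation at
60–80 Hz, while the two CPE segments are roughly ten-fold smaller
corrections with dispersions near the band edges (600–700 Hz and
25–30 Hz). This is the physical picture — the interface dominates
dry-electrode impedance and its temporal drift — and it is also the
configuration in which R0 and C0 are best determined by a single
sweep (see below).

What the generator does **not** emulate: sweat or hydration dynamics,
motion artifacts, electrode-area effects, frequency-correlated
instrument error, or any model misspecification — synthetic sweeps
come exactly from the model-3 family plus i.i.d. noise. Passing
end-to-end tests therefore shows the estimator and trend machinery
work when the model family is correct; they say nothing about
model-family adequacy on real skin.

## Identifiability, and what the validation studies show

A central empirical point, established with this package's own tools
(`zskin.fitting.linearized_stddevs`, run by
`examples/identifiability.py`): **the nine-parameter model 3 is not
practically identifiable from one 50-point sweep spanning 1.7 decades
at 1 % noise.** The Fisher/Jacobian dispersion bound at the default
dry-electrode truth is ≈ 8 % for R0 and ≈ 11 % for C0 but runs from
hundreds to over a thousand percent for the small-segment parameters
(Rs ≈ 290 %, R1 ≈ 650 %, R2 ≈ 1400 %), and exploratory redesign of
the truth configuration cannot bring the worst parameter into the
few-percent range — the sloppiness is intrinsic to summing three
dispersions inside so narrow a band. The recovery study in the test
suite confirms it empirically: the global multi-start minimizer
frequently reorganizes the segments into an equivalent-response
configuration far from the generating values while matching the sweep
to within noise (dual R² ≥ 0.999/0.98). Near-perfect R² and meaningful
per-parameter estimates are different claims; only the first is
supported at the full model-3 level. By contrast the same bound for
the single-time-constant fit of the same sweep is ≈ 0.3 % per
parameter.

Consequences adopted in the package defaults:

- Parameter-recovery guarantees are stated and tested where they hold:
  noiseless single-time-constant sweeps recover all parameters to
  < 0.1 %; at 1 % noise only the dominant interface pair (R0, C0) is
  estimated with useful accuracy, and the small-segment parameters are
  descriptive, not inferential.
- Per-session **trend classification defaults to model0**. Its
  effective R0 and C0 absorb the dominant interface segment's drift
  almost completely (the trend example: +30 % true R0 drift appears as
  ≈ +26 %; −25 % C0 as ≈ −22 %; −10 % wet R0 as ≈ −8 %) with
  per-point dispersion ≈ 0.3 %, making per-session trend calls
  essentially error-free. Fitting the full model 3 per time point is
  supported (`fit_session` takes any model) but its R0 trajectories
  carry ≈ 8 % scatter per point even in the best case — too noisy to
  call a −10 % drift reliably from six points.

## Problem sizes used in the validation studies

The shipped studies use 20 replicate spectra with 300 starts for the
headline dual-R² figures; 200 random circuits × 50 frequencies for
oracle equivalence of the evaluator (tolerance 10⁻¹² relative); 20
random truths for noiseless recovery; 20 replicates × 100 starts for
the noisy model-3 recovery study; and 20 dry + 20 wet replicate
sessions for trend recovery. These sizes give stable averages while
keeping each study in the minutes range on one CPU.

## Known limitations

- Magnitude R² on the linear scale under-weights the high-frequency
  end; a log-scale variant would score Bode-plot agreement more
  evenly. The linear form is kept as the documented definition.
- The absolute-value phase residual discards error sign (the norm the
  optimizer minimizes is unaffected).
- No uncertainty quantification beyond multi-start spread diagnostics;
  given the identifiability findings above, bootstrap or profile
  likelihood intervals on model 3 would be wide and strongly
  parameter-dependent.
- Inductive, Warburg/diffusion and nonlinear (amplitude-dependent)
  elements are out of scope, as is Kramers–Kronig validation.
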