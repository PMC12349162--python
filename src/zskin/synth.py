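"""Synthetic skin-electrode impedance sessions and cohorts.

Emulates the measurement campaign the analysis is designed for: four
electrode types (three dry tattoo electrodes - gold, silver, PEDOT:PSS -
and a wet pre-gelled Ag/AgCl reference), six subjects, six sweeps over
one hour, 50 log-spaced frequencies between 20 Hz and 1 kHz, magnitudes
in the tens of kilo-ohms at 20 Hz, phases between -90 and 0 degrees.

Each electrode type has an :class:`ElectrodeProfile`: a ground-truth
three-segment circuit (model3) at t = 0, a per-parameter drift law, and
an inter-subject spread.  Drift is log-linear in time:
``p(t) = p(0) * (1 + d)^(t / 60 min)`` where ``d`` is the signed
relative change over one hour.  Dry electrodes drift with the interface
drying out: the interface resistance R0 rises (+30 %/h by default) and
the interface capacitance C0 falls (-25 %/h); the wet electrode's gel
keeps improving contact so its R0 falls slightly (-10 %/h).  Measurement
noise is multiplicative log-normal on the magnitude (1 % relative by
default) and additive Gaussian on the phase (0.009 rad = 0.5 deg).

Ground-truth parameter values follow a hierarchical design: the first
parallel segment (R0 || C0, the skin-electrode interface proper)
carries most of the impedance, with its relaxation in the lower half of
the band, while the two CPE-bearing segments are smaller corrections
whose dispersions sit near the band edges.  This is both the physical
picture (the interface dominates dry-electrode impedance and its drift)
and the configuration in which the interface parameters R0 and C0 are
best determined by a single 50-point sweep; see the methods note for
the identifiability analysis behind it.

Every generator is deterministic given its seed, and
:func:`generate_cohort` returns a truth ledger alongside the data so
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .circuits import CircuitModel, ParameterSet, circuit_impedance, make_model
from .errors import ConfigurationError
from .spectra import (
    ELECTRODE_TYPES,
    ImpedanceSpectrum,
    SessionSeries,
    default_frequency_grid,
)

__all__ = [
    "NoiseModel",
    "ElectrodeProfile",
    "default_profiles",
    "generate_spectrum",
    "generate_session",
    "generate_cohort",
]

DRY_TYPES = ("gold", "silver", "pedot_pss")
WET_TYPES = ("agagcl",)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise assumptions (the campaign reports none; these are documented stand-ins)."""

    mag_sigma: float = 0.01        # relative sigma of log-normal multiplicative magnitude noise
    phase_sigma: float = 0.009     # rad, additive Gaussian phase noise (~0.5 deg)

    def __post_init__(self) -> None:
        if self.mag_sigma < 0 or self.phase_sigma < 0:
            raise ConfigurationError("noise sigmas must be >= 0")

    @staticmethod
    def none() -> "NoiseModel":
        return NoiseModel(0.0, 0.0)


@dataclass(frozen=True)
class ElectrodeProfile:
    """Ground truth for one electrode type.

    ``drift`` maps parameter name to its signed relative change over 60
    minutes, applied log-linearly in time.  ``spread_sigma`` is the
    log-normal sigma of the per-subject scale factor on R/C/Q
    parameters; ``alpha_jitter`` is the s.d. of a small additive
    per-subject perturbation of the CPE exponents.
    """

    electrode_type: str
    model: CircuitModel
    truth: ParameterSet
    drift: dict[str, float] = field(default_factory=dict)
    spread_sigma: float = 0.3
    alpha_jitter: float = 0.02

    def __post_init__(self) -> None:
        if self.electrode_type not in ELECTRODE_TYPES:
            raise ConfigurationError(f"unknown electrode type {self.electrode_type!r}")
        unknown = set(self.drift) - set(self.model.parameter_names)
        if unknown:
            raise ConfigurationError(f"drift refers to unknown parameter(s) {sorted(unknown)}")
        if self.electrode_type in DRY_TYPES:
            if not self.drift.get("R0", 0) > 0 or not self.drift.get("C0", 0) < 0:
                raise ConfigurationError(
                    "dry profiles must have R0 drift > 0 and C0 drift < 0"
                )
        else:
            if not self.drift.get("R0", 0) < 0:
                raise ConfigurationError("wet profiles must have R0 drift < 0")

    def parameters_at(self, t_min: float) -> ParameterSet:
        """Drift-adjusted parameter values at ``t_min`` minutes."""
        if t_min < 0:
            raise ConfigurationError(f"time must be >= 0 min, got {t_min}")
        values = dict(self.truth.values)
        for name, d in self.drift.items():
            values[name] = values[name] * (1.0 + d) ** (t_min / 60.0)
        return ParameterSet(values, dict(self.truth.bounds), dict(self.truth.units))

    def for_subject(self, rng: np.random.Generator) -> "ElectrodeProfile":
        """A subject-level copy with randomly scaled ground truth."""
        values = dict(self.truth.values)
        for name in values:
            if name.startswith("alpha"):
                if self.alpha_jitter > 0:
                    values[name] = float(
                        np.clip(values[name] + rng.normal(0.0, self.alpha_jitter), 0.35, 0.98)
                    )
            elif self.spread_sigma > 0:
                values[name] = float(values[name] * rng.lognormal(0.0, self.spread_sigma))
        return replace(self, truth=ParameterSet.from_values(values, self.truth.bounds))


def _capacitance(R: float, f_c: float) -> float:
    """C giving an R||C segment the characteristic frequency f_c."""
    return 1.0 / (2.0 * np.pi * R * f_c)


def _cpe_Q(R: float, f_c: float, alpha: float) -> float:
    """Q giving an R||CPE segment the characteristic frequency f_c."""
    return 1.0 / (R * (2.0 * np.pi * f_c) ** alpha)


def _model3_truth(
    Rs: float,
    R0: float, fc0: float,
    R1: float, fc1: float, alpha1: float,
    R2: float, fc2: float, alpha2: float,
) -> ParameterSet:
    """Three-segment ground truth parameterized by (R, f_c, alpha) per segment."""
    return ParameterSet.from_values(
        {
            "Rs": Rs,
            "R0": R0, "C0": _capacitance(R0, fc0),
            "R1": R1, "Q1": _cpe_Q(R1, fc1, alpha1), "alpha1": alpha1,
            "R2": R2, "Q2": _cpe_Q(R2, fc2, alpha2), "alpha2": alpha2,
        }
    )


def default_profiles() -> dict[str, ElectrodeProfile]:
    """The four study electrode types with their default ground truths.

    All four use the three-segment circuit (model3).  The dominant
    interface segment relaxes at 60-80 Hz; the high-frequency CPE
    segment near 600-700 Hz and the broad low-frequency CPE segment
    near 25-30 Hz are roughly ten-fold smaller corrections.  Dry types
    differ in level (gold highest); the wet Ag/AgCl profile sits lower
    with a larger interface capacitance, as gelled contact does.
    """
    model3 = make_model("model3")
    dry_drift = {"R0": 0.30, "C0": -0.25}
    wet_drift = {"R0": -0.10}
    profiles = {
        "gold": ElectrodeProfile(
            "gold",
            model3,
            _model3_truth(1.0e3, 3.2e4, 60.0, 3.2e3, 700.0, 0.85, 2.6e3, 25.0, 0.55),
            drift=dry_drift,
        ),
        "silver": ElectrodeProfile(
            "silver",
            model3,
            _model3_truth(9.0e2, 2.7e4, 70.0, 2.8e3, 650.0, 0.82, 2.2e3, 28.0, 0.58),
            drift=dry_drift,
        ),
        "pedot_pss": ElectrodeProfile(
            "pedot_pss",
            model3,
            _model3_truth(8.0e2, 2.2e4, 80.0, 2.4e3, 600.0, 0.80, 2.0e3, 30.0, 0.60),
            drift=dry_drift,
        ),
        "agagcl": ElectrodeProfile(
            "agagcl",
            model3,
            _model3_truth(8.0e2, 1.8e4, 60.0, 1.8e3, 700.0, 0.80, 1.5e3, 25.0, 0.55),
            drift=wet_drift,
        ),
    }
    return profiles


def generate_spectrum(
    profile: ElectrodeProfile,
    t_min: float = 0.0,
    noise: NoiseModel | None = None,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    subject: str | None = None,
    time_index: int | None = None,
) -> ImpedanceSpectrum:
    """One noisy sweep of ``profile`` at session time ``t_min`` minutes."""
    noise = noise if noise is not None else NoiseModel()
    grid = default_frequency_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    z = np.atleast_1d(circuit_impedance(profile.model, profile.parameters_at(t_min), grid))
    mags = np.abs(z)
    phases = np.angle(z)
    if noise.mag_sigma > 0:
        mags = mags * rng.lognormal(0.0, noise.mag_sigma, size=mags.size)
    if noise.phase_sigma > 0:
        phases = phases + rng.normal(0.0, noise.phase_sigma, size=phases.size)
    phases = np.clip(phases, -np.pi / 2, np.pi / 2)
    return ImpedanceSpectrum(
        frequencies=grid,
        magnitudes=mags,
        phases=phases,
        subject=subject,
        electrode_type=profile.electrode_type,
        time_index=time_index,
        time_min=float(t_min),
    )


def generate_session(
    profile: ElectrodeProfile,
    n_timepoints: int = 6,
    duration_min: float = 60.0,
    noise: NoiseModel | None = None,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    subject: str | None = None,
) -> SessionSeries:
    """Equally spaced sweeps over a session (default 6 sweeps over one hour)."""
    if n_timepoints < 2:
        raise ConfigurationError("a session needs n_timepoints >= 2")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    times = np.linspace(0.0, duration_min, n_timepoints)
    spectra = [
        generate_spectrum(
            profile, t, noise=noise, grid=grid, rng=rng, subject=subject, time_index=i
        )
        for i, t in enumerate(times)
    ]
    return SessionSeries(spectra)


def generate_cohort(
    profiles: dict[str, ElectrodeProfile] | None = None,
    n_subjects: int = 6,
    n_timepoints: int = 6,
    duration_min: float = 60.0,
    noise: NoiseModel | None = None,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], SessionSeries], dict[tuple[str, str], ElectrodeProfile]]:
    """Sessions for every subject x electrode type, plus the truth ledger.

    Returns ``(sessions, truths)`` both keyed by
    ``(subject_id, electrode_type)``; ``truths`` holds each subject's
    scaled profile so that recovery error can be measured against the
    exact generating parameters.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    profiles = profiles if profiles is not None else default_profiles()
    rng = np.random.default_rng(seed)
    sessions: dict[tuple[str, str], SessionSeries] = {}
    truths: dict[tuple[str, str], ElectrodeProfile] = {}
    for i in range(n_subjects):
        subject = f"S{i + 1}"
        for etype, profile in profiles.items():
            subject_profile = profile.for_subject(rng)
            truths[(subject, etype)] = subject_profile
            sessions[(subject, etype)] = generate_session(
                subject_profile,
                n_timepoints=n_timepoints,
                duration_min=duration_min,
                noise=noise,
                grid=grid,
                rng=rng,
                subject=subject,
            )
    return sessions, truths
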