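"""Weighted multi-start nonlinear least-squares estimation of circuit parameters.

The objective compares the modeled complex impedance Zhat(f) with the
measured spectrum separately in magnitude and phase.  Per frequency
point the residual vector holds two dimensionless components::

    r_mag(f) = w_mod * | |Zhat(f)| - |Z(f)| | / |Z(f)|
    r_phi(f) = w_phi * | arg Zhat(f) - arg Z(f) | / max(|arg Z(f)|, phase_floor)

with user weights ``w_mod``/``w_phi`` defaulting to 0.5 each, giving
balanced sensitivity to magnitude and phase error.  ``phase_floor``
(radians) keeps the phase denominator away from zero where the measured
phase crosses 0.

A single local fit is a trust-region-reflective bound-constrained least
squares run (``scipy.optimize.least_squares``), with R, C and Q
optimized in log10 space (they span many decades) and alpha in linear
space; the Jacobian is analytic.  To escape local minima the estimator
is multi-start: ``n_starts`` (default 300) initial vectors are drawn
log-uniformly inside the bounds (alpha uniformly) from a seeded
generator and the candidate with the smallest Euclidean residual norm
wins, ties broken by the lowest start index.

Fit quality is reported as two coefficients of determination

    R^2 = 1 - sum((Z - Zhat)^2) / sum((Z - Zbar)^2)

computed once on magnitudes (linear ohm scale) and once on phases
(radians).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .circuits import (
    CircuitModel,
    ParameterSet,
    circuit_impedance,
    circuit_impedance_jacobian,
    default_bounds,
    default_units,
)
from .errors import ConfigurationError, FittingError
from .spectra import ImpedanceSpectrum

__all__ = [
    "FitConfig",
    "FitResult",
    "residual",
    "r_squared",
    "fit_single_start",
    "fit_multistart",
    "compare_models",
]


@dataclass
class FitConfig:
    """Settings for one estimation run.

    Attributes
    ----------
    w_mod, w_phi
        Non-negative residual weights for the magnitude and phase
        blocks (default 0.5 each).
    n_starts
        Number of multi-start trials (default 300).
    rng_seed
        Seed for the initial-vector stream; fits are deterministic
        given (data, config, seed).
    bounds
        Optional per-parameter (lower, upper) overrides; unspecified
        parameters fall back to the model defaults.
    phase_floor
        Floor (radians) for the phase-residual denominator.
    """

    w_mod: float = 0.5
    w_phi: float = 0.5
    n_starts: int = 300
    rng_seed: int = 0
    bounds: dict[str, tuple[float, float]] | None = None
    phase_floor: float = 1e-3
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12

    def __post_init__(self) -> None:
        if self.w_mod < 0 or self.w_phi < 0 or self.w_mod + self.w_phi <= 0:
            raise ConfigurationError("weights must be >= 0 with w_mod + w_phi > 0")
        if self.n_starts < 1:
            raise ConfigurationError("n_starts must be >= 1")
        if self.phase_floor <= 0:
            raise ConfigurationError("phase_floor must be > 0")

    def resolve_bounds(self, model: CircuitModel) -> dict[str, tuple[float, float]]:
        bounds = default_bounds(model.parameter_names)
        if self.bounds:
            bounds.update({k: v for k, v in self.bounds.items() if k in bounds})
        for name, (lo, hi) in bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi or name.startswith("alpha")):
                raise ConfigurationError(f"bounds for {name!r} must be finite with 0 < lower < upper")
        return bounds


@dataclass
class FitResult:
    """Outcome of a (multi-start) fit."""

    model_name: str
    parameters: ParameterSet
    residual_norm: float
    r2_mag: float
    r2_phase: float
    n_converged: int = 1
    best_start_index: int = 0
    success: bool = True
    trial_norms: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "parameters": dict(self.parameters.values),
            "units": dict(self.parameters.units),
            "residual_norm": self.residual_norm,
            "r2_mag": self.r2_mag,
            "r2_phase": self.r2_phase,
            "n_converged": self.n_converged,
            "best_start_index": self.best_start_index,
            "success": self.success,
        }


# ---------------------------------------------------------------------
# residual and R^2
# ---------------------------------------------------------------------

def _signed_residual_parts(
    s: ImpedanceSpectrum, zhat: np.ndarray, cfg: FitConfig
) -> tuple[np.ndarray, np.ndarray]:
    mag = np.abs(zhat)
    r_mag = cfg.w_mod * (mag - s.magnitudes) / s.magnitudes
    den = np.maximum(np.abs(s.phases), cfg.phase_floor)
    r_phi = cfg.w_phi * (np.angle(zhat) - s.phases) / den
    return r_mag, r_phi


def residual(
    s: ImpedanceSpectrum,
    m: CircuitModel,
    p: ParameterSet | Mapping[str, float],
    cfg: FitConfig | None = None,
) -> np.ndarray:
    """Elementwise non-negative weighted residual (magnitude block then phase block).

    Length is ``2 * len(s)``.  The Euclidean norm of this vector is the
    quantity the estimator minimizes.
    """
    cfg = cfg or FitConfig()
    zhat = np.atleast_1d(circuit_impedance(m, p, s.frequencies))
    r_mag, r_phi = _signed_residual_parts(s, zhat, cfg)
    return np.concatenate([np.abs(r_mag), np.abs(r_phi)])


def r_squared(observed: Sequence[float], fitted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (<= 1)."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.size < 2:
        raise ValueError("observed and fitted must share a length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observed vector is constant")
    return 1.0 - float(np.sum((obs - fit) ** 2)) / ss_tot


# ---------------------------------------------------------------------
# parameter-vector transform (log10 for R/C/Q, linear for alpha)
# ---------------------------------------------------------------------

def _is_linear(name: str) -> bool:
    return name.startswith("alpha")


def _to_internal(values: Mapping[str, float], names: Sequence[str]) -> np.ndarray:
    return np.array(
        [values[n] if _is_linear(n) else np.log10(values[n]) for n in names], dtype=float
    )


def _from_internal(x: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    return {
        n: float(x[j]) if _is_linear(n) else float(10.0 ** x[j]) for j, n in enumerate(names)
    }


def _internal_bounds(bounds: Mapping[str, tuple[float, float]], names: Sequence[str]):
    lo = np.array([bounds[n][0] if _is_linear(n) else np.log10(bounds[n][0]) for n in names])
    hi = np.array([bounds[n][1] if _is_linear(n) else np.log10(bounds[n][1]) for n in names])
    return lo, hi


# ---------------------------------------------------------------------
# single-start and multi-start estimation
# ---------------------------------------------------------------------

def _make_objective(s: ImpedanceSpectrum, m: CircuitModel, cfg: FitConfig, names):
    freqs = s.frequencies
    mags = s.magnitudes
    phases = s.phases
    den = np.maximum(np.abs(phases), cfg.phase_floor)
    ln10 = np.log(10.0)

    def fun(x: np.ndarray) -> np.ndarray:
        values = _from_internal(x, names)
        zhat = np.atleast_1d(circuit_impedance(m, values, freqs))
        r_mag, r_phi = _signed_residual_parts(s, zhat, cfg)
        return np.concatenate([r_mag, r_phi])

    def jac(x: np.ndarray) -> np.ndarray:
        values = _from_internal(x, names)
        zhat, dz = circuit_impedance_jacobian(m, values, freqs)
        mag = np.abs(zhat)
        # d|Z|/dp and d(arg Z)/dp from the complex gradient
        re_proj = (np.conj(zhat)[:, None] * dz).real / mag[:, None]
        im_proj = (np.conj(zhat)[:, None] * dz).imag / (mag**2)[:, None]
        j_mag = cfg.w_mod * re_proj / mags[:, None]
        j_phi = cfg.w_phi * im_proj / den[:, None]
        jacobian = np.vstack([j_mag, j_phi])
        # chain rule for the log10-parameterized coordinates
        scale = np.array(
            [1.0 if _is_linear(n) else values[n] * ln10 for n in names], dtype=float
        )
        return jacobian * scale[None, :]

    return fun, jac


def fit_single_start(
    s: ImpedanceSpectrum,
    m: CircuitModel,
    p0: ParameterSet | Mapping[str, float],
    cfg: FitConfig | None = None,
) -> FitResult:
    """One bound-constrained local fit from initial guess ``p0``.

    Non-convergence is reported through ``success=False`` on the
    returned candidate, never as an exception.
    """
    cfg = cfg or FitConfig()
    names = m.parameter_names
    bounds = cfg.resolve_bounds(m)
    values0 = p0.values if isinstance(p0, ParameterSet) else dict(p0)
    lo, hi = _internal_bounds(bounds, names)
    x0 = np.clip(_to_internal(values0, names), lo, hi)
    fun, jac = _make_objective(s, m, cfg, names)
    try:
        sol = least_squares(
            fun,
            x0,
            jac=jac,
            bounds=(lo, hi),
            method="trf",
            xtol=cfg.xtol,
            ftol=cfg.ftol,
            gtol=cfg.gtol,
        )
        x, ok = sol.x, bool(sol.status > 0)
    except Exception:
        x, ok = x0, False
    best = _from_internal(np.clip(x, lo, hi), names)
    params = ParameterSet(values=best, bounds=dict(bounds), units=default_units(names))
    return _assemble_result(s, m, params, cfg, success=ok)


def _assemble_result(
    s: ImpedanceSpectrum,
    m: CircuitModel,
    params: ParameterSet,
    cfg: FitConfig,
    success: bool,
) -> FitResult:
    zhat = np.atleast_1d(circuit_impedance(m, params, s.frequencies))
    r_mag, r_phi = _signed_residual_parts(s, zhat, cfg)
    norm = float(np.linalg.norm(np.concatenate([r_mag, r_phi])))
    return FitResult(
        model_name=m.name,
        parameters=params,
        residual_norm=norm,
        r2_mag=r_squared(s.magnitudes, np.abs(zhat)),
        r2_phase=r_squared(s.phases, np.angle(zhat)),
        success=success,
    )


def _draw_start(rng: np.random.Generator, names, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    # internal coordinates are already log10 for R/C/Q, so a uniform
    # draw here is log-uniform in the physical parameter
    return rng.uniform(lo, hi)


def fit_multistart(
    s: ImpedanceSpectrum, m: CircuitModel, cfg: FitConfig | None = None
) -> FitResult:
    """Multi-start estimation: best of ``cfg.n_starts`` seeded local fits.

    Initial vectors are drawn sequentially from one seeded stream, so
    the first k starts of an ``n_starts = k`` run coincide with those of
    any longer run with the same seed (the best norm is therefore
    non-increasing in ``n_starts``).

    Raises
    ------
    FittingError
        If every start fails to produce a usable candidate.
    """
    cfg = cfg or FitConfig()
    names = m.parameter_names
    bounds = cfg.resolve_bounds(m)
    lo, hi = _internal_bounds(bounds, names)
    rng = np.random.default_rng(cfg.rng_seed)
    fun, jac = _make_objective(s, m, cfg, names)

    best_x: np.ndarray | None = None
    best_norm = np.inf
    best_index = -1
    n_converged = 0
    trial_norms = np.full(cfg.n_starts, np.nan)
    for i in range(cfg.n_starts):
        x0 = _draw_start(rng, names, lo, hi)
        try:
            sol = least_squares(
                fun, x0, jac=jac, bounds=(lo, hi), method="trf",
                xtol=cfg.xtol, ftol=cfg.ftol, gtol=cfg.gtol,
            )
        except Exception:
            continue
        if sol.status <= 0 or not np.all(np.isfinite(sol.x)):
            continue
        n_converged += 1
        norm = float(np.linalg.norm(sol.fun))
        trial_norms[i] = norm
        if norm < best_norm:  # strict: ties keep the lowest start index
            best_norm, best_x, best_index = norm, sol.x, i
    if best_x is None:
        raise FittingError(
            f"all {cfg.n_starts} starts failed for {m.name}; consider wider bounds"
        )
    values = _from_internal(np.clip(best_x, lo, hi), names)
    params = ParameterSet(values=values, bounds=dict(bounds), units=default_units(names))
    result = _assemble_result(s, m, params, cfg, success=True)
    result.n_converged = n_converged
    result.best_start_index = best_index
    result.trial_norms = trial_norms
    return result


def linearized_stddevs(
    s: ImpedanceSpectrum,
    m: CircuitModel,
    p: ParameterSet | Mapping[str, float],
    cfg: FitConfig | None = None,
    mag_sigma: float = 0.01,
    phase_sigma: float = 0.009,
) -> dict[str, float]:
    """First-order parameter dispersion at ``p`` under a stated noise model.

    Whitens the residual Jacobian by the per-component noise standard
    deviation (relative ``mag_sigma`` on magnitudes, absolute
    ``phase_sigma`` radians on phases) and returns, per parameter, the
    square root of the corresponding diagonal of the inverse Fisher
    information — i.e. the best-case *relative* standard deviation for
    R/C/Q (absolute for alpha) achievable by any unbiased fit of this
    spectrum.  Large values flag parameters the sweep cannot determine,
    however good the fit looks.
    """
    cfg = cfg or FitConfig()
    names = m.parameter_names
    _, jac = _make_objective(s, m, cfg, names)
    x = _to_internal(p.values if isinstance(p, ParameterSet) else p, names)
    J = jac(x)
    den = np.maximum(np.abs(s.phases), cfg.phase_floor)
    row_sigma = np.concatenate(
        [np.full(len(s), cfg.w_mod * mag_sigma), cfg.w_phi * phase_sigma / den]
    )
    Jw = J / row_sigma[:, None]
    cov = np.linalg.inv(Jw.T @ Jw)
    sig = np.sqrt(np.abs(np.diag(cov)))
    # internal coordinates are log10 for R/C/Q: convert to relative sigma
    return {
        n: float(sg if _is_linear(n) else sg * np.log(10.0))
        for n, sg in zip(names, sig)
    }


def compare_models(
    s: ImpedanceSpectrum,
    models: Sequence[CircuitModel],
    cfg: FitConfig | None = None,
    tie_tol: float = 1e-3,
):
    """Fit every candidate model and rank them.

    Primary score is the mean of r2_mag and r2_phase (higher is
    better); models whose scores agree within ``tie_tol`` are ordered
    by parameter count (parsimony wins).  Returns a pandas DataFrame
    sorted best-first, with a ``fit`` column holding each
    :class:`FitResult` (None for models whose fit failed).
    """
    import pandas as pd

    if len(models) < 2:
        raise ConfigurationError("compare_models needs at least 2 candidate models")
    cfg = cfg or FitConfig()
    rows = []
    for m in models:
        try:
            res = fit_multistart(s, m, cfg)
            rows.append(
                {
                    "model": m.name,
                    "n_parameters": m.n_parameters,
                    "r2_mag": res.r2_mag,
                    "r2_phase": res.r2_phase,
                    "score": 0.5 * (res.r2_mag + res.r2_phase),
                    "residual_norm": res.residual_norm,
                    "fit": res,
                }
            )
        except FittingError:
            rows.append(
                {
                    "model": m.name,
                    "n_parameters": m.n_parameters,
                    "r2_mag": np.nan,
                    "r2_phase": np.nan,
                    "score": -np.inf,
                    "residual_norm": np.nan,
                    "fit": None,
                }
            )
    df = pd.DataFrame(rows)
    # quantize the score so near-identical fits resolve on parsimony
    df["_score_bin"] = np.floor(df["score"] / tie_tol + 0.5)
    df = (
        df.sort_values(["_score_bin", "n_parameters"], ascending=[False, True])
        .drop(columns="_score_bin")
        .reset_index(drop=True)
    )
    df.index.name = "rank"
    return df
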