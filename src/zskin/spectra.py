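"""Impedance spectra, measurement sessions, and their CSV dialect.

A spectrum is one frequency sweep recorded in polar form: frequencies in
Hz, magnitudes |Z| in ohm, phases in radians (degrees only at the file
boundary, matching instrument exports).  Sessions collect the repeated
sweeps of one subject x electrode type over an hour-long sitting.

CSV dialect
-----------
UTF-8, comma separated, required header ``frequency_hz,z_mag_ohm,z_phase_deg``,
optional leading metadata comment lines ``# key: value``.  A session
manifest is a CSV with columns ``subject,electrode_type,time_min,file``
whose ``file`` paths are resolved relative to the manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ELECTRODE_TYPES",
    "ImpedanceSpectrum",
    "CartesianSpectrum",
    "SessionSeries",
    "polar_to_cartesian",
    "cartesian_to_polar",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_session_manifest",
    "write_session_manifest",
    "default_frequency_grid",
]

ELECTRODE_TYPES = ("gold", "silver", "pedot_pss", "agagcl")

_HEADER = ("frequency_hz", "z_mag_ohm", "z_phase_deg")


def default_frequency_grid(n_points: int = 50, f_min: float = 20.0, f_max: float = 1000.0) -> np.ndarray:
    """Log-spaced frequency grid over the biopotential band 20 Hz - 1 kHz."""
    return np.logspace(np.log10(f_min), np.log10(f_max), n_points)


@dataclass
class ImpedanceSpectrum:
    """One polar impedance sweep with session metadata.

    Phases are radians in memory.  Physically a passive skin-electrode
    interface has phase in [-pi/2, 0]; values in (0, pi/2] are accepted
    with a warning, anything outside [-pi/2, pi/2] is rejected.
    """

    frequencies: np.ndarray
    magnitudes: np.ndarray
    phases: np.ndarray
    subject: str | None = None
    electrode_type: str | None = None
    time_index: int | None = None
    time_min: float | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.frequencies.size
        if self.magnitudes.size != n or self.phases.size != n:
            raise ValidationError(
                f"length mismatch: {n} frequencies, {self.magnitudes.size} magnitudes, "
                f"{self.phases.size} phases"
            )
        if n == 0:
            raise ValidationError("empty spectrum")
        if np.any(~np.isfinite(self.frequencies)) or np.any(self.frequencies <= 0):
            raise ValidationError("frequencies must be finite and > 0")
        if np.any(np.diff(self.frequencies) <= 0):
            rows = np.where(np.diff(self.frequencies) <= 0)[0]
            raise ValidationError(f"frequencies not strictly increasing at row(s) {rows + 2}")
        bad = np.where(~np.isfinite(self.magnitudes) | (self.magnitudes <= 0))[0]
        if bad.size:
            raise ValidationError(f"non-positive magnitude at row(s) {bad + 1}")
        half_pi = np.pi / 2
        bad = np.where(~np.isfinite(self.phases) | (np.abs(self.phases) > half_pi + 1e-12))[0]
        if bad.size:
            raise ValidationError(f"phase outside [-90, 90] deg at row(s) {bad + 1}")
        if np.any(self.phases > 1e-12):
            warnings.warn(
                "phase above 0 deg: outside the physically expected [-90, 0] deg band",
                stacklevel=3,
            )
        if self.electrode_type is not None and self.electrode_type not in ELECTRODE_TYPES:
            raise ValidationError(
                f"unknown electrode_type {self.electrode_type!r}; expected one of {ELECTRODE_TYPES}"
            )

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def complex_impedance(self) -> np.ndarray:
        """Cartesian view Z' + j Z'' of the polar data."""
        return self.magnitudes * np.exp(1j * self.phases)


@dataclass
class CartesianSpectrum:
    """Real/imaginary impedance components Z', Z'' versus frequency."""

    frequencies: np.ndarray
    real: np.ndarray
    imaginary: np.ndarray


def polar_to_cartesian(s: ImpedanceSpectrum) -> CartesianSpectrum:
    """Convert polar (|Z|, theta) to Cartesian Z' = |Z| cos(theta), Z'' = |Z| sin(theta)."""
    return CartesianSpectrum(
        frequencies=s.frequencies.copy(),
        real=s.magnitudes * np.cos(s.phases),
        imaginary=s.magnitudes * np.sin(s.phases),
    )


def cartesian_to_polar(c: CartesianSpectrum, **metadata) -> ImpedanceSpectrum:
    """Inverse of :func:`polar_to_cartesian`."""
    return ImpedanceSpectrum(
        frequencies=np.asarray(c.frequencies, dtype=float).copy(),
        magnitudes=np.hypot(c.real, c.imaginary),
        phases=np.arctan2(c.imaginary, c.real),
        **metadata,
    )


@dataclass
class SessionSeries:
    """Time-ordered spectra for one subject x electrode type."""

    spectra: list[ImpedanceSpectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValidationError("a session needs at least one spectrum")
        times = self.times
        if any(t is None for t in times):
            raise ValidationError("every session spectrum needs time_min metadata")
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"session time points not strictly increasing: {list(times)}")
        grid = self.spectra[0].frequencies
        for i, s in enumerate(self.spectra[1:], start=1):
            if s.frequencies.size != grid.size or not np.allclose(s.frequencies, grid, rtol=1e-9):
                raise ValidationError(f"spectrum {i} is not on the shared frequency grid")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_min for s in self.spectra], dtype=float)

    @property
    def subject(self) -> str | None:
        return self.spectra[0].subject

    @property
    def electrode_type(self) -> str | None:
        return self.spectra[0].electrode_type

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


# ---------------------------------------------------------------------
# CSV boundary (degrees in files, radians in memory)
# ---------------------------------------------------------------------

_META_KEYS = {"subject": str, "electrode_type": str, "time_index": int, "time_min": float}


def write_spectrum_csv(s: ImpedanceSpectrum, path) -> None:
    path = Path(path)
    lines = []
    for key in _META_KEYS:
        value = getattr(s, key)
        if value is not None:
            lines.append(f"# {key}: {value}")
    lines.append(",".join(_HEADER))
    for f, m, ph in zip(s.frequencies, s.magnitudes, np.degrees(s.phases)):
        # repr of Python floats round-trips exactly
        lines.append(f"{float(f)!r},{float(m)!r},{float(ph)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_spectrum_csv(path) -> ImpedanceSpectrum:
    path = Path(path)
    meta: dict[str, object] = {}
    with path.open(encoding="utf-8") as fh:
        text = fh.read()
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            key = key.strip()
            if key in _META_KEYS:
                meta[key] = _META_KEYS[key](value.strip())
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _HEADER if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}; header must be {','.join(_HEADER)}")
    try:
        return ImpedanceSpectrum(
            frequencies=df["frequency_hz"].to_numpy(float),
            magnitudes=df["z_mag_ohm"].to_numpy(float),
            phases=np.radians(df["z_phase_deg"].to_numpy(float)),
            **meta,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_session_manifest(sessions: Sequence[SessionSeries], directory) -> Path:
    """Write each spectrum CSV plus a ``manifest.csv`` into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for session in sessions:
        for s in session:
            fname = f"{s.subject}_{s.electrode_type}_t{s.time_index:02d}.csv"
            write_spectrum_csv(s, directory / fname)
            rows.append(
                {
                    "subject": s.subject,
                    "electrode_type": s.electrode_type,
                    "time_min": s.time_min,
                    "file": fname,
                }
            )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_session_manifest(manifest_path) -> list[SessionSeries]:
    """Load every (subject, electrode_type) session listed in a manifest CSV."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"subject", "electrode_type", "time_min", "file"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{manifest_path}: manifest missing column(s) {sorted(missing)}")
    sessions = []
    for (_subject, _etype), group in df.groupby(["subject", "electrode_type"], sort=True):
        group = group.sort_values("time_min")
        spectra = []
        for _, row in group.iterrows():
            s = read_spectrum_csv(manifest_path.parent / row["file"])
            if s.time_min is None:
                s = replace(s, time_min=float(row["time_min"]))
            spectra.append(s)
        sessions.append(SessionSeries(spectra))
    return sessions
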