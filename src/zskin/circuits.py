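"""Equivalent-circuit element algebra for skin-electrode impedance.

A circuit is an ordered series chain of elements and parallel segments.
Three passive element kinds are supported:

``resistor``
    ``Z_R = R``
``capacitor``
    ``Z_C = 1 / (j 2*pi*f C)``
``cpe`` (constant phase element)
    ``Z_CPE = 1 / (Q (j 2*pi*f)^alpha)``

The CPE convention is the common electrochemical one with ``Q`` in
S*s^alpha; its phase is exactly ``-alpha * 90`` degrees at every
frequency, so it interpolates between a resistor of ``1/Q`` (alpha = 0)
and a capacitor of ``C = Q`` (alpha = 1).  All math uses frequency in Hz
with explicit ``2*pi`` factors.

Four built-in skin-electrode topologies are provided by
:func:`make_model`.  ``model0`` is the classical single-time-constant
circuit ``Rs - (R0 || C0)``; ``model1``-``model3`` add CPE-bearing
parallel segments of increasing detail (see each model's docstring and
the package methods note).  Custom topologies can be described by a
small config structure that round-trips through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = [
    "Element",
    "ParallelSegment",
    "CircuitModel",
    "ParameterSet",
    "element_impedance",
    "circuit_impedance",
    "circuit_impedance_jacobian",
    "make_model",
    "default_bounds",
    "default_units",
    "BUILTIN_MODELS",
]

_KINDS = ("resistor", "capacitor", "cpe")

# Per-kind scalar fields, in evaluation order.
_FIELDS = {"resistor": ("R",), "capacitor": ("C",), "cpe": ("Q", "alpha")}

# Default fitting bounds per parameter family (overridable everywhere).
# alpha is bounded away from 0 during fitting to avoid the resistor
# degeneracy CPE(alpha=0) == R = 1/Q; evaluation accepts the full [0, 1].
_DEFAULT_BOUNDS = {
    "R": (1.0, 1e8),        # ohm
    "C": (1e-13, 1e-3),     # farad
    "Q": (1e-12, 1e-2),     # S * s^alpha
    "alpha": (0.3, 1.0),
}

_UNITS = {"R": "ohm", "C": "F", "Q": "S*s^alpha", "alpha": ""}


def _check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ConfigurationError(f"parameter {name!r} must be finite and > 0, got {value!r}")


def _check_alpha(name: str, value: float) -> None:
    if not np.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"parameter {name!r} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class Element:
    """One passive element.

    Parameters
    ----------
    kind
        One of ``resistor``, ``capacitor``, ``cpe``.
    params
        Concrete scalar values keyed by field name (``R``, ``C``, ``Q``,
        ``alpha``).  May be empty for a symbolic element inside a
        :class:`CircuitModel`, in which case ``names`` maps each field
        to a model parameter label.
    names
        Model parameter labels, one per field of ``kind`` (for example
        ``("Q1", "alpha1")`` for a CPE).  Empty for a stand-alone
        concrete element.
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown element kind {self.kind!r}; expected one of {_KINDS}")
        fields = _FIELDS[self.kind]
        if self.names and len(self.names) != len(fields):
            raise ConfigurationError(
                f"{self.kind} takes {len(fields)} parameter name(s) {fields}, got {self.names}"
            )
        if self.params:
            missing = [f for f in fields if f not in self.params]
            if missing:
                raise ConfigurationError(f"{self.kind} element missing parameter(s) {missing}")
            for f in fields:
                (_check_alpha if f == "alpha" else _check_positive)(f, self.params[f])

    @property
    def fields(self) -> tuple[str, ...]:
        return _FIELDS[self.kind]

    # -- convenience constructors -------------------------------------
    @staticmethod
    def resistor(R: float) -> "Element":
        return Element("resistor", {"R": float(R)})

    @staticmethod
    def capacitor(C: float) -> "Element":
        return Element("capacitor", {"C": float(C)})

    @staticmethod
    def cpe(Q: float, alpha: float) -> "Element":
        return Element("cpe", {"Q": float(Q), "alpha": float(alpha)})


@dataclass(frozen=True)
class ParallelSegment:
    """Elements combined in parallel; admittances sum."""

    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        if len(self.elements) == 0:
            raise ConfigurationError("a parallel segment needs at least one element")


ChainEntry = Union[Element, ParallelSegment]


def _element_admittance(kind: str, vals: Sequence[float], omega: np.ndarray) -> np.ndarray:
    """Complex admittance of one element at angular frequencies omega."""
    if kind == "resistor":
        (R,) = vals
        return np.full_like(omega, 1.0 / R, dtype=complex)
    if kind == "capacitor":
        (C,) = vals
        return 1j * omega * C
    Q, alpha = vals
    return Q * (1j * omega) ** alpha


def _element_impedance_array(kind: str, vals: Sequence[float], omega: np.ndarray) -> np.ndarray:
    return 1.0 / _element_admittance(kind, vals, omega)


def element_impedance(e: Element, f) -> complex | np.ndarray:
    """Complex impedance of a concrete element at frequency ``f`` (Hz).

    Raises
    ------
    ConfigurationError
        If the element is symbolic (has no concrete parameter values)
        or a parameter is inadmissible.
    ValueError
        If any frequency is not strictly positive.
    """
    if not e.params:
        raise ConfigurationError("element has no concrete parameter values")
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0) or not np.all(np.isfinite(f_arr)):
        raise ValueError(f"frequency must be finite and > 0 Hz, got {f!r}")
    omega = 2.0 * np.pi * f_arr
    vals = [e.params[name] for name in e.fields]
    z = _element_impedance_array(e.kind, vals, omega)
    return complex(z) if np.isscalar(f) or f_arr.ndim == 0 else z


@dataclass(frozen=True)
class CircuitModel:
    """A named series chain of elements and parallel segments.

    ``parameter_names`` is the flat ordered list of free scalars, in
    chain order; it is a bijection onto the scalars of the chain.
    """

    name: str
    chain: tuple[ChainEntry, ...]

    def __post_init__(self) -> None:
        names = self._collect_names()
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigurationError(f"duplicate parameter names in chain: {sorted(dupes)}")

    def _collect_names(self) -> list[str]:
        names: list[str] = []
        for entry in self.chain:
            elems = entry.elements if isinstance(entry, ParallelSegment) else (entry,)
            for e in elems:
                if not e.names:
                    raise ConfigurationError(
                        f"element {e.kind!r} in model {self.name!r} has no parameter names"
                    )
                names.extend(e.names)
        return names

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self._collect_names())

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    # -- config round-trip --------------------------------------------
    def to_config(self) -> list[dict]:
        """Topology as a list of ``{"series": ...}`` / ``{"parallel": ...}`` entries."""
        out: list[dict] = []
        for entry in self.chain:
            if isinstance(entry, ParallelSegment):
                out.append(
                    {"parallel": [{"kind": e.kind, "name": _entry_name(e)} for e in entry.elements]}
                )
            else:
                out.append({"series": {"kind": entry.kind, "name": _entry_name(entry)}})
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_config(), sort_keys=False)


def _entry_name(e: Element) -> str:
    if e.kind == "cpe":
        # names are (Q<suffix>, alpha<suffix>); reconstruct the CPE label
        return "CPE" + e.names[0][1:]
    return e.names[0]


def _symbolic_element(kind: str, name: str) -> Element:
    if kind not in _KINDS:
        raise ConfigurationError(f"unknown element kind {kind!r}")
    if kind == "cpe":
        suffix = name[3:] if name.upper().startswith("CPE") else name
        return Element("cpe", names=(f"Q{suffix}", f"alpha{suffix}"))
    return Element(kind, names=(name,))


def _chain_from_config(config: Iterable[Mapping]) -> tuple[ChainEntry, ...]:
    chain: list[ChainEntry] = []
    for i, entry in enumerate(config):
        if not isinstance(entry, Mapping) or len(entry) != 1:
            raise ConfigurationError(
                f"chain entry {i} must be a single-key mapping 'series' or 'parallel', got {entry!r}"
            )
        ((key, value),) = entry.items()
        if key == "series":
            chain.append(_symbolic_element(value["kind"], value["name"]))
        elif key == "parallel":
            chain.append(
                ParallelSegment(tuple(_symbolic_element(e["kind"], e["name"]) for e in value))
            )
        else:
            raise ConfigurationError(f"chain entry {i}: unknown key {key!r}")
    if not chain:
        raise ConfigurationError("empty chain")
    return tuple(chain)


def _rc_segment(i: int) -> ParallelSegment:
    return ParallelSegment(
        (Element("resistor", names=(f"R{i}",)), Element("capacitor", names=(f"C{i}",)))
    )


def _rcpe_segment(i: int) -> ParallelSegment:
    return ParallelSegment(
        (Element("resistor", names=(f"R{i}",)), Element("cpe", names=(f"Q{i}", f"alpha{i}")))
    )


def _rs() -> Element:
    return Element("resistor", names=("Rs",))


def _builtin_models() -> dict[str, CircuitModel]:
    return {
        # single time constant: Rs - (R0 || C0)
        "model0": CircuitModel("model0", (_rs(), _rc_segment(0))),
        # Rs - (R0 || CPE0)
        "model1": CircuitModel("model1", (_rs(), _rcpe_segment(0))),
        # Rs - (R0 || C0) - (R1 || CPE1)
        "model2": CircuitModel("model2", (_rs(), _rc_segment(0), _rcpe_segment(1))),
        # Rs - (R0 || C0) - (R1 || CPE1) - (R2 || CPE2)
        "model3": CircuitModel("model3", (_rs(), _rc_segment(0), _rcpe_segment(1), _rcpe_segment(2))),
    }


BUILTIN_MODELS = tuple(_builtin_models())


def make_model(name: str, topology_config: Union[Iterable[Mapping], str, None] = None) -> CircuitModel:
    """Build a circuit model by name.

    Built-ins (``model0`` .. ``model3``) are the four skin-electrode
    candidate circuits; the first parallel segment ``R0 || C0`` (or
    ``R0 || CPE0`` for model1) represents the skin-electrode interface
    proper, further segments represent deeper epidermal layers.

    ``name="custom"`` requires ``topology_config``: either the config
    list accepted by :meth:`CircuitModel.to_config` or a YAML string of
    it.
    """
    builtins = _builtin_models()
    if name in builtins:
        if topology_config is not None:
            raise ConfigurationError(f"topology_config is only valid with name='custom', not {name!r}")
        return builtins[name]
    if name == "custom":
        if topology_config is None:
            raise ConfigurationError("name='custom' requires a topology_config")
        if isinstance(topology_config, str):
            topology_config = yaml.safe_load(topology_config)
        return CircuitModel("custom", _chain_from_config(topology_config))
    raise ConfigurationError(f"unknown model {name!r}; choose one of {sorted(builtins)} or 'custom'")


def default_bounds(parameter_names: Iterable[str]) -> dict[str, tuple[float, float]]:
    """Default (lower, upper) fitting bounds keyed by parameter name."""
    out = {}
    for name in parameter_names:
        family = "alpha" if name.startswith("alpha") else name[0]
        if family not in _DEFAULT_BOUNDS:
            raise ConfigurationError(f"no default bounds for parameter {name!r}")
        out[name] = _DEFAULT_BOUNDS[family]
    return out


def default_units(parameter_names: Iterable[str]) -> dict[str, str]:
    return {
        name: _UNITS["alpha" if name.startswith("alpha") else name[0]]
        for name in parameter_names
    }


@dataclass
class ParameterSet:
    """Named parameter values with bounds and units for one model."""

    values: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_values(cls, values: Mapping[str, float],
                    bounds: Mapping[str, tuple[float, float]] | None = None) -> "ParameterSet":
        values = dict(values)
        b = dict(bounds) if bounds is not None else default_bounds(values)
        return cls(values=values, bounds=b, units=default_units(values))

    def validate(self) -> None:
        for name, v in self.values.items():
            if name.startswith("alpha"):
                _check_alpha(name, v)
            else:
                _check_positive(name, v)
            lo, hi = self.bounds.get(name, (-np.inf, np.inf))
            if not (lo <= v <= hi):
                raise ConfigurationError(f"parameter {name!r} = {v!r} outside bounds ({lo}, {hi})")

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), dict(self.bounds), dict(self.units))


def _resolve(values: Mapping[str, float], e: Element) -> list[float]:
    return [values[n] for n in e.names]


def _check_complete(m: CircuitModel, values: Mapping[str, float]) -> None:
    missing = [n for n in m.parameter_names if n not in values]
    if missing:
        raise ConfigurationError(f"parameter set incomplete for {m.name}: missing {missing}")


def circuit_impedance(m: CircuitModel, p: "ParameterSet | Mapping[str, float]", f) -> complex | np.ndarray:
    """Complex impedance of model ``m`` at frequency/frequencies ``f`` (Hz).

    Series entries add as impedances; parallel segments add member
    admittances and invert.  ``p`` may be a :class:`ParameterSet` or a
    plain mapping of parameter name to value.
    """
    values = p.values if isinstance(p, ParameterSet) else p
    _check_complete(m, values)
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0) or not np.all(np.isfinite(f_arr)):
        raise ValueError(f"frequency must be finite and > 0 Hz, got {f!r}")
    omega = 2.0 * np.pi * np.atleast_1d(f_arr)
    z = np.zeros_like(omega, dtype=complex)
    for entry in m.chain:
        if isinstance(entry, ParallelSegment):
            y = np.zeros_like(omega, dtype=complex)
            for e in entry.elements:
                y += _element_admittance(e.kind, _resolve(values, e), omega)
            z += 1.0 / y
        else:
            z += _element_impedance_array(entry.kind, _resolve(values, entry), omega)
    if np.isscalar(f) or f_arr.ndim == 0:
        return complex(z[0])
    return z


def circuit_impedance_jacobian(
    m: CircuitModel, p: "ParameterSet | Mapping[str, float]", f
) -> tuple[np.ndarray, np.ndarray]:
    """Impedance and its gradient w.r.t. every model parameter.

    Returns
    -------
    z : complex ndarray, shape (n_freq,)
    dz : complex ndarray, shape (n_freq, n_parameters)
        ``dz[:, j]`` is the partial derivative of Z with respect to
        ``m.parameter_names[j]`` (linear scale).

    Derivatives follow the admittance algebra: for a parallel segment
    with total admittance Y, dZ/dp = -(dY/dp) / Y^2; member admittance
    derivatives are dY/dR = -1/R^2, dY/dC = j*omega,
    dY/dQ = (j*omega)^alpha, dY/dalpha = Y_cpe * ln(j*omega).
    """
    values = p.values if isinstance(p, ParameterSet) else p
    _check_complete(m, values)
    omega = 2.0 * np.pi * np.atleast_1d(np.asarray(f, dtype=float))
    names = m.parameter_names
    index = {n: j for j, n in enumerate(names)}
    z = np.zeros_like(omega, dtype=complex)
    dz = np.zeros((omega.size, len(names)), dtype=complex)
    log_jw = np.log(omega) + 1j * (np.pi / 2.0)

    for entry in m.chain:
        if isinstance(entry, ParallelSegment):
            y = np.zeros_like(omega, dtype=complex)
            dy = {}
            for e in entry.elements:
                vals = _resolve(values, e)
                ye = _element_admittance(e.kind, vals, omega)
                y += ye
                if e.kind == "resistor":
                    dy[e.names[0]] = np.full_like(omega, -1.0 / vals[0] ** 2, dtype=complex)
                elif e.kind == "capacitor":
                    dy[e.names[0]] = 1j * omega
                else:
                    q_name, a_name = e.names
                    dy[q_name] = ye / vals[0]
                    dy[a_name] = ye * log_jw
            z += 1.0 / y
            inv_y2 = 1.0 / y**2
            for pname, d in dy.items():
                dz[:, index[pname]] += -d * inv_y2
        else:
            vals = _resolve(values, entry)
            ze = _element_impedance_array(entry.kind, vals, omega)
            z += ze
            if entry.kind == "resistor":
                dz[:, index[entry.names[0]]] += 1.0
            elif entry.kind == "capacitor":
                dz[:, index[entry.names[0]]] += -ze / vals[0]
            else:
                q_name, a_name = entry.names
                dz[:, index[q_name]] += -ze / vals[0]
                dz[:, index[a_name]] += -ze * log_jw
    return z, dz
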