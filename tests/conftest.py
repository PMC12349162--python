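"""Shared fixtures and the independent impedance oracle.

The oracle evaluates a circuit chain with scalar ``cmath``-style
arithmetic, element by element and frequency by frequency, writing each
element impedance in explicit polar form.  It shares no code with the
vectorized evaluator in the package and serves as the reference in
equivalence tests.
"""

from __future__ import annotations

import cmath
import math

import numpy as np
import pytest

import zskin


def oracle_element_z(kind: str, name: str, values: dict, f: float) -> complex:
    """Impedance of one element by direct polar-form arithmetic."""
    w = 2.0 * math.pi * f
    if kind == "resistor":
        return complex(values[name], 0.0)
    if kind == "capacitor":
        # 1/(j w C) = (1/(w C)) * exp(-j pi/2)
        return (1.0 / (w * values[name])) * cmath.exp(-1j * math.pi / 2.0)
    suffix = name[3:] if name.upper().startswith("CPE") else name
    q, alpha = values[f"Q{suffix}"], values[f"alpha{suffix}"]
    # 1/(Q (j w)^a) = (1/(Q w^a)) * exp(-j a pi/2)
    return (1.0 / (q * w**alpha)) * cmath.exp(-1j * alpha * math.pi / 2.0)


def oracle_impedance(config: list, values: dict, f: float) -> complex:
    """Chain impedance from a topology config, scalar arithmetic only."""
    total = 0j
    for entry in config:
        if "series" in entry:
            e = entry["series"]
            total += oracle_element_z(e["kind"], e["name"], values, f)
        else:
            y = 0j
            for e in entry["parallel"]:
                y += 1.0 / oracle_element_z(e["kind"], e["name"], values, f)
            total += 1.0 / y
    return total


def random_circuit(rng: np.random.Generator):
    """A random 1-4 entry chain with log-uniform parameter values."""
    config, values = [], {}
    counter = 0

    def add_element(kind):
        nonlocal counter
        name = {"resistor": f"R{counter}", "capacitor": f"C{counter}", "cpe": f"CPE{counter}"}[kind]
        if kind == "resistor":
            values[f"R{counter}"] = 10.0 ** rng.uniform(0, 6)
        elif kind == "capacitor":
            values[f"C{counter}"] = 10.0 ** rng.uniform(-12, -4)
        else:
            values[f"Q{counter}"] = 10.0 ** rng.uniform(-10, -3)
            values[f"alpha{counter}"] = rng.uniform(0.0, 1.0)
        counter += 1
        return {"kind": kind, "name": name}

    for _ in range(rng.integers(1, 5)):
        if rng.random() < 0.4:
            config.append({"series": add_element(rng.choice(["resistor", "capacitor", "cpe"]))})
        else:
            n = int(rng.integers(1, 4))
            config.append(
                {"parallel": [add_element(rng.choice(["resistor", "capacitor", "cpe"])) for _ in range(n)]}
            )
    return config, values


@pytest.fixture(scope="session")
def profiles():
    return zskin.default_profiles()


@pytest.fixture(scope="session")
def gold_profile(profiles):
    return profiles["gold"]


@pytest.fixture(scope="session")
def wet_profile(profiles):
    return profiles["agagcl"]


@pytest.fixture()
def noiseless_gold_spectrum(gold_profile):
    return zskin.generate_spectrum(gold_profile, 0.0, noise=zskin.NoiseModel.none())
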