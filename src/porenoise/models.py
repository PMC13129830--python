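"""Noise-PSD model families for solid-state nanopore ionic-current recordings.

The open-pore current PSD is modelled as a sum of power-law components:
pink/brown low-frequency noise (``a1/f^2 + a2/f`` or a variable-exponent
``a/f^beta``), a white thermal+shot floor ``b``, a dielectric term ``c*f``
and a capacitive/amplifier term ``d*f^2``.  Four model variants differing in
how the low-frequency part is parameterised are exposed:

=====  =============================================  ==================
name   S(f)                                           parameters
=====  =============================================  ==================
4C4P   a/f + b + c f + d f^2                          (a, b, c, d)
4C5P   a/f^beta + b + c f + d f^2                     (a, beta, b, c, d)
5C5P   a1/f^2 + a2/f + b + c f + d f^2                (a1, a2, b, c, d)
5C7P   a1/f^beta1 + a2/f^beta2 + b + c f + d f^2      (a1, beta1, a2, beta2, b, c, d)
=====  =============================================  ==================

All amplitude parameters are physically non-negative; exponents are bounded
to [0, 2].  Amplitudes carry units of (PSD units)*Hz^(exponent-1) on
whichever scale (raw pA^2/Hz or normalized) the curve lives on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseModelSpec",
    "MODEL_SPECS",
    "MODEL_NAMES",
    "PhysicalNoiseParams",
    "get_model_spec",
    "coeffs_to_array",
    "coeffs_from_array",
    "validate_coeffs",
    "evaluate_model",
    "component_breakdown",
    "theoretical_white_noise",
    "theoretical_high_freq_noise",
    "BOLTZMANN",
    "ELEMENTARY_CHARGE",
]

BOLTZMANN = 1.380649e-23  # J/K
ELEMENTARY_CHARGE = 1.602176634e-19  # C

#: exponent parameters, bounded to [0, 2]; everything else is an amplitude in [0, inf)
EXPONENT_PARAMS = frozenset({"beta", "beta1", "beta2"})

EXPONENT_BOUNDS = (0.0, 2.0)


@dataclass(frozen=True)
class NoiseModelSpec:
    """Describes one noise-PSD model variant.

    Parameters are ordered; ``components`` maps a component name to the tuple
    of parameter names it consumes (amplitude first, optional exponent second).
    """

    name: str
    parameter_names: tuple[str, ...]
    components: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    def is_exponent(self, param: str) -> bool:
        return param in EXPONENT_PARAMS

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) bound arrays in parameter order."""
        lo = np.zeros(self.n_params)
        hi = np.array(
            [EXPONENT_BOUNDS[1] if self.is_exponent(p) else np.inf for p in self.parameter_names]
        )
        return lo, hi


MODEL_SPECS: dict[str, NoiseModelSpec] = {
    "4C4P": NoiseModelSpec(
        name="4C4P",
        parameter_names=("a", "b", "c", "d"),
        components=(
            ("flicker", ("a",)),
            ("white", ("b",)),
            ("dielectric", ("c",)),
            ("capacitive", ("d",)),
        ),
    ),
    "4C5P": NoiseModelSpec(
        name="4C5P",
        parameter_names=("a", "beta", "b", "c", "d"),
        components=(
            ("flicker_beta", ("a", "beta")),
            ("white", ("b",)),
            ("dielectric", ("c",)),
            ("capacitive", ("d",)),
        ),
    ),
    "5C5P": NoiseModelSpec(
        name="5C5P",
        parameter_names=("a1", "a2", "b", "c", "d"),
        components=(
            ("flicker2", ("a1",)),
            ("flicker", ("a2",)),
            ("white", ("b",)),
            ("dielectric", ("c",)),
            ("capacitive", ("d",)),
        ),
    ),
    "5C7P": NoiseModelSpec(
        name="5C7P",
        parameter_names=("a1", "beta1", "a2", "beta2", "b", "c", "d"),
        components=(
            ("flicker_beta1", ("a1", "beta1")),
            ("flicker_beta2", ("a2", "beta2")),
            ("white", ("b",)),
            ("dielectric", ("c",)),
            ("capacitive", ("d",)),
        ),
    ),
}

MODEL_NAMES = tuple(MODEL_SPECS)


def get_model_spec(model: "str | NoiseModelSpec") -> NoiseModelSpec:
    if isinstance(model, NoiseModelSpec):
        return model
    try:
        return MODEL_SPECS[model]
    except KeyError:
        raise ValueError(
            f"unknown noise model {model!r}; choose from {sorted(MODEL_SPECS)}"
        ) from None


def coeffs_to_array(spec: "str | NoiseModelSpec", coeffs: dict) -> np.ndarray:
    spec = get_model_spec(spec)
    missing = [p for p in spec.parameter_names if p not in coeffs]
    if missing:
        raise ValueError(f"coefficients missing parameters {missing} for model {spec.name}")
    extra = set(coeffs) - set(spec.parameter_names)
    if extra:
        raise ValueError(f"coefficients carry parameters {sorted(extra)} unknown to {spec.name}")
    return np.array([float(coeffs[p]) for p in spec.parameter_names])


def coeffs_from_array(spec: "str | NoiseModelSpec", values: np.ndarray) -> dict:
    spec = get_model_spec(spec)
    values = np.asarray(values, dtype=float)
    if values.shape != (spec.n_params,):
        raise ValueError(f"expected {spec.n_params} values for {spec.name}, got {values.shape}")
    return dict(zip(spec.parameter_names, values.tolist()))


def validate_coeffs(spec: "str | NoiseModelSpec", coeffs: dict) -> None:
    """Raise ValueError when a coefficient violates its bound."""
    spec = get_model_spec(spec)
    for p in spec.parameter_names:
        v = float(coeffs[p])
        if spec.is_exponent(p):
            if not (EXPONENT_BOUNDS[0] <= v <= EXPONENT_BOUNDS[1]):
                raise ValueError(f"exponent {p}={v} outside {EXPONENT_BOUNDS}")
        elif v < 0:
            raise ValueError(f"amplitude {p}={v} is negative")


def _check_frequencies(frequencies) -> np.ndarray:
    f = np.asarray(frequencies, dtype=float)
    if f.size and np.any(f <= 0):
        raise ValueError("model evaluation requires strictly positive frequencies (1/f terms)")
    return f


def _component_values(kind: str, params: tuple[float, ...], f: np.ndarray) -> np.ndarray:
    if kind == "flicker2":
        return params[0] / f**2
    if kind == "flicker":
        return params[0] / f
    if kind.startswith("flicker_beta"):
        amp, beta = params
        return amp * f ** (-beta)
    if kind == "white":
        return np.full_like(f, params[0])
    if kind == "dielectric":
        return params[0] * f
    if kind == "capacitive":
        return params[0] * f**2
    raise AssertionError(f"unknown component kind {kind}")


def component_breakdown(
    spec: "str | NoiseModelSpec", coeffs: dict, frequencies
) -> dict[str, np.ndarray]:
    """Per-component PSD curves; their sum equals :func:`evaluate_model`."""
    spec = get_model_spec(spec)
    f = _check_frequencies(frequencies)
    arr = coeffs_to_array(spec, coeffs)  # validates missing/extra first
    validate_coeffs(spec, coeffs)
    idx = {p: i for i, p in enumerate(spec.parameter_names)}
    out: dict[str, np.ndarray] = {}
    for comp_name, param_names in spec.components:
        params = tuple(arr[idx[p]] for p in param_names)
        # flicker_beta1/flicker_beta2 share the variable-exponent form
        kind = "flicker_beta" if comp_name.startswith("flicker_beta") else comp_name
        out[comp_name] = _component_values(kind, params, f)
    return out


def evaluate_model(spec: "str | NoiseModelSpec", coeffs: dict, frequencies) -> np.ndarray:
    """Total model PSD: elementwise sum of the spec's components."""
    parts = component_breakdown(spec, coeffs, frequencies)
    return np.sum(list(parts.values()), axis=0)


@dataclass(frozen=True)
class PhysicalNoiseParams:
    """Physical constants/quantities behind the white and high-frequency terms.

    SI units throughout: temperature in K, resistance in Ohm, current in A,
    capacitances in F, amplifier input voltage noise in V/sqrt(Hz).
    """

    T: float = 295.0
    R: float = 1.0e7
    I: float = 0.0
    D: float = 0.0
    C_chip: float = 0.0
    C_tot: float = 0.0
    v_n: float = 0.0
    k: float = BOLTZMANN
    q: float = ELEMENTARY_CHARGE

    def __post_init__(self):
        if self.T < 0:
            raise ValueError("temperature must be non-negative")
        if self.R <= 0:
            raise ValueError("resistance must be positive")
        if self.C_chip < 0 or self.C_tot < 0:
            raise ValueError("capacitances must be non-negative")


def theoretical_white_noise(params: PhysicalNoiseParams) -> float:
    """Thermal + shot white-noise PSD level, 4kT/R + 2qI, in A^2/Hz."""
    return 4.0 * params.k * params.T / params.R + 2.0 * params.q * abs(params.I)


def theoretical_high_freq_noise(params: PhysicalNoiseParams, frequencies) -> np.ndarray:
    """Dielectric + capacitive PSD, 8*pi*kT*D*C_chip*f + 4*pi^2*C_tot^2*v_n^2*f^2.

    The amplifier voltage-noise density enters squared, the standard form for
    a capacitively-coupled voltage noise converted to current noise.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    dielectric = 8.0 * np.pi * params.k * params.T * params.D * params.C_chip * f
    capacitive = 4.0 * np.pi**2 * params.C_tot**2 * params.v_n**2 * f**2
    return dielectric + capacitive
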