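"""Synthetic open-pore recordings with known noise coefficients.

Wetted and unwetted pores are emulated as spectral archetypes of the
five-component noise model a1/f^2 + a2/f + b + c f + d f^2 (raw scale,
pA^2/Hz).  The generator encodes the physics that matters for wettedness:

* the mean current follows Ohm's law, I = V/R, with unwetted pores drawing
  a much higher resistance (nanobubble-blocked lumen) and therefore a lower
  thermal+shot white floor b ~ 4kT/R + 2qI;
* flicker noise is Hooge-like, a2 = a * I^2, so the 1/f strength scales
  with the square of the current at every voltage;
* draws are rejected until the 1/f-to-white crossover a2/b lands below
  100 Hz (wetted: short 1/f region, broad white plateau) or above 1 kHz
  (unwetted: extended 1/f shoulder, narrowed white band).

Two generation routes exist: PSD-level (the model curve times independent
Gamma(n_averages, mean 1) factors per bin, emulating averaged-periodogram
sampling noise; fast, used for classifier-scale experiments) and
trace-level (frequency-domain colored-noise synthesis followed by a real
inverse FFT; used for end-to-end tests of the spectral pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import BOLTZMANN, ELEMENTARY_CHARGE, evaluate_model
from .psd import CurrentSegment, PsdEstimate

__all__ = [
    "ArchetypeConfig",
    "DatasetConfig",
    "WETTED_ARCHETYPE",
    "UNWETTED_ARCHETYPE",
    "DEFAULT_ARCHETYPES",
    "sample_coefficients",
    "synthesize_psd",
    "synthesize_trace",
    "generate_dataset",
    "SyntheticDataset",
    "welch_n_averages",
]

PA2_PER_A2 = 1e24  # 1 A^2/Hz = 1e24 pA^2/Hz

_FACTOR_NAMES = ("resistance", "hooge", "f2", "white", "dielectric", "capacitive")


@dataclass(frozen=True)
class ArchetypeConfig:
    """Distributional archetype for one wetting state.

    Medians are multiplied by lognormal factors (natural-log SD ``sigma``)
    at draw time.  ``crossover_max``/``crossover_min`` constrain the
    1/f-to-white crossover frequency a2/b (Hz) by rejection.
    """

    label: str
    resistance: float  # median R, Ohm
    hooge_strength: float  # a: a2 = a * I^2 with I in pA -> a2 in pA^2
    f2_strength: float  # median a1, pA^2*Hz
    white_factor: float = 1.2  # b = factor * (4kT/R + 2qI)
    dielectric: float = 1.0e-6  # median c, pA^2/Hz per Hz
    capacitive: float = 3.0e-11  # median d, pA^2/Hz per Hz^2
    sigma: float = 0.35  # lognormal spread per drawn factor
    crossover_max: float | None = None  # wetted: a2/b < this (Hz)
    crossover_min: float | None = None  # unwetted: a2/b > this (Hz)
    temperature: float = 295.0  # K
    max_rejections: int = 10_000

    def draw_factors(self, rng: np.random.Generator, sigma: float | None = None) -> dict:
        s = self.sigma if sigma is None else sigma
        z = rng.normal(0.0, s, size=len(_FACTOR_NAMES))
        return dict(zip(_FACTOR_NAMES, np.exp(z)))

    def coefficients_at(self, voltage: float, factors: dict) -> tuple[dict, float]:
        """Deterministic 5C5P coefficients (pA^2/Hz scale) and mean current
        (pA) for one draw of multiplicative factors at one voltage (mV)."""
        if voltage <= 0:
            raise ValueError("voltage must be positive")
        R = self.resistance * factors["resistance"]
        current_a = voltage * 1e-3 / R  # A
        current_pa = current_a * 1e12
        white_si = 4.0 * BOLTZMANN * self.temperature / R + 2.0 * ELEMENTARY_CHARGE * current_a
        coeffs = {
            "a1": self.f2_strength * factors["f2"],
            "a2": self.hooge_strength * factors["hooge"] * current_pa**2,
            "b": self.white_factor * factors["white"] * white_si * PA2_PER_A2,
            "c": self.dielectric * factors["dielectric"],
            "d": self.capacitive * factors["capacitive"],
        }
        return coeffs, current_pa

    def crossover_ok(self, coeffs: dict) -> bool:
        ratio = coeffs["a2"] / coeffs["b"]
        if self.crossover_max is not None and ratio >= self.crossover_max:
            return False
        if self.crossover_min is not None and ratio <= self.crossover_min:
            return False
        return True


WETTED_ARCHETYPE = ArchetypeConfig(
    label="wetted",
    resistance=1.0e7,  # ~100 nS: a conducting ~25 nm pore in 1 M KCl
    hooge_strength=5.0e-10,
    f2_strength=0.1,  # brown-noise corner vs 1/f near ~2 Hz at 100 mV
    crossover_max=100.0,
)

UNWETTED_ARCHETYPE = ArchetypeConfig(
    label="unwetted",
    resistance=5.0e8,  # nanobubble-blocked lumen: ~50x higher resistance
    hooge_strength=3.0e-5,
    f2_strength=2.0,  # brown-noise corner vs 1/f near ~2 Hz at 100 mV
    crossover_min=1000.0,
)

DEFAULT_ARCHETYPES = {"wetted": WETTED_ARCHETYPE, "unwetted": UNWETTED_ARCHETYPE}


def sample_coefficients(
    archetype: ArchetypeConfig, voltage: float, rng: np.random.Generator
) -> tuple[dict, float]:
    """One rejection-constrained coefficient draw at one voltage.

    Returns (5C5P coefficient dict on the raw pA^2/Hz scale, mean current
    in pA).  Raises on an infeasible archetype (rejection cap exhausted).
    """
    for _ in range(archetype.max_rejections):
        factors = archetype.draw_factors(rng)
        coeffs, current = archetype.coefficients_at(voltage, factors)
        if archetype.crossover_ok(coeffs):
            return coeffs, current
    raise ValueError(
        f"archetype {archetype.label!r} crossover constraints infeasible at "
        f"{voltage} mV after {archetype.max_rejections} rejections"
    )


def _sample_factors_all_voltages(
    archetype: ArchetypeConfig, voltages, rng: np.random.Generator
) -> dict:
    """Factor draw whose crossover constraint holds at every config voltage."""
    for _ in range(archetype.max_rejections):
        factors = archetype.draw_factors(rng)
        if all(
            archetype.crossover_ok(archetype.coefficients_at(v, factors)[0]) for v in voltages
        ):
            return factors
    raise ValueError(
        f"archetype {archetype.label!r} crossover constraints infeasible across "
        f"voltages {tuple(voltages)} after {archetype.max_rejections} rejections"
    )


def welch_n_averages(n_samples: int, nperseg: int) -> int:
    """Number of 50%-overlapped Welch windows in a segment."""
    if n_samples < nperseg:
        raise ValueError("segment shorter than one Welch window")
    return (n_samples - nperseg) // (nperseg // 2) + 1


def synthesize_psd(
    coeffs: dict,
    frequencies,
    n_averages: int,
    rng: np.random.Generator,
    mean_current: float = 0.0,
    voltage: float = 0.0,
    label: str = "unknown",
    group_id: str = "",
) -> PsdEstimate:
    """Model PSD with Welch-averaging sampling noise.

    Each bin is the 5C5P model value times an independent
    Gamma(shape=n_averages, mean=1) factor, the fluctuation law of an
    average of ``n_averages`` independent periodogram bins.
    """
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    f = np.asarray(frequencies, dtype=float)
    truth = evaluate_model("5C5P", coeffs, f)
    noise = rng.gamma(shape=n_averages, scale=1.0 / n_averages, size=f.size)
    return PsdEstimate(
        frequencies=f,
        values=truth * noise,
        normalized=False,
        mean_current=mean_current,
        voltage=voltage,
        n_averages=int(n_averages),
        label=label,
        group_id=group_id,
    )


def synthesize_trace(
    coeffs: dict,
    mean_current: float,
    sampling_rate: float,
    duration: float,
    rng: np.random.Generator,
    voltage: float = 0.0,
    pore_id: str = "pore0",
    experiment_id: str = "exp0",
    label: str = "unknown",
) -> CurrentSegment:
    """Colored-noise current trace whose one-sided PSD follows the model.

    Frequency-domain synthesis: each positive-frequency rFFT bin gets an
    independent complex Gaussian amplitude with E|Z_k|^2 = S(f_k)*fs*N/2,
    then a real inverse FFT; the constant mean current is added on top.
    """
    n = int(round(duration * sampling_rate))
    if n < 2:
        raise ValueError("duration * sampling_rate must be at least 2 samples")
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    spectrum = np.zeros(freqs.size)
    spectrum[1:] = evaluate_model("5C5P", coeffs, freqs[1:])
    z = np.zeros(freqs.size, dtype=complex)
    interior = slice(1, freqs.size - 1 if n % 2 == 0 else freqs.size)
    n_int = len(range(*interior.indices(freqs.size)))
    amp = np.sqrt(spectrum[interior] * sampling_rate * n / 4.0)
    z[interior] = amp * (rng.normal(size=n_int) + 1j * rng.normal(size=n_int))
    if n % 2 == 0:  # real Nyquist bin
        z[-1] = np.sqrt(spectrum[-1] * sampling_rate * n) * rng.normal()
    samples = np.fft.irfft(z, n=n) + mean_current
    return CurrentSegment(
        samples=samples,
        sampling_rate=sampling_rate,
        voltage=voltage,
        pore_id=pore_id,
        experiment_id=experiment_id,
        label=label,
    )


@dataclass(frozen=True)
class DatasetConfig:
    """Shape of a synthetic labelled dataset.

    Defaults mirror an open-pore screening campaign: six applied biases
    from 50 to 300 mV, four-second segments at 200 kHz, and a roughly 10:1
    wetted:unwetted imbalance realised at the pore level (40 vs 4 pores,
    five experiments each, four segments per pore-experiment-voltage cell;
    5280 segments, 240 pore-experiment groups in total).
    """

    n_wetted_pores: int = 40
    n_unwetted_pores: int = 4
    experiments_per_pore: int = 5
    voltages: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0)
    segments_per_cell: int = 4
    segment_length: float = 4.0  # s
    sampling_rate: float = 200_000.0  # Hz
    freq_resolution: float = 5.0  # Hz, for PSD-level generation
    pore_sigma: float = 0.35  # lognormal spread of pore-level factors
    experiment_sigma: float = 0.10  # extra spread between experiments of a pore
    seed: int = 0

    @property
    def nperseg(self) -> int:
        return int(round(self.sampling_rate / self.freq_resolution))

    @property
    def n_averages(self) -> int:
        return welch_n_averages(
            int(round(self.segment_length * self.sampling_rate)), self.nperseg
        )

    def frequency_grid(self) -> np.ndarray:
        """Positive one-sided Welch grid (the f=0 bin carries no model)."""
        df = self.freq_resolution
        return np.arange(df, self.sampling_rate / 2.0 + df / 2.0, df)


class SyntheticDataset:
    """A deterministic manifest of synthetic segments plus realizers.

    The manifest fixes every segment's label, group, voltage, true noise
    coefficients and private seed; ``realize_psd``/``realize_trace``
    materialise segments on demand so classifier-scale datasets never hold
    all spectra in memory at once.
    """

    def __init__(self, config: DatasetConfig, archetypes: dict, manifest: pd.DataFrame):
        self.config = config
        self.archetypes = archetypes
        self.manifest = manifest

    def __len__(self) -> int:
        return len(self.manifest)

    def true_coefficients(self, index: int) -> dict:
        row = self.manifest.iloc[index]
        return {k: float(row[f"true_{k}"]) for k in ("a1", "a2", "b", "c", "d")}

    def realize_psd(self, index: int) -> PsdEstimate:
        row = self.manifest.iloc[index]
        rng = np.random.default_rng(int(row["seed"]))
        return synthesize_psd(
            self.true_coefficients(index),
            self.config.frequency_grid(),
            n_averages=self.config.n_averages,
            rng=rng,
            mean_current=float(row["mean_current"]),
            voltage=float(row["voltage"]),
            label=row["label"],
            group_id=row["group_id"],
        )

    def realize_trace(self, index: int) -> CurrentSegment:
        row = self.manifest.iloc[index]
        rng = np.random.default_rng(int(row["seed"]))
        return synthesize_trace(
            self.true_coefficients(index),
            mean_current=float(row["mean_current"]),
            sampling_rate=self.config.sampling_rate,
            duration=self.config.segment_length,
            rng=rng,
            voltage=float(row["voltage"]),
            pore_id=row["pore_id"],
            experiment_id=row["experiment_id"],
            label=row["label"],
        )

    def iter_psds(self):
        for i in range(len(self)):
            yield self.realize_psd(i)


def generate_dataset(
    config: DatasetConfig, archetypes: dict | None = None
) -> SyntheticDataset:
    """Build the deterministic manifest of a labelled synthetic dataset.

    Coefficient draws are hierarchical: pore-level lognormal factors
    (spread ``pore_sigma``) times experiment-level jitter
    (``experiment_sigma``), with the archetype's crossover constraint
    enforced per pore-experiment jointly over all voltages.  Segments
    within a pore-experiment-voltage cell share coefficients and differ by
    Welch sampling noise (their private seeds).
    """
    archetypes = dict(archetypes or DEFAULT_ARCHETYPES)
    rng = np.random.default_rng(config.seed)
    records = []
    plan = [("wetted", config.n_wetted_pores), ("unwetted", config.n_unwetted_pores)]
    for label, n_pores in plan:
        arch = archetypes[label]
        for p in range(n_pores):
            pore_id = f"{label[0].upper()}{p:03d}"
            pore_factors = arch.draw_factors(rng, sigma=config.pore_sigma)
            for e in range(config.experiments_per_pore):
                experiment_id = f"exp{e:02d}"
                # experiment factors ride on the pore factors; rejection on the combined draw
                combined = None
                for _ in range(arch.max_rejections):
                    jitter = arch.draw_factors(rng, sigma=config.experiment_sigma)
                    cand = {k: pore_factors[k] * jitter[k] for k in pore_factors}
                    if all(
                        arch.crossover_ok(arch.coefficients_at(v, cand)[0])
                        for v in config.voltages
                    ):
                        combined = cand
                        break
                if combined is None:
                    # this pore's base draw cannot satisfy the crossover band: redraw the pore
                    pore_factors = _sample_factors_all_voltages(
                        arch, config.voltages, rng
                    )
                    combined = pore_factors
                for voltage in config.voltages:
                    coeffs, current = arch.coefficients_at(voltage, combined)
                    for s in range(config.segments_per_cell):
                        records.append(
                            {
                                "label": label,
                                "pore_id": pore_id,
                                "experiment_id": experiment_id,
                                "group_id": f"{pore_id}::{experiment_id}",
                                "voltage": voltage,
                                "segment_index": s,
                                "seed": int(rng.integers(0, 2**31 - 1)),
                                "mean_current": current,
                                **{f"true_{k}": v for k, v in coeffs.items()},
                            }
                        )
    manifest = pd.DataFrame.from_records(records)
    manifest.insert(0, "segment_id", np.arange(len(manifest)))
    return SyntheticDataset(config, archetypes, manifest)
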