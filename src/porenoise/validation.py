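"""Synthetic validation studies exercising the full analysis chain.

Each study regenerates its inputs from the archetype generator under the
stated conditions (four-second-equivalent spectra, 39 Welch averages,
six biases from 50 to 300 mV) and measures a property of the method:

* :func:`coefficient_recovery_study` — how accurately the 5C5P + HFLS fit
  recovers known coefficients through Welch sampling noise;
* :func:`model_ranking_study` — the model x weighting RMSE benchmark on
  spectra with both 1/f^2 and 1/f content (nested-model dominance and the
  variable-exponent non-identifiability signature);
* :func:`classifier_study` — mixed-voltage grouped CV and
  leave-one-voltage-out protocols on an imbalanced PSD-level dataset;
* :func:`monitor_study` — streaming one-second wettedness calls on
  well-separated archetype streams, checked against batch classification.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import cross_validate, leave_one_voltage_out, predict_wettedness, train_logistic
from .features import CLASSIFIER_FEATURES
from .fitting import BenchmarkResult, benchmark_models, fit_noise_model, prepare_psd
from .models import component_breakdown
from .monitor import run_monitor
from .pipeline import features_from_dataset, features_from_segments
from .psd import segment_trace
from .simulate import (
    DEFAULT_ARCHETYPES,
    DatasetConfig,
    generate_dataset,
    sample_coefficients,
    synthesize_psd,
    synthesize_trace,
)

logger = logging.getLogger(__name__)

__all__ = [
    "decade_dominant_components",
    "coefficient_recovery_study",
    "model_ranking_study",
    "classifier_study",
    "monitor_study",
]

VOLTAGES = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0)
COEFF_NAMES = ("a1", "a2", "b", "c", "d")
_COMPONENT_OF = {
    "flicker2": "a1",
    "flicker": "a2",
    "white": "b",
    "dielectric": "c",
    "capacitive": "d",
}


def decade_dominant_components(coeffs: dict, frequencies: np.ndarray) -> set[str]:
    """Coefficients whose component is the largest term over a frequency
    range spanning at least one decade of the band."""
    parts = component_breakdown("5C5P", coeffs, frequencies)
    stack = np.vstack([parts[k] for k in parts])
    winner = np.argmax(stack, axis=0)
    out = set()
    for i, comp in enumerate(parts):
        f_dom = frequencies[winner == i]
        if f_dom.size >= 2 and f_dom.max() / f_dom.min() >= 10.0:
            out.add(_COMPONENT_OF[comp])
    return out


def _archetype_psd_stream(n_psds: int, seed: int, n_averages: int = 39):
    """Alternating wetted/unwetted archetype draws across the six biases."""
    rng = np.random.default_rng(seed)
    grid = DatasetConfig().frequency_grid()
    for i in range(n_psds):
        label = "wetted" if i % 2 == 0 else "unwetted"
        voltage = VOLTAGES[i % len(VOLTAGES)]
        coeffs, current = sample_coefficients(DEFAULT_ARCHETYPES[label], voltage, rng)
        psd = synthesize_psd(coeffs, grid, n_averages, rng,
                             mean_current=current, voltage=voltage, label=label)
        yield coeffs, psd


def coefficient_recovery_study(n_psds: int = 50, seed: int = 0) -> pd.DataFrame:
    """Fit 5C5P + HFLS to archetype spectra with Welch sampling noise.

    Returns one row per coefficient: the median relative recovery error
    over the spectra where that coefficient's component dominates at
    least one decade of the fitting band, and the qualifying count.
    """
    errors: dict[str, list[float]] = {k: [] for k in COEFF_NAMES}
    for coeffs, psd in _archetype_psd_stream(n_psds, seed):
        prep = prepare_psd(psd)
        fit = fit_noise_model(prep, "5C5P", "HFLS")
        dominant = decade_dominant_components(coeffs, prep.frequencies)
        for k in dominant:
            recovered = fit.coefficients[k] * prep.normalization_sum
            errors[k].append(abs(recovered - coeffs[k]) / coeffs[k])
    rows = []
    for k in COEFF_NAMES:
        e = np.asarray(errors[k])
        rows.append(
            {
                "coefficient": k,
                "n_qualifying": int(e.size),
                "median_rel_error": float(np.median(e)) if e.size else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("coefficient")


def model_ranking_study(n_psds: int = 100, seed: int = 0) -> BenchmarkResult:
    """Benchmark all 16 model x weighting cells on archetype spectra.

    Every generated spectrum carries nonzero 1/f^2 and 1/f content, so the
    five-component model is the correctly-specified family.
    """
    psds = [psd for _, psd in _archetype_psd_stream(n_psds, seed)]
    return benchmark_models(psds)


def classifier_study(
    config: DatasetConfig | None = None,
    seed: int = 0,
    subset: tuple[str, ...] = CLASSIFIER_FEATURES,
    k: int = 10,
) -> dict:
    """Mixed-voltage CV and leave-one-voltage-out on the default dataset.

    The default :class:`DatasetConfig` supplies the study conditions:
    ~5300 four-second-equivalent segments across six biases at a 10:1
    wetted:unwetted imbalance, generated at PSD level, with no
    class rebalancing anywhere in the pipeline.
    """
    config = config or DatasetConfig(seed=seed)
    dataset = generate_dataset(config)
    features = features_from_dataset(dataset)
    features["label"] = dataset.manifest["label"].to_numpy()
    features["group_id"] = dataset.manifest["group_id"].to_numpy()
    cv_report = cross_validate(
        features, features["label"], features["group_id"], subset, k=k, seed=seed
    )
    lovo_reports = leave_one_voltage_out(
        features, features["label"], features["group_id"], subset
    )
    return {"features": features, "cv": cv_report, "lovo": lovo_reports}


def monitor_study(seed: int = 0, duration: float = 10.0) -> dict:
    """Streaming one-second monitoring of well-separated archetype streams.

    Trains the (logL, a2, b, V) classifier on a small PSD-level dataset,
    then runs the monitor over one wetted and one unwetted
    ``duration``-second stream and re-classifies the same windows in batch
    mode.  Returns per-stream call tables, the fraction of correct calls
    and whether streaming equals batch exactly.
    """
    rng = np.random.default_rng(seed + 1)
    train_cfg = DatasetConfig(
        n_wetted_pores=6, n_unwetted_pores=3, experiments_per_pore=1,
        segments_per_cell=1, seed=seed,
    )
    dataset = generate_dataset(train_cfg)
    features = features_from_dataset(dataset)
    features["label"] = dataset.manifest["label"].to_numpy()
    model = train_logistic(features, features["label"], CLASSIFIER_FEATURES)
    calls, correct, total, streaming_equals_batch = {}, 0, 0, True
    for label in ("wetted", "unwetted"):
        coeffs, current = sample_coefficients(DEFAULT_ARCHETYPES[label], 100.0, rng)
        stream = synthesize_trace(
            coeffs, current, 200_000.0, duration, rng, voltage=100.0, label=label
        )
        table = run_monitor(stream, model, window=1.0)
        calls[label] = table
        correct += int((table["call"] == label).sum())
        total += len(table)
        windows = segment_trace(
            stream.samples, stream.sampling_rate, 1.0,
            voltage=stream.voltage, label=stream.label,
        )
        batch = features_from_segments(windows)
        prob, batch_calls = predict_wettedness(model, batch)
        streaming_equals_batch &= bool(
            np.allclose(table["prob_unwetted"], prob)
            and (table["call"].to_numpy() == batch_calls).all()
        )
    return {
        "calls": calls,
        "accuracy": correct / total,
        "n_windows": total,
        "streaming_equals_batch": streaming_equals_batch,
    }
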