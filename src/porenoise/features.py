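"""Candidate classification features for pore-wettedness prediction.

Nine candidates are computed per segment:

``logL``
    log10 of the L-value, the current-normalized 1/f amplitude fitted in
    closed form to the raw PSD up to 100 Hz — a compact summary of excess
    low-frequency noise.
``a1, a2, b, c, d``
    Noise coefficients from the full-band 5C5P fit, reported on the raw
    pA^2/Hz scale; ``a2`` is additionally divided by the squared mean
    current so the Hooge-like I^2 scaling cancels and the feature tracks
    the pore, not the operating point.
``I_rms5k, delta_rms``
    RMS of the mean-subtracted current after a zero-phase 5 kHz low-pass,
    and |I_peak - I_rms5k| as a simple excursion metric (trace-level only).
``V``
    Applied bias in mV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .fitting import FitResult
from .psd import CurrentSegment, PsdEstimate

__all__ = [
    "FEATURE_CANDIDATES",
    "CLASSIFIER_FEATURES",
    "FeatureVector",
    "l_value",
    "normalized_a2",
    "rms_5khz",
    "build_feature_vector",
    "features_from_psd",
    "feature_frame",
]

FEATURE_CANDIDATES = ("logL", "a1", "a2", "b", "c", "d", "I_rms5k", "delta_rms", "V")

#: the compact subset identified as most informative for wettedness
CLASSIFIER_FEATURES = ("logL", "a2", "b", "V")

LOG_L_FLOOR = 1e-30


@dataclass
class FeatureVector:
    """Candidate features for one segment, plus label and group identity."""

    logL: float
    a1: float
    a2: float
    b: float
    c: float
    d: float
    I_rms5k: float
    delta_rms: float
    V: float
    label: str = "unknown"
    group_id: str = ""

    def as_dict(self) -> dict:
        return {
            **{k: getattr(self, k) for k in FEATURE_CANDIDATES},
            "label": self.label,
            "group_id": self.group_id,
        }


def l_value(
    psd: PsdEstimate, mean_current: float | None = None, f_max: float = 100.0
) -> tuple[float, float]:
    """Closed-form L-value from the raw-scale PSD.

    Fits ``S(f)/I^2 = A/f`` by unweighted least squares over
    ``[freq_resolution, f_max]`` Hz; returns ``(L, log10 L)`` with L = A,
    floored at 1e-30 before the log.  Invariant under the joint scaling
    (S -> k^2 S, I -> k I).
    """
    if psd.normalized:
        raise ValueError("l_value requires the raw-scale PSD")
    current = psd.mean_current if mean_current is None else mean_current
    if current == 0:
        raise ValueError("l_value requires a nonzero mean current")
    fmin = psd.freq_resolution
    mask = (psd.frequencies >= fmin) & (psd.frequencies <= f_max)
    if not mask.any():
        raise ValueError(f"no PSD bins in [{fmin}, {f_max}] Hz for the L-value fit")
    f = psd.frequencies[mask]
    s = psd.values[mask] / current**2
    basis = 1.0 / f
    L = float(np.dot(s, basis) / np.dot(basis, basis))
    return L, float(np.log10(max(L, LOG_L_FLOOR)))


def normalized_a2(
    fit: FitResult, mean_current: float | None = None, normalization_sum: float | None = None
) -> float:
    """Current-normalized 1/f coefficient: raw-scale a2 divided by I^2."""
    current = fit.mean_current if mean_current is None else mean_current
    if current == 0:
        raise ValueError("a2 normalization requires a nonzero mean current")
    scale = fit.normalization_sum if normalization_sum is None else normalization_sum
    a2_raw = fit.coefficients["a2"] * (scale if scale is not None else 1.0)
    return a2_raw / current**2


def rms_5khz(
    segment: CurrentSegment, cutoff: float = 5000.0, order: int = 4
) -> tuple[float, float, float]:
    """Low-passed RMS current and peak-excursion metrics.

    Zero-phase Butterworth low-pass at ``cutoff``; the segment mean is
    subtracted first so the open-pore DC level does not enter.  Returns
    ``(I_rms5k, I_peak, delta_rms)`` with delta_rms = |I_peak - I_rms5k|.
    """
    fs = segment.sampling_rate
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must lie below the Nyquist frequency {fs / 2} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, segment.samples - np.mean(segment.samples))
    i_rms = float(np.sqrt(np.mean(filtered**2)))
    i_peak = float(np.max(np.abs(filtered)))
    return i_rms, i_peak, abs(i_peak - i_rms)


def _fit_features(fit: FitResult) -> dict:
    if fit.model != "5C5P":
        raise ValueError(f"feature extraction requires a 5C5P fit, got {fit.model}")
    scale = fit.normalization_sum if fit.normalization_sum is not None else 1.0
    return {
        "a1": fit.coefficients["a1"] * scale,
        "a2": normalized_a2(fit),
        "b": fit.coefficients["b"] * scale,
        "c": fit.coefficients["c"] * scale,
        "d": fit.coefficients["d"] * scale,
    }


def build_feature_vector(
    segment: CurrentSegment, raw_psd: PsdEstimate, fit: FitResult
) -> FeatureVector:
    """Assemble all nine candidates from a segment, its raw PSD and its fit."""
    L, logL = l_value(raw_psd, mean_current=segment.mean_current)
    i_rms, _, delta = rms_5khz(segment)
    return FeatureVector(
        logL=logL,
        **_fit_features(fit),
        I_rms5k=i_rms,
        delta_rms=delta,
        V=segment.voltage,
        label=segment.label,
        group_id=segment.group_id,
    )


def features_from_psd(raw_psd: PsdEstimate, fit: FitResult) -> FeatureVector:
    """PSD-level feature vector (no time-domain samples available).

    The trace-only candidates ``I_rms5k`` and ``delta_rms`` are NaN.
    """
    L, logL = l_value(raw_psd)
    return FeatureVector(
        logL=logL,
        **_fit_features(fit),
        I_rms5k=np.nan,
        delta_rms=np.nan,
        V=raw_psd.voltage,
        label=raw_psd.label,
        group_id=raw_psd.group_id,
    )


def feature_frame(vectors) -> pd.DataFrame:
    """Stack feature vectors into a table, one row per segment."""
    return pd.DataFrame.from_records([v.as_dict() for v in vectors])
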