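"""Welch PSD estimation and normalization for open-pore current segments.

PSDs are one-sided, density-scaled (pA^2/Hz for current traces in pA), and
estimated with a Hann window, 50% overlap and a configurable frequency
resolution (default 5 Hz, so the segment length in samples per window is
``sampling_rate / freq_resolution``).  Normalization divides every retained
bin by the sum over the retained bins, so a normalized curve sums to one;
the sum is stored so raw-scale quantities can be recovered downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = ["CurrentSegment", "PsdEstimate", "welch_psd", "normalize_psd", "segment_trace"]

LABELS = ("wetted", "unwetted", "unknown")


@dataclass
class CurrentSegment:
    """A labelled window of ionic-current samples with acquisition metadata."""

    samples: np.ndarray  # current, pA
    sampling_rate: float  # Hz
    voltage: float = 0.0  # applied bias, mV
    pore_id: str = "pore0"
    experiment_id: str = "exp0"
    label: str = "unknown"
    start_time: float = 0.0  # s

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def group_id(self) -> str:
        """Pore-experiment combination, the leakage-control grouping key."""
        return f"{self.pore_id}::{self.experiment_id}"

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def mean_current(self) -> float:
        return float(np.mean(self.samples))


@dataclass
class PsdEstimate:
    """One-sided PSD curve on a uniform frequency grid.

    ``values`` are pA^2/Hz when raw and dimensionless (summing to one over
    the retained bins) when ``normalized``.  ``normalization_sum`` holds the
    raw-scale sum used for normalization, enabling de-normalization.
    """

    frequencies: np.ndarray  # Hz, strictly increasing, uniform spacing
    values: np.ndarray
    normalized: bool = False
    mean_current: float = 0.0  # pA
    voltage: float = 0.0  # mV
    n_averages: int = 1
    normalization_sum: float | None = None
    label: str = "unknown"
    group_id: str = ""

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frequencies.shape != self.values.shape:
            raise ValueError("frequencies and values must have the same length")
        if self.frequencies.size >= 2 and np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def freq_resolution(self) -> float:
        if self.frequencies.size < 2:
            raise ValueError("need at least two bins to define a frequency resolution")
        return float(self.frequencies[1] - self.frequencies[0])

    def band(self, fmin: float, fmax: float) -> "PsdEstimate":
        """Restrict to bins with fmin <= f <= fmax (metadata preserved)."""
        mask = (self.frequencies >= fmin) & (self.frequencies <= fmax)
        if not mask.any():
            raise ValueError(f"no PSD bins inside [{fmin}, {fmax}] Hz")
        return replace(self, frequencies=self.frequencies[mask], values=self.values[mask])


def welch_psd(
    segment: CurrentSegment,
    freq_resolution: float = 5.0,
    overlap_fraction: float = 0.5,
    window_shape: str = "hann",
) -> PsdEstimate:
    """Welch PSD of a current segment.

    Window length is ``sampling_rate / freq_resolution`` samples; the window
    mean is subtracted per Welch window so the DC open-pore level does not
    leak into the low-frequency bins (the mean current is kept separately in
    ``mean_current``).  The f=0 bin is retained in the output; fitting and
    normalization exclude it via band selection.
    """
    fs = segment.sampling_rate
    nperseg = int(round(fs / freq_resolution))
    n = segment.samples.size
    if n < nperseg:
        raise ValueError(
            f"segment too short for Welch PSD: need at least {nperseg} samples "
            f"({nperseg / fs:.3g} s at {fs:g} Hz), got {n}"
        )
    noverlap = int(round(nperseg * overlap_fraction))
    freqs, values = signal.welch(
        segment.samples,
        fs=fs,
        window=window_shape,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        return_onesided=True,
        scaling="density",
    )
    hop = nperseg - noverlap
    n_averages = (n - nperseg) // hop + 1
    return PsdEstimate(
        frequencies=freqs,
        values=values,
        normalized=False,
        mean_current=segment.mean_current,
        voltage=segment.voltage,
        n_averages=n_averages,
        label=segment.label,
        group_id=segment.group_id,
    )


def normalize_psd(psd: PsdEstimate) -> PsdEstimate:
    """Divide every bin by the sum over all retained bins.

    Intended to be applied after restricting to the fitting band, so the
    normalizing sum and the fit see the same points.  Idempotent: a curve
    that is already normalized is returned unchanged.
    """
    if psd.normalized:
        return psd
    total = float(np.sum(psd.values))
    if total <= 0:
        raise ValueError("cannot normalize an all-zero (or negative-sum) PSD")
    return replace(psd, values=psd.values / total, normalized=True, normalization_sum=total)


def segment_trace(
    samples,
    sampling_rate: float,
    window_length: float,
    hop: float | None = None,
    voltage: float = 0.0,
    pore_id: str = "pore0",
    experiment_id: str = "exp0",
    label: str = "unknown",
    start_time: float = 0.0,
) -> list[CurrentSegment]:
    """Cut a continuous trace into fixed-length windows.

    The final partial window is dropped.  ``hop`` defaults to the window
    length (contiguous, non-overlapping segments).
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    hop = window_length if hop is None else hop
    if hop <= 0:
        raise ValueError("hop must be positive")
    samples = np.asarray(samples, dtype=float)
    nwin = int(round(window_length * sampling_rate))
    nhop = int(round(hop * sampling_rate))
    if nwin > samples.size:
        raise ValueError("window_length exceeds trace duration")
    out = []
    for k, start in enumerate(range(0, samples.size - nwin + 1, nhop)):
        out.append(
            CurrentSegment(
                samples=samples[start : start + nwin],
                sampling_rate=sampling_rate,
                voltage=voltage,
                pore_id=pore_id,
                experiment_id=experiment_id,
                label=label,
                start_time=start_time + start / sampling_rate,
            )
        )
    return out
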