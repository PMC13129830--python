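"""End-to-end analysis pipelines: PSD -> fit -> features.

The canonical per-segment chain is: Welch PSD (raw scale, for the L-value)
-> fitting-band restriction + normalization -> 5C5P + HFLS fit -> feature
vector.  These helpers run that chain for trace-level segments, raw PSD
curves, and whole synthetic datasets (streamed, so classifier-scale runs
never hold every spectrum in memory).
"""

from __future__ import annotations

import logging

import pandas as pd

from .features import FeatureVector, build_feature_vector, feature_frame, features_from_psd
from .fitting import FitResult, fit_noise_model, prepare_psd
from .psd import CurrentSegment, PsdEstimate, welch_psd
from .simulate import SyntheticDataset

logger = logging.getLogger(__name__)

__all__ = ["analyze_psd", "analyze_segment", "features_from_dataset", "features_from_segments"]


def analyze_psd(
    raw_psd: PsdEstimate,
    model: str = "5C5P",
    weighting: str = "HFLS",
    segment: CurrentSegment | None = None,
    **fit_kw,
) -> tuple[FitResult, FeatureVector]:
    """Fit one raw PSD and assemble its feature vector.

    With a ``segment`` the trace-level RMS candidates are included;
    otherwise they are NaN (PSD-level route).
    """
    fit = fit_noise_model(prepare_psd(raw_psd), model, weighting, **fit_kw)
    if segment is not None:
        vec = build_feature_vector(segment, raw_psd, fit)
    else:
        vec = features_from_psd(raw_psd, fit)
    return fit, vec


def analyze_segment(
    segment: CurrentSegment,
    freq_resolution: float = 5.0,
    model: str = "5C5P",
    weighting: str = "HFLS",
    **fit_kw,
) -> tuple[PsdEstimate, FitResult, FeatureVector]:
    """Welch PSD, noise-model fit and feature vector for one segment."""
    raw = welch_psd(segment, freq_resolution=freq_resolution)
    fit, vec = analyze_psd(raw, model, weighting, segment=segment, **fit_kw)
    return raw, fit, vec


def features_from_dataset(
    dataset: SyntheticDataset, model: str = "5C5P", weighting: str = "HFLS"
) -> pd.DataFrame:
    """Feature table for a synthetic dataset via the PSD-level route.

    Segments are realized, fitted and discarded one at a time.
    """
    rows = []
    for i in range(len(dataset)):
        _, vec = analyze_psd(dataset.realize_psd(i), model, weighting)
        rows.append(vec)
        if (i + 1) % 500 == 0:
            logger.info("featurized %d/%d segments", i + 1, len(dataset))
    frame = feature_frame(rows)
    frame.insert(0, "segment_id", dataset.manifest["segment_id"].to_numpy())
    return frame


def features_from_segments(
    segments, freq_resolution: float = 5.0, model: str = "5C5P", weighting: str = "HFLS"
) -> pd.DataFrame:
    """Feature table for in-memory current segments (trace-level route)."""
    rows = []
    for seg in segments:
        _, _, vec = analyze_segment(seg, freq_resolution, model, weighting)
        rows.append(vec)
    return feature_frame(rows)
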