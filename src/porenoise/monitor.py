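"""Streaming pore-health monitoring on short windows.

A continuous open-pore recording is cut into short windows (default one
second) and each window runs the full chain — Welch PSD at 5 Hz
resolution, 5C5P + HFLS fit, feature vector, classifier probability and
wetted/unwetted call.  By construction the streaming calls equal
batch-mode classification of the same windows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import ClassifierModel, predict_wettedness
from .pipeline import analyze_segment
from .psd import CurrentSegment, segment_trace

logger = logging.getLogger(__name__)

__all__ = ["run_monitor"]


def run_monitor(
    stream: CurrentSegment,
    model: ClassifierModel,
    window: float = 1.0,
    hop: float | None = None,
    freq_resolution: float = 5.0,
) -> pd.DataFrame:
    """Classify every window of a continuous recording.

    Returns one row per window: start time, mean current, the model's
    feature values, the unwetted probability and the state call.  The
    window must hold at least one full Welch segment
    (``sampling_rate / freq_resolution`` samples).
    """
    nperseg = int(round(stream.sampling_rate / freq_resolution))
    if int(round(window * stream.sampling_rate)) < nperseg:
        raise ValueError(
            f"monitor window of {window} s is shorter than one Welch segment "
            f"({nperseg / stream.sampling_rate:.3g} s at {freq_resolution} Hz resolution)"
        )
    windows = segment_trace(
        stream.samples,
        stream.sampling_rate,
        window_length=window,
        hop=hop,
        voltage=stream.voltage,
        pore_id=stream.pore_id,
        experiment_id=stream.experiment_id,
        label=stream.label,
        start_time=stream.start_time,
    )
    rows = []
    for seg in windows:
        _, _, vec = analyze_segment(seg, freq_resolution=freq_resolution)
        feats = pd.DataFrame([vec.as_dict()])
        prob, call = predict_wettedness(model, feats)
        rows.append(
            {
                "start_time": seg.start_time,
                "mean_current": seg.mean_current,
                **{f: feats.at[0, f] for f in model.feature_subset},
                "prob_unwetted": float(prob[0]),
                "call": str(call[0]),
            }
        )
    logger.info("monitored %d windows of %.3g s", len(rows), window)
    return pd.DataFrame(rows)
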