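"""File formats: traces, fitted models, classifiers, reports, run configs.

Conventions (no vendor formats):

* traces — either CSV (``# key: value`` metadata header lines followed by
  one current sample in pA per line) or raw little-endian float32 with a
  JSON sidecar ``<path>.json`` carrying the metadata;
* fitted noise models and classifiers — JSON;
* feature tables and evaluation reports — CSV;
* run configuration — YAML (or JSON) mirroring the CLI flags.

Required trace metadata: ``sampling_rate`` (Hz), ``voltage`` (mV),
``pore_id``, ``experiment_id``; optional ``label`` and ``start_time``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierModel
from .fitting import FitResult
from .psd import CurrentSegment, PsdEstimate

__all__ = [
    "read_trace",
    "write_trace",
    "read_psd_csv",
    "write_psd_csv",
    "fit_result_to_dict",
    "save_fit_result",
    "save_classifier",
    "load_classifier",
    "load_run_config",
]

REQUIRED_TRACE_FIELDS = ("sampling_rate", "voltage", "pore_id", "experiment_id")
_NUMERIC_FIELDS = {"sampling_rate", "voltage", "start_time"}


def _segment_from(samples: np.ndarray, meta: dict, path) -> CurrentSegment:
    for key in REQUIRED_TRACE_FIELDS:
        if key not in meta:
            raise ValueError(f"trace {path} is missing required metadata field {key!r}")
    bad = np.flatnonzero(~np.isfinite(samples))
    if bad.size:
        raise ValueError(f"trace {path} contains a non-finite sample at index {bad[0]}")
    return CurrentSegment(
        samples=samples,
        sampling_rate=float(meta["sampling_rate"]),
        voltage=float(meta["voltage"]),
        pore_id=str(meta["pore_id"]),
        experiment_id=str(meta["experiment_id"]),
        label=str(meta.get("label", "unknown")),
        start_time=float(meta.get("start_time", 0.0)),
    )


def read_trace(path, format: str | None = None) -> CurrentSegment:
    """Read a current trace (pA) from CSV or raw float32 + JSON sidecar.

    ``format`` is inferred from the suffix when omitted (``.csv`` vs
    anything else).
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "raw"
    if format == "csv":
        meta: dict = {}
        values = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("#").partition(":")
                    meta[key.strip()] = val.strip()
                else:
                    values.append(float(line))
        # samples are written at float32 precision; 9 significant digits
        # round-trip exactly through float32
        samples = np.asarray(values, dtype=np.float32).astype(float)
    elif format == "raw":
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(f"raw trace {path} has no JSON sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        samples = np.fromfile(path, dtype="<f4").astype(float)
    else:
        raise ValueError(f"unknown trace format {format!r} (csv or raw)")
    return _segment_from(samples, meta, path)


def write_trace(segment: CurrentSegment, path, format: str | None = None) -> Path:
    """Write a trace as CSV or raw float32 + JSON sidecar (see read_trace)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "raw"
    meta = {
        "sampling_rate": segment.sampling_rate,
        "voltage": segment.voltage,
        "pore_id": segment.pore_id,
        "experiment_id": segment.experiment_id,
        "label": segment.label,
        "start_time": segment.start_time,
        "units": "pA",
    }
    if format == "csv":
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            for v in segment.samples:
                fh.write(f"{np.float32(v):.9g}\n")
    elif format == "raw":
        segment.samples.astype("<f4").tofile(path)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unknown trace format {format!r} (csv or raw)")
    return path


def write_psd_csv(psd: PsdEstimate, path) -> Path:
    path = Path(path)
    header = {
        "normalized": psd.normalized,
        "mean_current": psd.mean_current,
        "voltage": psd.voltage,
        "n_averages": psd.n_averages,
        "normalization_sum": psd.normalization_sum,
        "label": psd.label,
        "group_id": psd.group_id,
    }
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("frequency_hz,psd\n")
        for f, s in zip(psd.frequencies, psd.values):
            fh.write(f"{f:.9g},{s:.9g}\n")
    return path


def read_psd_csv(path) -> PsdEstimate:
    path = Path(path)
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
            elif line and not line.startswith("frequency"):
                f, s = line.split(",")
                rows.append((float(f), float(s)))
    arr = np.asarray(rows)
    norm_sum = meta.get("normalization_sum", "None")
    return PsdEstimate(
        frequencies=arr[:, 0],
        values=arr[:, 1],
        normalized=meta.get("normalized", "False") == "True",
        mean_current=float(meta.get("mean_current", 0.0)),
        voltage=float(meta.get("voltage", 0.0)),
        n_averages=int(meta.get("n_averages", 1)),
        normalization_sum=None if norm_sum == "None" else float(norm_sum),
        label=meta.get("label", "unknown"),
        group_id=meta.get("group_id", ""),
    )


def fit_result_to_dict(fit: FitResult) -> dict:
    d = dataclasses.asdict(fit)
    d.pop("residuals", None)
    return d


def save_fit_result(fit: FitResult, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(fit_result_to_dict(fit), indent=1))
    return path


def save_classifier(model: ClassifierModel, path, extra: dict | None = None) -> Path:
    path = Path(path)
    payload = {
        "feature_subset": list(model.feature_subset),
        "scaling_mean": model.scaling_mean.tolist(),
        "scaling_sd": model.scaling_sd.tolist(),
        "weights": model.weights.tolist(),
        "intercept": model.intercept,
        "hyperparams": model.hyperparams,
        "decision_threshold": model.decision_threshold,
        **(extra or {}),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_classifier(path) -> ClassifierModel:
    payload = json.loads(Path(path).read_text())
    return ClassifierModel(
        feature_subset=tuple(payload["feature_subset"]),
        scaling_mean=np.asarray(payload["scaling_mean"]),
        scaling_sd=np.asarray(payload["scaling_sd"]),
        weights=np.asarray(payload["weights"]),
        intercept=float(payload["intercept"]),
        hyperparams=dict(payload.get("hyperparams", {})),
        decision_threshold=float(payload.get("decision_threshold", 0.5)),
    )


def load_run_config(path) -> dict:
    """Run configuration from YAML or JSON; a missing path is an error."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}
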