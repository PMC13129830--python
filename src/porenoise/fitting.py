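"""Weighted, non-negativity-constrained fitting of noise-PSD models.

The fit minimises the sum of squared weighted residuals

    sum_i ( w_i * (S_i - S_model(f_i; p)) )^2,   p >= 0 (exponents in [0, 2])

over the normalized PSD, using the trust-region reflective algorithm with an
analytic Jacobian.  Weights come from the parametric family

    w_i = f_i^(-alpha_f) * S~_i^(-alpha_S)

with the four named schemes NW (0, 0), EFS (1, 1), HFLS (0.5, 0.5) and
LFHS (1, 0.5).  Initial guesses are obtained by closed-form single-component
least squares on per-component frequency windows, then refined jointly.

The statsmodels-style surface is :class:`NoisePsdModel` (construct from a
:class:`~porenoise.psd.PsdEstimate`, call :meth:`~NoisePsdModel.fit`) whose
results object carries the coefficient estimates, fit diagnostics, a
``summary()`` table and plotting helpers.  :func:`fit_noise_model` is the
functional core behind it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, lsq_linear

from .models import (
    MODEL_NAMES,
    NoiseModelSpec,
    coeffs_from_array,
    coeffs_to_array,
    component_breakdown,
    evaluate_model,
    get_model_spec,
)
from .psd import PsdEstimate, normalize_psd

logger = logging.getLogger(__name__)

__all__ = [
    "WeightingScheme",
    "WEIGHTING_SCHEMES",
    "WEIGHTING_NAMES",
    "FitWindows",
    "DEFAULT_FIT_WINDOWS",
    "FitResult",
    "get_weighting",
    "compute_weights",
    "initial_guess",
    "fit_noise_model",
    "compute_rmse",
    "prepare_psd",
    "benchmark_models",
    "BenchmarkResult",
    "NoisePsdModel",
    "NoisePsdFitResults",
]


@dataclass(frozen=True)
class WeightingScheme:
    """Residual weighting w_i = f_i^(-freq_exponent) * S~_i^(-psd_exponent)."""

    name: str
    freq_exponent: float
    psd_exponent: float

    def __post_init__(self):
        if self.freq_exponent < 0 or self.psd_exponent < 0:
            raise ValueError("weighting exponents must be non-negative")


WEIGHTING_SCHEMES: dict[str, WeightingScheme] = {
    "NW": WeightingScheme("NW", 0.0, 0.0),
    "EFS": WeightingScheme("EFS", 1.0, 1.0),
    "HFLS": WeightingScheme("HFLS", 0.5, 0.5),
    "LFHS": WeightingScheme("LFHS", 1.0, 0.5),
}

WEIGHTING_NAMES = tuple(WEIGHTING_SCHEMES)


def get_weighting(scheme: "str | WeightingScheme") -> WeightingScheme:
    if isinstance(scheme, WeightingScheme):
        return scheme
    try:
        return WEIGHTING_SCHEMES[scheme]
    except KeyError:
        raise ValueError(
            f"unknown weighting scheme {scheme!r}; choose from {sorted(WEIGHTING_SCHEMES)}"
        ) from None


def compute_weights(scheme: "str | WeightingScheme", psd: PsdEstimate) -> np.ndarray:
    """Per-bin fit weights on a normalized PSD.

    Zero PSD bins (possible in pathological synthetic input) are clipped to
    the smallest positive value present rather than producing infinities.
    """
    scheme = get_weighting(scheme)
    f = psd.frequencies
    s = psd.values
    if np.any(f <= 0):
        raise ValueError("weights require strictly positive frequencies; drop the f=0 bin")
    if scheme.freq_exponent == 0 and scheme.psd_exponent == 0:
        return np.ones_like(f)
    s_eff = s
    if scheme.psd_exponent > 0 and np.any(s <= 0):
        positive = s[s > 0]
        if positive.size == 0:
            raise ValueError("all PSD values are zero; cannot weight by PSD")
        floor = positive.min()
        logger.warning("clipping %d non-positive PSD bins to %g for weighting", np.sum(s <= 0), floor)
        s_eff = np.clip(s, floor, None)
    return f ** (-scheme.freq_exponent) * s_eff ** (-scheme.psd_exponent)


# Per-parameter frequency windows (Hz) for the closed-form single-component
# initial fits.  The generic low-frequency amplitude "a" of the 4-component
# models shares the 1/f window.
DEFAULT_WINDOW_TABLE: dict[str, tuple[float, float]] = {
    "a1": (0.0, 15.0),
    "a2": (15.0, 500.0),
    "a": (15.0, 500.0),
    "b": (700.0, 1000.0),
    "c": (7000.0, 10000.0),
    "d": (16000.0, 20000.0),
}


@dataclass(frozen=True)
class FitWindows:
    """Per-amplitude frequency intervals for initial single-component fits."""

    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOW_TABLE)
    )

    def __post_init__(self):
        for p, (lo, hi) in self.windows.items():
            if hi <= lo:
                raise ValueError(f"window for {p!r} is empty: ({lo}, {hi})")

    def bins(self, param: str, frequencies: np.ndarray) -> np.ndarray:
        """Indices of frequency bins inside the parameter's window, clipped
        to the available band; falls back to the bins nearest the window's
        midpoint when the clipped window is empty."""
        lo, hi = self.windows[param]
        mask = (frequencies >= lo) & (frequencies <= hi)
        if mask.any():
            return np.flatnonzero(mask)
        mid = 0.5 * (lo + hi)
        k = min(5, frequencies.size)
        idx = np.argsort(np.abs(frequencies - mid))[:k]
        logger.warning(
            "initial-guess window (%g, %g) Hz for %r has no bins in the available "
            "band [%g, %g]; falling back to the %d nearest bins",
            lo, hi, param, frequencies.min(), frequencies.max(), k,
        )
        return np.sort(idx)


DEFAULT_FIT_WINDOWS = FitWindows()

# Single-component closed-form least-squares amplitude estimates, by the
# exponent of the component's power law S(f) = amp * f^power.
_CLOSED_FORM_POWER = {"a1": -2.0, "a2": -1.0, "a": -1.0, "b": 0.0, "c": 1.0, "d": 2.0}

# Exponent parameters initialised at fixed values: a single variable-exponent
# term starts at 1/f; the two-term variant starts at the 1/f^2 + 1/f split.
_EXPONENT_INIT = {"beta": 1.0, "beta1": 2.0, "beta2": 1.0}


def _closed_form_amplitude(f: np.ndarray, s: np.ndarray, power: float) -> float:
    """Unweighted LS amplitude for S = amp * f^power: sum(S f^p)/sum(f^2p)."""
    basis = f**power
    return float(np.dot(s, basis) / np.dot(basis, basis))


def initial_guess(
    psd: PsdEstimate,
    spec: "str | NoiseModelSpec",
    windows: FitWindows | None = None,
) -> dict:
    """Per-component closed-form initial parameter estimates.

    Each amplitude is fitted alone on its frequency window by unweighted
    least squares of its single-component power law against the measured
    curve, clamped at zero; exponent parameters start at their fixed
    initial values (beta=1; beta1=2, beta2=1).
    """
    spec = get_model_spec(spec)
    windows = windows or DEFAULT_FIT_WINDOWS
    f, s = psd.frequencies, psd.values
    out: dict[str, float] = {}
    for p in spec.parameter_names:
        if spec.is_exponent(p):
            out[p] = _EXPONENT_INIT[p]
            continue
        idx = windows.bins(p, f)
        power = _CLOSED_FORM_POWER[p]
        if p == "a1" and spec.name == "5C7P":
            power = -_EXPONENT_INIT["beta1"]
        out[p] = max(0.0, _closed_form_amplitude(f[idx], s[idx], power))
    return out


@dataclass
class FitResult:
    """A fitted noise-PSD model with diagnostics."""

    model: str
    weighting: str
    coefficients: dict
    initial_guess: dict
    rmse: float
    objective: float  # final weighted SSR
    objective_initial: float  # weighted SSR at the initial guess
    converged: bool
    n_iterations: int
    message: str = ""
    residuals: np.ndarray | None = None
    normalization_sum: float | None = None
    mean_current: float = 0.0
    voltage: float = 0.0
    band: tuple[float, float] = (0.0, 0.0)

    @property
    def rmse_raw(self) -> float:
        """RMSE back on the raw pA^2/Hz scale (residuals times the
        normalization sum); equals ``rmse`` for a fit on a raw curve."""
        if self.normalization_sum is None:
            return self.rmse
        return self.rmse * self.normalization_sum


def _eval_params(spec: NoiseModelSpec, x: np.ndarray, f: np.ndarray, logf: np.ndarray) -> np.ndarray:
    return evaluate_model(spec, coeffs_from_array(spec, x), f)


def _jacobian_columns(
    spec: NoiseModelSpec, x: np.ndarray, f: np.ndarray, logf: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """d residual / d params for r = w * (S - model): columns -w * d model/dp."""
    idx = {p: i for i, p in enumerate(spec.parameter_names)}
    J = np.empty((f.size, spec.n_params))
    for comp, pnames in spec.components:
        if comp.startswith("flicker_beta"):
            amp_i, beta_i = idx[pnames[0]], idx[pnames[1]]
            fb = f ** (-x[beta_i])
            J[:, amp_i] = -w * fb
            J[:, beta_i] = w * x[amp_i] * logf * fb
        elif comp == "flicker2":
            J[:, idx[pnames[0]]] = -w / f**2
        elif comp == "flicker":
            J[:, idx[pnames[0]]] = -w / f
        elif comp == "white":
            J[:, idx[pnames[0]]] = -w
        elif comp == "dielectric":
            J[:, idx[pnames[0]]] = -w * f
        elif comp == "capacitive":
            J[:, idx[pnames[0]]] = -w * f**2
    return J


def _is_linear(spec: NoiseModelSpec) -> bool:
    """Fixed-exponent models are linear in their (amplitude) parameters."""
    return not any(spec.is_exponent(p) for p in spec.parameter_names)


def _amplitude_design(spec: NoiseModelSpec, f: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted design matrix of a fixed-exponent model (columns per amplitude)."""
    cols = []
    for comp, _ in spec.components:
        if comp == "flicker2":
            cols.append(w / f**2)
        elif comp == "flicker":
            cols.append(w / f)
        elif comp == "white":
            cols.append(w)
        elif comp == "dielectric":
            cols.append(w * f)
        elif comp == "capacitive":
            cols.append(w * f**2)
        else:
            raise AssertionError(f"component {comp} is not amplitude-linear")
    return np.column_stack(cols)


def fit_noise_model(
    psd: PsdEstimate,
    spec: "str | NoiseModelSpec" = "5C5P",
    scheme: "str | WeightingScheme" = "HFLS",
    windows: FitWindows | None = None,
    ftol: float = 1e-10,
    xtol: float = 1e-10,
    max_iter: int = 10_000,
    keep_residuals: bool = False,
) -> FitResult:
    """Fit a noise-PSD model to a normalized PSD curve.

    The curve must already be restricted to the fitting band (f > 0) and
    normalized (see :func:`prepare_psd`).  The fixed-exponent models
    (4C4P, 5C5P) form a convex bounded *linear* least-squares problem and
    are solved to the exact global optimum (active-set bounded-variable
    LS); the variable-exponent models (4C5P, 5C7P) run the bounded
    trust-region reflective iteration from the closed-form initial guess
    with an analytic Jacobian.  Non-convergence within the
    iteration cap is reported through ``converged=False``, not an exception.
    """
    spec = get_model_spec(spec)
    scheme = get_weighting(scheme)
    if not psd.normalized:
        raise ValueError("fit_noise_model expects a normalized PSD; use prepare_psd/normalize_psd")
    f = psd.frequencies
    s = psd.values
    if np.any(~np.isfinite(s)) or np.any(s < 0):
        raise ValueError("PSD values must be finite and non-negative")
    if np.any(f <= 0):
        raise ValueError("fitted band must exclude f <= 0")

    w = compute_weights(scheme, psd)
    logf = np.log(f)
    p0 = initial_guess(psd, spec, windows)
    x0 = coeffs_to_array(spec, p0)
    lo, hi = spec.bounds()

    def residual(x):
        return w * (s - _eval_params(spec, x, f, logf))

    if _is_linear(spec):
        A = _amplitude_design(spec, f, w)
        # column scaling: unit-norm columns keep the active-set iteration
        # well conditioned; positive scaling preserves the [0, inf) bounds
        col = np.linalg.norm(A, axis=0)
        col[col == 0] = 1.0
        res = lsq_linear(A / col, w * s, bounds=(lo, hi), method="bvls")
        res.x = res.x / col
        nfev = int(getattr(res, "nit", 0)) + 1
        converged = bool(res.success)
    else:
        res = least_squares(
            residual,
            x0,
            jac=lambda x: _jacobian_columns(spec, x, f, logf, w),
            bounds=(lo, hi),
            method="trf",
            ftol=ftol,
            xtol=xtol,
            gtol=1e-12,
            x_scale="jac",
            max_nfev=max_iter,
        )
        nfev = int(res.nfev)
        converged = bool(res.success and res.status != 0)

    x_hat = np.clip(res.x, lo, hi)
    coeffs = coeffs_from_array(spec, x_hat)
    r0 = residual(x0)
    r_hat = residual(x_hat)
    model_hat = _eval_params(spec, x_hat, f, logf)
    rmse = compute_rmse(psd, model_hat)
    return FitResult(
        model=spec.name,
        weighting=scheme.name,
        coefficients=coeffs,
        initial_guess=p0,
        rmse=rmse,
        objective=float(np.dot(r_hat, r_hat)),
        objective_initial=float(np.dot(r0, r0)),
        converged=converged,
        n_iterations=nfev,
        message=str(res.message),
        residuals=(s - model_hat) if keep_residuals else None,
        normalization_sum=psd.normalization_sum,
        mean_current=psd.mean_current,
        voltage=psd.voltage,
        band=(float(f[0]), float(f[-1])),
    )


def compute_rmse(psd: "PsdEstimate | np.ndarray", model_values) -> float:
    """Unweighted sqrt(mean((S_i - model_i)^2)) on the curve's own scale."""
    s = psd.values if isinstance(psd, PsdEstimate) else np.asarray(psd, dtype=float)
    m = np.asarray(model_values, dtype=float)
    if s.shape != m.shape:
        raise ValueError(f"length mismatch: data {s.shape} vs model {m.shape}")
    return float(np.sqrt(np.mean((s - m) ** 2)))


def prepare_psd(
    psd: PsdEstimate,
    fmin: float | None = None,
    fmax: float | None = None,
    guard_fraction: float = 0.9,
) -> PsdEstimate:
    """Restrict a raw Welch PSD to the fitting band and normalize it.

    Defaults: lower edge at the frequency resolution (dropping the f=0 bin),
    upper edge at ``guard_fraction`` times the top of the grid (anti-alias
    roll-off guard).  No-op on an already-normalized curve.
    """
    if psd.normalized:
        return psd
    if fmin is None:
        fmin = psd.freq_resolution
    if fmax is None:
        fmax = guard_fraction * float(psd.frequencies[-1])
    return normalize_psd(psd.band(fmin, fmax))


@dataclass
class BenchmarkResult:
    """Per-PSD fit RMSEs and aggregate statistics for model x weighting cells."""

    per_psd: pd.DataFrame  # columns: psd_index, model, weighting, rmse, converged, error

    def table(self) -> pd.DataFrame:
        """One row per model x weighting: mean, SD, median, quartiles and
        5th/95th percentiles of RMSE (failed fits excluded, counted)."""
        rows = []
        for (model, weighting), grp in self.per_psd.groupby(["model", "weighting"], sort=False):
            r = grp["rmse"].to_numpy(dtype=float)
            ok = np.isfinite(r)
            rr = r[ok]
            q = (
                np.percentile(rr, [5, 25, 50, 75, 95])
                if rr.size
                else np.full(5, np.nan)
            )
            rows.append(
                {
                    "model": model,
                    "weighting": weighting,
                    "mean": float(np.mean(rr)) if rr.size else np.nan,
                    "sd": float(np.std(rr)) if rr.size else np.nan,
                    "p05": q[0],
                    "q25": q[1],
                    "median": q[2],
                    "q75": q[3],
                    "p95": q[4],
                    "n": int(rr.size),
                    "n_failed": int((~ok).sum()),
                }
            )
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """RMSE box plot (log scale) per model x weighting cell."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        cells, data = [], []
        for (model, weighting), grp in self.per_psd.groupby(["model", "weighting"], sort=False):
            r = grp["rmse"].to_numpy(dtype=float)
            r = r[np.isfinite(r) & (r > 0)]
            if r.size:
                cells.append(f"{model}\n{weighting}")
                data.append(r)
        ax.boxplot(data, tick_labels=cells, whis=(5, 95), showmeans=True)
        ax.set_yscale("log")
        ax.set_ylabel("RMSE (normalized scale)")
        return ax


def benchmark_models(
    psds,
    specs=MODEL_NAMES,
    schemes=WEIGHTING_NAMES,
    windows: FitWindows | None = None,
    **fit_kw,
) -> BenchmarkResult:
    """Fit every model x weighting combination to every PSD.

    ``psds`` may contain raw or already-prepared curves; raw curves are
    passed through :func:`prepare_psd`.  A failing fit is recorded in its
    cell and does not abort the benchmark.
    """
    psds = list(psds)
    if not psds:
        raise ValueError("benchmark requires at least one PSD")
    records = []
    for i, psd in enumerate(psds):
        prepared = prepare_psd(psd)
        for spec in specs:
            for scheme in schemes:
                rec = {"psd_index": i, "model": get_model_spec(spec).name,
                       "weighting": get_weighting(scheme).name}
                try:
                    fit = fit_noise_model(prepared, spec, scheme, windows, **fit_kw)
                    rec.update(rmse=fit.rmse, converged=fit.converged, error="")
                except Exception as exc:  # recorded per-cell, not fatal
                    logger.warning("fit failed for PSD %d, %s+%s: %s", i, spec, scheme, exc)
                    rec.update(rmse=np.nan, converged=False, error=str(exc))
                records.append(rec)
    return BenchmarkResult(per_psd=pd.DataFrame.from_records(records))


class NoisePsdModel:
    """Noise-PSD model bound to one PSD curve.

    Parameters
    ----------
    psd : PsdEstimate
        Raw or normalized PSD.  Raw curves are restricted to
        ``[fmin, fmax]`` (defaults: frequency resolution, 0.9 x top of the
        grid) and normalized before fitting.
    model, weighting : str
        Model family (4C4P/4C5P/5C5P/5C7P) and weighting scheme
        (NW/EFS/HFLS/LFHS).
    """

    def __init__(
        self,
        psd: PsdEstimate,
        model: str = "5C5P",
        weighting: str = "HFLS",
        windows: FitWindows | None = None,
        fmin: float | None = None,
        fmax: float | None = None,
    ):
        self.raw_psd = psd
        self.psd = prepare_psd(psd, fmin=fmin, fmax=fmax)
        self.spec = get_model_spec(model)
        self.scheme = get_weighting(weighting)
        self.windows = windows or DEFAULT_FIT_WINDOWS

    def fit(self, **fit_kw) -> "NoisePsdFitResults":
        result = fit_noise_model(self.psd, self.spec, self.scheme, self.windows, **fit_kw)
        return NoisePsdFitResults(self, result)


class NoisePsdFitResults:
    """Results of a :class:`NoisePsdModel` fit."""

    def __init__(self, model: NoisePsdModel, result: FitResult):
        self.model = model
        self.result = result

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.result.coefficients, name="coefficient")

    @property
    def rmse(self) -> float:
        return self.result.rmse

    @property
    def rmse_raw(self) -> float:
        return self.result.rmse_raw

    @property
    def converged(self) -> bool:
        return self.result.converged

    def predict(self, frequencies=None, raw: bool = False) -> np.ndarray:
        """Model curve on the fitted (normalized) scale, or the raw pA^2/Hz
        scale when ``raw`` and the normalization sum is known."""
        f = self.model.psd.frequencies if frequencies is None else np.asarray(frequencies)
        values = evaluate_model(self.model.spec, self.result.coefficients, f)
        if raw and self.result.normalization_sum is not None:
            values = values * self.result.normalization_sum
        return values

    def components(self, frequencies=None) -> dict[str, np.ndarray]:
        f = self.model.psd.frequencies if frequencies is None else np.asarray(frequencies)
        return component_breakdown(self.model.spec, self.result.coefficients, f)

    def summary(self) -> str:
        r = self.result
        lines = [
            "Noise PSD fit",
            "=" * 46,
            f"model:        {r.model}    weighting: {r.weighting}",
            f"band:         [{r.band[0]:g}, {r.band[1]:g}] Hz "
            f"({self.model.psd.frequencies.size} bins)",
            f"mean current: {r.mean_current:.6g} pA   voltage: {r.voltage:g} mV",
            f"converged:    {r.converged}   (nfev={r.n_iterations})",
            f"RMSE:         {r.rmse:.9e} (normalized)",
        ]
        if r.normalization_sum is not None:
            lines.append(f"              {r.rmse_raw:.9e} pA^2/Hz (raw scale)")
        lines.append("-" * 46)
        lines.append(f"{'param':<8}{'estimate':>18}{'initial':>18}")
        for p in self.model.spec.parameter_names:
            lines.append(f"{p:<8}{r.coefficients[p]:>18.9e}{r.initial_guess[p]:>18.9e}")
        return "\n".join(lines)

    def plot(self, ax=None, show_components: bool = True):
        """Data and fitted curve (raw scale if available) on log-log axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        psd = self.model.psd
        scale = self.result.normalization_sum or 1.0
        f = psd.frequencies
        ax.loglog(f, psd.values * scale, lw=0.6, alpha=0.6, label="data")
        ax.loglog(f, self.predict() * scale, lw=1.5,
                  label=f"{self.result.model}+{self.result.weighting}")
        if show_components:
            for name, vals in self.components().items():
                ax.loglog(f, vals * scale, ls="--", lw=0.8, alpha=0.7, label=name)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("PSD (pA$^2$/Hz)" if self.result.normalization_sum else "PSD")
        ax.legend(fontsize=7)
        return ax
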