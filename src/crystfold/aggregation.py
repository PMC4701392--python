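"""Aggregation kinetics from turbidity time courses and ThT fluorescence.

Turbidity (light scattering at 360 nm) rises are fitted to
y(t) = y0 + sum_i y_i (1 - exp(-k_i t)) with one or two phases, or to a
straight line for slow, unsaturated growth; candidates are compared by AICc.
Thioflavin-T spectra are summarised as fold-change of the 475-495 nm band
over a zero-time baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    ConvergenceError,
    DegenerateBaselineError,
    InvalidKineticsError,
    ModelSelectionError,
)
from .spectra import EmissionSpectrum

__all__ = [
    "AggregationTrace",
    "AggregationFit",
    "THT_PEAK_WINDOW",
    "fit_exponential",
    "fit_linear",
    "select_kinetic_model",
    "tht_enhancement",
    "subtract_native_blank",
]

#: ThT emission band used for the fold-change readout (nm)
THT_PEAK_WINDOW = (475.0, 495.0)


@dataclass
class AggregationTrace:
    """Light-scattering (A360) time series for one refolding condition."""

    times_min: np.ndarray
    a360: np.ndarray
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.a360 = np.asarray(self.a360, dtype=float)
        if self.times_min.size < 8:
            raise ValueError("aggregation trace needs at least 8 points")
        if self.times_min.shape != self.a360.shape:
            raise ValueError("times and signals differ in length")
        if np.any(self.times_min < 0) or not np.all(np.isfinite(self.times_min)):
            raise ValueError("times must be finite and non-negative")
        if not np.all(np.diff(self.times_min) > 0):
            raise ValueError("times must be increasing")


@dataclass
class AggregationFit:
    """Exponential-phase (or linear) decomposition of a turbidity rise.

    ``y_offset`` is the t=0 signal; ``amplitudes``/``rates`` list the
    asymptotic increment and rate constant of each phase (fast first).
    For the linear model ``rates`` is empty and ``amplitudes`` holds the
    slope in signal units per minute.
    """

    y_offset: float
    amplitudes: list
    rates: list
    model: str
    rms: float
    aicc: float
    criterion: dict = field(default_factory=dict)
    standard_errors: dict = field(default_factory=dict)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "linear":
            return self.y_offset + self.amplitudes[0] * t
        y = np.full_like(t, self.y_offset)
        for a, k in zip(self.amplitudes, self.rates):
            y = y + a * (1.0 - np.exp(-k * t))
        return y

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "y_offset": float(self.y_offset),
            "amplitudes": [float(a) for a in self.amplitudes],
            "rates_per_min": [float(k) for k in self.rates],
            "rms": float(self.rms),
            "aicc": float(self.aicc),
            "criterion": {k: float(v) for k, v in self.criterion.items()},
        }


def _aicc(rss: float, n: int, k: int) -> float:
    if rss <= 0:
        rss = np.finfo(float).tiny
    aic = n * np.log(rss / n) + 2 * k
    denom = n - k - 1
    return aic + (2 * k * (k + 1) / denom if denom > 0 else np.inf)


def fit_exponential(trace: AggregationTrace, n_phases: int = 1) -> AggregationFit:
    """Least-squares fit of a 1- or 2-phase saturating exponential rise.

    Rates are constrained positive; for two phases they are reported
    fast-first (k1 > k2).  Raises if no start converges or the optimum
    collapses onto the zero-rate boundary.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, y = trace.times_min, trace.a360
    n = t.size
    span = float(y[-1] - y[0])
    tmax = float(t[-1]) if t[-1] > 0 else 1.0

    # time to ~63% of the rise gives the rate scale
    if span != 0:
        frac = (y - y[0]) / span
        i63 = int(np.argmax(frac >= 0.632)) or 1
        k_scale = 1.0 / max(t[i63], tmax / n)
    else:
        k_scale = 1.0 / tmax

    def model(x):
        y0 = x[0]
        out = np.full_like(t, y0)
        for j in range(n_phases):
            out = out + x[1 + 2 * j] * (1.0 - np.exp(-x[2 + 2 * j] * t))
        return out

    def residual(x):
        return model(x) - y

    def jacobian(x):
        J = np.empty((t.size, 1 + 2 * n_phases))
        J[:, 0] = 1.0
        for j in range(n_phases):
            decay = np.exp(-x[2 + 2 * j] * t)
            J[:, 1 + 2 * j] = 1.0 - decay
            J[:, 2 + 2 * j] = x[1 + 2 * j] * t * decay
        return J

    k_lo = 1e-9
    if n_phases == 1:
        starts = [
            np.array([y[0], span, k_scale]),
            np.array([y[0], span, k_scale / 10]),
            np.array([y[0], span, k_scale * 10]),
            np.array([y[0], max(span, 1e-6) * 2, k_scale / 3]),
        ]
        lo = np.array([-np.inf, -np.inf, k_lo])
        hi = np.array([np.inf, np.inf, np.inf])
    else:
        starts = [
            np.array([y[0], span / 2, k_scale * 5, span / 2, k_scale / 5]),
            np.array([y[0], span * 0.7, k_scale * 20, span * 0.3, k_scale / 20]),
            np.array([y[0], span * 0.3, k_scale * 2, span * 0.7, k_scale / 2]),
            np.array([y[0], span / 2, k_scale * 50, span / 2, k_scale]),
        ]
        lo = np.array([-np.inf, -np.inf, k_lo, -np.inf, k_lo])
        hi = np.full(5, np.inf)

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-12, None)
        try:
            res = optimize.least_squares(
                residual, x0, jac=jacobian, bounds=(lo, hi), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=200,
            )
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (res, rss)
        if rss < 1e-18 * n:
            break
    if best is None:
        raise ConvergenceError("did not converge")
    res, rss = best
    x = res.x
    phases = sorted(
        ((float(x[2 + 2 * j]), float(x[1 + 2 * j])) for j in range(n_phases)),
        reverse=True,
    )
    rates = [k for k, _ in phases]
    amps = [a for _, a in phases]
    if any(k <= 10 * k_lo for k in rates):
        raise InvalidKineticsError("invalid kinetics: rate collapsed to zero")
    kparams = 1 + 2 * n_phases
    se = {}
    try:
        _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
        if np.all(s > np.finfo(float).eps * max(res.jac.shape) * s[0]):
            cov = (vt.T / s**2) @ vt * rss / max(n - kparams, 1)
            names = ["y0"] + [f"{p}{j+1}" for j in range(n_phases) for p in ("y", "k")]
            se = dict(zip(names, np.sqrt(np.diag(cov))))
    except Exception:
        pass
    return AggregationFit(
        y_offset=float(x[0]), amplitudes=amps, rates=rates,
        model=f"exp{n_phases}", rms=float(np.sqrt(rss / n)),
        aicc=_aicc(rss, n, kparams), standard_errors=se,
    )


@dataclass
class LinearFit:
    slope: float
    intercept: float
    stderr_slope: float
    rms: float
    aicc: float


def fit_linear(trace: AggregationTrace) -> LinearFit:
    """Ordinary least-squares line through a (slow, unsaturated) rise."""
    t, y = trace.times_min, trace.a360
    res = stats.linregress(t, y)
    resid = y - (res.intercept + res.slope * t)
    rss = float(np.sum(resid**2))
    return LinearFit(
        slope=float(res.slope), intercept=float(res.intercept),
        stderr_slope=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        rms=float(np.sqrt(rss / t.size)), aicc=_aicc(rss, t.size, 2),
    )


def select_kinetic_model(trace: AggregationTrace) -> AggregationFit:
    """Fit exp1, exp2 and linear models; return the lowest-AICc fit.

    Ties go to the simpler model (linear < exp1 < exp2).  Raises
    ``ModelSelectionError`` when every candidate fails.
    """
    candidates: dict[str, AggregationFit] = {}
    lin = fit_linear(trace)
    candidates["linear"] = AggregationFit(
        y_offset=lin.intercept, amplitudes=[lin.slope], rates=[],
        model="linear", rms=lin.rms, aicc=lin.aicc,
    )
    for n_phases in (1, 2):
        try:
            candidates[f"exp{n_phases}"] = fit_exponential(trace, n_phases)
        except Exception:  # noqa: BLE001 - candidate failure is informative, not fatal
            continue
    if not candidates:
        raise ModelSelectionError("no model fits")
    aiccs = {name: f.aicc for name, f in candidates.items()}
    complexity = {"linear": 0, "exp1": 1, "exp2": 2}
    chosen = min(sorted(aiccs), key=lambda nm: (round(aiccs[nm], 9), complexity[nm]))
    fit = candidates[chosen]
    fit.criterion = aiccs
    return fit


def subtract_native_blank(trace: AggregationTrace, blank: AggregationTrace) -> AggregationTrace:
    """Subtract the denaturant-free native-protein control trace pointwise.

    Mismatched time grids are linearly interpolated onto the sample grid.
    """
    if np.array_equal(trace.times_min, blank.times_min):
        corrected = trace.a360 - blank.a360
    else:
        corrected = trace.a360 - np.interp(trace.times_min, blank.times_min, blank.a360)
    return AggregationTrace(trace.times_min.copy(), corrected,
                            condition=trace.condition, meta=dict(trace.meta))


def _peak_mean(spectrum: EmissionSpectrum, window: tuple[float, float]) -> float:
    wl = spectrum.wavelengths
    sel = (wl >= window[0]) & (wl <= window[1])
    if not np.any(sel):
        raise ValueError(f"no points in ThT window {window}")
    return float(np.mean(spectrum.intensities[sel]))


def tht_enhancement(
    baseline: EmissionSpectrum,
    timepoints: Sequence[EmissionSpectrum],
    window: tuple[float, float] = THT_PEAK_WINDOW,
) -> np.ndarray:
    """Fold-change of ThT peak-band intensity over the zero-time baseline.

    The readout is the mean intensity in ``window`` (default 475-495 nm),
    one ratio per timepoint spectrum.
    """
    for s in (baseline, *timepoints):
        if s.probe != "ThT":
            raise ValueError("tht_enhancement expects ThT spectra")
    for s in timepoints:
        if not np.array_equal(s.wavelengths, baseline.wavelengths):
            raise ValueError("timepoint spectra must share the baseline grid")
    ref = _peak_mean(baseline, window)
    if ref <= 0:
        raise DegenerateBaselineError("degenerate baseline: non-positive ThT intensity")
    return np.array([_peak_mean(s, window) / ref for s in timepoints])
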