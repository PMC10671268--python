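"""Segmentation and fitting of single light-scattering aggregation traces.

A sigmoidal trace is split into lag, nucleation and growth phases.  The
nucleation phase (between the detected onset and the inflection point) is
fitted with the quadratic rise ``I = I0 + K_agg (t - t0)^2``; the growth
phase (after the inflection) with the second-order polynomial
``I = I0 + v0 (t - t*) - B (t - t*)^2``, whose abscissa crossing of the
baseline level defines the lag duration t*.

Both fits are exposed as sklearn-style estimators (:class:`NucleationCurve`,
:class:`GrowthCurve`) and as thin functions returning result records
(:func:`fit_nucleation`, :func:`fit_growth`).  :class:`TraceAnalyzer` chains
onset detection, the nucleation fit, inflection detection and the growth fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .datatypes import (
    GrowthFit,
    KineticTrace,
    NucleationFit,
    OnsetResult,
    TraceAnalysis,
)
from .models import eval_growth, eval_nucleation

__all__ = [
    "TraceConfig",
    "NucleationCurve",
    "GrowthCurve",
    "TraceAnalyzer",
    "detect_onset",
    "find_inflection",
    "fit_nucleation",
    "fit_growth",
    "analyze_trace",
    "NoInflectionError",
]


class NoInflectionError(RuntimeError):
    """Raised when a trace has no rising segment with a derivative maximum."""


@dataclass
class TraceConfig:
    """Tunable knobs for trace segmentation and fitting.

    k_sigma: robust-SD multiple above the baseline that counts as a rise.
    baseline_frac: fraction of the trace (from the start) used as baseline
    window when it contains more points than ``baseline_min_points``.
    growth_end_frac: the growth-fit window ends where I first reaches this
    fraction of its maximum.  smooth_frac sets the moving-average width used
    for inflection detection (at least ``smooth_min_points`` points).
    """

    k_sigma: float = 4.0
    baseline_frac: float = 0.10
    baseline_min_points: int = 5
    growth_end_frac: float = 0.95
    smooth_frac: float = 0.02
    smooth_min_points: int = 5


def _r_squared(y, y_fit):
    ss_res = float(np.sum((y - y_fit) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def _check_fitted(est, attr):
    if not hasattr(est, attr):
        raise NotFittedError(
            f"{type(est).__name__} is not fitted yet; call fit() first")


class NucleationCurve(BaseEstimator):
    """Least-squares fit of the nucleation-stage quadratic intensity rise.

    Parameters
    ----------
    t0_init : float or None
        Initial guess for the rise onset t0 (s); defaults to the first time
        point of the fitted window.

    Attributes
    ----------
    K_agg_ : float
        Acceleration of aggregation (counts/s^2), constrained >= 0.
    t0_ : float
        Fitted onset time (s).
    I0_ : float
        Fitted baseline intensity.
    r_squared_ : float
    K_agg_stderr_ : float
    """

    def __init__(self, t0_init=None):
        self.t0_init = t0_init

    def fit(self, t, I):
        t = np.asarray(t, dtype=float)
        I = np.asarray(I, dtype=float)
        if len(t) < 5:
            raise ValueError("nucleation fit needs at least 5 points")
        t0_init = self.t0_init if self.t0_init is not None else t[0]
        t0_init = float(np.clip(t0_init, t[0] - (t[-1] - t[0]), t[-1]))
        span = t[-1] - t[0]
        dt_end = max(t[-1] - t0_init, span / len(t))
        K_init = max((I[-1] - I[0]) / dt_end**2, 1e-12)
        p0 = [I[0], K_init, t0_init]
        lower = [-np.inf, 0.0, t[0] - span]
        upper = [np.inf, np.inf, t[-1]]

        def model(tt, I0, K, t0):
            return eval_nucleation(tt, I0, K, t0)

        popt, pcov = curve_fit(model, t, I, p0=p0,
                               bounds=(lower, upper), maxfev=20000)
        self.I0_, self.K_agg_, self.t0_ = map(float, popt)
        self.K_agg_stderr_ = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
        self.r_squared_ = _r_squared(I, model(t, *popt))
        self.window_ = (float(t[0]), float(t[-1]))
        return self

    def predict(self, t):
        _check_fitted(self, "K_agg_")
        return eval_nucleation(np.asarray(t, dtype=float),
                               self.I0_, self.K_agg_, self.t0_)

    def result_(self) -> NucleationFit:
        _check_fitted(self, "K_agg_")
        return NucleationFit(K_agg=self.K_agg_, t0=self.t0_, I0=self.I0_,
                             r_squared=self.r_squared_, window=self.window_,
                             K_agg_stderr=self.K_agg_stderr_)


class GrowthCurve(BaseEstimator):
    """Fit of the growth-stage polynomial with the baseline level fixed.

    The model ``I = I0 + v0 (t - t*) - B (t - t*)^2`` has four symbols but
    only three independent polynomial coefficients, so the baseline ``I0``
    must be supplied (or is taken as the first intensity of the window).
    The fit is an ordinary quadratic least squares; t* is then the abscissa
    crossing of the fitted parabola at the level I0 (the geometric "length
    cut off on the abscissa"), v0 the slope at t*, and B minus the curvature.

    Attributes
    ----------
    v0_ : float
        Initial growth rate (counts/s), slope of the parabola at t*.
    t_star_ : float
        Lag duration (s).
    B_ : float
    I0_ : float
    r_squared_ : float
    over_curvature_ : bool
        True when the parabola peaks inside the first 10% of the window,
        i.e. the quadratic term dominates where the fit should be near-linear.
    """

    def __init__(self, I0=None):
        self.I0 = I0

    def fit(self, t, I):
        t = np.asarray(t, dtype=float)
        I = np.asarray(I, dtype=float)
        if len(t) < 5:
            raise ValueError("growth fit needs at least 5 points")
        I0 = float(I[0]) if self.I0 is None else float(self.I0)
        # shift time for conditioning
        ts = t - t[0]
        coeffs = np.polyfit(ts, I, 2)           # c2 ts^2 + c1 ts + c0
        c2, c1, c0 = (float(c) for c in coeffs)
        B = -c2
        # solve q(ts) = I0 for the crossing left of the vertex on a rising curve
        roots = np.roots([c2, c1, c0 - I0])
        roots = roots[np.isreal(roots)].real if len(roots) else np.array([])
        if len(roots) == 0:
            # parabola never reaches the baseline level: fall back to a
            # bounded nonlinear fit of (v0, t*, B)
            def model(tt, v0, t_star, Bp):
                dtt = np.clip(tt - t_star, 0.0, None)
                return I0 + v0 * dtt - Bp * dtt**2
            p0 = [max((I[-1] - I[0]) / (ts[-1] + 1e-9), 1e-9), 0.0, 0.0]
            popt, _ = curve_fit(model, ts, I, p0=p0,
                                bounds=([0, -ts[-1], -np.inf],
                                        [np.inf, ts[-1], np.inf]),
                                maxfev=20000)
            v0, t_star_s, B = (float(x) for x in popt)
        else:
            # earliest crossing at or before the data window
            t_star_s = float(np.min(roots))
            v0 = float(2 * c2 * t_star_s + c1)
        if v0 < 0:
            v0 = 0.0
        self.v0_ = v0
        self.t_star_ = float(t_star_s + t[0])
        self.B_ = B
        self.I0_ = I0
        fit_vals = np.polyval(coeffs, ts)
        self.r_squared_ = _r_squared(I, fit_vals)
        self.window_ = (float(t[0]), float(t[-1]))
        self.over_curvature_ = False
        if B > 0 and v0 > 0:
            t_peak = self.t_star_ + v0 / (2 * B)
            if t_peak < t[0] + 0.1 * (t[-1] - t[0]):
                self.over_curvature_ = True
                warnings.warn("growth fit peaks inside the first 10% of the "
                              "window (over-curvature)", stacklevel=2)
        return self

    def predict(self, t):
        _check_fitted(self, "v0_")
        t = np.asarray(t, dtype=float)
        return eval_growth(np.maximum(t, self.t_star_), self.I0_,
                           self.v0_, self.t_star_, self.B_)

    def result_(self) -> GrowthFit:
        _check_fitted(self, "v0_")
        return GrowthFit(v0=self.v0_, t_star=max(self.t_star_, 0.0), B=self.B_,
                         I0=self.I0_, r_squared=self.r_squared_,
                         window=self.window_, over_curvature=self.over_curvature_)


def _baseline_window(trace: KineticTrace, config: TraceConfig) -> int:
    n = max(config.baseline_min_points,
            int(round(config.baseline_frac * len(trace))))
    if n >= len(trace):
        raise ValueError("trace shorter than the baseline window")
    return n


def detect_onset(trace: KineticTrace, k_sigma: float | None = None,
                 config: TraceConfig | None = None) -> OnsetResult:
    """Earliest time the intensity persistently exceeds the baseline band.

    The baseline is the median over the initial window; the band is
    ``k_sigma`` robust standard deviations (1.4826 MAD) above it.  A point
    qualifies only if the next two points also exceed the band (persistence
    rule).  When no rise is found the last time point is returned with
    ``detected=False``.
    """
    config = config or TraceConfig()
    k = config.k_sigma if k_sigma is None else k_sigma
    nb = _baseline_window(trace, config)
    base = trace.I[:nb]
    med = float(np.median(base))
    mad = float(np.median(np.abs(base - med)))
    sd = 1.4826 * mad
    if sd == 0:
        sd = float(np.std(base))
    thr = med + k * sd
    above = trace.I > thr
    # persistence: the point and its two successors all above threshold
    for i in range(len(trace) - 2):
        if above[i] and above[i + 1] and above[i + 2]:
            return OnsetResult(time=float(trace.t[i]), detected=True, threshold=thr)
    return OnsetResult(time=float(trace.t[-1]), detected=False, threshold=thr)


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    width = max(1, width)
    if width % 2 == 0:
        width += 1
    kernel = np.ones(width) / width
    pad = width // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")


def find_inflection(trace: KineticTrace, config: TraceConfig | None = None,
                    onset_time: float | None = None) -> float:
    """Time of maximum first derivative of the smoothed trace.

    Searched between the onset (if given) and the time of maximum intensity;
    derivative plateaus are broken by the earliest time.  A strictly concave
    (growth-only) trace returns its first time point with a warning; a flat
    trace raises :class:`NoInflectionError`.
    """
    config = config or TraceConfig()
    span = float(np.ptp(trace.I))
    # robust point-to-point noise; a flat trace spans only a few noise SDs
    noise = 1.4826 * float(np.median(np.abs(np.diff(trace.I)))) / np.sqrt(2.0)
    if span <= max(8.0 * noise, 1e-12):
        raise NoInflectionError("no inflection: trace has no rising segment")
    width = max(config.smooth_min_points,
                int(round(config.smooth_frac * len(trace))))
    I_s = _smooth(trace.I, width)
    dI = np.gradient(I_s, trace.t)
    i_max_I = int(np.argmax(I_s))
    lo = 0
    if onset_time is not None:
        lo = int(np.searchsorted(trace.t, onset_time))
    hi = max(i_max_I, lo + 1)
    seg = dI[lo:hi + 1]
    if len(seg) == 0:
        raise NoInflectionError("no inflection: empty search window")
    # earliest index attaining the (near-)maximum derivative
    m = float(np.max(seg))
    i_rel = int(np.argmax(seg >= m * (1 - 1e-12)))
    i_inf = lo + i_rel
    if onset_time is None and i_inf <= width // 2:
        # a maximum inside the smoothing edge region means the derivative
        # was largest from the start: concave, growth-only trace
        warnings.warn("derivative maximal at the start: trace looks concave "
                      "(growth-only)", stacklevel=2)
        return float(trace.t[0])
    return float(trace.t[i_inf])


def _window_slice(t: np.ndarray, window: tuple) -> slice:
    lo, hi = window
    i0 = int(np.searchsorted(t, lo, side="left"))
    i1 = int(np.searchsorted(t, hi, side="right"))
    return slice(i0, i1)


def fit_nucleation(trace: KineticTrace, window: tuple,
                   t0_init: float | None = None) -> NucleationFit:
    """Fit the quadratic nucleation model over ``window = (t_start, t_end)``."""
    sl = _window_slice(trace.t, window)
    t, I = trace.t[sl], trace.I[sl]
    if len(t) < 5:
        raise ValueError("nucleation window contains fewer than 5 points")
    est = NucleationCurve(t0_init=window[0] if t0_init is None else t0_init)
    est.fit(t, I)
    return est.result_()


def fit_growth(trace: KineticTrace, window: tuple,
               I0: float | None = None,
               config: TraceConfig | None = None) -> GrowthFit:
    """Fit the growth polynomial over ``window``; I0 defaults to the trace baseline."""
    config = config or TraceConfig()
    sl = _window_slice(trace.t, window)
    t, I = trace.t[sl], trace.I[sl]
    if len(t) < 5:
        raise ValueError("growth window contains fewer than 5 points")
    if I0 is None:
        nb = _baseline_window(trace, config)
        I0 = float(np.median(trace.I[:nb]))
    est = GrowthCurve(I0=I0)
    est.fit(t, I)
    return est.result_()


class TraceAnalyzer(BaseEstimator):
    """Full per-trace pipeline: onset -> nucleation fit -> inflection -> growth fit.

    Deterministic given the trace and configuration.  After :meth:`fit` the
    assembled :class:`~aggkinetics.datatypes.TraceAnalysis` is available as
    ``analysis_``, and the stage results as ``nucleation_`` / ``growth_``.
    """

    def __init__(self, config: TraceConfig | None = None):
        self.config = config

    def fit(self, trace: KineticTrace, y=None):
        config = self.config or TraceConfig()
        onset = detect_onset(trace, config=config)
        if not onset.detected:
            self.analysis_ = TraceAnalysis(
                nucleation=None, growth=None, onset_time=None,
                inflection_time=None, onset_detected=False,
                trace_meta=trace.meta)
            self.nucleation_ = None
            self.growth_ = None
            return self
        try:
            t_inf = find_inflection(trace, config=config,
                                    onset_time=onset.time)
        except NoInflectionError as exc:
            raise NoInflectionError(f"inflection stage: {exc}") from exc

        # windows are kept fit-viable: at least 5 points each, extending
        # past the nominal boundary when the trace is sparse there
        i_onset = int(np.searchsorted(trace.t, onset.time))
        i_inf = int(np.searchsorted(trace.t, t_inf))
        i_nuc_end = max(i_inf, min(i_onset + 4, len(trace) - 1))
        nucleation = None
        if i_nuc_end > i_onset:
            try:
                nucleation = fit_nucleation(
                    trace, (onset.time, float(trace.t[i_nuc_end])),
                    t0_init=onset.time)
            except (ValueError, RuntimeError) as exc:
                raise RuntimeError(f"nucleation stage: {exc}") from exc

        I_s = _smooth(trace.I, max(config.smooth_min_points,
                                   int(round(config.smooth_frac * len(trace)))))
        target = I_s[0] + config.growth_end_frac * (np.max(I_s) - I_s[0])
        idx_end = np.nonzero(I_s >= target)[0]
        i_end = int(idx_end[0]) if len(idx_end) else len(trace) - 1
        i_end = min(max(i_end, i_inf + 4), len(trace) - 1)
        i_start = min(i_inf, i_end - 4)
        try:
            growth = fit_growth(trace, (float(trace.t[i_start]),
                                        float(trace.t[i_end])), config=config)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"growth stage: {exc}") from exc

        self.analysis_ = TraceAnalysis(
            nucleation=nucleation, growth=growth, onset_time=onset.time,
            inflection_time=t_inf, onset_detected=True, trace_meta=trace.meta)
        self.nucleation_ = nucleation
        self.growth_ = growth
        return self


def analyze_trace(trace: KineticTrace,
                  config: TraceConfig | None = None) -> TraceAnalysis:
    """Run the standard trace pipeline and return the assembled analysis."""
    return TraceAnalyzer(config=config).fit(trace).analysis_
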