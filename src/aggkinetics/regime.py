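"""Cross-series regressions and kinetic-regime classification.

The order of aggregation with respect to protein is the exponent b of the
power law ``K_agg = const [P]0^b`` (nucleation stage) or
``v0 = const [P]0^b`` (growth stage); b rounded to the nearest integer is
the stage order n_c.  A growth-stage order of 1 marks a denaturation-limited
(pseudo-first-order) regime; 2 marks a regime limited by the bimolecular
attachment of unfolded monomers to aggregates.

Chaperone suppression of either stage parameter is a Hill dose-response
with semi-saturation concentration [L]0.5 and coefficient h.  The decay of
the non-aggregated fraction is fitted with the shape-parameterized curve
(lag t*, half-decay t0.5, shape m), and, for a second-order regime, with a
straight line in the coordinates 1/c - 1/c0 whose slope is kII.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .datatypes import (
    FirstOrderFit,
    HillFit,
    KineticTrace,
    NonAggFit,
    NonAggTrace,
    OrderFit,
    RegimeCall,
    SecondOrderFit,
)
from .models import eval_hill, eval_nonagg, eval_power_law, second_order_transform

__all__ = [
    "PowerLaw",
    "HillCurve",
    "NonAggDecay",
    "SecondOrderRate",
    "FirstOrderDecay",
    "fit_order",
    "fit_dose_response",
    "fit_nonagg_curve",
    "fit_second_order",
    "fit_first_order",
    "intensity_vs_aggregated",
    "classify_regime",
    "LinearityDiagnostic",
]


def _r_squared(y, y_fit):
    ss_res = float(np.sum((np.asarray(y) - np.asarray(y_fit)) ** 2))
    ss_tot = float(np.sum((np.asarray(y) - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def _check_fitted(est, attr):
    if not hasattr(est, attr):
        raise NotFittedError(
            f"{type(est).__name__} is not fitted yet; call fit() first")


class PowerLaw(BaseEstimator):
    """Nonlinear least-squares fit of ``y = const * x**b``.

    Initialized from the ordinary log-log regression slope, then refined on
    the original scale (noise in the measured rate parameters is closer to
    additive than multiplicative).

    Attributes
    ----------
    b_ : float
        Power coefficient (order of aggregation when x is protein conc).
    const_ : float
    b_stderr_ : float
    n_c_ : int
        ``round(b_)``.
    """

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        if len(x) < 3:
            raise ValueError("order fit needs at least 3 points")
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("order fit requires strictly positive x and y")
        slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
        p0 = [float(np.exp(intercept)), float(slope)]
        popt, pcov = curve_fit(lambda xx, c, b: c * xx**b, x, y, p0=p0,
                               maxfev=20000)
        self.const_, self.b_ = (float(v) for v in popt)
        self.b_stderr_ = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
        self.n_c_ = int(round(self.b_))
        self.r_squared_ = _r_squared(y, popt[0] * x**popt[1])
        return self

    def predict(self, x):
        _check_fitted(self, "b_")
        return eval_power_law(np.asarray(x, dtype=float), self.const_, self.b_)

    def result_(self) -> OrderFit:
        _check_fitted(self, "b_")
        return OrderFit(b=self.b_, const=self.const_,
                        b_stderr=self.b_stderr_, n_c=self.n_c_)


class HillCurve(BaseEstimator):
    """Fit of the suppression ratio ``y/baseline = 1 / (1 + (L/L_half)**h)``.

    The upper asymptote is fixed at 1 (ratio form); only L_half and h are
    free.  ``baseline`` is the parameter value at zero ligand; when None it
    is taken from the y entry at L == 0 (required in that case).

    Attributes
    ----------
    L_half_ : float  (mM)
    h_ : float
    """

    def __init__(self, baseline=None):
        self.baseline = baseline

    def fit(self, L, y):
        L = np.asarray(L, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any(L < 0):
            raise ValueError("ligand concentrations must be >= 0")
        baseline = self.baseline
        if baseline is None:
            at_zero = y[L == 0]
            if len(at_zero) == 0:
                raise ValueError("no baseline given and no L == 0 entry")
            baseline = float(np.mean(at_zero))
        if baseline <= 0:
            raise ValueError("baseline must be > 0")
        ratio = y / baseline
        if np.all(ratio >= 1.0):
            warnings.warn("no suppression detected (all ratios >= 1); "
                          "Hill fit is unconstrained", stacklevel=2)
        # initial L_half: first crossing of 0.5, else median positive L
        pos = L > 0
        Lh0 = float(np.median(L[pos])) if np.any(pos) else 1.0
        below = pos & (ratio < 0.5)
        if np.any(below):
            Lh0 = float(L[below][0])
        popt, pcov = curve_fit(eval_hill, L, ratio, p0=[Lh0, 1.0],
                               bounds=([1e-12, 1e-3], [np.inf, 50.0]),
                               maxfev=20000)
        self.L_half_, self.h_ = (float(v) for v in popt)
        errs = np.sqrt(np.diag(pcov))
        self.L_half_stderr_ = float(errs[0])
        self.h_stderr_ = float(errs[1])
        self.baseline_ = baseline
        self.r_squared_ = _r_squared(ratio, eval_hill(L, *popt))
        return self

    def predict(self, L):
        _check_fitted(self, "L_half_")
        return eval_hill(np.asarray(L, dtype=float), self.L_half_, self.h_)

    def result_(self) -> HillFit:
        _check_fitted(self, "L_half_")
        return HillFit(L_half=self.L_half_, h=self.h_, baseline=self.baseline_,
                       L_half_stderr=self.L_half_stderr_,
                       h_stderr=self.h_stderr_, r_squared=self.r_squared_)


class NonAggDecay(BaseEstimator):
    """Fit of the non-aggregated-fraction decay with lag, half-time and shape.

    ``gamma = [1 + (2**(m-1)-1) (t-t*)/t0.5]**(-1/(m-1))`` for t > t*, 1
    before.  m is constrained to (1, 20]; a fit pinned near the lower bound
    (m -> 1, exponential limit) is flagged via ``at_lower_bound_``.
    """

    _M_LO = 1.0 + 1e-6

    def fit(self, t, gamma):
        t = np.asarray(t, dtype=float)
        gamma = np.asarray(gamma, dtype=float)
        if np.any(gamma <= 0) or np.any(gamma > 1.0 + 1e-9):
            raise ValueError("gamma must lie in (0, 1]")
        # non-physical rise check: allow noise but not a net increase
        if gamma[-1] > gamma[0] + 0.05:
            raise ValueError("gamma increases over time (non-physical)")
        drop = gamma < 0.98
        t_star0 = float(t[drop][0]) if np.any(drop) else float(t[0])
        half = gamma < 0.5
        t_half0 = (float(t[half][0]) - t_star0) if np.any(half) else float(t[-1] - t_star0)
        t_half0 = max(t_half0, (t[-1] - t[0]) / len(t))
        popt, pcov = curve_fit(
            eval_nonagg, t, gamma, p0=[max(t_star0, 0.0), t_half0, 2.0],
            bounds=([0.0, 1e-9, self._M_LO], [t[-1], np.inf, 20.0]),
            maxfev=20000)
        if int(np.sum(t > popt[0])) < 5:
            raise ValueError("too few points beyond the lag period")
        self.t_star_, self.t_half_, self.m_ = (float(v) for v in popt)
        self.at_lower_bound_ = self.m_ < 1.05
        self.r_squared_ = _r_squared(gamma, eval_nonagg(t, *popt))
        return self

    def predict(self, t):
        _check_fitted(self, "m_")
        return eval_nonagg(np.asarray(t, dtype=float),
                           self.t_star_, self.t_half_, self.m_)

    def result_(self) -> NonAggFit:
        _check_fitted(self, "m_")
        return NonAggFit(t_star=self.t_star_, t_half=self.t_half_, m=self.m_,
                         r_squared=self.r_squared_,
                         at_lower_bound=self.at_lower_bound_)


class SecondOrderRate(BaseEstimator):
    """Straight-line fit in second-order coordinates; the slope is kII.

    Each (t, gamma) point is transformed to ``1/(c0*gamma) - 1/c0`` and
    regressed against time in seconds.  The intercept is a diagnostic and
    should be near zero for a genuinely bimolecular depletion.

    Parameters
    ----------
    c0 : float
        Initial molar protein concentration (mol/L, per tetramer).
    time_unit : {"min", "s"}
        Unit of the time array passed to :meth:`fit`.
    """

    def __init__(self, c0=2.67e-6, time_unit="min"):
        self.c0 = c0
        self.time_unit = time_unit

    def fit(self, t, gamma):
        if self.c0 <= 0:
            raise ValueError("c0 must be > 0")
        if self.time_unit not in ("min", "s"):
            raise ValueError("time_unit must be 'min' or 's'")
        t = np.asarray(t, dtype=float)
        t_s = t * 60.0 if self.time_unit == "min" else t
        y = second_order_transform(np.asarray(gamma, dtype=float), self.c0)
        res = stats.linregress(t_s, y)
        self.k_II_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.k_II_stderr_ = float(res.stderr)
        return self

    def predict(self, t):
        _check_fitted(self, "k_II_")
        t = np.asarray(t, dtype=float)
        t_s = t * 60.0 if self.time_unit == "min" else t
        return self.k_II_ * t_s + self.intercept_

    def result_(self) -> SecondOrderFit:
        _check_fitted(self, "k_II_")
        return SecondOrderFit(k_II=self.k_II_, intercept=self.intercept_,
                              r_squared=self.r_squared_)


class FirstOrderDecay(BaseEstimator):
    """Single-exponential decay fit ``y = A * exp(-k t)`` (A fixed to 1 by default).

    Used to recover the first-order denaturation rate constant from
    native-fraction time courses; k is reported in the reciprocal of the
    time unit supplied.
    """

    def __init__(self, fit_amplitude=False):
        self.fit_amplitude = fit_amplitude

    def fit(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        pos = y > 0
        slope = -np.polyfit(t[pos], np.log(y[pos]), 1)[0] if np.sum(pos) >= 2 else 1.0
        k0 = max(float(slope), 1e-9)
        if self.fit_amplitude:
            popt, _ = curve_fit(lambda tt, A, k: A * np.exp(-k * tt), t, y,
                                p0=[max(y[0], 1e-9), k0],
                                bounds=([0, 0], [np.inf, np.inf]), maxfev=20000)
            self.amplitude_, self.k_ = (float(v) for v in popt)
        else:
            popt, _ = curve_fit(lambda tt, k: np.exp(-k * tt), t, y,
                                p0=[k0], bounds=(0, np.inf), maxfev=20000)
            self.k_ = float(popt[0])
            self.amplitude_ = 1.0
        self.r_squared_ = _r_squared(y, self.amplitude_ * np.exp(-self.k_ * t))
        return self

    def predict(self, t):
        _check_fitted(self, "k_")
        return self.amplitude_ * np.exp(-self.k_ * np.asarray(t, dtype=float))

    def result_(self) -> FirstOrderFit:
        _check_fitted(self, "k_")
        return FirstOrderFit(k=self.k_, amplitude=self.amplitude_,
                             r_squared=self.r_squared_)


# ---------------------------------------------------------------------------
# functional wrappers over the estimators
# ---------------------------------------------------------------------------


def fit_order(x, y) -> OrderFit:
    """Power-law order fit of a rate parameter vs concentration series."""
    return PowerLaw().fit(x, y).result_()


def fit_dose_response(L, y, baseline=None) -> HillFit:
    """Hill fit of a rate-parameter series vs ligand concentration (mM)."""
    return HillCurve(baseline=baseline).fit(L, y).result_()


def fit_nonagg_curve(trace: NonAggTrace) -> NonAggFit:
    """Fit the lag/shape decay to a non-aggregated-fraction time course."""
    return NonAggDecay().fit(trace.t, trace.gamma).result_()


def fit_second_order(trace: NonAggTrace, c0: float) -> SecondOrderFit:
    """kII from a gamma(t) trace (minutes) at molar concentration c0."""
    return SecondOrderRate(c0=c0, time_unit="min").fit(trace.t, trace.gamma).result_()


def fit_first_order(t, y) -> FirstOrderFit:
    """Rate constant of a single-exponential native-fraction decay."""
    return FirstOrderDecay().fit(t, y).result_()


class LinearityDiagnostic:
    """Result of regressing (I - I0) against a power of gamma_agg."""

    def __init__(self, slope, intercept, r_squared, quad_f, quad_p, n_points):
        self.slope = slope
        self.intercept = intercept
        self.r_squared = r_squared
        self.quad_f = quad_f
        self.quad_p = quad_p
        self.n_points = n_points

    def __repr__(self):
        return (f"LinearityDiagnostic(slope={self.slope:.4g}, "
                f"r_squared={self.r_squared:.4f}, quad_p={self.quad_p:.3g})")


def intensity_vs_aggregated(trace: KineticTrace, nonagg: NonAggTrace,
                            power: int = 1,
                            gamma_agg_min: float = 0.15) -> LinearityDiagnostic:
    """Test proportionality of the intensity rise to (gamma_agg)^power.

    gamma_agg = 1 - gamma_non-agg is interpolated onto the trace's time grid
    (the gamma trace is in minutes, the intensity trace in seconds).  A line
    is fitted to (I - I0) vs gamma_agg^power over gamma_agg > gamma_agg_min;
    an F-test for an added quadratic term over the full overlap quantifies
    curvature.  In a denaturation-limited regime power=1 is the linear
    choice; in a growth-limited regime power=2.
    """
    if power not in (1, 2):
        raise ValueError("power must be 1 or 2")
    t_gamma_s = nonagg.t * 60.0
    lo = max(trace.t[0], t_gamma_s[0])
    hi = min(trace.t[-1], t_gamma_s[-1])
    mask_t = (trace.t >= lo) & (trace.t <= hi)
    if np.sum(mask_t) < 4:
        raise ValueError("fewer than 4 overlapping points between traces")
    t_common = trace.t[mask_t]
    gamma_agg = 1.0 - np.interp(t_common, t_gamma_s, nonagg.gamma)
    I0 = float(trace.I[0])
    dI = trace.I[mask_t] - I0
    x_full = gamma_agg**power
    sel = gamma_agg > gamma_agg_min
    if np.sum(sel) < 4:
        raise ValueError("fewer than 4 points above the gamma_agg threshold")
    res = stats.linregress(x_full[sel], dI[sel])
    # F-test: does a quadratic term improve on the line over the full range?
    lin = np.polyfit(x_full, dI, 1)
    quad = np.polyfit(x_full, dI, 2)
    rss1 = float(np.sum((dI - np.polyval(lin, x_full)) ** 2))
    rss2 = float(np.sum((dI - np.polyval(quad, x_full)) ** 2))
    n = len(x_full)
    df2 = n - 3
    if df2 > 0 and rss2 > 0:
        f_stat = (rss1 - rss2) / (rss2 / df2)
        p_val = float(stats.f.sf(f_stat, 1, df2))
    else:
        f_stat, p_val = np.inf, 0.0
    return LinearityDiagnostic(slope=float(res.slope),
                               intercept=float(res.intercept),
                               r_squared=float(res.rvalue**2),
                               quad_f=float(f_stat), quad_p=p_val,
                               n_points=int(np.sum(sel)))


def classify_regime(order_growth: OrderFit, order_nucleation: OrderFit,
                    rounding_threshold: float = 0.35) -> RegimeCall:
    """Kinetic-regime call from the growth- and nucleation-stage orders.

    A growth-stage order of 1 means monomer attachment outruns unfolding
    and the overall process is denaturation-limited (pseudo-first-order);
    an order of 2 means the bimolecular attachment step itself limits.  A b
    farther than ``rounding_threshold`` from any integer is indeterminate.
    """
    b_g = order_growth.b
    n_g = int(round(b_g))
    ambiguous = abs(b_g - n_g) > rounding_threshold
    if ambiguous:
        stage = "indeterminate"
    elif n_g == 1:
        stage = "denaturation"
    elif n_g == 2:
        stage = "aggregate_growth"
    else:
        stage = "indeterminate"
    return RegimeCall(
        n_c_nucleation=order_nucleation.n_c,
        n_c_growth=n_g,
        limiting_stage=stage,
        evidence={
            "b_growth": b_g,
            "b_growth_stderr": order_growth.b_stderr,
            "b_nucleation": order_nucleation.b,
            "b_nucleation_stderr": order_nucleation.b_stderr,
        },
    )
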