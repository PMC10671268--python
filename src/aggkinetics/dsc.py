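"""DSC thermogram analysis: Tmax, calorimetric enthalpy and kden(T).

A linear chemical baseline interpolated between pre- and post-transition
windows is subtracted; the residual excess heat capacity (per mol of the
150 kDa tetramer) yields the transition maximum Tmax (smoothed argmax) and
the calorimetric enthalpy dH_cal (trapezoidal area).  For an irreversible
two-state transition the denaturation rate constant follows from the
thermogram as k(T) = v * Cp_ex(T) / (dH_cal - Q(T)), with v the scan rate
and Q(T) the heat absorbed up to T.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .datatypes import DSCResult, DSCTrace

__all__ = [
    "ThermogramAnalyzer",
    "analyze_thermogram",
    "kden_profile",
    "to_molar_heat_capacity",
]

_CAL_TO_J = 4.184


def to_molar_heat_capacity(trace: DSCTrace) -> np.ndarray:
    """Signal converted to excess molar heat capacity, kJ/(mol tetramer K).

    Raw instrument signal (ucal per deg C for the whole cell) divides by the
    moles of tetramer in the cell: n = conc[g/L] * volume[L] / M[g/mol].
    """
    if trace.signal_units == "kJ/mol/K":
        return trace.signal.copy()
    moles = (trace.conc * trace.cell_volume * 1e-3) / trace.molar_mass
    if moles <= 0:
        raise ValueError("cannot normalize: non-positive amount of protein")
    return trace.signal * 1e-6 * _CAL_TO_J / moles / 1e3  # ucal -> kJ/mol/K


def _smooth(y: np.ndarray, width: int = 5) -> np.ndarray:
    if width % 2 == 0:
        width += 1
    pad = width // 2
    kernel = np.ones(width) / width
    return np.convolve(np.pad(y, pad, mode="edge"), kernel, mode="valid")


class ThermogramAnalyzer(BaseEstimator):
    """Baseline subtraction and transition characterization of a thermogram.

    Parameters
    ----------
    pre_window, post_window : (T_lo, T_hi) or None
        Temperature windows flanking the transition used to anchor the
        linear baseline; default to the first and last 10% of the scan.
    smooth_points : int
        Moving-average width for the Tmax argmax (odd, default 5).

    Attributes
    ----------
    T_max_ : float (deg C)
    dH_cal_ : float (kJ/mol)
    cp_excess_ : ndarray (kJ/mol/K, baseline-subtracted)
    """

    def __init__(self, pre_window=None, post_window=None, smooth_points: int = 5):
        self.pre_window = pre_window
        self.post_window = post_window
        self.smooth_points = smooth_points

    def fit(self, trace: DSCTrace, y=None):
        T = trace.T
        cp = to_molar_heat_capacity(trace)
        span = T[-1] - T[0]
        pre = self.pre_window or (T[0], T[0] + 0.1 * span)
        post = self.post_window or (T[-1] - 0.1 * span, T[-1])
        pre_sel = (T >= pre[0]) & (T <= pre[1])
        post_sel = (T >= post[0]) & (T <= post[1])
        if np.sum(pre_sel) < 5 or np.sum(post_sel) < 5:
            raise ValueError("baseline windows must contain at least 5 points")
        x1, y1 = float(np.mean(T[pre_sel])), float(np.mean(cp[pre_sel]))
        x2, y2 = float(np.mean(T[post_sel])), float(np.mean(cp[post_sel]))
        slope = (y2 - y1) / (x2 - x1)
        intercept = y1 - slope * x1
        cp_ex = cp - (slope * T + intercept)

        cp_s = _smooth(cp_ex, self.smooth_points)
        i_max = int(np.argmax(cp_s))
        if (i_max <= 1 or i_max >= len(T) - 2
                or T[i_max] >= post[0] or T[i_max] <= pre[1]):
            raise ValueError("transition peak lies at the scan edge or "
                             "inside a baseline window")
        # refine the maximum by a parabola through the top of the peak
        # (contiguous region above 75% of the smoothed maximum): averages
        # the noise over the peak cap and gives sub-grid precision
        thr = 0.75 * cp_s[i_max]
        lo = i_max
        while lo > 0 and cp_s[lo - 1] >= thr:
            lo -= 1
        hi = i_max
        while hi < len(T) - 1 and cp_s[hi + 1] >= thr:
            hi += 1
        lo = min(lo, max(i_max - 3, 0))
        hi = max(hi, min(i_max + 3, len(T) - 1))
        a, b, _ = np.polyfit(T[lo:hi + 1] - T[i_max], cp_ex[lo:hi + 1], 2)
        t_refined = float(T[i_max] - b / (2 * a)) if a < 0 else float(T[i_max])
        if not T[lo] <= t_refined <= T[hi]:
            t_refined = float(T[i_max])
        self.T_max_ = t_refined
        self.dH_cal_ = float(np.trapezoid(cp_ex, T))
        self.baseline_slope_ = slope
        self.baseline_intercept_ = intercept
        self.cp_excess_ = cp_ex
        self.T_ = T.copy()
        return self

    def result_(self) -> DSCResult:
        if not hasattr(self, "T_max_"):
            raise NotFittedError("ThermogramAnalyzer is not fitted yet")
        return DSCResult(T_max=self.T_max_, dH_cal=self.dH_cal_,
                         baseline_slope=self.baseline_slope_,
                         baseline_intercept=self.baseline_intercept_,
                         T=self.T_, cp_excess=self.cp_excess_)


def analyze_thermogram(trace: DSCTrace, pre_window=None,
                       post_window=None) -> DSCResult:
    """Tmax, dH_cal and the excess heat capacity of one thermogram."""
    est = ThermogramAnalyzer(pre_window=pre_window, post_window=post_window)
    return est.fit(trace).result_()


def kden_profile(result: DSCResult, trace: DSCTrace,
                 T_query: float | None = None):
    """Denaturation rate constant k(T) from an irreversible two-state thermogram.

    ``k(T) = v * Cp_ex(T) / (dH_cal - Q(T))`` with the scan rate v in K/s
    and Q(T) the cumulative transition heat.  The profile is truncated
    (with a warning) where the remaining enthalpy falls below 2% of dH_cal.
    Returns ``(T, k)`` arrays in deg C and 1/s, plus the interpolated value
    at ``T_query`` (deg C) when given.
    """
    if result.dH_cal <= 0:
        raise ValueError("dH_cal must be > 0 to extract kinetics")
    if result.cp_excess is None or result.T is None:
        raise ValueError("result carries no excess-heat-capacity profile")
    T = result.T
    cp = np.clip(result.cp_excess, 0.0, None)
    v = trace.scan_rate / 60.0  # K/s
    Q = np.concatenate([[0.0],
                        np.cumsum(0.5 * (cp[1:] + cp[:-1]) * np.diff(T))])
    remaining = result.dH_cal - Q
    valid = remaining > 0.02 * result.dH_cal
    if not np.all(valid):
        warnings.warn("kden profile truncated where the transition is "
                      ">98% complete", stacklevel=2)
    k = np.full_like(T, np.nan)
    k[valid] = v * cp[valid] / remaining[valid]
    if T_query is None:
        return T, k
    k_at = float(np.interp(T_query, T[valid], k[valid]))
    return T, k, k_at
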