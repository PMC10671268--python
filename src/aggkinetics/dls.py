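"""Regularized inversion of DLS autocorrelation functions.

The intensity ACF g2(tau) is reduced to the field correlation through the
Siegert relation, g1 = sqrt((g2 - 1)/beta), and expanded on a log-spaced
grid of decay rates Gamma.  The amplitudes solve a non-negative least
squares problem with a second-difference (curvature) Tikhonov penalty — the
standard CONTIN-style formulation.  Contiguous amplitude peaks are then
segmented into populations and converted to hydrodynamic radii through the
Stokes-Einstein relation, reproducing the two-population (large Rh,1 /
small Rh,2) readout of the aggregation experiments.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .datatypes import ACF, SizeDistribution
from .models import stokes_einstein_rh

__all__ = [
    "AcfInversion",
    "invert_acf",
    "distribution_to_populations",
]


def _second_difference(n: int) -> np.ndarray:
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i] = 1.0
        D[i, i + 1] = -2.0
        D[i, i + 2] = 1.0
    return D


def _estimate_beta(g2: np.ndarray) -> float:
    b = float(np.median(g2[:3] - 1.0))
    if b <= 0:
        raise ValueError("cannot estimate beta: no intercept above 1")
    return b


class AcfInversion(BaseEstimator):
    """CONTIN-like decay-rate distribution from an intensity ACF.

    Parameters
    ----------
    grid_size : int
        Number of log-spaced Gamma grid points spanning
        [0.1/tau_max, 10/tau_min].
    alpha : float or None
        Curvature-penalty weight; when None an L-curve corner heuristic
        picks it from a log-spaced candidate set.

    Attributes
    ----------
    Gamma_grid_ : ndarray
    amplitudes_ : ndarray, >= 0 and summing to 1
    alpha_ : float
    residual_norm_ : float
    """

    def __init__(self, grid_size: int = 64, alpha: float | None = None):
        self.grid_size = grid_size
        self.alpha = alpha

    def fit(self, tau, g2, beta: float | None = None):
        tau = np.asarray(tau, dtype=float)
        g2 = np.asarray(g2, dtype=float)
        if beta is None:
            beta = _estimate_beta(g2)
        y = np.sqrt(np.clip(g2 - 1.0, 0.0, None) / beta)
        if float(np.max(y)) < 0.05 or float(y[0] - y[-1]) < 0.05:
            raise ValueError("no signal: ACF shows no resolvable decay")
        grid = np.geomspace(0.1 / tau[-1], 10.0 / tau[0], self.grid_size)
        K = np.exp(-np.outer(tau, grid))
        D = _second_difference(self.grid_size)

        def solve(alpha):
            A_stack = np.vstack([K, np.sqrt(alpha) * D])
            b_stack = np.concatenate([y, np.zeros(D.shape[0])])
            amps, _ = nnls(A_stack, b_stack)
            resid = float(np.linalg.norm(K @ amps - y))
            pen = float(np.linalg.norm(D @ amps))
            return amps, resid, pen

        if self.alpha is not None:
            amps, resid, _ = solve(self.alpha)
            alpha = float(self.alpha)
        else:
            candidates = np.geomspace(1e-7, 1.0, 15)
            sols = [solve(a) for a in candidates]
            log_r = np.log10([max(s[1], 1e-12) for s in sols])
            log_p = np.log10([max(s[2], 1e-12) for s in sols])
            # L-curve corner: maximum curvature of (log residual, log penalty)
            dx = np.gradient(log_r)
            dy = np.gradient(log_p)
            ddx = np.gradient(dx)
            ddy = np.gradient(dy)
            denom = (dx**2 + dy**2) ** 1.5
            with np.errstate(divide="ignore", invalid="ignore"):
                curvature = np.where(denom > 0, (dx * ddy - dy * ddx) / denom, 0.0)
            i_best = int(np.argmax(curvature))
            amps, resid, _ = sols[i_best]
            alpha = float(candidates[i_best])
        total = float(np.sum(amps))
        if total <= 0:
            raise ValueError("no signal: inversion returned empty distribution")
        self.Gamma_grid_ = grid
        self.amplitudes_ = amps / total
        self.alpha_ = alpha
        self.residual_norm_ = resid
        self.beta_ = float(beta)
        return self

    def predict(self, tau):
        """Reconstructed g2 on the supplied lag grid."""
        if not hasattr(self, "amplitudes_"):
            raise NotFittedError("AcfInversion is not fitted yet")
        tau = np.asarray(tau, dtype=float)
        g1 = np.exp(-np.outer(tau, self.Gamma_grid_)) @ self.amplitudes_
        # amplitudes are normalized, so g1(0) = 1 by construction
        return 1.0 + self.beta_ * g1**2

    def result_(self) -> SizeDistribution:
        if not hasattr(self, "amplitudes_"):
            raise NotFittedError("AcfInversion is not fitted yet")
        return SizeDistribution(Gamma_grid=self.Gamma_grid_,
                                amplitudes=self.amplitudes_,
                                regularization_alpha=self.alpha_,
                                residual_norm=self.residual_norm_)


def invert_acf(acf: ACF, grid_size: int = 64,
               alpha: float | None = None) -> SizeDistribution:
    """Decay-rate distribution of an ACF (beta estimated if absent)."""
    est = AcfInversion(grid_size=grid_size, alpha=alpha)
    est.fit(acf.tau, acf.g2, beta=acf.beta)
    return est.result_()


def distribution_to_populations(dist: SizeDistribution, acf: ACF,
                                max_pops: int = 2):
    """Segment the distribution into peaks and size them.

    Contiguous runs of amplitude above a small floor are split at local
    minima; each peak contributes an amplitude-weighted mean decay rate,
    converted to Rh (nm) via D = Gamma/q^2 and Stokes-Einstein.  Up to
    ``max_pops`` populations (largest weights) are returned as
    ``(Rh_nm, weight)`` sorted by Rh descending, weights renormalized to 1.
    """
    A = dist.amplitudes
    floor = 1e-3 * float(np.max(A)) if np.max(A) > 0 else 0.0
    active = A > floor
    peaks = []
    i = 0
    n = len(A)
    while i < n:
        if not active[i]:
            i += 1
            continue
        jx = i
        while jx + 1 < n and active[jx + 1]:
            jx += 1
        # split the run at interior local minima
        seg = A[i:jx + 1]
        splits = [i]
        for k in range(1, len(seg) - 1):
            if seg[k] < seg[k - 1] and seg[k] < seg[k + 1]:
                splits.append(i + k)
        splits.append(jx + 1)
        for a, b in zip(splits[:-1], splits[1:]):
            idx = np.arange(a, b if b > a else a + 1)
            w = float(np.sum(A[idx]))
            if w <= 0:
                continue
            gamma_bar = float(np.sum(A[idx] * dist.Gamma_grid[idx]) / w)
            peaks.append((gamma_bar, w))
        i = jx + 1
    if not peaks:
        return []
    peaks.sort(key=lambda p: -p[1])
    peaks = peaks[:max_pops]
    total = sum(w for _, w in peaks)
    pops = []
    for gamma_bar, w in peaks:
        D = gamma_bar / acf.q**2
        rh_m = float(stokes_einstein_rh(D, acf.T, acf.eta))
        pops.append((rh_m * 1e9, w / total))
    pops.sort(key=lambda p: -p[0])
    return pops
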