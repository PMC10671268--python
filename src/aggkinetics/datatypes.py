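"""Data containers for measured curves and fit results.

The measured-curve types (KineticTrace, NonAggTrace, ACF, DSCTrace) validate
their invariants on construction; the fit-result types are plain records
produced by the estimators and serializable to JSON via :func:`to_dict`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TraceMeta",
    "KineticTrace",
    "NonAggTrace",
    "ACF",
    "DSCTrace",
    "SizeTrace",
    "NucleationFit",
    "GrowthFit",
    "OrderFit",
    "HillFit",
    "NonAggFit",
    "SecondOrderFit",
    "FirstOrderFit",
    "OnsetResult",
    "TraceAnalysis",
    "RegimeCall",
    "SizeDistribution",
    "DSCResult",
    "to_dict",
]


def _as_array(x, name):
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class TraceMeta:
    """Sample metadata attached to every measured curve."""

    protein_conc: float = 0.0      # mg/mL
    ligand_conc: float = 0.0       # mM
    temperature: float = 56.0      # deg C
    viscosity: Optional[float] = None        # mPa s
    refractive_index: Optional[float] = None
    label: str = ""

    def __post_init__(self):
        if self.protein_conc < 0:
            raise ValueError("protein_conc must be >= 0")
        if self.ligand_conc < 0:
            raise ValueError("ligand_conc must be >= 0")
        if self.viscosity is not None and self.viscosity <= 0:
            raise ValueError("viscosity must be > 0 when given")


@dataclass
class KineticTrace:
    """A light-scattering aggregation trace: time (s) vs intensity (counts)."""

    t: np.ndarray
    I: np.ndarray
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self):
        self.t = _as_array(self.t, "t")
        self.I = _as_array(self.I, "I")
        if len(self.t) != len(self.I):
            raise ValueError("t and I must have equal length")
        if len(self.t) < 10:
            raise ValueError("a kinetic trace needs at least 10 points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.I < 0):
            raise ValueError("intensity must be non-negative")

    def __len__(self):
        return len(self.t)


@dataclass
class NonAggTrace:
    """Fraction of non-aggregated (supernatant) protein vs time (minutes)."""

    t: np.ndarray
    gamma: np.ndarray
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self):
        self.t = _as_array(self.t, "t")
        self.gamma = _as_array(self.gamma, "gamma")
        if len(self.t) != len(self.gamma):
            raise ValueError("t and gamma must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.gamma < 0) or np.any(self.gamma > 1.0 + 1e-9):
            raise ValueError("gamma must lie in [0, 1]")


@dataclass
class ACF:
    """DLS intensity autocorrelation function g2(tau) with optics metadata."""

    tau: np.ndarray                 # s
    g2: np.ndarray
    q: float                        # 1/m
    T: float                        # K
    eta: float                      # Pa s
    beta: Optional[float] = None    # coherence factor; estimated if None
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self):
        self.tau = _as_array(self.tau, "tau")
        self.g2 = _as_array(self.g2, "g2")
        if len(self.tau) != len(self.g2):
            raise ValueError("tau and g2 must have equal length")
        if len(self.tau) < 20:
            raise ValueError("an ACF needs at least 20 lag points")
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be strictly increasing")
        if self.q <= 0 or self.T <= 0 or self.eta <= 0:
            raise ValueError("q, T and eta must be > 0")


@dataclass
class DSCTrace:
    """A DSC thermogram: temperature (deg C) vs heat-capacity signal.

    ``signal_units`` is either ``"kJ/mol/K"`` (already molar excess heat
    capacity) or ``"ucal/C"`` (raw instrument signal, converted to molar
    units using conc, cell_volume and molar_mass during analysis).
    """

    T: np.ndarray                   # deg C
    signal: np.ndarray
    scan_rate: float = 1.0          # deg C / min
    conc: float = 0.73              # mg/mL
    cell_volume: float = 0.130      # mL
    molar_mass: float = 150_000.0   # g/mol
    signal_units: str = "kJ/mol/K"

    def __post_init__(self):
        self.T = _as_array(self.T, "T")
        self.signal = _as_array(self.signal, "signal")
        if len(self.T) != len(self.signal):
            raise ValueError("T and signal must have equal length")
        if len(self.T) < 50:
            raise ValueError("a thermogram needs at least 50 points")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("T must be strictly increasing")
        if self.scan_rate <= 0:
            raise ValueError("scan_rate must be > 0")
        if self.signal_units not in ("kJ/mol/K", "ucal/C"):
            raise ValueError(f"unknown signal_units {self.signal_units!r}")


@dataclass
class SizeTrace:
    """Per-time hydrodynamic-radius populations: list of (Rh_nm, weight)."""

    t: np.ndarray
    populations: list  # list (per time point) of lists of (Rh_nm, weight)
    meta: TraceMeta = field(default_factory=TraceMeta)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


@dataclass
class NucleationFit:
    """Quadratic nucleation-stage fit: I = I0 + K_agg (t - t0)^2."""

    K_agg: float                # counts / s^2
    t0: float                   # s
    I0: float                   # counts
    r_squared: float
    window: tuple               # (t_start, t_end), s
    K_agg_stderr: Optional[float] = None


@dataclass
class GrowthFit:
    """Growth-stage fit: I = I0 + v0 (t - t*) - B (t - t*)^2."""

    v0: float                   # counts / s
    t_star: float               # s
    B: float                    # counts / s^2
    I0: float                   # counts
    r_squared: float
    window: tuple
    v0_stderr: Optional[float] = None
    over_curvature: bool = False


@dataclass
class OrderFit:
    """Power-law fit y = const * x**b; n_c is b rounded to an integer."""

    b: float
    const: float
    b_stderr: float
    n_c: int

    def __post_init__(self):
        if self.const <= 0:
            raise ValueError("const must be > 0")
        if self.n_c != round(self.b):
            raise ValueError("n_c must equal round(b)")


@dataclass
class HillFit:
    """Hill dose-response fit of a rate-parameter ratio."""

    L_half: float               # mM
    h: float
    baseline: float             # parameter value at zero ligand
    L_half_stderr: Optional[float] = None
    h_stderr: Optional[float] = None
    r_squared: Optional[float] = None

    def __post_init__(self):
        if self.L_half <= 0 or self.h <= 0:
            raise ValueError("L_half and h must be > 0")


@dataclass
class NonAggFit:
    """Fit of the non-aggregated-fraction decay (lag + shaped decay)."""

    t_star: float               # min
    t_half: float               # min (half-decay interval past the lag)
    m: float
    r_squared: float
    at_lower_bound: bool = False


@dataclass
class SecondOrderFit:
    """Linear fit in second-order coordinates 1/c - 1/c0 vs t (seconds)."""

    k_II: float                 # L mol^-1 s^-1
    intercept: float            # L/mol, diagnostic (should be ~0)
    r_squared: float


@dataclass
class FirstOrderFit:
    """Single-exponential decay fit N(t)/N0 = exp(-k t)."""

    k: float                    # 1 / (unit of t)
    amplitude: float
    r_squared: float


@dataclass
class OnsetResult:
    """Detected aggregation onset; ``detected`` False means no rise found."""

    time: float                 # s
    detected: bool
    threshold: float


@dataclass
class TraceAnalysis:
    """Assembled per-trace analysis: onset, nucleation and growth fits."""

    nucleation: Optional[NucleationFit]
    growth: Optional[GrowthFit]
    onset_time: Optional[float]
    inflection_time: Optional[float]
    onset_detected: bool
    trace_meta: TraceMeta


@dataclass
class RegimeCall:
    """Kinetic-regime classification from the two stage orders."""

    n_c_nucleation: int
    n_c_growth: int
    limiting_stage: str         # "denaturation" | "aggregate_growth" | "indeterminate"
    evidence: dict


@dataclass
class SizeDistribution:
    """Regularized decay-rate distribution from an ACF inversion."""

    Gamma_grid: np.ndarray      # 1/s, log-spaced
    amplitudes: np.ndarray      # >= 0, sum to 1
    regularization_alpha: float
    residual_norm: float


@dataclass
class DSCResult:
    """Thermogram analysis: transition maximum, enthalpy and baseline."""

    T_max: float                # deg C
    dH_cal: float               # kJ/mol
    baseline_slope: float
    baseline_intercept: float
    T: Optional[np.ndarray] = None       # deg C grid of cp_excess
    cp_excess: Optional[np.ndarray] = None  # kJ/mol/K


def to_dict(obj):
    """Recursively convert a result dataclass to JSON-friendly primitives."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_dict(v) for v in obj]
    return obj
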