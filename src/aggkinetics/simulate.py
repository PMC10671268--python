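"""Mass-action forward simulator of thermal protein aggregation.

The mechanistic scheme: native protein N unfolds irreversibly to an
aggregation-prone intermediate (first-order, k_den); n_nuc intermediates
form a start nucleus cooperatively (k_nuc); aggregates grow by bimolecular
attachment of intermediates (k_grow, the kII of the growth stage); and
aggregates stick to each other with a constant Smoluchowski kernel
(k_stick).  The cluster-size spectrum is truncated at J_max with a hybrid
overflow bin that tracks the number and monomer-equivalent mass of clusters
larger than J_max, so total mass is conserved exactly.

Two presets realize the two kinetic regimes observed experimentally:

* regime A (no chaperone): dimeric nucleation, attachment much faster than
  unfolding (k_grow*c0 >> k_den) and active aggregate-aggregate sticking —
  the overall process is denaturation-limited and the growth-stage order of
  aggregation rounds to 1;
* regime B (saturating chaperone): a four-molecular start nucleus, slow
  attachment (k_grow*c0 << k_den) and suppressed sticking — the bimolecular
  growth step limits and the order rounds to 2.

The module also renders every synthetic observable used to exercise the
analysis pipeline: light-scattering traces (mass-squared weighting with a
fractal structure-factor rolloff), non-aggregated-fraction decays
(pelleting emulation), hydrodynamic-radius populations, dose-response
series, DLS autocorrelation functions and DSC thermograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .constants import DEFAULT_PROTEIN_MOLAR_MASS, celsius_to_kelvin, protein_molarity
from .datatypes import ACF, DSCTrace, KineticTrace, NonAggTrace, SizeTrace, TraceMeta
from .models import eval_hill, stokes_einstein_d

__all__ = [
    "SimConfig",
    "SpeciesTrajectory",
    "simulate_trajectory",
    "trajectory_to_intensity",
    "trajectory_to_gamma",
    "trajectory_to_rh",
    "make_regime_presets",
    "synth_dose_response",
    "synth_composite_trace",
    "synth_second_order_gamma",
    "synth_first_order_decay",
    "synth_acf",
    "synth_dsc",
    "synth_dsc_irreversible",
]


@dataclass
class SimConfig:
    """Parameters of the aggregation scheme and of the rendered observables.

    Rate constants: k_den (1/s) native -> intermediate; k_nuc
    ((L/mol)^(n_nuc-1)/s) cooperative nucleation of n_nuc intermediates;
    k_grow (L/mol/s) intermediate attachment to a cluster; k_stick (L/mol/s)
    cluster-cluster coagulation.  c0 is the monomer-equivalent tetramer
    concentration (mol/L).  j_pellet is the smallest cluster removed by the
    centrifugation emulation; d_f the mass-fractal dimension of the
    aggregates (Rh = R_mono * j**(1/d_f)); intensity_scale an arbitrary
    counts-per-molar factor.
    """

    c0: float = 2.67e-6
    k_den: float = 1.0e-3
    n_nuc: int = 2
    k_nuc: float = 1.0e4
    k_grow: float = 1.0e6
    k_stick: float = 0.0
    J_max: int = 64
    j_pellet: int = 10
    j_split: int = 10
    d_f: float = 2.5
    R_mono_nm: float = 4.5
    q_scatter: float = 1.868e7      # 1/m; 632.8 nm, 90 deg, n = 1.33
    intensity_scale: float = 1.0e9
    noise_sd_frac: float = 0.01
    seed: int = 0
    t_end: float = 3600.0
    n_times: int = 121
    t_grid: Optional[np.ndarray] = None

    def __post_init__(self):
        if min(self.k_den, self.k_nuc, self.k_grow, self.k_stick) < 0:
            raise ValueError("rate constants must be >= 0")
        if self.c0 <= 0:
            raise ValueError("c0 must be > 0")
        if not 2 <= self.n_nuc <= 6:
            raise ValueError("n_nuc must lie in [2, 6]")
        if self.j_pellet > self.J_max:
            raise ValueError("j_pellet must not exceed J_max")
        if not 1.0 < self.d_f <= 3.0:
            raise ValueError("d_f must lie in (1, 3]")
        if self.t_grid is None:
            self.t_grid = np.linspace(0.0, self.t_end, self.n_times)
        else:
            self.t_grid = np.asarray(self.t_grid, dtype=float)


@dataclass
class SpeciesTrajectory:
    """Concentrations over time: native N, clusters c_j (j=1..J_max), overflow.

    ``c`` has shape (n_times, J_max); column j-1 holds c_j, with j=1 the
    unfolded intermediate.  ``n_over`` / ``m_over`` are the number and
    monomer-equivalent molarity of clusters beyond J_max.
    """

    t: np.ndarray
    N: np.ndarray
    c: np.ndarray
    n_over: np.ndarray
    m_over: np.ndarray
    config: SimConfig = field(repr=False, default=None)

    def total_mass(self) -> np.ndarray:
        j = np.arange(1, self.c.shape[1] + 1)
        return self.N + self.c @ j.astype(float) + self.m_over


def _rhs(t, y, cfg: SimConfig):
    J = cfg.J_max
    N = y[0]
    c = y[1:J + 1]            # c[j-1] = c_j
    n_over = y[J + 1]
    dy = np.zeros_like(y)

    # denaturation N -> I
    r_den = cfg.k_den * N
    dy[0] -= r_den
    dy[1] += r_den

    c1 = c[0]
    # cooperative nucleation: n_nuc I -> cluster of size n_nuc
    if cfg.k_nuc > 0:
        J_rate = cfg.k_nuc * max(c1, 0.0) ** cfg.n_nuc
        dy[1] -= cfg.n_nuc * J_rate
        dy[cfg.n_nuc] += J_rate

    # monomer attachment to clusters j >= 2 (and to the overflow bin)
    if cfg.k_grow > 0:
        rates = cfg.k_grow * c1 * c[1:]          # sizes 2..J
        dy[1] -= np.sum(rates)
        dy[2:J + 1] -= rates
        dy[3:J + 1] += rates[:-1]                # j -> j+1 for j = 2..J-1
        # growth past the cap: the cluster moves to the overflow bin
        dy[J + 1] += rates[-1]
        dy[J + 2] += (J + 1) * rates[-1]
        r_over = cfg.k_grow * c1 * n_over
        dy[1] -= r_over
        dy[J + 2] += r_over

    # cluster-cluster sticking, constant kernel
    if cfg.k_stick > 0:
        s = np.clip(c[1:], 0.0, None)            # sizes 2..J
        S = float(np.sum(s))
        dy[2:J + 1] -= cfg.k_stick * s * S       # every partner pairing
        conv = np.convolve(s, s)                 # index p: size-sum p + 4
        sizes = np.arange(4, 4 + len(conv))
        gain = 0.5 * cfg.k_stick * conv
        in_range = sizes <= J
        dy[sizes[in_range]] += gain[in_range]
        dy[J + 1] += float(np.sum(gain[~in_range]))
        dy[J + 2] += float(np.sum(gain[~in_range] * sizes[~in_range]))
        # cluster + overflow: the cluster is absorbed (number unchanged)
        r_abs = cfg.k_stick * s * n_over
        dy[2:J + 1] -= r_abs
        dy[J + 2] += float(np.sum(r_abs * np.arange(2, J + 1)))
        # overflow + overflow: numbers merge, mass unchanged
        dy[J + 1] -= 0.5 * cfg.k_stick * n_over * n_over
    return dy


def simulate_trajectory(config: SimConfig) -> SpeciesTrajectory:
    """Integrate the aggregation scheme on the configured time grid.

    Deterministic stiff integration (BDF, rtol 1e-8, atol 1e-12*c0); raises
    if the solver fails or if total mass drifts by more than 1e-6*c0.
    """
    J = config.J_max
    y0 = np.zeros(J + 3)
    y0[0] = config.c0
    t_grid = config.t_grid
    sol = solve_ivp(_rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    args=(config,), method="BDF", rtol=1e-8,
                    atol=1e-12 * config.c0)
    if not sol.success:
        raise RuntimeError(f"aggregation ODE solver failed: {sol.message}")
    Y = sol.y.T
    traj = SpeciesTrajectory(t=t_grid.copy(), N=Y[:, 0], c=Y[:, 1:J + 1],
                             n_over=Y[:, J + 1], m_over=Y[:, J + 2],
                             config=config)
    drift = np.max(np.abs(traj.total_mass() - config.c0))
    if drift > 1e-6 * config.c0:
        raise RuntimeError(
            f"mass conservation violated: max drift {drift:.3e} mol/L")
    return traj


def structure_factor(j, cfg: SimConfig) -> np.ndarray:
    """Fisher-Burford structure factor of a mass-fractal j-mer.

    ``S(qR) = (1 + (2/(3 d_f)) (qR)^2)**(-d_f/2)`` with
    ``R = R_mono * j**(1/d_f)``.  Small clusters (qR << 1) scatter in the
    Rayleigh limit, S -> 1 and intensity per cluster goes as j^2; large
    fractal clusters roll over to S ~ (qR)^(-d_f), making intensity per
    cluster proportional to j — so the trace becomes linear in aggregated
    mass, as observed for heavily aggregated samples.
    """
    j = np.asarray(j, dtype=float)
    qR = cfg.q_scatter * cfg.R_mono_nm * 1e-9 * j ** (1.0 / cfg.d_f)
    return (1.0 + (2.0 / (3.0 * cfg.d_f)) * qR**2) ** (-cfg.d_f / 2.0)


def _overflow_intensity(traj: SpeciesTrajectory, cfg: SimConfig) -> np.ndarray:
    # overflow clusters: n * (mean mass)^2 * S(q R(mean mass))
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_j = np.where(traj.n_over > 1e-30, traj.m_over / traj.n_over, 1.0)
        contrib = np.where(traj.n_over > 1e-30,
                           traj.n_over * mean_j**2
                           * structure_factor(mean_j, cfg), 0.0)
    return contrib


def trajectory_to_intensity(traj: SpeciesTrajectory,
                            config: SimConfig | None = None) -> KineticTrace:
    """Render a light-scattering trace with mass-squared x form-factor weighting.

    I(t) = scale * [ (N + c_1) + sum_{j>=2} j^2 S(qR_j) c_j + overflow ]
    plus multiplicative Gaussian noise (config.noise_sd_frac, seeded).  The
    monomeric term (N + c_1) is the baseline: with no aggregation the trace
    is flat at that level.
    """
    cfg = config or traj.config
    j = np.arange(1, traj.c.shape[1] + 1, dtype=float)
    weights = j**2 * structure_factor(j, cfg)
    weights[0] = 1.0
    monomeric = traj.N + traj.c[:, 0]
    aggregate = traj.c[:, 1:] @ weights[1:] + _overflow_intensity(traj, cfg)
    I = cfg.intensity_scale * (monomeric + aggregate)
    if cfg.noise_sd_frac > 0:
        rng = np.random.default_rng(cfg.seed)
        I = I * (1.0 + cfg.noise_sd_frac * rng.standard_normal(len(I)))
    I = np.clip(I, 0.0, None)
    meta = TraceMeta(
        protein_conc=cfg.c0 * DEFAULT_PROTEIN_MOLAR_MASS,
        ligand_conc=0.0, temperature=56.0,
        label=f"sim c0={cfg.c0:.3g} M")
    return KineticTrace(t=traj.t.copy(), I=I, meta=meta)


def trajectory_to_gamma(traj: SpeciesTrajectory,
                        config: SimConfig | None = None) -> NonAggTrace:
    """Non-aggregated fraction after emulated pelleting of large clusters.

    Clusters of size >= j_pellet (and the overflow bin) are removed by the
    centrifugation emulation; gamma is the remaining protein mass over c0.
    Times are reported in minutes, matching the supernatant assay.
    """
    cfg = config or traj.config
    j = np.arange(1, traj.c.shape[1] + 1, dtype=float)
    keep = j < cfg.j_pellet
    supernatant = traj.N + traj.c[:, keep] @ j[keep]
    gamma = np.clip(supernatant / cfg.c0, 0.0, 1.0)
    meta = TraceMeta(protein_conc=cfg.c0 * DEFAULT_PROTEIN_MOLAR_MASS,
                     temperature=56.0, label="sim gamma_non-agg")
    return NonAggTrace(t=traj.t / 60.0, gamma=gamma, meta=meta)


def trajectory_to_rh(traj: SpeciesTrajectory,
                     config: SimConfig | None = None) -> SizeTrace:
    """Intensity-weighted hydrodynamic radii of the small and large populations.

    Clusters with j < j_split (monomeric species included) form the small
    population; j >= j_split plus the overflow bin the large one.  Each
    population reports the intensity-weighted mean of
    Rh(j) = R_mono * j**(1/d_f) and its normalized intensity weight.
    """
    cfg = config or traj.config
    Jdim = traj.c.shape[1]
    j = np.arange(1, Jdim + 1, dtype=float)
    rh_j = cfg.R_mono_nm * j ** (1.0 / cfg.d_f)
    pops_per_time = []
    for i in range(len(traj.t)):
        w = traj.c[i] * j**2
        w[0] += traj.N[i]  # native protein scatters like the monomer
        small_sel = j < cfg.j_split
        entries = []
        w_small = float(np.sum(w[small_sel]))
        if w_small > 0:
            rh_small = float(np.sum(w[small_sel] * rh_j[small_sel]) / w_small)
            entries.append([rh_small, w_small])
        w_large = float(np.sum(w[~small_sel]))
        rh_large_num = float(np.sum(w[~small_sel] * rh_j[~small_sel]))
        if traj.n_over[i] > 1e-30:
            mean_j = traj.m_over[i] / traj.n_over[i]
            w_of = traj.n_over[i] * mean_j**2
            rh_large_num += w_of * cfg.R_mono_nm * mean_j ** (1.0 / cfg.d_f)
            w_large += w_of
        if w_large > 0:
            entries.append([rh_large_num / w_large, w_large])
        total = sum(e[1] for e in entries)
        pops = [(rh, wt / total) for rh, wt in entries] if total > 0 else []
        # sorted by Rh descending, as reported for the two DLS populations
        pops.sort(key=lambda p: -p[0])
        pops_per_time.append(pops)
    meta = TraceMeta(protein_conc=cfg.c0 * DEFAULT_PROTEIN_MOLAR_MASS,
                     temperature=56.0, label="sim Rh populations")
    return SizeTrace(t=traj.t.copy(), populations=pops_per_time, meta=meta)


def make_regime_presets(regime: str, protein_conc: float = 0.4,
                        seed: int = 0) -> SimConfig:
    """Simulator configuration realizing one of the two kinetic regimes.

    Parameters
    ----------
    regime : {"A", "B"}
        "A": no chaperone — dimeric nucleation, fast attachment
        (k_grow*c0 >> k_den), active sticking; denaturation-limited, growth
        order rounds to 1.  "B": saturating chaperone — four-molecular start
        nuclei, slow attachment (k_grow*c0 << k_den, with k_grow set to the
        measured growth-stage kII), sticking suppressed; growth-limited,
        order rounds to 2.
    protein_conc : float
        Protein concentration in mg/mL (0.1-0.6 is the experimental range);
        converted internally to mol tetramer / L.
    """
    c0 = protein_molarity(protein_conc)
    if regime == "A":
        # slow dimeric nucleation (visible lag), attachment ~5000x faster
        # than unfolding, vigorous sticking (diffusion-limited cluster
        # aggregation, open fractals with d_f ~ 1.8): unfolding limits.
        return SimConfig(
            c0=c0, k_den=1.0e-3, n_nuc=2, k_nuc=1.0e3, k_grow=2.0e6,
            k_stick=1.0e6, J_max=64, j_pellet=5, d_f=1.8,
            noise_sd_frac=0.0, seed=seed, t_end=3600.0, n_times=121)
    if regime == "B":
        # cooperative 4-molecular start nuclei, attachment at the measured
        # growth-stage kII (k_grow*c0 << k_den), sticking suppressed by the
        # chaperone, compact clusters: bimolecular growth limits.
        return SimConfig(
            c0=c0, k_den=1.0e-3, n_nuc=4, k_nuc=1.0e13, k_grow=69.0,
            k_stick=0.0, J_max=64, j_pellet=5, d_f=2.5,
            noise_sd_frac=0.0, seed=seed, t_end=10800.0, n_times=121)
    raise ValueError(f"unknown regime {regime!r}; expected 'A' or 'B'")


# ---------------------------------------------------------------------------
# synthetic observables independent of the ODE core
# ---------------------------------------------------------------------------


def synth_dose_response(L_grid, L_half: float, h: float,
                        noise_sd_frac: float = 0.0, seed: int = 0,
                        baseline: float = 1.0):
    """Baseline-normalized Hill dose-response values with multiplicative noise.

    Returns ``(L, y)`` with ``y = baseline * (1 + noise) / (1 + (L/L_half)^h)``.
    """
    L = np.asarray(L_grid, dtype=float)
    y = baseline * eval_hill(L, L_half, h)
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + noise_sd_frac * rng.standard_normal(len(L)))
    return L, np.clip(y, 1e-12, None)


def synth_composite_trace(t, I0: float, K_agg: float, t0: float,
                          t_junction: float, B: float,
                          noise_sd_frac: float = 0.0, seed: int = 0,
                          meta: TraceMeta | None = None) -> KineticTrace:
    """Sigmoid-like trace: baseline, quadratic rise, then growth polynomial.

    The quadratic nucleation segment runs from t0 to t_junction; the growth
    polynomial continues from there with matched value and slope, so the
    junction is C1-continuous and the generating (v0, t*) follow from
    (K_agg, t0, t_junction, B).  The generating growth parameters are
    attached as ``generating_growth = (v0, t_star)`` on the returned trace.
    """
    if t_junction <= t0:
        raise ValueError("t_junction must exceed t0")
    t = np.asarray(t, dtype=float)
    I_j = I0 + K_agg * (t_junction - t0) ** 2
    v_j = 2.0 * K_agg * (t_junction - t0)
    # continuity: B u^2 + v_j u = I_j - I0 with u = t_junction - t*
    if B > 0:
        u = (-v_j + np.sqrt(v_j**2 + 4.0 * B * (I_j - I0))) / (2.0 * B)
    else:
        u = (I_j - I0) / v_j if v_j > 0 else 0.0
    t_star = t_junction - u
    v0 = v_j + 2.0 * B * u
    I = np.where(t <= t0, I0,
                 np.where(t <= t_junction,
                          I0 + K_agg * (t - t0) ** 2,
                          I0 + v0 * (t - t_star) - B * (t - t_star) ** 2))
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        peak = float(np.max(I) - I0)
        I = I + noise_sd_frac * peak * rng.standard_normal(len(t))
    trace = KineticTrace(t=t, I=np.clip(I, 0.0, None),
                         meta=meta or TraceMeta(label="synthetic composite"))
    trace.generating_growth = (float(v0), float(t_star))
    return trace


def synth_second_order_gamma(t_min, c0: float, k_II: float,
                             noise_sd_frac: float = 0.0,
                             seed: int = 0) -> NonAggTrace:
    """Exact bimolecular depletion ``gamma = 1 / (1 + c0 * kII * t)`` plus noise.

    ``t_min`` in minutes, ``kII`` in L/mol/s (the time conversion is done
    internally); multiplicative Gaussian noise on gamma.
    """
    t = np.asarray(t_min, dtype=float)
    gamma = 1.0 / (1.0 + c0 * k_II * t * 60.0)
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        gamma = gamma * (1.0 + noise_sd_frac * rng.standard_normal(len(t)))
    gamma = np.clip(gamma, 1e-9, 1.0)
    return NonAggTrace(t=t, gamma=gamma,
                       meta=TraceMeta(label="synthetic second-order decay"))


def synth_first_order_decay(t, k: float, noise_sd_frac: float = 0.0,
                            seed: int = 0):
    """Exponential native-fraction decay ``exp(-k t)`` with multiplicative noise."""
    t = np.asarray(t, dtype=float)
    y = np.exp(-k * t)
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + noise_sd_frac * rng.standard_normal(len(t)))
    return t, np.clip(y, 1e-12, None)


def synth_acf(populations, q: float, beta: float, tau_grid,
              noise_sd: float = 0.0, seed: int = 0,
              T: float = celsius_to_kelvin(56.0),
              eta: float = 0.5e-3) -> ACF:
    """DLS autocorrelation of a mixture of diffusing populations.

    ``populations`` is a list of (Rh_nm, weight) with weights summing to 1.
    g1(tau) = sum w_i exp(-Gamma_i tau) with Gamma_i = D(Rh_i) * q^2, and
    g2 = 1 + beta * g1^2 plus additive Gaussian noise of SD ``noise_sd``.
    """
    tau = np.asarray(tau_grid, dtype=float)
    weights = np.array([w for _, w in populations], dtype=float)
    if abs(float(np.sum(weights)) - 1.0) > 1e-6:
        raise ValueError("population weights must sum to 1")
    g1 = np.zeros_like(tau)
    for (rh_nm, w) in populations:
        D = stokes_einstein_d(rh_nm * 1e-9, T, eta)
        g1 += w * np.exp(-float(D) * q**2 * tau)
    g2 = 1.0 + beta * g1**2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g2 = g2 + noise_sd * rng.standard_normal(len(tau))
    return ACF(tau=tau, g2=g2, q=q, T=T, eta=eta, beta=beta)


def synth_dsc(T_grid, Tmax: float, dH: float, width: float = 4.0,
              baseline_slope: float = 0.0, baseline_offset: float = 0.0,
              conc: float = 0.73, noise_sd_frac: float = 0.0,
              seed: int = 0) -> DSCTrace:
    """Gaussian excess-heat-capacity peak with a linear baseline.

    The peak amplitude is chosen so the analytic area equals ``dH`` (kJ/mol
    tetramer): amplitude = dH / (width * sqrt(2 pi)).  Noise is Gaussian
    with SD ``noise_sd_frac`` of the amplitude.  Signal units: kJ/mol/K.
    """
    T = np.asarray(T_grid, dtype=float)
    if dH <= 0 or width <= 0:
        raise ValueError("dH and width must be > 0")
    amp = dH / (width * np.sqrt(2.0 * np.pi))
    signal = (amp * np.exp(-0.5 * ((T - Tmax) / width) ** 2)
              + baseline_slope * T + baseline_offset)
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        signal = signal + noise_sd_frac * amp * rng.standard_normal(len(T))
    return DSCTrace(T=T, signal=signal, scan_rate=1.0, conc=conc,
                    signal_units="kJ/mol/K")


def synth_dsc_irreversible(T_grid, k0: float, Ea: float, T0: float,
                           dH: float, scan_rate: float = 1.0) -> DSCTrace:
    """Thermogram of a two-state irreversible transition N -> D.

    The denaturation rate follows the exponential approximation
    ``k(T) = k0 * exp(Ea * (T - T0) / (R * T0^2))`` (T in kelvin, Ea in
    J/mol, k0 = k(T0) in 1/s).  The conversion alpha obeys
    d(alpha)/dT = k(T) (1 - alpha) / v with v the scan rate in K/s, and the
    excess heat capacity is dH * d(alpha)/dT.  Used as the forward model for
    validating the kden extraction.
    """
    R = 8.314462618
    T = np.asarray(T_grid, dtype=float)
    v = scan_rate / 60.0
    TK = T + 273.15
    T0K = T0 + 273.15
    k = k0 * np.exp(Ea * (TK - T0K) / (R * T0K**2))
    # integrate d(ln(1-alpha))/dT = -k/v by trapezoid
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (k[1:] + k[:-1]) * np.diff(T))]) / v
    one_minus_alpha = np.exp(-integral)
    cp = dH * k * one_minus_alpha / v
    return DSCTrace(T=T, signal=cp, scan_rate=scan_rate,
                    signal_units="kJ/mol/K")
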