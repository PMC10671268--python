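"""Forward simulator: conservation laws, oracles and rendered observables."""

import numpy as np
import pytest

from aggkinetics import (
    SimConfig,
    eval_hill,
    fit_dose_response,
    fit_first_order,
    make_regime_presets,
    simulate_trajectory,
    synth_acf,
    synth_dose_response,
    synth_dsc,
    trajectory_to_gamma,
    trajectory_to_intensity,
    trajectory_to_rh,
)
from aggkinetics.simulate import structure_factor


def euler_oracle(cfg, n_sub=100):
    """Independent fixed-step Euler integration with explicit per-reaction loops."""
    J = cfg.J_max
    N = cfg.c0
    c = np.zeros(J + 1)  # c[j] for j = 1..J
    n_over = m_over = 0.0
    t_grid = cfg.t_grid
    out = [(N, c.copy(), n_over, m_over)]
    for a, b in zip(t_grid[:-1], t_grid[1:]):
        dt = (b - a) / n_sub
        for _ in range(n_sub):
            dN = -cfg.k_den * N
            dc = np.zeros(J + 1)
            dn_o = dm_o = 0.0
            dc[1] += cfg.k_den * N
            if cfg.k_nuc > 0:
                r = cfg.k_nuc * c[1] ** cfg.n_nuc
                dc[1] -= cfg.n_nuc * r
                dc[cfg.n_nuc] += r
            if cfg.k_grow > 0:
                for j in range(2, J + 1):
                    r = cfg.k_grow * c[1] * c[j]
                    dc[1] -= r
                    dc[j] -= r
                    if j < J:
                        dc[j + 1] += r
                    else:
                        dn_o += r
                        dm_o += (J + 1) * r
                r = cfg.k_grow * c[1] * n_over
                dc[1] -= r
                dm_o += r
            if cfg.k_stick > 0:
                for i in range(2, J + 1):
                    for j in range(2, J + 1):
                        r = cfg.k_stick * c[i] * c[j]
                        dc[i] -= r  # counts each unordered pair twice overall
                        if i + j <= J:
                            dc[i + j] += 0.5 * r
                        else:
                            dn_o += 0.5 * r
                            dm_o += 0.5 * r * (i + j)
                for j in range(2, J + 1):
                    r = cfg.k_stick * c[j] * n_over
                    dc[j] -= r
                    dm_o += j * r
                dn_o -= 0.5 * cfg.k_stick * n_over**2
            N += dt * dN
            c += dt * dc
            n_over += dt * dn_o
            m_over += dt * dm_o
        out.append((N, c.copy(), n_over, m_over))
    return out


class TestTrajectory:
    def test_pure_denaturation_closed_form(self):
        cfg = SimConfig(c0=1e-6, k_den=2e-3, k_nuc=0.0, k_grow=0.0,
                        k_stick=0.0, t_end=2000.0, n_times=21)
        traj = simulate_trajectory(cfg)
        assert np.allclose(traj.N, 1e-6 * np.exp(-2e-3 * traj.t), rtol=1e-6)
        assert np.allclose(traj.c[:, 0], 1e-6 * (1 - np.exp(-2e-3 * traj.t)),
                           rtol=1e-6, atol=1e-15)

    @pytest.mark.parametrize("preset", ["A", "B"])
    def test_mass_conservation(self, preset):
        cfg = make_regime_presets(preset, protein_conc=0.4)
        traj = simulate_trajectory(cfg)
        assert np.max(np.abs(traj.total_mass() - cfg.c0)) <= 1e-6 * cfg.c0

    def test_against_euler_oracle_small_system(self):
        cfg = SimConfig(c0=1e-6, k_den=5e-3, n_nuc=2, k_nuc=5e3, k_grow=2e5,
                        k_stick=1e5, J_max=6, j_pellet=3, t_end=400.0,
                        n_times=9)
        traj = simulate_trajectory(cfg)
        oracle = euler_oracle(cfg, n_sub=2000)
        for i, (N, c, n_o, m_o) in enumerate(oracle):
            assert traj.N[i] == pytest.approx(N, abs=1e-4 * cfg.c0)
            assert np.allclose(traj.c[i], c[1:], atol=1e-4 * cfg.c0)
            assert traj.m_over[i] == pytest.approx(m_o, abs=1e-4 * cfg.c0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(k_den=-1.0)


class TestIntensityRendering:
    def test_all_monomer_trace_is_flat_baseline(self):
        cfg = SimConfig(c0=1e-6, k_den=1e-3, k_nuc=0.0, k_grow=0.0,
                        k_stick=0.0, noise_sd_frac=0.0, t_end=1000.0, n_times=21)
        trace = trajectory_to_intensity(simulate_trajectory(cfg))
        assert np.allclose(trace.I, trace.I[0], rtol=1e-9)

    def test_dimer_weighting(self):
        # a dimer-only state contributes ~4x its concentration (j^2 = 4,
        # with the structure factor within 1% of unity at j = 2)
        cfg = SimConfig(c0=1e-6, noise_sd_frac=0.0, t_end=9.0, n_times=10)
        traj = simulate_trajectory(cfg)
        x = 2.0e-7
        traj.c[:, :] = 0.0
        traj.N[:] = 0.0
        traj.c[:, 1] = x  # c_2
        trace = trajectory_to_intensity(traj, cfg)
        assert trace.I[0] == pytest.approx(cfg.intensity_scale * 4 * x, rel=0.01)

    def test_linearity_in_concentrations(self):
        cfg = SimConfig(c0=1e-6, noise_sd_frac=0.0, t_end=9.0, n_times=10)
        traj = simulate_trajectory(cfg)
        traj.N[:] = 2e-7
        traj.c[:, 3] = 1e-8
        base = trajectory_to_intensity(traj, cfg).I[0]
        traj.N[:] *= 2
        traj.c[:, 3] *= 2
        assert trajectory_to_intensity(traj, cfg).I[0] == pytest.approx(
            2 * base, rel=1e-9)

    def test_structure_factor_limits(self):
        cfg = SimConfig()
        assert structure_factor(1, cfg) == pytest.approx(1.0, abs=0.01)
        big = structure_factor(1e6, cfg)
        # deep-fractal rolloff: S ~ (qR)^-d_f, far below unity
        assert big < 1e-2


class TestGammaRendering:
    def test_initial_gamma_is_one(self):
        cfg = make_regime_presets("A", protein_conc=0.3)
        gamma = trajectory_to_gamma(simulate_trajectory(cfg))
        assert gamma.gamma[0] == pytest.approx(1.0)

    def test_monotone_non_increasing(self):
        for preset in ("A", "B"):
            cfg = make_regime_presets(preset, protein_conc=0.4)
            g = trajectory_to_gamma(simulate_trajectory(cfg)).gamma
            assert np.all(np.diff(g) <= 1e-9)

    def test_pellet_cutoff_one_removes_everything_nonnative(self):
        cfg = SimConfig(c0=1e-6, k_den=1e-3, k_nuc=0.0, k_grow=0.0,
                        k_stick=0.0, j_pellet=1, t_end=1000.0, n_times=11)
        traj = simulate_trajectory(cfg)
        gamma = trajectory_to_gamma(traj, cfg)
        assert np.allclose(gamma.gamma, traj.N / cfg.c0, atol=1e-9)

    def test_pure_denaturation_with_cutoff_two_never_pellets(self):
        cfg = SimConfig(c0=1e-6, k_den=1e-3, k_nuc=0.0, k_grow=0.0,
                        k_stick=0.0, j_pellet=2, t_end=1000.0, n_times=11)
        gamma = trajectory_to_gamma(simulate_trajectory(cfg), cfg)
        assert np.allclose(gamma.gamma, 1.0, atol=1e-9)


class TestRhRendering:
    def test_monomers_only_single_population_at_R_mono(self):
        cfg = SimConfig(c0=1e-6, k_den=1e-3, k_nuc=0.0, k_grow=0.0,
                        k_stick=0.0, t_end=100.0, n_times=3)
        size = trajectory_to_rh(simulate_trajectory(cfg))
        for pops in size.populations:
            assert len(pops) == 1
            rh, w = pops[0]
            assert rh == pytest.approx(cfg.R_mono_nm, rel=1e-9)
            assert w == pytest.approx(1.0)

    def test_compact_octamer_doubles_radius(self):
        # d_f = 3: Rh(8) = R_mono * 8^(1/3) = 2 R_mono
        cfg = SimConfig(c0=1e-6, d_f=3.0, t_end=9.0, n_times=10)
        traj = simulate_trajectory(cfg)
        traj.N[:] = 0.0
        traj.c[:, :] = 0.0
        traj.c[:, 7] = 1e-8  # c_8
        size = trajectory_to_rh(traj, cfg)
        rh, w = size.populations[0][0]
        assert rh == pytest.approx(2 * cfg.R_mono_nm, rel=1e-9)

    def test_population_weights_sum_to_one(self):
        cfg = make_regime_presets("A", protein_conc=0.4)
        size = trajectory_to_rh(simulate_trajectory(cfg))
        for pops in size.populations:
            assert sum(w for _, w in pops) == pytest.approx(1.0)


class TestRegimeScaling:
    def test_regime_A_gamma_curves_coincide_across_concentration(self):
        gammas = []
        for p in (0.2, 0.4, 0.6):
            cfg = make_regime_presets("A", protein_conc=p)
            gammas.append(trajectory_to_gamma(simulate_trajectory(cfg)).gamma)
        for g in gammas[1:]:
            assert np.max(np.abs(g - gammas[0])) < 0.08

    def test_regime_B_gamma_curves_differ_across_concentration(self):
        gammas = []
        for p in (0.2, 0.6):
            cfg = make_regime_presets("B", protein_conc=p)
            gammas.append(trajectory_to_gamma(simulate_trajectory(cfg)).gamma)
        assert np.max(np.abs(gammas[1] - gammas[0])) > 0.15

    def test_regime_A_early_aggregation_rate_approaches_k_den(self):
        cfg = make_regime_presets("A", protein_conc=0.4)
        gamma = trajectory_to_gamma(simulate_trajectory(cfg))
        # pseudo-first-order: gamma ~ exp(-k t) with k ~ k_den early
        sel = gamma.t * 60.0 <= 1800.0
        fit = fit_first_order(gamma.t[sel] * 60.0, gamma.gamma[sel])
        assert fit.k == pytest.approx(cfg.k_den, rel=0.15)


class TestSyntheticObservables:
    def test_dose_response_round_trip(self):
        L, y = synth_dose_response(np.array([0, 10, 25, 50, 75, 100.0]),
                                   L_half=52.0, h=1.8)
        assert np.allclose(y, eval_hill(L, 52.0, 1.8))
        fit = fit_dose_response(L, y)
        assert fit.L_half == pytest.approx(52.0, rel=1e-6)
        assert fit.h == pytest.approx(1.8, rel=1e-6)

    def test_acf_siegert_intercept_and_hand_value(self):
        tau = np.geomspace(1e-7, 1e-1, 100)
        acf = synth_acf([(100.0, 1.0)], q=1.868e7, beta=0.8, tau_grid=tau)
        assert acf.g2[0] == pytest.approx(1.8, abs=1e-3)
        # at tau = 1/Gamma the single-mode g2 is 1 + beta e^-2
        from aggkinetics import stokes_einstein_d
        Gamma = float(stokes_einstein_d(100e-9, acf.T, acf.eta)) * acf.q**2
        g2_at = 1 + 0.8 * np.exp(-2.0)
        acf2 = synth_acf([(100.0, 1.0)], q=1.868e7, beta=0.8,
                         tau_grid=np.geomspace(1e-9, 1.0 / Gamma, 20))
        assert acf2.g2[-1] == pytest.approx(g2_at, rel=1e-9)

    def test_acf_weights_must_normalize(self):
        with pytest.raises(ValueError):
            synth_acf([(100.0, 0.4), (10.0, 0.4)], q=1.868e7, beta=0.9,
                      tau_grid=np.geomspace(1e-6, 1e-2, 30))

    def test_dsc_peak_area_and_argmax(self):
        T = np.linspace(40, 80, 401)
        trace = synth_dsc(T, Tmax=61.9, dH=2090.0, width=4.0)
        assert T[np.argmax(trace.signal)] == pytest.approx(61.9, abs=0.1)
        area = np.trapezoid(trace.signal, T)
        assert area == pytest.approx(2090.0, rel=0.01)
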