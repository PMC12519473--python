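"""Compartmental RTM: bioavailability, ODE assembly, integration,
conservation, equilibrium closed forms and regime-limit agreement."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pcbrtm.congener_registry import Congener
from pcbrtm.particle_diffusion import ParticleGrid, particle_capacity_l
from pcbrtm.rtm_core import (
    IntegrationError,
    MicrocosmConfig,
    RTMParams,
    RTMState,
    assemble_nonshaken_system,
    assemble_shaken_system,
    assemble_system,
    bioavailability_factor,
    equilibrium_state,
    initial_state_from_sediment,
    load_microcosm_config,
    load_rtm_params,
    n_particles_for_sediment_mass,
    simulate,
    total_mass,
)
from pcbrtm.samplers import PufSpec, SpmeSpec


class TestBioavailability:
    def test_no_cells_fully_available(self):
        assert bioavailability_factor(123.0, 0.0) == 1.0

    def test_symmetric_point(self):
        assert bioavailability_factor(1.0, 1.0) == 0.5

    def test_hand_value(self):
        assert bioavailability_factor(4.0, 1.0) == pytest.approx(0.2)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bioavailability_factor(-1.0, 0.5)

    @given(st.floats(0, 1e3), st.floats(0, 10))
    def test_in_unit_interval(self, k_cell, x):
        b = bioavailability_factor(k_cell, x)
        assert 0 < b <= 1


class TestAssembly:
    def test_regime_dispatch_errors(self, shaken_cfg, nonshaken_cfg,
                                    base_params, pcb4):
        with pytest.raises(ValueError, match="nonshaken"):
            assemble_shaken_system(nonshaken_cfg, base_params, pcb4)
        with pytest.raises(ValueError, match="shaken"):
            assemble_nonshaken_system(shaken_cfg, base_params, pcb4)

    def test_inert_system_is_stationary(self, shaken_cfg, inert_params, pcb4):
        system = assemble_shaken_system(shaken_cfg, inert_params, pcb4)
        y = system.pack(RTMState(s_fast=5.0, s_slow=3.0, c_w=10.0, c_a=2.0,
                                 m_puf=1.0, m_spme=0.2))
        # residuals bounded by the 1e-12 sampler rates used to switch
        # the (strictly positive) sampler kinetics off
        assert np.allclose(system(0.0, y), 0.0, atol=1e-9)

    def test_nonshaken_zero_rates_steady(self, nonshaken_cfg, inert_params,
                                         pcb4):
        grid = replace(inert_params.particle, n_particles_equiv=1e6)
        p = replace(inert_params, particle=grid)
        system = assemble_nonshaken_system(nonshaken_cfg, p, pcb4)
        # uniform concentration everywhere: no gradients, no fluxes
        y = system.pack(RTMState(c_shell=np.full(grid.n_shells, 4.0),
                                 c_pw=4.0, c_w=4.0))
        dy = system(0.0, y)
        assert np.allclose(dy, 0.0, atol=1e-12)


class TestSimulate:
    def test_inert_trajectory_constant(self, shaken_cfg, inert_params, pcb4):
        system = assemble_shaken_system(shaken_cfg, inert_params, pcb4)
        y0 = RTMState(s_fast=6.0, s_slow=4.0, c_w=100.0)
        traj = simulate(system, y0, np.linspace(1, 75, 10))
        assert np.allclose(traj.series("c_w"), 100.0, rtol=1e-9)
        assert np.allclose(traj.series("s_fast"), 6.0, rtol=1e-9)

    def test_pure_decay_half_life(self, shaken_cfg, decay_params, pcb4):
        k = decay_params.k_bio
        system = assemble_shaken_system(shaken_cfg, decay_params, pcb4)
        t_half = np.log(2) / k
        traj = simulate(system, RTMState(c_w=80.0), [t_half, 2 * t_half],
                        tol=1e-10)
        assert traj.series("c_w")[0] == pytest.approx(40.0, rel=1e-6)
        assert traj.series("c_w")[1] == pytest.approx(20.0, rel=1e-6)
        # the degraded mass shows up in the sink compartment
        assert traj.series("m_degraded")[1] == pytest.approx(
            60.0 * shaken_cfg.v_w, rel=1e-6
        )

    def test_stiff_case_matches_fine_step_rk4(self, shaken_cfg, pcb4):
        """LSODA vs a brute-force fixed-step RK4 oracle (dt = 1e-5 d) on a
        stiff configuration (k_fast = 1000/d, k_bio = 17/d)."""
        p = RTMParams(k_fast=1000.0, k_slow=0.01, k_bio=17.0)
        system = assemble_shaken_system(shaken_cfg, p, pcb4)
        y0 = system.pack(initial_state_from_sediment(shaken_cfg, p, 100.0))
        dt, t_end = 1e-5, 0.1
        y = y0.copy()
        for _ in range(int(round(t_end / dt))):
            k1 = system(0, y)
            k2 = system(0, y + dt / 2 * k1)
            k3 = system(0, y + dt / 2 * k2)
            k4 = system(0, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        traj = simulate(system, system.unpack(y0), [t_end], tol=1e-10)
        got = traj.states[-1]
        ref = system.unpack(y)
        for name in ("s_fast", "s_slow", "c_w", "c_a", "m_degraded"):
            assert getattr(got, name) == pytest.approx(
                getattr(ref, name), rel=1e-5, abs=1e-12
            )

    def test_bad_times_rejected(self, shaken_cfg, inert_params, pcb4):
        system = assemble_shaken_system(shaken_cfg, inert_params, pcb4)
        with pytest.raises(ValueError):
            simulate(system, RTMState(), [2.0, 1.0])
        with pytest.raises(ValueError):
            simulate(system, RTMState(c_w=-1.0), [1.0])

    def test_states_nonnegative_after_strong_decay(self, shaken_cfg, pcb4):
        p = RTMParams(k_bio=17.0)
        system = assemble_shaken_system(shaken_cfg, p, pcb4)
        y0 = initial_state_from_sediment(shaken_cfg, p, 500.0)
        traj = simulate(system, y0, np.linspace(1, 35, 12))
        for s in traj.states:
            for name in ("s_fast", "s_slow", "c_w", "c_a", "m_puf", "m_spme"):
                assert getattr(s, name) >= 0.0


class TestConservation:
    @pytest.mark.parametrize("regime", ["shaken", "nonshaken"])
    @pytest.mark.parametrize("k_bio", [0.0, 0.6])
    def test_total_mass_constant(self, regime, k_bio, pcb4):
        cfg = MicrocosmConfig(regime=regime, x_cells=0.25)
        grid = ParticleGrid(n_shells=10)
        grid = replace(grid,
                       n_particles_equiv=n_particles_for_sediment_mass(grid, cfg.m_sed))
        p = RTMParams(k_bio=k_bio, k_cell=8.0, particle=grid)
        system = assemble_system(cfg, p, pcb4)
        y0 = initial_state_from_sediment(cfg, p, 1800.0)
        m0 = total_mass(y0, cfg, p)
        tol = 1e-8
        traj = simulate(system, y0, np.linspace(1, 75, 20), tol=tol)
        for s in traj.states:
            assert abs(total_mass(s, cfg, p) - m0) <= 10 * tol * m0

    def test_zero_state_zero_mass(self, shaken_cfg, base_params):
        assert total_mass(RTMState(), shaken_cfg, base_params) == 0.0

    def test_initial_state_reproduces_inventory(self, pcb4):
        for regime in ("shaken", "nonshaken"):
            cfg = MicrocosmConfig(regime=regime)
            grid = ParticleGrid(n_shells=8)
            grid = replace(grid,
                           n_particles_equiv=n_particles_for_sediment_mass(grid, cfg.m_sed))
            p = RTMParams(particle=grid)
            y0 = initial_state_from_sediment(cfg, p, 1800.0)
            assert total_mass(y0, cfg, p) == pytest.approx(18000.0, rel=1e-12)


class TestEquilibrium:
    def test_all_mass_dissolved_when_no_other_capacity(self, shaken_cfg):
        c = Congener("X", 2, log_kow=4.0, k_h=1e-12, k_d=0.0, mw=200.0)
        p = RTMParams(puf=PufSpec(k_puf_a=1e-12),
                      spme=SpmeSpec(k_fw=1e-12, v_coat_per_cm=1e-12))
        eq = equilibrium_state(shaken_cfg, p, c, 50.0)
        assert eq.c_w == pytest.approx(50.0 / shaken_cfg.v_w, rel=1e-9)

    def test_half_mass_in_air_by_symmetry(self):
        cfg = MicrocosmConfig(v_a=0.1, v_w=0.1)
        c = Congener("X", 2, log_kow=4.0, k_h=1.0, k_d=0.0, mw=200.0)
        p = RTMParams(puf=PufSpec(k_puf_a=1e-12),
                      spme=SpmeSpec(k_fw=1e-12, v_coat_per_cm=1e-12))
        eq = equilibrium_state(cfg, p, c, 10.0)
        assert eq.c_a * cfg.v_a == pytest.approx(5.0, rel=1e-9)

    def test_total_mass_exact_by_construction(self, pcb4):
        for regime in ("shaken", "nonshaken"):
            cfg = MicrocosmConfig(regime=regime, x_cells=0.25)
            grid = replace(ParticleGrid(n_shells=6), n_particles_equiv=1e7)
            p = RTMParams(k_cell=8.0, particle=grid)
            eq = equilibrium_state(cfg, p, pcb4, 1234.5)
            assert total_mass(eq, cfg, p) == pytest.approx(1234.5, rel=1e-12)

    def test_requires_no_degradation(self, shaken_cfg, pcb4):
        with pytest.raises(ValueError):
            equilibrium_state(shaken_cfg, RTMParams(k_bio=1.0), pcb4, 1.0)

    @pytest.mark.parametrize("regime", ["shaken", "nonshaken"])
    def test_long_horizon_integration_reaches_closed_form(self, regime, pcb4):
        """Every phase of the t -> infinity trajectory matches the
        closed-form equilibrium within 0.1%."""
        cfg = MicrocosmConfig(regime=regime, x_cells=0.25)
        grid = ParticleGrid(n_shells=8)
        grid = replace(grid,
                       n_particles_equiv=n_particles_for_sediment_mass(grid, cfg.m_sed))
        # modest PUF capacity so equilibration is reachable quickly
        p = RTMParams(k_cell=8.0, particle=grid, puf=PufSpec(k_puf_a=100.0))
        system = assemble_system(cfg, p, pcb4)
        y0 = initial_state_from_sediment(cfg, p, 1800.0)
        eq = equilibrium_state(cfg, p, pcb4, total_mass(y0, cfg, p))
        traj = simulate(system, y0, [5e4, 1e5], tol=1e-10)
        final = traj.states[-1]
        for name in ("c_w", "c_a", "m_puf", "m_spme"):
            assert getattr(final, name) == pytest.approx(
                getattr(eq, name), rel=1e-3
            )
        if regime == "shaken":
            assert final.s_fast == pytest.approx(eq.s_fast, rel=1e-3)
            assert final.s_slow == pytest.approx(eq.s_slow, rel=1e-3)
        else:
            assert final.c_pw == pytest.approx(eq.c_pw, rel=1e-3)


class TestStructuralProperties:
    def test_puf_day35_nonincreasing_in_k_bio(self, shaken_cfg, pcb4):
        masses = []
        for k_bio in (0.0, 0.5, 2.0, 17.0):
            p = RTMParams(k_bio=k_bio)
            system = assemble_shaken_system(shaken_cfg, p, pcb4)
            y0 = initial_state_from_sediment(shaken_cfg, p, 1800.0)
            traj = simulate(system, y0, [35.0])
            masses.append(traj.series("m_puf")[0])
        assert all(a >= b for a, b in zip(masses, masses[1:]))

    def test_inactive_cells_reproduce_control(self, pcb4):
        """k_cell = 0 and k_bio = 0 make the cell dose invisible: the
        treatment trajectory equals the control trajectory exactly."""
        p = RTMParams(k_cell=0.0, k_bio=0.0)
        times = np.linspace(1, 35, 8)
        trajs = []
        for x_cells in (0.0, 0.25):
            cfg = MicrocosmConfig(x_cells=x_cells)
            system = assemble_shaken_system(cfg, p, pcb4)
            y0 = initial_state_from_sediment(cfg, p, 1800.0)
            trajs.append(simulate(system, y0, times))
        for name in ("c_w", "c_a", "m_puf", "m_spme"):
            assert np.array_equal(trajs[0].series(name), trajs[1].series(name))

    def test_pool_split_symmetry_when_rates_equal(self, shaken_cfg, pcb4):
        """With k_fast = k_slow the fast/slow split is unobservable."""
        times = np.linspace(1, 35, 8)
        results = []
        for f_fast in (0.2, 0.8):
            p = RTMParams(k_fast=0.3, k_slow=0.3, f_fast=f_fast)
            system = assemble_shaken_system(shaken_cfg, p, pcb4)
            y0 = initial_state_from_sediment(shaken_cfg, p, 1800.0)
            traj = simulate(system, y0, times, tol=1e-10)
            results.append(
                (traj.series("c_w"), traj.series("m_puf"),
                 traj.series("s_fast") + traj.series("s_slow"))
            )
        for a, b in zip(*results):
            assert np.allclose(a, b, rtol=1e-7)

    def test_zero_boundary_layer_decouples_bed(self, nonshaken_cfg, pcb4):
        grid = replace(ParticleGrid(n_shells=8), n_particles_equiv=1e7)
        p = RTMParams(k_bl=0.0, particle=grid)
        system = assemble_nonshaken_system(nonshaken_cfg, p, pcb4)
        y0 = initial_state_from_sediment(nonshaken_cfg, p, 1800.0)
        traj = simulate(system, y0, np.linspace(1, 40, 6))
        bed_masses = [
            total_mass(s, nonshaken_cfg, p)
            - (s.c_w * nonshaken_cfg.v_w + s.c_a * nonshaken_cfg.v_a
               + s.m_puf + s.m_spme * p.spme.fiber_length_total
               + s.m_degraded + s.c_pw * nonshaken_cfg.v_pw)
            for s in traj.states
        ]
        assert np.allclose(bed_masses, bed_masses[0], rtol=1e-9)
        # water/air side saw nothing
        assert np.allclose(traj.series("c_w"), 0.0, atol=1e-12)

    def test_two_box_boundary_layer_relaxation(self, nonshaken_cfg, pcb4):
        """Bed switched off (no particles): porewater and overlying water
        relax as a closed two-box exponential."""
        grid = replace(ParticleGrid(n_shells=3), n_particles_equiv=0.0)
        p = RTMParams(
            k_bl=0.5, a_int=40.0, v_aw=0.0, particle=grid,
            puf=PufSpec(k_puf=1e-12), spme=SpmeSpec(k_sp=1e-12, k_fw=1e-12),
        )
        system = assemble_nonshaken_system(nonshaken_cfg, p, pcb4)
        c0 = 1000.0
        y0 = RTMState(c_shell=np.zeros(3), c_pw=c0)
        times = np.linspace(0.005, 0.6, 14)
        traj = simulate(system, y0, times, tol=1e-10)
        g = p.k_bl * p.a_int / 1000.0
        v_pw, v_w = nonshaken_cfg.v_pw, nonshaken_cfg.v_w
        rate = g * (1 / v_pw + 1 / v_w)
        c_eq = c0 * v_pw / (v_pw + v_w)
        expected_cw = c_eq * (1 - np.exp(-rate * times))
        assert np.allclose(traj.series("c_w"), expected_cw, rtol=1e-5)
        assert np.all(np.diff(traj.series("c_w")) > 0)

    def test_nonshaken_equilibrium_agrees_with_shaken_when_capacities_match(
        self, pcb4
    ):
        """With the bed's sorption capacity matched to the shaken two-site
        capacity, both regimes share the same closed-form partitioning."""
        cfg_s = MicrocosmConfig(regime="shaken")
        p_s = RTMParams()
        target_cap = cfg_s.m_sed * p_s.f_avail * pcb4.k_d / 1000.0
        grid = ParticleGrid(n_shells=6)
        n_eq = target_cap / particle_capacity_l(grid)
        cfg_ns = MicrocosmConfig(regime="nonshaken", v_pw=1e-9)
        p_ns = RTMParams(particle=replace(grid, n_particles_equiv=n_eq))
        eq_s = equilibrium_state(cfg_s, p_s, pcb4, 18000.0)
        eq_ns = equilibrium_state(cfg_ns, p_ns, pcb4, 18000.0)
        assert eq_ns.c_w == pytest.approx(eq_s.c_w, rel=1e-6)
        assert eq_ns.c_a == pytest.approx(eq_s.c_a, rel=1e-6)
        assert eq_ns.m_puf == pytest.approx(eq_s.m_puf, rel=1e-6)


class TestConfigIO:
    def test_microcosm_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "m_sed: 10.0\nv_w: 0.1\nv_a: 0.15\nregime: nonshaken\n"
            "x_cells: 0.25\n"
        )
        cfg = load_microcosm_config(path)
        assert cfg.regime == "nonshaken"
        assert cfg.x_cells == 0.25

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("m_sed: 10.0\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            load_microcosm_config(path)

    def test_params_with_nested_blocks(self, tmp_path):
        path = tmp_path / "p.yaml"
        path.write_text(
            "k_bio: 0.6\nalpha_fiber: 0.15\n"
            "particle: {n_shells: 8, radius: 0.005}\n"
            "puf: {k_puf: 50.0}\nspme: {k_sp: 2.0}\n"
        )
        p = load_rtm_params(path)
        assert p.k_bio == 0.6
        assert p.particle.n_shells == 8
        assert p.puf.k_puf == 50.0
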