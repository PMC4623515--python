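"""Solver contracts: membrane fluxes, mass bookkeeping, oracle agreement,
steady-state solvers, pulses and symmetry."""

from __future__ import annotations

import numpy as np
import pytest

from rootflux.dynamics import (
    InstabilityError,
    Pulse,
    SimulationParams,
    Simulator,
    membrane_flux_auxin,
    membrane_flux_cytokinin,
)
from rootflux.geometry import rasterize
from rootflux.layouts import condition_layout, wildtype_layout


@pytest.fixture()
def two_cell_sim(two_cell_fixture):
    tpl, lay = two_cell_fixture
    grid = rasterize(tpl, dx=0.5, wall_thickness=1.0)
    return Simulator(grid, lay, SimulationParams())


class TestMembraneFlux:
    def test_background_only(self):
        p = SimulationParams()
        j = membrane_flux_auxin(2.0, 3.0, {}, {}, p)
        assert j == pytest.approx(-p.P_e_bg * 2.0 + p.P_i_bg * 3.0)

    def test_pin_replaces_background_efflux(self):
        p = SimulationParams()
        j = membrane_flux_auxin(2.0, 3.0, {"PIN1": 1.0}, {"PIN1": 0.5}, p)
        assert j == pytest.approx(-0.5 * p.P_e_PIN * 2.0 + p.P_i_bg * 3.0)

    def test_importer_adds_to_background_influx(self):
        p = SimulationParams()
        j = membrane_flux_auxin(0.0, 1.0, {"importer": 1.0}, {"importer": 1.0}, p)
        assert j == pytest.approx(p.P_i_bg + p.P_i_AUX)

    def test_optional_additive_leak_on_pin_faces(self):
        p = SimulationParams(add_bg_efflux_on_pin_faces=True)
        j = membrane_flux_auxin(1.0, 0.0, {"PIN1": 1.0}, {"PIN1": 1.0}, p)
        assert j == pytest.approx(-(p.P_e_PIN + p.P_e_bg))

    def test_cytokinin_symmetric(self):
        assert membrane_flux_cytokinin(2.0, 5.0, 0.01) == pytest.approx(0.03)
        with pytest.raises(ValueError):
            membrane_flux_cytokinin(1.0, 1.0, -0.1)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            membrane_flux_auxin(-1.0, 0.0, {}, {}, SimulationParams())


class TestMassBookkeeping:
    def rand_state(self, sim, seed=0):
        rng = np.random.default_rng(seed)
        st = sim.initial_state()
        st.auxin = np.where(sim.inside, rng.uniform(1.0, 2.0, sim.grid.shape), 0.0)
        st.cytokinin = np.where(sim.inside, rng.uniform(0.5, 1.5, sim.grid.shape), 0.0)
        return st

    def test_diffusion_conserves_mass(self, two_cell_sim):
        sim = two_cell_sim
        st = self.rand_state(sim)
        sim.update_activities(st)
        m0 = sim.total_mass(st)
        for _ in range(10):
            sim.diffusion_step(st)
        m1 = sim.total_mass(st)
        assert m1[0] == pytest.approx(m0[0], rel=1e-12)
        assert m1[1] == pytest.approx(m0[1], rel=1e-12)

    def test_reaction_mass_identity(self, two_cell_sim):
        sim = two_cell_sim
        p = sim.params
        st = self.rand_state(sim, seed=1)
        m = sim.cell_mask
        n_pts = int(m.sum())
        exp_da = p.dt * (p.b_auxin * n_pts - p.delta_auxin * st.auxin[m].sum())
        exp_dc = p.dt * (p.b_cyt * n_pts - p.delta_cyt * st.cytokinin[m].sum())
        a0, c0 = sim.total_mass(st)
        sim.reaction_step(st)
        a1, c1 = sim.total_mass(st)
        assert a1 - a0 == pytest.approx(exp_da, rel=1e-12)
        assert c1 - c0 == pytest.approx(exp_dc, rel=1e-12)

    def test_full_step_mass_budget(self, two_cell_sim):
        """Per step, d(total)/dt equals production minus decay exactly."""
        sim = two_cell_sim
        p = sim.params
        st = self.rand_state(sim, seed=2)
        m = sim.cell_mask
        for _ in range(5):
            exp = p.dt * (p.b_auxin * m.sum() - p.delta_auxin * st.auxin[m].sum())
            a0 = sim.total_mass(st)[0]
            sim.step(st)
            assert sim.total_mass(st)[0] - a0 == pytest.approx(exp, rel=1e-10)


class TestSteadyStates:
    def test_uniform_cytokinin_b_over_delta(self, tiny_fixture):
        tpl, lay = tiny_fixture
        grid = rasterize(tpl, dx=0.5, wall_thickness=1.0)
        sim = Simulator(grid, lay, SimulationParams())
        st, rep = sim.run_to_steady_state(method="direct")
        assert rep.converged
        target = sim.params.b_cyt / sim.params.delta_cyt
        assert np.allclose(st.cytokinin[sim.inside], target, rtol=1e-6)

    def test_direct_matches_adi(self, two_cell_fixture):
        tpl, lay = two_cell_fixture
        grid = rasterize(tpl, dx=0.5, wall_thickness=1.0)
        # faster metabolism so the ADI path reaches steady state quickly
        p = SimulationParams(b_auxin=0.01, delta_auxin=0.01, b_cyt=0.01, delta_cyt=0.01)
        s_adi, rep_adi = Simulator(grid, lay, p).run_to_steady_state(method="adi")
        s_dir, rep_dir = Simulator(grid, lay, p).run_to_steady_state(method="direct")
        assert rep_adi.converged and rep_dir.converged
        ins = grid.inside_mask
        assert np.allclose(s_adi.auxin[ins], s_dir.auxin[ins], rtol=1e-4)
        assert np.allclose(s_adi.cytokinin[ins], s_dir.cytokinin[ins], rtol=1e-4)

    def test_explicit_euler_oracle(self, two_cell_fixture):
        """ADI transient agrees with a fully explicit reference to <= 0.5%."""
        tpl, lay = two_cell_fixture
        grid = rasterize(tpl, dx=0.5, wall_thickness=1.0)
        T = 0.5
        sim_a = Simulator(grid, lay, SimulationParams(dt=0.01))
        st_a = sim_a.initial_state()
        while st_a.t < T - 1e-9:
            sim_a.step(st_a)
        sim_e = Simulator(grid, lay, SimulationParams())
        st_e = sim_e.initial_state()
        dte = 2e-5
        for _ in range(int(round(T / dte))):
            st_e = sim_e.explicit_euler_step(st_e, dte)
        ins = grid.inside_mask
        scale = np.abs(st_e.auxin[ins]).max()
        assert np.abs(st_a.auxin[ins] - st_e.auxin[ins]).max() <= 0.005 * scale

    def test_symmetric_template_symmetric_steady_state(self, mini_grid):
        sim = Simulator(mini_grid, wildtype_layout(), SimulationParams(), static=True)
        st, rep = sim.run_to_steady_state(method="direct")
        assert rep.converged
        for fld in (st.auxin, st.cytokinin):
            ref = np.abs(fld).max()
            assert np.abs(fld - np.flip(fld, axis=0)).max() < 1e-6 * ref
            assert np.abs(fld - np.flip(fld, axis=1)).max() < 1e-6 * ref


class TestPulsesAndErrors:
    def test_pulse_clamps_activity(self, two_cell_fixture):
        tpl, lay = two_cell_fixture
        grid = rasterize(tpl, dx=0.5, wall_thickness=1.0)
        pulse = Pulse(cell_id=2, start=0.2, duration=0.5, transporter="importer", value=0.25)
        sim = Simulator(grid, lay, SimulationParams(), schedule=[pulse])
        st = sim.initial_state()
        k = sim.bound.kind_index("importer")
        c = sim.bound.cell_index[2]
        seen = {}
        for _ in range(12):
            t_at_update = st.t
            sim.step(st)
            seen[round(t_at_update, 1)] = float(st.activities[k, c])
        assert seen[0.0] == 1.0  # before the pulse window
        assert seen[0.4] == 0.25  # clamped
        assert seen[1.0] == 1.0  # released

    def test_unknown_schedule_cell_raises(self, two_cell_fixture):
        tpl, lay = two_cell_fixture
        grid = rasterize(tpl, dx=0.5, wall_thickness=1.0)
        with pytest.raises(ValueError):
            Simulator(grid, lay, schedule=[Pulse(cell_id=99, start=0.0, duration=1.0)])

    def test_reaction_instability_detected(self, two_cell_fixture):
        tpl, lay = two_cell_fixture
        grid = rasterize(tpl, dx=0.5, wall_thickness=1.0)
        sim = Simulator(grid, lay, SimulationParams(dt=1.0, delta_auxin=3.0))
        st = sim.initial_state()
        with pytest.raises(InstabilityError):
            for _ in range(5):
                sim.step(st)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SimulationParams(dt=0.0)
        with pytest.raises(ValueError):
            SimulationParams(D_auxin=-1.0)
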