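import numpy as np
import pytest

from mpetsim import (Dirichlet, ModelError, MPETState, SolverError,
                     TransferModel, advance_step, apply_boundary_conditions,
                     assemble_system, load_parameters, solve_steady,
                     solve_transient, transfer_rate, transfer_source_fields,
                     effective_permeability)
from mpetsim.geometry import TERRITORIES, generate_box_mesh
from mpetsim.waveforms import synthesize_inflow, territory_fluxes


class TestTransferModel:
    def test_rate_is_omega_times_pressure_difference(self, transfer_model):
        # omega_ev = 1e-13 m^2/N/s at a 100 Pa difference
        r = transfer_rate(("e", "v"), 750.0, 650.0, transfer_model)
        assert r == pytest.approx(1.0e-11)

    def test_equilibrium_gives_zero(self, transfer_model):
        assert transfer_rate(("c", "e"), 650.0, 650.0, transfer_model) == 0.0

    def test_antisymmetry(self, transfer_model):
        fwd = transfer_rate(("a", "c"), 800.0, 700.0, transfer_model)
        rev = transfer_rate(("c", "a"), 700.0, 800.0, transfer_model)
        assert fwd == -rev

    def test_arterial_csf_path_prohibited(self, transfer_model):
        with pytest.raises(ModelError):
            transfer_rate(("a", "e"), 800.0, 650.0, transfer_model)

    def test_source_fields_sum_to_zero_pointwise(self, transfer_model):
        rng = np.random.default_rng(0)
        p = {n: rng.normal(650.0, 50.0, size=40) for n in "acev"}
        src = transfer_source_fields(p, transfer_model)
        total = sum(src.values())
        assert np.abs(total).max() < 1e-24


class TestAssembly:
    def test_block_dimensions(self, coarse_shell, params, transfer_model):
        keff = effective_permeability(params, None, coarse_shell)
        sys_ = assemble_system(coarse_shell, params, keff, transfer_model,
                               dt=0.01)
        n = coarse_shell.n_nodes
        assert sys_.ndof == 7 * n    # 3 displacement + 4 pressures
        assert sys_.E.shape == (3 * n, 3 * n)
        assert sys_.B.shape == (n, 3 * n)

    def test_darcy_block_linear_in_permeability(self, coarse_shell, params,
                                                transfer_model):
        k1 = effective_permeability(params, None, coarse_shell)
        k2 = {n: (2.0 * v if n == "e" else v) for n, v in k1.items()}
        s1 = assemble_system(coarse_shell, params, k1, transfer_model, 0.01)
        s2 = assemble_system(coarse_shell, params, k2, transfer_model, 0.01)
        assert np.allclose((s2.K["e"] - 2.0 * s1.K["e"]).data, 0.0)
        assert np.allclose((s2.K["v"] - s1.K["v"]).data, 0.0)

    def test_zero_omega_removes_pressure_coupling(self, coarse_shell,
                                                  params, brain_fluxes):
        p0 = load_parameters({"omega": {k: 0.0 for k in params.omega}})
        keff = effective_permeability(p0, None, coarse_shell)
        tm = TransferModel.from_parameters(p0)
        fx = {t: brain_fluxes[t] for t in TERRITORIES}
        sys_ = assemble_system(coarse_shell, p0, keff, tm, dt=0.01)
        apply_boundary_conditions(sys_, coarse_shell, p0, fx)
        A = sys_.A_full.tocsr()
        pa = sys_.dofmap_p("a")
        pc = sys_.dofmap_p("c")
        assert abs(A[pa][:, pc]).max() == 0.0

    def test_missing_permeability_rejected(self, coarse_shell, params,
                                           transfer_model):
        keff = effective_permeability(params, None, coarse_shell)
        del keff["v"]
        with pytest.raises(ModelError):
            assemble_system(coarse_shell, params, keff, transfer_model, 0.01)


class TestBrainBCs:
    def test_cortical_displacement_rows_are_dirichlet(self, coarse_shell,
                                                      params, transfer_model,
                                                      brain_fluxes):
        keff = effective_permeability(params, None, coarse_shell)
        sys_ = assemble_system(coarse_shell, params, keff, transfer_model,
                               dt=0.01)
        apply_boundary_conditions(sys_, coarse_shell, params, brain_fluxes)
        cort = np.unique(coarse_shell.boundary_facets[
            coarse_shell.facet_tag == 1])
        for c in range(3):
            assert (sys_._kind[cort * sys_.n_fields + c] == 1).all()

    def test_venous_rows_fixed_to_back_pressure(self, coarse_shell, params,
                                                transfer_model,
                                                brain_fluxes):
        keff = effective_permeability(params, None, coarse_shell)
        sys_ = assemble_system(coarse_shell, params, keff, transfer_model,
                               dt=0.01)
        apply_boundary_conditions(sys_, coarse_shell, params, brain_fluxes)
        bnd = np.unique(coarse_shell.boundary_facets)
        dofs = bnd * sys_.n_fields + 3 + sys_.networks.index("v")
        assert (sys_._kind[dofs] == 1).all()
        st = sys_.default_initial_state()
        st = advance_step(sys_, st)
        assert np.allclose(st.p["v"][bnd], 650.0)

    def test_zero_inflow_zero_production_is_equilibrium(self, coarse_shell):
        # equilibrium is transfer-coefficient independent; solve with
        # coefficients inside the float64-conditioned range
        p0 = load_parameters(
            {"Q_p": 0.0,
             "omega": {"ac": 1e-10, "cv": 1e-10, "ce": 1e-12, "ev": 1e-10}})
        transfer_model = TransferModel.from_parameters(p0)
        keff = effective_permeability(p0, None, coarse_shell)
        waves = []
        for t in TERRITORIES:
            w = synthesize_inflow(1.0, mean_to_peak=1.0, territory=t)
            w.flows[:] = 0.0
            waves.append(w)
        fx = territory_fluxes(waves, coarse_shell)
        sys_ = assemble_system(coarse_shell, p0, keff, transfer_model,
                               dt=None)
        apply_boundary_conditions(sys_, coarse_shell, p0, fx)
        st = solve_steady(sys_)
        for n in "acev":
            assert np.abs(st.p[n] - 650.0).max() < 1e-9
        assert np.abs(st.u).max() < 1e-12
        assert st.aux["p_vent"] == pytest.approx(650.0)

    def test_missing_territory_flux_rejected(self, coarse_shell, params,
                                             transfer_model, brain_fluxes):
        keff = effective_permeability(params, None, coarse_shell)
        sys_ = assemble_system(coarse_shell, params, keff, transfer_model,
                               dt=0.01)
        fx = dict(brain_fluxes)
        del fx["VA_R"]
        with pytest.raises(ModelError, match="VA_R"):
            apply_boundary_conditions(sys_, coarse_shell, params, fx)


class TestTimeStepping:
    def test_steady_state_is_a_fixed_point(self, coarse_shell,
                                           steady_fluxes):
        # transfer coefficients in the float64-solvable range so the
        # steady solve itself is flux-accurate (see methods note)
        p = load_parameters(
            {"omega": {"ac": 1e-10, "cv": 1e-10, "ce": 1e-12, "ev": 1e-10}})
        keff = effective_permeability(p, None, coarse_shell)
        tm = TransferModel.from_parameters(p)
        s_steady = assemble_system(coarse_shell, p, keff, tm, dt=None)
        apply_boundary_conditions(s_steady, coarse_shell, p, steady_fluxes)
        st = solve_steady(s_steady)
        s_tr = assemble_system(coarse_shell, p, keff, tm, dt=0.05)
        apply_boundary_conditions(s_tr, coarse_shell, p, steady_fluxes)
        st2 = advance_step(s_tr, st)
        # relative to the spatial variation, the state must not move
        for n in "acev":
            scale = max(np.abs(st.p[n] - 650).max(), 1.0)
            assert np.abs(st2.p[n] - st.p[n]).max() / scale < 1e-6

    def test_transient_driver_runs_and_records(self, coarse_shell, params,
                                               transfer_model,
                                               brain_fluxes):
        keff = effective_permeability(params, None, coarse_shell)
        states, _ = solve_transient(coarse_shell, params, keff,
                                    transfer_model, brain_fluxes,
                                    t_end=0.1, dt=0.01)
        assert len(states) == 10
        for st in states:
            assert np.isfinite(st.u).all()
            for n in "acev":
                assert np.isfinite(st.p[n]).all()

    def test_bitwise_determinism(self, coarse_shell, params, transfer_model,
                                 brain_fluxes):
        keff = effective_permeability(params, None, coarse_shell)
        a, _ = solve_transient(coarse_shell, params, keff, transfer_model,
                               brain_fluxes, t_end=0.05, dt=0.01)
        b, _ = solve_transient(coarse_shell, params, keff, transfer_model,
                               brain_fluxes, t_end=0.05, dt=0.01)
        assert np.array_equal(a[-1].u, b[-1].u)
        for n in "acev":
            assert np.array_equal(a[-1].p[n], b[-1].p[n])

    def test_periodic_forcing_approaches_limit_cycle(self, coarse_shell,
                                                     params, transfer_model):
        keff = effective_permeability(params, None, coarse_shell)
        waves = [synthesize_inflow(300.0, territory=t, n_cycles=4,
                                   period=0.5)
                 for t in TERRITORIES]
        fx = territory_fluxes(waves, coarse_shell)
        states, _ = solve_transient(coarse_shell, params, keff,
                                    transfer_model, fx, t_end=2.0, dt=0.025)
        icp = np.array([s.p["e"].max() for s in states]).reshape(4, -1)
        peaks = icp.max(axis=1)
        deltas = np.abs(np.diff(peaks))
        assert deltas[-1] < deltas[0]

    def test_singular_configuration_raises(self):
        mesh = generate_box_mesh(2, 2, 2, 1, 1, 1)
        setup_params = load_parameters(
            {"omega": {"ac": 0.0, "cv": 0.0, "ce": 0.0, "ev": 0.0}})
        keff = effective_permeability(setup_params, None, mesh)
        tm = TransferModel.from_parameters(setup_params)
        sys_ = assemble_system(mesh, setup_params, keff, tm, dt=None,
                               networks=("e",), p_ref=0.0)
        # no Dirichlet anywhere, no transfer: pure-Neumann singular system
        sys_.apply_bcs([Dirichlet("u", np.arange(mesh.n_nodes), 0.0)])
        with pytest.raises(SolverError):
            solve_steady(sys_)
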