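import numpy as np
import pytest

from mpetsim import (MMHG, MPETState, derive_fields, darcy_velocity,
                     effective_permeability, export_fields,
                     fluid_content_increment, peak_summary, region_range,
                     synthesize_ptm)
from mpetsim.geometry import read_mesh


def make_state(mesh, p_fields, u=None, t=0.0):
    n = mesh.n_nodes
    return MPETState(np.zeros((n, 3)) if u is None else u,
                     p_fields, {}, t)


class TestDarcyVelocity:
    def test_uniform_pressure_gives_zero(self, shell_mesh, params, keff):
        st = make_state(shell_mesh,
                        {n: np.full(shell_mesh.n_nodes, 650.0)
                         for n in "acev"})
        v = darcy_velocity(st, keff, shell_mesh, params)
        # constant field: gradient vanishes up to float associativity
        for n in "acev":
            assert np.abs(v[n]).max() < 1e-15

    def test_linear_pressure_closed_form(self, shell_mesh, params, keff):
        g = np.array([1.0e4, -2.0e3, 5.0e2])     # Pa/m
        p_lin = shell_mesh.nodes @ g
        st = make_state(shell_mesh, {"e": p_lin})
        v = darcy_velocity(st, {"e": keff["e"]}, shell_mesh, params)
        expected = -(1.0e-10 / params.mu["e"]) * g
        assert np.allclose(v["e"], expected, rtol=1e-9)

    def test_anisotropic_attenuation_matches_tensor_algebra(self, shell_mesh,
                                                            params):
        ptm = synthesize_ptm(shell_mesh, 10.0, orientation="radial")
        keff_a = effective_permeability(params, ptm, shell_mesh)
        g = np.array([0.0, 0.0, 1.0e4])
        st = make_state(shell_mesh, {"e": shell_mesh.nodes @ g})
        v = darcy_velocity(st, {"e": keff_a["e"]}, shell_mesh, params)
        # independent 3x3 oracle, element by element
        expected = -np.einsum("eij,j->ei", keff_a["e"], g) / params.mu["e"]
        assert np.allclose(v["e"], expected, rtol=1e-9)


class TestFluidContent:
    def test_zero_at_reference(self, shell_mesh, params):
        st = make_state(shell_mesh,
                        {"e": np.full(shell_mesh.n_nodes, 650.0)})
        z = fluid_content_increment(st, params, shell_mesh)
        assert np.abs(z["e"]).max() == 0.0

    def test_storage_contribution(self, shell_mesh, params):
        # S_e = 3.9e-4 m^2/N at a 1000 Pa excess -> zeta_e = 0.39
        st = make_state(shell_mesh,
                        {"e": np.full(shell_mesh.n_nodes, 1650.0)})
        z = fluid_content_increment(st, params, shell_mesh)
        assert np.allclose(z["e"], 0.39)

    def test_dilation_contribution(self, shell_mesh, params):
        # alpha_e = 0.49 at div u = 0.01 -> zeta_e = 0.0049
        u = 0.01 / 3.0 * shell_mesh.nodes   # div u = 0.01 exactly
        st = make_state(shell_mesh,
                        {"e": np.full(shell_mesh.n_nodes, 650.0)}, u=u)
        z = fluid_content_increment(st, params, shell_mesh)
        assert np.allclose(z["e"], 0.49 * 0.01)


class TestRegionRange:
    def test_constant_field_has_zero_range(self, shell_mesh):
        f = np.full(shell_mesh.n_elements, 3.3)
        assert region_range(f, shell_mesh, "L") == 0.0

    def test_sinusoid_over_full_period_gives_two(self, shell_mesh):
        times = np.linspace(0.0, 2 * np.pi, 200)
        series = np.sin(times)[:, None] * np.ones(shell_mesh.n_elements)
        rng = region_range(series, shell_mesh, "R", times=times,
                           window=(0.0, 2 * np.pi))
        assert rng == pytest.approx(2.0, rel=1e-3)

    def test_manufactured_extremes_and_mmhg(self, shell_mesh):
        f = np.zeros((3, shell_mesh.n_elements))
        left = shell_mesh.hemisphere_elements("L")
        right = shell_mesh.hemisphere_elements("R")
        f[1, left[0]] = 2.0 * MMHG
        f[2, left[1]] = -1.0 * MMHG
        f[0, right[0]] = 99.0 * MMHG    # must not leak into L range
        assert region_range(f, shell_mesh, "L", in_mmhg=True) == \
            pytest.approx(3.0)

    def test_unlabeled_hemisphere_rejected(self, shell_mesh):
        with pytest.raises(Exception):
            region_range(np.zeros(shell_mesh.n_elements), shell_mesh, "X")


class TestPeakSummary:
    def test_all_zero_series_ties_break_low(self, shell_mesh, params, keff):
        st = make_state(shell_mesh, {n: np.zeros(shell_mesh.n_nodes)
                                     for n in "acev"})
        d = [derive_fields(st, keff, shell_mesh, params)]
        s = peak_summary(d)
        assert s["peak_clearance"]["value"] == 0.0
        assert s["peak_clearance"]["index"] == 0
        assert s["peak_clearance"]["t"] == 0.0

    def test_extrema_match_bruteforce_scan(self, shell_mesh, params, keff):
        rng = np.random.default_rng(4)
        series = []
        for t in (0.0, 0.5, 1.0):
            p = {n: 650.0 + rng.normal(0, 30, shell_mesh.n_nodes)
                 for n in "acev"}
            u = rng.normal(0, 1e-5, (shell_mesh.n_nodes, 3))
            series.append(derive_fields(make_state(shell_mesh, p, u, t),
                                        keff, shell_mesh, params))
        s = peak_summary(series)
        brute = max(np.linalg.norm(d.clearance, axis=1).max()
                    for d in series)
        assert s["peak_clearance"]["value"] == brute
        brute_z = min(d.zeta["e"].min() for d in series)
        assert s["min_zeta_e"]["value"] == brute_z

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            peak_summary([])


class TestExport:
    def test_round_trip_and_cadence(self, coarse_shell, params, tmp_path):
        keff = effective_permeability(params, None, coarse_shell)
        rng = np.random.default_rng(1)
        states = [make_state(
            coarse_shell,
            {n: 650.0 + rng.normal(0, 10, coarse_shell.n_nodes)
             for n in "acev"},
            rng.normal(0, 1e-6, (coarse_shell.n_nodes, 3)), t=0.01 * k)
            for k in range(10)]
        prefix = str(tmp_path / "run")
        written = export_fields(states, coarse_shell, keff, params, prefix,
                                cadence=5)
        assert len(written) == 2
        data = read_mesh(written[0])
        assert data.n_elements == coarse_shell.n_elements
        from mpetsim._vtk import read_vtk
        raw = read_vtk(written[0])
        assert np.allclose(raw["point_data"]["p_e"], states[0].p["e"])
        assert (tmp_path / "run_summary.csv").exists()

    def test_unwritable_path_raises(self, coarse_shell, params):
        keff = effective_permeability(params, None, coarse_shell)
        states = [make_state(coarse_shell,
                             {n: np.full(coarse_shell.n_nodes, 650.0)
                              for n in "acev"})]
        with pytest.raises(OSError):
            export_fields(states, coarse_shell, keff, params,
                          "/nonexistent-dir/run")
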