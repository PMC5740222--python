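"""Analytic consolidation oracles and convergence drivers gating the solver.

Two classical single-network Biot benchmarks with series solutions:

* Terzaghi's problem — a laterally confined column under a suddenly
  applied surface load, drained at the loaded surface.  The excess pore
  pressure obeys a 1-D diffusion equation with consolidation coefficient
  c_v = (k/mu) M m_v / (m_v + alpha^2 M), where m_v = lam + 2G is the
  constrained modulus and M = 1/S the Biot modulus; the initial undrained
  pressure is p0 = alpha M q / (m_v + alpha^2 M) for surface load q.

* Mandel's problem — a poroelastic slab squeezed between rigid
  frictionless platens, drained at the lateral edges.  Its pressure series
  exhibits the Mandel–Cryer effect: the centre pressure first rises above
  the undrained value before consolidation drains it.

The MPET solver, reduced to a single active network, must reproduce both
series on resolved meshes; a mesh-refinement driver checks that domain
statistics of the full four-network brain configuration converge as
elements shrink.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import core, fem
from .geometry import (XMAX, XMIN, YMAX, YMIN, ZMAX, ZMIN,
                       generate_box_mesh, generate_shell_mesh)
from .parameters import MPETParameters
from .ptm import effective_permeability
from .waveforms import default_waveforms, territory_fluxes


@dataclass
class ConsolidationSetup:
    """Single-network Biot problem data (SI units throughout)."""

    height: float = 1.0        # column height / plate half-width, m
    load: float = 1.0e4        # applied compressive load, Pa
    G: float = 3.0e6           # shear modulus, Pa
    lam: float = 4.0e6         # Lamé constant, Pa
    alpha: float = 1.0         # Biot-Willis coefficient
    S: float = 1.0e-6          # specific storage, 1/Pa
    k: float = 1.0e-10         # permeability, m^2
    mu: float = 1.0e-3         # viscosity, Pa s

    @property
    def m_v(self) -> float:
        """Constrained (oedometer) modulus lam + 2G."""
        return self.lam + 2.0 * self.G

    @property
    def M_biot(self) -> float:
        return 1.0 / self.S

    @property
    def c_v(self) -> float:
        """Consolidation coefficient (k/mu) M m_v / (m_v + alpha^2 M)."""
        M = self.M_biot
        return (self.k / self.mu) * M * self.m_v / \
            (self.m_v + self.alpha ** 2 * M)

    @property
    def p_undrained(self) -> float:
        """Initial pore pressure under an instantaneous load."""
        M = self.M_biot
        return self.alpha * M * self.load / \
            (self.m_v + self.alpha ** 2 * M)

    # drained / undrained elastic constants (used by the Mandel series)
    @property
    def nu(self) -> float:
        return self.lam / (2.0 * (self.lam + self.G))

    @property
    def K_drained(self) -> float:
        return self.lam + 2.0 * self.G / 3.0

    @property
    def skempton_B(self) -> float:
        Ku = self.K_drained + self.alpha ** 2 * self.M_biot
        return self.alpha * self.M_biot / Ku

    @property
    def nu_u(self) -> float:
        B, nu = self.skempton_B, self.nu
        num = 3.0 * nu + self.alpha * B * (1.0 - 2.0 * nu)
        return num / (3.0 - self.alpha * B * (1.0 - 2.0 * nu))

    def single_network_parameters(self) -> MPETParameters:
        """Wrap this setup as an MPET parameter set with only network 'e'
        active (the other networks are simply not assembled)."""
        p = MPETParameters(G=self.G, lam=self.lam)
        p.alpha = dict(p.alpha)
        p.alpha["e"] = self.alpha
        p.S = dict(p.S)
        p.S["e"] = self.S
        p.k_base = dict(p.k_base)
        p.k_base["e"] = self.k
        p.mu = dict(p.mu)
        p.mu["e"] = self.mu
        p.omega = {key: 0.0 for key in p.omega}
        p.Q_p = 0.0
        p.p_bp = 0.0
        return p


# ---------------------------------------------------------------------------
# series solutions

def terzaghi_solution(z, t, setup: ConsolidationSetup,
                      n_terms: int = 100):
    """Excess pore pressure p(z, t) of 1-D consolidation.

    Column occupies 0 <= z <= H with an impermeable rigid base at z = 0
    and the drained, loaded surface at z = H.  Truncation error is
    bounded by the first omitted term of the alternating exponential
    series.
    """
    t = np.asarray(t, dtype=float)
    if (t <= 0).any():
        raise ValueError("t must be positive")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    z = np.asarray(z, dtype=float)
    H = setup.height
    Tv = setup.c_v * t / H ** 2
    j = np.arange(n_terms)
    m = 2 * j + 1                                  # odd harmonics
    zz, tt, mm = np.broadcast_arrays(
        z[..., None], Tv[..., None], m)
    series = (4.0 / np.pi / mm *
              np.sin(mm * np.pi * (H - zz) / (2.0 * H)) *
              np.exp(-(mm ** 2) * np.pi ** 2 / 4.0 * tt))
    return setup.p_undrained * series.sum(axis=-1)


def mandel_roots(setup: ConsolidationSetup, n_roots: int = 50):
    """Roots of tan(a) = (1 - nu)/(nu_u - nu) * a (bracketed brentq)."""
    c = (1.0 - setup.nu) / (setup.nu_u - setup.nu)
    roots = np.empty(n_roots)
    f = lambda a: np.tan(a) - c * a
    for n in range(n_roots):
        lo = n * np.pi + 1e-9 if n else 1e-9
        hi = n * np.pi + np.pi / 2.0 - 1e-9
        try:
            roots[n] = brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)
        except ValueError as exc:
            raise RuntimeError(f"Mandel root {n} not bracketed in "
                               f"({lo:.6g}, {hi:.6g})") from exc
    return roots


def mandel_solution(x, t, setup: ConsolidationSetup,
                    n_roots: int = 50):
    """Pore pressure p(x, t) of Mandel's problem.

    The slab occupies |x| <= a (a = setup.height) with drained edges at
    x = +/-a and rigid frictionless platens applying a mean compressive
    stress ``setup.load`` (total force per platen divided by platen
    area).  Series in the roots a_n of tan a = (1-nu)/(nu_u-nu) a:

        p = 2 p0 sum_n [sin a_n /(a_n - sin a_n cos a_n)]
                   (cos(a_n x/a) - cos a_n) exp(-a_n^2 c_v t / a^2)

    with p0 = B (1 + nu_u) sigma0 / 3.  Early times exhibit the
    Mandel–Cryer pressure overshoot above p(x, 0+).
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be non-negative")
    x = np.asarray(x, dtype=float)
    a = setup.height
    if (np.abs(x) > a * (1 + 1e-12)).any():
        raise ValueError("|x| must be <= the plate half-width")
    roots = mandel_roots(setup, n_roots)
    p0 = setup.skempton_B * (1.0 + setup.nu_u) * setup.load / 3.0
    coef = np.sin(roots) / (roots - np.sin(roots) * np.cos(roots))
    xx, tt, aa = np.broadcast_arrays(x[..., None], t[..., None], roots)
    cc = np.broadcast_to(coef, aa.shape)
    series = cc * (np.cos(aa * xx / a) - np.cos(aa)) * \
        np.exp(-(aa ** 2) * setup.c_v * tt / a ** 2)
    return 2.0 * p0 * series.sum(axis=-1)


# ---------------------------------------------------------------------------
# FEM runs of the benchmark problems

def terzaghi_fem(setup: ConsolidationSetup, nz: int = 48,
                 dt_factor: float = 2.0e-3, probe_Tv=(0.05, 0.1, 0.2, 0.5)):
    """Run the single-network solver on the consolidation column.

    Returns (z nodes, probe times, fem pressures (T, nz+1), analytic
    pressures).  dt is ``dt_factor`` in dimensionless-time units.
    """
    H = setup.height
    w = H / max(nz // 8, 1)
    mesh = generate_box_mesh(1, 1, nz, w, w, H)
    params = setup.single_network_parameters()
    keff = effective_permeability(params, None, mesh)
    tm = core.TransferModel.from_parameters(params)

    nodes = mesh.nodes
    def nodeset(mask):
        return np.where(mask)[0]
    tol = 1e-12
    bcs = [
        core.Dirichlet("u", nodeset(np.abs(nodes[:, 0]) < tol), 0.0, comp=0),
        core.Dirichlet("u", nodeset(np.abs(nodes[:, 0] - w) < tol), 0.0,
                       comp=0),
        core.Dirichlet("u", nodeset(np.abs(nodes[:, 1]) < tol), 0.0, comp=1),
        core.Dirichlet("u", nodeset(np.abs(nodes[:, 1] - w) < tol), 0.0,
                       comp=1),
        core.Dirichlet("u", nodeset(np.abs(nodes[:, 2]) < tol), 0.0, comp=2),
        core.Dirichlet("e", nodeset(np.abs(nodes[:, 2] - H) < tol), 0.0),
        core.NormalPressureTraction(
            np.where(mesh.facet_tag == ZMAX)[0], setup.load),
    ]
    t_char = H ** 2 / setup.c_v
    dt = dt_factor * t_char
    probe_t = np.asarray(probe_Tv) * t_char

    sys_ = core.assemble_system(mesh, params, keff, tm, dt,
                                networks=("e",), p_ref=0.0)
    sys_.apply_bcs(bcs)
    # undrained initial condition: uniform p0, linear settlement
    n = mesh.n_nodes
    p0 = setup.p_undrained
    u0 = np.zeros((n, 3))
    u0[:, 2] = (setup.alpha * p0 - setup.load) / setup.m_v * nodes[:, 2]
    state = core.MPETState(u0, {"e": np.full(n, p0)}, {}, 0.0)

    # probe on the unique z line (all nodes share the 1-D profile)
    zs = np.unique(np.round(nodes[:, 2], 12))
    line = [np.where(np.abs(nodes[:, 2] - z) < 1e-11)[0] for z in zs]
    fem_p, ana_p, times = [], [], []
    k_probe = np.unique(np.maximum(np.round(probe_t / dt), 1).astype(int))
    for k in range(1, int(k_probe.max()) + 1):
        state = core.advance_step(sys_, state)
        if k in k_probe:
            prof = np.array([state.p["e"][idx].mean() for idx in line])
            fem_p.append(prof)
            ana_p.append(terzaghi_solution(zs, k * dt, setup))
            times.append(k * dt)
    return zs, np.array(times), np.array(fem_p), np.array(ana_p)


def mandel_fem(setup: ConsolidationSetup, nx: int = 40, ny: int = 16,
               dt_factor: float = 2.0e-3,
               probe_tau=(0.05, 0.1, 0.25, 0.5, 1.0),
               track_center=True):
    """Run the single-network solver on (a quarter of) Mandel's slab.

    Plane strain (u_z = 0 everywhere), symmetry planes at x = 0 and
    y = 0, drained free edge at x = a, rigid frictionless platen at
    y = b tied to one master dof and loaded with the total force.
    Returns (x nodes, probe times, fem pressures, analytic pressures,
    centre-pressure history).
    """
    a = setup.height
    b = a / 2.0
    mesh = generate_box_mesh(nx, ny, 1, a, b, a / max(nx, 1))
    params = setup.single_network_parameters()
    keff = effective_permeability(params, None, mesh)
    tm = core.TransferModel.from_parameters(params)
    nodes = mesh.nodes
    tol = 1e-12
    top_nodes = np.where(np.abs(nodes[:, 1] - b) < tol)[0]
    force_total = -setup.load * a * nodes[:, 2].max()   # quarter platen
    bcs = [
        core.Dirichlet("u", np.arange(mesh.n_nodes), 0.0, comp=2),
        core.Dirichlet("u", np.where(np.abs(nodes[:, 0]) < tol)[0], 0.0,
                       comp=0),
        core.Dirichlet("u", np.where(np.abs(nodes[:, 1]) < tol)[0], 0.0,
                       comp=1),
        core.Dirichlet("e", np.where(np.abs(nodes[:, 0] - a) < tol)[0],
                       0.0),
        core.RigidPlate(1, top_nodes, force_total),
    ]
    t_char = a ** 2 / setup.c_v
    dt = dt_factor * t_char
    probe_t = np.asarray(probe_tau) * t_char
    sys_ = core.assemble_system(mesh, params, keff, tm, dt,
                                networks=("e",), p_ref=0.0)
    sys_.apply_bcs(bcs)
    state = sys_.default_initial_state()   # u = 0, p = 0; load from t=0+

    xs = np.unique(np.round(nodes[:, 0], 12))
    cols = [np.where(np.abs(nodes[:, 0] - x) < 1e-11)[0] for x in xs]
    center = np.where((np.abs(nodes[:, 0]) < tol))[0]
    fem_p, ana_p, times, center_hist = [], [], [], []
    k_probe = np.unique(np.maximum(np.round(probe_t / dt), 1).astype(int))
    for k in range(1, int(k_probe.max()) + 1):
        state = core.advance_step(sys_, state)
        if track_center:
            center_hist.append((k * dt, state.p["e"][center].mean()))
        if k in k_probe:
            prof = np.array([state.p["e"][idx].mean() for idx in cols])
            fem_p.append(prof)
            ana_p.append(mandel_solution(xs, k * dt, setup))
            times.append(k * dt)
    return (xs, np.array(times), np.array(fem_p), np.array(ana_p),
            np.array(center_hist))


def run_verification(problem: str, refinement: int = 2,
                     setup: ConsolidationSetup | None = None,
                     tol: float = 0.01) -> dict:
    """Gate the solver against one analytic benchmark.

    ``refinement`` scales mesh density (and for the coarsest levels the
    time step); pass iff the space-time relative L2 error against the
    series is below ``tol`` (default 1%).
    """
    if setup is None:
        # the Mandel gate uses a stiffer-fluid setup (larger nu_u - nu)
        # so the Mandel-Cryer overshoot is pronounced and testable
        setup = ConsolidationSetup() if problem == "terzaghi" else \
            ConsolidationSetup(S=5e-8, lam=2e6)
    if problem == "terzaghi":
        nz = [12, 24, 48, 64][min(refinement, 3)]
        dtf = [8e-3, 4e-3, 2e-3, 1e-3][min(refinement, 3)]
        _, _, femp, anap = terzaghi_fem(setup, nz=nz, dt_factor=dtf)
        err = np.linalg.norm(femp - anap) / np.linalg.norm(anap)
        return {"problem": problem, "refinement": refinement,
                "rel_l2_error": float(err), "passed": bool(err < tol)}
    if problem == "mandel":
        nx = [12, 24, 40, 56][min(refinement, 3)]
        dtf = [8e-3, 4e-3, 2e-3, 1e-3][min(refinement, 3)]
        _, _, femp, anap, hist = mandel_fem(setup, nx=nx, ny=nx // 2,
                                            dt_factor=dtf)
        err = np.linalg.norm(femp - anap) / np.linalg.norm(anap)
        # Mandel-Cryer: centre pressure must overshoot its early value
        overshoot = float(hist[:, 1].max() / hist[0, 1])
        return {"problem": problem, "refinement": refinement,
                "rel_l2_error": float(err),
                "center_overshoot_ratio": overshoot,
                "nonmonotone": bool(overshoot > 1.0 and
                                    hist[-1, 1] < hist[:, 1].max()),
                "passed": bool(err < tol)}
    raise ValueError(f"unknown verification problem {problem!r}")


# ---------------------------------------------------------------------------
# mesh-independence study

DEFAULT_FAMILY = ((2, 2), (3, 3), (5, 5), (7, 6))


def convergence_study(family=DEFAULT_FAMILY, r_inner=0.03, r_outer=0.07,
                      n_meshes=None, case="control", activity="high",
                      t_end=0.25, dt=0.0125, params=None) -> pd.DataFrame:
    """Domain-mean solution statistics across a shell-mesh family.

    Runs the identical four-network brain configuration (same parameters,
    same territory inflow, same time window) on each member of a
    concentric-shell family of increasing resolution and tabulates
    volume-weighted domain means of |u|, the four pore pressures and the
    four Darcy speeds, plus probe values at three representative radial
    locations (mid-shell interior, near-cortical, near-ventricular).
    Successive-refinement differences gauge mesh independence.
    """
    from .postprocess import derive_fields
    family = list(family)
    if n_meshes is not None:
        family = family[:n_meshes]
    if len(family) < 3:
        raise ValueError("need at least 3 meshes in the family")
    if params is None:
        params = MPETParameters()
    rows = []
    for freq, layers in family:
        mesh = generate_shell_mesh(r_inner, r_outer, 1.0,
                                   resolution=(freq, layers))
        keff = effective_permeability(params, None, mesh)
        tm = core.TransferModel.from_parameters(params)
        waves = default_waveforms(case, activity,
                                  n_cycles=max(1, int(np.ceil(t_end))))
        fx = territory_fluxes(waves, mesh)
        n_steps = int(round(t_end / dt))
        states, _ = core.solve_transient(mesh, params, keff, tm, fx,
                                         t_end=t_end, dt=dt,
                                         record_every=n_steps)
        st = states[-1]
        vol = mesh.tet_volumes()
        vtot = vol.sum()
        d = derive_fields(st, keff, mesh, params)
        disp_el = fem.element_means(d.disp_mag, mesh.tets)
        row = {"elements": mesh.n_elements, "nodes": mesh.n_nodes,
               "mean_disp": float((disp_el * vol).sum() / vtot)}
        for net in st.p:
            p_el = fem.element_means(st.p[net], mesh.tets)
            speed = np.linalg.norm(d.darcy[net], axis=1)
            row[f"mean_p_{net}"] = float((p_el * vol).sum() / vtot)
            row[f"mean_v_{net}"] = float((speed * vol).sum() / vtot)
        # probe points at three radii along a fixed ray
        ray = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
        cent = mesh.tet_centroids()
        for tag, frac in (("interior", 0.5), ("cortical", 0.9),
                          ("ventricular", 0.1)):
            pt = ray * (r_inner + frac * (r_outer - r_inner))
            e = int(np.argmin(np.linalg.norm(cent - pt, axis=1)))
            row[f"probe_{tag}_icp"] = float(
                fem.element_means(st.p["e"], mesh.tets)[e])
            row[f"probe_{tag}_disp"] = float(disp_el[e])
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("elements").reset_index(drop=True)
    return df


def successive_differences(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """|q_{i+1} - q_i| for each tracked mean quantity in the family."""
    if columns is None:
        columns = [c for c in df.columns if c.startswith("mean_")]
    return df[columns].diff().abs().iloc[1:].reset_index(drop=True)
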