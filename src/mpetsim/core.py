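"""Coupled multi-network poroelastic solver (quasi-static Biot + Darcy).

Primitive fields: solid displacement u and one pore pressure p_i per
active fluid network, all discretized with continuous P1 elements on a
labeled tetrahedral mesh.  Governing system (quasi-static momentum plus
one continuity equation per network):

    div( 2 G eps(u) + lam tr eps I ) - sum_i alpha_i grad p_i = 0
    S_i dp_i/dt + alpha_i d(div u)/dt - div( (k_i / mu_i) grad p_i )
        = sum_j omega_ij (p_j - p_i)    over the allowed transfer pairs

Time discretization is monolithic backward Euler with a direct sparse
factorization; the system matrix is constant over a run, so one
factorization serves every step.  Boundary conditions are isolated,
swappable policy objects; the brain configuration (rigid skull, territory
inflow, lumped ventricular CSF reservoir with production and aqueduct
drainage, venous back-pressure) is one such set, and the consolidation
benchmarks use others.

The lumped ventricle treats the ventricular CSF pressure p_vent as one
extra scalar unknown: the CSF/ISF pressure on the ependymal surface is
tied to it, the wall traction is -p_vent n, and the reservoir balance
Q_production + Q_in(parenchyma->ventricle) = Q_aqueduct + dV_vent/dt with
Q_aqueduct = (p_vent - p_bp) / (mu_e R) closes the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .geometry import CORTICAL, VENTRICULAR, LabeledMesh, TERRITORIES
from .parameters import MPETParameters, NETWORKS, TRANSFER_PAIRS


class ModelError(ValueError):
    """Raised for physically prohibited configurations."""


class SolverError(RuntimeError):
    """Raised when the discrete system cannot be solved."""


# ---------------------------------------------------------------------------
# transfer model

@dataclass
class TransferModel:
    """Inter-network fluid exchange on a fixed directed pair set.

    The pair set excludes (a, e): direct arterial <-> CSF/ISF exchange is
    structurally prohibited, not merely given a zero coefficient.
    """

    omega: dict
    allowed_pairs: tuple = TRANSFER_PAIRS

    @classmethod
    def from_parameters(cls, params: MPETParameters) -> "TransferModel":
        return cls(omega=dict(params.omega))

    def pair_key(self, pair):
        a, b = pair
        if (a, b) in self.allowed_pairs:
            return a + b
        if (b, a) in self.allowed_pairs:
            return b + a
        raise ModelError(f"transfer between networks {a!r} and {b!r} is "
                         "prohibited")

    def coefficient(self, pair) -> float:
        return float(self.omega[self.pair_key(pair)])


def transfer_rate(pair, p_from: float, p_to: float,
                  tm: TransferModel) -> float:
    """Volumetric transfer density omega_pair (p_from - p_to), 1/s.

    Antisymmetric by construction: the sink in the donor network equals
    the source in the receiver.  A prohibited pair (e.g. arterial ->
    CSF/ISF) raises :class:`ModelError`.
    """
    w = tm.coefficient(pair)
    return w * (p_from - p_to)


def transfer_source_fields(p: dict, tm: TransferModel,
                           networks=NETWORKS) -> dict:
    """Nodal source density received by each network from all transfers."""
    src = {n: np.zeros_like(next(iter(p.values()))) for n in networks}
    for (i, j) in tm.allowed_pairs:
        if i not in p or j not in p:
            continue
        w = tm.omega[i + j]
        flow = w * (p[i] - p[j])
        src[i] -= flow
        src[j] += flow
    return src


# ---------------------------------------------------------------------------
# boundary-condition policies

@dataclass
class Dirichlet:
    """Fix a field (u component or one network pressure) on a node set."""
    field: str               # 'u' or a network name
    nodes: np.ndarray
    value: float = 0.0
    comp: int | None = None  # displacement component, None = all three


@dataclass
class NormalFlux:
    """Prescribed inward normal Darcy flux on a facet set (weak/Neumann)."""
    field: str
    facet_ids: np.ndarray
    flux: object             # callable t -> inward flux (m/s), or constant


@dataclass
class NormalPressureTraction:
    """Total-stress traction sigma . n = -P(t) n on a facet set."""
    facet_ids: np.ndarray
    pressure: object         # callable t -> Pa, or constant


@dataclass
class RigidPlate:
    """Tie one displacement component on a node set to a single master dof
    loaded by a total force (a frictionless rigid platen)."""
    comp: int
    nodes: np.ndarray
    force: object            # callable t -> N (signed, along +comp)
    name: str = "plate"


@dataclass
class VentricleReservoir:
    """Lumped ventricular CSF pocket behind the ependymal surface."""
    facet_ids: np.ndarray
    couple_wall_motion: bool = True
    name: str = "p_vent"


def brain_boundary_conditions(mesh: LabeledMesh, params: MPETParameters,
                              flux_bcs: dict) -> list:
    """The standard BC set of the perfused-brain configuration.

    Rigid skull: u = 0 on the cortical surface.  Arterial network:
    prescribed territory inflow fluxes on the cortical surface.
    Arteriole/capillary: impermeable on both surfaces (natural no-flux).
    CSF/ISF: no-flux at the cortex, lumped ventricular reservoir at the
    ependymal wall (production Q_p, aqueduct drainage resistance R,
    downstream pressure p_bp).  Venous: p_v = p_bp on both surfaces.
    """
    missing = [t for t in TERRITORIES if t not in flux_bcs]
    if missing:
        raise ModelError(f"missing territory fluxes: {missing}")
    cort_facets = np.where(mesh.facet_tag == CORTICAL)[0]
    vent_facets = np.where(mesh.facet_tag == VENTRICULAR)[0]
    if len(cort_facets) == 0 or len(vent_facets) == 0:
        raise ModelError("mesh must carry both cortical and ventricular "
                         "surfaces")
    cort_nodes = np.unique(mesh.boundary_facets[cort_facets])
    all_bnd_nodes = np.unique(mesh.boundary_facets)
    bcs = [
        Dirichlet("u", cort_nodes, 0.0),
        Dirichlet("v", all_bnd_nodes, params.p_bp),
        VentricleReservoir(vent_facets),
    ]
    for terr in TERRITORIES:
        tf = flux_bcs[terr]
        bcs.append(NormalFlux("a", np.asarray(tf.facet_ids), tf.flux))
    return bcs


# ---------------------------------------------------------------------------
# state

@dataclass
class MPETState:
    """Displacement + pore-pressure fields (and lumped scalars) at time t."""

    u: np.ndarray            # (N, 3), m
    p: dict                  # network -> (N,), Pa
    aux: dict = field(default_factory=dict)   # extra scalars (p_vent, ...)
    t: float = 0.0

    def copy(self):
        return MPETState(self.u.copy(), {k: v.copy()
                                         for k, v in self.p.items()},
                         dict(self.aux), self.t)


# ---------------------------------------------------------------------------
# discrete system

class DiscreteSystem:
    """Assembled monolithic block system on one mesh.

    Dofs are interleaved node-major (u_x, u_y, u_z then one pressure per
    active network at each node) with the lumped scalars last; Dirichlet
    and tied dofs are eliminated through a sparse restriction
    T: x_full = T x_reduced + g.
    """

    def __init__(self, mesh, params, keff, tm, dt, networks=NETWORKS,
                 p_ref=None):
        self.mesh = mesh
        self.params = params
        self.tm = tm
        self.dt = dt                      # None => steady problem
        self.networks = tuple(networks)
        self.n_nodes = mesh.n_nodes
        self.keff = keff
        # Pressures are solved as deviations from a constant reference
        # (default: the venous baseline).  The weakly anchored arterial/
        # capillary pressure levels then carry no large constant component,
        # which keeps the direct solve accurate despite the tiny transfer
        # coefficients; the hydrostatic equilibrium state is exactly zero.
        self.p_ref = params.p_bp if p_ref is None else float(p_ref)
        self._extra = []                  # names of lumped scalar dofs
        self._bcs = None
        self._lu = None

        vol, grads = fem.element_geometry(mesh.nodes, mesh.tets)
        self.vol, self.grads = vol, grads
        n = self.n_nodes

        self.E = fem.elasticity_matrix(mesh.nodes, mesh.tets, vol, grads,
                                       params.G, params.lam)
        self.M = fem.mass_matrix(mesh.nodes, mesh.tets, vol)
        self.B = fem.divergence_matrix(mesh.nodes, mesh.tets, vol, grads)
        self.K = {}
        for net in self.networks:
            kappa = keff[net] / params.mu[net]
            self.K[net] = fem.stiffness_matrix(mesh.nodes, mesh.tets, vol,
                                               grads, kappa)

    # -- layout ------------------------------------------------------------
    # Dofs are interleaved node-major (all fields of one node contiguous:
    # u_x, u_y, u_z, then one pressure per active network), lumped scalars
    # at the end.  Interleaving keeps the sparse factorization local.

    @property
    def n_fields(self):
        return 3 + len(self.networks)

    @property
    def ndof(self):
        return self.n_fields * self.n_nodes + len(self._extra)

    def dofmap_u(self):
        """Map (3N,) displacement dofs (node-major, comp minor) to global."""
        i = np.arange(3 * self.n_nodes)
        return (i // 3) * self.n_fields + (i % 3)

    def dofmap_p(self, net):
        return np.arange(self.n_nodes) * self.n_fields + 3 + \
            self.networks.index(net)

    def dof_extra(self, name):
        return self.n_fields * self.n_nodes + self._extra.index(name)

    def pack(self, state: MPETState) -> np.ndarray:
        """State -> full dof vector (pressures as deviations from p_ref)."""
        x = np.zeros(self.ndof)
        x[self.dofmap_u()] = state.u.ravel()
        for net in self.networks:
            x[self.dofmap_p(net)] = state.p[net] - self.p_ref
        for name in self._extra:
            x[self.dof_extra(name)] = state.aux.get(name, self.p_ref) - \
                self.p_ref
        return x

    def unpack(self, x, t) -> MPETState:
        n = self.n_nodes
        u = x[self.dofmap_u()].reshape(n, 3).copy()
        p = {net: x[self.dofmap_p(net)] + self.p_ref
             for net in self.networks}
        aux = {name: float(x[self.dof_extra(name)]) + self.p_ref
               for name in self._extra}
        return MPETState(u, p, aux, t)

    def default_initial_state(self) -> MPETState:
        n = self.n_nodes
        p0 = self.params.p_bp
        return MPETState(np.zeros((n, 3)),
                         {net: np.full(n, p0) for net in self.networks},
                         {name: p0 for name in self._extra}, 0.0)

    # -- boundary conditions and finalization -------------------------------

    def apply_bcs(self, bcs):
        """Register the BC policy list and build the reduced operator."""
        self._bcs = list(bcs)
        mesh, params, n = self.mesh, self.params, self.n_nodes
        # first pass: declare extra scalar dofs
        for bc in self._bcs:
            if isinstance(bc, (RigidPlate, VentricleReservoir)):
                if bc.name in self._extra:
                    raise ModelError(f"duplicate lumped dof {bc.name!r}")
                self._extra.append(bc.name)

        ndof = self.ndof
        nf = self.n_fields
        mu_map = self.dofmap_u()
        p_map = {net: self.dofmap_p(net) for net in self.networks}
        dt = self.dt

        blocks = []                       # (rowmap, colmap, matrix)
        blocks.append((mu_map, mu_map, self.E))
        for net in self.networks:
            pm_ = p_map[net]
            blocks.append((mu_map, pm_, -params.alpha[net] * self.B.T))
            blocks.append((pm_, pm_, self.K[net]))
            if dt is not None:
                blocks.append((pm_, pm_, (params.S[net] / dt) * self.M))
                blocks.append((pm_, mu_map,
                               (params.alpha[net] / dt) * self.B))
        for (i, j) in self.tm.allowed_pairs:
            if i not in self.networks or j not in self.networks:
                continue
            w = self.tm.omega[i + j]
            if w == 0.0:
                continue
            wM = w * self.M
            blocks.append((p_map[i], p_map[i], wM))
            blocks.append((p_map[j], p_map[j], wM))
            blocks.append((p_map[i], p_map[j], -wM))
            blocks.append((p_map[j], p_map[i], -wM))

        # history operator: contributes H x_n to the RHS each step
        hist_blocks = []
        if dt is not None:
            for net in self.networks:
                pm_ = p_map[net]
                hist_blocks.append((pm_, pm_, (params.S[net] / dt) *
                                    self.M))
                hist_blocks.append((pm_, mu_map,
                                    (params.alpha[net] / dt) * self.B))

        # constraint bookkeeping
        kind = np.zeros(ndof, dtype=np.int8)     # 0 free 1 fixed 2 tied
        fixed_value = np.zeros(ndof)
        tie_master = np.full(ndof, -1, dtype=np.int64)
        extra_rows = []          # (row, col, value) scalars into A
        extra_hist = []          # (row, col, value) scalars into H
        self._static_load = np.zeros(ndof)
        self._flux_loads = []    # (vector_per_unit_flux, flux_callable)
        self._traction_loads = []  # (vector, pressure_callable)

        for bc in self._bcs:
            if isinstance(bc, Dirichlet):
                nodes = np.asarray(bc.nodes, dtype=np.int64)
                if bc.field == "u":
                    comps = range(3) if bc.comp is None else [bc.comp]
                    for c in comps:
                        dofs = nodes * nf + c
                        kind[dofs] = 1
                        fixed_value[dofs] = bc.value
                else:
                    if bc.field not in self.networks:
                        raise ModelError(f"Dirichlet on unknown field "
                                         f"{bc.field!r}")
                    dofs = nodes * nf + 3 + self.networks.index(bc.field)
                    kind[dofs] = 1
                    fixed_value[dofs] = bc.value - self.p_ref
            elif isinstance(bc, NormalFlux):
                if bc.field not in self.networks:
                    raise ModelError(f"flux on unknown field {bc.field!r}")
                facets = mesh.boundary_facets[np.asarray(bc.facet_ids,
                                                         dtype=np.int64)]
                load = fem.boundary_load_vector(mesh.nodes, facets, 1.0)
                vec = np.zeros(ndof)
                vec[p_map[bc.field]] = load
                self._flux_loads.append((vec, bc.flux))
            elif isinstance(bc, NormalPressureTraction):
                fids = np.asarray(bc.facet_ids, dtype=np.int64)
                facets = mesh.boundary_facets[fids]
                normals = mesh.facet_normals()[fids]
                c = fem.boundary_normal_vector(mesh.nodes, facets, normals)
                vec = np.zeros(ndof)
                vec[mu_map] = -c
                self._traction_loads.append((vec, bc.pressure))
            elif isinstance(bc, RigidPlate):
                master = self.dof_extra(bc.name)
                dofs = np.asarray(bc.nodes, dtype=np.int64) * nf + bc.comp
                kind[dofs] = 2
                tie_master[dofs] = master
                vec = np.zeros(ndof)
                vec[master] = 1.0
                self._traction_loads.append(
                    (vec, bc.force if callable(bc.force)
                     else (lambda t, f=bc.force: f)))
            elif isinstance(bc, VentricleReservoir):
                master = self.dof_extra(bc.name)
                fids = np.asarray(bc.facet_ids, dtype=np.int64)
                facets = mesh.boundary_facets[fids]
                normals = mesh.facet_normals()[fids]
                if "e" not in self.networks:
                    raise ModelError("ventricle reservoir needs the CSF/ISF "
                                     "network")
                # tie ependymal CSF/ISF pressures to p_vent
                vnodes = np.unique(facets)
                dofs = vnodes * nf + 3 + self.networks.index("e")
                kind[dofs] = 2
                tie_master[dofs] = master
                # aqueduct drainage conductance
                geq = 1.0 / (params.mu["e"] * params.R_drain)
                extra_rows.append((master, master, geq))
                self._static_load[master] += \
                    (params.p_bp - self.p_ref) * geq + params.Q_p
                # wall traction -p_vent n couples u rows to the master col;
                # the constant p_ref part goes to the static load
                cvec = fem.boundary_normal_vector(mesh.nodes, facets,
                                                  normals)
                for d in np.nonzero(cvec)[0]:
                    extra_rows.append((mu_map[d], master, cvec[d]))
                self._static_load[mu_map] -= self.p_ref * cvec
                # ventricle volume change enters the reservoir balance
                if bc.couple_wall_motion and dt is not None:
                    for d in np.nonzero(cvec)[0]:
                        extra_rows.append((master, mu_map[d],
                                           -cvec[d] / dt))
                        extra_hist.append((master, mu_map[d],
                                           -cvec[d] / dt))
            else:
                raise ModelError(f"unknown boundary condition {bc!r}")

        # constant-pressure correction: the momentum coupling acts on the
        # absolute pressures, so the p_ref part of -sum alpha_i B^T p_i
        # moves to the static load (B^T 1 is a pure boundary integral)
        if self.p_ref != 0.0:
            s = np.asarray(self.B.T @ np.ones(n)).ravel()
            coef = sum(params.alpha[net] for net in self.networks)
            self._static_load[mu_map] += self.p_ref * coef * s

        # assemble the full operator from blocks + scalar entries
        rows, cols, vals = [], [], []
        for rmap, cmap, mat in blocks:
            coo = mat.tocoo()
            rows.append(rmap[coo.row])
            cols.append(cmap[coo.col])
            vals.append(coo.data)
        if extra_rows:
            er, ec, ev = zip(*extra_rows)
            rows.append(np.asarray(er, dtype=np.int64))
            cols.append(np.asarray(ec, dtype=np.int64))
            vals.append(np.asarray(ev, dtype=float))
        A = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(ndof, ndof)).tocsr()

        hr, hc, hv = [], [], []
        for rmap, cmap, mat in hist_blocks:
            coo = mat.tocoo()
            hr.append(rmap[coo.row])
            hc.append(cmap[coo.col])
            hv.append(coo.data)
        if extra_hist:
            er, ec, ev = zip(*extra_hist)
            hr.append(np.asarray(er, dtype=np.int64))
            hc.append(np.asarray(ec, dtype=np.int64))
            hv.append(np.asarray(ev, dtype=float))
        if hr:
            H = sp.coo_matrix((np.concatenate(hv),
                               (np.concatenate(hr), np.concatenate(hc))),
                              shape=(ndof, ndof)).tocsr()
        else:
            H = sp.csr_matrix((ndof, ndof))

        if (kind[ndof - len(self._extra):] != 0).any():
            raise ModelError("a lumped master dof cannot itself be "
                             "constrained")
        free = np.where(kind == 0)[0]
        red_index = np.full(ndof, -1, dtype=np.int64)
        red_index[free] = np.arange(len(free))
        tr, tc = [], []
        for d in range(ndof):
            if kind[d] == 0:
                tr.append(d); tc.append(red_index[d])
            elif kind[d] == 2:
                m = tie_master[d]
                if kind[m] != 0:
                    raise ModelError("tie master must be a free dof")
                tr.append(d); tc.append(red_index[m])
        T = sp.coo_matrix((np.ones(len(tr)), (tr, tc)),
                          shape=(ndof, len(free))).tocsr()
        g = np.where(kind == 1, fixed_value, 0.0)

        self.A_full, self.H, self.T, self.g = A, H, T, g
        self._kind = kind
        self._Ag = A @ g
        # symmetric diagonal equilibration keeps the factorization well
        # scaled across the disparate elasticity/Darcy/storage blocks
        A_red = (T.T @ A @ T).tocsr()
        self._A_red_unscaled = A_red
        d = np.abs(A_red.diagonal())
        d[d == 0] = 1.0
        self._scale = 1.0 / np.sqrt(d)
        Ds = sp.diags(self._scale)
        self.A_red = (Ds @ A_red @ Ds).tocsc()
        self._lu = None
        return self

    def _factorize(self):
        if self._lu is None:
            try:
                lu = spla.splu(self.A_red)
            except RuntimeError as exc:
                raise SolverError(f"singular discrete system: {exc}; check "
                                  "that at least one pressure Dirichlet/"
                                  "drainage path or nonzero transfer "
                                  "exists") from exc
            d = np.abs(lu.U.diagonal())
            ratio = d.min() / d.max()
            if ratio < 1e-12:
                raise SolverError(
                    f"discrete system is numerically singular at working "
                    f"precision (pivot ratio {ratio:.2e}); a field has no "
                    "effective Dirichlet/drainage/storage anchor at these "
                    "coefficients")
            self._lu = lu
        return self._lu

    def load_vector(self, t) -> np.ndarray:
        f = self._static_load.copy()
        for vec, flux in self._flux_loads:
            q = flux(t) if callable(flux) else flux
            f += q * vec
        for vec, pressure in self._traction_loads:
            P = pressure(t) if callable(pressure) else pressure
            f += P * vec
        return f

    def solve_full(self, b_full, n_refine: int = 3) -> np.ndarray:
        """Direct solve with a few steps of iterative refinement.

        The transfer coefficients span ~6 orders of magnitude below the
        Darcy/storage terms, so the reduced operator is severely
        ill-conditioned; refinement recovers small-residual solutions at
        the cost of cheap extra back-substitutions.
        """
        lu = self._factorize()
        A_unscaled = self._A_red_unscaled
        rhs = self.T.T @ (b_full - self._Ag)
        y = self._scale * lu.solve(self._scale * rhs)
        # refinement can diverge when kappa*eps ~ 1; keep the best iterate
        best_y, best_res = y, np.linalg.norm(rhs - A_unscaled @ y)
        for _ in range(n_refine):
            res_vec = rhs - A_unscaled @ y
            y = y + self._scale * lu.solve(self._scale * res_vec)
            rnorm = np.linalg.norm(rhs - A_unscaled @ y)
            if rnorm >= best_res:
                break
            best_y, best_res = y, rnorm
        y = best_y
        if not np.all(np.isfinite(y)):
            raise SolverError("solver produced non-finite values "
                              "(singular or ill-posed configuration)")
        return self.T @ y + self.g

    def residual_fluxes(self, x_full) -> np.ndarray:
        """Full residual A x - b_static; on constrained rows this is the
        discrete boundary flux (used for conservation accounting)."""
        return self.A_full @ x_full


def mass_balance(sys: DiscreteSystem, state: MPETState, t=0.0) -> dict:
    """Global fluid bookkeeping at one (steady) solution.

    Sources: prescribed arterial territory inflow and CSF production Q_p.
    Sinks: venous boundary outflow (recovered exactly as the residual of
    the venous Dirichlet rows, the discrete consistent boundary flux) and
    aqueduct drainage (p_vent - p_bp)/(mu_e R).  Returns the individual
    terms and the relative imbalance; at steady state the discrete system
    conserves mass to solver precision.
    """
    x = sys.pack(state)
    r = sys.A_full @ x - sys.load_vector(t)
    q_in = 0.0
    for vec, flux in sys._flux_loads:
        q = flux(t) if callable(flux) else flux
        q_in += q * vec.sum()
    venous_out = 0.0
    if "v" in sys.networks:
        dofs = sys.dofmap_p("v")
        fixed = dofs[sys._kind[dofs] == 1]
        # residual of a Dirichlet row is the (unprescribed) natural
        # boundary term +int phi kappa grad p . n = minus the outflow
        venous_out = -float(r[fixed].sum())
    aqueduct_out = 0.0
    params = sys.params
    for bc in sys._bcs:
        if isinstance(bc, VentricleReservoir):
            p_vent = state.aux[bc.name]
            aqueduct_out += (p_vent - params.p_bp) / \
                (params.mu["e"] * params.R_drain)
    src = q_in + params.Q_p
    sink = venous_out + aqueduct_out
    return {"arterial_inflow": q_in, "production": params.Q_p,
            "venous_outflow": venous_out, "aqueduct_outflow": aqueduct_out,
            "imbalance": src - sink,
            "relative_imbalance": (src - sink) / max(abs(src), 1e-300)}


# ---------------------------------------------------------------------------
# driver operations

def assemble_system(mesh: LabeledMesh, params: MPETParameters, keff,
                    tm: TransferModel, dt, networks=NETWORKS,
                    p_ref=None) -> DiscreteSystem:
    """Assemble the volume operators of the monolithic system.

    ``keff``: per-network per-element permeability tensors (m^2), e.g.
    from :func:`mpetsim.ptm.effective_permeability`.  ``dt=None`` builds
    the steady (time-derivative-free) operator.  BCs are applied
    separately; the matrix is finalized there.
    """
    for net in networks:
        if net not in keff:
            raise ModelError(f"missing permeability for network {net!r}")
        if keff[net].shape[0] != mesh.n_elements:
            raise ModelError(f"permeability of network {net!r} covers "
                             f"{keff[net].shape[0]} elements, mesh has "
                             f"{mesh.n_elements}")
    if dt is not None and dt <= 0:
        raise ModelError(f"dt must be positive, got {dt}")
    return DiscreteSystem(mesh, params, keff, tm, dt, networks, p_ref=p_ref)


def apply_boundary_conditions(sys: DiscreteSystem, mesh: LabeledMesh,
                              params: MPETParameters, flux_bcs=None,
                              bcs=None) -> DiscreteSystem:
    """Attach a BC policy list (default: the brain set) and finalize."""
    if bcs is None:
        bcs = brain_boundary_conditions(mesh, params, flux_bcs or {})
    return sys.apply_bcs(bcs)


def advance_step(sys: DiscreteSystem, state: MPETState) -> MPETState:
    """One backward-Euler step: solve at t + dt from the given state."""
    if sys.dt is None:
        raise SolverError("advance_step requires a transient system")
    t_new = state.t + sys.dt
    x_n = sys.pack(state)
    b = sys.H @ x_n + sys.load_vector(t_new)
    x = sys.solve_full(b)
    return sys.unpack(x, t_new)


def solve_steady(sys: DiscreteSystem, t=0.0) -> MPETState:
    """Solve the steady system (assembled with dt=None) at BC time t."""
    if sys.dt is not None:
        raise SolverError("solve_steady requires a steady system "
                          "(dt=None)")
    b = sys.load_vector(t)
    x = sys.solve_full(b)
    return sys.unpack(x, t)


def solve_transient(mesh: LabeledMesh, params: MPETParameters, keff,
                    tm: TransferModel, flux_bcs, t_end: float, dt: float,
                    initial: MPETState | None = None, bcs=None,
                    networks=NETWORKS, record_every: int = 1,
                    callback=None, p_ref=None):
    """Run backward-Euler from t=0 to t_end; returns recorded states.

    Default initial state: u = 0, all pressures at the venous baseline
    p_bp.  Deterministic: same inputs give bitwise-identical outputs.
    """
    if t_end <= 0 or dt <= 0:
        raise ModelError("t_end and dt must be positive")
    sys_ = assemble_system(mesh, params, keff, tm, dt, networks,
                           p_ref=p_ref)
    apply_boundary_conditions(sys_, mesh, params, flux_bcs, bcs=bcs)
    state = sys_.default_initial_state() if initial is None \
        else initial.copy()
    out = []
    n_steps = int(round(t_end / dt))
    for k in range(1, n_steps + 1):
        state = advance_step(sys_, state)
        if callback is not None:
            callback(state)
        if k % record_every == 0:
            out.append(state)
    return out, sys_
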