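"""Vectorized P1 tetrahedral finite-element kernels.

Continuous piecewise-linear elements for all fields (displacement is the
vector version, node-major dof ordering: dof(node n, comp c) = 3n + c).
All assembly routines return COO triplets or scipy.sparse matrices built
from exact per-element integrals (constant gradients on tets).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def element_geometry(nodes, tets):
    """Per-element volumes (M,) and shape-function gradients (M, 4, 3)."""
    x = nodes[tets]                       # (M, 4, 3)
    J = x[:, 1:] - x[:, :1]               # (M, 3, 3) rows are edge vectors
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    if (vol <= 0).any():
        raise ValueError("non-positive element volume encountered")
    Jinv = np.linalg.inv(J)               # (M, 3, 3)
    g = np.empty((len(tets), 4, 3))
    g[:, 1:] = Jinv.transpose(0, 2, 1)    # grad of barycentric 1..3
    g[:, 0] = -g[:, 1:].sum(axis=1)
    return vol, g


def _scatter(rows, cols, vals, shape):
    return sp.coo_matrix((vals.ravel(), (rows.ravel(), cols.ravel())),
                         shape=shape).tocsr()


def stiffness_matrix(nodes, tets, vol, grads, kappa):
    """Scalar Darcy stiffness: K[a,b] = sum_e vol_e g_a . (kappa_e g_b).

    kappa: per-element (M, 3, 3) tensor (already divided by viscosity or
    not, caller's choice of scaling).
    """
    kg = np.einsum("eij,ebj->ebi", kappa, grads)          # (M, 4, 3)
    ke = np.einsum("eai,ebi->eab", grads, kg) * vol[:, None, None]
    rows = np.repeat(tets[:, :, None], 4, axis=2)
    cols = np.repeat(tets[:, None, :], 4, axis=1)
    n = len(nodes)
    return _scatter(rows, cols, ke, (n, n))


def mass_matrix(nodes, tets, vol, coef=None):
    """Consistent P1 mass matrix: M[a,b] = vol (1 + delta_ab) / 20,
    optionally scaled by a per-element coefficient."""
    base = (np.ones((4, 4)) + np.eye(4)) / 20.0
    w = vol if coef is None else vol * coef
    me = base[None, :, :] * w[:, None, None]
    rows = np.repeat(tets[:, :, None], 4, axis=2)
    cols = np.repeat(tets[:, None, :], 4, axis=1)
    n = len(nodes)
    return _scatter(rows, cols, me, (n, n))


def elasticity_matrix(nodes, tets, vol, grads, G, lam):
    """Linear isotropic elasticity: int 2 G eps(u):eps(v) + lam div u div v.

    Entry (a i, b j) = vol [ lam g_a[i] g_b[j] + G (g_a[j] g_b[i]
    + delta_ij g_a . g_b) ].
    """
    gg = np.einsum("eai,ebi->eab", grads, grads)      # g_a . g_b
    term = lam * np.einsum("eai,ebj->eaibj", grads, grads)
    term += G * np.einsum("eaj,ebi->eaibj", grads, grads)
    term += G * np.einsum("eab,ij->eaibj", gg, np.eye(3))
    term *= vol[:, None, None, None, None]
    dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :])  # (M, 4, 3)
    rows = dof[:, :, :, None, None] * np.ones((1, 1, 1, 4, 3), dtype=int)
    cols = dof[:, None, None, :, :] * np.ones((1, 4, 3, 1, 1), dtype=int)
    n = 3 * len(nodes)
    return _scatter(rows.astype(np.int64), cols.astype(np.int64), term,
                    (n, n))


def divergence_matrix(nodes, tets, vol, grads):
    """Pressure-displacement coupling B[a, (b, j)] = int N_a dN_b/dx_j
    = vol/4 g_b[j].  Shape (n_nodes, 3 n_nodes)."""
    be = np.repeat((vol[:, None, None, None] / 4.0) * grads[:, None, :, :],
                   4, axis=1)                       # (M, 4a, 4b, 3)
    rows = np.repeat(tets[:, :, None, None], 4, axis=2) * \
        np.ones((1, 1, 1, 3), dtype=int)
    cols = (3 * tets[:, None, :, None] +
            np.arange(3)[None, None, None, :]) * \
        np.ones((1, 4, 1, 1), dtype=int)
    n = len(nodes)
    return _scatter(rows.astype(np.int64), cols.astype(np.int64), be,
                    (n, 3 * n))


def facet_geometry(nodes, facets):
    x = nodes[facets]
    nvec = 0.5 * np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    area = np.linalg.norm(nvec, axis=1)
    return area, nvec / area[:, None]


def boundary_load_vector(nodes, facets, values):
    """RHS from int_Gamma q phi ds with per-facet scalar q: area/3 per
    node.  values: scalar or (F,) array.  Returns (n_nodes,)."""
    area, _ = facet_geometry(nodes, facets)
    q = np.broadcast_to(np.asarray(values, dtype=float), area.shape)
    contrib = (q * area / 3.0)
    out = np.zeros(len(nodes))
    np.add.at(out, facets.ravel(),
              np.repeat(contrib[:, None], 3, axis=1).ravel())
    return out


def boundary_normal_vector(nodes, facets, normals=None):
    """c[(b, j)] = int_Gamma N_b n_j ds over the facet set; the weak-form
    coupling of a uniform normal traction/pressure.  Returns (3 n,)."""
    area, nrm = facet_geometry(nodes, facets)
    if normals is not None:
        nrm = normals
    contrib = (area[:, None] / 3.0) * nrm            # (F, 3)
    out = np.zeros(3 * len(nodes))
    for loc in range(3):
        idx = 3 * facets[:, loc][:, None] + np.arange(3)[None, :]
        np.add.at(out, idx.ravel(), contrib.ravel())
    return out


def element_gradients(p, tets, grads):
    """Per-element gradient of a P1 scalar field: (M, 3)."""
    return np.einsum("eai,ea->ei", grads, p[tets])


def element_divergence(u, tets, grads):
    """Per-element div of a P1 vector field u (n, 3): (M,)."""
    return np.einsum("eai,eai->e", grads, u[tets])


def element_means(p, tets):
    """Element averages of a nodal scalar field."""
    return p[tets].mean(axis=1)
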