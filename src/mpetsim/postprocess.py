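"""Derived fields and summary statistics from MPET solution series.

From the primitive fields (displacement u, pore pressures p_i) the
quantities of physiological interest are derived: per-network Darcy
(filtration) velocities v_i = -(k_i/mu_i) grad p_i — the CSF/ISF one is
"clearance", the arteriole/capillary one "blood perfusion" — the
increment of fluid content zeta_i = alpha_i div u + S_i (p_i - p_i,ref)
(positive = local fluid accumulation, negative = drainage), and the
intracranial pressure ICP, identified with the CSF/ISF pore pressure.

Internally everything is SI; report helpers convert to the units the
field's literature prints (mm/s for perfusion, cm/s for clearance, mmHg
for pressures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fem
from .core import MPETState
from .geometry import LabeledMesh
from .parameters import MPETParameters, NETWORKS

MMHG = 133.322              # Pa per mmHg


@dataclass
class DerivedFields:
    """Element-wise derived fields at one time level."""

    t: float
    darcy: dict              # network -> (M, 3), m/s
    zeta: dict               # network -> (M,), dimensionless
    icp: np.ndarray          # (N,), Pa (nodal, = p_e)
    disp_mag: np.ndarray     # (N,), m

    @property
    def clearance(self):
        return self.darcy["e"]

    @property
    def perfusion(self):
        return self.darcy["c"]


def darcy_velocity(state: MPETState, keff, mesh: LabeledMesh,
                   params: MPETParameters) -> dict:
    """Element-wise filtration velocity v_i = -(k_i/mu_i) grad p_i."""
    _, grads = fem.element_geometry(mesh.nodes, mesh.tets)
    out = {}
    for net, p in state.p.items():
        gp = fem.element_gradients(p, mesh.tets, grads)
        kappa = keff[net] / params.mu[net]
        out[net] = -np.einsum("eij,ej->ei", kappa, gp)
    return out


def fluid_content_increment(state: MPETState, params: MPETParameters,
                            mesh: LabeledMesh, p_ref=None) -> dict:
    """zeta_i = alpha_i div u + S_i (p_i - p_ref,i), element-wise.

    ``p_ref`` maps networks to the reference (initial equilibrium)
    pressure; default is the venous baseline p_bp for every network, the
    default initial condition of transient runs.
    """
    _, grads = fem.element_geometry(mesh.nodes, mesh.tets)
    divu = fem.element_divergence(state.u, mesh.tets, grads)
    out = {}
    for net, p in state.p.items():
        ref = params.p_bp if p_ref is None else p_ref[net]
        pbar = fem.element_means(p - ref, mesh.tets)
        out[net] = params.alpha[net] * divu + params.S[net] * pbar
    return out


def derive_fields(state: MPETState, keff, mesh: LabeledMesh,
                  params: MPETParameters, p_ref=None) -> DerivedFields:
    return DerivedFields(
        t=state.t,
        darcy=darcy_velocity(state, keff, mesh, params),
        zeta=fluid_content_increment(state, params, mesh, p_ref),
        icp=state.p["e"].copy(),
        disp_mag=np.linalg.norm(state.u, axis=1),
    )


def region_range(field_series, mesh: LabeledMesh, hemisphere,
                 times=None, window=None, in_mmhg=False) -> float:
    """max - min of an element-wise scalar field over one hemisphere.

    ``field_series``: array (T, n_elements) or a list of per-time arrays.
    ``window``: optional (t0, t1) restricting the reported time window
    (requires ``times``); the convention for pressure ranges is the last
    full simulated cycle.  ``in_mmhg`` converts a Pa-valued field.
    """
    arr = np.asarray(field_series, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    els = mesh.hemisphere_elements(hemisphere)
    if window is not None:
        if times is None:
            raise ValueError("window requires times")
        times = np.asarray(times)
        sel = (times >= window[0] - 1e-12) & (times <= window[1] + 1e-12)
        arr = arr[sel]
        if arr.size == 0:
            raise ValueError("window selects no time samples")
    sub = arr[:, els]
    rng = float(sub.max() - sub.min())
    return rng / MMHG if in_mmhg else rng


def peak_summary(derived_series) -> dict:
    """Global space-time extrema of the derived fields.

    Returns peak clearance and perfusion speed (m/s), peak displacement
    magnitude (m) and the extreme CSF/ISF fluid-content increments, each
    with the element (node for displacement) and time of occurrence.
    Ties break to the lowest index and earliest time.
    """
    if not derived_series:
        raise ValueError("empty series")

    def scan(extract, reduce="max"):
        best = None
        for d in derived_series:
            vals = extract(d)
            idx = int(np.argmax(vals)) if reduce == "max" \
                else int(np.argmin(vals))
            v = float(vals[idx])
            better = best is None or (v > best[0] if reduce == "max"
                                      else v < best[0])
            if better:
                best = (v, idx, d.t)
        return {"value": best[0], "index": best[1], "t": best[2]}

    return {
        "peak_clearance": scan(
            lambda d: np.linalg.norm(d.clearance, axis=1)),
        "peak_perfusion": scan(
            lambda d: np.linalg.norm(d.perfusion, axis=1)),
        "peak_displacement": scan(lambda d: d.disp_mag),
        "max_zeta_e": scan(lambda d: d.zeta["e"]),
        "min_zeta_e": scan(lambda d: d.zeta["e"], reduce="min"),
    }


def summary_frame(derived_series, mesh: LabeledMesh) -> pd.DataFrame:
    """Per-step scalar summaries (domain means and extrema) as a table."""
    vol = mesh.tet_volumes()
    vtot = vol.sum()
    rows = []
    for d in derived_series:
        row = {"t": d.t,
               "mean_disp": float(d.disp_mag.mean()),
               "max_disp": float(d.disp_mag.max()),
               "icp_min": float(d.icp.min()),
               "icp_max": float(d.icp.max())}
        for net in d.darcy:
            speed = np.linalg.norm(d.darcy[net], axis=1)
            row[f"mean_v_{net}"] = float((speed * vol).sum() / vtot)
            row[f"max_v_{net}"] = float(speed.max())
            row[f"max_zeta_{net}"] = float(d.zeta[net].max())
            row[f"min_zeta_{net}"] = float(d.zeta[net].min())
        rows.append(row)
    return pd.DataFrame(rows)


def export_fields(states, mesh: LabeledMesh, keff, params, path_prefix,
                  cadence: int = 1, p_ref=None):
    """Write VTK snapshots every ``cadence`` steps + a full summary CSV.

    Produces ``<prefix>_NNNN.vtk`` files carrying u, p_i (point data) and
    darcy_i, zeta_i (cell data), plus ``<prefix>_summary.csv`` with one
    row per state.  Returns the list of written VTK paths.
    """
    from .geometry import write_vtk_mesh
    written = []
    derived_all = []
    for k, st in enumerate(states):
        d = derive_fields(st, keff, mesh, params, p_ref)
        derived_all.append(d)
        if k % cadence != 0:
            continue
        pdata = {"u": st.u, "disp_mag": d.disp_mag}
        for net in st.p:
            pdata[f"p_{net}"] = st.p[net]
        pdata["icp"] = d.icp
        cdata = {}
        for net in d.darcy:
            cdata[f"darcy_{net}"] = d.darcy[net]
            cdata[f"zeta_{net}"] = d.zeta[net]
        out = f"{path_prefix}_{k:04d}.vtk"
        try:
            write_vtk_mesh(mesh, out, point_data=pdata, cell_data=cdata)
        except OSError as exc:
            raise OSError(f"cannot write field file {out}: {exc}") from exc
        written.append(out)
    summary_frame(derived_all, mesh).to_csv(f"{path_prefix}_summary.csv",
                                            index=False)
    return written
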