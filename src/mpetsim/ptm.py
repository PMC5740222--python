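"""Per-element anisotropic permeability tensor maps for the CSF/ISF network.

A permeability tensor map (PTM) assigns one dimensionless symmetric
positive-definite 3x3 tensor ``D_e`` to every tetrahedral element.  The
actual CSF/ISF permeability entering Darcy's law is the scalar base
permeability times this tensor, ``k_e,base * D_e``; the three blood
networks stay isotropic, ``k_i * I``.  In subject-specific work the map is
estimated from diffusion imaging (permeability and diffusion tensors
sharing the principal eigenvector); here a synthesizer generates maps with
a prescribed anisotropy ratio and orientation rule.  Synthetic tensors are
normalized to unit determinant so the (geometric) mean permeability is
unchanged by the anisotropy ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import LabeledMesh
from .parameters import MPETParameters, NETWORKS

_PTM_COLUMNS = ("element", "xx", "yy", "zz", "xy", "xz", "yz")


class PTMError(ValueError):
    """Raised for malformed or non-SPD tensor maps."""


@dataclass
class PermeabilityTensorMap:
    """Element-wise dimensionless SPD tensors, shape (n_elements, 3, 3)."""

    tensors: np.ndarray

    def __post_init__(self):
        self.tensors = np.ascontiguousarray(self.tensors, dtype=float)
        if self.tensors.ndim != 3 or self.tensors.shape[1:] != (3, 3):
            raise PTMError(f"tensors must have shape (n, 3, 3), got "
                           f"{self.tensors.shape}")

    @property
    def element_count(self) -> int:
        return self.tensors.shape[0]

    def validate(self, atol=1e-10):
        asym = np.abs(self.tensors - self.tensors.transpose(0, 2, 1)).max(
            axis=(1, 2))
        if (asym > atol).any():
            raise PTMError(f"tensor of element {int(np.argmax(asym))} is "
                           "not symmetric")
        eig = np.linalg.eigvalsh(0.5 * (self.tensors +
                                        self.tensors.transpose(0, 2, 1)))
        lam_min = eig[:, 0]
        if (lam_min <= 0).any():
            e = int(np.argmin(lam_min))
            raise PTMError(f"tensor of element {e} is not positive definite "
                           f"(smallest eigenvalue {lam_min[e]:.3g})")
        return self


def identity_ptm(n_elements: int) -> PermeabilityTensorMap:
    t = np.broadcast_to(np.eye(3), (n_elements, 3, 3)).copy()
    return PermeabilityTensorMap(t)


def load_ptm(path, mesh: LabeledMesh) -> PermeabilityTensorMap:
    """Load a PTM from CSV (columns element, xx, yy, zz, xy, xz, yz) or a
    legacy-VTK file carrying the six component arrays as tet cell data."""
    path = str(path)
    if path.endswith(".vtk"):
        from ._vtk import VTK_TETRA, read_vtk
        data = read_vtk(path)
        tet_ids = [i for i, t in enumerate(data["cell_types"])
                   if t == VTK_TETRA]
        comp = {}
        for name in _PTM_COLUMNS[1:]:
            key = f"ptm_{name}"
            if key not in data["cell_data"]:
                raise PTMError(f"{path}: missing cell array {key}")
            comp[name] = np.asarray(data["cell_data"][key], dtype=float)[
                tet_ids]
        n = len(tet_ids)
    else:
        df = pd.read_csv(path)
        missing = set(_PTM_COLUMNS) - set(df.columns)
        if missing:
            raise PTMError(f"{path}: missing columns {sorted(missing)}")
        df = df.sort_values("element")
        if not np.array_equal(df["element"].to_numpy(),
                              np.arange(len(df))):
            raise PTMError(f"{path}: element indices must be 0..n-1 without "
                           "gaps")
        comp = {name: df[name].to_numpy(dtype=float)
                for name in _PTM_COLUMNS[1:]}
        n = len(df)
    if n != mesh.n_elements:
        raise PTMError(f"{path}: {n} tensors for a mesh of "
                       f"{mesh.n_elements} elements")
    t = np.empty((n, 3, 3))
    t[:, 0, 0] = comp["xx"]; t[:, 1, 1] = comp["yy"]; t[:, 2, 2] = comp["zz"]
    t[:, 0, 1] = t[:, 1, 0] = comp["xy"]
    t[:, 0, 2] = t[:, 2, 0] = comp["xz"]
    t[:, 1, 2] = t[:, 2, 1] = comp["yz"]
    return PermeabilityTensorMap(t).validate()


def save_ptm(ptm: PermeabilityTensorMap, path) -> None:
    t = ptm.tensors
    pd.DataFrame({
        "element": np.arange(ptm.element_count),
        "xx": t[:, 0, 0], "yy": t[:, 1, 1], "zz": t[:, 2, 2],
        "xy": t[:, 0, 1], "xz": t[:, 0, 2], "yz": t[:, 1, 2],
    }).to_csv(path, index=False)


def _orthonormal_frames(e1):
    """Complete unit vectors e1 (n, 3) to right-handed orthonormal frames."""
    e1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
    helper = np.zeros_like(e1)
    smallest = np.argmin(np.abs(e1), axis=1)
    helper[np.arange(len(e1)), smallest] = 1.0
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=2)   # columns are the frame vectors


def synthesize_ptm(mesh: LabeledMesh, anisotropy_ratio: float,
                   orientation: str = "radial", seed: int = 0,
                   axis=(0.0, 0.0, 1.0)) -> PermeabilityTensorMap:
    """Synthetic PTM with eigenvalues (ratio, 1, 1) scaled to det = 1.

    ``orientation`` selects the principal-eigenvector rule: ``radial``
    (along the element-centroid radial direction, mimicking the
    predominantly radial white-matter tracts of a shell geometry),
    ``uniform-random`` (seeded isotropic random directions) or
    ``fixed-axis`` (a single global axis).  ``ratio=1`` returns exact
    identity tensors under every rule.
    """
    r = float(anisotropy_ratio)
    if r < 1.0:
        raise ValueError(f"anisotropy_ratio must be >= 1, got {r}")
    n = mesh.n_elements
    if r == 1.0:
        return identity_ptm(n)
    if orientation == "radial":
        e1 = mesh.tet_centroids()
        norms = np.linalg.norm(e1, axis=1)
        e1 = np.where(norms[:, None] > 0, e1, [[0.0, 0.0, 1.0]])
    elif orientation == "uniform-random":
        rng = np.random.default_rng(seed)
        e1 = rng.normal(size=(n, 3))
    elif orientation == "fixed-axis":
        e1 = np.broadcast_to(np.asarray(axis, dtype=float), (n, 3)).copy()
    else:
        raise ValueError(f"unknown orientation rule {orientation!r}")
    Q = _orthonormal_frames(e1)
    scale = r ** (-1.0 / 3.0)           # det(diag(r,1,1) * scale^3) = 1
    lam = np.array([r, 1.0, 1.0]) * scale
    t = np.einsum("nik,k,njk->nij", Q, lam, Q)
    t = 0.5 * (t + t.transpose(0, 2, 1))
    return PermeabilityTensorMap(t)


def effective_permeability(params: MPETParameters,
                           ptm: PermeabilityTensorMap | None,
                           mesh: LabeledMesh) -> dict:
    """Per-network element-wise permeability tensors (m^2).

    The CSF/ISF network gets ``k_e,base * D_e``; the blood networks are
    isotropic ``k_i * I``.  An absent map is the identity map, so both
    paths run through the same multiplication and agree bitwise.
    """
    n = mesh.n_elements
    if ptm is None:
        ptm = identity_ptm(n)
    if ptm.element_count != n:
        raise ValueError(f"PTM has {ptm.element_count} tensors for a mesh "
                         f"of {n} elements")
    eye = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    keff = {}
    for net in NETWORKS:
        base = ptm.tensors if net == "e" else eye
        keff[net] = params.k_base[net] * base
    return keff
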