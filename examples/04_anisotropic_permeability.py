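"""Effect of an anisotropic permeability tensor map on CSF/ISF clearance.

The CSF/ISF permeability is the scalar base value times a per-element
dimensionless SPD tensor (in subject-specific work derived from diffusion
imaging; here synthesized).  With radially oriented principal
eigenvectors — mimicking predominantly radial white-matter tracts —
clearance is channelled along the ventricle-to-cortex direction.
"""

import numpy as np

from mpetsim import (TransferModel, default_waveforms, derive_fields,
                     effective_permeability, generate_shell_mesh,
                     load_parameters, solve_transient, synthesize_ptm,
                     territory_fluxes)

mesh = generate_shell_mesh(0.03, 0.07, 1.0, resolution=(3, 3))
params = load_parameters()
tm = TransferModel.from_parameters(params)
waves = default_waveforms("control", "high", n_cycles=2)
fx = territory_fluxes(waves, mesh)

for ratio in (1.0, 10.0):
    ptm = synthesize_ptm(mesh, ratio, orientation="radial", seed=0)
    keff = effective_permeability(params, ptm, mesh)
    states, _ = solve_transient(mesh, params, keff, tm, fx, t_end=1.0,
                                dt=0.02)
    d = derive_fields(states[-1], keff, mesh, params)
    v = d.clearance
    rhat = mesh.tet_centroids()
    rhat /= np.linalg.norm(rhat, axis=1, keepdims=True)
    radial = np.abs(np.einsum("ei,ei->e", v, rhat))
    speed = np.linalg.norm(v, axis=1)
    frac = radial.sum() / max(speed.sum(), 1e-300)
    print(f"anisotropy ratio {ratio:4.0f}: peak clearance "
          f"{speed.max() * 1e2:.4f} cm/s, radial fraction {frac:.3f}")
# The radial fraction rises with the anisotropy ratio: the tensor map
# steers clearance along its principal (radial) eigenvector while the
# unit-determinant normalization keeps the mean permeability comparable.
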