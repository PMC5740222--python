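"""Scalar constants of the four-network poroelastic (MPET) system.

The model couples one linearly elastic solid matrix (brain parenchyma,
shear modulus ``G`` and Lamé constant ``lam``) with four communicating
fluid networks indexed ``a`` (arterial), ``c`` (arteriole/capillary),
``e`` (CSF/ISF) and ``v`` (venous).  Each network carries a Biot–Willis
coefficient ``alpha[i]``, a specific storage ``S[i]`` (m^2 N^-1), a scalar
base permeability ``k_base[i]`` (m^2) and a fluid viscosity ``mu[i]``
(Pa s).  Inter-network fluid exchange is governed by the four transfer
coefficients ``omega`` (m^2 N^-1 s^-1) on the directed pairs
a->c, c->v, c->e and e->v; exchange between the arterial and CSF/ISF
networks is structurally prohibited.

All values are strictly SI.  Defaults are the published reference set for
human parenchyma; viscosities are standard literature values for blood
(2.5e-3 Pa s) and CSF (1.0e-3 Pa s) because the reference table does not
print them.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field, asdict

import yaml

NETWORKS = ("a", "c", "e", "v")

#: Directed inter-network transfer pairs.  (a, e) is absent on purpose:
#: no direct arterial <-> CSF/ISF exchange.
TRANSFER_PAIRS = (("a", "c"), ("c", "v"), ("c", "e"), ("e", "v"))


class ParameterError(ValueError):
    """Raised for unknown keys or non-numeric values in a config."""


def _default_alpha():
    return {"a": 0.25, "c": 0.25, "e": 0.49, "v": 0.01}


def _default_S():
    return {"a": 2.9e-4, "c": 2.9e-4, "e": 3.9e-4, "v": 1.5e-5}


def _default_k():
    return {"a": 1.0e-10, "c": 1.0e-10, "e": 1.0e-10, "v": 1.0e-10}


def _default_mu():
    # blood networks vs CSF/ISF; not part of the published table
    return {"a": 2.5e-3, "c": 2.5e-3, "e": 1.0e-3, "v": 2.5e-3}


def _default_omega():
    return {"ac": 1.5e-19, "cv": 1.5e-19, "ev": 1.0e-13, "ce": 1.0e-20}


@dataclass
class MPETParameters:
    """Complete scalar parameter set of the MPET system (SI units)."""

    G: float = 216.0           # shear modulus, Pa
    lam: float = 505.0         # Lamé's first constant, Pa
    alpha: dict = field(default_factory=_default_alpha)   # Biot-Willis, -
    S: dict = field(default_factory=_default_S)           # storage, m^2/N
    k_base: dict = field(default_factory=_default_k)      # permeability, m^2
    mu: dict = field(default_factory=_default_mu)         # viscosity, Pa s
    omega: dict = field(default_factory=_default_omega)   # transfer, m^2/N/s
    phi: float = 0.2           # total porosity, -
    Q_p: float = 5.8e-9        # CSF production rate, m^3/s
    p_bp: float = 650.0        # venous baseline/back pressure, Pa
    R_drain: float = 8.5e13    # aqueduct drainage resistance constant, m^-3
    L_char: float = 70e-3      # characteristic length, m
    d_char: float = 3e-3       # characteristic diameter, m

    def alpha_sum(self) -> float:
        return float(sum(self.alpha[n] for n in NETWORKS))

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


_SCALAR_FIELDS = ("G", "lam", "phi", "Q_p", "p_bp", "R_drain",
                  "L_char", "d_char")
_DICT_FIELDS = {
    "alpha": NETWORKS,
    "S": NETWORKS,
    "k_base": NETWORKS,
    "mu": NETWORKS,
    "omega": tuple("".join(p) for p in TRANSFER_PAIRS),
}


def _check_number(key, value):
    if isinstance(value, bool) or not isinstance(value, numbers.Real):
        raise ParameterError(f"parameter {key!r}: non-numeric value {value!r}")
    return float(value)


def load_parameters(config=None) -> "MPETParameters":
    """Build a validated parameter set: defaults overridden by ``config``.

    ``config`` may be None, a mapping, or a path to a YAML file holding a
    flat mapping.  Dict-valued fields accept either a full/partial mapping
    (``alpha: {e: 0.3}``) or suffixed flat keys (``alpha_e: 0.3``).
    Unknown keys and non-numeric values raise :class:`ParameterError`; a
    set violating a hard invariant is rejected as well.
    """
    p = MPETParameters()
    if config is None:
        config = {}
    elif isinstance(config, (str, bytes)) or hasattr(config, "__fspath__"):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ParameterError(f"config must be a mapping, got {type(config)}")

    for key, value in config.items():
        if key in _SCALAR_FIELDS:
            setattr(p, key, _check_number(key, value))
            continue
        if key in _DICT_FIELDS:
            if not isinstance(value, dict):
                raise ParameterError(
                    f"parameter {key!r} expects a mapping of "
                    f"{_DICT_FIELDS[key]} entries")
            target = getattr(p, key)
            for sub, v in value.items():
                if sub not in _DICT_FIELDS[key]:
                    raise ParameterError(f"unknown entry {key}.{sub!r}")
                target[sub] = _check_number(f"{key}.{sub}", v)
            continue
        # flat suffixed form, e.g. alpha_e, omega_ev, k_base_a
        matched = False
        for base, subs in _DICT_FIELDS.items():
            if key.startswith(base + "_"):
                sub = key[len(base) + 1:]
                if sub in subs:
                    getattr(p, base)[sub] = _check_number(key, value)
                    matched = True
                break
        if not matched:
            raise ParameterError(f"unknown parameter key {key!r}")

    violations = validate_parameters(p)
    if violations:
        raise ParameterError("invalid parameter set: " + "; ".join(violations))
    return p


def validate_parameters(p: MPETParameters) -> list[str]:
    """Return a list of invariant-violation descriptions (empty iff valid).

    Checks positivity of the elastic, storage, permeability and viscosity
    constants, non-negativity of transfer/production/drainage constants,
    the per-network bound 0 <= alpha_i <= 1 and the admissibility
    constraint phi <= sum_i alpha_i <= 1.  Never raises.
    """
    out = []
    for name in ("G", "lam"):
        if getattr(p, name) <= 0:
            out.append(f"{name} must be > 0, got {getattr(p, name)}")
    for name, dct in (("S", p.S), ("k_base", p.k_base), ("mu", p.mu)):
        for n in NETWORKS:
            if n not in dct:
                out.append(f"{name}[{n}] missing")
            elif dct[n] <= 0:
                out.append(f"{name}[{n}] must be > 0, got {dct[n]}")
    for pair in _DICT_FIELDS["omega"]:
        w = p.omega.get(pair)
        if w is None:
            out.append(f"omega[{pair}] missing")
        elif w < 0:
            out.append(f"omega[{pair}] must be >= 0, got {w}")
    for name in ("Q_p", "R_drain"):
        if getattr(p, name) < 0:
            out.append(f"{name} must be >= 0, got {getattr(p, name)}")
    for n in NETWORKS:
        a = p.alpha.get(n)
        if a is None:
            out.append(f"alpha[{n}] missing")
        elif not (0.0 <= a <= 1.0):
            out.append(f"alpha[{n}] must lie in [0, 1], got {a}")
    if all(n in p.alpha for n in NETWORKS):
        s = p.alpha_sum()
        if s > 1.0 + 1e-12:
            out.append(f"alpha sum {s:.6g} exceeds 1")
        if s < p.phi - 1e-12:
            out.append(f"alpha sum {s:.6g} below total porosity {p.phi}")
    if not (0.0 <= p.phi <= 1.0):
        out.append(f"phi must lie in [0, 1], got {p.phi}")
    return out
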