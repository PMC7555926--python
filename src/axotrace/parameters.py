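"""Membrane parameters of the two-compartment myelinated-axon model.

The model lumps a motor axon into a node and an internode coupled by the
Barrett-Barrett pathway through and under the myelin sheath.  Every quantity
that the excitability fitting machinery may perturb -- maximal conductances,
the electrogenic Na+/K+-pump current, capacitances, gating kinetics -- lives
on :class:`AxonParameters`.

Unit system (self-consistent): potentials mV, time ms, current pA,
conductance nS, capacitance pF (pA = nS*mV and ms = pF/nS).  Outward
membrane current is positive; a depolarizing stimulus is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "RateSpec",
    "AxonParameters",
    "GATE_FAMILIES",
    "STATE_GATES",
    "default_parameters",
]

#: kinetic families; each has one alpha/beta rate pair and one Q10
GATE_FAMILIES = ("m", "h", "p", "s", "nf", "q")

#: gating state variables -> (kinetic family, compartment driving the gate)
#: node: transient Na (m, h), persistent Na (p), slow K (s_n), fast K (nf_n)
#: internode: slow K (s_i), fast K (nf_i), HCN (q)
STATE_GATES = {
    "m": ("m", "node"),
    "h": ("h", "node"),
    "p": ("p", "node"),
    "s_n": ("s", "node"),
    "s_i": ("s", "internode"),
    "nf_n": ("nf", "node"),
    "nf_i": ("nf", "internode"),
    "q": ("q", "internode"),
}

_RATE_FORMS = ("linoid", "sigmoid", "expg")


@dataclass(frozen=True)
class RateSpec:
    """One voltage-dependent rate function alpha(V) or beta(V), in 1/ms.

    Forms
    -----
    linoid   : A*(V-B)/(1-exp(-(V-B)/C)); the removable singularity at
               V == B takes its analytic limit A*C.  A decreasing linoid
               rate uses A < 0 together with C < 0 (so A*C > 0).
    sigmoid  : A/(1+exp(-(V-B)/C))
    expg     : A*exp((V-B)/C)
    """

    form: str
    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if self.form not in _RATE_FORMS:
            raise ValueError(f"unknown rate form {self.form!r}; expected one of {_RATE_FORMS}")
        if self.C == 0.0:
            raise ValueError("rate slope C must be nonzero")

    def __call__(self, V):
        V = np.asarray(V, dtype=float)
        u = (V - self.B) / self.C
        if self.form == "linoid":
            # A*C*u/(1-exp(-u)) with the u->0 limit A*C
            with np.errstate(over="ignore", under="ignore"):
                denom = -np.expm1(-u)
                safe = np.abs(u) > 1e-9
                out = np.where(
                    safe,
                    self.A * self.C * np.divide(u, np.where(safe, denom, 1.0)),
                    self.A * self.C * (1.0 + u / 2.0),
                )
        elif self.form == "sigmoid":
            with np.errstate(over="ignore"):
                out = self.A / (1.0 + np.exp(-u))
        else:  # expg
            with np.errstate(over="ignore"):
                out = self.A * np.exp(u)
        out = np.nan_to_num(out, nan=0.0, posinf=np.finfo(float).max / 1e6)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {"form": self.form, "A": self.A, "B": self.B, "C": self.C}

    @classmethod
    def from_dict(cls, d: dict) -> "RateSpec":
        return cls(form=d["form"], A=float(d["A"]), B=float(d["B"]), C=float(d["C"]))


def _default_rate_coeffs() -> dict:
    """Placeholder; real defaults ship in data/default_axon.yml."""
    raise RuntimeError("use default_parameters()")


@dataclass(frozen=True)
class AxonParameters:
    """Full parameter set of the node/internode axon model.

    Conductances are maximal values in nS, capacitances in pF, currents in
    pA and potentials in mV.  ``I_pump`` is the net outward Na+/K+-pump
    current; ``f_pump_node`` assigns a fraction of it to the nodal
    compartment (default: proportional to nodal share of capacitance).
    """

    # passive structure
    C_n: float
    C_i: float
    G_BB: float
    G_Lk_n: float
    G_Lk_i: float
    # nodal/internodal active conductances
    G_NaT: float
    f_NaP: float
    G_Ks_n: float
    G_Ks_i: float
    G_Kf_n: float
    G_Kf_i: float
    G_H: float
    # reversal potentials
    E_Na: float
    E_K: float
    E_H: float
    E_Lk: float
    # pump
    I_pump: float
    f_pump_node: float
    # temperature handling
    T: float = 37.0
    T_ref: float = 37.0
    q10: dict = field(default_factory=lambda: {g: 1.0 for g in GATE_FAMILIES})
    # voltage-dependent rate coefficients, per kinetic family
    rate_coeffs: dict = field(default_factory=_default_rate_coeffs)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for name in ("C_n", "C_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("G_NaT", "G_Ks_n", "G_Ks_i", "G_Kf_n", "G_Kf_i",
                     "G_H", "G_Lk_n", "G_Lk_i", "G_BB"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("f_NaP", "f_pump_node"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (self.E_K < self.E_Lk < self.E_Na):
            raise ValueError("reversal potentials must satisfy E_K < E_Lk < E_Na")
        missing = [g for g in GATE_FAMILIES if g not in self.rate_coeffs]
        if missing:
            raise ValueError(f"rate_coeffs missing families: {missing}")
        for fam, pair in self.rate_coeffs.items():
            for side in ("alpha", "beta"):
                if not isinstance(pair.get(side), RateSpec):
                    raise ValueError(f"rate_coeffs[{fam!r}][{side!r}] must be a RateSpec")

    # -- convenience -----------------------------------------------------
    def q10_factor(self, family: str) -> float:
        """Temperature scaling Q10**((T-T_ref)/10) for one kinetic family."""
        return float(self.q10[family]) ** ((self.T - self.T_ref) / 10.0)

    def pump_split(self) -> tuple[float, float]:
        """(nodal, internodal) pump current in pA."""
        return self.f_pump_node * self.I_pump, (1.0 - self.f_pump_node) * self.I_pump

    def with_changes(self, **changes) -> "AxonParameters":
        """Copy with scalar fields replaced (gating tables shared)."""
        return replace(self, **changes)

    # -- serialization ---------------------------------------------------
    _SCALARS = ("C_n", "C_i", "G_BB", "G_Lk_n", "G_Lk_i", "G_NaT", "f_NaP",
                "G_Ks_n", "G_Ks_i", "G_Kf_n", "G_Kf_i", "G_H",
                "E_Na", "E_K", "E_H", "E_Lk", "I_pump", "f_pump_node",
                "T", "T_ref")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self._SCALARS}
        d["q10"] = dict(self.q10)
        d["rate_coeffs"] = {
            fam: {side: spec.to_dict() for side, spec in pair.items()}
            for fam, pair in self.rate_coeffs.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AxonParameters":
        d = dict(d)
        rc = {
            fam: {side: RateSpec.from_dict(spec) for side, spec in pair.items()}
            for fam, pair in d.pop("rate_coeffs").items()
        }
        q10 = {k: float(v) for k, v in d.pop("q10").items()}
        return cls(rate_coeffs=rc, q10=q10, **{k: float(v) for k, v in d.items()})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, src) -> "AxonParameters":
        if hasattr(src, "read"):
            data = yaml.safe_load(src.read())
        else:
            with open(src) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def free_names(self) -> Iterator[str]:
        yield from self._SCALARS


def default_parameters() -> AxonParameters:
    """Packaged baseline parameter set (versioned config, see data/)."""
    ref = resources.files("axotrace.data").joinpath("default_axon.yml")
    with ref.open("r") as fh:
        return AxonParameters.from_yaml(fh)
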