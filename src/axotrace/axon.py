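"""Two-compartment active-membrane model of a myelinated motor axon.

A single node of Ranvier and its internode are coupled by the
Barrett-Barrett conductance through and under the myelin sheath.  The node
carries transient and persistent Na+ currents, slow and fast K+ currents
and leak; the internode carries slow/fast K+, HCN (h-current) and leak.
The Na+/K+ pump contributes a voltage-independent net outward current
split between the compartments.

The model always operates "unclamped": the resting state is re-solved
whenever parameters change, so that conductance or pump perturbations are
allowed to move the resting membrane potential, as threshold-tracking
model fitting requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import _kernels
from .errors import ConfigurationError, SolverError
from .parameters import GATE_FAMILIES, STATE_GATES, AxonParameters

__all__ = [
    "AxonState",
    "Trajectory",
    "AxonSim",
    "gating_rates",
    "steady_state_gates",
    "membrane_currents",
    "resting_state",
    "integrate",
]

#: order of gating states in the packed state vector (after V_n, V_i)
STATE_ORDER = ("m", "h", "p", "s_n", "s_i", "nf_n", "nf_i", "q")

_ALIASES = {"n_f": "nf_n", "n_f_n": "nf_n", "n_f_i": "nf_i"}


@dataclass(frozen=True)
class AxonState:
    """Instantaneous model state: compartment potentials (mV) and gates."""

    V_n: float
    V_i: float
    m: float
    h: float
    p: float
    s_n: float
    s_i: float
    nf_n: float
    nf_i: float
    q: float

    def __post_init__(self):
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            raise ValueError("non-finite axon state")
        gates = vec[2:]
        if np.any(gates < -1e-12) or np.any(gates > 1 + 1e-12):
            raise ValueError("gating variables must lie in [0, 1]")

    def to_vector(self) -> np.ndarray:
        return np.array([self.V_n, self.V_i] + [getattr(self, g) for g in STATE_ORDER])

    @classmethod
    def from_vector(cls, y) -> "AxonState":
        y = np.asarray(y, dtype=float)
        return cls(V_n=y[0], V_i=y[1], **{g: y[2 + i] for i, g in enumerate(STATE_ORDER)})


@dataclass
class Trajectory:
    """Densely sampled integration output."""

    t: np.ndarray          # ms
    y: np.ndarray          # (n, 10) state vectors

    @property
    def V_n(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def V_i(self) -> np.ndarray:
        return self.y[:, 1]

    def gate(self, name: str) -> np.ndarray:
        name = _ALIASES.get(name, name)
        return self.y[:, 2 + STATE_ORDER.index(name)]

    def final_state(self) -> AxonState:
        return AxonState.from_vector(self.y[-1])

    def state_at(self, t: float) -> AxonState:
        i = int(np.argmin(np.abs(self.t - t)))
        if abs(self.t[i] - t) > 1e-6:
            raise ValueError(f"time {t} ms not on the trajectory grid")
        return AxonState.from_vector(self.y[i])

    def to_dataframe(self):
        import pandas as pd

        cols = {"time_ms": self.t, "V_n_mV": self.V_n, "V_i_mV": self.V_i}
        for i, g in enumerate(STATE_ORDER):
            cols[g] = self.y[:, 2 + i]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ----------------------------------------------------------------------
# rate evaluation
# ----------------------------------------------------------------------

def _family_of(gate_id: str) -> str:
    gate_id = _ALIASES.get(gate_id, gate_id)
    if gate_id in STATE_GATES:
        return STATE_GATES[gate_id][0]
    if gate_id in GATE_FAMILIES:
        return gate_id
    raise ConfigurationError(f"unknown gate id {gate_id!r}")


def gating_rates(gate_id: str, V, params: AxonParameters):
    """alpha(V), beta(V) in 1/ms for one gate, Q10-scaled to params.T.

    Removable singularities of the linoid form are evaluated by their
    analytic limit, so the result is finite for any finite V.
    """
    fam = _family_of(gate_id)
    if not np.all(np.isfinite(np.asarray(V, dtype=float))):
        raise ValueError("V must be finite")
    scale = params.q10_factor(fam)
    pair = params.rate_coeffs[fam]
    return scale * pair["alpha"](V), scale * pair["beta"](V)


def steady_state_gates(V_n: float, V_i: float, params: AxonParameters) -> dict:
    """Gate steady-state values x_inf = alpha/(alpha+beta) at given potentials."""
    out = {}
    for g, (fam, comp) in STATE_GATES.items():
        v = V_n if comp == "node" else V_i
        a, b = gating_rates(fam, v, params)
        out[g] = a / (a + b)
    return out


# ----------------------------------------------------------------------
# currents
# ----------------------------------------------------------------------

def membrane_currents(state: AxonState, params: AxonParameters) -> dict:
    """Per-channel membrane currents in pA (outward positive).

    The coupling current is reported node->internode; it is internal and
    therefore excluded from the compartment totals' ionic bookkeeping
    identity checked by ``node_total``/``internode_total``.
    """
    p = params
    ip_n, ip_i = p.pump_split()
    na_t = p.G_NaT * state.m ** 3 * state.h * (state.V_n - p.E_Na)
    na_p = p.G_NaT * p.f_NaP * state.p ** 3 * (state.V_n - p.E_Na)
    ks_n = p.G_Ks_n * state.s_n * (state.V_n - p.E_K)
    kf_n = p.G_Kf_n * state.nf_n ** 4 * (state.V_n - p.E_K)
    lk_n = p.G_Lk_n * (state.V_n - p.E_Lk)
    ks_i = p.G_Ks_i * state.s_i * (state.V_i - p.E_K)
    kf_i = p.G_Kf_i * state.nf_i ** 4 * (state.V_i - p.E_K)
    ih = p.G_H * state.q * (state.V_i - p.E_H)
    lk_i = p.G_Lk_i * (state.V_i - p.E_Lk)
    coupling = p.G_BB * (state.V_n - state.V_i)
    out = {
        "Na_t": na_t, "Na_p": na_p, "Ks_n": ks_n, "Kf_n": kf_n,
        "Lk_n": lk_n, "pump_n": ip_n,
        "Ks_i": ks_i, "Kf_i": kf_i, "H": ih, "Lk_i": lk_i, "pump_i": ip_i,
        "coupling": coupling,
    }
    out["node_total"] = na_t + na_p + ks_n + kf_n + lk_n + ip_n
    out["internode_total"] = ks_i + kf_i + ih + lk_i + ip_i
    out["total"] = out["node_total"] + out["internode_total"]
    return out


# ----------------------------------------------------------------------
# rate tables + simulator
# ----------------------------------------------------------------------

_V_MIN, _V_MAX, _DV = -250.0, 100.0, 0.05


class _RateTables:
    """x_inf, alpha+beta and per-step decay factors on a fine voltage grid."""

    def __init__(self, params: AxonParameters, dt: float):
        self.v0 = _V_MIN
        self.dv = _DV
        self.dt = dt
        grid = np.arange(_V_MIN, _V_MAX + _DV / 2, _DV)
        n = grid.size
        self.xinf = np.empty((len(GATE_FAMILIES), n))
        self.rate = np.empty((len(GATE_FAMILIES), n))
        for i, fam in enumerate(GATE_FAMILIES):
            a, b = gating_rates(fam, grid, params)
            tot = np.maximum(a + b, 1e-12)
            self.xinf[i] = a / tot
            self.rate[i] = tot
        self.decay = np.exp(-self.rate * dt)


_TABLE_CACHE: dict = {}


def _tables_for(params: AxonParameters, dt: float) -> _RateTables:
    key = (
        tuple(sorted((f, s.form, s.A, s.B, s.C)
                     for f, pair in params.rate_coeffs.items()
                     for side, s in pair.items())),
        tuple(sorted(params.q10.items())), params.T, params.T_ref, dt,
    )
    tab = _TABLE_CACHE.get(key)
    if tab is None:
        tab = _RateTables(params, dt)
        if len(_TABLE_CACHE) > 32:
            _TABLE_CACHE.clear()
        _TABLE_CACHE[key] = tab
    return tab


def _consts(params: AxonParameters) -> np.ndarray:
    p = params
    ip_n, ip_i = p.pump_split()
    return np.array([
        p.C_n, p.C_i, p.G_NaT, p.f_NaP, p.G_Ks_n, p.G_Ks_i, p.G_Kf_n,
        p.G_Kf_i, p.G_H, p.G_Lk_n, p.G_Lk_i, p.G_BB,
        p.E_Na, p.E_K, p.E_H, p.E_Lk, ip_n, ip_i,
    ])


def _normalize_segments(stimulus, t0: float, t_end: float):
    """Piecewise-constant node stimulus -> (edges, amps) covering [t0, t_end]."""
    segs = sorted((float(a), float(b), float(amp)) for a, b, amp in (stimulus or []))
    edges = [t0]
    amps = []
    cur = t0
    for a, b, amp in segs:
        if b <= a:
            raise ValueError("stimulus segment must have positive duration")
        a, b = max(a, t0), min(b, t_end)
        if b <= a:
            continue
        if a < cur - 1e-12:
            raise ValueError("overlapping stimulus segments")
        if a > cur + 1e-12:
            edges.append(a)
            amps.append(0.0)
        edges.append(b)
        amps.append(amp)
        cur = b
    if cur < t_end - 1e-12:
        edges.append(t_end)
        amps.append(0.0)
    return np.asarray(edges), np.asarray(amps)


class AxonSim:
    """Reusable integrator bound to one parameter set.

    Builds the gating-rate tables once; repeated runs (threshold bisection,
    conditioning trajectories) then cost only the inner stepping loop.
    """

    def __init__(self, params: AxonParameters, dt: float = 0.01):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.params = params
        self.dt = dt
        self.tables = _tables_for(params, dt)
        self.consts = _consts(params)
        self._rest: AxonState | None = None

    # -- resting state ---------------------------------------------------
    def _residual(self, v):
        V_n, V_i = v
        gates = steady_state_gates(V_n, V_i, self.params)
        st = AxonState(V_n=V_n, V_i=V_i, **gates)
        cur = membrane_currents(st, self.params)
        return [cur["node_total"] + cur["coupling"],
                cur["internode_total"] - cur["coupling"]]

    def resting_state(self, tol: float = 1e-10) -> AxonState:
        """Solve the unclamped resting point (all derivatives ~ 0).

        Starts from several initial guesses and keeps the most
        hyperpolarized stable solution; raises SolverError when no
        subthreshold fixed point is found.
        """
        if self._rest is not None:
            return self._rest
        sols = []
        for v0 in (self.params.E_Lk, -80.0, -70.0, -90.0, -60.0):
            res = optimize.root(self._residual, [v0, v0], method="hybr",
                                options={"xtol": 1e-12})
            if res.success and np.all(np.isfinite(res.x)) and res.x[0] < -40.0:
                if max(abs(r) for r in self._residual(res.x)) < 1e-6:
                    sols.append(tuple(res.x))
        if not sols:
            raise SolverError(
                "resting-state solve failed: no subthreshold fixed point "
                f"(last residual {self._residual([self.params.E_Lk] * 2)})")
        V_n, V_i = min(sols, key=lambda s: s[0])
        gates = steady_state_gates(V_n, V_i, self.params)
        st = AxonState(V_n=V_n, V_i=V_i, **gates)
        # derivative check per contract: |dV/dt| < 1e-6 mV/ms
        cur = membrane_currents(st, self.params)
        dVn = -(cur["node_total"] + cur["coupling"]) / self.params.C_n
        dVi = -(cur["internode_total"] - cur["coupling"]) / self.params.C_i
        if abs(dVn) > 1e-6 or abs(dVi) > 1e-6:
            raise SolverError(f"resting state not converged: dV/dt=({dVn}, {dVi})")
        self._rest = st
        return st

    # -- integration -----------------------------------------------------
    def run(self, state0: AxonState, stimulus, t_end: float, t0: float = 0.0,
            record: bool = True, window=(np.inf, -np.inf),
            early_stop: bool = False):
        """Integrate from ``state0``; returns (Trajectory | None, vmax, y_end).

        ``window`` is the [lo, hi] time interval over which the maximum
        nodal potential is tracked (used for the action-potential
        criterion).
        """
        if t_end <= t0:
            raise ValueError("t_end must exceed t0")
        edges, amps = _normalize_segments(stimulus, t0, t_end)
        y = state0.to_vector().copy()
        if record:
            n_max = int(np.ceil((t_end - t0) / self.dt)) + len(amps) + 2
            rec_t = np.empty(n_max)
            rec_y = np.empty((n_max, 10))
        else:
            rec_t = np.empty(0)
            rec_y = np.empty((0, 10))
        tb = self.tables
        n_rec, vmax = _kernels.run_segments(
            y, t0, edges, amps, self.dt, tb.xinf, tb.rate, tb.decay,
            tb.v0, 1.0 / tb.dv, self.consts, rec_t, rec_y,
            float(window[0]), float(window[1]), early_stop)
        if not np.all(np.isfinite(y)):
            raise SolverError("non-finite state during integration")
        traj = Trajectory(rec_t[:n_rec], rec_y[:n_rec]) if record else None
        return traj, vmax, y


# ----------------------------------------------------------------------
# module-level convenience API
# ----------------------------------------------------------------------

def resting_state(params: AxonParameters) -> AxonState:
    """Unclamped resting state for a parameter set (solved fresh each call)."""
    return AxonSim(params).resting_state()


def integrate(state0: AxonState, params: AxonParameters, stimulus,
              t_end: float, dt_max: float = 0.01) -> Trajectory:
    """Integrate the model under a piecewise-constant nodal stimulus.

    ``stimulus`` is an iterable of (t_start, t_end, amplitude_pA) segments;
    gaps are zero current.  Sampling is uniform at ``dt_max``.
    """
    sim = AxonSim(params, dt=dt_max)
    traj, _, _ = sim.run(state0, stimulus, t_end)
    return traj
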