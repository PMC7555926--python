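"""Threshold-tracking protocols and scalar excitability indices.

Simulates the standard motor-nerve excitability battery against the
node/internode model: strength-duration behaviour, threshold electrotonus
(100 ms polarizing currents), the current-threshold (I/V) relationship
(200 ms currents) and the recovery cycle after a supramaximal conditioning
stimulus, with the minimum interstimulus interval at 2.5 ms.

In a single-axon model the response is all-or-none, so "threshold" is the
minimal 1-ms current that elicits an action potential (nodal potential
crossing 0 mV within 3 ms of test onset), located by bisection.  All
percentage quantities are expressed relative to the unconditioned control
threshold of the same run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axon import AxonSim, AxonState
from .errors import InexcitableError, ProtocolError, SpontaneousActivityError
from .parameters import AxonParameters

__all__ = [
    "ExcitabilityCurves",
    "ExcitabilityIndices",
    "ThresholdTracker",
    "ProtocolLattices",
    "fit_weiss",
    "run_all_protocols",
]


@dataclass(frozen=True)
class ProtocolLattices:
    """Config-exposed stimulus lattices (ms or % of control threshold)."""

    sd_durations: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    te_levels: tuple = (40.0, 20.0, -20.0, -40.0)
    te_delays: tuple = (1.5, 4.0, 7.0, 10.0, 13.0, 16.0, 20.0, 26.0, 33.0,
                        42.0, 60.0, 80.0, 100.0, 110.0, 130.0, 160.0, 200.0)
    te_duration: float = 100.0
    iv_levels: tuple = tuple(float(x) for x in range(50, -101, -10))
    iv_duration: float = 200.0
    rc_isis: tuple = (2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0, 7.0, 8.0, 10.0,
                      13.0, 18.0, 24.0, 32.0, 43.0, 56.0, 75.0, 100.0,
                      140.0, 200.0)
    subexc_window: tuple = (10.0, 100.0)
    ted_window: tuple = (10.0, 20.0)


@dataclass
class ExcitabilityCurves:
    """Per-paradigm excitability data; the currency compared by fitting.

    sd : (duration ms, threshold pA) pairs
    te : {conditioning level % -> (delay ms, threshold reduction %) pairs}
    iv : (conditioning level %, threshold reduction %) pairs
    rc : (interstimulus interval ms, threshold change %) pairs
    """

    sd: np.ndarray
    te: dict
    iv: np.ndarray
    rc: np.ndarray

    def __post_init__(self):
        self.sd = np.asarray(self.sd, dtype=float)
        self.iv = np.asarray(self.iv, dtype=float)
        self.rc = np.asarray(self.rc, dtype=float)
        self.te = {float(k): np.asarray(v, dtype=float) for k, v in self.te.items()}
        self.validate()

    def validate(self):
        for name, arr in (("sd", self.sd), ("iv", self.iv), ("rc", self.rc)):
            if arr.size and arr.ndim != 2:
                raise ValueError(f"{name} must be an (n, 2) array")
        for name, arr in [("sd", self.sd), ("rc", self.rc)] + [
                (f"te[{k}]", v) for k, v in self.te.items()]:
            if arr.size and np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError(f"{name} x-lattice must be strictly increasing")
        if self.rc.size and self.rc[0, 0] < 2.5 - 1e-9:
            raise ValueError("recovery-cycle ISIs must start at >= 2.5 ms")


@dataclass(frozen=True)
class ExcitabilityIndices:
    """Scalar summaries of the excitability battery.

    ted_10_20           mean depolarizing TE threshold reduction, 10-20 ms (%)
    resting_iv_slope    d(conditioning level)/d(threshold reduction) near rest
    refractoriness_2p5  recovery-cycle threshold change at 2.5 ms (%)
    superexcitability_5 threshold *reduction* at 5 ms (%; positive = more excitable)
    subexcitability     max late threshold increase, 10-100 ms (%; floored at 0)
    sdtc                strength-duration time constant (ms)
    rheobase            Weiss-law rheobase (pA)
    """

    ted_10_20: float
    resting_iv_slope: float
    refractoriness_2p5: float
    superexcitability_5: float
    subexcitability: float
    sdtc: float
    rheobase: float

    def as_dict(self) -> dict:
        return {
            "ted_10_20": self.ted_10_20,
            "resting_iv_slope": self.resting_iv_slope,
            "refractoriness_2p5": self.refractoriness_2p5,
            "superexcitability_5": self.superexcitability_5,
            "subexcitability": self.subexcitability,
            "sdtc": self.sdtc,
            "rheobase": self.rheobase,
        }


def fit_weiss(durations, thresholds):
    """Weiss-law reduction of a strength-duration curve.

    Regresses charge Q(t) = I(t)*t linearly on duration t; the slope is
    rheobase and intercept/slope the strength-duration time constant.
    Returns (sdtc_ms, rheobase_pA, r_squared).
    """
    t = np.asarray(durations, dtype=float)
    i = np.asarray(thresholds, dtype=float)
    q = i * t
    slope, intercept = np.polyfit(t, q, 1)
    resid = q - (slope * t + intercept)
    ss_tot = np.sum((q - q.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return intercept / slope, slope, r2


def _add_pulse(segments, onset, dur, amp):
    """Superimpose a rectangular pulse on non-overlapping segments."""
    pts = sorted({onset, onset + dur} | {e for s in segments for e in s[:2]})
    out = []
    for a, b in zip(pts[:-1], pts[1:]):
        mid = 0.5 * (a + b)
        level = sum(s[2] for s in segments if s[0] <= mid < s[1])
        if onset <= mid < onset + dur:
            level += amp
        out.append((a, b, level))
    # merge leading/trailing zero segments is unnecessary; keep explicit
    return out


class ThresholdTracker:
    """Runs the excitability battery for one parameter set.

    The unconditioned 1-ms control threshold T0 is established once at
    construction (unclamped: the resting state is re-solved first) and all
    conditioned thresholds are expressed relative to it.
    """

    def __init__(self, params: AxonParameters, dt: float = 0.01,
                 lattices: ProtocolLattices | None = None,
                 ap_window: float = 3.0, bracket_rtol: float = 0.005,
                 test_duration: float = 1.0, supramax_factor: float = 2.0,
                 upper_bound_factor: float = 50.0):
        self.params = params
        self.lat = lattices or ProtocolLattices()
        self.sim = AxonSim(params, dt=dt)
        self.ap_window = ap_window
        self.bracket_rtol = bracket_rtol
        self.test_duration = test_duration
        self.supramax_factor = supramax_factor
        self.upper_bound_factor = upper_bound_factor
        self.rest = self.sim.resting_state()
        self.T0 = self._threshold_from(self.rest, 0.0, [], 0.0, test_duration,
                                       hint=None)

    # -- core threshold search -------------------------------------------
    def _spikes(self, state0, t0, background, onset, dur, amp) -> bool:
        segs = _add_pulse(list(background), onset, dur, amp)
        t_end = onset + dur + self.ap_window
        _, vmax, _ = self.sim.run(state0, segs, t_end, t0=t0, record=False,
                                  window=(onset, t_end), early_stop=True)
        return vmax > 0.0

    def _threshold_from(self, state0, t0, background, onset, dur,
                        hint=None) -> float:
        """Bisection on test amplitude; returns the bracket midpoint."""
        if self._spikes(state0, t0, background, onset, dur, 0.0):
            raise SpontaneousActivityError(
                "action potential with zero test amplitude")
        scale = hint if hint is not None else (self.T0 if hasattr(self, "T0") else 100.0)
        cap = (self.upper_bound_factor * self.T0
               if hasattr(self, "T0") else 1e7)
        lo, hi = 0.0, scale
        while not self._spikes(state0, t0, background, onset, dur, hi):
            lo = hi
            hi *= 2.0
            if hi > cap:
                raise InexcitableError(
                    f"no action potential up to {hi:.3g} pA")
        while (hi - lo) > self.bracket_rtol * 0.5 * (hi + lo):
            mid = 0.5 * (lo + hi)
            if self._spikes(state0, t0, background, onset, dur, mid):
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    def find_threshold(self, duration: float, context=None) -> float:
        """Threshold current (pA) for a test pulse of ``duration`` ms.

        ``context`` optionally supplies (conditioning_segments, test_onset);
        conditioning is simulated from rest before the search.
        """
        if duration <= 0:
            raise ValueError("duration must be > 0")
        if context is None:
            return self._threshold_from(self.rest, 0.0, [], 0.0, duration)
        background, onset = context
        background = [tuple(map(float, s)) for s in background]
        if onset > 0:
            traj, _, y_end = self.sim.run(
                self.rest, [s for s in background if s[0] < onset],
                t_end=onset, record=False)
            state0 = AxonState.from_vector(y_end)
        else:
            state0 = self.rest
        remaining = [s for s in background if s[1] > onset]
        return self._threshold_from(state0, onset, remaining, onset, duration)

    # -- paradigms --------------------------------------------------------
    def run_strength_duration(self):
        """SD curve + (sdtc, rheobase, r2) via the Weiss-law regression."""
        durs = np.asarray(self.lat.sd_durations)
        thr = [self._threshold_from(self.rest, 0.0, [], 0.0, d,
                                    hint=self.T0 * self.test_duration / d)
               for d in durs]
        sdtc, rheo, r2 = fit_weiss(durs, thr)
        return np.column_stack([durs, thr]), sdtc, rheo, r2

    def _te_curve(self, level: float, delays) -> np.ndarray:
        amp = level / 100.0 * self.T0
        dur = self.lat.te_duration
        cond = [(0.0, dur, amp)]
        t_max = max(delays)
        traj, _, _ = self.sim.run(self.rest, cond, t_end=t_max, record=True)
        rows = []
        for d in delays:
            state_d = traj.state_at(d) if d > 0 else self.rest
            rem = [(d, dur, amp)] if d < dur else []
            thr = self._threshold_from(state_d, d, rem, d, self.test_duration)
            rows.append((d, 100.0 * (self.T0 - thr) / self.T0))
        return np.asarray(rows)

    def run_threshold_electrotonus(self, levels=None, delays=None):
        """TE curves per conditioning level + TEd 10-20 ms (from +40%)."""
        levels = self.lat.te_levels if levels is None else levels
        delays = self.lat.te_delays if delays is None else delays
        te = {float(lv): self._te_curve(lv, delays) for lv in levels}
        ted = self.ted_10_20(te)
        return te, ted

    def ted_10_20(self, te: dict) -> float:
        lo, hi = self.lat.ted_window
        curve = te[40.0]
        mask = (curve[:, 0] >= lo - 1e-9) & (curve[:, 0] <= hi + 1e-9)
        return float(curve[mask, 1].mean())

    def _iv_point(self, level: float) -> float:
        # the polarizing current stays on while the test pulse is delivered
        # at the end of the 200 ms conditioning
        amp = level / 100.0 * self.T0
        dur = self.lat.iv_duration
        _, _, y_end = self.sim.run(self.rest, [(0.0, dur, amp)], t_end=dur,
                                   record=False)
        state = AxonState.from_vector(y_end)
        tail = dur + self.test_duration + self.ap_window
        thr = self._threshold_from(state, dur, [(dur, tail, amp)], dur,
                                   self.test_duration)
        return 100.0 * (self.T0 - thr) / self.T0

    def run_current_threshold(self, levels=None):
        """I/V curve + resting slope from the +/-10% points.

        Points where the axon is inexcitable at the search bound are
        recorded as NaN; the resting slope uses only the +/-10% points.
        """
        levels = self.lat.iv_levels if levels is None else levels
        rows = []
        for lv in levels:
            if lv == 0.0:
                rows.append((0.0, 0.0))
                continue
            try:
                rows.append((lv, self._iv_point(lv)))
            except InexcitableError:
                if abs(lv) <= 10.0 + 1e-9:
                    raise
                rows.append((lv, np.nan))
        iv = np.asarray(sorted(rows), dtype=float)
        slope = self.resting_iv_slope(iv)
        return iv, slope

    def resting_iv_slope(self, iv: np.ndarray) -> float:
        tr = {lv: r for lv, r in iv}
        if 10.0 not in tr or -10.0 not in tr:
            raise ProtocolError("I/V curve lacks the +/-10% points")
        return float(20.0 / (tr[10.0] - tr[-10.0]))

    def _rc_conditioning(self):
        amp = self.supramax_factor * self.T0
        cond = [(0.0, self.test_duration, amp)]
        t_max = max(self.lat.rc_isis)
        traj, vmax, _ = self.sim.run(self.rest, cond, t_end=t_max,
                                     record=True, window=(0.0, 3.0))
        if vmax <= 0.0:
            raise ProtocolError("supramaximal conditioning failed to elicit "
                                "an action potential")
        return traj

    def run_recovery_cycle(self, isis=None):
        """RC curve + (refractoriness@2.5, superexcitability@5, subexcitability)."""
        isis = self.lat.rc_isis if isis is None else isis
        traj = self._rc_conditioning()
        rows = []
        for isi in isis:
            state = traj.state_at(isi)
            thr = self._threshold_from(state, isi, [], isi, self.test_duration)
            rows.append((isi, 100.0 * (thr - self.T0) / self.T0))
        rc = np.asarray(rows)
        return rc, *self.rc_indices(rc)

    def rc_indices(self, rc: np.ndarray):
        tc = {isi: v for isi, v in rc}
        if 2.5 not in tc or 5.0 not in tc:
            raise ProtocolError("recovery cycle must include 2.5 and 5 ms")
        lo, hi = self.lat.subexc_window
        late = rc[(rc[:, 0] >= lo - 1e-9) & (rc[:, 0] <= hi + 1e-9), 1]
        if late.size == 0:
            raise ProtocolError(
                f"no recovery-cycle points in the {lo}-{hi} ms "
                "subexcitability window")
        sub = max(0.0, float(late.max()))
        return float(tc[2.5]), float(-tc[5.0]), sub

    # -- aggregates -------------------------------------------------------
    def run_all(self):
        """Full battery -> (ExcitabilityCurves, ExcitabilityIndices)."""
        sd, sdtc, rheo, _ = self.run_strength_duration()
        te, ted = self.run_threshold_electrotonus()
        iv, slope = self.run_current_threshold()
        rc, refr, sup, sub = self.run_recovery_cycle()
        curves = ExcitabilityCurves(sd=sd, te=te, iv=iv, rc=rc)
        idx = ExcitabilityIndices(
            ted_10_20=ted, resting_iv_slope=slope, refractoriness_2p5=refr,
            superexcitability_5=sup, subexcitability=sub, sdtc=sdtc,
            rheobase=rheo)
        return curves, idx

    def indices(self) -> ExcitabilityIndices:
        """Scalar indices only, via reduced lattices (calibration fast path).

        Computes just the thresholds the indices are defined on: the
        depolarizing TE curve inside the TEd window, the +/-10% I/V points,
        and the recovery cycle at 2.5 ms, 5 ms and the subexcitability
        window.  Index values agree with ``run_all`` because those lattice
        points coincide.
        """
        lat = self.lat
        lo, hi = lat.ted_window
        delays = [d for d in lat.te_delays if lo - 1e-9 <= d <= hi + 1e-9]
        te = {40.0: self._te_curve(40.0, delays)}
        ted = self.ted_10_20(te)
        iv = np.asarray(sorted([(-10.0, self._iv_point(-10.0)),
                                (10.0, self._iv_point(10.0))]))
        slope = self.resting_iv_slope(iv)
        slo, shi = lat.subexc_window
        isis = sorted({2.5, 5.0} | {i for i in lat.rc_isis
                                    if slo - 1e-9 <= i <= shi + 1e-9})
        traj = self._rc_conditioning()
        rc = []
        for isi in isis:
            state = traj.state_at(isi)
            thr = self._threshold_from(state, isi, [], isi, self.test_duration)
            rc.append((isi, 100.0 * (thr - self.T0) / self.T0))
        refr, sup, sub = self.rc_indices(np.asarray(rc))
        sd, sdtc, rheo, _ = self.run_strength_duration()
        return ExcitabilityIndices(
            ted_10_20=ted, resting_iv_slope=slope, refractoriness_2p5=refr,
            superexcitability_5=sup, subexcitability=sub, sdtc=sdtc,
            rheobase=rheo)


def run_all_protocols(params: AxonParameters, **kwargs):
    """Convenience wrapper: full excitability battery for a parameter set."""
    return ThresholdTracker(params, **kwargs).run_all()
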