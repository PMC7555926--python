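"""Weighted least-squares fitting of membrane parameters to excitability data.

Two fitting modes mirror how threshold-tracking model studies proceed:

* **baseline calibration** -- the model is first fitted to the control
  group's excitability *indices* (group mean +/- SEM), because published
  group data are index tables;
* **curve fitting** -- from a calibrated baseline, one or more membrane
  parameters are re-optimized against *recorded curves* (threshold change
  vs. delay/interval per paradigm), minimizing the weighted discrepancy
  with paradigm weights 0.5 (strength-duration), 1 (threshold
  electrotonus), 1 (current-threshold) and 3 (recovery cycle).

The single-parameter scan ranks candidate membrane parameters by how much
of the discrepancy between two datasets each explains alone -- the
procedure behind attributing a group difference to the Na+/K+-pump
current.  Everything runs in unclamped mode: each candidate parameter set
re-solves its own resting potential before protocols are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ConfigurationError
from .parameters import AxonParameters
from .protocols import ExcitabilityCurves, ExcitabilityIndices, ThresholdTracker

__all__ = [
    "DiscrepancyWeights",
    "FitResult",
    "ScanResult",
    "discrepancy",
    "calibrate_baseline",
    "fit_parameters",
    "single_parameter_scan",
    "add_second_parameter",
    "ExcitabilityModel",
    "ExcitabilityFitResults",
    "DEFAULT_SCAN_CANDIDATES",
]

#: candidate membrane parameters for single-parameter scans
DEFAULT_SCAN_CANDIDATES = (
    "G_NaT", "f_NaP", "G_Ks_n", "G_Ks_i", "G_Kf_n", "G_Kf_i", "G_H",
    "G_BB", "G_Lk_n", "G_Lk_i", "I_pump", "C_i",
)


@dataclass(frozen=True)
class DiscrepancyWeights:
    """Per-paradigm weights of the discrepancy (defaults 0.5/1/1/3)."""

    w_sd: float = 0.5
    w_te: float = 1.0
    w_iv: float = 1.0
    w_rc: float = 3.0

    def __post_init__(self):
        w = (self.w_sd, self.w_te, self.w_iv, self.w_rc)
        if any(x < 0 for x in w):
            raise ValueError("weights must be non-negative")
        if not any(x > 0 for x in w):
            raise ValueError("at least one weight must be positive")


def _curve_sq_err(sim: np.ndarray, rec: np.ndarray, log_threshold: bool) -> float:
    if sim.shape != rec.shape or not np.allclose(sim[:, 0], rec[:, 0]):
        raise ValueError("simulated and recorded x-lattices differ; "
                         "resample before computing the discrepancy")
    if log_threshold:
        ys, yr = 100.0 * np.log10(sim[:, 1]), 100.0 * np.log10(rec[:, 1])
    else:
        ys, yr = sim[:, 1], rec[:, 1]
    ok = np.isfinite(ys) & np.isfinite(yr)
    if not np.any(ok):
        raise ValueError("no finite points in paradigm")
    return float(np.mean((ys[ok] - yr[ok]) ** 2))


def discrepancy(sim: ExcitabilityCurves, rec: ExcitabilityCurves,
                w: DiscrepancyWeights = DiscrepancyWeights()) -> float:
    """Weighted mean-squared discrepancy between two excitability datasets.

    D = sum_p w_p * mean_i (y_sim - y_rec)^2, where y is percentage
    threshold change for TE/IV/RC and 100*log10(threshold) for SD.  A
    pseudo-metric on curve space: non-negative, symmetric, zero iff the
    curves agree on the (shared) lattice.
    """
    d = 0.0
    if w.w_sd > 0:
        if sim.sd.size == 0 or rec.sd.size == 0:
            raise ValueError("empty sd paradigm with nonzero weight")
        d += w.w_sd * _curve_sq_err(sim.sd, rec.sd, log_threshold=True)
    if w.w_te > 0:
        if not sim.te or not rec.te:
            raise ValueError("empty te paradigm with nonzero weight")
        if set(sim.te) != set(rec.te):
            raise ValueError("te conditioning levels differ")
        errs = [_curve_sq_err(sim.te[k], rec.te[k], False) for k in sim.te]
        d += w.w_te * float(np.mean(errs))
    if w.w_iv > 0:
        if sim.iv.size == 0 or rec.iv.size == 0:
            raise ValueError("empty iv paradigm with nonzero weight")
        d += w.w_iv * _curve_sq_err(sim.iv, rec.iv, False)
    if w.w_rc > 0:
        if sim.rc.size == 0 or rec.rc.size == 0:
            raise ValueError("empty rc paradigm with nonzero weight")
        d += w.w_rc * _curve_sq_err(sim.rc, rec.rc, False)
    return d


@dataclass
class FitResult:
    """Outcome of one optimization run."""

    changed_parameters: dict          # name -> (baseline, fitted)
    discrepancy_before: float
    discrepancy_after: float
    converged: bool
    n_evaluations: int
    seed: int
    params: AxonParameters = None     # fitted parameter set

    @property
    def pct_reduction(self) -> float:
        if self.discrepancy_before <= 0:
            return 0.0
        return 100.0 * (self.discrepancy_before - self.discrepancy_after) \
            / self.discrepancy_before


@dataclass
class ScanResult:
    """Ranking of single-parameter fits, best (largest reduction) first."""

    ranking: list                     # [(name, best_value, pct_reduction)]
    fits: dict                        # name -> FitResult
    baseline: FitResult               # zero-change reference

    def __post_init__(self):
        self.ranking = sorted(self.ranking, key=lambda r: -r[2])

    @property
    def best(self) -> str:
        return self.ranking[0][0]


# ----------------------------------------------------------------------
# parameter transforms
# ----------------------------------------------------------------------

_LOG_PARAMS = {"G_NaT", "G_Ks_n", "G_Ks_i", "G_Kf_n", "G_Kf_i", "G_H",
               "G_BB", "G_Lk_n", "G_Lk_i", "C_n", "C_i"}
_PUMP_SCALE = 10.0      # pA per optimizer unit
_FRAC_SCALE = 0.01      # f_NaP units per optimizer unit
_LOG_SPAN = 3.0         # conductances searched within e^-3 .. e^+3 of baseline
_PUMP_SPAN = 15.0       # pump searched within +/-150 pA of baseline


class _Transform:
    """Maps an optimizer vector to an AxonParameters copy.

    Conductances and capacitances move multiplicatively (log-space, so
    positivity is structural); the pump current moves additively; f_NaP is
    box-bounded in [0, 1].
    """

    def __init__(self, baseline: AxonParameters, names):
        unknown = [n for n in names if n not in baseline._SCALARS]
        if unknown:
            raise ConfigurationError(f"unknown free parameters: {unknown}")
        self.baseline = baseline
        self.names = list(names)

    def x0(self) -> np.ndarray:
        return np.zeros(len(self.names))

    def bounds(self):
        out = []
        for n in self.names:
            if n in _LOG_PARAMS:
                out.append((-_LOG_SPAN, _LOG_SPAN))
            elif n == "I_pump":
                out.append((-_PUMP_SPAN, _PUMP_SPAN))
            elif n in ("f_NaP", "f_pump_node"):
                base = getattr(self.baseline, n)
                out.append(((0.0 - base) / _FRAC_SCALE,
                            (1.0 - base) / _FRAC_SCALE))
            else:
                out.append((-10.0, 10.0))
        return out

    def invert(self, values: dict) -> np.ndarray:
        """Optimizer coordinates for given parameter values (warm starts)."""
        x = self.x0()
        for i, n in enumerate(self.names):
            if n not in values:
                continue
            base = getattr(self.baseline, n)
            v = values[n]
            if n in _LOG_PARAMS:
                x[i] = math.log(v / base)
            elif n == "I_pump":
                x[i] = (v - base) / _PUMP_SCALE
            elif n in ("f_NaP", "f_pump_node"):
                x[i] = (v - base) / _FRAC_SCALE
            else:
                x[i] = v - base
        return x

    def apply(self, x) -> AxonParameters:
        changes = {}
        for n, v in zip(self.names, x):
            base = getattr(self.baseline, n)
            if n in _LOG_PARAMS:
                changes[n] = base * math.exp(float(np.clip(v, -_LOG_SPAN, _LOG_SPAN)))
            elif n == "I_pump":
                changes[n] = base + _PUMP_SCALE * float(v)
            elif n in ("f_NaP", "f_pump_node"):
                changes[n] = float(np.clip(base + _FRAC_SCALE * v, 0.0, 1.0))
            else:
                changes[n] = base + float(v)
        return self.baseline.with_changes(**changes)


# ----------------------------------------------------------------------
# objectives
# ----------------------------------------------------------------------

_INDEX_FIELDS = ("ted_10_20", "resting_iv_slope", "refractoriness_2p5",
                 "superexcitability_5", "subexcitability")


def _index_objective(params, targets: dict, scales: dict, tracker_opts) -> float:
    try:
        idx = ThresholdTracker(params, **tracker_opts).indices()
    except Exception:
        return 1e6
    tot = 0.0
    for k, target in targets.items():
        tot += ((getattr(idx, k) - target) / scales[k]) ** 2
    return tot


def simulate_on_lattices(params, rec: ExcitabilityCurves,
                         tracker_opts: dict | None = None) -> ExcitabilityCurves:
    """Simulate the battery on the x-lattices of ``rec`` (unclamped)."""
    tracker_opts = tracker_opts or {}
    tr = ThresholdTracker(params, **tracker_opts)
    sd_d = rec.sd[:, 0]
    thr = [tr._threshold_from(tr.rest, 0.0, [], 0.0, d,
                              hint=tr.T0 * tr.test_duration / d)
           for d in sd_d]
    te = {lv: tr._te_curve(lv, rec.te[lv][:, 0]) for lv in rec.te}
    iv = []
    for lv in rec.iv[:, 0]:
        if lv == 0.0:
            iv.append((0.0, 0.0))
            continue
        try:
            iv.append((lv, tr._iv_point(lv)))
        except Exception:
            iv.append((lv, np.nan))
    traj = tr._rc_conditioning()
    rc = []
    for isi in rec.rc[:, 0]:
        st = traj.state_at(isi)
        t = tr._threshold_from(st, isi, [], isi, tr.test_duration)
        rc.append((isi, 100.0 * (t - tr.T0) / tr.T0))
    return ExcitabilityCurves(sd=np.column_stack([sd_d, thr]), te=te,
                              iv=np.asarray(sorted(iv)), rc=np.asarray(rc))


def _curve_objective(params, rec, w, tracker_opts) -> float:
    try:
        sim = simulate_on_lattices(params, rec, tracker_opts)
        return discrepancy(sim, rec, w)
    except Exception:
        return 1e6


# ----------------------------------------------------------------------
# optimizers
# ----------------------------------------------------------------------

def _minimize(fun, transform: _Transform, seed: int, n_restarts: int,
              maxfev: int, jitter: float = 0.35, x_start=None):
    """Seeded multi-start Nelder-Mead; the first start is the baseline point
    (or the supplied warm start)."""
    rng = np.random.default_rng(seed)
    bounds = transform.bounds()
    best = None
    n_eval = 0
    for r in range(max(1, n_restarts)):
        if r == 0:
            x0 = transform.x0() if x_start is None else np.asarray(x_start, float)
        else:
            x0 = np.array([np.clip(rng.normal(0.0, jitter), lo, hi)
                           for lo, hi in bounds])
        if len(x0) == 1:
            # coarse bracket sweep, then bounded refinement: robust to the
            # small-scale structure a noisy objective has
            lo, hi = bounds[0]
            grid = np.linspace(lo, hi, 9)
            fg = [fun(np.array([v])) for v in grid]
            j = int(np.argmin(fg))
            g_lo = grid[max(j - 1, 0)]
            g_hi = grid[min(j + 1, len(grid) - 1)]
            res = optimize.minimize_scalar(
                lambda v: fun(np.array([v])), bounds=(g_lo, g_hi),
                method="bounded",
                options={"xatol": 2e-3, "maxiter": max(maxfev - 9, 8)})
            if res.fun <= fg[j]:
                x, f = np.array([res.x]), res.fun
            else:
                x, f = np.array([grid[j]]), fg[j]
            nev, ok = res.nfev + 9, res.success
        else:
            # explicit initial simplex: the default one degenerates at x=0
            step = 0.25
            simplex = [x0]
            for j in range(len(x0)):
                v = x0.copy()
                lo, hi = bounds[j]
                v[j] = v[j] + step if v[j] + step <= hi else v[j] - step
                simplex.append(v)
            res = optimize.minimize(
                fun, x0, method="Nelder-Mead", bounds=bounds,
                options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-4,
                         "adaptive": len(x0) > 4,
                         "initial_simplex": np.asarray(simplex)})
            x, f, nev, ok = res.x, res.fun, res.nfev, res.success
        n_eval += nev
        if best is None or f < best[1]:
            best = (x, f, ok)
        if len(x0) == 1:
            break  # bounded scalar search is deterministic; restarts add nothing
    return best[0], best[1], n_eval, best[2]


def calibrate_baseline(targets, free_params, seed: int = 0,
                       start: AxonParameters | None = None,
                       scales: dict | None = None, n_restarts: int = 3,
                       maxfev: int = 600, tracker_opts: dict | None = None):
    """Fit free membrane parameters to excitability-index targets.

    Parameters
    ----------
    targets : dict | ExcitabilityIndices
        Index name -> target value (group mean).
    free_params : sequence of str
        AxonParameters field names allowed to move.
    scales : dict, optional
        Index name -> scale (the printed SEM of each index); defaults to 1.
    seed : int
        Controls the multi-start jitter; the first start is always the
        unperturbed ``start`` parameter set, so results depend only weakly
        on the seed.

    Returns (fitted AxonParameters, FitResult).
    """
    if isinstance(targets, ExcitabilityIndices):
        targets = {k: v for k, v in targets.as_dict().items()
                   if k in _INDEX_FIELDS}
    start = start if start is not None else _default_params()
    scales = dict(scales or {k: 1.0 for k in targets})
    tracker_opts = tracker_opts or {}
    tf = _Transform(start, free_params)
    fun = lambda x: _index_objective(tf.apply(x), targets, scales, tracker_opts)
    f0 = fun(tf.x0())
    x, f, n_eval, ok = _minimize(fun, tf, seed, n_restarts, maxfev)
    if f > f0:
        x, f = tf.x0(), f0
    fitted = tf.apply(x)
    changed = {n: (getattr(start, n), getattr(fitted, n)) for n in tf.names}
    res = FitResult(changed_parameters=changed, discrepancy_before=f0,
                    discrepancy_after=f, converged=bool(ok or f < f0),
                    n_evaluations=n_eval, seed=seed, params=fitted)
    return fitted, res


def fit_parameters(baseline: AxonParameters, rec: ExcitabilityCurves,
                   free_params, w: DiscrepancyWeights = DiscrepancyWeights(),
                   seed: int = 0, n_restarts: int = 1, maxfev: int = 120,
                   tracker_opts: dict | None = None,
                   start_values: dict | None = None) -> FitResult:
    """Minimize the curve discrepancy over ``free_params`` from ``baseline``.

    The search is bounded (conductances stay positive via a log transform,
    f_NaP in [0, 1]) and deterministic for a given seed.  ``start_values``
    warm-starts selected free parameters (e.g. at a previous fit's optimum),
    which guarantees the nested fit is at least as good.
    """
    if not free_params:
        raise ValueError("free_params must be nonempty")
    tracker_opts = tracker_opts or {}
    tf = _Transform(baseline, free_params)
    fun = lambda x: _curve_objective(tf.apply(x), rec, w, tracker_opts)
    x_start = tf.invert(start_values) if start_values else None
    f0 = fun(x_start if x_start is not None else tf.x0())
    x, f, n_eval, ok = _minimize(fun, tf, seed, n_restarts, maxfev,
                                 x_start=x_start)
    if f > f0:     # never accept a fit worse than the starting point
        x, f = (x_start if x_start is not None else tf.x0()), f0
    fitted = tf.apply(x)
    changed = {n: (getattr(baseline, n), getattr(fitted, n)) for n in tf.names}
    return FitResult(changed_parameters=changed, discrepancy_before=f0,
                     discrepancy_after=f, converged=bool(ok or f <= f0),
                     n_evaluations=n_eval, seed=seed, params=fitted)


def single_parameter_scan(baseline: AxonParameters, rec: ExcitabilityCurves,
                          candidates=DEFAULT_SCAN_CANDIDATES,
                          w: DiscrepancyWeights = DiscrepancyWeights(),
                          seed: int = 0, maxfev: int = 40,
                          tracker_opts: dict | None = None) -> ScanResult:
    """Rank candidate parameters by single-parameter discrepancy reduction."""
    if not candidates:
        raise ValueError("candidates must be nonempty")
    fits = {}
    ranking = []
    for name in candidates:
        fr = fit_parameters(baseline, rec, [name], w=w, seed=seed,
                            maxfev=maxfev, tracker_opts=tracker_opts)
        fits[name] = fr
        _, val = fr.changed_parameters[name]
        ranking.append((name, val, fr.pct_reduction))
    d0 = next(iter(fits.values())).discrepancy_before
    base_fit = FitResult(changed_parameters={}, discrepancy_before=d0,
                         discrepancy_after=d0, converged=True,
                         n_evaluations=0, seed=seed, params=baseline)
    return ScanResult(ranking=ranking, fits=fits, baseline=base_fit)


def add_second_parameter(scan: ScanResult, baseline: AxonParameters,
                         rec: ExcitabilityCurves,
                         candidates=DEFAULT_SCAN_CANDIDATES,
                         w: DiscrepancyWeights = DiscrepancyWeights(),
                         seed: int = 0, maxfev: int = 150,
                         tracker_opts: dict | None = None) -> list:
    """Incremental percentage-point improvement of each second parameter
    added on top of the best single-parameter fit of ``scan``."""
    best = scan.best
    _, best_val = scan.fits[best].changed_parameters[best]
    out = []
    for name in candidates:
        if name == best:
            continue
        fr = fit_parameters(baseline, rec, [best, name], w=w, seed=seed,
                            maxfev=maxfev, tracker_opts=tracker_opts,
                            start_values={best: best_val})
        out.append((name, fr.pct_reduction - scan.fits[best].pct_reduction))
    return sorted(out, key=lambda r: -r[1])


def _default_params():
    from .parameters import default_parameters
    return default_parameters()


# ----------------------------------------------------------------------
# model / results objects
# ----------------------------------------------------------------------

class ExcitabilityModel:
    """Axon excitability model bound to recorded data.

    Construct from recorded curves (or index targets via
    :meth:`from_indices`) plus a baseline parameter set, then call
    :meth:`fit` or :meth:`scan`.
    """

    def __init__(self, recorded: ExcitabilityCurves | None,
                 baseline: AxonParameters | None = None,
                 weights: DiscrepancyWeights = DiscrepancyWeights()):
        self.recorded = recorded
        self.baseline = baseline if baseline is not None else _default_params()
        self.weights = weights
        self._index_targets = None
        self._index_scales = None

    @classmethod
    def from_indices(cls, targets: dict, scales: dict | None = None,
                     baseline: AxonParameters | None = None) -> "ExcitabilityModel":
        m = cls(recorded=None, baseline=baseline)
        m._index_targets = dict(targets)
        m._index_scales = dict(scales) if scales else {k: 1.0 for k in targets}
        return m

    def fit(self, free_params, seed: int = 0, **kw) -> "ExcitabilityFitResults":
        if self._index_targets is not None:
            _, fr = calibrate_baseline(
                self._index_targets, free_params, seed=seed,
                start=self.baseline, scales=self._index_scales, **kw)
        else:
            fr = fit_parameters(self.baseline, self.recorded, free_params,
                                w=self.weights, seed=seed, **kw)
        return ExcitabilityFitResults(self, fr)

    def scan(self, candidates=DEFAULT_SCAN_CANDIDATES, seed: int = 0,
             **kw) -> ScanResult:
        if self.recorded is None:
            raise ValueError("parameter scans require recorded curves")
        return single_parameter_scan(self.baseline, self.recorded,
                                     candidates, w=self.weights, seed=seed, **kw)


class ExcitabilityFitResults:
    """Fit results: parameter changes, discrepancies and diagnostics."""

    def __init__(self, model: ExcitabilityModel, fit: FitResult):
        self.model = model
        self.fit = fit
        self.params = fit.params

    @property
    def pct_reduction(self) -> float:
        return self.fit.pct_reduction

    def indices(self) -> ExcitabilityIndices:
        return ThresholdTracker(self.params).indices()

    def summary(self) -> str:
        fr = self.fit
        lines = [
            "Excitability model fit",
            "=" * 58,
            f"{'parameter':<14}{'baseline':>14}{'fitted':>14}{'change':>14}",
            "-" * 58,
        ]
        for n, (b, v) in fr.changed_parameters.items():
            lines.append(f"{n:<14}{b:>14.4g}{v:>14.4g}{v - b:>+14.4g}")
        lines += [
            "-" * 58,
            f"discrepancy before {fr.discrepancy_before:.6g}",
            f"discrepancy after  {fr.discrepancy_after:.6g}",
            f"reduction          {fr.pct_reduction:.1f}%",
            f"converged          {fr.converged}",
            f"evaluations        {fr.n_evaluations}",
            f"seed               {fr.seed}",
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Overlay recorded and fitted recovery-cycle curves."""
        import matplotlib.pyplot as plt

        rec = self.model.recorded
        if rec is None:
            raise ValueError("no recorded curves to plot against")
        sim = simulate_on_lattices(self.params, rec)
        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(rec.rc[:, 0], rec.rc[:, 1], "o", label="recorded")
        ax.semilogx(sim.rc[:, 0], sim.rc[:, 1], "-", label="fitted")
        ax.set_xlabel("interstimulus interval (ms)")
        ax.set_ylabel("threshold change (%)")
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.legend()
        return ax
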