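"""Metabolic indices, behavioural threshold estimation and cohort statistics.

Scalar computations used in diet-induced prediabetes studies of the rat:

* HOMA-IR: fasting insulin (mU/L) x fasting glucose (mmol/L) / 22.5
* TyG index: ln(fasting triglycerides (mg/dL) x fasting glucose (mg/dL) / 2)
* Lee index: body weight (g)^(1/3) / naso-anal length (cm); the exponent is
  configurable (0.33 is sometimes printed in place of 1/3)
* glucose-tolerance AUC: trapezoidal area of the excursion curve, mmol/L x min
* 50% paw-withdrawal threshold from a von Frey up-down response sequence
* Pearson/Spearman correlation with the exact t-transform p-value
* group comparison gated on Shapiro-Wilk normality (t-test vs Mann-Whitney U)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import SequenceError

__all__ = [
    "RatRecord",
    "CorrelationResult",
    "GroupComparison",
    "homa_ir",
    "tyg_index",
    "lee_index",
    "gtt_auc",
    "pearson_p_from_r",
    "pearson_test",
    "spearman_test",
    "compare_groups",
    "VON_FREY_FILAMENTS",
    "vonfrey_50pwt",
    "probit_mle_50pwt",
    "validate_updown_sequence",
]

#: the 10-filament von Frey set spanning 0.4-15 g, started at 2 g
VON_FREY_FILAMENTS = (0.4, 0.6, 1.0, 1.4, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0)

GTT_MINUTES = (0, 15, 30, 45, 60, 90, 120, 180)


@dataclass
class RatRecord:
    """One animal's metabolic, behavioural and electrophysiological data.

    Units: masses g, lengths cm, glucose mmol/L, insulin mU/L, leptin
    ng/mL, triglycerides and HDL mg/dL, cytokines pg/mL, SNAP uV,
    superexcitability %.
    """

    id: str
    group: str                       # "chow" | "CAF"
    body_weight: float = np.nan
    fat_mass: float = np.nan
    lean_mass: float = np.nan
    naso_anal_length: float = np.nan
    rpWAT: float = np.nan
    liver_weight: float = np.nan
    FBG: float = np.nan
    insulin: float = np.nan
    leptin: float = np.nan
    triglycerides: float = np.nan
    HDL: float = np.nan
    TNF_alpha: float = np.nan
    IL6: float = np.nan
    SNAP: float = np.nan
    superexcitability: float = np.nan
    gtt: list = field(default_factory=list)       # [(minute, mmol/L)]
    vonfrey: list = field(default_factory=list)   # [(filament g, bool)]

    def __post_init__(self):
        if self.group not in ("chow", "CAF"):
            raise ValueError(f"unknown group {self.group!r}")
        for minute, _ in self.gtt:
            if minute not in GTT_MINUTES:
                raise ValueError(f"GTT minute {minute} not in {GTT_MINUTES}")


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    n: int
    p: float

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")


@dataclass(frozen=True)
class GroupComparison:
    test: str                        # "t" | "mannwhitney"
    statistic: float
    p: float
    shapiro_p_a: float
    shapiro_p_b: float


# ----------------------------------------------------------------------
# metabolic indices (pure functions)
# ----------------------------------------------------------------------

def homa_ir(insulin: float, fbg: float) -> float:
    """Homeostatic model assessment of insulin resistance."""
    if insulin < 0 or fbg < 0:
        raise ValueError("insulin and glucose must be non-negative")
    return insulin * fbg / 22.5


def tyg_index(tg: float, glucose: float) -> float:
    """Triglyceride-glucose index, both inputs in mg/dL."""
    if tg <= 0 or glucose <= 0:
        raise ValueError("triglycerides and glucose must be positive")
    return math.log(tg * glucose / 2.0)


def lee_index(weight: float, length: float, exponent: float = 1.0 / 3.0) -> float:
    """Rodent adiposity index weight^exponent / naso-anal length."""
    if weight <= 0 or length <= 0:
        raise ValueError("weight and length must be positive")
    return weight ** exponent / length


def gtt_auc(curve) -> float:
    """Trapezoidal area under a glucose-excursion curve, mmol/L x min."""
    arr = np.asarray(sorted(curve), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (minute, glucose) points")
    if np.any(arr[:, 1] < 0):
        raise ValueError("glucose must be non-negative")
    return float(np.trapezoid(arr[:, 1], arr[:, 0]))


# ----------------------------------------------------------------------
# correlations
# ----------------------------------------------------------------------

def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a correlation via t = r*sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return np.finfo(float).tiny
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _corr(x, y, method: str) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if method == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    r = float(np.clip(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy), -1, 1))
    return CorrelationResult(method=method, r=r, n=n, p=max(
        pearson_p_from_r(r, n), np.finfo(float).tiny))


def pearson_test(x, y) -> CorrelationResult:
    """Pearson correlation with the exact t-transform two-sided p."""
    return _corr(x, y, "pearson")


def spearman_test(x, y) -> CorrelationResult:
    """Spearman correlation: Pearson on midranks, t-transform p."""
    return _corr(x, y, "spearman")


# ----------------------------------------------------------------------
# group comparison
# ----------------------------------------------------------------------

def compare_groups(a, b, alpha_norm: float = 0.05) -> GroupComparison:
    """Two-group comparison gated on Shapiro-Wilk normality.

    Both groups normal at ``alpha_norm`` -> unpaired two-sided t-test;
    otherwise Mann-Whitney U (midranks for ties).  Degenerate
    (zero-variance) groups are routed to Mann-Whitney.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")

    def _shapiro_p(v):
        if np.ptp(v) == 0:
            return 0.0     # constant data: not plausibly normal
        return float(stats.shapiro(v).pvalue)

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa > alpha_norm and pb > alpha_norm:
        res = stats.ttest_ind(a, b)
        return GroupComparison("t", float(res.statistic), float(res.pvalue),
                               pa, pb)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison("mannwhitney", float(res.statistic),
                           float(res.pvalue), pa, pb)


# ----------------------------------------------------------------------
# von Frey up-down 50% paw-withdrawal threshold
# ----------------------------------------------------------------------

def validate_updown_sequence(sequence, filament_set=VON_FREY_FILAMENTS,
                             start: float = 2.0) -> list:
    """Check a response sequence against the up-down rule.

    Starts at the 2 g filament; a positive response steps to the next
    lighter filament, a negative response to the next heavier; testing
    stops after four further stimuli once the response first changes, or
    at either end of the filament set.  Returns [(index, response)] with
    indices into ``filament_set``.
    """
    fils = sorted(filament_set)
    if len(sequence) == 0:
        raise SequenceError("empty response sequence")
    try:
        i = fils.index(start)
    except ValueError:
        raise SequenceError(f"starting filament {start} g not in the set")
    out = []
    first_change = None
    for k, (f, resp) in enumerate(sequence):
        if abs(fils[i] - f) > 1e-9:
            raise SequenceError(
                f"presentation {k + 1}: expected {fils[i]} g, got {f} g")
        resp = bool(resp)
        out.append((i, resp))
        if first_change is None and k > 0 and resp != out[k - 1][1]:
            first_change = k
        done = (first_change is not None and k - first_change >= 4)
        at_edge = (resp and i == 0) or (not resp and i == len(fils) - 1)
        last = k == len(sequence) - 1
        if last:
            if not (done or at_edge):
                raise SequenceError(
                    "sequence ended before four post-change stimuli or a "
                    "boundary filament was reached")
            break
        if done or at_edge:
            raise SequenceError("sequence continues past its stopping rule")
        i = i - 1 if resp else i + 1
    return out


def _nll_probit(theta, xs, resps, sigma):
    z = (xs - theta) / sigma
    p = stats.norm.cdf(z)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(np.where(resps, np.log(p), np.log(1 - p)))


def probit_mle_50pwt(sequence, filament_set=VON_FREY_FILAMENTS) -> float:
    """50% threshold by brute-force probit maximum likelihood.

    Assumes P(withdrawal | force g) = Phi((log10 g - log10 theta)/sigma)
    with sigma equal to the mean log-spacing of the filament set; maximizes
    the sequence likelihood over log10(theta) on a fine grid plus local
    refinement.  This estimator defines the pattern coefficients used by
    :func:`vonfrey_50pwt` and is exposed as an alternative estimator.
    """
    fils = np.log10(np.asarray(sorted(filament_set), dtype=float))
    sigma = float(np.mean(np.diff(fils)))
    xs = np.array([math.log10(f) for f, _ in sequence])
    resps = np.array([bool(r) for _, r in sequence])
    if resps.all() or (~resps).all():
        # monotone likelihood: MLE sits at a boundary
        return float(10 ** fils[0]) if resps.all() else float(10 ** fils[-1])
    lo, hi = fils[0] - 2 * sigma, fils[-1] + 2 * sigma
    grid = np.linspace(lo, hi, 600)
    nll = np.array([_nll_probit(t, xs, resps, sigma) for t in grid])
    t0 = grid[int(np.argmin(nll))]
    res = optimize.minimize_scalar(
        _nll_probit, bounds=(max(lo, t0 - 0.1), min(hi, t0 + 0.1)),
        args=(xs, resps, sigma), method="bounded",
        options={"xatol": 1e-7})
    theta = float(10 ** res.x)
    return float(np.clip(theta, 10 ** fils[0], 10 ** fils[-1]))


#: pattern -> k coefficient cache for the table-based estimator
_K_TABLE: dict = {}


def vonfrey_50pwt(sequence, filament_set=VON_FREY_FILAMENTS,
                  method: str = "table") -> float:
    """50% paw-withdrawal threshold (g) from an up-down response sequence.

    Boundary rules: continuous positive responses down to the weakest
    filament are assigned the weakest force (0.4 g for the default set);
    continuous negative responses up to the strongest are assigned the
    strongest (15 g).  Interior patterns use 10**(x_f + k*delta), where
    x_f is log10 of the final filament, delta the mean log10 filament
    spacing, and k the pattern coefficient derived from the probit
    maximum-likelihood oracle (the table is generated on first use and
    cached per pattern).  ``method="probit"`` returns the oracle value
    directly.
    """
    idxs = validate_updown_sequence(sequence, filament_set)
    fils = sorted(filament_set)
    responses = [r for _, r in idxs]
    if all(responses) and idxs[-1][0] == 0:
        return float(fils[0])
    if not any(responses) and idxs[-1][0] == len(fils) - 1:
        return float(fils[-1])
    if method == "probit":
        return probit_mle_50pwt(sequence, filament_set)
    if method != "table":
        raise ValueError("method must be 'table' or 'probit'")
    logf = np.log10(np.asarray(fils, dtype=float))
    delta = float(np.mean(np.diff(logf)))
    x_f = math.log10(sequence[-1][0])
    key = (tuple(filament_set), tuple(idxs))
    if key not in _K_TABLE:
        theta = probit_mle_50pwt(sequence, filament_set)
        _K_TABLE[key] = (math.log10(theta) - x_f) / delta
    k = _K_TABLE[key]
    return float(np.clip(10 ** (x_f + k * delta), fils[0], fils[-1]))
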