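"""Seeded synthetic rat cohorts with the statistical structure the
analysis pipeline assumes.

Two diet groups (chow control vs. cafeteria/CAF) are drawn from
multivariate normals whose group means and SDs default to the study-scale
summary statistics of a 13-15 week cafeteria-diet experiment (SD
reconstructed from SEM at n = 14/group).  Pairwise correlation targets
between superexcitability and metabolic measures are *pooled-cohort*
correlations; the generator solves for the within-group correlation that
reproduces each pooled target given the configured group separation, then
repairs the within-group matrix to the nearest positive semi-definite one
(the repair, if any, is logged).

Per-rat glucose-tolerance curves, probit-governed von Frey up-down
response sequences and noisy "recorded" excitability curves complete the
pipeline inputs, so every analysis stage can run without any download.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .parameters import AxonParameters
from .protocols import ExcitabilityCurves, ThresholdTracker
from .studystats import GTT_MINUTES, VON_FREY_FILAMENTS, RatRecord

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "generate_gtt",
    "generate_vonfrey_sequence",
    "generate_recorded_excitability",
]

log = logging.getLogger(__name__)

_SQRT_N = math.sqrt(14.0)

#: group (mean, SD) per metabolic field; SD = printed SEM * sqrt(14) where
#: a group summary exists, otherwise study-scale values chosen for realism
DEFAULT_FIELD_STATS = {
    #                     chow                CAF
    "body_weight":      ((548.0, 11.0 * _SQRT_N), (765.0, 26.0 * _SQRT_N)),
    "fat_mass":         ((80.0, 18.0),            (210.0, 45.0)),
    "lean_mass":        ((420.0, 25.0),           (505.0, 35.0)),
    "naso_anal_length": ((26.7, 0.3 * _SQRT_N),   (28.2, 0.2 * _SQRT_N)),
    "rpWAT":            ((4.0, 0.4 * _SQRT_N),    (14.3, 1.2 * _SQRT_N)),
    "liver_weight":     ((14.1, 0.4 * _SQRT_N),   (18.9, 0.7 * _SQRT_N)),
    "FBG":              ((5.0, 0.1 * _SQRT_N),    (5.5, 0.1 * _SQRT_N)),
    "insulin":          ((4.0, 1.4),              (11.0, 3.5)),
    "leptin":           ((2.1, 0.4 * _SQRT_N),    (5.7, 0.5 * _SQRT_N)),
    "triglycerides":    ((116.0, 7.3 * _SQRT_N),  (157.0, 9.5 * _SQRT_N)),
    "HDL":              ((58.23, 2.61 * _SQRT_N), (40.93, 1.80 * _SQRT_N)),
    "TNF_alpha":        ((1418.0, 115.0 * 3.0),   (2761.0, 563.0 * 3.0)),
    "IL6":              ((891.0, 52.2 * math.sqrt(11)), (1173.1, 143.4 * _SQRT_N)),
    "SNAP":             ((19.06, 1.73 * _SQRT_N), (19.91, 2.64 * _SQRT_N)),
    "superexcitability": ((-0.65, 0.68 * _SQRT_N), (2.14, 0.83 * _SQRT_N)),
}

#: pooled-cohort correlation targets with superexcitability
DEFAULT_CORR_TARGETS = {
    ("superexcitability", "fat_mass"): 0.497,
    ("superexcitability", "body_weight"): 0.483,
    ("superexcitability", "lean_mass"): 0.469,
    ("superexcitability", "HDL"): -0.495,
    ("superexcitability", "leptin"): 0.484,
    ("superexcitability", "rpWAT"): 0.506,
    # adiposity block is closely interrelated
    ("fat_mass", "body_weight"): 0.90,
    ("fat_mass", "lean_mass"): 0.88,
    ("body_weight", "lean_mass"): 0.92,
}

#: glucose excursion: baseline + A*(t/t_peak)*exp(1 - t/t_peak)
DEFAULT_GTT_SHAPE = {
    "chow": {"amplitude": 4.0, "t_peak": 30.0, "noise_sd": 0.3},
    "CAF":  {"amplitude": 6.0, "t_peak": 45.0, "noise_sd": 0.3},
}

#: latent log10 paw-withdrawal threshold (g) and psychometric slope
DEFAULT_VONFREY = {
    "chow": {"log_theta_mean": math.log10(3.0), "log_theta_sd": 0.22},
    "CAF":  {"log_theta_mean": math.log10(4.0), "log_theta_sd": 0.22},
    "sigma": 0.2,
}


@dataclass
class CohortConfig:
    """Generative settings for a two-group synthetic cohort."""

    n_per_group: int = 14
    field_stats: dict = field(default_factory=lambda: dict(DEFAULT_FIELD_STATS))
    corr_targets: dict = field(default_factory=lambda: dict(DEFAULT_CORR_TARGETS))
    gtt_shape: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_GTT_SHAPE.items()})
    vonfrey: dict = field(default_factory=lambda: {
        k: (dict(v) if isinstance(v, dict) else v)
        for k, v in DEFAULT_VONFREY.items()})
    excitability_noise_sd: float = 1.0    # % multiplicative log-threshold noise
    seed: int = 0
    #: set after generation: realized within-group correlation matrix
    realized_correlation: np.ndarray | None = None
    corr_fields: tuple = ()

    def __post_init__(self):
        if self.n_per_group < 0:
            raise ValueError("n_per_group must be >= 0")
        for name, (c, k) in self.field_stats.items():
            if c[1] <= 0 or k[1] <= 0:
                raise ValueError(f"SD for {name} must be positive")


def _within_correlation(cfg: CohortConfig):
    """Solve for within-group correlations hitting the pooled targets.

    For equal-size groups the pooled covariance decomposes as
    cov_pool = cov_within + (dx/2)(dy/2) where d is the between-group mean
    difference; given target pooled correlations this is inverted for the
    within-group correlation, clipped into (-0.95, 0.95) with a log
    message if the target is unattainable.
    """
    names = sorted({n for pair in cfg.corr_targets for n in pair})
    k = len(names)
    idx = {n: i for i, n in enumerate(names)}
    corr = np.eye(k)
    for (a, b), r_pool in cfg.corr_targets.items():
        (ca, kaf), (cb, kbf) = cfg.field_stats[a], cfg.field_stats[b]
        da, db = (kaf[0] - ca[0]) / 2.0, (kbf[0] - cb[0]) / 2.0
        var_wa = (ca[1] ** 2 + kaf[1] ** 2) / 2.0
        var_wb = (cb[1] ** 2 + kbf[1] ** 2) / 2.0
        cov_b = da * db
        cov_needed = r_pool * math.sqrt((var_wa + da * da) * (var_wb + db * db)) - cov_b
        rho_w = cov_needed / math.sqrt(var_wa * var_wb)
        if abs(rho_w) > 0.95:
            log.info("within-group correlation for (%s, %s) clipped from "
                     "%.3f to +/-0.95", a, b, rho_w)
            rho_w = math.copysign(0.95, rho_w)
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho_w
    # nearest-PSD repair by eigenvalue clipping
    w, v = np.linalg.eigh(corr)
    if w.min() < 1e-8:
        log.info("correlation matrix repaired: min eigenvalue %.3g", w.min())
        w = np.clip(w, 1e-8, None)
        corr = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return names, corr


def generate_gtt(cfg: CohortConfig, rat: RatRecord,
                 rng: np.random.Generator | None = None) -> list:
    """Glucose excursion on the study lattice {0, 15, ..., 180} min.

    The curve starts exactly at the rat's fasting glucose; later points
    follow the gamma-shaped excursion plus seeded Gaussian noise.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    shape = cfg.gtt_shape[rat.group]
    base = rat.FBG
    out = []
    for t in GTT_MINUTES:
        if t == 0:
            out.append((t, float(base)))
            continue
        y = base + shape["amplitude"] * (t / shape["t_peak"]) \
            * math.exp(1.0 - t / shape["t_peak"])
        y += shape["noise_sd"] * rng.standard_normal()
        out.append((t, float(max(y, 0.5))))
    return out


def generate_vonfrey_sequence(cfg: CohortConfig, rat: RatRecord,
                              rng: np.random.Generator | None = None,
                              theta: float | None = None) -> list:
    """Up-down von Frey response sequence under a probit psychometric.

    P(withdrawal | force g) = Phi((log10 g - log10 theta_rat)/sigma).
    Starts at the 2 g filament; positive responses step down, negative
    step up; stops four stimuli after the first response change or at
    either end of the filament set.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    vf = cfg.vonfrey
    if theta is None:
        g = vf[rat.group]
        theta = 10 ** (g["log_theta_mean"] + g["log_theta_sd"] * rng.standard_normal())
    sigma = vf["sigma"]
    fils = sorted(VON_FREY_FILAMENTS)
    i = fils.index(2.0)
    seq = []
    first_change = None
    from scipy.stats import norm
    while True:
        f = fils[i]
        if sigma <= 0:
            resp = f >= theta
        else:
            p = norm.cdf((math.log10(f) - math.log10(theta)) / sigma)
            resp = bool(rng.random() < p)
        seq.append((f, resp))
        k = len(seq) - 1
        if first_change is None and k > 0 and resp != seq[k - 1][1]:
            first_change = k
        if first_change is not None and k - first_change >= 4:
            break
        if (resp and i == 0) or (not resp and i == len(fils) - 1):
            break
        i = i - 1 if resp else i + 1
    return seq


def generate_cohort(cfg: CohortConfig) -> list:
    """Draw a full two-group cohort of RatRecords (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    names, corr = _within_correlation(cfg)
    cfg.realized_correlation = corr
    cfg.corr_fields = tuple(names)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))
    other = [n for n in cfg.field_stats if n not in names]
    rats = []
    for gi, group in enumerate(("chow", "CAF")):
        for j in range(cfg.n_per_group):
            z = chol @ rng.standard_normal(len(names))
            rec = {}
            for n, zv in zip(names, z):
                mean, sd = cfg.field_stats[n][gi]
                rec[n] = mean + sd * zv
            for n in other:
                mean, sd = cfg.field_stats[n][gi]
                rec[n] = mean + sd * rng.standard_normal()
            for n in rec:     # physiological floors: masses/levels stay positive
                if n != "superexcitability":
                    rec[n] = max(rec[n], 0.01 * abs(cfg.field_stats[n][gi][0]))
            rat = RatRecord(id=f"{group}_{j + 1:02d}", group=group, **rec)
            rat.gtt = generate_gtt(cfg, rat, rng)
            rat.vonfrey = generate_vonfrey_sequence(cfg, rat, rng)
            rats.append(rat)
    return rats


def generate_recorded_excitability(params: AxonParameters,
                                   noise_sd: float = 1.0, seed: int = 0,
                                   tracker_opts: dict | None = None
                                   ) -> ExcitabilityCurves:
    """Noisy "recorded" excitability curves from the axon model.

    Runs the full threshold-tracking battery, then multiplies every
    measured threshold (the control threshold included) by exp(eps) with
    eps ~ N(0, (noise_sd/100)^2); percentage curves are recomputed from
    the noised thresholds, as a real threshold tracker would.
    """
    rng = np.random.default_rng(seed)
    tr = ThresholdTracker(params, **(tracker_opts or {}))
    curves, _ = tr.run_all()
    s = noise_sd / 100.0

    def noise():
        return math.exp(s * rng.standard_normal()) if s > 0 else 1.0

    t0 = tr.T0 * noise()
    sd = curves.sd.copy()
    sd[:, 1] = [t * noise() for t in sd[:, 1]]
    te = {}
    for lv, arr in curves.te.items():
        arr = arr.copy()
        thr = tr.T0 * (1.0 - arr[:, 1] / 100.0)
        arr[:, 1] = 100.0 * (t0 - thr * np.array([noise() for _ in thr])) / t0
        te[lv] = arr
    iv = curves.iv.copy()
    thr = tr.T0 * (1.0 - iv[:, 1] / 100.0)
    iv[:, 1] = 100.0 * (t0 - thr * np.array([noise() for _ in thr])) / t0
    rc = curves.rc.copy()
    thr = tr.T0 * (1.0 + rc[:, 1] / 100.0)
    rc[:, 1] = 100.0 * (thr * np.array([noise() for _ in thr]) - t0) / t0
    return ExcitabilityCurves(sd=sd, te=te, iv=iv, rc=rc)
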