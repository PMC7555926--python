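"""File schemas: excitability-curve CSVs, cohort CSVs, parameter configs.

Excitability curves use one CSV per paradigm in a directory:

    sd.csv  paradigm,series,x_ms_or_pct,threshold_pA
    te.csv  paradigm,series,x_ms_or_pct,threshold_change_pct   (series = level %)
    iv.csv  paradigm,series,x_ms_or_pct,threshold_change_pct
    rc.csv  paradigm,series,x_ms_or_pct,threshold_change_pct

x_ms_or_pct is delay/ISI/duration in ms (TE, RC, SD) or conditioning level
in % of control threshold (IV).  Values round-trip at full precision
(shortest-repr float formatting).  Schema violations raise SchemaError
with the offending file, column or line.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig
from .errors import SchemaError
from .parameters import AxonParameters
from .protocols import ExcitabilityCurves
from .studystats import RatRecord

__all__ = [
    "write_excitability_csv",
    "read_excitability_csv",
    "write_cohort_csv",
    "read_cohort_csv",
    "RunConfig",
]

_CURVE_COLS = ["paradigm", "series", "x_ms_or_pct", "threshold_change_pct"]


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
_SD_COLS = ["paradigm", "series", "x_ms_or_pct", "threshold_pA"]


def _write_exact(df: pd.DataFrame, path) -> None:
    """CSV write with shortest-repr floats (exact value round-trip)."""
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(repr)
    out.to_csv(path, index=False)


def _check_cols(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")


def write_excitability_csv(curves: ExcitabilityCurves, outdir) -> None:
    """Write one CSV per paradigm into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sd = pd.DataFrame({"paradigm": "sd", "series": "-",
                       "x_ms_or_pct": curves.sd[:, 0],
                       "threshold_pA": curves.sd[:, 1]})
    _write_exact(sd, outdir / "sd.csv")
    rows = []
    for lv in sorted(curves.te, reverse=True):
        arr = curves.te[lv]
        for x, y in arr:
            rows.append(("te", f"{lv:+g}", x, y))
    _write_exact(pd.DataFrame(rows, columns=_CURVE_COLS), outdir / "te.csv")
    iv = pd.DataFrame({"paradigm": "iv", "series": "-",
                       "x_ms_or_pct": curves.iv[:, 0],
                       "threshold_change_pct": curves.iv[:, 1]})
    _write_exact(iv, outdir / "iv.csv")
    rc = pd.DataFrame({"paradigm": "rc", "series": "-",
                       "x_ms_or_pct": curves.rc[:, 0],
                       "threshold_change_pct": curves.rc[:, 1]})
    _write_exact(rc, outdir / "rc.csv")


def read_excitability_csv(indir) -> ExcitabilityCurves:
    """Read the per-paradigm CSVs written by :func:`write_excitability_csv`."""
    indir = Path(indir)
    for name in ("sd", "te", "iv", "rc"):
        if not (indir / f"{name}.csv").exists():
            raise SchemaError(f"{indir}: missing {name}.csv")
    sd_df = _read_csv(indir / "sd.csv")
    _check_cols(sd_df, _SD_COLS, indir / "sd.csv")
    sd = sd_df[["x_ms_or_pct", "threshold_pA"]].to_numpy(float)
    te_df = _read_csv(indir / "te.csv")
    _check_cols(te_df, _CURVE_COLS, indir / "te.csv")
    te = {}
    for series, grp in te_df.groupby("series"):
        try:
            lv = float(series)
        except ValueError:
            raise SchemaError(f"te.csv: series {series!r} is not a "
                              "conditioning level in %")
        te[lv] = grp[["x_ms_or_pct", "threshold_change_pct"]].to_numpy(float)
    iv_df = _read_csv(indir / "iv.csv")
    _check_cols(iv_df, _CURVE_COLS, indir / "iv.csv")
    iv = iv_df[["x_ms_or_pct", "threshold_change_pct"]].to_numpy(float)
    rc_df = _read_csv(indir / "rc.csv")
    _check_cols(rc_df, _CURVE_COLS, indir / "rc.csv")
    rc = rc_df[["x_ms_or_pct", "threshold_change_pct"]].to_numpy(float)
    bad = np.nonzero(rc[:, 0] < 2.5 - 1e-9)[0]
    if bad.size:
        warnings.warn(
            f"rc.csv line(s) {[int(i) + 2 for i in bad]}: interstimulus "
            "interval below the 2.5 ms recovery-cycle minimum",
            stacklevel=2)
        rc = rc[rc[:, 0] >= 2.5 - 1e-9]
    try:
        return ExcitabilityCurves(sd=sd, te=te, iv=iv, rc=rc)
    except ValueError as e:
        raise SchemaError(f"{indir}: {e}") from e


# ----------------------------------------------------------------------
# cohort tables
# ----------------------------------------------------------------------

_SCALAR_FIELDS = [f.name for f in dataclasses.fields(RatRecord)
                  if f.name not in ("gtt", "vonfrey")]


def write_cohort_csv(rats, outdir) -> None:
    """Write cohort.csv (one row per rat) + long-format gtt.csv/vonfrey.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_exact(pd.DataFrame([{f: getattr(r, f) for f in _SCALAR_FIELDS}
                               for r in rats]), outdir / "cohort.csv")
    gtt = [(r.id, m, g) for r in rats for m, g in r.gtt]
    _write_exact(pd.DataFrame(gtt, columns=["id", "minute",
                                            "glucose_mmol_per_L"]),
                 outdir / "gtt.csv")
    vf = [(r.id, k + 1, f, int(resp))
          for r in rats for k, (f, resp) in enumerate(r.vonfrey)]
    pd.DataFrame(vf, columns=["id", "presentation", "filament_g", "response"]) \
        .to_csv(outdir / "vonfrey.csv", index=False)


def read_cohort_csv(indir) -> list:
    """Read the cohort written by :func:`write_cohort_csv`."""
    indir = Path(indir)
    path = indir / "cohort.csv"
    if not path.exists():
        raise SchemaError(f"{indir}: missing cohort.csv")
    df = _read_csv(path)
    _check_cols(df, ["id", "group"], path)
    rats = {}
    for _, row in df.iterrows():
        kwargs = {f: row[f] for f in _SCALAR_FIELDS if f in df.columns}
        kwargs["id"] = str(kwargs["id"])
        rats[kwargs["id"]] = RatRecord(**kwargs)
    gtt_path = indir / "gtt.csv"
    if gtt_path.exists():
        g = _read_csv(gtt_path)
        _check_cols(g, ["id", "minute", "glucose_mmol_per_L"], gtt_path)
        for rid, grp in g.groupby("id"):
            if str(rid) in rats:
                rats[str(rid)].gtt = list(zip(grp["minute"].astype(int),
                                              grp["glucose_mmol_per_L"]))
    vf_path = indir / "vonfrey.csv"
    if vf_path.exists():
        v = _read_csv(vf_path).sort_values(["id", "presentation"])
        _check_cols(v, ["id", "presentation", "filament_g", "response"], vf_path)
        for rid, grp in v.groupby("id"):
            if str(rid) in rats:
                rats[str(rid)].vonfrey = [(float(f), bool(r)) for f, r in
                                          zip(grp["filament_g"], grp["response"])]
    return list(rats.values())


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Resolved settings of one pipeline run; written next to its outputs."""

    command: str = ""
    params_file: str | None = None
    cohort_dir: str | None = None
    excitability_dir: str | None = None
    out_dir: str = "."
    seed: int = 0
    weights: tuple = (0.5, 1.0, 1.0, 3.0)
    dt_ms: float = 0.01
    bracket_rtol: float = 0.005
    extra: dict = dataclasses.field(default_factory=dict)

    def write(self, outdir) -> None:
        from . import __version__

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = dataclasses.asdict(self)
        payload["axotrace_version"] = __version__
        payload["weights"] = list(self.weights)
        with open(outdir / "run_config.yml", "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def load_params(path) -> AxonParameters:
    return AxonParameters.from_yaml(path)


def save_params(params: AxonParameters, path) -> None:
    params.to_yaml(path)
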