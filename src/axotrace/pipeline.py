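"""Cohort-level analysis: derived indices, group tests, correlation matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .studystats import (compare_groups, gtt_auc, homa_ir, lee_index,
                         pearson_test, spearman_test, tyg_index,
                         vonfrey_50pwt)

__all__ = ["derive_indices", "study_tables"]

#: mmol/L -> mg/dL for glucose
MGDL_PER_MMOL = 18.0

_COMPARE_FIELDS = (
    "body_weight", "fat_mass", "lean_mass", "naso_anal_length", "rpWAT",
    "liver_weight", "FBG", "insulin", "leptin", "triglycerides", "HDL",
    "TNF_alpha", "IL6", "SNAP", "superexcitability",
    "homa_ir", "tyg_index", "lee_index", "gtt_auc", "pwt_50",
)

_CORR_FIELDS = (
    "fat_mass", "body_weight", "lean_mass", "HDL", "leptin", "rpWAT",
    "triglycerides", "FBG", "insulin", "homa_ir", "gtt_auc", "TNF_alpha",
    "IL6",
)


def derive_indices(rats) -> pd.DataFrame:
    """Per-rat metabolic/behavioural indices alongside the raw fields."""
    rows = []
    for r in rats:
        row = {"id": r.id, "group": r.group}
        for f in ("body_weight", "fat_mass", "lean_mass", "naso_anal_length",
                  "rpWAT", "liver_weight", "FBG", "insulin", "leptin",
                  "triglycerides", "HDL", "TNF_alpha", "IL6", "SNAP",
                  "superexcitability"):
            row[f] = getattr(r, f)
        row["homa_ir"] = (homa_ir(r.insulin, r.FBG)
                          if np.isfinite(r.insulin * r.FBG) else np.nan)
        row["tyg_index"] = (tyg_index(r.triglycerides, r.FBG * MGDL_PER_MMOL)
                            if np.isfinite(r.triglycerides * r.FBG) else np.nan)
        row["lee_index"] = (lee_index(r.body_weight, r.naso_anal_length)
                            if np.isfinite(r.body_weight * r.naso_anal_length)
                            else np.nan)
        row["gtt_auc"] = gtt_auc(r.gtt) if len(r.gtt) >= 2 else np.nan
        row["pwt_50"] = vonfrey_50pwt(r.vonfrey) if r.vonfrey else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def study_tables(rats, fdr: bool = False) -> dict:
    """Index table, normality-gated group comparisons and correlations.

    Correlations pair superexcitability with each metabolic measure over
    the pooled cohort; the method is Pearson unless either variable fails
    Shapiro-Wilk normality (p < 0.05), in which case Spearman is used.
    P-values are unadjusted unless ``fdr`` (Benjamini-Hochberg) is set.
    """
    idx = derive_indices(rats)
    chow = idx[idx.group == "chow"]
    caf = idx[idx.group == "CAF"]

    comp_rows = []
    for f in _COMPARE_FIELDS:
        a = chow[f].dropna().to_numpy()
        b = caf[f].dropna().to_numpy()
        if a.size < 3 or b.size < 3:
            continue
        try:
            res = compare_groups(a, b)
        except ValueError:
            continue
        comp_rows.append({
            "variable": f, "chow_mean": a.mean(),
            "chow_sem": a.std(ddof=1) / np.sqrt(a.size),
            "caf_mean": b.mean(), "caf_sem": b.std(ddof=1) / np.sqrt(b.size),
            "test": res.test, "statistic": res.statistic, "p": res.p,
        })

    corr_rows = []
    sup = idx["superexcitability"]
    for f in _CORR_FIELDS:
        pair = idx[["superexcitability", f]].dropna()
        if len(pair) < 3:
            continue
        x, y = pair["superexcitability"].to_numpy(), pair[f].to_numpy()
        normal = (stats.shapiro(x).pvalue > 0.05
                  and stats.shapiro(y).pvalue > 0.05)
        res = pearson_test(x, y) if normal else spearman_test(x, y)
        corr_rows.append({"variable": f, "method": res.method, "r": res.r,
                          "n": res.n, "p": res.p})
    corr = pd.DataFrame(corr_rows)
    if fdr and len(corr):
        corr["p_fdr"] = stats.false_discovery_control(corr["p"], method="bh")

    return {"indices": idx, "group_comparisons": pd.DataFrame(comp_rows),
            "correlations": corr}
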