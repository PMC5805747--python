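"""Paired statistics, t-test power, dose arithmetic, and cohort summaries.

Lung areas and CNRs are compared before/after pneumothorax induction with
Student's two-tailed t test for paired samples; the power of that test for a
given mean paired difference and its standard deviation uses the noncentral
t distribution with noncentrality ``(mu_d / sd_d) * sqrt(n)`` and ``n - 1``
degrees of freedom.  Percent changes are averaged per animal (mean of
per-animal percent changes, not percent change of the means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    p: float  # two-tailed
    mean_diff: float
    sd_diff: float
    n: int


def paired_ttest(before, after) -> PairedTTestResult:
    """Student's two-tailed t test for paired samples (df = n - 1)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be 1-D arrays of equal length")
    n = before.size
    if n < 2:
        raise ValueError("need at least two pairs")
    diff = after - before
    sd = float(diff.std(ddof=1))
    if sd == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    res = sps.ttest_rel(after, before)
    return PairedTTestResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        mean_diff=float(diff.mean()),
        sd_diff=sd,
        n=n,
    )


def power_paired_ttest(mu_d: float, sd_d: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided power of the paired t test from the noncentral t distribution.

    ``ncp = (mu_d / sd_d) * sqrt(n)``, ``df = n - 1``; returns the
    probability of rejecting at level ``alpha``.
    """
    if sd_d <= 0:
        raise ValueError("sd_d must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    ncp = (mu_d / sd_d) * np.sqrt(n)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    return float(power)


def organ_dose_from_dap(dap_gy_cm2: float, weighting_factor: float) -> float:
    """Organ-specific dose in mSv from a dose area product.

    Convention: the dose area product in Gy cm^2 times the dimensionless
    tissue weighting factor is reported directly in mSv (0.5 Gy cm^2 with
    K = 0.16 gives 0.08 mSv).
    """
    if dap_gy_cm2 < 0 or weighting_factor < 0:
        raise ValueError("dap and weighting factor must be non-negative")
    return dap_gy_cm2 * weighting_factor


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

CNR_COLUMNS = {
    "darkfield_filtered": "cnr_df_filtered",
    "darkfield_unfiltered": "cnr_df_unfiltered",
    "transmission_unfiltered": "cnr_t_unfiltered",
    "transmission_filtered": "cnr_t_filtered",
}


def percent_change(before, after) -> np.ndarray:
    """Per-sample percent change, (after - before) / before * 100."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    return (after - before) / before * 100.0


def cohort_summary(results: pd.DataFrame) -> dict:
    """Summarize one cohort's CNRs and projected areas.

    ``results`` holds one row per animal with columns ``animal_id``,
    ``in_vivo``, ``has_lateral``, the four CNR columns (NaN for animals
    without a lateral pneumothorax) and the four area columns
    ``area_affected_before/after``, ``area_control_before/after`` in cm^2.

    Returns a nested dict with CNR mean +- sd per modality/filter over the
    lateral animals, area means, mean per-animal percent changes, paired
    p-values, and the ex-vivo vs in-vivo CNR comparison (unpaired two-tailed
    t test per modality).
    """
    required = {"animal_id", "in_vivo", "has_lateral"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    if len(results) < 2:
        raise ValueError("cohort statistics need at least two animals")

    out: dict = {"n_animals": int(len(results))}

    lateral = results[results["has_lateral"]]
    cnrs = {}
    for name, col in CNR_COLUMNS.items():
        if col in results.columns and lateral[col].notna().sum() >= 2:
            vals = lateral[col].dropna().to_numpy(dtype=float)
            cnrs[name] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
                "n": int(vals.size),
            }
    out["cnr"] = cnrs

    if {"cnr_df_filtered", "cnr_t_unfiltered"} <= set(results.columns):
        paired = lateral.dropna(subset=["cnr_df_filtered", "cnr_t_unfiltered"])
        if len(paired) >= 2:
            res = paired_ttest(
                paired["cnr_t_unfiltered"], paired["cnr_df_filtered"]
            )
            out["cnr_df_vs_t_p"] = res.p

    # ex vivo vs in vivo, unpaired two-tailed t per modality
    ev = {}
    for name, col in CNR_COLUMNS.items():
        if col not in results.columns:
            continue
        a = lateral.loc[~lateral["in_vivo"], col].dropna()
        b = lateral.loc[lateral["in_vivo"], col].dropna()
        if len(a) >= 2 and len(b) >= 2:
            ev[name] = float(sps.ttest_ind(a, b).pvalue)
    out["ex_vivo_vs_in_vivo_p"] = ev

    area_cols = {
        "area_affected_before", "area_affected_after",
        "area_control_before", "area_control_after",
    }
    if area_cols <= set(results.columns):
        areas = {}
        for side in ("affected", "control"):
            b = results[f"area_{side}_before"].to_numpy(dtype=float)
            a = results[f"area_{side}_after"].to_numpy(dtype=float)
            res = paired_ttest(b, a)
            areas[side] = {
                "before_mean": float(b.mean()),
                "before_sd": float(b.std(ddof=1)),
                "after_mean": float(a.mean()),
                "after_sd": float(a.std(ddof=1)),
                "mean_percent_change": float(percent_change(b, a).mean()),
                "p": res.p,
                "n": res.n,
            }
        out["areas"] = areas
    return out


def summary_to_text(summary: dict) -> str:
    """Human-readable cohort report; p-values to 4 decimals."""
    lines = [f"cohort summary ({summary['n_animals']} animals)"]
    for name, s in summary.get("cnr", {}).items():
        lines.append(
            f"  CNR {name:25s} {s['mean']:.2f} +- {s['sd']:.2f} (n={s['n']})"
        )
    if "cnr_df_vs_t_p" in summary:
        lines.append(
            "  filtered dark-field vs unfiltered transmission CNR: "
            f"p = {summary['cnr_df_vs_t_p']:.4f}"
        )
    for name, p in summary.get("ex_vivo_vs_in_vivo_p", {}).items():
        lines.append(f"  ex vivo vs in vivo {name}: p = {p:.4f}")
    for side, s in summary.get("areas", {}).items():
        lines.append(
            f"  {side} retro-diaphragmatic area: "
            f"{s['before_mean']:.1f} +- {s['before_sd']:.1f} -> "
            f"{s['after_mean']:.1f} +- {s['after_sd']:.1f} cm^2 "
            f"({s['mean_percent_change']:+.1f}%; p = {s['p']:.4f}; n = {s['n']})"
        )
    return "\n".join(lines)
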