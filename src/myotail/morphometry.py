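"""Filament morphometry, solubility curves and cell-integration scoring.

Summarizes negative-stain EM measurements of GST–LMM minifilaments
(length/width populations per genotype, bundling frequency per image
field), salt-dependent solubility assays, and the categorical scoring of
eGFP–myosin integration into cardiomyocyte sarcomeres.  Group comparisons
use two-tailed Welch (unequal-variance) t tests against the wild type, with
significance stars at p < 0.01 (**), p < 0.001 (***) and p < 1e-4 (****).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from statsmodels.stats.proportion import proportion_confint

WT_LABEL = "WT"
#: EM-morphometry significance bands: ** p<0.01, *** p<0.001, **** p<<0.001.
STAR_BANDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"))
#: Cell-imaging significance bands: * p<0.05, ** p<0.001, *** p<0.0001.
CELL_STAR_BANDS = ((1e-4, "***"), (1e-3, "**"), (5e-2, "*"))
INTEGRATION_CATEGORIES = ("integrated", "partial", "aggregated")


def stars(p: float, bands=STAR_BANDS) -> str:
    for cut, sym in bands:
        if p < cut:
            return sym
    return ""


def filament_stats(
    records: pd.DataFrame, value: str = "length_nm", reference: str = WT_LABEL
) -> pd.DataFrame:
    """Per-group mean/SD/SEM/n plus Welch tests vs the reference group.

    ``records`` needs columns ``group`` and ``value`` (length_nm or
    width_nm); rows with missing values are ignored.  Groups with fewer
    than two records are summarized but excluded from testing.
    """
    df = records.dropna(subset=[value])
    rows = []
    ref_vals = df.loc[df["group"] == reference, value].to_numpy()
    for group, sub in df.groupby("group", sort=False):
        vals = sub[value].to_numpy()
        if len(vals) == 0:
            warnings.warn(f"group {group!r}: no records, excluded")
            continue
        row = {
            "group": group,
            "n": len(vals),
            "mean": vals.mean(),
            "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            "sem": stats.sem(vals) if len(vals) > 1 else np.nan,
        }
        if group != reference and len(vals) >= 2 and len(ref_vals) >= 2:
            t, p = stats.ttest_ind(vals, ref_vals, equal_var=False)
            row.update({"t": t, "p_vs_ref": p, "stars": stars(p)})
        rows.append(row)
    return pd.DataFrame(rows)


def bundle_fraction(
    records: pd.DataFrame, alpha: float = 0.05, method: str = "wilson"
) -> pd.DataFrame:
    """Percentage of image fields containing bundles per group, with binomial CI.

    ``records`` needs ``group``, ``field_id`` and boolean ``bundled``; a
    field counts as bundled if any of its rows is flagged.
    """
    per_field = records.groupby(["group", "field_id"], sort=False)["bundled"].any().reset_index()
    rows = []
    for group, sub in per_field.groupby("group", sort=False):
        k = int(sub["bundled"].sum())
        n = len(sub)
        lo, hi = proportion_confint(k, n, alpha=alpha, method=method)
        rows.append(
            {
                "group": group,
                "n_fields": n,
                "bundled_pct": 100.0 * k / n,
                "ci_low_pct": 100.0 * lo,
                "ci_high_pct": 100.0 * hi,
            }
        )
    return pd.DataFrame(rows)


def _logistic_solubility(s: np.ndarray, midpoint: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(s - midpoint) / width))


def solubility_curve(points: pd.DataFrame, fit_midpoint: bool = True) -> tuple[pd.DataFrame, "dict | None"]:
    """Fraction soluble vs NaCl and an optional logistic half-solubility fit.

    ``points`` needs ``NaCl_mM``, ``supernatant`` and ``total`` (any
    consistent concentration unit); supernatant above total is clipped to a
    fraction of 1 with a warning.  Returns the per-point table and, when
    fitted, a dict with the half-solubility midpoint (mM) and width.
    """
    df = points.copy()
    if (df["total"] <= 0).any():
        raise ValueError("total concentration must be positive")
    frac = df["supernatant"] / df["total"]
    if (frac > 1).any():
        warnings.warn("supernatant exceeds total for some points — fraction clipped to 1")
    df["fraction_soluble"] = np.clip(frac, 0.0, 1.0)
    fit = None
    if fit_midpoint and df["NaCl_mM"].nunique() >= 3:
        s = df["NaCl_mM"].to_numpy(dtype=float)
        f = df["fraction_soluble"].to_numpy(dtype=float)
        try:
            popt, _ = curve_fit(
                _logistic_solubility, s, f,
                p0=[float(np.median(s)), 30.0], maxfev=10_000,
            )
            fit = {"midpoint_mM": float(popt[0]), "width_mM": float(abs(popt[1]))}
        except RuntimeError:
            warnings.warn("half-solubility logistic fit did not converge")
    return df, fit


def integration_summary(
    scores: pd.DataFrame, reference: str = WT_LABEL, min_cells: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Integration-category percentages per experiment and group comparisons.

    ``scores`` needs ``group``, ``experiment``, ``category`` (one row per
    cell; categories ``integrated`` / ``partial`` / ``aggregated``).
    Returns ``(per_experiment, summary)``: per-experiment percentages
    (summing to 100 per experiment) and the mean ± SD across experiments per
    group/category with Welch tests vs the reference.
    """
    bad = set(scores["category"]) - set(INTEGRATION_CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    rows = []
    for (group, exp), sub in scores.groupby(["group", "experiment"], sort=False):
        n = len(sub)
        if n < min_cells:
            warnings.warn(f"{group}/{exp}: only {n} cells (< {min_cells} recommended)")
        for cat in INTEGRATION_CATEGORIES:
            rows.append(
                {
                    "group": group,
                    "experiment": exp,
                    "category": cat,
                    "pct": 100.0 * (sub["category"] == cat).sum() / n,
                    "n_cells": n,
                }
            )
    per_exp = pd.DataFrame(rows)

    summary_rows = []
    for (group, cat), sub in per_exp.groupby(["group", "category"], sort=False):
        vals = sub["pct"].to_numpy()
        row = {
            "group": group,
            "category": cat,
            "mean_pct": vals.mean(),
            "sd_pct": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            "n_experiments": len(vals),
        }
        if group != reference:
            ref = per_exp[(per_exp["group"] == reference) & (per_exp["category"] == cat)]["pct"]
            if len(ref) >= 2 and len(vals) >= 2:
                _, p = stats.ttest_ind(vals, ref, equal_var=False)
                row.update({"p_vs_ref": p, "stars": stars(p, CELL_STAR_BANDS)})
        summary_rows.append(row)
    return per_exp, pd.DataFrame(summary_rows)
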