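"""Trend tests of flux ratios against condition covariates, with BH-FDR.

Each of the 13 branch-point ratios is averaged across replicates within a
condition and regressed (OLS) on one covariate: Na+ concentration, the
natural log of Mg2+ concentration, or doubling time.  Two-sided slope
p-values are corrected across ratios with the Benjamini–Hochberg step-up
procedure.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from omiclust.errors import ValidationError
from omiclust.io_model import FluxRatioTable, RegressionResult

COVARIATES = ("na_mM", "log_mg_mM", "doubling_time_min")


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``adjusted_(i) = min_{j >= i} p_(j) * m / j`` on the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adjusted_sorted
    return [float(x) for x in adjusted]


def _covariate_values(means, covariate: str) -> np.ndarray:
    if covariate == "na_mM":
        return means["na_mM"].to_numpy(dtype=float)
    if covariate == "log_mg_mM":
        mg = means["mg_mM"].to_numpy(dtype=float)
        if np.any(mg <= 0):
            raise ValidationError("mg_mM must be > 0 for the log transform")
        return np.log(mg)
    if covariate == "doubling_time_min":
        if "doubling_time_min" not in means.columns:
            raise ValidationError("flux table lacks a doubling_time_min column")
        return means["doubling_time_min"].to_numpy(dtype=float)
    raise ValidationError(f"unknown covariate {covariate!r}; allowed: {COVARIATES}")


def regress_flux(f: FluxRatioTable, covariate: str) -> list[RegressionResult]:
    """Per-ratio OLS of replicate-averaged ratio values on the covariate.

    A constant response gives slope 0 with p = 1 by convention; a constant
    covariate is an error.  Adjusted p-values are BH across the ratios.
    """
    agg_cols = {"value": "mean", "na_mM": "first", "mg_mM": "first"}
    if "doubling_time_min" in f.data.columns:
        agg_cols["doubling_time_min"] = "first"
    results: list[tuple[str, float, float, float, int]] = []
    for ratio in sorted(f.data["ratio_name"].unique()):
        sub = f.data[f.data["ratio_name"] == ratio]
        means = sub.groupby("condition_id", sort=True).agg(agg_cols).reset_index()
        x = _covariate_values(means, covariate)
        y = means["value"].to_numpy(dtype=float)
        if len(np.unique(x)) < 3:
            raise ValidationError(
                f"ratio {ratio!r}: fewer than 3 distinct covariate values"
            )
        if np.ptp(x) == 0:
            raise ValidationError(f"ratio {ratio!r}: zero covariate variance")
        if np.ptp(y) == 0:
            results.append((ratio, 0.0, float(y[0]), 1.0, len(y)))
            continue
        fit = stats.linregress(x, y)
        results.append(
            (ratio, float(fit.slope), float(fit.intercept), float(fit.pvalue), len(y))
        )
    adjusted = bh_fdr([r[3] for r in results])
    return [
        RegressionResult(
            ratio_name=name,
            covariate_name=covariate,
            slope=slope,
            intercept=intercept,
            p_value=p,
            p_adjusted=p_adj,
            n=n,
        )
        for (name, slope, intercept, p, n), p_adj in zip(results, adjusted)
    ]
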