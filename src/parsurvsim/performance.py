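"""Simulation performance measures with Monte-Carlo standard errors.

Repetition-level results are summarized per grouping (sample size x
event proportion x selection criterion x estimand) into:

* coverage — fraction of repetitions whose 95% CI contains the truth;
* MAE, MAPE, RMSE — mean absolute, mean absolute percentage, and root
  mean squared error of the point estimates against the truth;
* probability of 20% error — fraction of repetitions whose estimate
  misses the truth by more than 20% in relative terms;
* proportion identifying the true distribution as best fitting.

Monte-Carlo standard errors use the binomial formula for proportions and
sample-SD / sqrt(n) for means; the RMSE's MCSE comes from the delta
method applied to the mean squared error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "coverage",
    "error_metrics",
    "prob_large_error",
    "prop_true_distribution",
    "proportion_mcse",
    "performance_table",
]


def proportion_mcse(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n))


def _as_array(values, name):
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return a


def coverage(lowers, uppers, truth: float):
    """Fraction of intervals containing ``truth``, with its MCSE."""
    lo = _as_array(lowers, "lowers")
    hi = _as_array(uppers, "uppers")
    if lo.shape != hi.shape:
        raise ValueError("lower and upper bounds must align")
    if not np.isfinite(truth):
        raise ValueError("truth must be finite")
    hit = (lo <= truth) & (truth <= hi)
    p = float(np.mean(hit))
    return p, proportion_mcse(p, hit.size)


def error_metrics(estimates, truth: float):
    """(mae, mape, rmse) against ``truth`` with matching MCSEs.

    MAPE is on the percent scale.  Returns two dicts: point values and
    MCSEs.
    """
    est = _as_array(estimates, "estimates")
    n = est.size
    if truth == 0 or not np.isfinite(truth):
        raise ValueError("truth must be finite and non-zero")
    abs_err = np.abs(est - truth)
    sq_err = (est - truth) ** 2
    mae = float(np.mean(abs_err))
    mape = float(100.0 * np.mean(abs_err / abs(truth)))
    mse = float(np.mean(sq_err))
    rmse = float(np.sqrt(mse))
    sd = lambda x: float(np.std(x, ddof=1)) if n > 1 else 0.0
    mcse = {
        "mae": sd(abs_err) / np.sqrt(n),
        "mape": 100.0 * sd(abs_err / abs(truth)) / np.sqrt(n),
        # delta method: se(rmse) = se(mse) / (2 rmse)
        "rmse": sd(sq_err) / np.sqrt(n) / (2.0 * rmse) if rmse > 0 else 0.0,
    }
    return {"mae": mae, "mape": mape, "rmse": rmse}, mcse


def prob_large_error(estimates, truth: float, threshold: float = 0.2):
    """Fraction of estimates off by more than ``threshold`` (relative)."""
    est = _as_array(estimates, "estimates")
    if truth == 0 or not np.isfinite(truth):
        raise ValueError("truth must be finite and non-zero")
    big = np.abs(est - truth) / abs(truth) > threshold
    p = float(np.mean(big))
    return p, proportion_mcse(p, big.size)


def prop_true_distribution(was_true_flags):
    """Fraction of repetitions whose selected family is the true one."""
    flags = np.asarray(was_true_flags)
    if flags.size == 0:
        raise ValueError("no selections supplied")
    p = float(np.mean(flags.astype(bool)))
    return p, proportion_mcse(p, flags.size)


def performance_table(
    estimands_df: pd.DataFrame,
    selections_df: pd.DataFrame,
    truth: dict,
    error_threshold: float = 0.2,
) -> pd.DataFrame:
    """Aggregate repetition-level rows into the per-grouping measure table.

    Parameters
    ----------
    estimands_df : DataFrame
        Columns rep, n_obs, pe, criterion, estimand, point, lo, hi.
        Repetitions with a missing/non-finite point (no-selection or
        CI-failure markers) are excluded per grouping, visibly via
        ``n_reps_used``.
    selections_df : DataFrame
        Columns rep, n_obs, pe, criterion, chosen_family, was_true_family.
    truth : dict
        estimand name -> true population value.
    """
    rows = []
    sel_grouped = selections_df.groupby(["n_obs", "pe", "criterion"])
    prop_true = {
        key: prop_true_distribution(g["was_true_family"].to_numpy())
        for key, g in sel_grouped
    }
    has_cis = estimands_df[["lo", "hi"]].notna().to_numpy().any()
    for (n_obs, pe, criterion, estimand), g in estimands_df.groupby(
        ["n_obs", "pe", "criterion", "estimand"]
    ):
        ok = np.isfinite(g["point"].to_numpy())
        g_ok = g[ok]
        n_used = len(g_ok)
        row = {
            "n_obs": n_obs,
            "pe": pe,
            "criterion": criterion,
            "estimand": estimand,
            "n_reps_used": n_used,
        }
        if n_used:
            est = g_ok["point"].to_numpy()
            point, mcse = error_metrics(est, truth[estimand])
            row.update(point)
            row.update({f"{k}_mcse": v for k, v in mcse.items()})
            p20, p20_se = prob_large_error(
                est, truth[estimand], threshold=error_threshold
            )
            row["prob_20pct_error"] = p20
            row["prob_20pct_error_mcse"] = p20_se
            lo, hi = g_ok["lo"].to_numpy(), g_ok["hi"].to_numpy()
            with_ci = np.isfinite(lo) & np.isfinite(hi)
            if has_cis and with_ci.any():
                cov, cov_se = coverage(
                    lo[with_ci], hi[with_ci], truth[estimand]
                )
                row["coverage"] = cov
                row["coverage_mcse"] = cov_se
        key = (n_obs, pe, criterion)
        if key in prop_true:
            p, se = prop_true[key]
            row["prop_true_distribution"] = p
            row["prop_true_distribution_mcse"] = se
        rows.append(row)
    cols = [
        "n_obs", "pe", "criterion", "estimand", "n_reps_used",
        "coverage", "coverage_mcse", "mae", "mae_mcse", "mape", "mape_mcse",
        "rmse", "rmse_mcse", "prob_20pct_error", "prob_20pct_error_mcse",
        "prop_true_distribution", "prop_true_distribution_mcse",
    ]
    table = pd.DataFrame(rows)
    for c in cols:
        if c not in table.columns:
            table[c] = np.nan
    return (
        table[cols]
        .sort_values(["criterion", "estimand", "n_obs", "pe"])
        .reset_index(drop=True)
    )
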