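"""Stimulation-induced cytokine deltas and robust group regression.

For every subject and cytokine the analysis works on the EW-M
concentration difference (pg/ml), mapped through a signed symmetric
log10 transform, and regressed on clinical group (AC as the reference
level) with a Huber M-estimator. p-values are Wald tests from the
asymptotic normal; BH adjustment runs across cytokines per coefficient.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import RobustFitResult
from .diffexpr import benjamini_hochberg

logger = logging.getLogger(__name__)

HUBER_K = 1.345  # 95% Gaussian efficiency


def compute_delta(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject EW-M concentration differences (pg/ml).

    Subject-cytokine pairs missing either condition are dropped and
    counted in the log.
    """
    wide = table.pivot_table(
        index=["subject_id", "group", "cytokine"],
        columns="condition",
        values="concentration",
        aggfunc="first",
    )
    for cond in ("EW", "M"):
        if cond not in wide.columns:
            wide[cond] = np.nan
    n_unpaired = int(wide[["EW", "M"]].isna().any(axis=1).sum())
    if n_unpaired:
        logger.info("dropped %d unpaired subject-cytokine entries", n_unpaired)
    wide = wide.dropna(subset=["EW", "M"])
    out = wide.reset_index()
    out["delta"] = out["EW"] - out["M"]
    return out[["subject_id", "group", "cytokine", "delta"]]


def log10_transform_delta(delta, offset: float = 1.0):
    """Signed symmetric log10: sign(d) * log10(1 + |d|/offset).

    The raw log10 of an EW-M delta is undefined for non-positive values;
    this transform is odd, monotone, zero at zero, and approaches
    log10(delta/offset) for large positive deltas. The default offset of
    1 pg/ml matches the assay floor scale.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    d = np.asarray(delta, dtype=float)
    out = np.sign(d) * np.log10(1.0 + np.abs(d) / offset)
    return out if out.ndim else float(out)


def huber_robust_fit(
    y,
    groups,
    cytokine: str = "",
    k: float = HUBER_K,
    maxiter: int = 50,
    tol: float = 1e-8,
) -> RobustFitResult:
    """Huber M-estimation of group effects on transformed deltas.

    Iteratively reweighted least squares with the Huber psi function
    (tuning constant ``k``), scale from the rescaled median absolute
    deviation. The design is an intercept plus treatment-coded group
    indicators with AC as the baseline when present (otherwise the
    alphabetically first group).
    """
    y = np.asarray(y, dtype=float)
    groups = pd.Series(list(groups), dtype=str)
    if len(y) != len(groups):
        raise ValueError("y and groups must have equal length")
    counts = groups.value_counts()
    if (counts >= 3).sum() < 2:
        raise ValueError("need >= 3 subjects in >= 2 groups")
    levels = sorted(counts.index)
    if "AC" in levels:
        levels = ["AC"] + [g for g in levels if g != "AC"]
    X = np.column_stack(
        [np.ones(len(y))] + [(groups == g).to_numpy(float) for g in levels[1:]]
    )
    names = ["intercept"] + list(levels[1:])

    if np.ptp(y) == 0.0:
        coefs = pd.DataFrame(
            {"coef": [y[0]] + [0.0] * (len(names) - 1),
             "se": 0.0, "p_value": 1.0},
            index=names,
        )
        return RobustFitResult(cytokine=cytokine, coefficients=coefs,
                               converged=True, n_obs=len(y), scale=0.0)

    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=k))
    res = model.fit(maxiter=maxiter, tol=tol, scale_est="mad", conv="coefs")
    n_iter = len(res.fit_history.get("params", []))
    converged = n_iter < maxiter
    if not converged:
        logger.warning("Huber fit for %s did not converge in %d iterations",
                       cytokine or "<cytokine>", maxiter)
    coefs = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "p_value": res.pvalues},
        index=names,
    )
    return RobustFitResult(
        cytokine=cytokine,
        coefficients=coefs,
        converged=converged,
        n_obs=len(y),
        scale=float(res.scale),
    )


def fit_cytokine_responses(
    table: pd.DataFrame,
    offset: float = 1.0,
    k: float = HUBER_K,
) -> pd.DataFrame:
    """Robust group regression for every cytokine in a long-format panel.

    Returns one row per (cytokine, non-reference group) with the Huber
    coefficient in transformed log10 units, its standard error, Wald
    p-value, and BH adjustment across cytokines within each coefficient.
    """
    deltas = compute_delta(table)
    deltas["y"] = log10_transform_delta(deltas["delta"].to_numpy(), offset=offset)
    rows = []
    for cyt, sub in deltas.groupby("cytokine", sort=True):
        fit = huber_robust_fit(sub["y"].to_numpy(), sub["group"], cytokine=cyt, k=k)
        for grp, r in fit.coefficients.iterrows():
            if grp == "intercept":
                continue
            rows.append(
                {
                    "cytokine": cyt,
                    "group": grp,
                    "coef": r["coef"],
                    "se": r["se"],
                    "p_value": r["p_value"],
                    "converged": fit.converged,
                    "n_obs": fit.n_obs,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_p"] = np.nan
        for grp in out["group"].unique():
            mask = out["group"] == grp
            out.loc[mask, "fdr_p"] = benjamini_hochberg(
                np.clip(out.loc[mask, "p_value"].to_numpy(), 1e-300, 1.0)
            )
    return out.reset_index(drop=True)
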