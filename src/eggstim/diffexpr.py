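"""Per-gene linear-model contrasts, probe preprocessing and DEG signatures.

Three contrast families cover the study design:

1. between-group within one culture condition (e.g. BER vs AC on EW
   samples), adjusting for gender and batch;
2. within-group stimulation response: per-subject EW-M differences
   tested against zero, adjusting for gender and batch;
3. difference of differences: the EW-M response of one group versus
   another (the stimulation-by-group interaction), on per-subject
   differences with gender and batch covariates.

Pairing is handled by explicit per-subject differencing (families 2-3)
rather than subject fixed effects, which keeps every design full-rank.
Per-gene statistics are plain OLS t-tests; no empirical-Bayes variance
moderation is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ContrastSpec, DEGSignature

logger = logging.getLogger(__name__)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_probes_by_detection(
    probe_matrix: pd.DataFrame,
    detected: pd.DataFrame,
    min_fraction: float = 0.20,
) -> pd.DataFrame:
    """Drop probes detected above background in fewer than ``min_fraction``
    of samples (a probe detected in exactly the threshold fraction is
    retained)."""
    if detected.shape != probe_matrix.shape:
        raise ValueError(
            f"detection matrix shape {detected.shape} does not match "
            f"probe matrix shape {probe_matrix.shape}"
        )
    detected = detected.reindex(index=probe_matrix.index, columns=probe_matrix.columns)
    if detected.isna().any().any():
        raise ValueError("detection matrix labels do not match probe matrix")
    frac = detected.astype(bool).mean(axis=1)
    keep = frac >= min_fraction
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filtered %d / %d probes below %.0f%% detection",
                    n_dropped, len(keep), 100 * min_fraction)
    return probe_matrix.loc[keep]


def collapse_probes_to_genes(probe_matrix: pd.DataFrame, probe2gene) -> pd.DataFrame:
    """One row per gene: the probe with the highest mean expression.

    Unmapped probes are dropped (counted in the log). Mean ties break to
    the lexicographically smallest probe id.
    """
    mapped = [p for p in probe_matrix.index if p in probe2gene]
    n_unmapped = len(probe_matrix) - len(mapped)
    if n_unmapped:
        logger.info("dropped %d unmapped probes", n_unmapped)
    sub = probe_matrix.loc[mapped]
    means = sub.mean(axis=1)
    choice = {}  # gene -> probe
    for probe in sorted(mapped):  # sorted: ties go to smallest probe id
        gene = probe2gene[probe]
        best = choice.get(gene)
        if best is None or means[probe] > means[best]:
            choice[gene] = probe
    genes = sorted(choice)
    out = sub.loc[[choice[g] for g in genes]]
    out.index = genes
    return out


def _append_dummies(X_cols, names, series, prefix):
    """Treatment-coded dummies for a categorical covariate (first level ref)."""
    levels = sorted(pd.unique(series))
    for lv in levels[1:]:
        X_cols.append((series == lv).to_numpy(float))
        names.append(f"{prefix}[{lv}]")


def _drop_aliased(X: np.ndarray, names, protected: int):
    """Keep a maximal independent column subset, scanning left to right.

    The first ``protected`` columns (intercept and contrast term) must be
    independent; a rank-deficiency there is an error rather than a drop.
    """
    keep = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
        else:
            if j < protected:
                raise ValueError(f"design column {names[j]!r} is aliased")
            logger.warning("dropping aliased covariate column %r", names[j])
    return X[:, keep], [names[j] for j in keep]


def _ols_per_gene(Y: np.ndarray, X: np.ndarray, coef_idx: int):
    """Vectorized OLS of every row of Y on the shared design X.

    Returns (coef, t, p, df_resid) for the column ``coef_idx``.
    """
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError(f"zero residual degrees of freedom (n={n}, p={p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv.T  # genes x p
    resid = Y - beta @ X.T
    sigma2 = np.einsum("ij,ij->i", resid, resid) / df
    se = np.sqrt(np.maximum(sigma2, 1e-300) * xtx_inv[coef_idx, coef_idx])
    coef = beta[:, coef_idx]
    t = coef / se
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    return coef, t, np.clip(pval, np.finfo(float).tiny, 1.0), df


def _subject_deltas(expr: pd.DataFrame, samples: pd.DataFrame, groups):
    """Per-subject EW-M expression differences for subjects in ``groups``."""
    meta = samples[samples["group"].isin(groups)]
    by_subj = {}
    info = []
    for subj, sub in meta.groupby("subject_id", sort=True):
        stim = sub.set_index("stimulation")["sample_id"]
        if "EW" not in stim.index or "M" not in stim.index:
            logger.info("subject %s lacks a paired EW/M sample; skipped", subj)
            continue
        by_subj[subj] = expr[stim["EW"]].to_numpy() - expr[stim["M"]].to_numpy()
        row = sub.iloc[0]
        info.append({"subject_id": subj, "group": row["group"],
                     "gender": row["gender"], "batch": row["batch"],
                     "ew": stim["EW"], "m": stim["M"]})
    if not by_subj:
        raise ValueError("no paired subjects for the requested groups")
    info = pd.DataFrame(info)
    delta = np.column_stack([by_subj[s] for s in info["subject_id"]])
    return delta, info


def fit_contrast(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: ContrastSpec,
) -> pd.DataFrame:
    """Per-gene linear-model statistics for one contrast.

    Returns a table with ``gene_id, log2FC, ave_expr, p_value, fdr_p,
    contrast_id``, BH-adjusted within this contrast and sorted by
    (p ascending, \\|log2FC\\| descending, gene_id).
    """
    samples = samples.reset_index(drop=True)
    if contrast.family == "between_group_within_condition":
        sel = samples[
            samples["group"].isin([contrast.group_a, contrast.group_b])
            & (samples["stimulation"] == contrast.condition)
        ]
        for g in (contrast.group_a, contrast.group_b):
            if (sel["group"] == g).sum() < 3:
                raise ValueError(f"fewer than 3 samples in group {g}")
        Y = expr[sel["sample_id"]].to_numpy().astype(float)
        cols = [np.ones(len(sel)), (sel["group"] == contrast.group_a).to_numpy(float)]
        names = ["intercept", "group"]
        _append_dummies(cols, names, sel["gender"], "gender")
        _append_dummies(cols, names, sel["batch"], "batch")
        X = np.column_stack(cols)
        ave = Y.mean(axis=1)
    else:
        if contrast.family == "within_group_EW_vs_M":
            groups = [contrast.group_a]
        else:
            groups = [contrast.group_a, contrast.group_b]
        delta, info = _subject_deltas(expr, samples, groups)
        for g in groups:
            if (info["group"] == g).sum() < 3:
                raise ValueError(f"fewer than 3 paired subjects in group {g}")
        Y = delta
        cols = [np.ones(len(info))]
        names = ["intercept"]
        if contrast.family == "difference_of_differences":
            cols.append((info["group"] == contrast.group_a).to_numpy(float))
            names.append("group")
        _append_dummies(cols, names, info["gender"], "gender")
        _append_dummies(cols, names, info["batch"], "batch")
        X = np.column_stack(cols)
        if contrast.family == "within_group_EW_vs_M":
            # center covariates so the intercept is the adjusted mean delta
            X[:, 1:] -= X[:, 1:].mean(axis=0)
        used = list(info["ew"]) + list(info["m"])
        ave = expr[used].to_numpy().mean(axis=1)

    coef_idx = 0 if contrast.family == "within_group_EW_vs_M" else 1
    protected = coef_idx + 1
    X, names = _drop_aliased(X, names, protected)
    coef, _t, pval, _df = _ols_per_gene(Y, X, coef_idx)

    out = pd.DataFrame(
        {
            "gene_id": expr.index,
            "log2FC": coef,
            "ave_expr": ave,
            "p_value": pval,
            "fdr_p": benjamini_hochberg(pval),
            "contrast_id": contrast.contrast_id,
        }
    )
    out = out.sort_values(
        by=["p_value", "log2FC", "gene_id"],
        key=lambda s: -s.abs() if s.name == "log2FC" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def standardize_signature(
    deg: pd.DataFrame,
    direction: str,
    n_significant: int = 500,
    n_top: int = 200,
) -> DEGSignature:
    """Size-standardized DEG signature for one direction.

    Among genes whose fold-change sign matches ``direction``, take the
    ``n_significant`` smallest p-values, then keep the ``n_top`` largest
    absolute fold changes of those, ordered by |log2FC| descending.
    Genes with log2FC exactly 0 belong to neither direction. Ties break
    by (p ascending, |log2FC| descending, gene_id ascending).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sign = 1 if direction == "up" else -1
    sub = deg[np.sign(deg["log2FC"]) == sign].copy()
    sub["abs_fc"] = sub["log2FC"].abs()
    sub = sub.sort_values(
        by=["p_value", "abs_fc", "gene_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).head(n_significant)
    sub = sub.sort_values(
        by=["abs_fc", "p_value", "gene_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).head(n_top)
    contrast_id = deg["contrast_id"].iloc[0] if len(deg) else ""
    return DEGSignature(
        contrast_id=contrast_id,
        direction=direction,
        gene_ids=list(sub["gene_id"]),
    )
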