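"""Lightweight weighted correlation network analysis.

Builds an unsigned soft-thresholded adjacency (|Pearson r|^beta, default
beta = 7), the topological overlap matrix (TOM), detects modules by
average-linkage hierarchical clustering of the TOM dissimilarity with a
static height cut, summarizes each module by its eigengene (first
principal component of the z-scored member genes), merges modules whose
eigengenes are closer than a dissimilarity cutoff (default 0.29), and
associates eigengenes with external traits by simple linear regression
with BH adjustment.

Modules are labelled numerically in order of size (1 = largest); label 0
marks unassigned genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ModulePartition
from .diffexpr import benjamini_hochberg

logger = logging.getLogger(__name__)

DEFAULT_BETA = 7
DEFAULT_MIN_MODULE_SIZE = 50
DEFAULT_MERGE_CUTOFF = 0.29
DEFAULT_CUT_FRACTION = 0.995  # static cut at this fraction of the top merge height


def soft_adjacency(expr: pd.DataFrame, beta: float = DEFAULT_BETA) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency a_ij = |cor(i,j)|^beta.

    Genes with zero variance across samples are removed (logged) since
    their correlation is undefined. The diagonal is 1.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    sd = expr.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("removed %d zero-variance genes", int((~keep).sum()))
        expr = expr.loc[keep]
    r = np.corrcoef(expr.to_numpy())
    a = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with k the connectivity (row sum minus the diagonal), and
    TOM_ii = 1.
    """
    a = adjacency.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.max(np.abs(a - a.T)) > 1e-10:
        raise ValueError("adjacency is not symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    num = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom_dissimilarity: pd.DataFrame,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float | None = None,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    ``cut_height`` defaults to ``DEFAULT_CUT_FRACTION`` times the top
    merge height of the dendrogram. Clusters smaller than
    ``min_module_size`` are left unassigned (label 0); surviving modules
    are renumbered by size descending.
    """
    d = tom_dissimilarity.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    genes = tom_dissimilarity.index
    condensed = squareform(d, checks=False)
    Z = linkage(condensed, method="average")
    if cut_height is None:
        cut_height = DEFAULT_CUT_FRACTION * float(Z[:, 2].max())
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = _relabel_by_size(raw, min_module_size)
    if labels.max() == 0:
        logger.warning("no cluster reached min_module_size=%d; all genes unassigned",
                       min_module_size)
    return ModulePartition(assignment=pd.Series(labels, index=genes, name="module"))


def _relabel_by_size(raw: np.ndarray, min_module_size: int) -> np.ndarray:
    counts = pd.Series(raw).value_counts()
    keep = counts[counts >= min_module_size]
    # size descending, ties by original cluster id for determinism
    ordered = sorted(keep.items(), key=lambda kv: (-kv[1], kv[0]))
    mapping = {old: new for new, (old, _) in enumerate(ordered, start=1)}
    return np.array([mapping.get(x, 0) for x in raw], dtype=int)


def module_eigengene(
    expr: pd.DataFrame,
    partition: ModulePartition,
    module: int,
) -> pd.Series:
    """First principal component of the z-scored member genes, unit norm
    over samples, oriented so the mean correlation with members is >= 0."""
    genes = partition.genes_in(module)
    if len(genes) < 2:
        raise ValueError(f"module {module} has fewer than 2 genes")
    sub = expr.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        logger.info("dropping %d zero-variance genes from module %d eigengene",
                    int((sd == 0).sum()), module)
        sub = sub.loc[sd > 0]
        sd = sd.loc[sd > 0]
    z = (sub.sub(sub.mean(axis=1), axis=0)).div(sd, axis=0).to_numpy()
    _u, _s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    member_cor = z @ eig  # z rows are standardized, so this is prop. to r
    if member_cor.mean() < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns, name=f"ME{module}")


def eigengene_matrix(expr: pd.DataFrame, partition: ModulePartition) -> pd.DataFrame:
    rows = {
        label: module_eigengene(expr, partition, label)
        for label in partition.module_labels()
    }
    return pd.DataFrame(rows).T


def merge_modules(
    expr: pd.DataFrame,
    partition: ModulePartition,
    cutoff: float = DEFAULT_MERGE_CUTOFF,
) -> ModulePartition:
    """Iteratively merge the closest module pair while their eigengene
    dissimilarity (1 - Pearson r) is below ``cutoff``.

    Eigengenes are recomputed after every merge; final labels are
    renumbered by module size descending.
    """
    assignment = partition.assignment.copy()
    while True:
        labels = sorted(set(assignment.values) - {0})
        if len(labels) < 2:
            break
        eg = eigengene_matrix(expr, ModulePartition(assignment))
        r = np.corrcoef(eg.to_numpy())
        dis = 1.0 - r
        np.fill_diagonal(dis, np.inf)
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] >= cutoff:
            break
        a, b = labels[i], labels[j]
        logger.info("merging modules %d and %d (eigengene dissimilarity %.3f)",
                    a, b, dis[i, j])
        assignment[assignment == b] = a
    # renumber by size descending
    raw = assignment.to_numpy()
    sizes = pd.Series(raw[raw != 0]).value_counts()
    ordered = sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0]))
    mapping = {old: new for new, (old, _) in enumerate(ordered, start=1)}
    relabelled = np.array([mapping.get(x, 0) for x in raw], dtype=int)
    return ModulePartition(pd.Series(relabelled, index=assignment.index, name="module"))


def eigengene_subject_deltas(
    eigengenes: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Per-subject EW-M eigengene differences (modules x subjects), for
    association against per-subject traits such as cytokine deltas."""
    meta = samples.set_index("sample_id")
    cols = {}
    for subj, sub in meta.groupby("subject_id", sort=True):
        stim = pd.Series(sub.index, index=sub["stimulation"])
        if "EW" in stim.index and "M" in stim.index:
            cols[subj] = eigengenes[stim["EW"]] - eigengenes[stim["M"]]
    return pd.DataFrame(cols)


def module_trait_association(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Simple linear regression of every trait on every eigengene.

    Both inputs are observation-aligned matrices (modules x obs and
    traits x obs); observations missing from either side are dropped per
    pair. Constant traits yield slope 0, p = 1 (logged). BH adjustment
    runs across all (module, trait) pairs.
    """
    common = [c for c in eigengenes.columns if c in traits.columns]
    if not common:
        raise ValueError("no shared observations between eigengenes and traits")
    rows = []
    for label in eigengenes.index:
        x_full = eigengenes.loc[label, common].astype(float)
        for trait in traits.index:
            y_full = traits.loc[trait, common].astype(float)
            ok = x_full.notna() & y_full.notna()
            x, y = x_full[ok].to_numpy(), y_full[ok].to_numpy()
            if len(x) < 3 or np.ptp(y) == 0 or np.ptp(x) == 0:
                if len(x) >= 3:
                    logger.info("constant eigengene/trait for (%s, %s); p set to 1",
                                label, trait)
                slope, rval, p = 0.0, 0.0, 1.0
            else:
                fit = stats.linregress(x, y)
                slope, rval, p = fit.slope, fit.rvalue, fit.pvalue
            rows.append({"module": label, "trait": trait, "slope": slope,
                         "r": rval, "p_value": p, "n": len(x)})
    out = pd.DataFrame(rows)
    out["fdr_p"] = benjamini_hochberg(np.clip(out["p_value"].to_numpy(), 1e-300, 1.0))
    return out
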