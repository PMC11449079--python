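"""Nonparametric differential expression between bolted and nonbolted plants.

With ~68 individual plants per comparison, a rank-sum test per gene is both
robust and well powered, and no between-sample scaling beyond CPM is applied
(a majority of the transcriptome is expected to shift, which violates the
assumptions of TMM-style normalisation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mann_whitney_per_gene",
    "bh_adjust",
    "classify_de",
    "de_table",
]

#: Largest group size at which the exact Mann-Whitney null is enumerated
#: (ties force the normal approximation regardless).
EXACT_MAX_N = 8


def _as_bool_groups(groups, columns) -> np.ndarray:
    g = pd.Series(groups)
    if not g.index.equals(pd.RangeIndex(len(g))) and set(g.index) >= set(columns):
        g = g.loc[list(columns)]
    elif len(g) != len(columns):
        raise ValueError("group labels do not match sample columns")
    vals = g.to_numpy()
    uniq = set(np.unique(vals))
    if not uniq <= {0, 1, True, False}:
        raise ValueError("groups must be binary (0/1)")
    mask = vals.astype(bool)
    if mask.all() or (~mask).all():
        raise ValueError("both groups must be nonempty")
    return mask


def mann_whitney_per_gene(cpm: pd.DataFrame, groups) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per gene (group 1 vs group 0).

    The exact null distribution is enumerated when both group sizes are at
    most ``EXACT_MAX_N`` and the gene has no ties; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    mask = _as_bool_groups(groups, cpm.columns)
    a = cpm.loc[:, cpm.columns[mask]].to_numpy(dtype=float)
    b = cpm.loc[:, cpm.columns[~mask]].to_numpy(dtype=float)
    n1, n0 = a.shape[1], b.shape[1]
    if max(n1, n0) > EXACT_MAX_N:
        res = stats.mannwhitneyu(a, b, axis=1, method="asymptotic", use_continuity=True)
        u = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        u = np.empty(len(cpm))
        p = np.empty(len(cpm))
        for i in range(len(cpm)):
            row = np.concatenate([a[i], b[i]])
            method = "exact" if len(np.unique(row)) == len(row) else "asymptotic"
            r = stats.mannwhitneyu(a[i], b[i], method=method, use_continuity=True)
            u[i], p[i] = r.statistic, r.pvalue
    return pd.DataFrame({"u_stat": u, "p_value": np.clip(p, 0.0, 1.0)}, index=cpm.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_de(
    p_adjusted, log2fc, alpha: float = 0.05, lfc_threshold: float = 0.1
) -> np.ndarray:
    """up / down / not_de per gene from adjusted p and log2 fold change."""
    p_adjusted = np.asarray(p_adjusted, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    if p_adjusted.shape != log2fc.shape:
        raise ValueError("p_adjusted and log2fc must align gene-wise")
    sig = p_adjusted < alpha
    out = np.full(p_adjusted.shape, "not_de", dtype=object)
    out[sig & (log2fc > lfc_threshold)] = "up"
    out[sig & (log2fc < -lfc_threshold)] = "down"
    return out


def de_table(
    cpm: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    lfc_threshold: float = 0.1,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full DE result: U statistic, raw/adjusted p, log2FC, class per gene.

    log2FC is log2((mean_group1 + c) / (mean_group0 + c)) of CPM group means;
    the pseudocount c keeps zero-mean genes finite while leaving large means
    essentially untouched.
    """
    mask = _as_bool_groups(groups, cpm.columns)
    res = mann_whitney_per_gene(cpm, groups)
    mean1 = cpm.loc[:, cpm.columns[mask]].mean(axis=1).to_numpy()
    mean0 = cpm.loc[:, cpm.columns[~mask]].mean(axis=1).to_numpy()
    log2fc = np.log2((mean1 + pseudocount) / (mean0 + pseudocount))
    p_adj = bh_adjust(res["p_value"].to_numpy())
    res = res.assign(
        p_adjusted=p_adj,
        log2fc=log2fc,
        de_class=classify_de(p_adj, log2fc, alpha=alpha, lfc_threshold=lfc_threshold),
    )
    return res
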