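"""Variant processing and association; GRN edge filtering against a prior.

Genotypes arrive as a VCF (phased or unphased GT plus GQ), are filtered at
the call level (genotype quality, call rate), encoded as alternate-allele
dosages in {0, 1, 2} ("0|1" and "1|0" collapse to 1), and cleaned at the
variant level (all-heterozygous variants removed, minor-allele-frequency
floor). Dosages are then correlated with pseudotime or continuous traits;
a |Pearson r| threshold flags candidate developmental variants.

Edge lists from any network-inference method are filtered by a minimum
weight, a top-fraction rank cut, and intersection with a TF-binding prior.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "load_and_filter_genotypes",
    "variant_measure_correlation",
    "subgroups_from_dosage_pca",
    "subgroup_expression_models",
    "filter_grn_edges",
    "classify_tf_direction",
]


def load_and_filter_genotypes(
    vcf_path,
    gq_min: float = 40,
    call_rate_min: float = 0.8,
    maf_min: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Read a VCF into a variant x sample dosage matrix with QC filters.

    Per call, genotypes with GQ below ``gq_min`` become missing. Variants are
    kept only if biallelic, called in at least ``call_rate_min`` of samples,
    fully called after the GQ filter (no imputation is performed; incomplete
    variants are dropped and counted), not all-heterozygous, and with minor
    allele frequency >= ``maf_min``. Returns (dosages, report dict).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    n = len(samples)
    report = {"multiallelic": 0, "low_call_rate": 0, "incomplete": 0,
              "all_het": 0, "low_maf": 0, "kept": 0}
    rows, ids = [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            report["multiallelic"] += 1
            continue
        gts = var.genotypes  # [allele_a, allele_b, phased] per sample
        gq = var.gt_quals
        dosage = np.full(n, -1, dtype=np.int64)
        for s in range(n):
            a, b = gts[s][0], gts[s][1]
            if a < 0 or b < 0:
                continue
            if gq is not None and np.isfinite(gq[s]) and gq[s] < gq_min:
                continue
            if a > 1 or b > 1:
                raise ValueError(f"malformed GT at {var.ID or var.POS}")
            dosage[s] = a + b  # 0|1 and 1|0 both encode dosage 1
        called = dosage >= 0
        if called.mean() < call_rate_min:
            report["low_call_rate"] += 1
            continue
        if not called.all():
            report["incomplete"] += 1
            continue
        if (dosage == 1).all():
            report["all_het"] += 1
            continue
        af = dosage.sum() / (2 * n)
        if min(af, 1 - af) < maf_min:
            report["low_maf"] += 1
            continue
        rows.append(dosage)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        report["kept"] += 1
    dosages = pd.DataFrame(
        np.array(rows, dtype=np.int64).reshape(len(rows), n),
        index=pd.Index(ids, name="variant_id"),
        columns=samples,
    )
    return dosages, report


def variant_measure_correlation(
    dosages: pd.DataFrame, measure: pd.Series, threshold: float = 0.5
) -> pd.DataFrame:
    """|Pearson r| between each variant's dosage and a per-sample measure.

    ``measure`` may be pseudotime rank, biomass or leaf area; it must cover
    every sample. Constant-dosage variants have undefined correlation and are
    reported as NaN, never selected.
    """
    measure = measure.loc[dosages.columns].astype(float)
    m = measure.to_numpy()
    if np.ptp(m) == 0:
        raise ValueError("measure is constant across samples")
    D = dosages.to_numpy(dtype=float)
    mc = m - m.mean()
    Dc = D - D.mean(axis=1, keepdims=True)
    denom = np.sqrt((Dc**2).sum(axis=1) * (mc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Dc @ mc / denom, np.nan)
    out = pd.DataFrame({"r": r, "abs_r": np.abs(r)}, index=dosages.index)
    out["selected"] = out["abs_r"] > threshold
    out.loc[out["r"].isna(), "selected"] = False
    return out


def subgroups_from_dosage_pca(dosages: pd.DataFrame) -> pd.Series:
    """Binary sample subgroups from the sign of the first principal component
    of the centered dosage matrix — one admissible definition of the
    variant-derived population split."""
    D = dosages.to_numpy(dtype=float)
    Dc = D - D.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Dc, full_matrices=False)
    pc1 = vt[0]
    if pc1.sum() < 0:  # fix the sign for determinism
        pc1 = -pc1
    return pd.Series((pc1 > 0).astype(int), index=dosages.columns, name="subgroup")


def subgroup_expression_models(
    expr: pd.DataFrame, subgroup: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene linear model of log2(TPM + 1) on a binary subgroup label.

    The slope's t-test (equivalent to the pooled-variance two-sample t-test)
    is BH-adjusted across genes; genes with adjusted p < ``alpha`` are
    flagged as subgroup-associated.
    """
    subgroup = subgroup.loc[expr.columns].astype(int)
    g = subgroup.to_numpy()
    if len(np.unique(g)) < 2:
        raise ValueError("both subgroups must be nonempty")
    Y = np.log2(expr.to_numpy(dtype=float) + 1.0)
    n1, n0 = int(g.sum()), int((1 - g).sum())
    m1 = Y[:, g == 1].mean(axis=1)
    m0 = Y[:, g == 0].mean(axis=1)
    ss1 = ((Y[:, g == 1] - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((Y[:, g == 0] - m0[:, None]) ** 2).sum(axis=1)
    df = n1 + n0 - 2
    pooled = (ss1 + ss0) / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, (m1 - m0) / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df=df)
    p_adj = bh_adjust(p)
    return pd.DataFrame(
        {"slope": m1 - m0, "t_stat": t, "p_value": p, "p_adjusted": p_adj,
         "associated": p_adj < alpha},
        index=expr.index,
    )


def filter_grn_edges(
    edges: pd.DataFrame,
    min_weight: float = 1e-10,
    top_fraction: float = 0.05,
    prior: set | pd.DataFrame | None = None,
    top_base: str = "post",
) -> pd.DataFrame:
    """Weight floor -> top-fraction rank cut -> binding-prior intersection.

    ``edges`` has columns regulator, target, weight. The top-fraction count
    is ceil(top_fraction * n) where n is the post-floor edge count by default
    (``top_base='pre'`` uses the original count instead). Ties at the cutoff
    break deterministically by (weight desc, regulator, target). ``prior`` is
    a set of (regulator, target) pairs or a two-column DataFrame; None skips
    the intersection.
    """
    if len(edges) == 0:
        raise ValueError("empty edge list")
    if edges.duplicated(subset=["regulator", "target"]).any():
        raise ValueError("duplicate (regulator, target) pairs")
    if not np.isfinite(edges["weight"].to_numpy()).all():
        raise ValueError("non-finite edge weights")
    base_n = len(edges)
    kept = edges[edges["weight"] >= min_weight].copy()
    n_for_cut = base_n if top_base == "pre" else len(kept)
    n_keep = math.ceil(top_fraction * n_for_cut)
    kept = kept.sort_values(
        by=["weight", "regulator", "target"], ascending=[False, True, True]
    ).head(n_keep)
    if prior is not None:
        if isinstance(prior, pd.DataFrame):
            prior = set(zip(prior["regulator"], prior["target"]))
        mask = [
            (r, t) in prior for r, t in zip(kept["regulator"], kept["target"])
        ]
        kept = kept[np.array(mask, dtype=bool)] if len(kept) else kept
    return kept.reset_index(drop=True)


def classify_tf_direction(fit) -> str:
    """'decreasing' if the curve starts above where it ends, else 'increasing'.

    ``fit`` is a rescaled curve evaluator (e.g. a SplineFit): the comparison
    is f(0) > f(1) strictly; equality falls to the 'increasing' branch.
    """
    vals = fit(np.array([0.0, 1.0]))
    return "decreasing" if vals[0] > vals[1] else "increasing"
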