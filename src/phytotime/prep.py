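"""Expression-matrix I/O and preprocessing.

Matrices are plain pandas DataFrames with genes (or transcripts/variants) on
the rows and samples on the columns; TSVs carry the row-identifier as the
first column. Units (TPM, CPM, counts) are the caller's responsibility and are
documented per function.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "read_matrix_tsv",
    "read_trait_tsv",
    "read_tx2gene",
    "read_go_map",
    "aggregate_isoforms",
    "filter_low_expression",
    "cpm_from_counts",
    "sample_correlation_clustering",
]


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a feature-by-sample TSV (first column = feature id)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    if m.index.has_duplicates:
        raise ValueError("duplicate feature identifiers in matrix")
    return m


def read_trait_tsv(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", index_col=0)
    if "bolted" in t and not set(np.unique(t["bolted"])) <= {0, 1}:
        raise ValueError("bolted column must be binary 0/1")
    return t


def read_tx2gene(path) -> pd.Series:
    """Two-column TSV transcript_id<TAB>gene_id -> Series mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "gene_id"])
    return df.set_index("transcript_id")["gene_id"]


def read_go_map(path) -> pd.DataFrame:
    """Two-column TSV gene_id<TAB>term_id (many-to-many)."""
    return pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"])


def aggregate_isoforms(tx_matrix: pd.DataFrame, tx2gene: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Sum transcript-level values to gene level.

    Every transcript must map to a gene; unmapped ids are reported in the
    raised error so quantification/annotation mismatches surface early.
    """
    if tx_matrix.index.has_duplicates:
        dups = tx_matrix.index[tx_matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate transcript rows: {dups[:5]}")
    mapping = pd.Series(dict(tx2gene)) if not isinstance(tx2gene, pd.Series) else tx2gene
    if len(mapping) == 0:
        raise ValueError("empty transcript-to-gene mapping")
    unmapped = tx_matrix.index.difference(mapping.index)
    if len(unmapped):
        raise ValueError(f"transcripts with no gene mapping: {sorted(unmapped)[:10]}")
    genes = mapping.loc[tx_matrix.index].to_numpy()
    out = tx_matrix.groupby(genes, sort=True).sum()
    out.index.name = "gene_id"
    return out


def filter_low_expression(
    m: pd.DataFrame, zero_sample_min: int = 10, min_tpm: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genes with TPM 0 in >= ``zero_sample_min`` samples, or below
    ``min_tpm`` in every sample.

    Returns (filtered matrix, removal report with per-criterion flags).
    """
    if zero_sample_min < 1:
        raise ValueError("zero_sample_min must be >= 1")
    vals = m.to_numpy()
    many_zero = (vals == 0).sum(axis=1) >= zero_sample_min
    all_low = (vals < min_tpm).all(axis=1)
    removed = many_zero | all_low
    report = pd.DataFrame(
        {"many_zero": many_zero, "all_low": all_low, "removed": removed}, index=m.index
    )
    return m.loc[~removed], report


def cpm_from_counts(reads: pd.DataFrame) -> pd.DataFrame:
    """Counts -> counts-per-million per sample; columns then sum to 1e6."""
    totals = reads.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    return reads * 1e6 / totals


def sample_correlation_clustering(
    m: pd.DataFrame, n_clusters: int = 2
) -> tuple[pd.Series, np.ndarray, pd.Series]:
    """Hierarchical clustering of samples on 1 - Pearson correlation.

    Uses complete linkage; returns (labels, linkage matrix, outlier flags).
    A sample is flagged as an outlier when the height at which it first merges
    exceeds the 95th percentile of all cophenetic distances — flagged only,
    never silently removed.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    vals = m.to_numpy(dtype=float)
    sds = vals.std(axis=0)
    if (sds == 0).any():
        bad = m.columns[sds == 0].tolist()
        raise ValueError(f"constant sample columns (undefined correlation): {bad}")
    corr = np.corrcoef(vals.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # guard tiny asymmetries
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    labels = pd.Series(
        hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust"), index=m.columns, name="cluster"
    )
    coph = hierarchy.cophenet(Z)
    cut = np.percentile(coph, 95)
    coph_sq = squareform(coph)
    np.fill_diagonal(coph_sq, np.inf)
    first_merge = coph_sq.min(axis=1)
    outliers = pd.Series(first_merge > cut, index=m.columns, name="outlier")
    if outliers.any():
        warnings.warn(
            f"samples flagged as clustering outliers: {m.columns[outliers].tolist()}",
            stacklevel=2,
        )
    return labels, Z, outliers
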