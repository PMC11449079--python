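"""Consensus pseudotime for small asynchronous plant populations.

Standard trajectory-inference methods need hundreds to thousands of cells;
a bench population of tens of plants is far below that. This module instead
exploits the assumption that most differentially expressed genes change
monotonically with developmental age: each DE gene is normalised to a [0, 1]
profile oriented to rise with age (downregulated genes are flipped), genes
are randomly partitioned into groups, each group orders the samples by its
summed normalised expression, and the per-group orderings are combined into a
consensus by assigning each sample to its most common predicted position.

Because several samples can share a modal position (and some positions can go
unclaimed), the consensus uses an explicit deterministic resolution rule:
positions are processed in order, each claimed position goes to the claimant
with the smallest mean rank across groups, and unclaimed positions are filled
at the end by the remaining samples ordered by mean rank. When modes are
uninformative this degrades gracefully to mean-rank ordering.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "normalize_for_pseudotime",
    "partition_genes",
    "order_samples_by_group",
    "consensus_order",
    "orient_pseudotime",
    "ConsensusPseudotime",
]


def normalize_for_pseudotime(
    tpm: pd.DataFrame, de: pd.DataFrame, flip_down: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalise DE genes to directed [0, 1] profiles.

    Per gene: z-score TPM across samples, truncate at +/-3, min-max rescale
    to [0, 1], then (if ``flip_down``) replace x by 1-x for downregulated
    genes so every profile increases with biological age.

    Only genes classified up or down in ``de`` are admitted. Genes with zero
    variance, or constant after clipping, cannot be rescaled and are excluded
    with a warning. Returns (normalised matrix, direction Series).
    """
    keep = de.index[de["de_class"].isin(["up", "down"])]
    keep = keep.intersection(tpm.index)
    sub = tpm.loc[keep].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    nonconst = sd[:, 0] > 0
    z = np.clip((sub[nonconst] - mu[nonconst]) / sd[nonconst], -3.0, 3.0)
    zmin = z.min(axis=1, keepdims=True)
    zmax = z.max(axis=1, keepdims=True)
    spread = (zmax - zmin)[:, 0]
    ok = spread > 0
    x = (z[ok] - zmin[ok]) / (zmax[ok] - zmin[ok])
    kept_ids = keep[nonconst][ok]
    dropped = len(keep) - len(kept_ids)
    if dropped:
        warnings.warn(f"excluded {dropped} constant/degenerate gene(s) from normalization",
                      stacklevel=2)
    directions = de.loc[kept_ids, "de_class"].rename("direction")
    if flip_down:
        x = np.where((directions == "down").to_numpy()[:, None], 1.0 - x, x)
    norm = pd.DataFrame(x, index=kept_ids, columns=tpm.columns)
    return norm, directions


def partition_genes(gene_ids, n_groups: int = 100, seed: int | None = None) -> list[np.ndarray]:
    """Random balanced partition of genes into ``n_groups`` disjoint groups."""
    gene_ids = np.asarray(list(gene_ids))
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > len(gene_ids):
        raise ValueError("n_groups cannot exceed the number of genes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(gene_ids))
    return [gene_ids[idx] for idx in np.array_split(perm, n_groups)]


def order_samples_by_group(norm: pd.DataFrame, group) -> list:
    """Samples sorted ascending by the group's summed normalised expression.

    Ties are broken by lexicographic sample identifier so the ordering is a
    pure function of the data.
    """
    group = list(group)
    if len(group) == 0:
        raise ValueError("empty gene group")
    sums = norm.loc[group].sum(axis=0)
    order = sorted(norm.columns, key=lambda s: (sums[s], str(s)))
    return order


def _ranks_from_orderings(orderings: list[list], samples: list) -> np.ndarray:
    """G x n matrix of 1-based positions per sample."""
    n = len(samples)
    pos = {s: i for i, s in enumerate(samples)}
    ranks = np.empty((len(orderings), n), dtype=np.int64)
    for g, ordering in enumerate(orderings):
        if len(ordering) != n:
            raise ValueError("orderings of unequal length")
        for r, s in enumerate(ordering, start=1):
            ranks[g, pos[s]] = r
    return ranks


def consensus_order(group_ranks: np.ndarray) -> np.ndarray:
    """Combine per-group sample positions into one consensus permutation.

    ``group_ranks`` is G x n with each row a permutation of 1..n. Each
    sample's modal position is computed (mode ties -> smaller position);
    collisions and gaps are resolved deterministically by mean rank as
    described in the module docstring. Returns the consensus rank (1..n)
    per sample.
    """
    group_ranks = np.asarray(group_ranks)
    if group_ranks.ndim != 2:
        raise ValueError("group_ranks must be a G x n matrix")
    G, n = group_ranks.shape
    for g in range(G):
        if not np.array_equal(np.sort(group_ranks[g]), np.arange(1, n + 1)):
            raise ValueError(f"row {g} is not a permutation of 1..{n}")
    modal = np.empty(n, dtype=np.int64)
    for s in range(n):
        counts = np.bincount(group_ranks[:, s], minlength=n + 1)
        modal[s] = counts.argmax()  # argmax returns the smallest tied position
    mean_rank = group_ranks.mean(axis=0)

    consensus = np.zeros(n, dtype=np.int64)
    unassigned = set(range(n))
    unclaimed_positions = []
    for p in range(1, n + 1):
        claimants = [s for s in unassigned if modal[s] == p]
        if claimants:
            chosen = min(claimants, key=lambda s: (mean_rank[s], s))
            consensus[chosen] = p
            unassigned.discard(chosen)
        else:
            unclaimed_positions.append(p)
    leftovers = sorted(unassigned, key=lambda s: (mean_rank[s], s))
    for p, s in zip(unclaimed_positions, leftovers):
        consensus[s] = p
    return consensus


def orient_pseudotime(consensus_rank: pd.Series, bolted: pd.Series) -> tuple[pd.Series, bool]:
    """Ensure bolted plants sit late in pseudotime.

    If the mean consensus rank of bolted samples is below that of nonbolted
    samples the ordering is reversed. Returns (oriented ranks, reversed flag).
    """
    bolted = bolted.loc[consensus_rank.index].astype(bool)
    if bolted.all() or (~bolted).all():
        warnings.warn("all samples share one bolting status; orientation unchanged", stacklevel=2)
        return consensus_rank, False
    if consensus_rank[bolted].mean() < consensus_rank[~bolted].mean():
        n = len(consensus_rank)
        return (n + 1 - consensus_rank), True
    return consensus_rank, False


class ConsensusPseudotime(TransformerMixin, BaseEstimator):
    """Consensus rank-sum pseudotime ordering.

    Parameters
    ----------
    n_groups : int
        Number of random disjoint gene groups, each of which produces an
        independent sample ordering.
    random_state : int or None
        Seed for the gene partition.

    Attributes
    ----------
    group_orderings_ : ndarray of shape (n_groups, n_samples)
        Per-group 1-based position of each sample.
    consensus_rank_ : Series
        Consensus position (1..n) per sample, oriented if ``orient`` ran.
    pseudotime_ : Series
        (rank-1)/(n-1), the pseudotime position in [0, 1] per sample.
    reversed_ : bool
        Whether orientation reversed the raw consensus.
    """

    def __init__(self, n_groups: int = 100, random_state: int | None = None):
        self.n_groups = n_groups
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        """Fit on a samples x genes matrix of directed [0, 1] profiles."""
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        norm = X.T  # genes x samples internally
        n_groups = min(self.n_groups, norm.shape[0])
        self.groups_ = partition_genes(norm.index, n_groups=n_groups, seed=self.random_state)
        samples = list(norm.columns)
        orderings = [order_samples_by_group(norm, g) for g in self.groups_]
        self.group_orderings_ = _ranks_from_orderings(orderings, samples)
        ranks = consensus_order(self.group_orderings_)
        self.consensus_rank_ = pd.Series(ranks, index=samples, name="consensus_rank")
        self.reversed_ = False
        self._finalize()
        return self

    def _finalize(self):
        n = len(self.consensus_rank_)
        self.pseudotime_ = ((self.consensus_rank_ - 1) / (n - 1)).rename("pseudotime_position")

    def orient(self, bolted: pd.Series):
        """Reverse the ordering if bolted plants sit early; records the flag."""
        self.consensus_rank_, self.reversed_ = orient_pseudotime(self.consensus_rank_, bolted)
        self._finalize()
        return self

    def transform(self, X=None):
        """Return pseudotime positions of the fitted samples (transductive)."""
        return self.pseudotime_.to_numpy()[:, None]

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)
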