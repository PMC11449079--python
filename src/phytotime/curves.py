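"""Smoothing and timing analysis of expression over pseudotime.

Each gene's normalised expression over the pseudotime axis is smoothed with a
cubic B-spline penalised by the integrated squared second derivative:

    minimise  ||y - B c||^2 + lambda * c' P c,   P_ij = int B_i'' B_j''

a linear smoother whose generalized cross-validation score
GCV = n * RSS / (n - tr(H))^2 approximates leave-one-out error. A single
(basis size, lambda) pair is chosen by minimising summed GCV across genes,
the best-fitting genes are retained, curves are rescaled to [0, 1], genes
whose derivative never changes sign (within a small tolerance) are flagged
monotone, and each monotone gene is summarised by the area under its rescaled
curve — small AUC means the gene changes early in pseudotime (increasing
genes are first flipped to 1-x so the convention is shared).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import LinAlgError, solve
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "PenalizedBSplineSmoother",
    "SplineFit",
    "fit_penalized_spline",
    "fit_gene_curves",
    "select_hyperparameters",
    "select_top_genes_by_gcv",
    "range_iqr_filter",
    "monotonicity_flag",
    "auc_timing",
    "timing_table",
    "shape_distance",
    "KShapeClusterer",
    "wss_elbow",
    "nemenyi_all_pairs",
    "compact_letter_display",
    "go_group_auc_tests",
]

#: Evaluation grid used for rescaling, monotonicity and curve export.
EVAL_GRID = np.linspace(0.0, 1.0, 201)


def _knots(n_basis: int) -> np.ndarray:
    """Clamped cubic knot vector on [0, 1] with equally spaced interior knots."""
    if n_basis < 4:
        raise ValueError("cubic splines need n_basis >= 4")
    interior = np.linspace(0.0, 1.0, n_basis - 2)[1:-1]
    return np.concatenate([[0.0] * 4, interior, [1.0] * 4])


def _design(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    n_basis = len(knots) - 4
    return BSpline(knots, np.eye(n_basis), 3)(t)


def _second_derivative_penalty(knots: np.ndarray) -> np.ndarray:
    """Exact int_0^1 B_i'' B_j'' via 2-point Gauss-Legendre per knot span.

    Second derivatives of cubic B-splines are piecewise linear, so their
    products are piecewise quadratic and the 2-point rule is exact.
    """
    n_basis = len(knots) - 4
    d2 = BSpline(knots, np.eye(n_basis), 3).derivative(2)
    breaks = np.unique(knots)
    gl_x, gl_w = np.polynomial.legendre.leggauss(2)
    P = np.zeros((n_basis, n_basis))
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = (b - a) / 2.0
        pts = (a + b) / 2.0 + half * gl_x
        vals = d2(pts)  # (2, n_basis)
        P += half * (vals.T * gl_w) @ vals
    return P


class PenalizedBSplineSmoother(BaseEstimator):
    """Cubic B-spline smoother with a second-derivative roughness penalty.

    Parameters
    ----------
    n_basis : int
        Number of cubic B-spline basis functions (>= 4); interior knots are
        equally spaced on [0, 1].
    lam : float
        Roughness penalty weight lambda >= 0. The penalty null space contains
        all linear functions, so linear data is reproduced for any lambda.

    Attributes
    ----------
    coef_ : ndarray
        Fitted basis coefficients.
    hat_trace_ : float
        Effective degrees of freedom tr(H).
    rss_, gcv_ : float
        Residual sum of squares and n*RSS/(n - tr(H))^2.
    degenerate_ : bool
        True when n - tr(H) <= 0 (oversmoothing degeneracy); such fits are
        rejected by the selection machinery.
    """

    def __init__(self, n_basis: int = 12, lam: float = 1.0):
        self.n_basis = n_basis
        self.lam = lam

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(t) != len(y):
            raise ValueError("positions and values must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        knots = _knots(self.n_basis)
        B = _design(t, knots)
        P = _second_derivative_penalty(knots)
        A = B.T @ B + self.lam * P
        try:
            coef = solve(A, B.T @ y, assume_a="sym")
            hat_trace = float(np.trace(solve(A, B.T @ B, assume_a="sym")))
        except LinAlgError:
            coef, *_ = np.linalg.lstsq(A, B.T @ y, rcond=None)
            hat_trace = float(np.trace(np.linalg.lstsq(A, B.T @ B, rcond=None)[0]))
        self.knots_ = knots
        self.coef_ = coef
        self.spline_ = BSpline(knots, coef, 3)
        n = len(y)
        resid = y - B @ coef
        self.rss_ = float(resid @ resid)
        self.hat_trace_ = hat_trace
        denom = n - hat_trace
        self.degenerate_ = denom <= 1e-10
        self.gcv_ = math.inf if self.degenerate_ else n * self.rss_ / denom**2
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).ravel()
        return self.spline_(t)

    def hat_matrix(self, X) -> np.ndarray:
        """Smoother (hat) matrix at the training positions; O(n^2) memory."""
        t = np.asarray(X, dtype=float).ravel()
        B = _design(t, self.knots_)
        P = _second_derivative_penalty(self.knots_)
        A = B.T @ B + self.lam * P
        return B @ np.linalg.solve(A, B.T)


@dataclass
class SplineFit:
    """A fitted, [0, 1]-rescalable curve for one gene."""

    gene_id: str
    smoother: PenalizedBSplineSmoother
    grid_min: float
    grid_max: float
    gcv: float

    def __call__(self, t) -> np.ndarray:
        """Rescaled evaluator: min 0 / max 1 over the dense evaluation grid."""
        raw = self.smoother.predict(np.asarray(t, dtype=float))
        return (raw - self.grid_min) / (self.grid_max - self.grid_min)

    def raw(self, t) -> np.ndarray:
        return self.smoother.predict(np.asarray(t, dtype=float))

    def derivative(self, t) -> np.ndarray:
        """Derivative of the rescaled curve."""
        d = self.smoother.spline_.derivative(1)(np.asarray(t, dtype=float))
        return d / (self.grid_max - self.grid_min)

    def integral(self) -> float:
        """Exact integral of the rescaled curve over [0, 1]."""
        raw_int = self.smoother.spline_.integrate(0.0, 1.0)
        return float((raw_int - self.grid_min) / (self.grid_max - self.grid_min))


def fit_penalized_spline(y, positions, n_basis: int = 12, lam: float = 1.0,
                         gene_id: str = "gene") -> SplineFit:
    """Fit one gene and wrap it with its [0, 1] rescaling."""
    sm = PenalizedBSplineSmoother(n_basis=n_basis, lam=lam).fit(positions, y)
    grid_vals = sm.predict(EVAL_GRID)
    lo, hi = float(grid_vals.min()), float(grid_vals.max())
    if hi - lo <= 0:
        raise ValueError(f"flat fitted curve for {gene_id}; cannot rescale")
    return SplineFit(gene_id=gene_id, smoother=sm, grid_min=lo, grid_max=hi, gcv=sm.gcv_)


def _batch_fit(Y: np.ndarray, t: np.ndarray, n_basis: int, lam: float):
    """Fit all genes sharing one position grid; returns (coef matrix, gcv, trH).

    One factorisation serves every gene because the design depends only on
    the positions.
    """
    knots = _knots(n_basis)
    B = _design(t, knots)
    P = _second_derivative_penalty(knots)
    A = B.T @ B + lam * P
    try:
        C = solve(A, B.T @ Y.T, assume_a="sym")
        hat_trace = float(np.trace(solve(A, B.T @ B, assume_a="sym")))
    except LinAlgError:
        C = np.linalg.lstsq(A, B.T @ Y.T, rcond=None)[0]
        hat_trace = float(np.trace(np.linalg.lstsq(A, B.T @ B, rcond=None)[0]))
    resid = Y.T - B @ C
    rss = (resid**2).sum(axis=0)
    n = len(t)
    denom = n - hat_trace
    gcv = np.full(len(Y), np.inf) if denom <= 1e-10 else n * rss / denom**2
    return C.T, gcv, hat_trace


def select_hyperparameters(
    Y: pd.DataFrame,
    positions,
    basis_grid=(8, 12, 16, 20, 24),
    lambda_grid=tuple(np.logspace(-6, 2, 9)),
) -> tuple[int, float, pd.DataFrame]:
    """One (n_basis, lambda) pair minimising total GCV across all genes.

    ``Y`` is genes x samples with columns already in pseudotime order at the
    given positions. Returns (n_basis, lambda, full grid surface).
    """
    if len(basis_grid) == 0 or len(lambda_grid) == 0:
        raise ValueError("hyperparameter grids must be nonempty")
    t = np.asarray(positions, dtype=float)
    vals = Y.to_numpy(dtype=float)
    rows = []
    for nb in basis_grid:
        for lam in lambda_grid:
            _, gcv, _ = _batch_fit(vals, t, nb, lam)
            total = float(gcv.sum()) if np.isfinite(gcv).all() else math.inf
            rows.append({"n_basis": nb, "lam": lam, "total_gcv": total})
    surface = pd.DataFrame(rows)
    if not np.isfinite(surface["total_gcv"]).any():
        raise ValueError("all hyperparameter combinations gave degenerate fits")
    best = surface.loc[surface["total_gcv"].idxmin()]
    return int(best["n_basis"]), float(best["lam"]), surface


def fit_gene_curves(
    Y: pd.DataFrame, positions, n_basis: int, lam: float
) -> tuple[dict[str, SplineFit], pd.Series]:
    """Fit every gene at fixed hyperparameters; returns (fits, gcv Series).

    Genes whose fitted curve is flat on the evaluation grid cannot be
    rescaled and are dropped with a warning.
    """
    t = np.asarray(positions, dtype=float)
    coefs, gcv, _ = _batch_fit(Y.to_numpy(dtype=float), t, n_basis, lam)
    knots = _knots(n_basis)
    fits: dict[str, SplineFit] = {}
    dropped = []
    for i, gid in enumerate(Y.index):
        sm = PenalizedBSplineSmoother(n_basis=n_basis, lam=lam)
        sm.knots_ = knots
        sm.coef_ = coefs[i]
        sm.spline_ = BSpline(knots, coefs[i], 3)
        sm.gcv_ = float(gcv[i])
        grid_vals = sm.spline_(EVAL_GRID)
        lo, hi = float(grid_vals.min()), float(grid_vals.max())
        if hi - lo <= 0:
            dropped.append(gid)
            continue
        fits[gid] = SplineFit(gene_id=gid, smoother=sm, grid_min=lo, grid_max=hi,
                              gcv=float(gcv[i]))
    if dropped:
        warnings.warn(f"dropped {len(dropped)} flat fitted curve(s)", stacklevel=2)
    return fits, pd.Series({g: f.gcv for g, f in fits.items()}, name="gcv")


def select_top_genes_by_gcv(gcv: pd.Series, k: int = 4000) -> pd.Index:
    """The k genes with smallest GCV; boundary ties broken by gene id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(gcv):
        raise ValueError("k exceeds the number of fitted genes")
    order = sorted(gcv.index, key=lambda g: (gcv[g], str(g)))
    return pd.Index(order[:k])


def range_iqr_filter(raw: pd.DataFrame, max_ratio: float = 4.0) -> pd.Series:
    """Keep flag per gene: drop when (max-min)/IQR > max_ratio.

    Spiky genes (a few samples far above the rest) smooth badly; an IQR of 0
    is treated as an infinite ratio, hence dropped.
    """
    vals = raw.to_numpy(dtype=float)
    if vals.shape[1] == 0:
        raise ValueError("empty value rows")
    rng_ = vals.max(axis=1) - vals.min(axis=1)
    q75, q25 = np.percentile(vals, [75, 25], axis=1)
    iqr = q75 - q25
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(iqr > 0, rng_ / np.where(iqr > 0, iqr, 1.0), np.inf)
    keep = pd.Series(ratio <= max_ratio, index=raw.index, name="keep")
    return keep


def monotonicity_flag(fit: SplineFit, tol: float = 1e-3, grid=None) -> tuple[bool, str]:
    """(monotone, direction) from the derivative of the rescaled curve.

    Derivative values within +/-tol are set to 0 before checking sign
    changes, so shallow numerical dips do not disqualify a gene. Direction
    comes from the surviving sign; if every value is within tolerance the
    endpoint rule sign(f(1) - f(0)) decides.
    """
    g = EVAL_GRID if grid is None else np.asarray(grid, dtype=float)
    d = fit.derivative(g)
    d = np.where(np.abs(d) <= tol, 0.0, d)
    has_pos = bool((d > 0).any())
    has_neg = bool((d < 0).any())
    monotone = not (has_pos and has_neg)
    if has_pos and not has_neg:
        direction = "increasing"
    elif has_neg and not has_pos:
        direction = "decreasing"
    else:
        vals = fit(np.array([0.0, 1.0]))
        direction = "decreasing" if vals[0] > vals[1] else "increasing"
    return monotone, direction


def auc_timing(fit: SplineFit, direction: str) -> float:
    """AUC timing statistic of a monotone, rescaled curve.

    Decreasing genes: integral of the curve; increasing genes: integral of
    1 - curve. Either way a small AUC marks a gene that changes early in
    pseudotime. Computed exactly from the spline antiderivative.
    """
    monotone, _ = monotonicity_flag(fit)
    if not monotone:
        raise ValueError(f"{fit.gene_id}: AUC is defined only for monotone curves")
    integral = fit.integral()
    auc = integral if direction == "decreasing" else 1.0 - integral
    return float(min(max(auc, 0.0), 1.0))


def timing_table(fits: dict[str, SplineFit], tol: float = 1e-3) -> pd.DataFrame:
    """Per-gene monotone flag, direction and AUC (NaN for non-monotone)."""
    rows = []
    for gid, fit in fits.items():
        monotone, direction = monotonicity_flag(fit, tol=tol)
        auc = auc_timing(fit, direction) if monotone else np.nan
        rows.append({"gene_id": gid, "monotone": monotone, "direction": direction, "auc": auc})
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# shape-based clustering


def shape_distance(x, y) -> float:
    """Shape-based distance: 1 - max over shifts of the normalised
    cross-correlation CC_w(x, y)/(||x|| ||y||). Symmetric, in [0, 2], and
    invariant to positive scaling of either series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("series must share a length >= 2")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm series")
    cc = np.correlate(x, y, mode="full")
    return float(1.0 - cc.max() / (nx * ny))


def _best_shift(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Zero-padded shift of x maximising cross-correlation with ref."""
    cc = np.correlate(ref, x, mode="full")
    lag = int(cc.argmax()) - (len(x) - 1)
    out = np.zeros_like(x)
    if lag >= 0:
        out[lag:] = x[: len(x) - lag]
    else:
        out[:lag] = x[-lag:]
    return out


def _shape_extract(members: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Cluster centroid maximising summed squared NCC with its members.

    Members are aligned to the reference, and the centroid is the leading
    eigenvector of the aligned-series Gram matrix (the k-shape shape
    extraction step), sign-fixed toward the reference.
    """
    S = np.stack([_best_shift(m, ref) for m in members])
    M = S.T @ S
    _, vecs = np.linalg.eigh(M)
    mu = vecs[:, -1]
    if mu @ ref < 0:
        mu = -mu
    norm = np.linalg.norm(mu)
    return mu / norm if norm > 0 else ref


class KShapeClusterer(ClusterMixin, BaseEstimator):
    """k-shape-style clustering of expression curves under shape distance.

    Iterates assignment (nearest centroid by :func:`shape_distance`) and
    shape extraction; the best of ``n_init`` seeded restarts by within-cluster
    sum of squared distances (WSS) is kept.

    Attributes: ``labels_``, ``cluster_centers_``, ``wss_`` (= ``inertia_``).
    """

    def __init__(self, n_clusters: int = 2, n_init: int = 5, max_iter: int = 50,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = len(X)
        if self.n_clusters > n:
            raise ValueError("more clusters than curves")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            labels, centers, wss = self._run_once(X, rng)
            if best is None or wss < best[2]:
                best = (labels, centers, wss)
        self.labels_, self.cluster_centers_, self.wss_ = best
        self.inertia_ = self.wss_
        return self

    def _run_once(self, X, rng):
        n, k = len(X), self.n_clusters
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        labels = np.zeros(n, dtype=int)
        for _ in range(self.max_iter):
            D = np.array([[shape_distance(x, c) for c in centers] for x in X])
            new_labels = D.argmin(axis=1)
            for j in range(k):  # revive empty clusters with a random member
                if not (new_labels == j).any():
                    new_labels[rng.integers(n)] = j
            if (new_labels == labels).all() and _ > 0:
                break
            labels = new_labels
            for j in range(k):
                centers[j] = _shape_extract(X[labels == j], centers[j])
        wss = float(sum(shape_distance(X[i], centers[labels[i]]) ** 2 for i in range(n)))
        return labels, centers, wss


def wss_elbow(curves, k_range=range(2, 11), n_restarts: int = 5,
              random_state: int | None = None):
    """WSS curve over k plus an automatic elbow.

    Returns (results dict k -> fitted KShapeClusterer, wss Series, k_selected).
    The selected k maximises the second difference of the WSS curve — a
    reproducible stand-in for picking the elbow by eye; callers may override.
    """
    curves = np.asarray(curves, dtype=float)
    ks = list(k_range)
    if max(ks) > len(curves):
        raise ValueError("k exceeds the number of curves")
    results = {}
    wss = {}
    for i, k in enumerate(ks):
        seed = None if random_state is None else random_state + i
        km = KShapeClusterer(n_clusters=k, n_init=n_restarts, random_state=seed).fit(curves)
        results[k] = km
        wss[k] = km.wss_
    wss = pd.Series(wss, name="wss")
    if len(ks) >= 3:
        second_diff = wss.to_numpy()[:-2] - 2 * wss.to_numpy()[1:-1] + wss.to_numpy()[2:]
        k_selected = ks[1 + int(np.argmax(second_diff))]
    else:
        k_selected = ks[int(np.argmin(wss.to_numpy()))]
    return results, wss, k_selected


# ---------------------------------------------------------------------------
# GO-group timing tests


def nemenyi_all_pairs(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs Nemenyi post hoc on pooled ranks with the chi-square
    approximation (tie-corrected); returns a symmetric p-value DataFrame."""
    names = list(groups)
    sizes = {g: len(groups[g]) for g in names}
    pooled = np.concatenate([groups[g] for g in names])
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        mean_ranks[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (tie_counts**3 - tie_counts).sum() / (N**3 - N)
    var_term = N * (N + 1) / 12.0 * tie_corr
    k = len(names)
    P = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            stat = (mean_ranks[gi] - mean_ranks[gj]) ** 2 / (
                var_term * (1.0 / sizes[gi] + 1.0 / sizes[gj])
            )
            p = float(stats.chi2.sf(stat, df=k - 1))
            P.loc[gi, gj] = P.loc[gj, gi] = p
    return P


def compact_letter_display(pairwise_p: pd.DataFrame, alpha: float = 0.01) -> dict[str, str]:
    """Insert-and-absorb compact letter display: groups sharing no letter
    differ at the given significance level."""
    names = list(pairwise_p.index)
    letters: list[set[str]] = [set(names)]
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            if pairwise_p.loc[gi, gj] >= alpha:
                continue
            new: list[set[str]] = []
            for L in letters:
                if gi in L and gj in L:
                    new.extend(c for c in (L - {gi}, L - {gj}) if c)
                else:
                    new.append(L)
            # absorb: deduplicate, then drop proper subsets
            uniq = [set(s) for s in dict.fromkeys(frozenset(L) for L in new)]
            letters = [L for L in uniq if not any(L < other for other in uniq)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for idx, L in enumerate(letters):
        ch = alphabet[idx % len(alphabet)]
        for g in L:
            out[g] += ch
    return {g: "".join(sorted(v)) for g, v in out.items()}


def go_group_auc_tests(
    timing: pd.DataFrame,
    go_map: pd.DataFrame,
    size_bounds: tuple[int, int] = (10, 200),
    alpha: float = 0.01,
) -> dict:
    """Do annotation terms differ in expression timing?

    AUC values of monotone genes are grouped by term (terms restricted to a
    comparable annotated-gene count via ``size_bounds``), tested with
    Kruskal-Wallis, and followed by the Nemenyi all-pairs post hoc with a
    compact letter display at corrected p < ``alpha``.
    """
    mono = timing[timing["monotone"] & timing["auc"].notna()]
    merged = go_map[go_map["gene_id"].isin(mono.index)]
    groups = {}
    for term, sub in merged.groupby("term_id"):
        genes = sub["gene_id"].unique()
        if size_bounds[0] <= len(genes) <= size_bounds[1]:
            groups[term] = mono.loc[genes, "auc"].to_numpy()
    if len(groups) < 2:
        raise ValueError("fewer than 2 eligible terms within size bounds")
    _, omnibus_p = stats.kruskal(*groups.values())
    pairwise = nemenyi_all_pairs(groups)
    letters = compact_letter_display(pairwise, alpha=alpha)
    return {
        "omnibus_p": float(omnibus_p),
        "significant": bool(omnibus_p < alpha),
        "pairwise_p": pairwise,
        "letters": letters,
        "group_sizes": {t: len(v) for t, v in groups.items()},
    }
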