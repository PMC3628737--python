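"""Robust taxon x lipid correlation screen with q-value FDR control.

The screen correlates every genus-level taxon against every lipid species
across pooled observations using the biweight midcorrelation (bicor), a
median/MAD-based correlation with Tukey biweight downweighting of outlying
observations.  Significance comes from the Student-t approximation (optionally
a permutation test), and multiplicity over the taxa x lipids grid is handled
with Storey q-values, which estimate the null proportion pi0 instead of
assuming every test null as Benjamini-Hochberg does.  Pairs with q below a
cut-off and |r| above a magnitude floor form the significant selection; the
full r matrix restricted to features with at least one significant pair is
ordered by two-way average-linkage (UPGMA) hierarchical clustering for
heatmap display and downstream biclustering.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

DEFAULT_R_MIN = 0.5
DEFAULT_Q_MAX = 0.05


def _biweight_prepare(x: np.ndarray, c: float = 9.0) -> np.ndarray:
    """Median-centred, biweight-weighted, unit-norm version of ``x``.

    bicor(x, y) is the inner product of the prepared vectors.  With
    ``u_i = (x_i - med x) / (c * mad x)`` (unscaled MAD) the weight is
    ``(1 - u_i^2)^2`` inside |u| < 1 and zero outside.  A zero MAD (more than
    half the values tied) makes the biweight undefined; the standard fallback
    is Pearson-style handling of that vector (mean centring, unit weights).
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        warnings.warn(
            "zero median absolute deviation; falling back to Pearson weighting",
            RuntimeWarning,
            stacklevel=3,
        )
        centred = x - x.mean()
        norm = np.sqrt(np.sum(centred**2))
        if norm == 0.0:
            raise ValueError("constant vector has no defined correlation")
        return centred / norm
    u = (x - med) / (c * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    a = (x - med) * w
    norm = np.sqrt(np.sum(a**2))
    if norm == 0.0:
        raise ValueError("all observations received zero biweight")
    return a / norm


def bicor(x, y, c: float = 9.0) -> float:
    """Biweight midcorrelation of two equal-length vectors (n >= 5)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    r = float(_biweight_prepare(x, c) @ _biweight_prepare(y, c))
    return float(np.clip(r, -1.0, 1.0))


def bicor_matrix(X: pd.DataFrame, Y: pd.DataFrame, c: float = 9.0) -> pd.DataFrame:
    """All-pairs bicor between columns of ``X`` and columns of ``Y``.

    Rows of the result index ``X``'s columns; columns index ``Y``'s columns.
    The biweight factorises per vector, so the matrix is a single product of
    prepared column blocks.
    """
    if not X.index.equals(Y.index):
        raise ValueError("X and Y must share the same sample index")
    A = np.column_stack([_biweight_prepare(X.iloc[:, j].to_numpy(), c) for j in range(X.shape[1])])
    B = np.column_stack([_biweight_prepare(Y.iloc[:, j].to_numpy(), c) for j in range(Y.shape[1])])
    R = np.clip(A.T @ B, -1.0, 1.0)
    return pd.DataFrame(R, index=X.columns, columns=Y.columns)


def bicor_pvalue(r, n: int):
    """Two-sided p for a correlation via the Student-t approximation.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` against t with n-2 df.  Handles
    |r| = 1 as p = 0.  Accepts scalars or arrays.
    """
    if n < 5:
        raise ValueError("need at least 5 observations")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p if p.ndim else float(p)


def bicor_permutation_pvalue(x, y, n_permutations: int = 10000, rng=None, c: float = 9.0) -> float:
    """Permutation p-value for bicor (permutes ``y``); two-sided.

    Uses the add-one correction (b + 1) / (B + 1) so the estimate is never 0.
    """
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    observed = abs(bicor(x, y, c))
    a = _biweight_prepare(x, c)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(y))
        r = abs(float(a @ _biweight_prepare(y[perm], c)))
        hits += r >= observed
    return (hits + 1) / (n_permutations + 1)


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on a lambda
    grid and smoothed with a cubic spline; the estimate is the smoothed value
    at the largest lambda, clipped to (0, 1].  Falls back to 1 when the
    estimate is unstable (non-finite or > 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value vector")
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if np.all(pi0_lambda == pi0_lambda[0]):
        pi0 = float(pi0_lambda[0])  # degenerate (e.g. all p equal): no smoothing
    else:
        try:
            spline = interpolate.UnivariateSpline(lambdas, pi0_lambda, k=3)
            pi0 = float(spline(lambdas[-1]))
        except Exception:
            pi0 = 1.0
    if not np.isfinite(pi0) or pi0 > 1.0 or pi0 <= 0.0:
        pi0 = 1.0
    return pi0


def qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q_i = min_{p_j >= p_i} pi0 * m * p_j / rank(p_j).

    With ``pi0`` forced to 1 this reduces exactly to Benjamini-Hochberg
    adjusted p-values.  Monotone in p and bounded by 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class CorrelationScreen:
    """Result of the all-pairs robust correlation screen."""

    r: pd.DataFrame          # taxa x lipids bicor
    p: pd.DataFrame          # two-sided p per pair
    q: pd.DataFrame          # Storey q per pair (FDR over the whole grid)
    mask: pd.DataFrame       # significant selection: q < q_max and |r| >= r_min
    n_obs: int               # pooled observations per pair
    r_min: float
    q_max: float
    pi0: float
    pairs: pd.DataFrame = field(default=None)  # tidy significant-pair list

    @property
    def n_significant(self) -> int:
        return int(self.mask.to_numpy().sum())

    @property
    def significant_taxa(self) -> list[str]:
        return list(self.mask.index[self.mask.any(axis=1)])

    @property
    def significant_lipids(self) -> list[str]:
        return list(self.mask.columns[self.mask.any(axis=0)])


def screen(
    abundance: pd.DataFrame,
    lipid: pd.DataFrame,
    r_min: float = DEFAULT_R_MIN,
    q_max: float = DEFAULT_Q_MAX,
    c: float = 9.0,
) -> CorrelationScreen:
    """Run the full taxa x lipids bicor screen on shared samples.

    Observations are pooled over whatever time points the two tables share
    (rows are matched by sample ID); at least 10 shared samples are required.
    """
    shared = abundance.index.intersection(lipid.index)
    if len(shared) == 0:
        raise ValueError("abundance and lipid tables share no samples")
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared samples; need >= 10")
    X = abundance.loc[shared]
    Y = lipid.loc[shared]
    n = len(shared)
    r = bicor_matrix(X, Y, c=c)
    p_flat = bicor_pvalue(r.to_numpy().ravel(), n)
    pi0 = estimate_pi0(p_flat)
    q_flat = qvalues(p_flat, pi0=pi0)
    p = pd.DataFrame(p_flat.reshape(r.shape), index=r.index, columns=r.columns)
    q = pd.DataFrame(q_flat.reshape(r.shape), index=r.index, columns=r.columns)
    mask = (q < q_max) & (r.abs() >= r_min)
    scr = CorrelationScreen(
        r=r, p=p, q=q, mask=mask, n_obs=n, r_min=r_min, q_max=q_max, pi0=pi0
    )
    scr.pairs = significant_pairs(scr)
    return scr


def significant_pairs(scr: CorrelationScreen) -> pd.DataFrame:
    """Tidy list of selected (taxon, lipid) pairs sorted by |r| descending."""
    rows = []
    mask = scr.mask.to_numpy()
    ti, li = np.nonzero(mask)
    for i, j in zip(ti, li):
        rows.append(
            {
                "taxon": scr.r.index[i],
                "lipid": scr.r.columns[j],
                "r": scr.r.iat[i, j],
                "p": scr.p.iat[i, j],
                "q": scr.q.iat[i, j],
            }
        )
    out = pd.DataFrame(rows, columns=["taxon", "lipid", "r", "p", "q"])
    return out.reindex(out["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)


def screen_summary(scr: CorrelationScreen, annotations: pd.DataFrame | None = None) -> dict:
    """Headline counts: pairs, taxa, and per-lipid-class shares of hits."""
    summary = {
        "n_tests": int(scr.r.size),
        "n_significant_pairs": scr.n_significant,
        "n_significant_taxa": len(scr.significant_taxa),
        "n_significant_lipids": len(scr.significant_lipids),
        "pi0": scr.pi0,
    }
    if scr.n_significant and annotations is not None:
        classes = annotations.loc[scr.pairs["lipid"], "lipid_class"]
        shares = classes.value_counts(normalize=True)
        summary["class_shares"] = shares.to_dict()
    return summary


def two_way_cluster(
    r: pd.DataFrame,
    mask: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Two-way UPGMA clustering of the correlation matrix.

    Restricts to rows/columns with at least one significant cell when a mask
    is given (the convention for correlation heatmaps showing only features
    with a significant partner), then clusters rows and columns with average
    linkage on correlation distance (1 - Pearson r between profile rows).
    Returns the reordered matrix and the two linkage matrices.
    """
    if mask is not None:
        keep_rows = mask.any(axis=1)
        keep_cols = mask.any(axis=0)
        r = r.loc[keep_rows, keep_cols]
    if r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 matrix to cluster")
    row_link = _correlation_linkage(r.to_numpy())
    col_link = _correlation_linkage(r.to_numpy().T)
    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    return r.iloc[row_order, col_order], row_link, col_link


def _correlation_linkage(mat: np.ndarray) -> np.ndarray:
    # Correlation distance is undefined for constant rows; jitter-free
    # fallback: treat constant rows as maximally distant from everything and
    # identical to each other (distance 0) for determinism.
    sd = mat.std(axis=1)
    if np.any(sd == 0):
        d = np.ones((len(mat), len(mat)))
        finite = sd > 0
        if finite.sum() >= 2:
            sub = 1.0 - np.corrcoef(mat[finite])
            d[np.ix_(finite, finite)] = sub
        const = np.nonzero(~finite)[0]
        d[np.ix_(const, const)] = 0.0
        np.fill_diagonal(d, 0.0)
        dist = d[np.triu_indices(len(mat), k=1)]
    else:
        dist = pdist(mat, metric="correlation")
    return hierarchy.linkage(np.clip(dist, 0.0, None), method="average")
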