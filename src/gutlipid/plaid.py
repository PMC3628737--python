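"""Constant plaid-model biclustering of a correlation matrix.

The plaid model expresses a matrix as a background effect plus overlapping
layers, each a row-subset x column-subset block with its own effect:

    Y_ij ~ mu0 + sum_k mu_k rho_ik kappa_jk,

with binary memberships rho, kappa and, in the constant variant used here, a
single scalar effect mu_k per layer.  Layers are fitted greedily on the
residual matrix by alternating updates of the effect and the memberships, and
each candidate layer must survive a permutation acceptance test: its sum of
squares has to exceed that of the best layer fitted to each of ``n_shuffles``
entry-permuted copies of the residuals.  With S reference shuffles this is a
one-sided permutation test at level 1/(S+1) per layer, so the default S = 39
keeps the chance of accepting any spurious layer on pure noise near 2.5%.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PlaidParams:
    """Tuning parameters for the constant plaid fit."""

    max_layers: int = 5
    row_release: float = 0.7
    col_release: float = 0.7
    n_shuffles: int = 39
    background: bool = True
    max_iterations: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        for name in ("row_release", "col_release"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class Bicluster:
    """One accepted plaid layer."""

    rows: np.ndarray      # boolean row membership
    cols: np.ndarray      # boolean column membership
    effect: float         # layer effect mu_k
    sum_squares: float    # mu_k^2 * |rows| * |cols|


@dataclass
class BiclusterSet:
    """Fitted plaid decomposition."""

    layers: list[Bicluster]
    background_effect: float
    residual: np.ndarray
    params: PlaidParams
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def _fit_layer(Z: np.ndarray, params: PlaidParams, rng: np.random.Generator):
    """Fit one constant layer to the residual matrix.

    Initialisation is a randomised rank-1 seeding: rows/columns whose leading
    singular-vector loadings (with a random orientation and a random
    inclusion quantile) are on the dominant side.  Updates alternate the
    layer effect (mean of included cells) with membership updates: a row is
    included when its squared-error reduction is positive and at least
    ``(1 - row_release)`` of the best row's reduction.
    """
    n, m = Z.shape
    try:
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        u1, v1 = u[:, 0], vt[0]
    except np.linalg.LinAlgError:
        u1 = rng.standard_normal(n)
        v1 = rng.standard_normal(m)
    q = rng.uniform(0.5, 0.8)
    # The leading singular pair is sign-ambiguous and a coherent block may
    # sit in any of the four orientation corners; start from the corner with
    # the largest initial |effect| * sqrt(block size).
    best = None
    for su in (1.0, -1.0):
        for sv in (1.0, -1.0):
            r_sel = su * u1 >= np.quantile(su * u1, q)
            c_sel = sv * v1 >= np.quantile(sv * v1, q)
            if not r_sel.any():
                r_sel = r_sel.copy()
                r_sel[np.argmax(su * u1)] = True
            if not c_sel.any():
                c_sel = c_sel.copy()
                c_sel[np.argmax(sv * v1)] = True
            mu0 = Z[np.ix_(r_sel, c_sel)].mean()
            score = abs(mu0) * np.sqrt(r_sel.sum() * c_sel.sum())
            if best is None or score > best[0]:
                best = (score, r_sel, c_sel)
    _, rows, cols = best
    for _ in range(params.max_iterations):
        mu = Z[np.ix_(rows, cols)].mean()
        if mu == 0.0:
            break
        # Row scores: SS reduction from including row i over current columns.
        row_scores = mu * (2.0 * Z[:, cols].sum(axis=1) - cols.sum() * mu)
        new_rows = _release_select(row_scores, params.row_release)
        col_scores = mu * (2.0 * Z[new_rows].sum(axis=0) - new_rows.sum() * mu)
        new_cols = _release_select(col_scores, params.col_release)
        if np.array_equal(new_rows, rows) and np.array_equal(new_cols, cols):
            rows, cols = new_rows, new_cols
            break
        rows, cols = new_rows, new_cols
    mu = Z[np.ix_(rows, cols)].mean()
    ss = float(mu**2 * rows.sum() * cols.sum())
    return rows, cols, float(mu), ss


def _release_select(scores: np.ndarray, release: float) -> np.ndarray:
    best = scores.max()
    if best <= 0:
        keep = np.zeros_like(scores, dtype=bool)
        keep[np.argmax(scores)] = True
        return keep
    keep = (scores > 0) & (scores >= (1.0 - release) * best)
    if not keep.any():
        keep[np.argmax(scores)] = True
    return keep


def fit_plaid(
    matrix: pd.DataFrame | np.ndarray,
    params: PlaidParams | None = None,
) -> BiclusterSet:
    """Fit the constant plaid model with permutation layer acceptance.

    Layers are accepted while their sum of squares beats the best layer
    fitted to each of ``params.n_shuffles`` random entry permutations of the
    current residuals; fitting stops at the first rejection or at
    ``max_layers``.  Deterministic given ``params.seed``.
    """
    if params is None:
        params = PlaidParams()
    if isinstance(matrix, pd.DataFrame):
        row_labels = list(matrix.index)
        col_labels = list(matrix.columns)
        Y = matrix.to_numpy(dtype=float)
    else:
        Y = np.asarray(matrix, dtype=float)
        row_labels = list(range(Y.shape[0]))
        col_labels = list(range(Y.shape[1]))
    if Y.ndim != 2 or min(Y.shape) < 2:
        raise ValueError("matrix must be at least 2 x 2")
    if not np.all(np.isfinite(Y)):
        raise ValueError("matrix contains non-finite entries")
    rng = np.random.default_rng(params.seed)
    mu0 = float(Y.mean()) if params.background else 0.0
    Z = Y - mu0
    layers: list[Bicluster] = []
    for _ in range(params.max_layers):
        rows, cols, mu, ss = _fit_layer(Z, params, rng)
        if ss <= 0:
            break
        reference = []
        flat = Z.ravel()
        for _ in range(params.n_shuffles):
            perm = rng.permutation(flat.size).reshape(Z.shape)
            _, _, _, ss_ref = _fit_layer(flat[perm], params, rng)
            reference.append(ss_ref)
        if ss <= max(reference):
            break
        Z = Z - mu * np.outer(rows, cols)
        layers.append(Bicluster(rows=rows, cols=cols, effect=mu, sum_squares=ss))
    return BiclusterSet(
        layers=layers,
        background_effect=mu0,
        residual=Z,
        params=params,
        row_labels=row_labels,
        col_labels=col_labels,
    )


def bicluster_summary(
    bset: BiclusterSet,
    r_matrix: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy per-layer membership table with layer effects and mean r.

    One row per (layer, axis, member); empty layers are reported, not
    dropped.  When the underlying correlation matrix is supplied the mean
    correlation of each layer's block is included.
    """
    rows = []
    for k, layer in enumerate(bset.layers, start=1):
        members_r = [bset.row_labels[i] for i in np.nonzero(layer.rows)[0]]
        members_c = [bset.col_labels[j] for j in np.nonzero(layer.cols)[0]]
        mean_r = np.nan
        if r_matrix is not None and members_r and members_c:
            mean_r = float(r_matrix.loc[members_r, members_c].to_numpy().mean())
        if not members_r or not members_c:
            rows.append(
                {"layer": k, "axis": "empty", "member": None,
                 "effect": layer.effect, "mean_r": mean_r}
            )
            continue
        for m in members_r:
            rows.append({"layer": k, "axis": "taxon", "member": m,
                         "effect": layer.effect, "mean_r": mean_r})
        for m in members_c:
            rows.append({"layer": k, "axis": "lipid", "member": m,
                         "effect": layer.effect, "mean_r": mean_r})
    return pd.DataFrame(rows, columns=["layer", "axis", "member", "effect", "mean_r"])


def membership_jaccard(layer: Bicluster, true_rows: np.ndarray, true_cols: np.ndarray) -> float:
    """Jaccard index between a layer's cell set and a reference block."""
    est = np.outer(layer.rows, layer.cols)
    ref = np.outer(np.asarray(true_rows, dtype=bool), np.asarray(true_cols, dtype=bool))
    inter = np.logical_and(est, ref).sum()
    union = np.logical_or(est, ref).sum()
    return float(inter / union) if union else 1.0
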