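"""Temporal and population similarity of omics profiles.

Intra-individual stability is the Pearson correlation (across features, on
the log10 scale) of one subject's profiles at two time points;
inter-individual similarity is the mean pairwise Pearson correlation between
different subjects' profiles at one time point.  A subject-specific ecosystem
shows intra well above inter; a homeostatically controlled compartment shows
both high.  Group differences in per-subject stability are compared with the
two-sided Wilcoxon rank-sum test.
"""
from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

MIN_SHARED_FEATURES = 10


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < MIN_SHARED_FEATURES:
        raise ValueError(
            f"fewer than {MIN_SHARED_FEATURES} pairwise-complete features"
        )
    a, b = a[mask], b[mask]
    return float(stats.pearsonr(a, b).statistic)


def intra_subject_similarity(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    tp_pair: tuple[int, int],
) -> pd.DataFrame:
    """Per-subject profile correlation between two time points.

    Returns a DataFrame indexed by subject with columns ``r`` and ``group``.
    Subjects missing either time point are excluded with a warning.
    """
    t1, t2 = tp_pair
    rows = []
    for subject, sub in metadata.groupby("subject", sort=True):
        s1 = sub.index[sub["timepoint"] == t1]
        s2 = sub.index[sub["timepoint"] == t2]
        if len(s1) != 1 or len(s2) != 1:
            warnings.warn(f"subject {subject} missing a time point; excluded", stacklevel=2)
            continue
        r = _pearson_rows(
            table.loc[s1[0]].to_numpy(dtype=float),
            table.loc[s2[0]].to_numpy(dtype=float),
        )
        rows.append({"subject": subject, "r": r, "group": sub["group"].iloc[0]})
    if not rows:
        raise ValueError("no subject has both time points")
    return pd.DataFrame(rows).set_index("subject")


def inter_subject_similarity(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    tp: int,
) -> pd.Series:
    """Mean pairwise between-subject profile correlation per group at one TP."""
    out = {}
    at_tp = metadata[metadata["timepoint"] == tp]
    for group, sub in at_tp.groupby("group", sort=True):
        samples = [s for s in sub.index if s in table.index]
        if len(samples) < 2:
            warnings.warn(f"group {group!r} has < 2 subjects at TP{tp}; undefined", stacklevel=2)
            out[group] = np.nan
            continue
        profiles = table.loc[samples].to_numpy(dtype=float)
        rs = [
            _pearson_rows(profiles[i], profiles[j])
            for i, j in itertools.combinations(range(len(samples)), 2)
        ]
        out[group] = float(np.mean(rs))
    return pd.Series(out, name=f"inter_r_tp{tp}")


def compare_group_stability(r_a, r_b) -> float:
    """Two-sided Wilcoxon rank-sum p for per-subject stability of two groups."""
    a = np.asarray(r_a, dtype=float)
    b = np.asarray(r_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs at least one value")
    if len(a) < 2 and len(b) < 2:
        raise ValueError("insufficient data: one observation per group")
    if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
        warnings.warn("all values tied; p = 1 by convention", stacklevel=2)
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def stability_report(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    tp_pairs: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Group x statistic stability table.

    One row per group; columns are mean between-subject r at each time point
    and mean (SD) within-subject r for each consecutive time-point pair.
    """
    tps = sorted(metadata["timepoint"].unique())
    if tp_pairs is None:
        tp_pairs = list(zip(tps[:-1], tps[1:]))
    groups = sorted(metadata["group"].unique())
    out = pd.DataFrame(index=groups)
    for tp in tps:
        out[f"between_tp{tp}"] = inter_subject_similarity(table, metadata, tp)
    for t1, t2 in tp_pairs:
        intra = intra_subject_similarity(table, metadata, (t1, t2))
        grp = intra.groupby("group")["r"]
        out[f"within_tp{t1}_vs_tp{t2}"] = grp.mean()
        out[f"within_tp{t1}_vs_tp{t2}_sd"] = grp.std()
    return out


def pca_scores(table: pd.DataFrame, n_components: int = 2):
    """Centered-data principal component scores and explained variance.

    Returns ``(scores, explained_variance_ratio)``; scores is a DataFrame
    indexed like the table with columns PC1..PCk.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = table.to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        warnings.warn("constant matrix: zero variance to explain", stacklevel=2)
        k = min(n_components, min(X.shape) - 1) or 1
        scores = pd.DataFrame(
            np.zeros((X.shape[0], k)),
            index=table.index,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        return scores, np.zeros(k)
    k = min(n_components, min(X.shape))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X - X.mean(axis=0))
    return (
        pd.DataFrame(scores, index=table.index, columns=[f"PC{i + 1}" for i in range(k)]),
        pca.explained_variance_ratio_,
    )
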