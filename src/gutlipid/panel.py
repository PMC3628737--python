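"""Correlation of taxa against the enzymatic serum lipid panel.

The biochemically determined panel (total cholesterol, LDL and HDL
cholesterol, triglycerides, in mmol/L) goes through the identical statistical
path as the full lipidomics screen: biweight midcorrelation per (taxon,
analyte) pair and Storey q-values over the taxa x analytes grid.  This is
the cross-platform corroboration step: a taxon-lipid association seen in the
mass-spectrometric profile should reappear, with the same sign, against the
corresponding enzymatic analyte.
"""
from __future__ import annotations

import warnings

import pandas as pd

from .correlate import bicor_matrix, bicor_pvalue, estimate_pi0, qvalues

PANEL_ANALYTES = ("TC", "LDL", "HDL", "TG")


def panel_screen(
    abundance: pd.DataFrame,
    panel: pd.DataFrame,
    r_min: float = 0.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Taxa x analytes robust-correlation screen.

    Returns a tidy DataFrame (taxon, analyte, r, p, q, significant) over all
    pairs; the ``significant`` flag applies ``q < q_max`` and ``|r| >=
    r_min``.  Constant analytes are excluded with a warning; at least 10
    shared samples are required.
    """
    shared = abundance.index.intersection(panel.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared samples; need >= 10")
    X = abundance.loc[shared]
    P = panel.loc[shared].astype(float)
    if (P < 0).any().any():
        raise ValueError("panel concentrations must be non-negative")
    keep = P.std(axis=0) > 0
    dropped = list(P.columns[~keep])
    if dropped:
        warnings.warn(f"constant analytes excluded: {dropped}", stacklevel=2)
    P = P.loc[:, keep]
    if P.shape[1] == 0:
        raise ValueError("no non-constant analytes")
    r = bicor_matrix(X, P)
    n = len(shared)
    p_flat = bicor_pvalue(r.to_numpy().ravel(), n)
    q_flat = qvalues(p_flat, pi0=estimate_pi0(p_flat))
    long = r.stack().rename("r").reset_index()
    long.columns = ["taxon", "analyte", "r"]
    long["p"] = p_flat
    long["q"] = q_flat
    long["significant"] = (long["q"] < q_max) & (long["r"].abs() >= r_min)
    return long


def significant_panel_table(result: pd.DataFrame) -> pd.DataFrame:
    """Pivot of significant correlations only, taxa x analytes (NaN elsewhere).

    Mirrors the usual presentation where only significant positive and
    negative correlations are printed.
    """
    sig = result[result["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=[a for a in PANEL_ANALYTES])
    wide = sig.pivot(index="taxon", columns="analyte", values="r")
    order = [a for a in PANEL_ANALYTES if a in wide.columns]
    return wide[order].sort_index()
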