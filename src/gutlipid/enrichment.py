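"""Fisher exact over-representation tests for biclusters and lipid categories.

Each enrichment contrasts membership in a selected set (a bicluster layer or
the significant-correlation selection) against membership in a structural
category (odd/even carbon count, SAFA/MUFA/PUFA saturation, long acyl chain,
ether linkage for lipids; phylum or Clostridium-cluster label for taxa) via a
2x2 contingency table.  Two-sided p-values follow the probability-mass rule
(sum of all hypergeometric outcomes no more likely than the observed table);
the odds ratio reported is the sample estimate ad/bc.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import lipids as _lipids


@dataclass(frozen=True)
class EnrichmentResult:
    """One 2x2 over-representation test."""

    category: str
    a: int  # in set, in category
    b: int  # in set, not in category
    c: int  # out of set, in category
    d: int  # out of set, not in category
    odds_ratio: float
    p: float

    @property
    def table(self):
        return ((self.a, self.b), (self.c, self.d))


def fisher_exact_2x2(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Exact hypergeometric test on a 2x2 table; returns (odds ratio, p).

    The odds ratio is ad/bc (inf when bc = 0 and ad > 0, nan for 0/0).  A
    zero margin makes the table degenerate; p = 1 by convention.
    """
    ((a, b), (c, d)) = table
    cells = np.array([a, b, c, d])
    if np.any(cells < 0) or not np.issubdtype(cells.dtype, np.integer):
        if np.any(cells != np.floor(cells)) or np.any(cells < 0):
            raise ValueError("cells must be non-negative integers")
    a, b, c, d = (int(v) for v in cells)
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("zero margin in 2x2 table; p = 1 by convention", stacklevel=2)
        oddsr = _sample_odds_ratio(a, b, c, d)
        return oddsr, 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return _sample_odds_ratio(a, b, c, d), float(p)


def _sample_odds_ratio(a, b, c, d) -> float:
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return a * d / (b * c)


def _one_test(selected: set, category_members: set, universe: set, label: str) -> EnrichmentResult:
    a = len(selected & category_members)
    b = len(selected - category_members)
    c = len((universe - selected) & category_members)
    d = len(universe - selected - category_members)
    oddsr, p = fisher_exact_2x2(((a, b), (c, d)))
    return EnrichmentResult(category=label, a=a, b=b, c=c, d=d, odds_ratio=oddsr, p=p)


#: Category levels tested for lipids: (column, level, label)
_LIPID_CATEGORY_LEVELS = (
    ("parity", "odd", "odd_carbons"),
    ("parity", "even", "even_carbons"),
    ("saturation", "SAFA", "SAFA"),
    ("saturation", "MUFA", "MUFA"),
    ("saturation", "PUFA", "PUFA"),
    ("long_chain", True, "long_chain"),
    ("ether", True, "ether"),
)


def category_enrichment(
    selected_lipids: Iterable[str],
    universe_lipids: Iterable[str],
    long_chain_threshold: int = _lipids.DEFAULT_LONG_CHAIN_THRESHOLD,
) -> pd.DataFrame:
    """Structural-category enrichment of a lipid selection within a universe.

    One row per category level (odd/even carbons, SAFA/MUFA/PUFA, long
    chain, ether linkage).  The selection must be a subset of the universe;
    an empty selection yields p = 1 throughout.
    """
    universe = list(dict.fromkeys(universe_lipids))
    selected = set(selected_lipids)
    if not selected <= set(universe):
        raise ValueError("selected lipids must be a subset of the universe")
    ann = _lipids.annotate_lipids(universe, long_chain_threshold=long_chain_threshold)
    uni = set(universe)
    results = []
    for column, level, label in _LIPID_CATEGORY_LEVELS:
        members = set(ann.index[ann[column] == level])
        results.append(_one_test(selected, members, uni, label))
    return _as_frame(results)


def taxon_enrichment(
    member_taxa: Iterable[str],
    universe_taxa: Iterable[str],
    taxon_groups: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Over-representation of taxonomic group labels in a bicluster.

    ``taxon_groups`` maps taxon name to a phylum or Clostridium-cluster
    label; taxa without a label are skipped with a warning.
    """
    if isinstance(taxon_groups, pd.Series):
        taxon_groups = taxon_groups.to_dict()
    universe = list(dict.fromkeys(universe_taxa))
    selected = set(member_taxa)
    if not selected <= set(universe):
        raise ValueError("bicluster taxa must be a subset of the universe")
    unknown = [t for t in universe if t not in taxon_groups]
    if unknown:
        warnings.warn(
            f"{len(unknown)} taxa lack a group label and are skipped", stacklevel=2
        )
    labelled = [t for t in universe if t in taxon_groups]
    uni = set(labelled)
    selected &= uni
    labels = sorted({taxon_groups[t] for t in labelled})
    results = []
    for label in labels:
        members = {t for t in labelled if taxon_groups[t] == label}
        results.append(_one_test(selected, members, uni, label))
    return _as_frame(results)


def _as_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
            }
            for r in results
        ]
    ).set_index("category")
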