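"""Lipid species nomenclature: parsing, structural categories, class composition.

Serum lipidomics platforms report species at the sum-composition level,
``CLASS(C:D)`` — lipid class abbreviation, total acyl carbon count ``C`` and
total number of double bonds ``D``.  A trailing ``e`` on the double-bond count
(e.g. ``PC(38:4e)``) marks an ether-linked (alkyl/plasmalogen) species.  The
structural categories derived here — carbon-count parity, degree of
saturation, chain length, ether linkage — carry biological meaning: odd-carbon
and polyunsaturated fatty acids cannot be synthesised by humans and point to a
dietary, bacterial or marine origin, while ether phosphatidylcholines
(plasmalogens) act as endogenous antioxidants.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The lipid classes recognised by the default grammar.
LIPID_CLASSES = (
    "Cer",     # ceramide
    "ChoE",    # cholesteryl ester
    "lysoPC",  # lysophosphatidylcholine
    "lysoPE",  # lysophosphatidylethanolamine
    "PA",      # phosphatidic acid
    "PG",      # phosphatidylglycerol
    "PC",      # phosphatidylcholine
    "PE",      # phosphatidylethanolamine
    "PS",      # phosphatidylserine
    "SM",      # sphingomyelin
    "TG",      # triglyceride
)

# Longest alternatives first so "lysoPC" is not consumed as "PC".
_CLASS_ALT = "|".join(sorted(LIPID_CLASSES, key=len, reverse=True))
#: Default species grammar: CLASS(C:D) with optional trailing ether marker.
DEFAULT_NAME_PATTERN = rf"^(?P<cls>{_CLASS_ALT})\((?P<carbons>\d+):(?P<db>\d+)(?P<ether>e?)\)$"

#: Default total-carbon cut-off for the "long acyl chain" category.  Chosen
#: for TG-class comparisons (three acyl chains averaging 18 carbons); it is a
#: tunable, not a community standard.
DEFAULT_LONG_CHAIN_THRESHOLD = 54


class LipidNameError(ValueError):
    """Raised when a species name does not match the grammar."""


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed sum-composition lipid species."""

    raw_name: str
    lipid_class: str
    carbons: int
    double_bonds: int
    ether: bool = False

    def format(self) -> str:
        """Canonical name; inverse of :func:`parse_lipid_name`."""
        marker = "e" if self.ether else ""
        return f"{self.lipid_class}({self.carbons}:{self.double_bonds}{marker})"


@dataclass(frozen=True)
class LipidCategoryFlags:
    """Structural categories used for enrichment testing."""

    parity: str        # "odd" | "even"
    saturation: str    # "SAFA" | "MUFA" | "PUFA"
    long_chain: bool
    ether: bool


def parse_lipid_name(name: str, pattern: str = DEFAULT_NAME_PATTERN) -> LipidSpecies:
    """Parse ``CLASS(C:D[e])`` into a :class:`LipidSpecies`.

    Parameters
    ----------
    name:
        Species name, e.g. ``"TG(54:5)"`` or ``"PC(38:4e)"``.
    pattern:
        Regex override for alternative ether-marker dialects; must expose
        groups ``cls``, ``carbons``, ``db`` and ``ether``.
    """
    if not isinstance(name, str):
        raise LipidNameError(f"lipid name must be a string, got {type(name).__name__}")
    m = re.match(pattern, name.strip())
    if m is None:
        # Identify the offending token for a useful message.
        head = re.match(rf"^({_CLASS_ALT})", name.strip())
        if head is None:
            raise LipidNameError(f"unknown lipid class in {name!r}")
        raise LipidNameError(f"malformed composition after class {head.group(1)!r} in {name!r}")
    carbons = int(m.group("carbons"))
    double_bonds = int(m.group("db"))
    if carbons == 0:
        raise LipidNameError(f"carbon count must be positive in {name!r}")
    return LipidSpecies(
        raw_name=name.strip(),
        lipid_class=m.group("cls"),
        carbons=carbons,
        double_bonds=double_bonds,
        ether=m.group("ether") == "e",
    )


def categorize(
    species: LipidSpecies,
    long_chain_threshold: int = DEFAULT_LONG_CHAIN_THRESHOLD,
) -> LipidCategoryFlags:
    """Derive category flags from a parsed species.

    SAFA/MUFA/PUFA correspond to 0 / 1 / >=2 double bonds; ``long_chain``
    means total carbons >= ``long_chain_threshold``.
    """
    if species.double_bonds == 0:
        saturation = "SAFA"
    elif species.double_bonds == 1:
        saturation = "MUFA"
    else:
        saturation = "PUFA"
    return LipidCategoryFlags(
        parity="odd" if species.carbons % 2 else "even",
        saturation=saturation,
        long_chain=species.carbons >= long_chain_threshold,
        ether=species.ether,
    )


def annotate_lipids(
    names: Iterable[str],
    long_chain_threshold: int = DEFAULT_LONG_CHAIN_THRESHOLD,
    pattern: str = DEFAULT_NAME_PATTERN,
) -> pd.DataFrame:
    """Parse and categorise a collection of names into an annotation table.

    Returns a DataFrame indexed by name with columns ``lipid_class``,
    ``carbons``, ``double_bonds``, ``ether``, ``parity``, ``saturation``,
    ``long_chain``.  Unparseable names are reported together with their
    positions in a single error.
    """
    rows = []
    bad: list[tuple[int, str]] = []
    for i, name in enumerate(names):
        try:
            sp = parse_lipid_name(name, pattern=pattern)
        except LipidNameError:
            bad.append((i, str(name)))
            continue
        flags = categorize(sp, long_chain_threshold=long_chain_threshold)
        rows.append(
            {
                "name": sp.raw_name,
                "lipid_class": sp.lipid_class,
                "carbons": sp.carbons,
                "double_bonds": sp.double_bonds,
                "ether": sp.ether,
                "parity": flags.parity,
                "saturation": flags.saturation,
                "long_chain": flags.long_chain,
            }
        )
    if bad:
        listing = ", ".join(f"{name!r} (index {i})" for i, name in bad[:10])
        raise LipidNameError(f"{len(bad)} unparseable lipid names: {listing}")
    return pd.DataFrame(rows).set_index("name")


def class_composition(
    lipid_table: pd.DataFrame,
    assume_log10: bool = True,
    pattern: str = DEFAULT_NAME_PATTERN,
) -> pd.DataFrame:
    """Per-class species counts and shares of the lipid pool.

    Parameters
    ----------
    lipid_table:
        Samples x lipid species intensity table (columns are species names).
    assume_log10:
        If true (the default), intensities are log10 values and are unlogged
        before summation so that intensity shares refer to the linear scale.

    Returns
    -------
    DataFrame indexed by class with columns ``n_species``, ``count_share``
    and ``intensity_share``; both share columns sum to 1.
    """
    ann = annotate_lipids(lipid_table.columns, pattern=pattern)
    values = lipid_table.to_numpy(dtype=float)
    if assume_log10:
        values = np.power(10.0, values)
    totals = pd.Series(values.sum(axis=0), index=lipid_table.columns)
    per_class_total = totals.groupby(ann["lipid_class"]).sum()
    counts = ann["lipid_class"].value_counts()
    out = pd.DataFrame(
        {
            "n_species": counts,
            "count_share": counts / counts.sum(),
            "intensity_share": per_class_total / per_class_total.sum(),
        }
    )
    return out.sort_values("n_species", ascending=False)


def export_annotations(
    names: Iterable[str],
    path,
    long_chain_threshold: int = DEFAULT_LONG_CHAIN_THRESHOLD,
) -> pd.DataFrame:
    """Write the annotation table as TSV and return it."""
    ann = annotate_lipids(names, long_chain_threshold=long_chain_threshold)
    ann.to_csv(path, sep="\t")
    return ann


def default_lipid_catalog(class_counts: Mapping[str, int] | None = None) -> list[str]:
    """Enumerate a deterministic catalogue of species names per class.

    Each class has a canonical ordered candidate grid over sum compositions
    with realistic carbon and double-bond ranges; the first ``n`` candidates
    are taken per class.  The default counts total 407 species over the 11
    classes with triglycerides (~37%), phosphatidylcholines (~25%) and
    phosphatidylethanolamines (~13%) dominating, the remaining classes each
    contributing between roughly 7% and 0.3% of the species pool.
    """
    if class_counts is None:
        class_counts = DEFAULT_CLASS_COUNTS
    unknown = set(class_counts) - set(LIPID_CLASSES)
    if unknown:
        raise ValueError(f"unknown lipid classes: {sorted(unknown)}")
    names: list[str] = []
    for cls in LIPID_CLASSES:
        n = int(class_counts.get(cls, 0))
        if n < 0:
            raise ValueError(f"negative species count for {cls}")
        candidates = _CLASS_GRIDS[cls]
        if n > len(candidates):
            raise ValueError(
                f"requested {n} {cls} species but the candidate grid has only {len(candidates)}"
            )
        for carbons, db, ether in candidates[:n]:
            marker = "e" if ether else ""
            names.append(f"{cls}({carbons}:{db}{marker})")
    return names


def _grid(carbon_range, db_range, ether=False):
    return [(c, d, ether) for c in carbon_range for d in db_range]


# Canonical candidate grids: sum compositions a serum lipidomics platform
# typically resolves.  Ordering is deterministic (carbons outer, double bonds
# inner) so a given per-class count always yields the same name set.
_CLASS_GRIDS: dict[str, list[tuple[int, int, bool]]] = {
    "TG": _grid(range(42, 62, 2), range(0, 10)) + _grid(range(43, 62, 2), range(0, 5)),
    "PC": (
        _grid(range(30, 42, 2), range(0, 7))
        + _grid(range(31, 40, 2), range(0, 6))
        + _grid(range(30, 42, 2), range(0, 5), ether=True)
    ),
    "PE": (
        _grid(range(32, 42, 2), range(0, 7))
        + _grid(range(32, 42, 2), range(0, 3), ether=True)
        + [(33, 1, False), (35, 1, False), (37, 1, False)]
    ),
    "SM": _grid(range(32, 46, 1), (1, 2)),
    "ChoE": _grid(range(18, 22), range(0, 6)),
    "PA": _grid(range(32, 40), (0, 1)),
    "PG": _grid(range(34, 40), (0, 1)),
    "lysoPC": _grid(range(14, 19), (0, 1)),
    "PS": _grid(range(36, 39), (0, 1)),
    "Cer": _grid(range(34, 39), (1,)),
    "lysoPE": [(20, 4, False), (18, 0, False)],
}

#: Default per-class species counts (sum: 407).
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "TG": 150,
    "PC": 102,
    "PE": 53,
    "SM": 28,
    "ChoE": 24,
    "PA": 16,
    "PG": 12,
    "lysoPC": 10,
    "PS": 6,
    "Cer": 5,
    "lysoPE": 1,
}
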