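"""Synthetic paired microbiota/lipidome cohort generator with ground truth.

The generator emulates a two-arm probiotic intervention cohort profiled at
several time points with a phylogenetic microarray (genus-level log10
hybridization signals) and serum UPLC-MS lipidomics (log10 intensities).
Each feature follows a Gaussian variance-component model on the log10 scale

    x[s, t, f] = baseline + m[f] + a[s, f] + e[s, t, f]

with the feature effect ``m`` (shared by all subjects), the subject effect
``a`` and the observation noise ``e`` drawn independently per feature from
zero-mean Gaussians with variances ``(sigma2_shared, sigma2_subject,
sigma2_noise)``.  Under this model the expected inter-individual profile
correlation (Pearson r across features between two subjects) is
``sigma2_shared / total`` and the expected intra-individual correlation
(same subject, two time points) is ``(sigma2_shared + sigma2_subject) /
total``.  The default components are calibrated so the microbiota hits
intra ~0.94 / inter ~0.77 and the lipidome intra ~0.92 / inter ~0.90,
reproducing the characteristic contrast between the subject-specific gut
microbiota and the homeostatically controlled serum lipidome.

On top of this null structure the generator plants (i) a transient
group-by-time abundance spike on one taxon, emulating detectable excretion of
an ingested probiotic strain, and (ii) latent-variable taxon-lipid
associations with analytically chosen loadings so each planted pair attains a
target population correlation.  Everything planted is recorded in a
:class:`GroundTruthLedger` so recovery can be tested end to end.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import lipids as _lipids

MICROBIOTA = "microbiota"
LIPIDOME = "lipidome"


@dataclass(frozen=True)
class VarianceComponents:
    """Per-omic variance components on the log10 scale (dimensionless)."""

    shared: float
    subject: float
    noise: float

    def __post_init__(self):
        comps = (self.shared, self.subject, self.noise)
        if not all(np.isfinite(comps)):
            raise ValueError("variance components must be finite")
        if any(c < 0 for c in comps):
            raise ValueError("variance components must be non-negative")
        if sum(comps) == 0:
            raise ValueError("variance components must not all be zero")

    @property
    def total(self) -> float:
        return self.shared + self.subject + self.noise

    @property
    def expected_intra_r(self) -> float:
        return (self.shared + self.subject) / self.total

    @property
    def expected_inter_r(self) -> float:
        return self.shared / self.total


@dataclass(frozen=True)
class PlantedAssociation:
    """A taxon linked to a set of lipids through a shared latent variable."""

    taxon_index: int
    lipid_indices: tuple[int, ...]
    target_correlation: float

    def __post_init__(self):
        if not self.lipid_indices:
            raise ValueError("lipid_indices must be nonempty")
        if not abs(self.target_correlation) < 1:
            raise ValueError("|target_correlation| must be < 1")


@dataclass(frozen=True)
class PlantedEffect:
    """A log10 fold change on one taxon in one (group, time point) cell."""

    taxon_index: int
    group: str
    timepoint: int
    log10_fold_change: float


@dataclass
class GroundTruthLedger:
    """Record of everything the generator planted."""

    planted_associations: list[PlantedAssociation] = field(default_factory=list)
    planted_effect: PlantedEffect | None = None
    realized_variance_components: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_associations": [dataclasses.asdict(a) for a in self.planted_associations],
            "planted_effect": (
                dataclasses.asdict(self.planted_effect) if self.planted_effect else None
            ),
            "realized_variance_components": self.realized_variance_components,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthLedger":
        payload = json.loads(text)
        assocs = [
            PlantedAssociation(
                taxon_index=a["taxon_index"],
                lipid_indices=tuple(a["lipid_indices"]),
                target_correlation=a["target_correlation"],
            )
            for a in payload["planted_associations"]
        ]
        eff = payload.get("planted_effect")
        return cls(
            planted_associations=assocs,
            planted_effect=PlantedEffect(**eff) if eff else None,
            realized_variance_components=payload.get("realized_variance_components", {}),
        )


# Default variance components calibrated to the target stability profile.
DEFAULT_MICROBIOTA_VC = VarianceComponents(shared=0.77, subject=0.17, noise=0.06)
DEFAULT_LIPID_VC = VarianceComponents(shared=0.90, subject=0.02, noise=0.08)

# Named taxa placed at fixed indices so default planted structure reads well.
_NAMED_TAXA = {
    0: "Lactobacillus rhamnosus et rel.",
    1: "Ruminococcus gnavus et rel.",
    2: "Collinsella",
    3: "Dorea formicigenerans et rel.",
    4: "Moraxellaceae",
    5: "Actinomycetaceae",
}

_PHYLA = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria", "Verrucomicrobia")
_PHYLUM_WEIGHTS = (0.60, 0.15, 0.10, 0.10, 0.05)
_NAMED_PHYLA = {
    0: ("Firmicutes", "Bacilli"),
    1: ("Firmicutes", "Clostridium cluster XIVa"),
    2: ("Actinobacteria", "Coriobacteriaceae"),
    3: ("Firmicutes", "Clostridium cluster XIVa"),
    4: ("Proteobacteria", "Gammaproteobacteria"),
    5: ("Actinobacteria", "Actinomycetales"),
}


@dataclass
class CohortDesign:
    """Design of the synthetic paired cohort.

    Defaults emulate a 25-subject two-arm trial (11 probiotic / 14 placebo),
    three microbiota time points, two lipidomics time points, 131 genus-level
    taxa and 407 lipid species over 11 classes.
    """

    n_subjects: int = 25
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"probiotic": 11, "placebo": 14}
    )
    n_timepoints: int = 3
    n_lipid_timepoints: int = 2
    n_taxa: int = 131
    lipid_class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(_lipids.DEFAULT_CLASS_COUNTS)
    )
    microbiota_vc: VarianceComponents = DEFAULT_MICROBIOTA_VC
    lipid_vc: VarianceComponents = DEFAULT_LIPID_VC
    microbiota_baseline: float = 3.0
    lipid_baseline: float = 5.0
    planted_associations: Sequence[PlantedAssociation] | None = None
    planted_effect: PlantedEffect | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_timepoints < 2 or self.n_lipid_timepoints < 2:
            raise ValueError("need >= 2 time points")
        if self.n_lipid_timepoints > self.n_timepoints:
            raise ValueError("lipid time points must be a prefix of microbiota time points")
        if sum(self.group_sizes.values()) != self.n_subjects:
            raise ValueError("group sizes must sum to n_subjects")
        if self.planted_associations is None:
            self.planted_associations = default_planted_associations(self)
        if self.planted_effect is None:
            self.planted_effect = default_planted_effect()
        for assoc in self.planted_associations:
            if assoc.taxon_index >= self.n_taxa:
                raise ValueError("planted association taxon_index out of range")
        if self.planted_effect is not None:
            eff = self.planted_effect
            if eff.taxon_index >= self.n_taxa:
                raise ValueError("planted effect taxon_index out of range")
            if eff.group not in self.group_sizes:
                raise ValueError(f"unknown group {eff.group!r} in planted effect")
            if not 1 <= eff.timepoint <= self.n_timepoints:
                raise ValueError("planted effect timepoint out of range")

    @property
    def n_lipids(self) -> int:
        return sum(self.lipid_class_counts.values())

    def lipid_names(self) -> list[str]:
        return _lipids.default_lipid_catalog(self.lipid_class_counts)

    def taxon_names(self) -> list[str]:
        names = []
        for i in range(self.n_taxa):
            names.append(_NAMED_TAXA.get(i, f"Uncultured clostridiales {i:03d} et rel."))
        return names


def default_planted_effect() -> PlantedEffect:
    """A ten-fold transient spike of the ingested-probiotic taxon at TP2."""
    return PlantedEffect(taxon_index=0, group="probiotic", timepoint=2, log10_fold_change=1.0)


def default_planted_associations(design: "CohortDesign") -> list[PlantedAssociation]:
    """Planted taxon-lipid associations emulating a realistic screen outcome.

    A Clostridium-cluster taxon positively tied to a large set of
    triglycerides, a Coriobacteriaceae taxon tied to a cholesteryl ester, a
    second clostridial taxon tied to a few TGs, and a Proteobacteria taxon
    negatively tied to ether phosphatidylcholines.
    """
    names = _lipids.default_lipid_catalog(design.lipid_class_counts)
    index = {n: i for i, n in enumerate(names)}

    def pick(prefix: str, k: int, ether: bool | None = None, skip: set[int] = frozenset()):
        out = []
        for n, i in index.items():
            if not n.startswith(prefix) or i in skip:
                continue
            if ether is not None and n.endswith("e)") != ether:
                continue
            out.append(i)
            if len(out) == k:
                break
        if len(out) < k:
            raise ValueError(f"catalogue has fewer than {k} species matching {prefix!r}")
        return tuple(out)

    tg_main = pick("TG(", 30)
    if "TG(54:5)" in index:  # anchor species used in worked examples
        tg_main = tuple(sorted(set(tg_main[:29]) | {index["TG(54:5)"]}))
    tg_rest = pick("TG(", 4, skip=set(tg_main))
    choe = (index.get("ChoE(20:5)", pick("ChoE(", 1)[0]),)
    ether_pc = pick("PC(", 6, ether=True)
    return [
        PlantedAssociation(1, tg_main, 0.61),
        PlantedAssociation(3, tg_rest, 0.58),
        PlantedAssociation(2, choe, 0.59),
        PlantedAssociation(4, ether_pc, -0.55),
    ]


def _subject_metadata(design: CohortDesign) -> pd.DataFrame:
    subjects, groups = [], []
    i = 1
    for group, size in design.group_sizes.items():
        for _ in range(size):
            subjects.append(f"S{i:02d}")
            groups.append(group)
            i += 1
    return pd.DataFrame({"subject": subjects, "group": groups})


def sample_metadata(design: CohortDesign, n_timepoints: int | None = None) -> pd.DataFrame:
    """Long-format sample sheet: sample_id, subject, timepoint, group."""
    if n_timepoints is None:
        n_timepoints = design.n_timepoints
    subj = _subject_metadata(design)
    rows = []
    for _, r in subj.iterrows():
        for t in range(1, n_timepoints + 1):
            rows.append(
                {
                    "sample_id": f"{r.subject}_T{t}",
                    "subject": r.subject,
                    "timepoint": t,
                    "group": r.group,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_profiles(
    design: CohortDesign,
    omic: str,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a samples x features log10 profile matrix for one omic.

    Returns ``(table, metadata)`` with the table indexed by sample ID.
    Deterministic given ``design.seed`` (or an explicit ``rng``).
    """
    if omic == MICROBIOTA:
        vc, n_feat, n_tp, baseline = (
            design.microbiota_vc,
            design.n_taxa,
            design.n_timepoints,
            design.microbiota_baseline,
        )
        feat_names = design.taxon_names()
    elif omic == LIPIDOME:
        vc, n_feat, n_tp, baseline = (
            design.lipid_vc,
            design.n_lipids,
            design.n_lipid_timepoints,
            design.lipid_baseline,
        )
        feat_names = design.lipid_names()
    else:
        raise ValueError(f"unknown omic {omic!r}")
    if rng is None:
        rng = np.random.default_rng(_split_seed(design.seed, omic))
    n_sub = design.n_subjects
    m = rng.normal(0.0, np.sqrt(vc.shared), size=n_feat)
    a = rng.normal(0.0, np.sqrt(vc.subject), size=(n_sub, n_feat))
    e = rng.normal(0.0, np.sqrt(vc.noise), size=(n_sub, n_tp, n_feat))
    x = baseline + m[None, None, :] + a[:, None, :] + e
    meta = sample_metadata(design, n_tp)
    table = pd.DataFrame(
        x.reshape(n_sub * n_tp, n_feat), index=meta.index, columns=feat_names
    )
    return table, meta


def plant_association(
    abundance: pd.DataFrame,
    lipid: pd.DataFrame,
    assoc: PlantedAssociation,
    design: CohortDesign,
    rng: np.random.Generator,
    metadata_micro: pd.DataFrame | None = None,
) -> None:
    """Inject a shared latent into a taxon column and its lipid columns.

    The latent is one independent N(0,1) draw per (subject, time point)
    observation; loadings are scaled to each feature's per-observation
    standard deviation so every planted pair attains the target population
    correlation rho: with loading ``lam = sigma * sqrt(rho / (1 - rho))`` the
    correlation of two features sharing the latent is exactly rho.  Modifies
    the tables in place.
    """
    rho = assoc.target_correlation
    if not abs(rho) < 1:
        raise ValueError("|target_correlation| must be < 1")
    if assoc.taxon_index >= abundance.shape[1]:
        raise IndexError("taxon index out of range")
    if max(assoc.lipid_indices) >= lipid.shape[1]:
        raise IndexError("lipid index out of range")
    if rho == 0.0:
        return
    if metadata_micro is None:
        metadata_micro = sample_metadata(design, design.n_timepoints)
    # One latent value per (subject, timepoint) over the union of time points.
    latent = pd.Series(
        rng.standard_normal(len(metadata_micro)), index=metadata_micro.index
    )
    _apply_association(abundance, lipid, assoc, design, latent)


def plant_effect(
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    effect: PlantedEffect,
) -> None:
    """Add the log10 fold change to the named taxon in its (group, TP) cell."""
    if effect.taxon_index >= abundance.shape[1]:
        raise IndexError("taxon index out of range")
    if effect.group not in set(metadata["group"]):
        raise ValueError(f"unknown group {effect.group!r}")
    if effect.timepoint not in set(metadata["timepoint"]):
        raise ValueError(f"unknown timepoint {effect.timepoint!r}")
    mask = (metadata["group"] == effect.group) & (metadata["timepoint"] == effect.timepoint)
    rows = metadata.index[mask]
    abundance.loc[rows, abundance.columns[effect.taxon_index]] += effect.log10_fold_change


# Enzymatic panel construction: analyte = mean + sd * z where z loads on an
# association latent, reproducing cross-platform corroboration of the planted
# taxon-lipid links.  Means/SDs are typical adult serum values in mmol/L.
_PANEL_SPEC = {
    "TC": (5.10, 1.02),
    "LDL": (3.00, 1.21),
    "HDL": (1.50, 0.33),
    "TG": (1.20, 0.71),
}


def _split_seed(seed: int, label: str) -> int:
    """Derive a child seed below 2**31 from the master seed and a label."""
    h = np.uint32(seed & 0x7FFFFFFF)
    for ch in label.encode():
        h = np.uint32((int(h) * 31 + ch) % 2147483647)
    return int(h)


def generate_cohort(design: CohortDesign):
    """Generate the full cohort.

    Returns ``(abundance, lipid, metadata, panel, ledger)``: the microbiota
    table (all time points), the lipid table (lipidomics time points), the
    microbiota sample sheet, the enzymatic lipid panel (lipidomics samples)
    and the ground-truth ledger.  Byte-identical on re-run for a fixed design.
    """
    abundance, meta_micro = generate_profiles(design, MICROBIOTA)
    lipid, meta_lipid = generate_profiles(design, LIPIDOME)
    rng_assoc = np.random.default_rng(_split_seed(design.seed, "associations"))
    latents = {}
    for assoc in design.planted_associations:
        # Record the latent so the panel can corroborate the association.
        latent_rng = np.random.default_rng(rng_assoc.integers(2**31))
        latent = pd.Series(
            latent_rng.standard_normal(len(meta_micro)), index=meta_micro.index
        )
        _apply_association(abundance, lipid, assoc, design, latent)
        latents[assoc.taxon_index] = (assoc, latent)
    if design.planted_effect is not None:
        plant_effect(abundance, meta_micro, design.planted_effect)
    panel = _generate_panel(design, meta_lipid, latents)
    ledger = GroundTruthLedger(
        planted_associations=list(design.planted_associations),
        planted_effect=design.planted_effect,
        realized_variance_components={
            MICROBIOTA: _realized_vc(design.microbiota_vc),
            LIPIDOME: _realized_vc(design.lipid_vc),
        },
    )
    return abundance, lipid, meta_micro, panel, ledger


def _apply_association(abundance, lipid, assoc, design, latent):
    rho = assoc.target_correlation
    if rho == 0.0:
        return
    mag = np.sqrt(abs(rho) / (1 - abs(rho)))
    sd_taxon = np.sqrt(design.microbiota_vc.subject + design.microbiota_vc.noise)
    sd_lipid = np.sqrt(design.lipid_vc.subject + design.lipid_vc.noise)
    abundance.iloc[:, assoc.taxon_index] += (
        mag * sd_taxon * latent.loc[abundance.index].to_numpy()
    )
    sign = np.sign(rho)
    for j in assoc.lipid_indices:
        lipid.iloc[:, j] += sign * mag * sd_lipid * latent.loc[lipid.index].to_numpy()


def _generate_panel(design, meta_lipid, latents):
    rng = np.random.default_rng(_split_seed(design.seed, "panel"))
    n = len(meta_lipid)
    z = {k: rng.standard_normal(n) for k in _PANEL_SPEC}
    # Panel loadings on planted latents: the taxon-latent correlation is
    # sqrt(rho/(1+... )) -- concretely corr(taxon, latent) = sqrt(|rho|), so a
    # panel analyte with corr(analyte, latent) = sqrt(|rho'|) gives a
    # taxon-analyte correlation of sqrt(|rho * rho'|).
    loadings = {"TG": (1, 0.59), "TC": (2, 0.52), "LDL": (2, 0.55), "HDL": (1, -0.36)}
    values = {}
    for analyte, (mean, sd) in _PANEL_SPEC.items():
        zi = z[analyte]
        if analyte in loadings:
            taxon_idx, rho2 = loadings[analyte]
            if taxon_idx in latents:
                _, latent = latents[taxon_idx]
                lam = np.sqrt(abs(rho2))
                zi = np.sign(rho2) * lam * latent.loc[meta_lipid.index].to_numpy() + np.sqrt(
                    1 - lam**2
                ) * zi
        values[analyte] = np.maximum(mean + sd * zi, 0.05)
    return pd.DataFrame(values, index=meta_lipid.index)


def _realized_vc(vc: VarianceComponents) -> dict[str, float]:
    return {
        "shared": vc.shared,
        "subject": vc.subject,
        "noise": vc.noise,
        "expected_intra_r": vc.expected_intra_r,
        "expected_inter_r": vc.expected_inter_r,
    }


def taxon_annotation(design: CohortDesign) -> pd.DataFrame:
    """Phylum / Clostridium-cluster labels per taxon for enrichment tests."""
    rng = np.random.default_rng(_split_seed(design.seed, "taxonomy"))
    names = design.taxon_names()
    phyla, groups = [], []
    clusters = ("Clostridium cluster IV", "Clostridium cluster XIVa", "Clostridium cluster IX", "Bacilli")
    for i in range(design.n_taxa):
        if i in _NAMED_PHYLA:
            p, g = _NAMED_PHYLA[i]
        else:
            p = rng.choice(_PHYLA, p=_PHYLUM_WEIGHTS)
            g = rng.choice(clusters) if p == "Firmicutes" else p
        phyla.append(p)
        groups.append(g)
    return pd.DataFrame({"phylum": phyla, "group_label": groups}, index=names)
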