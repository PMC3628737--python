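"""Synthetic cohort generator: calibration, planting, determinism."""
import numpy as np
import pandas as pd
import pytest

from gutlipid import correlate as co
from gutlipid import simulate as sim
from gutlipid import stability as st


def small_design(**kw):
    defaults = dict(
        n_subjects=10,
        group_sizes={"probiotic": 5, "placebo": 5},
        n_taxa=40,
        lipid_class_counts={"TG": 20, "PC": 10},
        planted_associations=[],
        planted_effect=sim.PlantedEffect(0, "probiotic", 2, 0.0),
        seed=0,
    )
    defaults.update(kw)
    return sim.CohortDesign(**defaults)


def test_deterministic_given_seed():
    d = sim.CohortDesign(seed=7)
    out1 = sim.generate_cohort(d)
    out2 = sim.generate_cohort(sim.CohortDesign(seed=7))
    for a, b in zip(out1[:2], out2[:2]):
        pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(out1[3], out2[3])


def test_different_seed_changes_values():
    a1 = sim.generate_cohort(sim.CohortDesign(seed=1))[0]
    a2 = sim.generate_cohort(sim.CohortDesign(seed=2))[0]
    assert not np.allclose(a1.to_numpy(), a2.to_numpy())


def test_zero_noise_gives_identical_profiles_within_subject():
    d = small_design(microbiota_vc=sim.VarianceComponents(0.7, 0.3, 0.0))
    table, meta = sim.generate_profiles(d, sim.MICROBIOTA)
    intra = st.intra_subject_similarity(table, meta, (1, 2))
    assert np.allclose(intra["r"], 1.0)


def test_pure_noise_gives_independent_profiles():
    d = small_design(
        n_taxa=400,
        microbiota_vc=sim.VarianceComponents(0.0, 0.0, 1.0),
    )
    table, meta = sim.generate_profiles(d, sim.MICROBIOTA)
    inter = st.inter_subject_similarity(table, meta, 1)
    assert abs(inter).max() < 0.15  # Monte-Carlo error at 400 features


def test_variance_component_calibration_hits_stability_targets():
    """Microbiota components (0.77, 0.17, 0.06) -> intra ~0.94, inter ~0.77."""
    intra_all, inter_all = [], []
    for seed in range(5):
        d = sim.CohortDesign(seed=seed, planted_associations=[],
                             planted_effect=sim.PlantedEffect(0, "probiotic", 2, 0.0))
        table, meta = sim.generate_profiles(d, sim.MICROBIOTA)
        intra_all.append(st.intra_subject_similarity(table, meta, (1, 2))["r"].mean())
        inter_all.append(st.inter_subject_similarity(table, meta, 1).mean())
    assert np.mean(intra_all) == pytest.approx(0.94, abs=0.02)
    assert np.mean(inter_all) == pytest.approx(0.77, abs=0.03)


def test_invalid_variance_components_rejected():
    with pytest.raises(ValueError):
        sim.VarianceComponents(-0.1, 0.5, 0.5)
    with pytest.raises(ValueError):
        sim.VarianceComponents(0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        sim.VarianceComponents(np.nan, 0.5, 0.5)


def test_plant_association_recovers_target_correlation():
    """Planted rho = 0.6 pairs: sample bicor within 0.6 +/- 0.25 (n = 44)."""
    hits, rs = 0, []
    n_seeds = 40
    for seed in range(n_seeds):
        d = sim.CohortDesign(
            n_subjects=22,
            group_sizes={"probiotic": 11, "placebo": 11},
            n_taxa=20,
            lipid_class_counts={"TG": 20},
            planted_associations=[sim.PlantedAssociation(0, (0,), 0.6)],
            planted_effect=sim.PlantedEffect(0, "probiotic", 2, 0.0),
            seed=seed,
        )
        ab, lip, meta, panel, ledger = sim.generate_cohort(d)
        shared = ab.index.intersection(lip.index)
        r = co.bicor(ab.loc[shared].iloc[:, 0], lip.loc[shared].iloc[:, 0])
        rs.append(r)
        hits += abs(r - 0.6) <= 0.25
    assert hits / n_seeds >= 0.95
    assert np.mean(rs) == pytest.approx(0.6, abs=0.06)  # near-unbiased


def test_disjoint_associations_stay_independent():
    d = sim.CohortDesign(
        n_subjects=25,
        group_sizes={"probiotic": 11, "placebo": 14},
        n_taxa=20,
        lipid_class_counts={"TG": 20},
        planted_associations=[
            sim.PlantedAssociation(0, (0,), 0.6),
            sim.PlantedAssociation(1, (1,), 0.6),
        ],
        planted_effect=sim.PlantedEffect(0, "probiotic", 2, 0.0),
        seed=5,
    )
    rs = []
    for seed in range(20):
        d.seed = seed
        ab, lip, *_ = sim.generate_cohort(d)
        rs.append(np.corrcoef(lip.iloc[:, 0], lip.iloc[:, 1])[0, 1])
    assert abs(np.mean(rs)) < 0.1


def test_plant_effect_shifts_only_named_cell():
    d = small_design()
    table, meta = sim.generate_profiles(d, sim.MICROBIOTA)
    before = table.copy()
    eff = sim.PlantedEffect(0, "probiotic", 2, np.log10(2.0))
    sim.plant_effect(table, meta, eff)
    delta = table - before
    target = (meta["group"] == "probiotic") & (meta["timepoint"] == 2)
    assert np.allclose(delta.loc[target.values, table.columns[0]], np.log10(2.0))
    delta.loc[target.values, table.columns[0]] = 0.0
    assert np.allclose(delta.to_numpy(), 0.0)


def test_plant_effect_zero_is_identity():
    d = small_design()
    table, meta = sim.generate_profiles(d, sim.MICROBIOTA)
    before = table.copy()
    sim.plant_effect(table, meta, sim.PlantedEffect(0, "probiotic", 2, 0.0))
    pd.testing.assert_frame_equal(table, before)


def test_plant_effect_unknown_cell_rejected():
    d = small_design()
    table, meta = sim.generate_profiles(d, sim.MICROBIOTA)
    with pytest.raises(ValueError):
        sim.plant_effect(table, meta, sim.PlantedEffect(0, "nope", 2, 0.1))
    with pytest.raises(ValueError):
        sim.plant_effect(table, meta, sim.PlantedEffect(0, "probiotic", 9, 0.1))


def test_invalid_association_rejected():
    with pytest.raises(ValueError):
        sim.PlantedAssociation(0, (1,), 1.0)
    with pytest.raises(ValueError):
        sim.PlantedAssociation(0, (), 0.5)


def test_ledger_lists_planted_items(default_cohort):
    ledger = default_cohort["ledger"]
    design = default_cohort["design"]
    assert ledger.planted_associations == list(design.planted_associations)
    assert ledger.planted_effect == design.planted_effect
    roundtrip = sim.GroundTruthLedger.from_json(ledger.to_json())
    assert roundtrip.planted_associations == ledger.planted_associations
    assert roundtrip.planted_effect == ledger.planted_effect


def test_default_lipid_names_all_parseable(default_cohort):
    from gutlipid import lipids as lp

    ann = lp.annotate_lipids(default_cohort["lipid"].columns)
    assert len(ann) == 407
    assert ann["lipid_class"].nunique() == 11


def test_metadata_layout(default_cohort):
    meta = default_cohort["metadata"]
    assert meta.groupby("subject").size().eq(3).all()
    assert set(meta["group"]) == {"probiotic", "placebo"}
    assert (meta.groupby("group")["subject"].nunique() == pd.Series(
        {"placebo": 14, "probiotic": 11})).all()


def test_panel_nonnegative(default_cohort):
    assert (default_cohort["panel"] >= 0).all().all()
    assert list(default_cohort["panel"].columns) == ["TC", "LDL", "HDL", "TG"]
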