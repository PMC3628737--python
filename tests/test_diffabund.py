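"""Moderated intervention tests, shrinkage behaviour and empirical power."""
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from gutlipid import diffabund as da
from gutlipid import simulate as sim
from tests.conftest import make_table


def test_bh_adjust_hand_computed():
    # step-up: min over j>=i of m*p_(j)/j; all four collapse to 0.04
    out = da.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])


def test_bh_adjust_edge_cases():
    assert da.bh_adjust([0.3]) == pytest.approx([0.3])
    assert np.allclose(da.bh_adjust(np.ones(5)), 1.0)
    with pytest.warns(UserWarning, match="NaN"):
        out = da.bh_adjust([0.01, np.nan])
    assert np.isnan(out[1])


def test_squeeze_equal_variances_complete_shrinkage():
    """All s2 equal: spread is below sampling scatter, so d0 = inf and the
    posterior equals the common value; moderated t then equals ordinary t."""
    with pytest.warns(UserWarning, match="complete shrinkage"):
        post, d0, s0 = da.squeeze_variances(np.full(50, 0.25), df=10)
    assert np.isinf(d0)
    assert np.allclose(post, 0.25, rtol=1e-6)


def test_squeeze_heterogeneous_variances_between_limits():
    rng = np.random.default_rng(0)
    true = rng.uniform(0.05, 2.0, 200)
    s2 = true * rng.chisquare(8, 200) / 8
    post, d0, s0 = da.squeeze_variances(s2, df=8)
    assert 0 < d0 < np.inf
    lo, hi = np.minimum(s2, s0), np.maximum(s2, s0)
    assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)


def test_moderated_t_between_ordinary_and_prior_t(paired_metadata):
    meta = paired_metadata(8, groups=("probiotic",))
    rng = np.random.default_rng(1)
    values = rng.normal(0, rng.uniform(0.1, 1.0, 60), size=(len(meta), 60))
    res = da.fit_moderated_contrast(make_table(meta, values), meta, groups=("probiotic",))
    t_prior = res.table["effect_log10"] / np.sqrt(res.s0_2 / 8)
    lo = np.minimum(res.table["t"], t_prior)
    hi = np.maximum(res.table["t"], t_prior)
    assert np.all(res.table["moderated_t"] >= lo - 1e-9)
    assert np.all(res.table["moderated_t"] <= hi + 1e-9)
    assert np.all(np.sign(res.table["moderated_t"]) == np.sign(res.table["t"]))


def test_matches_limma_on_paired_fixture(tmp_path, paired_metadata):
    """Moderated t and p agree with the reference empirical-Bayes pipeline."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    rng = np.random.default_rng(42)
    n_taxa, n_sub = 30, 12
    diffs = rng.normal(0.1, rng.uniform(0.2, 0.8, (n_taxa, 1)), (n_taxa, n_sub))
    meta = paired_metadata(n_sub, groups=("g",))
    values = np.zeros((2 * n_sub, n_taxa))
    values[1::2] = diffs.T
    res = da.fit_moderated_contrast(make_table(meta, values), meta, groups=("g",))
    np.savetxt(tmp_path / "diffs.tsv", diffs, delimiter="\t")
    script = textwrap.dedent(
        """
        suppressMessages(library(limma))
        d <- as.matrix(read.table(commandArgs(TRUE)[1]))
        fit <- eBayes(lmFit(d, design = matrix(1, ncol(d), 1)))
        write.table(data.frame(t = fit$t[, 1], p = fit$p.value[, 1],
                               d0 = fit$df.prior, s02 = fit$s2.prior),
                    commandArgs(TRUE)[2], sep = "\t", row.names = FALSE)
        """
    )
    (tmp_path / "oracle.R").write_text(script)
    subprocess.run(
        ["Rscript", str(tmp_path / "oracle.R"), str(tmp_path / "diffs.tsv"),
         str(tmp_path / "out.tsv")],
        check=True, capture_output=True,
    )
    ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
    assert res.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
    assert res.s0_2 == pytest.approx(ref["s02"].iloc[0], rel=1e-6)
    assert np.allclose(res.table["moderated_t"], ref["t"], rtol=1e-6)
    assert np.allclose(res.table["p"], ref["p"], rtol=1e-6)


def test_null_type_one_error_controlled(paired_metadata):
    """No planted effect: BH-adjusted discoveries stay at the nominal rate."""
    false_flag_seeds = 0
    n_seeds = 40
    for seed in range(n_seeds):
        d = sim.CohortDesign(
            seed=seed,
            planted_associations=[],
            planted_effect=sim.PlantedEffect(0, "probiotic", 2, 0.0),
        )
        table, meta = sim.generate_profiles(d, sim.MICROBIOTA)
        res = da.fit_moderated_contrast(table, meta, groups=("probiotic", "placebo"))
        false_flag_seeds += (res.table["p_adjusted"] < 0.05).any()
    # family-wise false-flag probability under BH at 0.05 is <= 0.05;
    # binomial upper bound over 40 seeds
    assert false_flag_seeds <= 7


def test_planted_effect_detected(default_cohort):
    res = da.fit_moderated_contrast(
        default_cohort["abundance"],
        default_cohort["metadata"],
        groups=("probiotic", "placebo"),
    )
    flagged = res.table[res.table["p_adjusted"] < 0.05]
    assert list(flagged.index) == ["Lactobacillus rhamnosus et rel."]
    assert flagged["effect_log10"].iloc[0] == pytest.approx(1.0, abs=0.35)


def test_contrast_requires_enough_subjects(paired_metadata):
    meta = paired_metadata(1)
    table = make_table(meta, np.random.default_rng(0).normal(size=(len(meta), 5)))
    with pytest.raises(ValueError, match="fewer than 2"):
        da.fit_moderated_contrast(table, meta, groups=("probiotic", "placebo"))


def test_power_null_insertion_matches_false_positive_rate(default_cohort):
    res = da.empirical_power(default_cohort["abundance"], 1.0, 8, reps=60, seed=3)
    assert res.detection_rates.iloc[0] <= 0.05


def test_power_saturates_at_huge_fold_change(default_cohort):
    res = da.empirical_power(default_cohort["abundance"], 1e6, 8, reps=30, seed=3)
    assert res.detection_rates.iloc[0] == 1.0


def test_power_monotone_in_fold_change_and_n(default_cohort):
    table = default_cohort["abundance"]
    small = da.empirical_power(table, 3.0, [4, 8], reps=60, seed=4, noise_sd=0.1)
    assert small.detection_rates.loc[8] >= small.detection_rates.loc[4]
    weak = da.empirical_power(table, 2.0, 8, reps=60, seed=4, noise_sd=0.1)
    strong = da.empirical_power(table, 8.0, 8, reps=60, seed=4, noise_sd=0.1)
    assert strong.detection_rates.loc[8] >= weak.detection_rates.loc[8]


def test_power_rejects_bad_inputs(default_cohort):
    with pytest.raises(ValueError):
        da.empirical_power(default_cohort["abundance"], -1.0, 8)
    with pytest.raises(ValueError):
        da.empirical_power(default_cohort["abundance"], 2.0, 8, reps=0)
    with pytest.raises(ValueError):
        da.empirical_power(default_cohort["abundance"], 2.0, 500, reps=1)
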