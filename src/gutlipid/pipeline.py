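"""End-to-end orchestration: stability -> intervention tests -> screen ->
biclustering -> enrichment -> panel, with all outputs written as TSV."""
from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import correlate, diffabund, enrichment, io, lipids, panel as panel_mod, plaid, simulate, stability

log = logging.getLogger("gutlipid.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: io.RunConfig) -> dict:
    """Execute the full analysis; returns a report dict and writes a bundle.

    When no input paths are configured, a default synthetic cohort is
    generated (seeded by ``config.seed``) so the pipeline runs end to end
    with no external data.
    """
    io.configure_logging(config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config": {
        "r_min": config.r_min, "q_max": config.q_max,
        "long_chain_threshold": config.long_chain_threshold,
    }}
    log.info("run starting: seed=%s r_min=%s q_max=%s", config.seed, config.r_min, config.q_max)

    stage = "load"
    try:
        if config.abundance and config.lipids and config.metadata:
            abundance = io.read_feature_table(config.abundance)
            lipid = io.read_feature_table(config.lipids)
            metadata = io.read_metadata(config.metadata)
            io.check_tables_match(abundance, metadata, "abundance")
            io.check_tables_match(lipid, metadata, "lipids")
            panel = io.read_feature_table(config.panel) if config.panel else None
            ledger = None
        else:
            design = simulate.CohortDesign(seed=config.seed)
            abundance, lipid, metadata, panel, ledger = simulate.generate_cohort(design)
            io.write_feature_table(abundance, out / "abundance.tsv")
            io.write_feature_table(lipid, out / "lipids.tsv")
            io.write_metadata(metadata, out / "metadata.tsv")
            io.write_feature_table(panel, out / "panel.tsv")
            io.write_ledger(ledger, out / "ground_truth.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    try:
        stage = "lipid_annotation"
        annotations = lipids.annotate_lipids(
            lipid.columns, long_chain_threshold=config.long_chain_threshold
        )
        annotations.to_csv(out / "lipid_annotations.tsv", sep="\t")
        composition = lipids.class_composition(lipid)
        composition.to_csv(out / "lipid_class_composition.tsv", sep="\t")
        report["n_lipid_species"] = int(len(annotations))
        report["n_lipid_classes"] = int(annotations["lipid_class"].nunique())

        stage = "stability"
        stab = stability.stability_report(abundance, metadata)
        stab.to_csv(out / "stability_microbiota.tsv", sep="\t")
        lip_meta = metadata.loc[metadata.index.intersection(lipid.index)]
        stab_lip = stability.stability_report(lipid, lip_meta)
        stab_lip.to_csv(out / "stability_lipids.tsv", sep="\t")
        report["stability_microbiota"] = stab.to_dict()
        report["stability_lipids"] = stab_lip.to_dict()
        intra = stability.intra_subject_similarity(abundance, metadata, (1, 2))
        grp = [g for _, g in intra.groupby("group")["r"]]
        if len(grp) == 2:
            report["stability_group_difference_p"] = stability.compare_group_stability(*grp)

        stage = "differential_abundance"
        contrast = diffabund.fit_moderated_contrast(
            abundance, metadata, groups=tuple(sorted(metadata["group"].unique(), reverse=True)[:2])
        )
        contrast.table.to_csv(out / "differential_abundance.tsv", sep="\t")
        hits = contrast.table[contrast.table["p_adjusted"] < 0.05]
        report["n_differential_taxa"] = int(len(hits))
        report["differential_taxa"] = list(hits.index)

        stage = "power"
        power = diffabund.empirical_power(
            abundance,
            fold_change=config.power_fold_change,
            sample_sizes=list(config.power_sample_sizes),
            reps=config.power_reps,
            seed=config.seed,
        )
        power.detection_rates.rename_axis("n").to_csv(out / "power_curve.tsv", sep="\t")
        report["power"] = power.detection_rates.to_dict()

        stage = "correlation_screen"
        scr = correlate.screen(abundance, lipid, r_min=config.r_min, q_max=config.q_max)
        io.write_feature_table(scr.r.rename_axis("taxon"), out / "screen_r.tsv")
        io.write_feature_table(scr.q.rename_axis("taxon"), out / "screen_q.tsv")
        scr.pairs.to_csv(out / "significant_pairs.tsv", sep="\t", index=False)
        report["screen"] = correlate.screen_summary(scr, annotations)

        stage = "clustering"
        if scr.n_significant and len(scr.significant_taxa) >= 2 and len(scr.significant_lipids) >= 2:
            ordered, row_link, col_link = correlate.two_way_cluster(scr.r, scr.mask)
            io.write_feature_table(ordered.rename_axis("taxon"), out / "heatmap_matrix.tsv")
            _heatmap(ordered, out / "heatmap.png")

            stage = "biclustering"
            params = plaid.PlaidParams(
                max_layers=config.plaid_max_layers,
                n_shuffles=config.plaid_n_shuffles,
                seed=config.seed,
            )
            restricted = scr.r.loc[scr.significant_taxa, scr.significant_lipids]
            bset = plaid.fit_plaid(restricted, params)
            summary = plaid.bicluster_summary(bset, restricted)
            summary.to_csv(out / "biclusters.tsv", sep="\t", index=False)
            report["n_biclusters"] = bset.n_layers

            stage = "enrichment"
            enrich_rows = []
            universe = scr.significant_lipids
            for k, layer in enumerate(bset.layers, start=1):
                members = [bset.col_labels[j] for j in np.nonzero(layer.cols)[0]]
                res = enrichment.category_enrichment(
                    members, universe, long_chain_threshold=config.long_chain_threshold
                )
                res["set"] = f"bicluster_{k}"
                enrich_rows.append(res.reset_index())
            if enrich_rows:
                pd.concat(enrich_rows).to_csv(out / "lipid_enrichment.tsv", sep="\t", index=False)
                report["n_enrichment_tests"] = int(sum(len(r) for r in enrich_rows))
        else:
            log.info("no significant structure to cluster; skipping heatmap/biclusters")
            report["n_biclusters"] = 0

        stage = "panel"
        if panel is not None:
            pscreen = panel_mod.panel_screen(abundance, panel, q_max=config.q_max)
            pscreen.to_csv(out / "panel_screen.tsv", sep="\t", index=False)
            sig = panel_mod.significant_panel_table(pscreen)
            sig.to_csv(out / "panel_significant.tsv", sep="\t")
            report["n_panel_significant"] = int(pscreen["significant"].sum())
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2) + "\n")
    log.info("run complete: %s", out / "report.json")
    return report


def _heatmap(matrix: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(10, 6))
    vmax = np.abs(matrix.to_numpy()).max() or 1.0
    im = ax.imshow(matrix.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xlabel("lipid species")
    ax.set_ylabel("genus-level taxa")
    fig.colorbar(im, ax=ax, label="biweight midcorrelation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
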