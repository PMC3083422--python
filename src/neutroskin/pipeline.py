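"""End-to-end orchestration: simulate → select → cluster → qPCR → stats → microdose.

Each stage reads only paths derived from the output directory, stamps every
output file with the config hash and seed, and logs its wall time to
stderr.  A stage failure aborts the run with the failing stage named;
outputs of completed stages are retained.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import arrays as arr
from . import group_stats as gs
from . import microdosim as md
from . import synthetic as syn
from .clustering import hierarchical_cluster
from .config import RunConfig

__all__ = ["StageError", "run_pipeline"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _write_tsv(table: pd.DataFrame, path: Path, header: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        table.to_csv(fh, sep="\t", index=index)


def _design(config: RunConfig) -> syn.StudyDesign:
    return syn.StudyDesign(
        n_genes=config.n_genes,
        replicates_per_condition=config.replicates_per_condition,
        mice_per_group=config.mice_per_group,
    )


def _noise(config: RunConfig) -> syn.NoiseModel:
    return syn.NoiseModel(
        spot_sd=config.spot_sd,
        dye_bias_coeffs=config.dye_bias_coeffs,
        flag_rate=config.flag_rate,
        low_signal_rate=config.low_signal_rate,
        ct_sd=config.ct_sd,
        seed=config.seed,
    )


def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    design = _design(config)
    effects = syn.PlantedEffects.default(design)
    noise = _noise(config)
    arrays = syn.generate_microarrays(design, effects, noise)
    array_dir = outdir / "arrays"
    syn.write_arrays(arrays, array_dir, header_comment=config.header_comment)
    syn.write_ground_truth(effects, outdir / "ground_truth.tsv")

    qpcr_genes = []
    for members in effects.blocks.values():
        qpcr_genes.extend(members[: config.n_qpcr_genes_per_block])
    null_pool = [g for g in design.gene_ids if g not in set().union(*effects.blocks.values())]
    qpcr_genes.extend(null_pool[: config.n_qpcr_genes_per_block])
    planted = effects.log2fc.loc[qpcr_genes].copy()
    planted.insert(0, syn.SHAM_GROUP, 0.0)
    qpcr = syn.generate_qpcr(design, qpcr_genes, planted, noise,
                             reference_gene=config.reference_gene)
    _write_tsv(qpcr, outdir / "qpcr_ct.tsv", config.header_comment)

    # a KRT6-like induction at the low dose, flat at the high dose
    labels = design.condition_labels
    medians = {syn.SHAM_GROUP: 30.0, labels[0]: 60.0, labels[1]: 70.0,
               labels[2]: 35.0, labels[3]: 30.0}
    dens = syn.generate_densitometry(
        medians, spread=config.densitometry_spread, design=design,
        outlier_rate=config.densitometry_outlier_rate, seed=config.seed + 7,
    )
    _write_tsv(dens, outdir / "densitometry.tsv", config.header_comment)
    return {"array_dir": str(array_dir), "n_arrays": len(arrays),
            "qpcr_genes": qpcr_genes}


def stage_select(config: RunConfig, outdir: Path) -> dict:
    design = _design(config)
    array_dir = outdir / "arrays"
    normalized, gene_ids = {}, {}
    for cond in design.condition_labels:
        for rep in range(1, design.replicates_per_condition + 1):
            path = array_dir / f"{cond}_rep{rep}.tsv"
            try:
                table = arr.read_two_channel_tsv(path)
            except arr.FormatError as exc:
                raise StageError(f"read_two_channel_tsv failed on {path}: {exc}") from exc
            mask = arr.filter_spots(table)
            normalized[(cond, rep)] = arr.lowess_normalize(
                table, mask, span=config.lowess_span, iterations=config.lowess_iterations
            )
            gene_ids[(cond, rep)] = table["gene_id"]
    expr = arr.aggregate_conditions(normalized, design, gene_ids)
    selected = arr.select_modulated(
        expr,
        fold_threshold=config.fold_threshold,
        min_conditions=config.min_conditions,
        alpha=config.alpha,
        t_mode=config.t_mode,
    )
    _write_tsv(selected, outdir / "modulated_genes.tsv", config.header_comment, index=True)
    expr.replicates.to_csv(outdir / "expression_replicates.tsv", sep="\t")
    return {"n_selected": len(selected), "n_genes_tested": len(expr.genes)}


def stage_cluster(config: RunConfig, outdir: Path) -> dict:
    selected = pd.read_csv(outdir / "modulated_genes.tsv", sep="\t", comment="#",
                           index_col="gene_id")
    fc_cols = [c for c in selected.columns if c.startswith("log2fc_")]
    if len(selected) < 2:
        log.info("stage_cluster: fewer than 2 modulated genes; skipping clustering")
        return {"clustered": 0}
    profiles = selected[fc_cols].to_numpy()
    dend = hierarchical_cluster(profiles, labels=selected.index)
    dend.write_json(outdir / "dendrogram.json")
    ordered = selected[fc_cols].iloc[dend.leaf_order()].clip(
        lower=-config.heat_clip, upper=config.heat_clip
    )
    _write_tsv(ordered, outdir / "heat_matrix.tsv", config.header_comment, index=True)
    return {"clustered": len(selected)}


def stage_qpcr(config: RunConfig, outdir: Path, qpcr_genes: list[str]) -> dict:
    qpcr = pd.read_csv(outdir / "qpcr_ct.tsv", sep="\t", comment="#")
    folds = []
    for gene in qpcr_genes:
        folds.append(gs.ddct_fold(qpcr, gene, config.reference_gene, config.calibrator_group))
    fold_table = pd.concat(folds, ignore_index=True)
    _write_tsv(fold_table, outdir / "qpcr_folds.tsv", config.header_comment)

    rows = []
    for gene, sub in fold_table.groupby("gene"):
        groups = [g["fold"].to_numpy() for _, g in sub.groupby("group")]
        names = [name for name, _ in sub.groupby("group")]
        f, p = gs.one_way_anova(groups)
        tk = gs.tukey_hsd(groups, alpha=config.alpha)
        sig = ";".join(f"{names[i]}|{names[j]}" for i, j in tk.significant) if p < config.alpha else ""
        rows.append({"gene": gene, "anova_F": f, "anova_p": p, "significant_pairs": sig})
    stats_table = pd.DataFrame(rows)
    _write_tsv(stats_table, outdir / "qpcr_stats.tsv", config.header_comment)
    return {"n_genes": len(rows)}


def stage_densitometry(config: RunConfig, outdir: Path) -> dict:
    dens = pd.read_csv(outdir / "densitometry.tsv", sep="\t", comment="#")
    dens["density_norm"] = gs.densitometry_normalize(dens)
    summaries = []
    groups, names = [], []
    for name, sub in dens.groupby("group"):
        w = gs.whisker_summary(sub["density_norm"])
        summaries.append({"group": name, "median": w.median, "q1": w.q1, "q3": w.q3,
                          "whisker_low": w.whisker_low, "whisker_high": w.whisker_high,
                          "n_outliers": w.outliers.size})
        groups.append(sub["density_norm"].to_numpy())
        names.append(name)
    f, p = gs.one_way_anova(groups)
    tk = gs.tukey_hsd(groups, alpha=config.alpha)
    table = pd.DataFrame(summaries)
    table["anova_F"], table["anova_p"] = f, p
    table["significant_pairs"] = ";".join(
        f"{names[i]}|{names[j]}" for i, j in tk.significant
    ) if p < config.alpha else ""
    _write_tsv(table, outdir / "densitometry_stats.tsv", config.header_comment)
    return {"anova_p": p}


def stage_microdose(config: RunConfig, outdir: Path) -> dict:
    scan = md.f2_scan(config.doses, config.diameters,
                      reference=(config.ref_dose, config.ref_diameter, config.ref_f2))
    _write_tsv(scan, outdir / "f2_scan.tsv", config.header_comment)
    return {"n_rows": len(scan)}


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages in dependency order; returns the report manifest.

    Deterministic stages rerun byte-identically under an identical config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash, "seed": config.seed, "stages": {}}
    state: dict = {}
    stages = [
        ("simulate", lambda: stage_simulate(config, outdir)),
        ("select", lambda: stage_select(config, outdir)),
        ("cluster", lambda: stage_cluster(config, outdir)),
        ("qpcr", lambda: stage_qpcr(config, outdir, state["simulate"]["qpcr_genes"])),
        ("stats", lambda: stage_densitometry(config, outdir)),
        ("microdose", lambda: stage_microdose(config, outdir)),
    ]
    for name, fn in stages:
        t0 = time.time()
        try:
            state[name] = fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        dt = time.time() - t0
        log.info("stage %s finished in %.2f s", name, dt)
        manifest["stages"][name] = {"seconds": round(dt, 3), **_jsonable(state[name])}
    (outdir / "report.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out
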