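"""End-to-end orchestration: simulate/read -> preprocess -> QC -> network ->
association -> predictor, with per-stage outputs and a JSON run summary.

The stage order is: probe filtering, ComBat batch adjustment, outlier
removal, replicate collapse and twin-pair averaging, then the analysis
stages.  All outputs are TSV/JSON; identical config + seed reproduces
identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from .association import (
    island_enrichment,
    probe_age_association,
    select_significant,
    storey_qvalues,
    tss_offset_summary,
)
from .concordance import (
    concordance_report,
    drift_vs_age,
    pair_clustering_fraction,
    sample_dendrogram,
)
from .network import (
    NetworkConfig,
    detect_modules,
    linkage_to_text,
    module_age_stats,
    module_eigenloci,
)
from .predictor import MarkerSpec, lasso_screen, loo_evaluate, significance_prune
from .preprocess import average_pairs, combat_adjust, filter_probes, flag_outliers
from .simulate import default_config, simulate_dataset

__all__ = ["RunConfig", "run_pipeline"]

ALL_STAGES = ("qc", "network", "associate", "predict")


@dataclass
class RunConfig:
    """Pipeline configuration; every stage parameter in one place."""

    simulate: bool = True
    sim: dict = field(default_factory=dict)           # SimulationConfig overrides
    beta_path: str | None = None
    sheet_path: str | None = None
    annotation_path: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    min_mean: float = 0.05
    max_mean: float = 0.95
    outlier_k: float = 3.0
    network: dict = field(default_factory=dict)       # NetworkConfig overrides
    q_cut: float = 0.05
    pi0_method: str = "smoother"
    include_controls: bool = False                    # association on twins only by default
    markers: list[str] | None = None                  # e.g. ["cg000001^2", "cg000002"]
    lasso_top_k: int = 5
    prune_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        bad = [s for s in cfg.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; choose from {ALL_STAGES}")
        if not cfg.simulate:
            for p in (cfg.beta_path, cfg.sheet_path, cfg.annotation_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input path missing or absent: {p}")
        return cfg


def _drop_samples(bm, sheet, drop: set[str]):
    """Remove samples plus their replicates and co-twins (pairs stay complete)."""
    meta = sheet.data.set_index("sample_id")
    expanded = set(drop)
    for sid in list(drop):
        rep = meta.loc[sid, "replicate_of"] if sid in meta.index else None
        primary = sid if pd.isna(rep) or rep in (None, "") else str(rep)
        expanded.add(primary)
        expanded |= set(meta.index[meta["replicate_of"] == primary])
        pid = meta.loc[primary, "pair_id"]
        if pd.notna(pid):
            expanded |= set(meta.index[meta["pair_id"] == pid])
    keep = [s for s in bm.sample_ids if s not in expanded]
    return mio.BetaMatrix(bm.data[keep]), sheet.subset(keep), sorted(expanded & set(bm.sample_ids))


def _twin_columns(bm, sheet):
    meta = sheet.data.set_index("sample_id")
    return [s for s in bm.sample_ids if meta.loc[s, "cohort"] == "twin"]


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run the enabled stages and write all outputs below ``outdir``.

    Returns the run summary (also written as ``run_summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {"version": __version__, "seed": cfg.seed,
                     "stages": list(cfg.stages)}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest.append(name)

    # -- acquire data -------------------------------------------------------
    if cfg.simulate:
        sim_cfg = default_config(seed=cfg.seed, **cfg.sim)
        bm, sheet, ann, truth = simulate_dataset(sim_cfg)
        emit("beta.tsv", lambda p: mio.write_beta_matrix(bm, p))
        emit("samples.csv", lambda p: mio.write_sample_sheet(sheet, p))
        emit("annotation.csv", lambda p: mio.write_probe_annotation(ann, p))
        emit("truth_probes.tsv", lambda p: truth.probes.to_csv(p, sep="\t", index=False))
        summary["simulation"] = {"n_probes": sim_cfg.n_probes,
                                 "n_samples": len(sheet.sample_ids)}
    else:
        bm = mio.read_beta_matrix(cfg.beta_path)
        sheet = mio.read_sample_sheet(cfg.sheet_path)
        ann = mio.read_probe_annotation(cfg.annotation_path)
    bm, sheet, ann, align_report = mio.align(bm, sheet, ann)
    summary["alignment"] = align_report.to_dict()

    # -- preprocessing -------------------------------------------------------
    bm = bm.drop_incomplete_probes()
    bm, filter_report = filter_probes(bm, cfg.min_mean, cfg.max_mean)
    summary["filter"] = filter_report.to_dict()
    bm = combat_adjust(bm, sheet)
    outliers = flag_outliers(bm, k=cfg.outlier_k) if len(bm.sample_ids) >= 4 else []
    bm, sheet, removed = _drop_samples(bm, sheet, set(outliers)) if outliers else (bm, sheet, [])
    summary["outliers"] = {"flagged": outliers, "removed": removed}
    emit("beta_preprocessed.tsv", lambda p: mio.write_beta_matrix(bm, p))

    # -- QC: concordance / drift / clustering -------------------------------
    if "qc" in cfg.stages:
        qc: dict = {"concordance": concordance_report(bm, sheet).to_dict()}
        meta = sheet.data
        n_pairs = meta[(meta["cohort"] == "twin") & meta["replicate_of"].isna()]["pair_id"].nunique()
        if n_pairs >= 3:
            qc["drift"] = {m: drift_vs_age(bm, sheet, m).to_dict()
                           for m in ("one_minus_pearson", "euclidean", "manhattan")}
        if n_pairs >= 2:
            qc["pair_clustering_fraction"] = pair_clustering_fraction(bm, sheet)
        Z = sample_dendrogram(bm)
        emit("sample_dendrogram.txt",
             lambda p: Path(p).write_text(linkage_to_text(Z, bm.sample_ids) + "\n"))
        summary["qc"] = qc

    # -- pair averaging ------------------------------------------------------
    bm_avg, sheet_avg = average_pairs(bm, sheet)
    emit("beta_pair_averaged.tsv", lambda p: mio.write_beta_matrix(bm_avg, p))
    twin_cols = _twin_columns(bm_avg, sheet_avg)
    analysis_cols = bm_avg.sample_ids if cfg.include_controls or not twin_cols else twin_cols
    bm_an = mio.BetaMatrix(bm_avg.data[analysis_cols])
    ages_an = sheet_avg.ages_for(analysis_cols)

    assoc = None
    if "network" in cfg.stages or "associate" in cfg.stages:
        assoc = probe_age_association(bm_an, ages_an)

    # -- co-methylation network ---------------------------------------------
    if "network" in cfg.stages:
        net_cfg = NetworkConfig(**cfg.network)
        assignment, Z = detect_modules(bm_an, net_cfg)
        eigen = module_eigenloci(bm_an, assignment)
        mod_stats = module_age_stats(eigen, ages_an, probe_t=assoc["t"],
                                     assignment=assignment)
        emit("modules.tsv", lambda p: assignment.to_frame().to_csv(p, sep="\t", index=False))
        emit("eigenloci.tsv", lambda p: pd.DataFrame(
            {el.module: el.scores for el in eigen}, index=bm_an.sample_ids
        ).rename_axis("sample_id").to_csv(p, sep="\t"))
        emit("module_age_stats.tsv", lambda p: mod_stats.to_csv(p, sep="\t"))
        emit("probe_dendrogram.txt",
             lambda p: Path(p).write_text(linkage_to_text(Z, bm_an.probe_ids) + "\n"))
        summary["network"] = {
            "module_sizes": {m: s for m, s in assignment.sizes.items()},
            "module_age": mod_stats.drop(columns=["estimable"]).to_dict("index"),
        }

    # -- per-probe association -----------------------------------------------
    selection = None
    if "associate" in cfg.stages:
        assoc = assoc.copy()
        assoc["q"] = storey_qvalues(assoc["p"].to_numpy(), pi0_method=cfg.pi0_method)
        sel, selection = select_significant(assoc, q_cut=cfg.q_cut)
        emit("association.tsv", lambda p: assoc.to_csv(p, sep="\t"))
        summary["association"] = {k: v for k, v in selection.to_dict().items()
                                  if k != "probe_ids"}
        if selection.n_selected:
            annotated = set(ann.probe_ids)
            background = [p for p in assoc.index if p in annotated]
            sel_ann = [p for p in selection.probe_ids if p in annotated]
            if sel_ann:
                table, odds, fp = island_enrichment(sel_ann, ann, background)
                med, wording = tss_offset_summary(sel_ann, ann)
                summary["association"]["island_enrichment"] = {
                    "table": table.tolist(), "odds_ratio": odds, "p": fp,
                }
                summary["association"]["tss_offset"] = {"median_bp": med,
                                                        "wording": wording}

    # -- predictor ------------------------------------------------------------
    if "predict" in cfg.stages:
        if cfg.markers:
            spec = MarkerSpec.from_strings(cfg.markers)
        else:
            ranked = lasso_screen(bm_an, ages_an, top_k=cfg.lasso_top_k)
            emit("lasso_screen.tsv", lambda p: ranked.to_csv(p, sep="\t", index=False))
            spec, _model = significance_prune(bm_an, ages_an,
                                              list(ranked["probe_id"]),
                                              alpha=cfg.prune_alpha)
        if spec is None:
            summary["predictor"] = {"note": "all candidate markers pruned"}
        else:
            from .predictor import fit_age_model

            model = fit_age_model(bm_an, ages_an, spec)
            loo = loo_evaluate(bm_an, ages_an, spec)
            preds = pd.DataFrame({"sample_id": loo.sample_ids,
                                  "observed_age": loo.observed,
                                  "predicted_age": loo.predicted})
            emit("predictions.tsv", lambda p: preds.to_csv(p, sep="\t", index=False))
            summary["predictor"] = {"markers": spec.term_names,
                                    "model": model.to_dict(),
                                    "loo": loo.to_dict()}

    summary["manifest"] = manifest
    mio.write_run_summary(summary, outdir / "run_summary.json")
    return summary
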