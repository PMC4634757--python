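"""End-to-end orchestration: simulate -> quantify -> select -> fit -> predict.

Each stage writes its artifacts into the run directory and records them in
``manifest.yaml`` together with the configuration hash, the seed and every
threshold actually applied.  Reruns with the same configuration and seed
produce byte-identical tables; ``resume=True`` skips completed stages.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, hurdle, io, predict, qpcr, simulate
from .config import PipelineConfig, config_hash, validate_config
from .core import COMPARTMENTS, STAGES, InvalidArgument

__all__ = ["run_pipeline", "STAGE_NAMES"]

logger = logging.getLogger(__name__)

STAGE_NAMES = ("simulate", "qpcr", "de", "biomarkers", "fit", "predict")


def _panel_params(cfg: PipelineConfig, seed: int) -> simulate.HurdleSimParams:
    kw = dict(n_genes=cfg.panel_genes, seed=seed)
    if cfg.panel_archetype == "separated":
        return simulate.HurdleSimParams.separated_panel(**kw)
    if cfg.panel_archetype == "pd_pm_confounded":
        return simulate.HurdleSimParams.pd_pm_binary_confounded(**kw)
    if cfg.panel_archetype == "correlated":
        return simulate.HurdleSimParams.correlated_stages(**kw)
    return simulate.HurdleSimParams(**kw)


class _Run:
    def __init__(self, cfg: PipelineConfig, out_dir: Path, resume: bool):
        self.cfg = cfg
        self.dir = out_dir
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.yaml"
        if resume and self.manifest_path.exists():
            self.manifest = yaml.safe_load(self.manifest_path.read_text())
            if self.manifest.get("config_hash") != config_hash(cfg):
                raise InvalidArgument("resume requested but configuration changed")
        else:
            self.manifest = {
                "config_hash": config_hash(cfg),
                "seed": cfg.seed,
                "config": cfg.to_dict(),
                "unknown_keys": getattr(cfg, "_unknown", {}),
                "thresholds": {
                    "glm_fdr": cfg.glm_fdr,
                    "pairwise_p": cfg.pairwise_p,
                    "fc_threshold": cfg.fc_threshold,
                    "biomarker_fdr": cfg.biomarker_fdr,
                    "biomarker_fc_gc": cfg.biomarker_fc_gc,
                    "biomarker_fc_o": cfg.biomarker_fc_o,
                    "detection_cutoff": cfg.detection_cutoff,
                    "control_margin": cfg.control_margin,
                },
                "stages": {},
            }

    def done(self, stage: str) -> bool:
        info = self.manifest["stages"].get(stage)
        if not info or info.get("status") != "done":
            return False
        return all((self.dir / a).exists() for a in info.get("artifacts", []))

    def record(self, stage: str, artifacts: list[str], status: str = "done") -> None:
        self.manifest["stages"][stage] = {"status": status, "artifacts": artifacts}
        self.manifest_path.write_text(yaml.safe_dump(self.manifest, sort_keys=True))


def run_pipeline(
    config: dict | PipelineConfig | None = None,
    resume: bool = False,
    stages: tuple = STAGE_NAMES,
) -> Path:
    """Execute the requested stages in dependency order; returns the run
    directory.  A stage failure marks the stage ``failed`` in the manifest
    (partial artifacts retained) and re-raises."""
    if isinstance(config, PipelineConfig):
        cfg, warnings = config, []
    else:
        cfg, warnings = validate_config(config if isinstance(config, dict) else {})
    for w in warnings:
        logger.warning(w)
    run = _Run(cfg, Path(cfg.out_dir), resume)
    for stage in STAGE_NAMES:
        if stage not in stages:
            continue
        if resume and run.done(stage):
            logger.info("stage %s already complete; skipping", stage)
            continue
        fn = globals()[f"_stage_{stage}"]
        try:
            artifacts = fn(run)
        except Exception:
            run.record(stage, [], status="failed")
            raise
        run.record(stage, artifacts)
    return run.dir


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(run: _Run) -> list[str]:
    cfg = run.cfg
    design = simulate.generate_design()
    counts, truth = simulate.simulate_counts(
        design,
        simulate.CountSimParams(
            n_genes=cfg.n_genes,
            baseline_mean=cfg.baseline_mean,
            dispersion=cfg.dispersion,
            de_fraction=cfg.de_fraction,
            log2_effect=cfg.log2_effect,
            seed=cfg.seed,
        ),
    )
    panel = simulate.simulate_hurdle_panel(design, _panel_params(cfg, cfg.seed + 1))
    io.write_design(design, run.dir / "design.tsv")
    io.write_counts(counts, run.dir / "counts.tsv")
    truth.labels.index.name = "gene"
    truth.labels.to_csv(run.dir / "counts_truth.tsv", sep="\t")
    io.write_matrix(panel.rel, run.dir / "panel_rel.tsv")
    io.write_matrix(panel.det, run.dir / "panel_det.tsv")
    truth_doc = {
        "detection_logit": [[float(x) for x in r] for r in panel.truth["detection_logit"]],
        "level_mean": [[float(x) for x in r] for r in panel.truth["level_mean"]],
        "resid_sd": float(panel.truth["resid_sd"]),
        "b_binary": panel.truth["b_binary"].round(10).to_dict(),
        "b_level": panel.truth["b_level"].round(10).to_dict(),
        "u_binary": panel.truth["u_binary"].round(10).to_dict(),
        "u_level": panel.truth["u_level"].round(10).to_dict(),
    }
    (run.dir / "panel_truth.yaml").write_text(yaml.safe_dump(truth_doc, sort_keys=True))
    return [
        "design.tsv", "counts.tsv", "counts_truth.tsv",
        "panel_rel.tsv", "panel_det.tsv", "panel_truth.yaml",
    ]


def _stage_qpcr(run: _Run) -> list[str]:
    """Forward-simulate Ct data from the panel quantities, then run the
    quantification chain back: efficiency fit, detection calling, Pfaffl
    quantification and reference normalization."""
    cfg = run.cfg
    rel = io.read_matrix(run.dir / "panel_rel.tsv")
    rng = np.random.default_rng(cfg.seed + 2)
    # three stable synthetic references, constant quantity across samples
    refs = ["REF1", "REF2", "REF3"]
    ref_rel = pd.DataFrame(1.0, index=refs, columns=rel.columns)
    full = pd.concat([rel, ref_rel])
    eff_true = pd.Series(rng.uniform(1.85, 2.0, len(full)), index=full.index)
    ct = qpcr.simulate_ct(full, efficiency=eff_true, calibrator_ct=25.0, cycle_cutoff=cfg.detection_cutoff)

    dilutions = np.array([1.0, 1 / 3, 1 / 9, 1 / 18, 1 / 36])
    curves = {}
    for gene in full.index:
        cts = 25.0 - np.log(dilutions) / np.log(eff_true[gene])
        curves[gene] = qpcr.fit_efficiency(dilutions, cts, gene=gene)
    eff_fit = pd.Series({g: c.efficiency for g, c in curves.items()})
    eff_table = pd.DataFrame(
        {"slope": {g: c.slope for g, c in curves.items()}, "efficiency": eff_fit}
    )
    eff_table.index.name = "gene"
    eff_table.to_csv(run.dir / "efficiencies.tsv", sep="\t", float_format="%.12g")

    det = qpcr.call_detection(ct, cycle_cutoff=cfg.detection_cutoff)
    quant = qpcr.pfaffl_table(ct, eff_fit)
    norm = qpcr.normalize_by_references(quant, refs)
    io.write_ct_long(ct, run.dir / "ct_table.tsv")
    io.write_matrix(det, run.dir / "qpcr_det.tsv")
    io.write_matrix(norm, run.dir / "qpcr_rel_normalized.tsv")
    return ["efficiencies.tsv", "ct_table.tsv", "qpcr_det.tsv", "qpcr_rel_normalized.tsv"]


def _stage_de(run: _Run) -> list[str]:
    cfg = run.cfg
    counts = io.read_counts(run.dir / "counts.tsv")
    design = io.read_design(run.dir / "design.tsv")
    dispersions = de.estimate_dispersion(counts, design)
    artifacts = []
    tables = {}
    for comp in COMPARTMENTS:
        table = de.compartment_stage_de(counts, design, comp, dispersions=dispersions)
        tables[comp] = table
        sel = de.select_stage_de(
            table, glm_fdr=cfg.glm_fdr, pairwise_p=cfg.pairwise_p, fc_threshold=cfg.fc_threshold
        )
        for name, df in ((f"de_{comp}.tsv", table), (f"de_{comp}_selected.tsv", sel)):
            df.index.name = "gene"
            df.to_csv(run.dir / name, sep="\t", float_format="%.12g")
            artifacts.append(name)
    summary = de.transition_summary(
        counts, design, pairwise_p=cfg.pairwise_p, fc_threshold=cfg.fc_threshold, de_tables=tables
    )
    summary.to_csv(run.dir / "transition_summary.tsv", sep="\t", index=False)
    artifacts.append("transition_summary.tsv")
    return artifacts


def _stage_biomarkers(run: _Run) -> list[str]:
    cfg = run.cfg
    counts = io.read_counts(run.dir / "counts.tsv")
    design = io.read_design(run.dir / "design.tsv")
    dispersions = de.estimate_dispersion(counts, design)
    artifacts = []
    for target in cfg.biomarker_targets:
        fc = cfg.biomarker_fc_o if target.endswith("O") else cfg.biomarker_fc_gc
        table = de.select_biomarkers(
            counts, design, target, fc_threshold=fc, fdr=cfg.biomarker_fdr, dispersions=dispersions
        )
        name = f"biomarkers_{target}.tsv"
        table.index.name = "gene"
        table.to_csv(run.dir / name, sep="\t", float_format="%.12g")
        artifacts.append(name)
    return artifacts


def _stage_fit(run: _Run) -> list[str]:
    rel = io.read_matrix(run.dir / "panel_rel.tsv")
    det = io.read_matrix(run.dir / "panel_det.tsv").astype(int)
    design = io.read_design(run.dir / "design.tsv")
    fit = hurdle.fit_hurdle(det, rel, design)
    io.save_hurdle_fit(fit, run.dir / "hurdle_fit.yaml")
    report = hurdle.stage_effect_correlations(fit)
    doc = {}
    for part, entry in report.items():
        doc[part] = {
            "overall": None if entry["overall"] is None else entry["overall"].round(6).to_dict(),
            "within": {c: m.round(6).to_dict() for c, m in entry["within"].items()},
        }
    (run.dir / "stage_correlations.yaml").write_text(yaml.safe_dump(doc, sort_keys=True))
    sig = hurdle.random_effect_significance(det, None, design, part="presence")
    sig.to_csv(run.dir / "presence_component_significance.tsv", sep="\t", index=False, float_format="%.6g")
    return ["hurdle_fit.yaml", "stage_correlations.yaml", "presence_component_significance.tsv"]


def _stage_predict(run: _Run) -> list[str]:
    cfg = run.cfg
    rel = io.read_matrix(run.dir / "panel_rel.tsv")
    det = io.read_matrix(run.dir / "panel_det.tsv").astype(int)
    design = io.read_design(run.dir / "design.tsv")
    fit = io.load_hurdle_fit(run.dir / "hurdle_fit.yaml")
    rng = np.random.default_rng(cfg.seed + 3)
    vectors = {
        (s, c): predict.resample_vectors(rel, det, design, s, c, n=cfg.resample_n, seed=rng)
        for c in COMPARTMENTS
        for s in STAGES
    }
    report = predict.evaluate_predictions(fit, vectors, variant=cfg.predictor_variant)
    report.posteriors.to_csv(run.dir / "posteriors.tsv", sep="\t", index=False, float_format="%.12g")
    report.mean_true_posterior.to_csv(run.dir / "mean_true_posterior.tsv", sep="\t", float_format="%.12g")
    conf = pd.concat(report.confusion, names=["compartment", "true_stage"])
    conf.to_csv(run.dir / "confusion.tsv", sep="\t")
    predict.plot_posterior_panels(report, str(run.dir / "posterior_panels.png"))
    return ["posteriors.tsv", "mean_true_posterior.tsv", "confusion.tsv", "posterior_panels.png"]
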