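"""Pipeline configuration: defaults, validation, normalization.

Default thresholds are the study's published gates: stage-regulated genes
at GLM FDR < 5% with pairwise p < 1% and fold change > 2; biomarkers at
FDR < 5% with fold change > 3 (granulosa targets) or > 10 (oocyte
targets); 100 resampled vectors per stage.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass

import yaml

from .core import InvalidArgument

__all__ = ["PipelineConfig", "validate_config", "config_hash"]

#: study reference genes; synthetic panels name their own references
DEFAULT_REFERENCE_GENES = ("ACTB", "TMED4", "RPL19")


@dataclass
class PipelineConfig:
    out_dir: str = "follisig_run"
    seed: int = 0

    # selection thresholds
    glm_fdr: float = 0.05
    pairwise_p: float = 0.01
    fc_threshold: float = 2.0
    biomarker_fdr: float = 0.05
    biomarker_fc_gc: float = 3.0
    biomarker_fc_o: float = 10.0

    # qPCR
    reference_genes: tuple = DEFAULT_REFERENCE_GENES
    detection_cutoff: float = 40.0
    control_margin: float = 3.0

    # count simulation
    n_genes: int = 300
    baseline_mean: float = 100.0
    dispersion: float = 0.2
    de_fraction: float = 0.05
    log2_effect: float = 2.0

    # biomarker panel
    panel_genes: int = 24
    panel_archetype: str = "separated"  # default | separated | pd_pm_confounded | correlated
    biomarker_targets: tuple = ("PDO", "SAG")

    # prediction
    resample_n: int = 100
    predictor_variant: str = "full"  # full | binary

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reference_genes"] = list(self.reference_genes)
        d["biomarker_targets"] = list(self.biomarker_targets)
        return d


_ARCHETYPES = ("default", "separated", "pd_pm_confounded", "correlated")


def validate_config(raw: dict | None) -> tuple["PipelineConfig", list[str]]:
    """Fill defaults and validate; returns (config, warnings).

    Unknown keys warn and are preserved in the run manifest; contradictory
    or out-of-range values raise a single aggregated error.
    """
    raw = dict(raw or {})
    warnings: list[str] = []
    known = set(PipelineConfig().to_dict())
    unknown = {k: raw.pop(k) for k in list(raw) if k not in known}
    for k in unknown:
        warnings.append(f"unknown config key preserved in manifest: {k!r}")
    cfg = PipelineConfig(**{**raw})
    errors: list[str] = []
    for name in ("glm_fdr", "pairwise_p", "biomarker_fdr"):
        v = getattr(cfg, name)
        if not 0 < v <= 1:
            errors.append(f"{name} must lie in (0, 1], got {v}")
    for name in ("fc_threshold", "biomarker_fc_gc", "biomarker_fc_o"):
        if getattr(cfg, name) <= 1:
            errors.append(f"{name} must exceed 1")
    for name in ("n_genes", "panel_genes"):
        if getattr(cfg, name) < 1:
            errors.append(f"{name} must be positive")
    if cfg.resample_n < 0:
        errors.append(f"resample_n must be >= 0, got {cfg.resample_n}")
    if cfg.seed < 0 or cfg.seed >= 2**31:
        errors.append("seed must lie in [0, 2^31)")
    if cfg.predictor_variant not in ("full", "binary"):
        errors.append(f"unknown predictor variant {cfg.predictor_variant!r}")
    if cfg.panel_archetype not in _ARCHETYPES:
        errors.append(f"panel_archetype must be one of {_ARCHETYPES}")
    if cfg.dispersion < 0 or not 0 <= cfg.de_fraction <= 1:
        errors.append("dispersion must be >= 0 and de_fraction in [0, 1]")
    if errors:
        raise InvalidArgument("invalid configuration:\n  - " + "\n  - ".join(errors))
    if cfg.pairwise_p >= cfg.glm_fdr:
        warnings.append("pairwise_p >= glm_fdr: allowed, but unusual for this design")
    cfg._unknown = unknown  # type: ignore[attr-defined]
    return cfg, warnings


def config_hash(cfg: PipelineConfig) -> str:
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
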